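"""Five-family tree-ensemble regression benchmark with PSO-tuned
hyperparameters.

The target is the dose-model IR label; predictors are the tabular patient
features (weight, height, BMI, age, breast thickness, total DLP — BMI can
be dropped, since it is derivable from its parents). Each family is tuned
by minimizing k-fold cross-validated MSE on the training split (default;
tuning on the held-out split is available for protocol comparison but is
test-set leakage and flagged as such), refit on the full training split,
and scored on the held-out split with MSE, MAE, MAPE and R².

Families: histogram-based gradient-boosted trees (LightGBM), classic
gradient boosting, extremely randomized trees, AdaBoost over depth-limited
trees, and random forest.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from lightgbm import LGBMRegressor
from sklearn.ensemble import (
    AdaBoostRegressor,
    ExtraTreesRegressor,
    GradientBoostingRegressor,
    RandomForestRegressor,
)
from sklearn.model_selection import KFold
from sklearn.tree import DecisionTreeRegressor

from .cohort import split_cohort
from .dose_model import LabelledCohort
from .pso import Dimension, PSOConfig, PSOTrace, SearchSpace, optimize

__all__ = [
    "FEATURE_COLUMNS",
    "MetricsReport",
    "ModelSpec",
    "FittedModel",
    "BenchRow",
    "BenchResult",
    "evaluate_metrics",
    "cohort_frame",
    "default_model_specs",
    "tune_and_fit",
    "run_benchmark",
]

log = logging.getLogger(__name__)

#: display names used across the benchmark and the explanation reports
FEATURE_COLUMNS = ("Weight", "Height", "BMI", "Age", "Bt", "TotalDLP")

MODEL_RANDOM_STATE = 42
MAPE_EPSILON = 1e-8


def cohort_frame(cohort: LabelledCohort, include_bmi: bool = True) -> tuple[pd.DataFrame, np.ndarray]:
    """Feature matrix and IR target vector for a labelled cohort."""
    rows = {
        "Weight": [p.weight for p in cohort.patients],
        "Height": [p.height for p in cohort.patients],
        "BMI": [p.bmi for p in cohort.patients],
        "Age": [p.age for p in cohort.patients],
        "Bt": [p.breast_thickness for p in cohort.patients],
        "TotalDLP": [p.total_dlp for p in cohort.patients],
    }
    X = pd.DataFrame(rows, columns=list(FEATURE_COLUMNS))
    if not include_bmi:
        X = X.drop(columns=["BMI"])
    return X, np.asarray(cohort.ir, dtype=float)


@dataclass(frozen=True)
class MetricsReport:
    """Held-out regression metrics; MAPE stored as a fraction."""

    mse: float
    mae: float
    mape: float
    r2: float

    def to_dict(self) -> dict:
        return {"mse": self.mse, "mae": self.mae, "mape": self.mape, "r2": self.r2}


def evaluate_metrics(y_true: Sequence[float], y_pred: Sequence[float]) -> MetricsReport:
    """MSE, MAE, MAPE (fraction) and R² of predictions against targets.

    Targets with |y| below a small epsilon are excluded from MAPE with a
    warning; if all are excluded MAPE is NaN. R² uses 1 − SSres/SStot with
    SStot about the mean of ``y_true``.
    """
    y = np.asarray(y_true, dtype=float)
    yh = np.asarray(y_pred, dtype=float)
    if y.shape != yh.shape or y.ndim != 1 or y.size < 2:
        raise ValueError(f"need equal-length 1-d arrays of size >= 2, got {y.shape}, {yh.shape}")
    err = y - yh
    mse = float(np.mean(err**2))
    mae = float(np.mean(np.abs(err)))
    ok = np.abs(y) > MAPE_EPSILON
    if not ok.all():
        warnings.warn(
            f"MAPE: excluding {int((~ok).sum())} target(s) with |y| <= {MAPE_EPSILON}",
            RuntimeWarning,
            stacklevel=2,
        )
    mape = float(np.mean(np.abs(err[ok]) / np.abs(y[ok]))) if ok.any() else float("nan")
    sstot = float(np.sum((y - y.mean()) ** 2))
    ssres = float(np.sum(err**2))
    r2 = 1.0 - ssres / sstot if sstot > 0 else float("nan")
    return MetricsReport(mse=mse, mae=mae, mape=mape, r2=r2)


@dataclass(frozen=True)
class ModelSpec:
    """A model family: name, estimator factory over tunable hyperparameters,
    and the PSO search space (which must contain every hyperparameter the
    factory consumes)."""

    name: str
    factory: Callable[[Mapping[str, float | int]], object]
    space: SearchSpace


def _lgbm(params: Mapping) -> LGBMRegressor:
    return LGBMRegressor(
        n_estimators=params["n_estimators"],
        max_depth=params["max_depth"],
        learning_rate=params["learning_rate"],
        random_state=MODEL_RANDOM_STATE,
        n_jobs=1,
        verbose=-1,
        min_child_samples=5,
    )


def _gb(params: Mapping) -> GradientBoostingRegressor:
    return GradientBoostingRegressor(
        n_estimators=params["n_estimators"],
        max_depth=params["max_depth"],
        learning_rate=params["learning_rate"],
        min_samples_split=params["min_samples_split"],
        random_state=MODEL_RANDOM_STATE,
    )


def _extra(params: Mapping) -> ExtraTreesRegressor:
    return ExtraTreesRegressor(
        n_estimators=params["n_estimators"],
        max_depth=params["max_depth"],
        min_samples_split=params["min_samples_split"],
        min_samples_leaf=params["min_samples_leaf"],
        random_state=MODEL_RANDOM_STATE,
        n_jobs=1,
    )


def _ada(params: Mapping) -> AdaBoostRegressor:
    return AdaBoostRegressor(
        estimator=DecisionTreeRegressor(
            max_depth=params["max_depth"], random_state=MODEL_RANDOM_STATE
        ),
        n_estimators=params["n_estimators"],
        learning_rate=params["learning_rate"],
        random_state=MODEL_RANDOM_STATE,
    )


def _rf(params: Mapping) -> RandomForestRegressor:
    return RandomForestRegressor(
        n_estimators=params["n_estimators"],
        max_depth=params["max_depth"],
        min_samples_split=params["min_samples_split"],
        random_state=MODEL_RANDOM_STATE,
        n_jobs=1,
    )


def default_model_specs() -> list[ModelSpec]:
    """The five benchmark families with their default search boxes.

    Ranges bracket the hyperparameter values such cohorts select in
    practice (tree counts 50-300, shallow-to-moderate depths, log-uniform
    learning rates); the sequential boosting families get tighter depth caps
    since depth beyond ~8 on a ~500-patient table only buys variance.
    """
    n_est = Dimension("n_estimators", 50, 300, integer=True)
    depth = Dimension("max_depth", 2, 14, integer=True)
    lr = Dimension("learning_rate", 0.01, 0.5, log_scale=True)
    mss = Dimension("min_samples_split", 2, 10, integer=True)
    msl = Dimension("min_samples_leaf", 1, 5, integer=True)
    return [
        ModelSpec("hist_gradient_boosting", _lgbm, SearchSpace((n_est, depth, lr))),
        ModelSpec(
            "gradient_boosting",
            _gb,
            SearchSpace((n_est, Dimension("max_depth", 2, 8, integer=True), lr, mss)),
        ),
        ModelSpec("extra_trees", _extra, SearchSpace((n_est, depth, mss, msl))),
        ModelSpec(
            "adaboost",
            _ada,
            SearchSpace(
                (
                    n_est,
                    Dimension("max_depth", 2, 10, integer=True),
                    Dimension("learning_rate", 0.01, 1.0, log_scale=True),
                )
            ),
        ),
        ModelSpec("random_forest", _rf, SearchSpace((n_est, depth, mss))),
    ]


@dataclass
class FittedModel:
    spec: ModelSpec
    model: object
    best_params: dict[str, float | int]
    best_score: float
    trace: PSOTrace
    n_objective_calls: int


def _cv_mse(factory, params, X: pd.DataFrame, y, folds: int, cv_seed: int) -> float:
    kf = KFold(n_splits=folds, shuffle=True, random_state=cv_seed)
    errs = []
    for tr, va in kf.split(X):
        model = factory(params)
        model.fit(X.iloc[tr], y[tr])
        pred = model.predict(X.iloc[va])
        errs.append(np.mean((y[va] - pred) ** 2))
    return float(np.mean(errs))


def tune_and_fit(
    spec: ModelSpec,
    train: LabelledCohort,
    pso_config: PSOConfig = PSOConfig(),
    seed: int = 0,
    cv_folds: int = 3,
    include_bmi: bool = True,
    holdout: LabelledCohort | None = None,
) -> FittedModel:
    """PSO-tune one family and refit on the full training split.

    The tuning objective is ``cv_folds``-fold CV MSE on ``train``. Passing
    ``holdout`` switches the objective to MSE on that split instead — the
    protocol some studies report, but it selects hyperparameters against the
    evaluation data and is methodologically unsound; use it only for
    comparison.
    """
    if len(train) < 2 * cv_folds:
        raise ValueError(f"training cohort of {len(train)} too small for {cv_folds}-fold CV")
    X, y = cohort_frame(train, include_bmi=include_bmi)
    if holdout is not None:
        Xh, yh = cohort_frame(holdout, include_bmi=include_bmi)
        log.warning("tuning %s against the held-out split (leaky protocol)", spec.name)

    n_calls = 0
    cache: dict[tuple, float] = {}

    def objective(params: Mapping[str, float | int]) -> float:
        nonlocal n_calls
        n_calls += 1
        key = tuple(sorted(params.items()))
        if key not in cache:
            if holdout is not None:
                model = spec.factory(params)
                model.fit(X, y)
                cache[key] = float(np.mean((yh - model.predict(Xh)) ** 2))
            else:
                cache[key] = _cv_mse(spec.factory, params, X, y, cv_folds, cv_seed=seed)
        return cache[key]

    best_params, best_score, trace = optimize(objective, spec.space, pso_config, seed=seed)
    model = spec.factory(best_params)
    model.fit(X, y)
    return FittedModel(
        spec=spec,
        model=model,
        best_params=best_params,
        best_score=best_score,
        trace=trace,
        n_objective_calls=n_calls,
    )


@dataclass
class BenchRow:
    name: str
    best_params: dict | None
    metrics: MetricsReport | None
    predictions: np.ndarray | None
    trace: PSOTrace | None
    failed: bool = False
    error: str | None = None

    def to_dict(self) -> dict:
        d = {"model": self.name, "failed": self.failed, "error": self.error,
             "best_params": self.best_params}
        if self.metrics is not None:
            d.update(self.metrics.to_dict())
        if self.predictions is not None:
            d["predictions"] = [float(v) for v in self.predictions]
        if self.trace is not None:
            d["trace"] = self.trace.to_dict()
        return d


@dataclass
class BenchResult:
    """One row per family; the fitted models are kept for explanation."""

    rows: list[BenchRow]
    models: dict[str, FittedModel]
    y_test: np.ndarray
    split_report: dict

    @property
    def any_failed(self) -> bool:
        return any(r.failed for r in self.rows)

    def table(self) -> pd.DataFrame:
        recs = []
        for r in self.rows:
            m = r.metrics
            recs.append(
                {
                    "model": r.name,
                    "mse": m.mse if m else np.nan,
                    "mae": m.mae if m else np.nan,
                    "mape": m.mape if m else np.nan,
                    "r2": m.r2 if m else np.nan,
                    "hyperparameters": json.dumps(r.best_params) if r.best_params else "",
                }
            )
        return pd.DataFrame(recs)

    def to_dict(self) -> dict:
        return {
            "rows": [r.to_dict() for r in self.rows],
            "y_test": [float(v) for v in self.y_test],
            "split_report": self.split_report,
        }


def run_benchmark(
    cohort: LabelledCohort,
    specs: Sequence[ModelSpec] | None = None,
    split_seed: int = 42,
    train_fraction: float = 0.8,
    pso_config: PSOConfig = PSOConfig(),
    seed: int = 0,
    cv_folds: int = 3,
    include_bmi: bool = True,
    leaky: bool = False,
) -> BenchResult:
    """Split, tune, fit and score every family; one row per model.

    A family that fails to fit is marked failed and the run continues; the
    caller should treat ``result.any_failed`` as a non-zero exit condition.
    """
    specs = list(default_model_specs() if specs is None else specs)
    train, test, report = split_cohort(cohort, train_fraction, seed=split_seed)
    X_test, y_test = cohort_frame(test, include_bmi=include_bmi)

    rows: list[BenchRow] = []
    models: dict[str, FittedModel] = {}
    for i, spec in enumerate(specs):
        try:
            fitted = tune_and_fit(
                spec,
                train,
                pso_config=pso_config,
                seed=seed + i,
                cv_folds=cv_folds,
                include_bmi=include_bmi,
                holdout=test if leaky else None,
            )
            pred = np.asarray(fitted.model.predict(X_test), dtype=float)
            rows.append(
                BenchRow(
                    name=spec.name,
                    best_params=dict(fitted.best_params),
                    metrics=evaluate_metrics(y_test, pred),
                    predictions=pred,
                    trace=fitted.trace,
                )
            )
            models[spec.name] = fitted
        except Exception as exc:  # keep the benchmark going, flag the row
            log.exception("model %s failed", spec.name)
            rows.append(BenchRow(name=spec.name, best_params=None, metrics=None,
                                 predictions=None, trace=None, failed=True,
                                 error=str(exc)))
    return BenchResult(rows=rows, models=models, y_test=y_test,
                       split_report=report.to_dict())
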