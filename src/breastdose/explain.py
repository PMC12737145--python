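"""Local surrogate explanations for single dose predictions.

For one patient, the black-box regressor is probed with standard-normal
perturbations in standardized feature space, each perturbation weighted by
an RBF kernel on its distance to the patient, and a ridge-regularized
weighted linear model is fitted on binarized bin-membership features
(1 when the perturbed value falls in the same training quartile bin as the
patient's value). The surrogate's coefficients are the signed per-feature
contributions, in prediction units (mGy), and each feature is reported with
the quartile condition it satisfies on the standardized scale (e.g.
``Weight > 0.49``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = ["TrainingStats", "FeatureContribution", "Explanation",
           "discretize_feature", "explain_instance"]

log = logging.getLogger(__name__)


class DegenerateFeatureError(ValueError):
    """A feature has zero spread in the training data."""


@dataclass(frozen=True)
class FeatureStats:
    """Mean/sd and raw-scale quartiles of one training feature."""

    mean: float
    sd: float
    q1: float
    q2: float
    q3: float

    def __post_init__(self) -> None:
        if not self.sd > 0:
            raise DegenerateFeatureError(f"zero training sd (mean {self.mean})")

    def z(self, x: float | np.ndarray):
        return (x - self.mean) / self.sd

    @property
    def z_quartiles(self) -> tuple[float, float, float]:
        return (self.z(self.q1), self.z(self.q2), self.z(self.q3))


@dataclass(frozen=True)
class TrainingStats:
    """Per-feature standardization and quartile statistics, in a fixed
    feature order."""

    features: tuple[str, ...]
    stats: dict[str, FeatureStats]

    @classmethod
    def from_frame(cls, X: pd.DataFrame) -> "TrainingStats":
        stats = {}
        for col in X.columns:
            v = X[col].to_numpy(dtype=float)
            sd = float(v.std(ddof=0))
            if sd <= 0:
                raise DegenerateFeatureError(f"feature {col!r} has zero training sd")
            q1, q2, q3 = (float(q) for q in np.quantile(v, [0.25, 0.5, 0.75]))
            stats[col] = FeatureStats(mean=float(v.mean()), sd=sd, q1=q1, q2=q2, q3=q3)
        return cls(features=tuple(X.columns), stats=stats)


def discretize_feature(value: float, stats: FeatureStats, name: str = "x") -> tuple[str, int]:
    """Quartile bin (1-4) of a raw value and its condition string on the
    standardized scale.

    Bin edges are the training quartiles; extreme bins render one-sided
    (``x <= zq1`` / ``x > zq3``), middle bins two-sided. Values exactly on a
    quartile close the lower interval (the median belongs to bin 2).
    """
    zq1, zq2, zq3 = stats.z_quartiles
    z = stats.z(value)
    if z <= zq1:
        return f"{name} <= {zq1:.2f}", 1
    if z <= zq2:
        return f"{zq1:.2f} < {name} <= {zq2:.2f}", 2
    if z <= zq3:
        return f"{zq2:.2f} < {name} <= {zq3:.2f}", 3
    return f"{name} > {zq3:.2f}", 4


def _bin_index(z: np.ndarray, zq: tuple[float, float, float]) -> np.ndarray:
    # vectorized 1-4 binning on the standardized scale
    return 1 + (z > zq[0]).astype(int) + (z > zq[1]).astype(int) + (z > zq[2]).astype(int)


@dataclass(frozen=True)
class FeatureContribution:
    feature: str
    condition: str
    value: float
    contribution: float

    def to_dict(self) -> dict:
        return {"feature": self.feature, "condition": self.condition,
                "value": self.value, "contribution": self.contribution}


@dataclass(frozen=True)
class Explanation:
    """Top-k signed feature contributions to one prediction.

    Additivity: intercept + sum of contributions equals ``local_prediction``
    (the surrogate's value at the instance) exactly; ``model_prediction`` is
    the black-box value the surrogate approximates.
    """

    instance_id: str
    contributions: tuple[FeatureContribution, ...]
    intercept: float
    local_prediction: float
    model_prediction: float

    def to_dict(self) -> dict:
        return {
            "instance_id": self.instance_id,
            "contributions": [c.to_dict() for c in self.contributions],
            "intercept": self.intercept,
            "local_prediction": self.local_prediction,
            "model_prediction": self.model_prediction,
        }


def _weighted_ridge(B: np.ndarray, y: np.ndarray, w: np.ndarray, alpha: float
                    ) -> tuple[np.ndarray, float]:
    """Closed-form weighted ridge with unpenalized intercept; bumps the
    penalty and retries if the normal equations are singular."""
    n, d = B.shape
    A = np.column_stack([np.ones(n), B])
    W = w[:, None]
    for attempt in range(6):
        pen = alpha * 10**attempt
        lhs = A.T @ (W * A)
        lhs[1:, 1:] += pen * np.eye(d)
        rhs = A.T @ (w * y)
        try:
            beta = np.linalg.solve(lhs, rhs)
            return beta[1:], float(beta[0])
        except np.linalg.LinAlgError:
            log.warning("singular surrogate design; raising ridge penalty to %g",
                        alpha * 10 ** (attempt + 1))
    raise np.linalg.LinAlgError("surrogate design remained singular")


def explain_instance(
    predict_fn: Callable[[np.ndarray], np.ndarray],
    instance: Sequence[float],
    training_stats: TrainingStats,
    instance_id: str = "",
    n_samples: int = 5000,
    kernel_width: float | None = None,
    ridge: float = 1e-3,
    top_k: int = 5,
    seed: int = 0,
) -> Explanation:
    """Explain one prediction of ``predict_fn``.

    ``instance`` is the raw feature vector in ``training_stats.features``
    order; ``predict_fn`` maps a raw (n, d) array to n predictions.
    ``kernel_width`` defaults to 0.75·sqrt(d). Deterministic under ``seed``.
    """
    feats = training_stats.features
    d = len(feats)
    x = np.asarray(instance, dtype=float)
    if x.shape != (d,):
        raise ValueError(f"instance must have {d} features, got shape {x.shape}")
    if n_samples < 100:
        raise ValueError(f"n_samples must be >= 100, got {n_samples}")
    if kernel_width is None:
        kernel_width = 0.75 * np.sqrt(d)

    means = np.array([training_stats.stats[f].mean for f in feats])
    sds = np.array([training_stats.stats[f].sd for f in feats])
    zqs = [training_stats.stats[f].z_quartiles for f in feats]

    rng = np.random.default_rng(seed)
    Z = rng.standard_normal((n_samples, d))
    raw = Z * sds + means
    y = np.asarray(predict_fn(raw), dtype=float)

    z_inst = (x - means) / sds
    dist = np.linalg.norm(Z - z_inst, axis=1)
    w = np.exp(-(dist**2) / kernel_width**2)

    inst_bins = np.array([_bin_index(np.array([z_inst[j]]), zqs[j])[0] for j in range(d)])
    B = np.column_stack(
        [(_bin_index(Z[:, j], zqs[j]) == inst_bins[j]).astype(float) for j in range(d)]
    )

    # stage 1: rank features by |coefficient| on the full binarized design
    coef_all, _ = _weighted_ridge(B, y, w, ridge)
    order = np.argsort(-np.abs(coef_all))[: min(top_k, d)]
    # stage 2: refit on the selected features so additivity holds exactly
    coef, intercept = _weighted_ridge(B[:, order], y, w, ridge)

    # at the instance every bin-membership indicator is 1
    local_pred = intercept + float(coef.sum())
    model_pred = float(np.asarray(predict_fn(x[None, :]), dtype=float)[0])

    contributions = []
    for j, c in sorted(zip(order, coef), key=lambda t: -abs(t[1])):
        fname = feats[j]
        cond, _ = discretize_feature(x[j], training_stats.stats[fname], name=fname)
        contributions.append(
            FeatureContribution(feature=fname, condition=cond, value=float(x[j]),
                                contribution=float(c))
        )
    return Explanation(
        instance_id=instance_id,
        contributions=tuple(contributions),
        intercept=intercept,
        local_prediction=local_pred,
        model_prediction=model_pred,
    )
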