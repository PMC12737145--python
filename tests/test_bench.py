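"""Regression metrics and the PSO-tuned benchmark contract.

Model-fitting tests run on a 120-patient cohort with a deliberately tiny
PSO budget: they check the bookkeeping and reproducibility contracts, not
headline accuracy (that lives in the acceptance suite).
"""

import numpy as np
import pytest

from breastdose.bench import (
    cohort_frame,
    default_model_specs,
    evaluate_metrics,
    run_benchmark,
    tune_and_fit,
)
from breastdose.pso import Dimension, PSOConfig, SearchSpace


class TestMetrics:
    def test_hand_computed_example(self):
        m = evaluate_metrics([10, 20, 30], [12, 18, 33])
        assert m.mse == pytest.approx(17 / 3)
        assert m.mae == pytest.approx(7 / 3)
        assert m.mape == pytest.approx(0.4 / 3)
        assert m.r2 == pytest.approx(1 - 17 / 200)

    def test_perfect_and_null_predictors(self):
        y = np.array([3.0, 7.0, 11.0, 5.0])
        perfect = evaluate_metrics(y, y)
        assert (perfect.mse, perfect.mae, perfect.mape) == (0, 0, 0)
        assert perfect.r2 == 1.0
        null = evaluate_metrics(y, np.full_like(y, y.mean()))
        assert null.r2 == pytest.approx(0.0)

    def test_jensen_inequality(self):
        rng = np.random.default_rng(0)
        y = rng.uniform(1, 50, 100)
        pred = y + rng.normal(0, 3, 100)
        m = evaluate_metrics(y, pred)
        assert m.mae**2 <= m.mse + 1e-12

    def test_near_zero_targets_warn_and_exclude(self):
        with pytest.warns(RuntimeWarning, match="MAPE"):
            m = evaluate_metrics([0.0, 10.0, 20.0], [1.0, 11.0, 19.0])
        # MAPE over the two valid targets only
        assert m.mape == pytest.approx((0.1 + 0.05) / 2)
        assert np.isfinite(m.mse) and np.isfinite(m.mae)

    def test_shape_validation(self):
        with pytest.raises(ValueError):
            evaluate_metrics([1.0], [1.0])
        with pytest.raises(ValueError):
            evaluate_metrics([1.0, 2.0], [1.0, 2.0, 3.0])


class TestTuneAndFit:
    def test_objective_call_count(self, small_labelled, tiny_pso):
        spec = default_model_specs()[0]
        fitted = tune_and_fit(spec, small_labelled, pso_config=tiny_pso, seed=0, cv_folds=3)
        # initial swarm evaluation plus one evaluation per particle-iteration
        assert fitted.n_objective_calls == 3 + 3 * 2

    def test_degenerate_space_forced_outcome(self, small_labelled, tiny_pso):
        spec = default_model_specs()[0]
        forced = type(spec)(
            name=spec.name,
            factory=spec.factory,
            space=SearchSpace(
                (
                    Dimension("n_estimators", 60, 60, integer=True),
                    Dimension("max_depth", 3, 3, integer=True),
                    Dimension("learning_rate", 0.1, 0.1 + 1e-12, log_scale=True),
                )
            ),
        )
        fitted = tune_and_fit(forced, small_labelled, pso_config=tiny_pso, seed=1, cv_folds=3)
        assert fitted.best_params["n_estimators"] == 60
        assert fitted.best_params["max_depth"] == 3
        assert fitted.best_params["learning_rate"] == pytest.approx(0.1)

    def test_tuned_beats_defaults_under_same_folds(self, small_labelled):
        """Tuned CV MSE is never worse than the family default config's."""
        from breastdose.bench import _cv_mse

        spec = default_model_specs()[0]
        fitted = tune_and_fit(
            spec, small_labelled, pso_config=PSOConfig(6, 6), seed=2, cv_folds=3
        )
        X, y = cohort_frame(small_labelled)
        default_cfg = {"n_estimators": 100, "max_depth": 6, "learning_rate": 0.1}
        default_mse = _cv_mse(spec.factory, default_cfg, X, y, folds=3, cv_seed=2)
        assert fitted.best_score <= default_mse + 1e-12

    def test_too_small_cohort_rejected(self, small_labelled, tiny_pso):
        from breastdose.dose_model import LabelledCohort

        tiny = LabelledCohort(
            patients=small_labelled.patients[:6],
            ir=small_labelled.ir[:6],
            params=small_labelled.params,
        )
        with pytest.raises(ValueError, match="too small"):
            tune_and_fit(default_model_specs()[0], tiny, pso_config=tiny_pso, cv_folds=5)


class TestRunBenchmark:
    def test_one_row_per_model(self, result):
        assert [r.name for r in result.rows] == ["hist_gradient_boosting", "random_forest"]
        assert not result.any_failed

    def test_metrics_recomputable_from_predictions(self, result):
        for row in result.rows:
            m = evaluate_metrics(result.y_test, row.predictions)
            assert m == row.metrics

    def test_jensen_on_every_row(self, result):
        for row in result.rows:
            assert row.metrics.mae**2 <= row.metrics.mse + 1e-12

    def test_determinism(self, small_labelled, tiny_pso, result):
        specs = [s for s in default_model_specs() if s.name in
                 ("hist_gradient_boosting", "random_forest")]
        again = run_benchmark(small_labelled, specs=specs, pso_config=tiny_pso,
                              seed=5, cv_folds=3)
        for a, b in zip(result.rows, again.rows):
            assert a.best_params == b.best_params
            assert a.metrics == b.metrics
            assert np.array_equal(a.predictions, b.predictions)

    def test_failing_model_marks_row_and_continues(self, small_labelled, tiny_pso):
        from breastdose.bench import ModelSpec

        def broken(params):
            raise RuntimeError("cannot build model")

        specs = [
            ModelSpec("broken", broken, default_model_specs()[0].space),
            default_model_specs()[-1],
        ]
        res = run_benchmark(small_labelled, specs=specs, pso_config=tiny_pso,
                            seed=1, cv_folds=3)
        assert res.rows[0].failed and not res.rows[1].failed
        assert res.any_failed

    def test_table_layout(self, result):
        df = result.table()
        assert list(df.columns) == ["model", "mse", "mae", "mape", "r2", "hyperparameters"]
        assert len(df) == 2


def test_noise_degrades_fit(small_cohort):
    """Heavy label noise must lower R² relative to the noiseless cohort."""
    from breastdose.dose_model import (
        DoseModelParams, calibrate_k, label_cohort, normalization_stats_from_cohort,
    )

    stats = normalization_stats_from_cohort(small_cohort)
    params = DoseModelParams(k=calibrate_k(small_cohort, stats), stats=stats)
    clean = label_cohort(small_cohort, params)
    noisy = label_cohort(small_cohort, params, noise_sd=10.0,
                         rng=np.random.default_rng(0))
    spec = [default_model_specs()[0]]
    cfg = PSOConfig(4, 3)
    r_clean = run_benchmark(clean, specs=spec, pso_config=cfg, seed=3, cv_folds=3)
    r_noisy = run_benchmark(noisy, specs=spec, pso_config=cfg, seed=3, cv_folds=3)
    assert r_noisy.rows[0].metrics.r2 < r_clean.rows[0].metrics.r2
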