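import numpy as np
import pytest

from breastdose.cohort import GeneratorConfig, generate_cohort
from breastdose.dose_model import (
    DoseModelParams,
    FeatureRange,
    NormalizationStats,
    PatientRecord,
    calibrate_k,
    label_cohort,
    normalization_stats_from_cohort,
)


@pytest.fixture
def stats():
    """Reference ranges wide enough to hold every hand-built patient."""
    return NormalizationStats(
        bmi=FeatureRange(15.0, 45.0),
        bt=FeatureRange(25.0, 80.0),
        age=FeatureRange(33.0, 88.0),
    )


@pytest.fixture
def params(stats):
    return DoseModelParams(k=0.05, stats=stats)


@pytest.fixture
def patient():
    return PatientRecord(
        patient_id="P0", weight=73.1, height=1.59, age=58.6,
        breast_thickness=50.0, total_dlp=250.0,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """120 synthetic patients: big enough to split and fit, small enough
    to keep model-fitting tests fast."""
    return generate_cohort(GeneratorConfig(n=120, seed=7))


@pytest.fixture(scope="session")
def tiny_pso():
    """Deliberately small swarm for contract (not accuracy) tests."""
    from breastdose.pso import PSOConfig

    return PSOConfig(n_particles=3, n_iterations=2)


@pytest.fixture(scope="session")
def result(small_labelled, tiny_pso):
    """Two-family benchmark on the small cohort, shared across modules."""
    from breastdose.bench import default_model_specs, run_benchmark

    specs = [s for s in default_model_specs() if s.name in
             ("hist_gradient_boosting", "random_forest")]
    return run_benchmark(small_labelled, specs=specs, pso_config=tiny_pso,
                         seed=5, cv_folds=3)


@pytest.fixture(scope="session")
def small_labelled(small_cohort):
    stats = normalization_stats_from_cohort(small_cohort)
    k = calibrate_k(small_cohort, stats)
    params = DoseModelParams(k=k, stats=stats)
    return label_cohort(small_cohort, params)
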