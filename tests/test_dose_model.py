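"""Dose-model arithmetic: BMI, normalization, BODY factor, IR and k."""

import json
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from breastdose.dose_model import (
    CalibrationError,
    DegenerateRangeError,
    DoseModelParams,
    FeatureRange,
    InvalidPatientError,
    NormalizationStats,
    PatientRecord,
    body_factor,
    calibrate_k,
    compute_bmi,
    internal_radiation,
    label_cohort,
    minmax_normalize,
    normalization_stats_from_cohort,
)


@pytest.mark.parametrize(
    "weight,height,expected",
    [
        (73.1, 1.59, 73.1 / 1.59**2),   # cohort-mean anthropometrics
        (46.0, 1.77, 46.0 / 1.77**2),   # lightest/tallest extreme
        (5.0, 1.0, 5.0),                # unit height is the identity
    ],
)
def test_bmi_formula(weight, height, expected):
    assert compute_bmi(weight, height) == pytest.approx(expected, rel=1e-12)


@pytest.mark.parametrize("weight,height", [(0, 1.6), (-3, 1.6), (70, 0), (70, -1)])
def test_bmi_rejects_nonpositive(weight, height):
    with pytest.raises(InvalidPatientError):
        compute_bmi(weight, height)


class TestMinmaxNormalize:
    @pytest.mark.parametrize(
        "x,lo,hi,expected",
        [(2.0, 2.0, 8.0, 0.0), (8.0, 2.0, 8.0, 1.0), (5.0, 2.0, 8.0, 0.5),
         (-10.0, 2.0, 8.0, 0.0), (100.0, 2.0, 8.0, 1.0)],
    )
    def test_values_and_clamping(self, x, lo, hi, expected):
        assert minmax_normalize(x, lo, hi) == expected

    def test_degenerate_range_raises(self):
        with pytest.raises(DegenerateRangeError):
            minmax_normalize(1.0, 5.0, 5.0)
        with pytest.raises(DegenerateRangeError):
            FeatureRange(5.0, 4.0)

    @given(st.floats(-1e6, 1e6), st.floats(-100, 100), st.floats(0.1, 100))
    def test_always_in_unit_interval(self, x, lo, span):
        assert 0.0 <= minmax_normalize(x, lo, lo + span) <= 1.0


class TestBodyFactor:
    def test_convex_combination_bounds(self, params):
        assert body_factor(1, 1, 1, params) == pytest.approx(1.0)
        assert body_factor(0, 0, 0, params) == 0.0
        # BMI weight alone is 40%
        assert body_factor(1, 0, 0, params) == pytest.approx(0.40)

    def test_weights_must_sum_to_one(self, stats):
        with pytest.raises(ValueError):
            DoseModelParams(k=1.0, stats=stats, w_bmi=0.5, w_bt=0.3, w_age=0.3)

    def test_product_form(self, stats):
        p = DoseModelParams(k=1.0, stats=stats, product_form=True)
        assert body_factor(0.5, 0.5, 0.5, p) == pytest.approx(0.125)
        assert body_factor(0.0, 1.0, 1.0, p) == 0.0

    @given(st.floats(0, 1), st.floats(0, 1), st.floats(0, 1))
    def test_bounded_by_input_extremes(self, f1, f2, f3):
        stats = NormalizationStats(
            bmi=FeatureRange(0, 1), bt=FeatureRange(0, 1), age=FeatureRange(0, 1)
        )
        p = DoseModelParams(k=1.0, stats=stats)
        b = body_factor(f1, f2, f3, p)
        assert min(f1, f2, f3) - 1e-12 <= b <= max(f1, f2, f3) + 1e-12


class TestInternalRadiation:
    def test_identity_scaling(self, stats):
        p = DoseModelParams(k=1.0, stats=stats)
        # patient at all three maxima -> all factors 1 -> IR = DLP
        pat = PatientRecord("x", weight=45 * 1.0**2, height=1.0, age=88,
                            breast_thickness=80, total_dlp=100.0)
        assert internal_radiation(pat, p) == pytest.approx(100.0)

    def test_zero_at_all_minima(self, stats):
        p = DoseModelParams(k=1.0, stats=stats)
        pat = PatientRecord("x", weight=15.0, height=1.0, age=33,
                            breast_thickness=25, total_dlp=500.0)
        assert internal_radiation(pat, p) == 0.0

    def test_linear_in_dlp(self, params, patient):
        ir1 = internal_radiation(patient, params)
        doubled = PatientRecord("y", patient.weight, patient.height, patient.age,
                                patient.breast_thickness, 2 * patient.total_dlp)
        assert internal_radiation(doubled, params) == pytest.approx(2 * ir1, rel=1e-12)

    @settings(max_examples=50, deadline=None)
    @given(
        st.floats(46, 133), st.floats(1.47, 1.77), st.floats(33, 88),
        st.floats(25, 80), st.floats(68.81, 914.5), st.floats(1, 50),
    )
    def test_monotone_in_each_factor(self, w, h, a, bt, dlp, bump):
        """IR never decreases when BMI, BT or age increases at fixed DLP."""
        stats = NormalizationStats(
            bmi=FeatureRange(10, 70), bt=FeatureRange(25, 80), age=FeatureRange(33, 88)
        )
        p = DoseModelParams(k=0.1, stats=stats)
        base = PatientRecord("b", w, h, a, bt, dlp)
        ir0 = internal_radiation(base, p)
        heavier = PatientRecord("h", w + bump, h, a, bt, dlp)
        older = PatientRecord("o", w, h, a + bump, bt, dlp)
        thicker = PatientRecord("t", w, h, a, bt + bump, dlp)
        for variant in (heavier, older, thicker):
            assert internal_radiation(variant, p) >= ir0 - 1e-12


class TestCalibrateK:
    def test_closed_form_single_patient(self, stats):
        # DLP·BODY = 100 exactly: all factors at max, DLP 100, k-free product
        pat = PatientRecord("x", weight=45.0, height=1.0, age=88,
                            breast_thickness=80, total_dlp=100.0)
        k = calibrate_k([pat], stats, target_mean=9.76)
        assert k == pytest.approx(0.0976, rel=1e-12)

    def test_fixed_point_and_mean_invariant(self, small_cohort):
        stats = normalization_stats_from_cohort(small_cohort)
        k = calibrate_k(small_cohort, stats, target_mean=9.76)
        params = DoseModelParams(k=k, stats=stats)
        labelled = label_cohort(small_cohort, params)
        assert np.mean(labelled.ir) == pytest.approx(9.76, rel=1e-9)
        # current mean as target is a fixed point of calibration
        k2 = calibrate_k(small_cohort, stats, target_mean=float(np.mean(labelled.ir)) / k)
        assert k2 == pytest.approx(1.0, rel=1e-9)

    def test_dlp_homogeneity(self, small_cohort):
        stats = normalization_stats_from_cohort(small_cohort)
        k1 = calibrate_k(small_cohort, stats, target_mean=9.76)
        scaled = [
            PatientRecord(p.patient_id, p.weight, p.height, p.age,
                          p.breast_thickness, 3.0 * p.total_dlp)
            for p in small_cohort
        ]
        k3 = calibrate_k(scaled, stats, target_mean=9.76)
        assert k3 == pytest.approx(k1 / 3.0, rel=1e-12)

    def test_impossible_calibration(self, stats):
        # single patient at all three minima: DLP·BODY = 0
        pat = PatientRecord("x", weight=15.0, height=1.0, age=33,
                            breast_thickness=25, total_dlp=100.0)
        with pytest.raises(CalibrationError):
            calibrate_k([pat], stats, target_mean=9.76)


class TestLabelCohort:
    def test_empty_cohort(self, params):
        labelled = label_cohort([], params)
        assert len(labelled) == 0

    def test_max_patient_gets_full_dlp(self, stats):
        p = DoseModelParams(k=1.0, stats=stats)
        pat = PatientRecord("x", weight=45.0, height=1.0, age=88,
                            breast_thickness=80, total_dlp=914.5)
        labelled = label_cohort([pat], p)
        assert labelled.ir[0] == pytest.approx(914.5)

    def test_relabelling_idempotent(self, small_labelled):
        again = label_cohort(small_labelled.patients, small_labelled.params)
        assert again.ir == small_labelled.ir

    def test_ir_nonnegative_and_zero_iff_zero_product(self, small_labelled):
        assert all(v >= 0 for v in small_labelled.ir)
        assert all(v > 0 for v in small_labelled.ir)  # no patient at all minima here


def test_params_json_round_trip(params):
    restored = DoseModelParams.from_json(params.to_json())
    assert restored == params
    # bit-exact: serialized form is stable
    assert json.loads(restored.to_json()) == json.loads(params.to_json())
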