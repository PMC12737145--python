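# Methods

## The dose model

Scanner consoles report the dose-length product (DLP, mGy·cm) of a chest-CT
acquisition, but DLP is an exposure index, not the dose absorbed by any
organ. For the breast — a radiosensitive organ lying inside the thoracic
scan range — `breastdose` models the absorbed dose (IR, mGy) as DLP scaled
by a patient-specific body-size correction:

    IR = k · DLP · BODY
    BODY = 0.40·F1 + 0.30·F2 + 0.30·F3

where F1, F2, F3 are min-max-normalized BMI, mammographic breast thickness
(BT, mm) and age (years), each clamped to [0, 1] against reference-cohort
minima and maxima, and k is an empirical scale. The weights (0.40/0.30/0.30)
encode the assumption that overall body habitus dominates breast absorption,
with breast thickness and age contributing equally and less; they must sum
to 1, making BODY a convex combination bounded in [0, 1].

A literal three-factor product `IR = k·DLP·F1·F2·F3` is also implemented
(`product_form=True`). It is not the default: any patient sitting at a
single cohort minimum would receive exactly zero dose, which is not
physical — scattered dose to the breast never vanishes for a scanned
patient. The weighted sum degrades gracefully instead (IR = 0 only for the
patient at all three minima simultaneously).

Two modelling caveats are worth stating plainly. First, the model makes IR
*increase* with normalized BMI, whereas photon attenuation arguments would
make dose to deep tissue *decrease* with habitus at fixed tube output; in
practice automatic exposure control raises DLP with body size, and the model
leans on that coupling. We implement the model as defined and flag this as a
question about the model, not about the code. Second, "breast thickness" is
the compressed-breast thickness measured at mammography, used here as a
standing proxy for breast tissue quantity/density.

### Calibration of k

k is never meaningful in isolation (it absorbs the cm⁻¹ scale of DLP and
the dimensionless BODY term), so it is obtained by mean calibration: given
a reference cohort and a target mean breast dose (default 9.76 mGy, a
plausible per-exam chest-CT breast dose),

    k = target_mean / mean_i(DLP_i · BODY_i).

This makes the labelled cohort's mean IR equal the target to 1e-9 relative
tolerance by construction (verified in the tests). Normalization minima and
maxima are computed over the *full* labelling cohort, before any train/test
split — labels are defined cohort-wide, and the stats are persisted with the
model parameters so any patient can be relabelled bit-identically.
Degenerate ranges (min = max) raise an error rather than silently returning
a midpoint: a cohort with zero spread in a factor is broken input.

## The synthetic cohort generator

No patient-level data ship with the package; the generator emulates a
single-scanner female screening cohort of 653 patients:

| feature | marginal | default |
|---|---|---|
| weight (kg) | truncated normal | mean 73.1, sd 15, bounds [46, 133] |
| height (m) | truncated normal | mean 1.59, sd 0.06, bounds [1.47, 1.77] |
| age (y) | truncated normal | mean 58.6, sd 12, bounds [33, 88] |
| breast thickness (mm) | truncated normal | mean 50, sd 12, bounds [25, 80] |
| DLP (mGy·cm) | truncated lognormal | log-mean log(230), log-sd 0.55, bounds [68.81, 914.5] |

Means and bounds for weight, height and age, and the DLP bounds, are the
published cohort summaries this pipeline reproduces; the unreported
standard deviations are set so the stated extremes sit 2–4 sd from the
mean, which is where observed extremes of a ~650-patient sample plausibly
live. Breast thickness has no published summary; 50 ± 12 mm brackets the
39–57 mm instance values visible in the published per-patient explanation
examples. DLP is right-skewed (lognormal) because a single protocol with
automatic exposure control produces a long upper tail, and the resulting
labelled doses span ≈1–50 mGy with mean 9.76 — matching the published dose
summary (1.08–52.7, mean 9.76).

Dependence is a Gaussian copula over (weight, height, age, BT, DLP) with
Spearman targets weight–height 0.3, weight–BT 0.4 and weight–DLP 0.5 (the
last emulating exposure control raising tube output with body size); rank
targets are mapped to latent Pearson correlations by r = 2·sin(πρ/6), and
the monotone marginal transforms preserve them. The hospital cohort's true
joint distribution is unknown: these correlations are assumptions, they are
configurable, and nothing downstream depends on their exact values.

Label noise defaults to 0 — IR is by definition a deterministic function of
the features — so the regression benchmark measures pure function
approximation. A positive `label_noise_sd` adds Gaussian mGy noise to mimic
measurement-style irreducible error.

**What passing tests on this cohort do not show:** real anthropometrics are
not truncated-normal, real DLP depends on protocol details we do not model
(pitch, kV, rotation time), and real label noise is not zero. Results here
demonstrate that the pipeline recovers a known data-generating process, not
that the dose model is clinically accurate.

## PSO hyperparameter tuning

The tuner is a classic inertia-weight particle swarm over mixed
integer/continuous boxes: velocities update as
`v ← 0.7·v + 1.5·r1·(p_best−x) + 1.5·r2·(g_best−x)`, positions are clamped
to bounds, velocities to ±0.5·range, integer dimensions are rounded at
evaluation time, and log-scale dimensions (learning rates) are searched in
log space. Defaults are 10 particles × 20 iterations — a 210-evaluation
budget under which the swarm converges within roughly 10 iterations on
these search boxes. Coefficients 0.7/1.5/1.5 are standard mid-range PSO
settings; all are configurable. Non-finite objective values are treated as
+∞ with a logged warning. The full per-iteration p_best/g_best trace is
retained; g_best is non-increasing by construction and the tests assert it.

The tuning objective is 3-fold cross-validated MSE **on the training split
only**. Tuning against the held-out split (selecting hyperparameters by
test error) is supported behind `--paper-leaky` purely so the effect of
that protocol can be quantified; it is test-set leakage and the default
never does it. Three folds (rather than five or more) keep the full
five-family benchmark tractable on one CPU at n ≈ 520 while leaving each
validation fold ~170 patients, plenty for ranking hyperparameter
configurations on a smooth noiseless target.

## The benchmark

Five tree-ensemble families, all with `random_state = 42`:
histogram-based gradient-boosted trees (LightGBM), classic gradient
boosting, extremely randomized trees, AdaBoost over depth-limited trees,
and random forest. Search boxes: tree count [50, 300] everywhere; depth
[2, 14] for LightGBM, extra trees and random forest, capped at 8 for
gradient boosting and 10 for AdaBoost's base tree (exact-splitter boosting
beyond those depths on a ~500-row table mostly buys variance and runtime);
learning rates log-uniform in [0.01, 0.5] (boosting) or [0.01, 1.0]
(AdaBoost); min_samples_split [2, 10] and min_samples_leaf [1, 5] where the
family exposes them.

Features handed to the regressors: Weight, Height, BMI, Age, Bt, TotalDLP.
BMI is included by default even though it is derivable from weight and
height (`include_bmi=False` drops it; both configurations run end to end).
Held-out metrics are MSE, MAE, MAPE (stored as a fraction, rendered as
percent in reports) and R² = 1 − SSres/SStot. Targets below 1e-8 mGy are
excluded from MAPE with a warning. The metrics are recomputable from the
stored predictions, and MAE² ≤ MSE (Jensen) is asserted on every row.

## Local explanations

Single predictions are explained with a kernel-weighted local surrogate:
5000 standard-normal perturbations in z-scored feature space, RBF weights
`exp(−d²/w²)` with `w = 0.75·√d`, features binarized by whether the
perturbed value falls in the same training-quartile bin as the patient's
value, and a weighted ridge fit (penalty 1e-3, raised ×10 on a singular
design). Conditions render on the standardized scale — one-sided for the
extreme bins (`Weight > 0.49`-style), two-sided for the middle bins, with
values exactly on a quartile closing the lower interval. The top-5 features
by |coefficient| are re-fitted alone so that intercept + Σ contributions
equals the surrogate prediction at the instance exactly (asserted to
1e-9); contributions are in prediction units (mGy).

Because the surrogate is local, a feature that is globally positively
associated with dose (TotalDLP) can receive a negative contribution for a
patient in a low-DLP bin: the surrogate measures the effect of *being in
that bin* relative to the locally weighted baseline. This is expected
behavior of bin-based local surrogates, not a defect.

## Problem sizes and runtime

The pipeline and acceptance protocol use the full 653-patient cohort
(522/131 split) with the 10×20 PSO budget. Unit and property tests run on a
120-patient cohort with a 3×2 swarm: those sizes exercise every contract
(determinism, bookkeeping, invariants) in seconds, while headline accuracy
is asserted only at full scale in the acceptance tests. A full five-family
benchmark takes a few minutes on one CPU, dominated by the exact-splitter
sklearn ensembles; LightGBM tuning takes ~30 s.

## Known limitations

- The dose model is a phenomenological surrogate: no photon transport, no
  SSDE, no scanner geometry. k's mean calibration pins only the first
  moment of the dose distribution.
- Absolute-error metrics (MSE, MAE, and to a lesser degree MAPE) of the
  benchmark scale with the dose variance of the generated cohort, which is
  not pinned by the published summaries the generator matches (mean and
  range); comparisons of absolute errors across cohorts with different
  spreads are not meaningful.
- The copula correlations are assumptions; rank-correlation recovery is
  tested (±0.1 at n ≥ 500) but no claim is made that they match any real
  cohort.
- PSO is a heuristic: the lattice test asserts ≥ 90% success over 50 seeds
  on enumerable spaces, not global optimality in general.
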