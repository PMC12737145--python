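"""Synthetic chest-CT patient cohorts.

Emulates a single-scanner female screening cohort (n = 653): truncated-normal
marginals for weight, height, age and mammographic breast thickness, a
right-skewed truncated-lognormal DLP, and a Gaussian copula that imposes
configurable pairwise rank correlations (weight–height, weight–breast
thickness, and weight–DLP by default, the last emulating automatic exposure
control raising tube output with body size). The joint distribution of the
real cohort is unknown; the correlation defaults are assumptions, documented
as such, and every piece is configurable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .dose_model import LabelledCohort, PatientRecord

__all__ = [
    "MarginalSpec",
    "GeneratorConfig",
    "generate_cohort",
    "split_cohort",
    "SplitReport",
]

FEATURES = ("weight", "height", "age", "breast_thickness", "dlp")


@dataclass(frozen=True)
class MarginalSpec:
    """One feature's marginal: truncated normal, or truncated lognormal
    when ``log=True`` (mean/sd then apply to log(x))."""

    mean: float
    sd: float
    lower: float
    upper: float
    log: bool = False

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError(f"marginal bounds invalid: [{self.lower}, {self.upper}]")
        if not self.sd > 0:
            raise ValueError(f"marginal sd must be positive, got {self.sd}")

    def ppf(self, u: np.ndarray) -> np.ndarray:
        """Quantile function of the truncated distribution at u in (0, 1)."""
        if self.log:
            dist = sps.norm(loc=self.mean, scale=self.sd)
            lo, hi = math.log(self.lower), math.log(self.upper)
        else:
            dist = sps.norm(loc=self.mean, scale=self.sd)
            lo, hi = self.lower, self.upper
        flo, fhi = dist.cdf(lo), dist.cdf(hi)
        x = dist.ppf(flo + u * (fhi - flo))
        if self.log:
            x = np.exp(x)
        # guard against ppf round-off at the extremes
        return np.clip(x, self.lower, self.upper)


def _default_marginals() -> dict[str, MarginalSpec]:
    return {
        # cohort summary values: mean weight 73.1 kg (46-133), height 1.59 m
        # (1.47-1.77), age 58.6 y (33-88); DLP observed range 68.81-914.5
        "weight": MarginalSpec(73.1, 15.0, 46.0, 133.0),
        "height": MarginalSpec(1.59, 0.06, 1.47, 1.77),
        "age": MarginalSpec(58.6, 12.0, 33.0, 88.0),
        # breast thickness: no printed summary; 50±12 mm bracketing the
        # 39-57 mm instance values seen in the explanation examples
        "breast_thickness": MarginalSpec(50.0, 12.0, 25.0, 80.0),
        # right-skewed: single protocol, wide output range
        "dlp": MarginalSpec(math.log(230.0), 0.55, 68.81, 914.5, log=True),
    }


def _default_rank_corr() -> dict[tuple[str, str], float]:
    return {
        ("weight", "height"): 0.3,
        ("weight", "breast_thickness"): 0.4,
        ("weight", "dlp"): 0.5,
    }


@dataclass(frozen=True)
class GeneratorConfig:
    """Cohort size, seed, per-feature marginals and rank-correlation targets."""

    n: int = 653
    seed: int = 0
    marginals: dict[str, MarginalSpec] = field(default_factory=_default_marginals)
    rank_corr: dict[tuple[str, str], float] = field(default_factory=_default_rank_corr)
    label_noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"n must be >= 1, got {self.n}")
        if self.label_noise_sd < 0:
            raise ValueError("label_noise_sd must be non-negative")
        missing = set(FEATURES) - set(self.marginals)
        if missing:
            raise ValueError(f"marginals missing for features: {sorted(missing)}")
        for pair, rho in self.rank_corr.items():
            if not all(f in FEATURES for f in pair):
                raise ValueError(f"unknown feature in correlation pair {pair}")
            if not -1.0 < rho < 1.0:
                raise ValueError(f"rank correlation {pair} = {rho} outside (-1, 1)")

    def latent_correlation(self) -> np.ndarray:
        """Gaussian-copula latent (Pearson) correlation matrix.

        Spearman targets map to latent correlations via r = 2·sin(π·ρ/6).
        Raises if the resulting matrix is not positive semi-definite.
        """
        d = len(FEATURES)
        corr = np.eye(d)
        idx = {f: i for i, f in enumerate(FEATURES)}
        for (a, b), rho in self.rank_corr.items():
            r = 2.0 * math.sin(math.pi * rho / 6.0)
            corr[idx[a], idx[b]] = corr[idx[b], idx[a]] = r
        eigmin = np.linalg.eigvalsh(corr).min()
        if eigmin < -1e-10:
            raise ValueError(
                f"correlation targets are infeasible (min eigenvalue {eigmin:.3g})"
            )
        return corr


def generate_cohort(config: GeneratorConfig) -> list[PatientRecord]:
    """Draw ``config.n`` patients; deterministic under ``config.seed``.

    Gaussian copula: latent multivariate normal -> uniform marginals ->
    per-feature truncated quantile transform. Monotone marginal transforms
    preserve the latent rank correlations.
    """
    rng = np.random.default_rng(config.seed)
    corr = config.latent_correlation()
    # eigendecomposition root: tolerant of semi-definite targets
    w, v = np.linalg.eigh(corr)
    root = v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    z = rng.standard_normal((config.n, len(FEATURES))) @ root.T
    u = sps.norm.cdf(z)
    # keep ppf strictly inside (0, 1)
    u = np.clip(u, 1e-12, 1.0 - 1e-12)

    cols = {f: config.marginals[f].ppf(u[:, i]) for i, f in enumerate(FEATURES)}
    return [
        PatientRecord(
            patient_id=f"P{i:04d}",
            weight=float(cols["weight"][i]),
            height=float(cols["height"][i]),
            age=float(cols["age"][i]),
            breast_thickness=float(cols["breast_thickness"][i]),
            total_dlp=float(cols["dlp"][i]),
        )
        for i in range(config.n)
    ]


@dataclass(frozen=True)
class SplitReport:
    """Comparability summary of the IR label distribution per split."""

    n_train: int
    n_test: int
    train_mean: float
    test_mean: float
    train_range: tuple[float, float]
    test_range: tuple[float, float]

    def to_dict(self) -> dict:
        return {
            "n_train": self.n_train,
            "n_test": self.n_test,
            "train_mean_ir": self.train_mean,
            "test_mean_ir": self.test_mean,
            "train_ir_range": list(self.train_range),
            "test_ir_range": list(self.test_range),
        }


def split_cohort(
    cohort: LabelledCohort, train_fraction: float, seed: int
) -> tuple[LabelledCohort, LabelledCohort, SplitReport]:
    """Random disjoint/exhaustive split with train size floor(n·fraction).

    Returns (train, test, report); the report carries the mean and range of
    IR per split so train/test dose comparability can be checked.
    """
    n = len(cohort)
    if n == 0:
        raise ValueError("cannot split an empty cohort")
    if not 0.0 < train_fraction < 1.0:
        raise ValueError(f"train_fraction must be in (0, 1), got {train_fraction}")
    n_train = int(math.floor(n * train_fraction))
    if n_train == 0 or n_train == n:
        raise ValueError(
            f"split of {n} at fraction {train_fraction} leaves an empty side"
        )
    perm = np.random.default_rng(seed).permutation(n)
    tr_idx, te_idx = np.sort(perm[:n_train]), np.sort(perm[n_train:])

    def _take(idx: np.ndarray) -> LabelledCohort:
        return LabelledCohort(
            patients=tuple(cohort.patients[i] for i in idx),
            ir=tuple(cohort.ir[i] for i in idx),
            params=cohort.params,
        )

    train, test = _take(tr_idx), _take(te_idx)
    report = SplitReport(
        n_train=len(train),
        n_test=len(test),
        train_mean=float(np.mean(train.ir)),
        test_mean=float(np.mean(test.ir)),
        train_range=(min(train.ir), max(train.ir)),
        test_range=(min(test.ir), max(test.ir)),
    )
    return train, test, report
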