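"""Calibration and quality semantics of pooled sequencing.

Pooled sequencing yields per-pool allele-frequency estimates rather than
genotypes.  This module holds the operations that give those estimates their
quality semantics: variant-quality cutoff calibration from spike-in controls,
rounding of raw frequency estimates onto the singleton grid of a pool,
inference of the additive estimation-error variance s_e from a concordance
set of genotyped SNPs, concordance summaries, and read-coverage QC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class PoolSpec:
    """One sequenced pool: arm label, allele count 2N, read totals, coverage."""

    pool_id: str
    arm: Literal["case", "control"]
    n_alleles: int
    n_reads: int = 0
    mean_coverage: float = 0.0

    def __post_init__(self) -> None:
        if self.n_alleles <= 0 or self.n_alleles % 2:
            raise ValueError("n_alleles must be a positive even count (2N)")
        if self.mean_coverage < 0:
            raise ValueError("mean_coverage must be >= 0")


@dataclass(frozen=True)
class CalibrationResult:
    """Variant-quality thresholds calibrated from spike-in controls.

    ``high_cutoff`` maximizes specificity (lowest positive-control score),
    ``low_cutoff`` maximizes sensitivity (highest negative-control score).
    ``separable`` records whether the control score distributions overlap.
    """

    high_cutoff: float
    low_cutoff: float
    separable: bool

    def __post_init__(self) -> None:
        if self.separable and not self.high_cutoff > self.low_cutoff:
            raise ValueError("separable calibration requires high_cutoff > low_cutoff")


@dataclass(frozen=True)
class EstimationError:
    """Per-arm additive variance of pooled frequency estimates (s_e)."""

    se_case: float
    se_control: float
    n_snps_used: int = 0

    def __post_init__(self) -> None:
        if self.se_case < 0 or self.se_control < 0:
            raise ValueError("estimation-error variances must be >= 0")


def calibrate_quality_cutoffs(
    pos_scores: Sequence[float], neg_scores: Sequence[float]
) -> CalibrationResult:
    """Calibrate variant-quality cutoffs from spiked positive/negative controls.

    The high-quality cutoff is the lowest positive-control score (no positive
    control is lost); the lower cutoff is the highest negative-control score
    (no negative control is called).  When the two distributions overlap the
    result is flagged non-separable instead of guessing a cutpoint.
    """
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both control score lists must be non-empty")
    high = float(pos.min())
    low = float(neg.max())
    return CalibrationResult(high_cutoff=high, low_cutoff=low, separable=high > low)


def round_allele_frequency(raw, n_alleles: int):
    """Round a raw frequency to the nearest multiple of 1/n_alleles.

    Pooled estimates are reported on the grid of achievable pool frequencies,
    whose spacing is one singleton allele (1/2N).  Half-way ties round away
    from zero.  Accepts scalars or arrays.
    """
    if n_alleles <= 0:
        raise ValueError("n_alleles must be positive")
    arr = np.asarray(raw, dtype=float)
    if ((arr < 0) | (arr > 1)).any():
        raise ValueError("raw frequency outside [0, 1]")
    rounded = np.floor(arr * n_alleles + 0.5) / n_alleles
    if np.isscalar(raw) or arr.ndim == 0:
        return float(rounded)
    return rounded


def estimate_estimation_error(
    observed: Sequence[float], expected: Sequence[float]
) -> float:
    """Mean squared error of observed vs expected allele frequencies.

    This is the additive variance component s_e (squared-frequency units)
    that pooled estimation contributes on top of binomial sampling; it is
    inferred from SNPs with an independent genotype-based frequency.
    """
    obs = np.asarray(observed, dtype=float)
    exp = np.asarray(expected, dtype=float)
    if obs.size == 0 or obs.shape != exp.shape:
        raise ValueError("observed and expected must be equal-length, non-empty")
    return float(np.mean((obs - exp) ** 2))


def af_concordance(
    observed: Sequence[float], expected: Sequence[float]
) -> tuple[float, float]:
    """Pearson r and mean absolute difference of paired frequency estimates."""
    obs = np.asarray(observed, dtype=float)
    exp = np.asarray(expected, dtype=float)
    if obs.size < 3 or obs.shape != exp.shape:
        raise ValueError("need >= 3 paired frequency values")
    if np.ptp(obs) == 0 or np.ptp(exp) == 0:
        raise ValueError("correlation undefined for a constant frequency vector")
    r = stats.pearsonr(obs, exp).statistic
    mad = float(np.mean(np.abs(obs - exp)))
    return float(r), mad


def coverage_qc(
    site_coverages: Sequence[float], threshold: float = 30.0
) -> tuple[set[int], float]:
    """Flag sites with read coverage below the detection-saturation threshold.

    Variant-detection power saturates around 30 reads per site per allele;
    sites strictly below ``threshold`` are flagged.  Returns the flagged site
    indices and the flagged fraction.
    """
    cov = np.asarray(site_coverages, dtype=float)
    if (cov < 0).any():
        raise ValueError("coverages must be >= 0")
    flagged = np.flatnonzero(cov < threshold)
    frac = float(flagged.size / cov.size) if cov.size else 0.0
    return set(int(i) for i in flagged), frac


def classify_variants(
    scores: Sequence[float], calibration: CalibrationResult
) -> np.ndarray:
    """Label variant scores 'high', 'low', or 'fail' against calibrated cutoffs.

    'high' means at or above the high-quality cutoff; 'low' means below it but
    at or above the sensitivity cutoff (only meaningful when separable).
    """
    s = np.asarray(scores, dtype=float)
    out = np.full(s.shape, "fail", dtype=object)
    out[s >= calibration.low_cutoff] = "low"
    out[s >= calibration.high_cutoff] = "high"
    return out


def _round_half_away(x: float) -> int:
    """Integer rounding with half-way ties away from zero."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))
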