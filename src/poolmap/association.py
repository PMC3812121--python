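"""Per-variant case/control association on pooled allele-frequency estimates.

The central statistic is a two-proportion Z-test modified for pooled
sequencing: because per-arm frequencies are *estimates* from pooled reads,
their estimation error contributes an additive variance component s_e on top
of binomial sampling.  With case/control frequencies p_A, p_B over N_A, N_B
alleles and pooled frequency p_0,

    sigma_s^2 = p_0 (1 - p_0) (1/N_A + 1/N_B)
    z = (p_A - p_B) / sqrt(sigma_s^2 + s_e,A + s_e,B)

and z is referred to the standard normal.  Setting both s_e to zero recovers
the textbook pooled two-proportion test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from poolmap.pool_model import EstimationError

#: Canonical columns of the per-variant table shared across modules.
VARIANT_COLUMNS = [
    "variant_id",
    "chrom",
    "pos",
    "ref",
    "alt",
    "af_case",
    "af_control",
    "n_case_alleles",
    "n_control_alleles",
    "region_class",
]


@dataclass(frozen=True)
class AssociationResult:
    """Modified Z-test output for one variant."""

    p0: float
    sigma_s: float
    z: float
    p_value: float
    or_allelic: float
    af_ratio: float


def modified_two_proportion_z(
    p_case,
    p_control,
    n_case_alleles,
    n_control_alleles,
    se_case=0.0,
    se_control=0.0,
):
    """Two-proportion Z-test with additive estimation-error variance.

    Parameters are the per-arm frequency estimates, allele totals (2N per
    arm), and the per-arm estimation-error variances s_e in squared-frequency
    units.  Scalars return an :class:`AssociationResult`; array inputs return
    a dict of arrays (vectorized over variants).

    Raises a ``ValueError`` when the pooled frequency is 0 or 1 with no
    estimation-error variance (the test statistic is then undefined).
    """
    p_a = np.asarray(p_case, dtype=float)
    p_b = np.asarray(p_control, dtype=float)
    n_a = np.asarray(n_case_alleles, dtype=float)
    n_b = np.asarray(n_control_alleles, dtype=float)
    s_a = np.asarray(se_case, dtype=float)
    s_b = np.asarray(se_control, dtype=float)
    if ((p_a < 0) | (p_a > 1) | (p_b < 0) | (p_b > 1)).any():
        raise ValueError("frequencies must lie in [0, 1]")
    if (n_a <= 0).any() or (n_b <= 0).any():
        raise ValueError("allele counts must be positive")
    if (s_a < 0).any() or (s_b < 0).any():
        raise ValueError("estimation-error variances must be >= 0")

    p0 = (p_a * n_a + p_b * n_b) / (n_a + n_b)
    var_sampling = p0 * (1.0 - p0) * (1.0 / n_a + 1.0 / n_b)
    var_total = var_sampling + s_a + s_b
    if (var_total <= 0).any():
        raise ValueError(
            "degenerate variance: pooled frequency is 0 or 1 with zero s_e"
        )
    sigma_s = np.sqrt(var_sampling)
    z = (p_a - p_b) / np.sqrt(var_total)
    p_value = 2.0 * stats.norm.sf(np.abs(z))

    with np.errstate(divide="ignore", invalid="ignore"):
        or_allelic = (p_a / (1.0 - p_a)) / (p_b / (1.0 - p_b))
        af_ratio = p_a / p_b

    if p0.ndim == 0:
        return AssociationResult(
            p0=float(p0),
            sigma_s=float(sigma_s),
            z=float(z),
            p_value=float(p_value),
            or_allelic=float(or_allelic),
            af_ratio=float(af_ratio),
        )
    return {
        "p0": p0,
        "sigma_s": sigma_s,
        "z": z,
        "p_value": p_value,
        "or_allelic": or_allelic,
        "af_ratio": af_ratio,
    }


def allelic_odds_ratio(p_case: float, p_control: float) -> float:
    """Allelic odds ratio [p_A/(1-p_A)] / [p_B/(1-p_B)].

    Both frequencies must lie strictly inside (0, 1); a boundary frequency
    makes the odds undefined.
    """
    if not (0.0 < p_case < 1.0 and 0.0 < p_control < 1.0):
        raise ValueError("odds ratio undefined at boundary frequencies")
    return (p_case / (1.0 - p_case)) / (p_control / (1.0 - p_control))


def allele_frequency_ratio(p_case: float, p_control: float) -> float:
    """Plain frequency ratio p_A / p_B (reported alongside the odds ratio)."""
    if p_control <= 0:
        raise ValueError("frequency ratio undefined when control frequency is 0")
    return p_case / p_control


def scan_common_variants(
    variants: pd.DataFrame,
    se: EstimationError,
    tag_ids: list[str],
    maf_cutoff: float = 0.05,
) -> tuple[pd.DataFrame, int]:
    """Common-variant association scan against the tag-SNP threshold.

    Tests every variant with pooled minor-allele frequency strictly above
    ``maf_cutoff`` using the modified Z-test, then compares each P-value to
    the *least significant* (largest) P among the previously associated tag
    SNPs.  A variant "beats the tags" when its P is strictly below that
    threshold.  Returns the tested table ranked by P (with ``log10_p``,
    ``beats_tags`` and the region class) and the count of variants stronger
    than the tags.
    """
    missing = [t for t in tag_ids if t not in set(variants["variant_id"])]
    if missing:
        raise ValueError(f"tag SNPs absent from variant table: {missing}")

    df = variants.copy()
    pooled = (
        df["af_case"] * df["n_case_alleles"] + df["af_control"] * df["n_control_alleles"]
    ) / (df["n_case_alleles"] + df["n_control_alleles"])
    df["pooled_maf"] = np.minimum(pooled, 1.0 - pooled)

    tested = df[df["pooled_maf"] > maf_cutoff].copy()
    if tested.empty:
        raise ValueError("no variant exceeds the MAF cutoff")
    res = modified_two_proportion_z(
        tested["af_case"].to_numpy(),
        tested["af_control"].to_numpy(),
        tested["n_case_alleles"].to_numpy(),
        tested["n_control_alleles"].to_numpy(),
        se.se_case,
        se.se_control,
    )
    tested["z"] = res["z"]
    tested["p_value"] = res["p_value"]
    tested["log10_p"] = np.log10(tested["p_value"])

    tag_rows = tested[tested["variant_id"].isin(tag_ids)]
    if tag_rows.empty:
        raise ValueError("no tag SNP survives the MAF cutoff")
    threshold = float(tag_rows["p_value"].max())
    tested["beats_tags"] = tested["p_value"] < threshold
    tested = tested.sort_values("p_value", kind="mergesort").reset_index(drop=True)
    tested.attrs["tag_threshold"] = threshold
    return tested, int(tested["beats_tags"].sum())
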