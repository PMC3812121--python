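"""Rare-variant collapsing and one-tail Fisher burden tests.

Rare variants (minor-allele frequency below 1% in both arms) are collapsed
into a single pseudo-variant per arm: the collapsed allele frequency is the
summed minor-allele count over qualifying variants divided by the arm allele
total.  The burden comparison between arms is a one-tail Fisher exact test
on the reconstructed carrier counts, with conserved-site subsets and
flanking-region controls selecting which variants qualify.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

from poolmap.pool_model import _round_half_away


@dataclass(frozen=True)
class BurdenResult:
    """Collapsed rare-variant burden comparison between arms."""

    n_variants_case: int
    n_variants_control: int
    collapsed_af_case: float
    collapsed_af_control: float
    odds_ratio: float
    p_one_tail: float
    tail: str = "depletion"


def _minor_orientation(df: pd.DataFrame) -> pd.Series:
    """True where the alt allele is the pooled minor allele."""
    pooled = (
        df["af_case"] * df["n_case_alleles"] + df["af_control"] * df["n_control_alleles"]
    ) / (df["n_case_alleles"] + df["n_control_alleles"])
    return pooled <= 0.5


def _minor_freqs(df: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
    """Per-arm frequency of the pooled minor allele."""
    alt_minor = _minor_orientation(df)
    f_case = df["af_case"].where(alt_minor, 1.0 - df["af_case"])
    f_ctrl = df["af_control"].where(alt_minor, 1.0 - df["af_control"])
    return f_case, f_ctrl


def _apply_site_filter(variants: pd.DataFrame, site_filter: str) -> pd.DataFrame:
    if site_filter == "all":
        return variants[variants["region_class"] == "candidate"]
    if site_filter == "conserved":
        if "conserved" not in variants.columns:
            raise ValueError("site_filter='conserved' needs a 'conserved' column")
        return variants[
            (variants["region_class"] == "candidate") & variants["conserved"]
        ]
    if site_filter == "flanking":
        return variants[variants["region_class"] == "flanking"]
    raise ValueError("site_filter must be one of {'all', 'conserved', 'flanking'}")


def collapse_rare_variants(
    variants: pd.DataFrame,
    arm: Literal["case", "control"],
    maf_cutoff: float = 0.01,
    site_filter: str = "all",
) -> tuple[int, float]:
    """Collapse qualifying rare variants in one arm.

    A variant qualifies when its minor-allele frequency is strictly below
    ``maf_cutoff`` in *both* arms (and the minor allele segregates at all).
    ``site_filter`` restricts to candidate regions ('all'), conserved sites
    within candidate regions ('conserved'), or the flanking-region control
    ('flanking').  Returns the number of qualifying variants observed in the
    arm and the collapsed allele frequency (summed minor-allele count over
    the arm allele total).
    """
    if arm not in ("case", "control"):
        raise ValueError("arm must be 'case' or 'control'")
    df = _apply_site_filter(variants, site_filter)
    if df.empty:
        return 0, 0.0
    f_case, f_ctrl = _minor_freqs(df)
    qualifies = (f_case < maf_cutoff) & (f_ctrl < maf_cutoff) & ((f_case + f_ctrl) > 0)
    df = df[qualifies]
    if df.empty:
        return 0, 0.0
    f_arm = (f_case if arm == "case" else f_ctrl)[qualifies]
    n_alleles = df[f"n_{arm}_alleles"]
    counts = np.array(
        [_round_half_away(f * n) for f, n in zip(f_arm, n_alleles)], dtype=int
    )
    arm_total = int(n_alleles.iloc[0])
    if (n_alleles != arm_total).any():
        raise ValueError("inconsistent allele totals within one arm")
    n_observed = int((counts > 0).sum())
    collapsed_af = float(counts.sum() / arm_total)
    return n_observed, collapsed_af


def fisher_one_tail_burden(
    case_carriers: int,
    case_alleles: int,
    control_carriers: int,
    control_alleles: int,
    tail: Literal["depletion", "enrichment", "auto"] = "auto",
) -> BurdenResult:
    """One-tail Fisher exact test of collapsed rare-allele counts.

    The 2x2 table is (carrier, non-carrier) alleles by arm.  Under the null,
    the case carrier count X is hypergeometric given the margins; the
    'depletion' tail is P(X <= observed), 'enrichment' is P(X >= observed).
    'auto' tests in the observed direction (depletion when the case carrier
    frequency is below the control frequency).  The odds ratio is computed
    from the collapsed carrier frequencies.
    """
    if case_alleles <= 0 or control_alleles <= 0:
        raise ValueError("allele totals must be positive")
    if not (0 <= case_carriers <= case_alleles and 0 <= control_carriers <= control_alleles):
        raise ValueError("carrier counts must lie within allele totals")

    f_case = case_carriers / case_alleles
    f_ctrl = control_carriers / control_alleles
    if tail == "auto":
        tail = "depletion" if f_case <= f_ctrl else "enrichment"
    table = [
        [case_carriers, case_alleles - case_carriers],
        [control_carriers, control_alleles - control_carriers],
    ]
    alternative = "less" if tail == "depletion" else "greater"
    p = float(stats.fisher_exact(table, alternative=alternative).pvalue)

    if 0.0 < f_case < 1.0 and 0.0 < f_ctrl < 1.0:
        odds_ratio = (f_case / (1 - f_case)) / (f_ctrl / (1 - f_ctrl))
    else:
        odds_ratio = float("nan")
    return BurdenResult(
        n_variants_case=case_carriers,
        n_variants_control=control_carriers,
        collapsed_af_case=f_case,
        collapsed_af_control=f_ctrl,
        odds_ratio=odds_ratio,
        p_one_tail=p,
        tail=tail,
    )


def burden_table(
    variants: pd.DataFrame,
    site_filters: tuple[str, ...] = ("all", "conserved", "flanking"),
    maf_cutoff: float = 0.01,
) -> pd.DataFrame:
    """Collapsed-burden summary across site filters (one row per filter)."""
    rows = []
    for site_filter in site_filters:
        n_case, af_case = collapse_rare_variants(
            variants, "case", maf_cutoff, site_filter
        )
        n_ctrl, af_ctrl = collapse_rare_variants(
            variants, "control", maf_cutoff, site_filter
        )
        sub = _apply_site_filter(variants, site_filter)
        if sub.empty:
            rows.append(
                dict(region=site_filter, n_case=0, collapsed_af_case=0.0,
                     n_control=0, collapsed_af_control=0.0,
                     odds_ratio=float("nan"), p_one_tail=float("nan"))
            )
            continue
        case_total = int(sub["n_case_alleles"].iloc[0])
        ctrl_total = int(sub["n_control_alleles"].iloc[0])
        res = fisher_one_tail_burden(
            _round_half_away(af_case * case_total),
            case_total,
            _round_half_away(af_ctrl * ctrl_total),
            ctrl_total,
        )
        rows.append(
            dict(
                region=site_filter,
                n_case=n_case,
                collapsed_af_case=af_case,
                n_control=n_ctrl,
                collapsed_af_control=af_ctrl,
                odds_ratio=res.odds_ratio,
                p_one_tail=res.p_one_tail,
            )
        )
    return pd.DataFrame(rows)


def exclusive_variant_table(
    variants: pd.DataFrame, maf_max: float = 0.05
) -> pd.DataFrame:
    """Variants present in exactly one arm at minor frequency <= ``maf_max``.

    Returns the qualifying rows with an added ``exclusive_to`` column
    ('case' or 'control').
    """
    f_case, f_ctrl = _minor_freqs(variants)
    case_only = (f_ctrl == 0) & (f_case > 0) & (f_case <= maf_max)
    ctrl_only = (f_case == 0) & (f_ctrl > 0) & (f_ctrl <= maf_max)
    out = variants[case_only | ctrl_only].copy()
    out["exclusive_to"] = np.where(case_only[case_only | ctrl_only], "case", "control")
    return out.reset_index(drop=True)
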