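"""Haplotype-level fine-mapping from a phased reference panel.

Within a high-LD interval, chromosomes cluster into a handful of major
haplotypes.  Pooled sequencing cannot observe haplotypes directly, so each
major haplotype is proxied by tag SNPs in tight LD (r^2 > 0.9) with
haplotype membership in the phased panel; the haplotype frequency in a pool
is estimated by averaging the pool frequencies of its tags.  Association is
then tested by Fisher's exact test on reconstructed allele counts, with a
conditional test that removes one haplotype from the gene pool to establish
independence of effects, recombinant detection from individual tag
genotypes, and a joint binomial GLM on individual-level dosages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from poolmap.panel import HaplotypePanel
from poolmap.pool_model import _round_half_away


@dataclass(frozen=True)
class LDStats:
    """Pairwise linkage disequilibrium between two biallelic loci."""

    D: float
    D_prime: float
    r2: float


@dataclass(frozen=True)
class HaplotypeGroup:
    """One exact-identity haplotype cluster from a phased panel."""

    label: str
    vector: tuple[int, ...]
    chromosome_indices: tuple[int, ...]
    frequency: float
    is_major: bool


@dataclass(frozen=True)
class TagSet:
    """Tag SNPs in tight LD with one haplotype group.

    ``orientations[i]`` is the allele (0 or 1) linked to haplotype
    membership for ``snp_ids[i]``.
    """

    hap_id: str
    snp_ids: tuple[str, ...]
    r2_values: tuple[float, ...]
    orientations: tuple[int, ...]

    def __len__(self) -> int:
        return len(self.snp_ids)


@dataclass(frozen=True)
class HaplotypeFrequencyEstimate:
    """Pool-level haplotype frequency from tag-SNP averaging."""

    frequency: float
    per_tag: dict[str, float]
    spread: float  # standard deviation across tags


@dataclass
class HaplotypeAssociation:
    """Case/control association summary for one major haplotype."""

    hap_id: str
    freq_case: float
    freq_control: float
    odds_ratio: float
    ci95: tuple[float, float]
    p_fisher: float
    conditional_or: float | None = None
    conditional_p: float | None = None
    or_defined: bool = True


# --------------------------------------------------------------------- LD
def ld_stats(gamete_counts) -> LDStats:
    """LD statistics from 2x2 gamete counts [[n_AB, n_Ab], [n_aB, n_ab]].

    D = p_AB - p_A p_B; D' normalizes |D| by its maximum given the allele
    frequencies (min(p_A(1-p_B), (1-p_A)p_B) for D > 0, mirrored for D < 0);
    r^2 = D^2 / [p_A(1-p_A) p_B(1-p_B)].  Both loci must be polymorphic.
    """
    counts = np.asarray(gamete_counts, dtype=float).reshape(2, 2)
    if (counts < 0).any():
        raise ValueError("gamete counts must be >= 0")
    total = counts.sum()
    if total <= 0:
        raise ValueError("total gamete count must be positive")
    p_ab = counts[0, 0] / total
    p_a = counts[0].sum() / total
    p_b = counts[:, 0].sum() / total
    if p_a in (0.0, 1.0) or p_b in (0.0, 1.0):
        raise ValueError("LD undefined at a monomorphic locus")
    d = p_ab - p_a * p_b
    if d >= 0:
        d_max = min(p_a * (1 - p_b), (1 - p_a) * p_b)
    else:
        d_max = min(p_a * p_b, (1 - p_a) * (1 - p_b))
    d_prime = abs(d) / d_max if d_max > 0 else 0.0
    r2 = d * d / (p_a * (1 - p_a) * p_b * (1 - p_b))
    return LDStats(D=float(d), D_prime=float(d_prime), r2=float(r2))


# ------------------------------------------------------------- clustering
def cluster_major_haplotypes(
    panel: HaplotypePanel,
    interval: tuple[int, int] | None = None,
    freq_cutoff: float = 0.05,
) -> tuple[list[HaplotypeGroup], float]:
    """Cluster panel chromosomes by exact allele-vector identity.

    ``interval`` restricts to sites with 1-based position in
    [interval[0], interval[1]] (inclusive); None uses all sites.  Groups at
    frequency >= ``freq_cutoff`` are major (ties at the boundary count as
    major).  Returns groups sorted by descending frequency (labelled hap1,
    hap2, ... for majors, then rare groups) and the fraction of chromosomes
    carried by major haplotypes.
    """
    if interval is None:
        cols = np.arange(panel.n_sites)
    else:
        lo, hi = interval
        cols = np.flatnonzero((panel.positions >= lo) & (panel.positions <= hi))
    if cols.size == 0:
        raise ValueError("interval contains no panel sites")
    sub = panel.haplotypes[:, cols]

    vectors, inverse = np.unique(sub, axis=0, return_inverse=True)
    n = panel.n_chromosomes
    order = []
    for g in range(vectors.shape[0]):
        members = np.flatnonzero(inverse == g)
        order.append((members.size, g, members))
    # descending size; ties broken by first chromosome index for determinism
    order.sort(key=lambda t: (-t[0], int(t[2][0])))

    groups: list[HaplotypeGroup] = []
    covered = 0
    major_rank = 0
    for size, g, members in order:
        freq = size / n
        is_major = freq >= freq_cutoff
        if is_major:
            major_rank += 1
            label = f"hap{major_rank}"
            covered += size
        else:
            label = f"rare{g}"
        groups.append(
            HaplotypeGroup(
                label=label,
                vector=tuple(int(a) for a in vectors[g]),
                chromosome_indices=tuple(int(i) for i in members),
                frequency=freq,
                is_major=is_major,
            )
        )
    return groups, covered / n


def select_tag_snps(
    panel: HaplotypePanel,
    hap_group: HaplotypeGroup,
    r2_cutoff: float = 0.9,
) -> TagSet:
    """Select SNPs in tight LD (r^2 > cutoff) with haplotype membership.

    For each panel site, r^2 is computed between the 0/1 allele indicator
    and the haplotype-membership indicator across chromosomes.  The linked
    allele orientation (which allele marks membership) is recorded per tag.
    An empty TagSet is returned when no site qualifies (flagged, not fatal).
    """
    member = np.zeros(panel.n_chromosomes, dtype=float)
    member[list(hap_group.chromosome_indices)] = 1.0
    p_m = member.mean()
    if p_m in (0.0, 1.0):
        raise ValueError("haplotype group must be a proper subset of the panel")

    snp_ids, r2s, orientations = [], [], []
    for j in range(panel.n_sites):
        allele = panel.haplotypes[:, j].astype(float)
        p_a = allele.mean()
        if p_a in (0.0, 1.0):
            continue
        d = float(np.mean(allele * member)) - p_a * p_m
        r2 = d * d / (p_a * (1 - p_a) * p_m * (1 - p_m))
        if r2 > r2_cutoff:
            snp_ids.append(panel.site_ids[j])
            r2s.append(float(r2))
            orientations.append(1 if d > 0 else 0)
    return TagSet(
        hap_id=hap_group.label,
        snp_ids=tuple(snp_ids),
        r2_values=tuple(r2s),
        orientations=tuple(orientations),
    )


def estimate_haplotype_frequencies(
    tags: TagSet, pool_afs: Mapping[str, float]
) -> HaplotypeFrequencyEstimate:
    """Estimate a haplotype's pool frequency by averaging its tag-SNP AFs.

    ``pool_afs`` maps SNP id to the derived-allele frequency in the pool;
    tags whose linked allele is the reference are flipped before averaging.
    The per-tag values and their spread are reported so callers can judge
    (and, if they choose, exclude) outlying tags.
    """
    if len(tags) == 0:
        raise ValueError(f"empty tag set for {tags.hap_id}: cannot estimate frequency")
    missing = [s for s in tags.snp_ids if s not in pool_afs]
    if missing:
        raise ValueError(f"no pool frequency for tag SNPs: {missing}")
    per_tag = {
        snp: (pool_afs[snp] if orient == 1 else 1.0 - pool_afs[snp])
        for snp, orient in zip(tags.snp_ids, tags.orientations)
    }
    values = np.array(list(per_tag.values()), dtype=float)
    return HaplotypeFrequencyEstimate(
        frequency=float(values.mean()),
        per_tag=per_tag,
        spread=float(values.std(ddof=0)),
    )


# ------------------------------------------------------------ association
def _log_or_ci(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Wald 95% CI for the odds ratio of table [[a, b], [c, d]]."""
    log_or = math.log((a * d) / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return (math.exp(log_or - 1.959963984540054 * se),
            math.exp(log_or + 1.959963984540054 * se))


def haplotype_fisher_test(
    freq_case: float,
    n_case_alleles: int,
    freq_control: float,
    n_control_alleles: int,
    hap_id: str = "hap",
) -> HaplotypeAssociation:
    """Fisher exact test of a haplotype frequency difference between pools.

    Counts are reconstructed as round(freq x alleles) per arm (frequencies
    are the only pool-level observable); the P-value is the two-sided Fisher
    exact probability, the odds ratio is the table cross-product, and the
    95% CI uses the normal approximation on the log odds ratio.  Tables with
    a zero margin return P = 1 with the odds ratio flagged undefined.
    """
    if not (0 <= freq_case <= 1 and 0 <= freq_control <= 1):
        raise ValueError("frequencies must lie in [0, 1]")
    a = _round_half_away(freq_case * n_case_alleles)
    c = _round_half_away(freq_control * n_control_alleles)
    b = n_case_alleles - a
    d = n_control_alleles - c
    if min(a + c, b + d) == 0:
        return HaplotypeAssociation(
            hap_id=hap_id,
            freq_case=freq_case,
            freq_control=freq_control,
            odds_ratio=float("nan"),
            ci95=(float("nan"), float("nan")),
            p_fisher=1.0,
            or_defined=False,
        )
    p = float(stats.fisher_exact([[a, b], [c, d]]).pvalue)
    if min(a, b, c, d) == 0:
        return HaplotypeAssociation(
            hap_id=hap_id,
            freq_case=freq_case,
            freq_control=freq_control,
            odds_ratio=float("nan"),
            ci95=(float("nan"), float("nan")),
            p_fisher=p,
            or_defined=False,
        )
    return HaplotypeAssociation(
        hap_id=hap_id,
        freq_case=freq_case,
        freq_control=freq_control,
        odds_ratio=(a * d) / (b * c),
        ci95=_log_or_ci(a, b, c, d),
        p_fisher=p,
    )


def conditional_independence_test(
    counts_case: Mapping[str, int],
    counts_control: Mapping[str, int],
    target_hap: str,
    excluded_hap: str,
) -> tuple[float, float]:
    """Re-test a haplotype after excluding another from the gene pool.

    Chromosomes carrying ``excluded_hap`` are removed from both arms'
    denominators and the Fisher exact test of ``target_hap`` vs the
    remaining chromosomes is recomputed.  Returns (odds ratio, two-sided P).
    """
    if target_hap == excluded_hap:
        raise ValueError("target and excluded haplotypes must differ")
    for counts in (counts_case, counts_control):
        if target_hap not in counts or excluded_hap not in counts:
            raise ValueError("target and excluded haplotypes must appear in counts")
    a = counts_case[target_hap]
    c = counts_control[target_hap]
    b = sum(counts_case.values()) - counts_case[excluded_hap] - a
    d = sum(counts_control.values()) - counts_control[excluded_hap] - c
    if min(b, d) < 0:
        raise ValueError("haplotype counts exceed arm totals")
    p = float(stats.fisher_exact([[a, b], [c, d]]).pvalue)
    odds_ratio = (a * d) / (b * c) if min(b, c) > 0 and a * d >= 0 else float("nan")
    return odds_ratio, p


# ----------------------------------------------- individual-level validation
def detect_recombinants(
    genotypes: pd.DataFrame,
    risk_tags: Sequence[str],
    protective_tags: Sequence[str],
) -> list[str]:
    """Identify individuals with recombinant haplotypes from tag dosages.

    On an intact haplotype every tag of its tag set travels together, so a
    non-recombinant individual carries equal dosages at all tags within a
    set.  An individual whose dosages differ within the risk set or within
    the protective set carries a chromosome with only part of a tagged
    haplotype and is reported as recombinant.  Rows with missing tag
    dosages must be excluded upstream.
    """
    for cols in (risk_tags, protective_tags):
        missing = [c for c in cols if c not in genotypes.columns]
        if missing:
            raise ValueError(f"genotype table lacks tag columns: {missing}")
    if genotypes[list(risk_tags) + list(protective_tags)].isna().any().any():
        raise ValueError("missing tag dosages; drop incomplete individuals first")
    out = []
    for _, row in genotypes.iterrows():
        discordant = any(
            row[list(tag_set)].nunique() > 1
            for tag_set in (risk_tags, protective_tags)
            if len(tag_set) > 0
        )
        if discordant:
            out.append(str(row["individual_id"]))
    return out


def joint_glm_test(
    individuals: pd.DataFrame,
    risk_col: str = "dosage_risk",
    protective_col: str = "dosage_prot",
    status_col: str = "status",
) -> dict:
    """Joint binomial-family GLM of case status on two haplotype dosages.

    Fits logit P(case) = b0 + b_r * dosage_risk + b_p * dosage_prot and
    reports exponentiated coefficients (per-haplotype odds ratios) with
    Wald 95% CIs and P-values.  Complete separation is flagged and no
    estimate is returned for it.
    """
    df = individuals
    n_case = int((df[status_col] == 1).sum())
    if n_case < 2 or len(df) - n_case < 2:
        raise ValueError("need >= 2 individuals per arm")
    dosages = df[[risk_col, protective_col]].to_numpy()
    if not np.isin(dosages, (0, 1, 2)).all():
        raise ValueError("dosages must be 0, 1 or 2")
    exog = sm.add_constant(df[[risk_col, protective_col]].astype(float), has_constant="add")
    model = sm.GLM(df[status_col].astype(float), exog, family=sm.families.Binomial())
    import warnings

    from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", PerfectSeparationWarning)
        try:
            fit = model.fit()
        except Exception as exc:  # pragma: no cover - statsmodels failure path
            return {"separation": True, "detail": str(exc)}
    if any(issubclass(w.category, PerfectSeparationWarning) for w in caught):
        return {"separation": True, "detail": "perfect separation detected"}
    if np.abs(fit.params.iloc[1:]).max() > 15 or np.isnan(fit.bse).any():
        return {"separation": True, "detail": "quasi-complete separation"}
    ci = fit.conf_int()
    result: dict = {"separation": False, "n": int(len(df))}
    for name, key in ((risk_col, "risk"), (protective_col, "protective")):
        result[key] = {
            "or": float(np.exp(fit.params[name])),
            "ci95": (float(np.exp(ci.loc[name, 0])), float(np.exp(ci.loc[name, 1]))),
            "p": float(fit.pvalues[name]),
        }
    return result
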