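"""Synthetic inputs for the pooled fine-mapping pipeline.

Everything the pipeline consumes can be generated here under a fixed seed:
a phased haplotype panel with a small number of major haplotypes on a
high-LD background, a retrospective case/control cohort drawn from a
logistic disease model with one risk and one protective haplotype, per-pool
allele-frequency estimates with binomial sampling plus an additive Gaussian
estimation error rounded to the singleton grid, spike-in control quality
scores, and an individual-level tag-genotype validation table.

Defaults describe the emulated study: 186 panel chromosomes (93 phased
individuals) over 39 sites, four major haplotypes jointly covering 77% of
chromosomes, a cohort of 127 cases and 135 controls at 5.5% baseline
prevalence with haplotype odds ratios 1.89 (risk) and 0.50 (protective),
two sequencing pools per arm (192 + 62 case and 150 + 120 control alleles),
and estimation-error variances 0.00081 (case) / 0.00032 (control).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from poolmap.panel import HaplotypePanel
from poolmap.pool_model import _round_half_away, round_allele_frequency


class GenerationError(RuntimeError):
    """Requested cohort composition cannot be reached."""


# ------------------------------------------------------------------ configs
@dataclass(frozen=True)
class PanelConfig:
    """Shape of the phased reference panel."""

    n_chromosomes: int = 186
    n_sites: int = 39
    major_hap_freqs: tuple[float, ...] = (0.29, 0.23, 0.13, 0.12)
    rare_hap_mass: float = 0.23
    region_length: int = 103_000
    seed: int = 0
    risk_index: int = 2  # rank (0-based, descending frequency) of the risk major
    protective_index: int = 3

    def __post_init__(self) -> None:
        if self.n_chromosomes <= 0 or self.n_chromosomes % 2:
            raise ValueError("n_chromosomes must be a positive even count")
        if any(f < 0.05 for f in self.major_hap_freqs):
            raise ValueError("each major haplotype frequency must be >= 0.05")
        if sum(self.major_hap_freqs) + self.rare_hap_mass > 1 + 1e-9:
            raise ValueError("major frequencies plus rare mass exceed 1")
        if self.n_sites < 2 * len(self.major_hap_freqs):
            raise ValueError("need enough sites for private tags plus background")


@dataclass(frozen=True)
class CohortConfig:
    """Retrospective case/control cohort under a logistic disease model."""

    n_cases: int = 127
    n_controls: int = 135
    risk_hap_or: float = 1.89
    protective_hap_or: float = 0.50
    baseline_prevalence: float = 0.055
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise ValueError("cohort counts must be positive")
        if self.risk_hap_or <= 0 or self.protective_hap_or <= 0:
            raise ValueError("odds ratios must be positive")
        if not 0 < self.baseline_prevalence < 1:
            raise ValueError("baseline prevalence must lie in (0, 1)")


@dataclass(frozen=True)
class PoolNoiseConfig:
    """Additive estimation-error variance per arm, in squared frequency."""

    se_case: float = 0.00081
    se_control: float = 0.00032
    read_depth_per_allele: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.se_case < 0 or self.se_control < 0:
            raise ValueError("estimation-error variances must be >= 0")


# ------------------------------------------------------------------- panel
def gen_haplotype_panel(cfg: PanelConfig = PanelConfig()) -> HaplotypePanel:
    """Generate a phased panel with planted major haplotypes.

    Each major haplotype is a distinct allele vector carried by
    round(freq x n_chromosomes) chromosomes and carries at least one private
    derived allele (a perfect tag).  Remaining chromosomes are mutated
    copies of the majors with every private allele removed and a fraction of
    background sites flipped, so they never re-enter a major group.
    Deterministic under the config seed.
    """
    rng = np.random.default_rng(cfg.seed)
    k = len(cfg.major_hap_freqs)
    counts = [_round_half_away(f * cfg.n_chromosomes) for f in cfg.major_hap_freqs]
    n_rare = cfg.n_chromosomes - sum(counts)
    if n_rare < 0:
        raise ValueError("rounded major haplotype counts exceed the panel size")

    # sites 0..k-1 are reserved private tags; the rest are shared background
    majors = np.zeros((k, cfg.n_sites), dtype=np.int8)
    for i in range(k):
        majors[i, i] = 1
    background = rng.integers(0, 2, size=(k, cfg.n_sites - k), dtype=np.int8)
    majors[:, k:] = background

    rows = [np.repeat(majors, counts, axis=0)]
    if n_rare:
        src = rng.integers(0, k, size=n_rare)
        rare = majors[src].copy()
        rare[:, :k] = 0  # rare chromosomes never carry a private tag allele
        flips = rng.random(size=(n_rare, cfg.n_sites - k)) < 0.15
        # guarantee each rare chromosome mutates somewhere in the background
        for i in range(n_rare):
            if not flips[i].any():
                flips[i, rng.integers(0, cfg.n_sites - k)] = True
        rare[:, k:] ^= flips.astype(np.int8)
        rows.append(rare)
    haplotypes = np.concatenate(rows, axis=0)

    positions = np.linspace(1, cfg.region_length, cfg.n_sites).round().astype(np.int64)
    panel = HaplotypePanel(
        haplotypes=haplotypes,
        site_ids=[f"snp{j:03d}" for j in range(cfg.n_sites)],
        positions=positions,
        chrom="chr2",
        ancestral=np.zeros(cfg.n_sites, dtype=np.int8),
        risk_hap=cfg.risk_index,
        protective_hap=cfg.protective_index,
    )
    return panel


def _major_membership(panel: HaplotypePanel) -> tuple[np.ndarray, np.ndarray]:
    """Risk/protective membership indicators over panel chromosomes."""
    from poolmap.haplotypes import cluster_major_haplotypes

    groups, _ = cluster_major_haplotypes(panel)
    majors = [g for g in groups if g.is_major]
    if panel.risk_hap is None or panel.protective_hap is None:
        raise ValueError("panel lacks designated risk/protective haplotypes")
    if max(panel.risk_hap, panel.protective_hap) >= len(majors):
        raise ValueError("designated haplotype rank exceeds the major count")
    risk = np.zeros(panel.n_chromosomes, dtype=bool)
    prot = np.zeros(panel.n_chromosomes, dtype=bool)
    risk[list(majors[panel.risk_hap].chromosome_indices)] = True
    prot[list(majors[panel.protective_hap].chromosome_indices)] = True
    return risk, prot


def gen_cohort(
    panel: HaplotypePanel, cfg: CohortConfig = CohortConfig()
) -> pd.DataFrame:
    """Sample a case/control cohort from the panel under the disease model.

    Individuals are pairs of panel chromosomes drawn with replacement; case
    status is Bernoulli with log-odds
    logit(baseline) + d_risk ln(OR_risk) + d_prot ln(OR_prot) where the d
    are haplotype dosages.  Rejection sampling continues until the requested
    case and control counts are filled (retrospective design).  Columns:
    individual_id, chrom1, chrom2, dosage_risk, dosage_prot, status.
    """
    rng = np.random.default_rng(cfg.seed)
    risk, prot = _major_membership(panel)
    base_logit = float(np.log(cfg.baseline_prevalence / (1 - cfg.baseline_prevalence)))
    beta_r = float(np.log(cfg.risk_hap_or))
    beta_p = float(np.log(cfg.protective_hap_or))

    need = {1: cfg.n_cases, 0: cfg.n_controls}
    kept: list[tuple[int, int, int, int, int]] = []
    max_draws = 2000 * (cfg.n_cases + cfg.n_controls) + 100_000
    drawn = 0
    while need[0] > 0 or need[1] > 0:
        if drawn >= max_draws:
            raise GenerationError(
                "could not fill requested case/control counts; "
                "an arm has (near-)zero probability under this disease model"
            )
        m = min(4096, max_draws - drawn)
        drawn += m
        c1 = rng.integers(0, panel.n_chromosomes, size=m)
        c2 = rng.integers(0, panel.n_chromosomes, size=m)
        d_r = risk[c1].astype(int) + risk[c2].astype(int)
        d_p = prot[c1].astype(int) + prot[c2].astype(int)
        eta = base_logit + beta_r * d_r + beta_p * d_p
        p_case = 1.0 / (1.0 + np.exp(-eta))
        status = (rng.random(m) < p_case).astype(int)
        for i in range(m):
            s = int(status[i])
            if need[s] > 0:
                need[s] -= 1
                kept.append((int(c1[i]), int(c2[i]), int(d_r[i]), int(d_p[i]), s))
            if need[0] == 0 and need[1] == 0:
                break

    df = pd.DataFrame(
        kept, columns=["chrom1", "chrom2", "dosage_risk", "dosage_prot", "status"]
    )
    df.insert(0, "individual_id", [f"S{i:04d}" for i in range(len(df))])
    return df


# -------------------------------------------------------------- pooled AFs
def default_pool_split(cohort: pd.DataFrame) -> dict[str, tuple[str, np.ndarray]]:
    """Two sequencing pools per arm, sized like the emulated study.

    The first case pool takes 96/127 of cases and the first control pool
    75/135 of controls (the remainder forms the second pool of each arm),
    reproducing pool allele counts 192/62 and 150/120 at default cohort
    sizes.  Returns {pool_id: (arm, cohort row indices)}.
    """
    split: dict[str, tuple[str, np.ndarray]] = {}
    for arm, status, frac in (("case", 1, 96 / 127), ("control", 0, 75 / 135)):
        idx = np.flatnonzero((cohort["status"] == status).to_numpy())
        if idx.size < 2:
            raise ValueError(f"need at least 2 {arm} individuals to form two pools")
        n1 = min(max(_round_half_away(frac * idx.size), 1), idx.size - 1)
        split[f"{arm}_1"] = (arm, idx[:n1])
        split[f"{arm}_2"] = (arm, idx[n1:])
    return split


def gen_pooled_af(
    panel: HaplotypePanel,
    cohort: pd.DataFrame,
    noise: PoolNoiseConfig = PoolNoiseConfig(),
    pool_split: dict[str, tuple[str, np.ndarray]] | None = None,
) -> pd.DataFrame:
    """Per-pool allele-frequency estimates for every panel site.

    For each pool, the true frequency is the allele mean over the pool's
    2N chromosomes; the estimate adds Gaussian noise with the arm's
    estimation-error variance, truncates to [0, 1], and rounds to the
    nearest multiple of one singleton allele (1/2N).  Long format with one
    row per (site, pool).
    """
    if pool_split is None:
        pool_split = default_pool_split(cohort)
    if not pool_split:
        raise ValueError("pool_split must define at least one pool")
    arms = {arm for arm, _ in pool_split.values()}
    if not {"case", "control"} <= arms:
        raise ValueError("pool_split needs at least one case and one control pool")
    rng = np.random.default_rng(noise.seed)
    frames = []
    for pool_id, (arm, rows) in pool_split.items():
        rows = np.asarray(rows, dtype=int)
        if rows.size == 0:
            raise ValueError(f"pool {pool_id} is empty")
        chroms = np.concatenate(
            [cohort["chrom1"].to_numpy()[rows], cohort["chrom2"].to_numpy()[rows]]
        )
        n_alleles = chroms.size
        truth = panel.haplotypes[chroms].mean(axis=0)
        se = noise.se_case if arm == "case" else noise.se_control
        noisy = truth + rng.normal(0.0, np.sqrt(se), size=truth.size)
        noisy = np.clip(noisy, 0.0, 1.0)
        estimate = round_allele_frequency(noisy, n_alleles)
        frames.append(
            pd.DataFrame(
                {
                    "variant_id": panel.site_ids,
                    "chrom": panel.chrom,
                    "pos": panel.positions,
                    "pool_id": pool_id,
                    "arm": arm,
                    "n_alleles": n_alleles,
                    "true_af": truth,
                    "af_estimate": estimate,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def combine_pools(pool_af: pd.DataFrame) -> pd.DataFrame:
    """Collapse per-pool estimates into one variant table (arm-level AFs).

    Arm frequencies are allele-count-weighted means over the arm's pools;
    allele totals are summed.  Output carries the canonical variant-table
    columns with region_class defaulting to 'candidate'.
    """
    def _arm(df: pd.DataFrame, arm: str) -> pd.DataFrame:
        sub = df[df["arm"] == arm]
        grouped = sub.groupby("variant_id", sort=False).apply(
            lambda g: pd.Series(
                {
                    f"af_{arm}": np.average(g["af_estimate"], weights=g["n_alleles"]),
                    f"n_{arm}_alleles": int(g["n_alleles"].sum()),
                    f"true_af_{arm}": np.average(g["true_af"], weights=g["n_alleles"]),
                }
            ),
            include_groups=False,
        )
        return grouped

    meta = pool_af.drop_duplicates("variant_id")[["variant_id", "chrom", "pos"]]
    out = (
        meta.set_index("variant_id")
        .join(_arm(pool_af, "case"))
        .join(_arm(pool_af, "control"))
        .reset_index()
    )
    out["n_case_alleles"] = out["n_case_alleles"].astype(int)
    out["n_control_alleles"] = out["n_control_alleles"].astype(int)
    out["ref"] = "A"
    out["alt"] = "G"
    out["region_class"] = "candidate"
    return out


def gen_rare_variants(
    n_variants: int,
    n_case_alleles: int,
    n_control_alleles: int,
    freq_range: tuple[float, float] = (0.001, 0.008),
    region_class: str = "candidate",
    conserved_fraction: float = 0.5,
    chrom: str = "chr2",
    pos_start: int = 200_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Variant-table rows for rare alleles observed in the pools.

    Rare variants are simulated directly at the allele-count level: each
    draws a true population frequency uniform on ``freq_range`` and
    per-arm counts binomially; the pool estimate is the count over the arm
    allele total (rare counts sit on the singleton grid, where the additive
    Gaussian estimation error is irrelevant compared to one allele).
    A ``conserved`` flag is assigned to a fixed fraction of rows.
    """
    rng = np.random.default_rng(seed)
    q = rng.uniform(*freq_range, size=n_variants)
    c_case = rng.binomial(n_case_alleles, q)
    c_ctrl = rng.binomial(n_control_alleles, q)
    conserved = rng.random(n_variants) < conserved_fraction
    return pd.DataFrame(
        {
            "variant_id": [f"rare_{region_class}_{i:03d}" for i in range(n_variants)],
            "chrom": chrom,
            "pos": pos_start + np.arange(n_variants) * 37,
            "ref": "C",
            "alt": "T",
            "af_case": c_case / n_case_alleles,
            "af_control": c_ctrl / n_control_alleles,
            "n_case_alleles": n_case_alleles,
            "n_control_alleles": n_control_alleles,
            "region_class": region_class,
            "conserved": conserved,
        }
    )


# ------------------------------------------------------------- calibration
def gen_spikein_scores(
    n_pos: int = 13, n_neg: int = 50, separation: float = 10.0, seed: int = 0
) -> pd.DataFrame:
    """Labelled variant-quality scores for spiked positive/negative controls.

    Negative-control scores are uniform on [10, 30]; positive-control
    scores are uniform on [30 + separation, 50 + separation].  A positive
    separation therefore guarantees that the lowest positive score exceeds
    the highest negative score; a negative separation yields overlapping
    distributions.  Columns: label ('positive'/'negative'), score.
    """
    if n_pos < 1 or n_neg < 1:
        raise ValueError("control counts must be >= 1")
    rng = np.random.default_rng(seed)
    neg = rng.uniform(10.0, 30.0, size=n_neg)
    pos = rng.uniform(30.0 + separation, 50.0 + separation, size=n_pos)
    return pd.DataFrame(
        {
            "label": ["positive"] * n_pos + ["negative"] * n_neg,
            "score": np.concatenate([pos, neg]),
        }
    )


# ------------------------------------- individual-level genotype validation
def gen_validation_genotypes(
    cohort: pd.DataFrame,
    n_tags_risk: int = 3,
    n_tags_protective: int = 3,
    n_recombinant: tuple[int, int] = (2, 7),
    n_low_quality: tuple[int, int] = (1, 3),
    seed: int = 0,
) -> pd.DataFrame:
    """Individual-level tag-SNP genotype table derived from a cohort.

    Each individual's dosage is replicated across the tags of each set
    (intact haplotypes carry all their tags together).  ``n_recombinant``
    (cases, controls) individuals get one discordant tag dosage, and
    ``n_low_quality`` individuals get a missing value, exercising the
    exclusion steps of the validation analysis.  Tag columns are named
    rtag1.. and ptag1..
    """
    rng = np.random.default_rng(seed)
    df = cohort[["individual_id", "status", "dosage_risk", "dosage_prot"]].copy()
    for i in range(n_tags_risk):
        df[f"rtag{i + 1}"] = df["dosage_risk"].astype(float)
    for i in range(n_tags_protective):
        df[f"ptag{i + 1}"] = df["dosage_prot"].astype(float)

    def _pick(status: int, n: int, taken: set[int]) -> list[int]:
        pool = [i for i in np.flatnonzero((df["status"] == status).to_numpy())
                if i not in taken]
        if len(pool) < n:
            raise ValueError("not enough individuals for requested perturbations")
        chosen = rng.choice(len(pool), size=n, replace=False)
        return [pool[int(j)] for j in chosen]

    taken: set[int] = set()
    for status, n in ((1, n_recombinant[0]), (0, n_recombinant[1])):
        for row in _pick(status, n, taken):
            taken.add(row)
            col = f"rtag{int(rng.integers(1, n_tags_risk + 1))}"
            cur = df.at[row, col]
            df.at[row, col] = cur + 1 if cur < 2 else cur - 1
    for status, n in ((1, n_low_quality[0]), (0, n_low_quality[1])):
        for row in _pick(status, n, taken):
            taken.add(row)
            df.at[row, f"ptag{int(rng.integers(1, n_tags_protective + 1))}"] = np.nan
    return df.drop(columns=["dosage_risk", "dosage_prot"])


def replica_validation_genotypes() -> pd.DataFrame:
    """Synthetic replica of the individual-level tag-genotype validation table.

    The real study's supplementary genotype table is not redistributable, so
    this deterministic stand-in reproduces its *structure* and headline
    numbers: after dropping 4 low-quality individuals (1 case, 3 controls)
    and 9 recombinants (2 cases, 7 controls), the remaining covariate
    patterns have empirical odds exactly consistent with per-haplotype odds
    ratios 1.89 (risk) and 0.50 (protective), so the joint binomial GLM
    recovers those values.  Columns match :func:`gen_validation_genotypes`.
    """
    rows: list[dict] = []

    def add(n: int, status: int, d_risk, d_prot) -> None:
        for _ in range(n):
            rows.append(
                dict(status=status, rtag1=d_risk, rtag2=d_risk, rtag3=d_risk,
                     ptag1=d_prot, ptag2=d_prot, ptag3=d_prot)
            )

    # covariate cells with odds 2/3 (baseline), 2/3 * 1.89, 2/3 * 0.50
    add(60, 1, 0.0, 0.0)
    add(90, 0, 0.0, 0.0)
    add(63, 1, 1.0, 0.0)
    add(50, 0, 1.0, 0.0)
    add(21, 1, 0.0, 1.0)
    add(63, 0, 0.0, 1.0)
    df = pd.DataFrame(rows)
    # recombinants: discordant within the risk tag set (2 cases, 7 controls)
    recomb = []
    for status, n in ((1, 2), (0, 7)):
        for _ in range(n):
            recomb.append(
                dict(status=status, rtag1=1.0, rtag2=1.0, rtag3=0.0,
                     ptag1=0.0, ptag2=0.0, ptag3=0.0)
            )
    # low-quality individuals: missing genotype at one tag (1 case, 3 controls)
    lowq = []
    for status, n in ((1, 1), (0, 3)):
        for _ in range(n):
            lowq.append(
                dict(status=status, rtag1=0.0, rtag2=0.0, rtag3=0.0,
                     ptag1=np.nan, ptag2=0.0, ptag3=0.0)
            )
    df = pd.concat([df, pd.DataFrame(recomb), pd.DataFrame(lowq)], ignore_index=True)
    df.insert(0, "individual_id", [f"V{i:04d}" for i in range(len(df))])
    return df
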