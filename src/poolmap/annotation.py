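"""Regulatory annotation of candidate variants.

Covers selection of conserved candidate regions from PhastCons-style
elements, per-site conservation flags from PhyloP-style P-values,
transcription-factor binding-site disruption scoring with position weight
matrices (ancestral vs derived allele), overlap with regulatory intervals
(open chromatin / bound sequence), and identification of variants private
to a single major haplotype.

Intervals follow the BED convention (0-based half-open).  A position is
deemed inside an interval when start <= pos < end; the rule lives in one
helper (:func:`position_in_interval`) so every overlap decision in the
package shares the same boundary semantics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from poolmap.haplotypes import HaplotypeGroup
from poolmap.panel import HaplotypePanel

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
_BASES = "ACGT"


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval with an optional class label."""

    chrom: str
    start: int  # 0-based inclusive
    end: int  # exclusive
    score: float | None = None
    interval_class: Literal["candidate", "flanking", "regulatory"] = "candidate"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("interval start must be < end")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class PWM:
    """Position weight matrix: per-position log-odds score for A, C, G, T."""

    motif_id: str
    matrix: np.ndarray  # (length, 4)
    source_tf: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "matrix", np.asarray(self.matrix, dtype=float))
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("PWM matrix must have shape (length, 4)")
        if self.matrix.shape[0] < 1 or not np.isfinite(self.matrix).all():
            raise ValueError("PWM needs >= 1 position with finite scores")

    def __len__(self) -> int:
        return self.matrix.shape[0]

    def reverse_complement(self) -> "PWM":
        """The matrix scoring the reverse strand (reversed, A<->T, C<->G)."""
        return PWM(self.motif_id, self.matrix[::-1, ::-1], self.source_tf)


@dataclass(frozen=True)
class BindingDelta:
    """Binding-score change between ancestral and derived alleles."""

    motif_id: str
    score_ancestral: float
    score_derived: float
    percent_change: float
    n_hits: int
    excluded: bool
    exclusion_reason: str = ""


def position_in_interval(pos: int, start: int, end: int) -> bool:
    """Half-open containment: start <= pos < end (end exclusive)."""
    return start <= pos < end


def select_candidate_regions(
    elements: Sequence[GenomicInterval],
    min_len: int = 50,
    max_gap: int = 200,
) -> list[GenomicInterval]:
    """Select conserved elements worth sequencing.

    An element qualifies on its own when longer than ``min_len`` bp, or as a
    member of a cluster: a run of elements separated by gaps < ``max_gap``
    whose summed element length exceeds ``min_len``.  Input must be sorted
    and non-overlapping per chromosome.
    """
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for el in elements:
        by_chrom.setdefault(el.chrom, []).append(el)
    selected: list[GenomicInterval] = []
    for chrom_elements in by_chrom.values():
        prev_end = None
        for el in chrom_elements:
            if prev_end is not None and el.start < prev_end:
                raise ValueError("elements must be sorted and non-overlapping")
            prev_end = el.end
        # split into gap-defined clusters
        cluster: list[GenomicInterval] = []
        clusters: list[list[GenomicInterval]] = []
        for el in chrom_elements:
            if cluster and el.start - cluster[-1].end >= max_gap:
                clusters.append(cluster)
                cluster = []
            cluster.append(el)
        if cluster:
            clusters.append(cluster)
        for cl in clusters:
            span = sum(el.length for el in cl)
            cluster_ok = len(cl) > 1 and span > min_len
            for el in cl:
                if el.length > min_len or cluster_ok:
                    selected.append(el)
    return selected


def flag_conserved_sites(
    scores: pd.DataFrame, alpha: float = 0.05
) -> tuple[pd.Series, int]:
    """Flag evolutionarily conserved sites from per-site P-values.

    ``scores`` needs columns ``pos`` and ``p_value``; a site is conserved
    when its P-value is strictly below ``alpha``.  Missing (NaN) scores are
    left unflagged and counted.  Returns (boolean Series indexed by pos,
    number of missing sites).
    """
    p = scores["p_value"]
    if ((p < 0) | (p > 1)).any():
        raise ValueError("P-values must lie in [0, 1]")
    flags = (p < alpha).fillna(False)
    flags.index = scores["pos"].to_numpy()
    return flags, int(p.isna().sum())


def _best_window_score(pwm: PWM, sequence: str) -> float:
    """Max additive matrix score over all windows of both strands."""
    idx = np.array([_BASES.index(b) for b in sequence.upper()], dtype=int)
    k = len(pwm)
    if idx.size < k:
        raise ValueError("sequence shorter than the motif")
    best = -np.inf
    for matrix in (pwm.matrix, pwm.reverse_complement().matrix):
        col_scores = matrix[np.arange(k)[:, None], idx[None, :]]  # (k, L)
        for start in range(idx.size - k + 1):
            score = float(col_scores[np.arange(k), start + np.arange(k)].sum())
            best = max(best, score)
    return best


def _count_hits(pwm: PWM, sequence: str, hit_threshold: float) -> int:
    """Number of windows (either strand) scoring >= hit_threshold."""
    idx = np.array([_BASES.index(b) for b in sequence.upper()], dtype=int)
    k = len(pwm)
    hits = 0
    for matrix in (pwm.matrix, pwm.reverse_complement().matrix):
        for start in range(idx.size - k + 1):
            window = idx[start : start + k]
            if float(matrix[np.arange(k), window].sum()) >= hit_threshold:
                hits += 1
    return hits


def pwm_binding_delta(
    pwm: PWM,
    sequence_ancestral: str,
    sequence_derived: str,
    max_hits: int = 20,
    hit_fraction: float = 0.8,
) -> BindingDelta:
    """Score the binding-site disruption caused by a single-base change.

    The binding score of an allele is the maximum windowed sum of matrix
    scores over both strands of its sequence ("binding energy" in the
    additive log-odds sense).  The reported change is
    (ancestral - derived) / ancestral x 100 (positive = derived allele
    weakens binding).  Two filters mirror standard motif-scan hygiene:
    alleles scoring identically are excluded (the variant cannot matter to
    this motif), and motifs with more than ``max_hits`` windows scoring
    above ``hit_fraction`` of the motif's maximum are excluded as
    non-specific.
    """
    if len(sequence_ancestral) != len(sequence_derived):
        raise ValueError("allele sequences must have equal length")
    diffs = sum(a != b for a, b in zip(sequence_ancestral, sequence_derived))
    if diffs > 1:
        raise ValueError("allele sequences must differ at one position at most")
    score_anc = _best_window_score(pwm, sequence_ancestral)
    score_der = _best_window_score(pwm, sequence_derived)
    hit_threshold = hit_fraction * float(pwm.matrix.max(axis=1).sum())
    n_hits = max(
        _count_hits(pwm, sequence_ancestral, hit_threshold),
        _count_hits(pwm, sequence_derived, hit_threshold),
    )
    if score_anc > 0:
        percent = (score_anc - score_der) / score_anc * 100.0
    else:
        percent = float("nan")
    excluded, reason = False, ""
    if score_anc == score_der:
        excluded, reason = True, "equivalent score for both alleles"
    elif n_hits > max_hits:
        excluded, reason = True, f"non-specific motif ({n_hits} hits > {max_hits})"
    return BindingDelta(
        motif_id=pwm.motif_id,
        score_ancestral=score_anc,
        score_derived=score_der,
        percent_change=percent,
        n_hits=n_hits,
        excluded=excluded,
        exclusion_reason=reason,
    )


def regulatory_overlap(
    variants: pd.DataFrame, regulatory: Sequence[GenomicInterval]
) -> pd.Series:
    """Flag variants falling inside any regulatory interval.

    ``variants`` needs ``chrom`` and ``pos`` columns.  Containment uses the
    package-wide half-open rule (start <= pos < end).  Returns a boolean
    Series aligned with the variant table.
    """
    flags = np.zeros(len(variants), dtype=bool)
    pos = variants["pos"].to_numpy()
    chrom = variants["chrom"].to_numpy()
    for iv in regulatory:
        flags |= (chrom == iv.chrom) & (pos >= iv.start) & (pos < iv.end)
    return pd.Series(flags, index=variants.index, name="regulatory")


def exclusive_to_haplotype(
    panel: HaplotypePanel, hap_groups: Sequence[HaplotypeGroup]
) -> dict[str, list[str]]:
    """Variants whose derived allele is private to one major haplotype.

    A site qualifies for a major haplotype when every chromosome carrying
    the derived allele belongs to that haplotype's group — strictly: one
    extra carrier on a rare chromosome disqualifies the site.  Returns
    {haplotype label: [site ids]} for the major groups.
    """
    out: dict[str, list[str]] = {}
    carriers_by_site = [
        set(np.flatnonzero(panel.haplotypes[:, j]).tolist())
        for j in range(panel.n_sites)
    ]
    for group in hap_groups:
        if not group.is_major:
            continue
        members = set(group.chromosome_indices)
        private = [
            panel.site_ids[j]
            for j, carriers in enumerate(carriers_by_site)
            if carriers and carriers <= members
        ]
        out[group.label] = private
    return out
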