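"""Readers and writers for the pipeline's plain-text formats.

Tabular inputs (variant, pool, genotype, concordance, spike-in tables) are
TSV read through pandas; interval tracks are BED (0-based half-open);
position weight matrices use a small text format of one ``>motif_id  tf``
header line followed by one whitespace-separated ``A C G T`` score row per
motif position.  Reports are JSON written with sorted keys so identical
runs produce byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from poolmap.annotation import PWM, GenomicInterval

REQUIRED_VARIANT_COLUMNS = [
    "variant_id",
    "chrom",
    "pos",
    "af_case",
    "af_control",
    "n_case_alleles",
    "n_control_alleles",
]


def read_variant_table(path) -> pd.DataFrame:
    """Read the per-variant TSV, validating the canonical columns."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in REQUIRED_VARIANT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"variant table {path} lacks columns: {missing}")
    if "region_class" not in df.columns:
        df["region_class"] = "candidate"
    return df


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_spikein_scores(path) -> tuple[list[float], list[float]]:
    """Read a (label, score) control TSV into positive and negative lists."""
    df = pd.read_csv(path, sep="\t")
    if not {"label", "score"} <= set(df.columns):
        raise ValueError("spike-in table needs 'label' and 'score' columns")
    pos = df.loc[df["label"] == "positive", "score"].tolist()
    neg = df.loc[df["label"] == "negative", "score"].tolist()
    return pos, neg


def read_concordance_table(path) -> pd.DataFrame:
    """Read the observed/expected allele-frequency concordance TSV."""
    df = pd.read_csv(path, sep="\t")
    needed = {"variant_id", "observed_af", "expected_af", "arm"}
    if not needed <= set(df.columns):
        raise ValueError(f"concordance table needs columns {sorted(needed)}")
    return df


def read_genotype_table(path) -> pd.DataFrame:
    """Read the individual-level tag-dosage TSV (individual_id, status, tags)."""
    df = pd.read_csv(path, sep="\t")
    if not {"individual_id", "status"} <= set(df.columns):
        raise ValueError("genotype table needs 'individual_id' and 'status' columns")
    return df


def read_bed(path, interval_class: str = "candidate") -> list[GenomicInterval]:
    """Read a BED file into intervals.

    A 4th (name) column equal to 'candidate', 'flanking' or 'regulatory'
    overrides ``interval_class``; a 5th column is kept as the score.
    """
    intervals: list[GenomicInterval] = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed BED line: {line!r}")
        cls = interval_class
        if len(parts) >= 4 and parts[3] in ("candidate", "flanking", "regulatory"):
            cls = parts[3]
        score = (
            float(parts[4]) if len(parts) >= 5 and parts[4] not in (".", "") else None
        )
        intervals.append(
            GenomicInterval(
                chrom=parts[0],
                start=int(parts[1]),
                end=int(parts[2]),
                score=score,
                interval_class=cls,  # type: ignore[arg-type]
            )
        )
    return intervals


def write_bed(intervals: Sequence[GenomicInterval], path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            score = "." if iv.score is None else f"{iv.score:g}"
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.interval_class}\t{score}\n")


def read_pwms(path) -> list[PWM]:
    """Read one or more PWMs from the package's matrix text format."""
    pwms: list[PWM] = []
    motif_id, source_tf, rows = None, "", []

    def _flush() -> None:
        if motif_id is not None:
            if not rows:
                raise ValueError(f"PWM {motif_id} has no score rows")
            pwms.append(PWM(motif_id, np.array(rows, dtype=float), source_tf))

    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith(">"):
            _flush()
            head = line[1:].split()
            motif_id = head[0]
            source_tf = head[1] if len(head) > 1 else ""
            rows = []
        else:
            values = [float(v) for v in line.split()]
            if len(values) != 4:
                raise ValueError("each PWM row needs exactly 4 scores (A C G T)")
            rows.append(values)
    _flush()
    if not pwms:
        raise ValueError(f"no PWM found in {path}")
    return pwms


def write_json_report(obj: dict, path) -> None:
    """Serialize a report deterministically (sorted keys, fixed separators)."""
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_default)
        fh.write("\n")
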