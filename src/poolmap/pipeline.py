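"""End-to-end orchestration of the fine-mapping stages.

One YAML configuration drives the run: quality calibration from spike-in
controls, the common-variant association scan, rare-variant burden tests,
haplotype mapping (clustering, tag selection, pool-frequency estimation,
Fisher and conditional tests, recombinant exclusion, joint GLM), and
regulatory annotation.  Every stage writes its own TSV/JSON output under
the configured directory and a consolidated JSON report ties them
together.  Identical config + seed produces byte-identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from poolmap import annotation as ann
from poolmap import association, haplotypes, io, pool_model, rare_burden
from poolmap.panel import HaplotypePanel

log = logging.getLogger("poolmap")


class ConfigurationError(ValueError):
    """Invalid or incomplete pipeline configuration."""


class StageError(RuntimeError):
    """A pipeline stage failed; the message is stage-labelled."""


@dataclass
class PipelineConfig:
    """Paths and parameters for one fine-mapping run."""

    panel_vcf: Path
    variants: Path
    spikein: Path
    output_dir: Path
    genotypes: Path | None = None
    regions_bed: Path | None = None
    conservation: Path | None = None
    regulatory_bed: Path | None = None
    concordance: Path | None = None
    seed: int = 0
    params: dict[str, Any] = field(default_factory=dict)

    DEFAULT_PARAMS = {
        "maf_cutoff_common": 0.05,
        "rare_maf_cutoff": 0.01,
        "r2_cutoff": 0.9,
        "hap_freq_cutoff": 0.05,
        "conserved_alpha": 0.05,
        "coverage_threshold": 30.0,
        "se_case": 0.00081,
        "se_control": 0.00032,
        "tag_ids": None,
        "risk_tag_cols": None,
        "protective_tag_cols": None,
        "exclude_recombinants": True,
    }

    def param(self, key: str):
        return self.params.get(key, self.DEFAULT_PARAMS[key])

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        inputs = raw.get("inputs", {})
        base = Path(path).parent

        def _p(key: str, required: bool = False) -> Path | None:
            val = inputs.get(key)
            if val is None:
                if required:
                    raise ConfigurationError(f"config lacks required input '{key}'")
                return None
            p = Path(val)
            return p if p.is_absolute() else base / p

        out = raw.get("output_dir", "finemap_out")
        out_path = Path(out) if Path(out).is_absolute() else base / out
        return cls(
            panel_vcf=_p("panel_vcf", required=True),
            variants=_p("variants", required=True),
            spikein=_p("spikein", required=True),
            genotypes=_p("genotypes"),
            regions_bed=_p("regions_bed"),
            conservation=_p("conservation"),
            regulatory_bed=_p("regulatory_bed"),
            concordance=_p("concordance"),
            output_dir=out_path,
            seed=int(raw.get("seed", 0)),
            params=raw.get("params", {}) or {},
        )

    def validate(self) -> None:
        for name in ("panel_vcf", "variants", "spikein", "genotypes", "regions_bed",
                     "conservation", "regulatory_bed", "concordance"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise ConfigurationError(f"input path for '{name}' does not exist: {p}")


def _annotate_regions(variants: pd.DataFrame, cfg: PipelineConfig) -> pd.DataFrame:
    """Attach region_class (from BED) and conserved flags (from PhyloP P)."""
    df = variants.copy()
    if cfg.regions_bed is not None:
        intervals = io.read_bed(cfg.regions_bed)
        cls = np.full(len(df), "flanking", dtype=object)
        for iv in intervals:
            if iv.interval_class == "regulatory":
                continue
            inside = (df["chrom"].to_numpy() == iv.chrom) & (
                (df["pos"].to_numpy() >= iv.start) & (df["pos"].to_numpy() < iv.end)
            )
            cls[inside] = iv.interval_class
        df["region_class"] = cls
    if cfg.conservation is not None:
        scores = pd.read_csv(cfg.conservation, sep="\t")
        flags, _ = ann.flag_conserved_sites(scores, cfg.param("conserved_alpha"))
        df["conserved"] = df["pos"].map(flags).fillna(False).astype(bool)
    elif "conserved" not in df.columns:
        df["conserved"] = False
    return df


def run_fine_mapping(cfg: PipelineConfig) -> dict:
    """Execute all stages in order and return the consolidated report."""
    cfg.validate()
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {"seed": cfg.seed}

    # ---- stage 1: calibration ------------------------------------------
    try:
        pos, neg = io.read_spikein_scores(cfg.spikein)
        calib = pool_model.calibrate_quality_cutoffs(pos, neg)
        report["calibration"] = {
            "high_cutoff": calib.high_cutoff,
            "low_cutoff": calib.low_cutoff,
            "separable": calib.separable,
            "n_positive": len(pos),
            "n_negative": len(neg),
        }
        se_case, se_control = cfg.param("se_case"), cfg.param("se_control")
        if cfg.concordance is not None:
            conc = io.read_concordance_table(cfg.concordance)
            by_arm = {}
            for arm in ("case", "control"):
                sub = conc[conc["arm"] == arm]
                if len(sub):
                    by_arm[arm] = pool_model.estimate_estimation_error(
                        sub["observed_af"], sub["expected_af"]
                    )
            se_case = by_arm.get("case", se_case)
            se_control = by_arm.get("control", se_control)
            report["calibration"]["se_case"] = se_case
            report["calibration"]["se_control"] = se_control
        io.write_json_report(report["calibration"], out / "calibration.json")
    except (OSError, ValueError) as exc:
        raise StageError(f"calibration stage failed: {exc}") from exc

    se = pool_model.EstimationError(se_case=se_case, se_control=se_control)

    # ---- stage 2: association scan -------------------------------------
    try:
        variants = _annotate_regions(io.read_variant_table(cfg.variants), cfg)
        tag_ids = cfg.param("tag_ids")
        if not tag_ids:
            raise ValueError("params.tag_ids must list the reference tag SNPs")
        scan, n_strong = association.scan_common_variants(
            variants, se, list(tag_ids), cfg.param("maf_cutoff_common")
        )
        io.write_table(scan, out / "assoc_scan.tsv")
        report["association"] = {
            "n_tested": int(len(scan)),
            "tag_threshold_p": scan.attrs["tag_threshold"],
            "n_stronger_than_tags": n_strong,
            "top_variant": scan.iloc[0]["variant_id"],
            "top_p": float(scan.iloc[0]["p_value"]),
        }
    except (OSError, ValueError, KeyError) as exc:
        raise StageError(f"association stage failed: {exc}") from exc

    # ---- stage 3: rare-variant burden -----------------------------------
    try:
        filters = ["all", "flanking"]
        if "conserved" in variants.columns and variants["conserved"].any():
            filters.insert(1, "conserved")
        burden = rare_burden.burden_table(
            variants, tuple(filters), cfg.param("rare_maf_cutoff")
        )
        io.write_table(burden, out / "rare_burden.tsv")
        exclusive = rare_burden.exclusive_variant_table(variants)
        io.write_table(exclusive, out / "exclusive_variants.tsv")
        report["rare_burden"] = {
            row["region"]: {
                "n_case": int(row["n_case"]),
                "n_control": int(row["n_control"]),
                "odds_ratio": None if np.isnan(row["odds_ratio"]) else float(row["odds_ratio"]),
                "p_one_tail": None if np.isnan(row["p_one_tail"]) else float(row["p_one_tail"]),
            }
            for _, row in burden.iterrows()
        }
        report["rare_burden"]["n_exclusive"] = int(len(exclusive))
    except (OSError, ValueError) as exc:
        raise StageError(f"rare-burden stage failed: {exc}") from exc

    # ---- stage 4: haplotype mapping -------------------------------------
    try:
        panel = HaplotypePanel.from_vcf(cfg.panel_vcf)
        groups, coverage = haplotypes.cluster_major_haplotypes(
            panel, freq_cutoff=cfg.param("hap_freq_cutoff")
        )
        majors = [g for g in groups if g.is_major]
        af_case = dict(zip(variants["variant_id"], variants["af_case"]))
        af_ctrl = dict(zip(variants["variant_id"], variants["af_control"]))
        n_case = int(variants["n_case_alleles"].iloc[0])
        n_ctrl = int(variants["n_control_alleles"].iloc[0])
        hap_report: dict[str, Any] = {
            "n_major": len(majors),
            "major_coverage": coverage,
            "haplotypes": {},
        }
        counts_case: dict[str, int] = {}
        counts_ctrl: dict[str, int] = {}
        assoc_by_hap: dict[str, haplotypes.HaplotypeAssociation] = {}
        for g in majors:
            tags = haplotypes.select_tag_snps(panel, g, cfg.param("r2_cutoff"))
            entry: dict[str, Any] = {
                "panel_frequency": g.frequency,
                "n_tags": len(tags),
                "tag_snps": list(tags.snp_ids),
            }
            if len(tags) == 0:
                entry["note"] = "no tag SNP at the r2 cutoff; haplotype not testable"
                hap_report["haplotypes"][g.label] = entry
                continue
            est_case = haplotypes.estimate_haplotype_frequencies(
                tags, {k: af_case[k] for k in tags.snp_ids if k in af_case}
            )
            est_ctrl = haplotypes.estimate_haplotype_frequencies(
                tags, {k: af_ctrl[k] for k in tags.snp_ids if k in af_ctrl}
            )
            res = haplotypes.haplotype_fisher_test(
                est_case.frequency, n_case, est_ctrl.frequency, n_ctrl, hap_id=g.label
            )
            assoc_by_hap[g.label] = res
            counts_case[g.label] = pool_model._round_half_away(est_case.frequency * n_case)
            counts_ctrl[g.label] = pool_model._round_half_away(est_ctrl.frequency * n_ctrl)
            entry.update(
                freq_case=res.freq_case,
                freq_control=res.freq_control,
                odds_ratio=None if not res.or_defined else res.odds_ratio,
                ci95=None if not res.or_defined else list(res.ci95),
                p_fisher=res.p_fisher,
                tag_spread_case=est_case.spread,
            )
            hap_report["haplotypes"][g.label] = entry
        counts_case["other"] = n_case - sum(counts_case.values())
        counts_ctrl["other"] = n_ctrl - sum(counts_ctrl.values())

        tested = [h for h in assoc_by_hap if assoc_by_hap[h].or_defined]
        risk_label = max(tested, key=lambda h: assoc_by_hap[h].odds_ratio, default=None)
        prot_label = min(tested, key=lambda h: assoc_by_hap[h].odds_ratio, default=None)
        if risk_label and prot_label and risk_label != prot_label:
            for target, excluded in ((risk_label, prot_label), (prot_label, risk_label)):
                c_or, c_p = haplotypes.conditional_independence_test(
                    counts_case, counts_ctrl, target, excluded
                )
                hap_report["haplotypes"][target]["conditional_or"] = c_or
                hap_report["haplotypes"][target]["conditional_p"] = c_p
            hap_report["risk_haplotype"] = risk_label
            hap_report["protective_haplotype"] = prot_label

        if cfg.genotypes is not None:
            geno = io.read_genotype_table(cfg.genotypes)
            risk_cols = cfg.param("risk_tag_cols") or [
                c for c in geno.columns if c.startswith("rtag")
            ]
            prot_cols = cfg.param("protective_tag_cols") or [
                c for c in geno.columns if c.startswith("ptag")
            ]
            tag_cols = list(risk_cols) + list(prot_cols)
            complete = geno.dropna(subset=tag_cols)
            n_lowq = len(geno) - len(complete)
            recomb = haplotypes.detect_recombinants(complete, risk_cols, prot_cols)
            glm_input = complete
            if cfg.param("exclude_recombinants"):
                glm_input = complete[~complete["individual_id"].isin(recomb)]
            glm_input = glm_input.assign(
                dosage_risk=glm_input[risk_cols].max(axis=1).astype(int),
                dosage_prot=glm_input[prot_cols].max(axis=1).astype(int),
            )
            glm = haplotypes.joint_glm_test(glm_input)
            hap_report["validation"] = {
                "n_individuals": int(len(geno)),
                "n_low_quality_excluded": int(n_lowq),
                "n_recombinant": len(recomb),
                "recombinants_excluded": bool(cfg.param("exclude_recombinants")),
                "glm": glm,
            }
        io.write_json_report(hap_report, out / "haplotypes.json")
        report["haplotype_mapping"] = hap_report
    except (OSError, ValueError, KeyError) as exc:
        raise StageError(f"haplotype stage failed: {exc}") from exc

    # ---- stage 5: annotation --------------------------------------------
    try:
        ann_df = variants[["variant_id", "chrom", "pos", "region_class", "conserved"]].copy()
        if cfg.regulatory_bed is not None:
            reg = [
                iv for iv in io.read_bed(cfg.regulatory_bed, "regulatory")
            ]
            ann_df["regulatory"] = ann.regulatory_overlap(ann_df, reg)
        else:
            ann_df["regulatory"] = False
        private = ann.exclusive_to_haplotype(panel, groups)
        hap_of_site = {
            sid: label for label, sites in private.items() for sid in sites
        }
        ann_df["private_to"] = ann_df["variant_id"].map(hap_of_site).fillna("")
        io.write_table(ann_df, out / "annotation.tsv")
        report["annotation"] = {
            "n_conserved": int(ann_df["conserved"].sum()),
            "n_regulatory": int(ann_df["regulatory"].sum()),
            "private_variants": {k: len(v) for k, v in private.items()},
        }
    except (OSError, ValueError, KeyError) as exc:
        raise StageError(f"annotation stage failed: {exc}") from exc

    io.write_json_report(report, out / "report.json")
    return report
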