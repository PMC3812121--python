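"""Phased haplotype reference panel over a genomic interval.

The panel is the in-memory analog of a phased VCF restricted to biallelic
SNPs: an (n_chromosomes x n_sites) 0/1 matrix plus site metadata.  Rows are
phased chromosomes (two consecutive rows per individual when written to or
read from VCF); columns are sites ordered by position.  Allele 1 is the
derived (alternate) allele throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class HaplotypePanel:
    """Phased chromosomes x biallelic sites over a fine-mapped interval.

    Attributes
    ----------
    haplotypes :
        int8 array of shape (n_chromosomes, n_sites), entries 0/1.
    site_ids :
        Variant identifiers, one per column.
    positions :
        1-based site positions, strictly increasing.
    chrom :
        Chromosome label shared by all sites.
    ancestral :
        Optional per-site ancestral allele code (0 or 1); -1 when unknown.
    """

    haplotypes: np.ndarray
    site_ids: list[str]
    positions: np.ndarray
    chrom: str = "chr2"
    ancestral: np.ndarray | None = None
    # indices (into major-haplotype ordering) designated by the generator
    risk_hap: int | None = field(default=None, compare=False)
    protective_hap: int | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if self.haplotypes.ndim != 2:
            raise ValueError("haplotypes must be a 2-D chromosome x site array")
        n_chrom, n_sites = self.haplotypes.shape
        if len(self.site_ids) != n_sites or len(self.positions) != n_sites:
            raise ValueError("site metadata length does not match haplotype columns")
        if not np.isin(self.haplotypes, (0, 1)).all():
            raise ValueError("panel alleles must be biallelic, coded 0/1")

    @property
    def n_chromosomes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.haplotypes.shape[1]

    def site_index(self, site_id: str) -> int:
        try:
            return self.site_ids.index(site_id)
        except ValueError:
            raise KeyError(f"unknown site id: {site_id}") from None

    def allele_frequencies(self) -> np.ndarray:
        """Derived-allele frequency per site across the panel."""
        return self.haplotypes.mean(axis=0)

    # ------------------------------------------------------------------ VCF
    def to_vcf(self, path) -> None:
        """Write the panel as an uncompressed phased VCF (GT fields "a|b").

        Chromosomes 2i and 2i+1 become the two phased alleles of sample i;
        the panel must therefore hold an even number of chromosomes.
        """
        if self.n_chromosomes % 2:
            raise ValueError("phased VCF output needs an even chromosome count")
        n_ind = self.n_chromosomes // 2
        samples = [f"IND{i:04d}" for i in range(n_ind)]
        lines = [
            "##fileformat=VCFv4.2",
            f"##contig=<ID={self.chrom}>",
            '##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">',
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples),
        ]
        alleles = ("A", "G")  # placeholder ref/alt bases; the 0/1 coding is what matters
        for j in range(self.n_sites):
            anc = -1 if self.ancestral is None else int(self.ancestral[j])
            info = "." if anc < 0 else f"AA={alleles[anc]}"
            gts = "\t".join(
                f"{self.haplotypes[2 * i, j]}|{self.haplotypes[2 * i + 1, j]}"
                for i in range(n_ind)
            )
            lines.append(
                f"{self.chrom}\t{self.positions[j]}\t{self.site_ids[j]}\t"
                f"{alleles[0]}\t{alleles[1]}\t.\tPASS\t{info}\tGT\t{gts}"
            )
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")

    @classmethod
    def from_vcf(cls, path) -> "HaplotypePanel":
        """Load a phased panel from a VCF of biallelic sites (via cyvcf2)."""
        from cyvcf2 import VCF

        vcf = VCF(str(path))
        columns: list[np.ndarray] = []
        site_ids: list[str] = []
        positions: list[int] = []
        ancestral: list[int] = []
        chrom = "chr2"
        for v in vcf:
            if len(v.ALT) != 1:
                raise ValueError(f"site {v.ID} is not biallelic")
            chrom = v.CHROM
            gts = np.array([g[:2] for g in v.genotypes], dtype=np.int8)
            if (gts < 0).any():
                raise ValueError(f"missing genotype at {v.ID}; panel must be complete")
            columns.append(gts.reshape(-1))
            site_ids.append(v.ID or f"{v.CHROM}:{v.POS}")
            positions.append(v.POS)
            aa = v.INFO.get("AA")
            if aa is None:
                ancestral.append(-1)
            else:
                ancestral.append(0 if aa == v.REF else 1)
        vcf.close()
        if not columns:
            raise ValueError("no sites found in panel VCF")
        return cls(
            haplotypes=np.column_stack(columns),
            site_ids=site_ids,
            positions=np.array(positions),
            chrom=chrom,
            ancestral=np.array(ancestral, dtype=np.int8),
        )
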