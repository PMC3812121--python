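# poolmap

Fine-mapping a disease-associated locus from **pooled-sequencing allele
frequencies**: calibrated variant detection, an association test that
propagates pooled estimation error, rare-variant burden collapsing, and
haplotype-level association through tag SNPs drawn from a phased reference
panel.

## Who this is for

Pooled sequencing genotypes a cohort by the pool: DNA from all cases (and,
separately, all controls) is sequenced together, so the data are per-variant
allele-frequency *estimates* rather than individual genotypes.  That design
is cheap enough to sequence a whole candidate locus deeply, but every
downstream statistic must account for the extra noise of estimating a
frequency from pooled reads, and haplotype effects can only be reached
indirectly through tag SNPs.  `poolmap` packages the full analysis layer
for such a study — it was built around a case/control fine-mapping design
with two sequencing pools per arm (254 case and 270 control alleles), a
phased reference panel of 186 chromosomes, and a locus whose common
variation collapses into four major haplotypes, one risk-promoting and one
protective.

## The core statistic

For case/control frequency estimates p_A, p_B over N_A, N_B alleles, with
pooled frequency p₀ = (p_A N_A + p_B N_B)/(N_A + N_B),

    σ_s² = p₀(1 − p₀)(1/N_A + 1/N_B)
    z    = (p_A − p_B) / √(σ_s² + s_e,A + s_e,B)

where s_e,A and s_e,B are per-arm estimation-error variances inferred as
the mean squared error of pooled estimates against genotype-based
frequencies on a concordance SNP set.  z is referred to the standard
normal (two-sided).  With s_e = 0 this is exactly the textbook pooled
two-proportion Z-test.

Around it: quality-cutoff calibration from spike-in controls, frequency
rounding to the singleton grid (1/2N), rare-variant collapsing with
one-tail Fisher exact burden tests, D′/r² LD statistics, major-haplotype
clustering and tag-SNP selection (r² > 0.9), haplotype frequency
estimation by tag averaging, Fisher and conditional-independence tests,
recombinant detection, a joint binomial GLM on individual tag genotypes,
and PWM-based binding-site disruption scoring.  A synthetic-data module
generates every input under a fixed seed, so the whole pipeline runs at
desk scale with no external data.

## Worked example

```python
from poolmap.association import modified_two_proportion_z
from poolmap import synthetic as syn
from poolmap.haplotypes import (cluster_major_haplotypes, select_tag_snps,
                                estimate_haplotype_frequencies,
                                haplotype_fisher_test)

# A common nonsynonymous variant: 50.2% in 254 case alleles vs 51.2% in
# 270 control alleles, estimation-error variances 0.00081 / 0.00032.
res = modified_two_proportion_z(0.502, 0.512, 254, 270, 0.00081, 0.00032)
print(f"z = {res.z:.3f}, two-sided P = {res.p_value:.2f}")

# A full synthetic study: panel -> cohort -> pooled estimates -> haplotypes.
panel = syn.gen_haplotype_panel(syn.PanelConfig(seed=0))
cohort = syn.gen_cohort(panel, syn.CohortConfig(seed=1))
pool_af = syn.gen_pooled_af(panel, cohort, syn.PoolNoiseConfig(seed=2))
variants = syn.combine_pools(pool_af)

groups, coverage = cluster_major_haplotypes(panel)
majors = [g for g in groups if g.is_major]
print(f"{len(majors)} major haplotypes cover {coverage:.1%} of panel chromosomes")

risk = majors[panel.risk_hap]
tags = select_tag_snps(panel, risk, r2_cutoff=0.9)
af_case = dict(zip(variants.variant_id, variants.af_case))
af_ctrl = dict(zip(variants.variant_id, variants.af_control))
fc = estimate_haplotype_frequencies(tags, af_case).frequency
fk = estimate_haplotype_frequencies(tags, af_ctrl).frequency
assoc = haplotype_fisher_test(fc, 254, fk, 270, hap_id=risk.label)
print(f"risk haplotype {risk.label}: {fc:.3f} (cases) vs {fk:.3f} (controls), "
      f"OR = {assoc.odds_ratio:.2f} (95% CI {assoc.ci95[0]:.2f}-{assoc.ci95[1]:.2f}), "
      f"Fisher P = {assoc.p_fisher:.2g}")
```

Output:

```
z = -0.181, two-sided P = 0.86
4 major haplotypes cover 76.9% of panel chromosomes
risk haplotype hap3: 0.236 (cases) vs 0.100 (controls), OR = 2.78 (95% CI 1.70-4.55), Fisher P = 3.3e-05
```

The first line says the variant shows no case/control difference once
sampling and pooled-estimation noise are both counted (z near zero, P
0.86).  The last line is one seeded realization of the synthetic study:
the planted risk haplotype is recovered at an elevated case frequency with
a significant Fisher test (the generating per-dosage odds ratio is 1.89;
single-replicate estimates scatter around the design value — see
`docs/methods.md`).

## Command line

```sh
finemap simulate --out demo --seed 7      # write a synthetic input bundle
finemap run --config demo/config.yaml     # run every stage, write reports
```

Individual stages are available as `finemap calibrate | assoc-scan |
rare-burden | haplotypes | annotate`, each a thin wrapper over the library.
Identical config and seed produce byte-identical outputs.

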