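# Methods

`poolmap` implements the statistical layer of a pooled-sequencing
fine-mapping study of a binary phenotype at a candidate locus: two pools of
case DNA and two pools of control DNA are sequenced, yielding per-variant
allele-frequency *estimates* rather than genotypes, and all downstream
inference must respect both the binomial sampling of alleles into the
cohort and the additional error of estimating a frequency from pooled
reads.

## The modified two-proportion Z-test

For a variant with case/control frequency estimates p_A, p_B over N_A, N_B
alleles, the pooled frequency is p_0 = (p_A N_A + p_B N_B)/(N_A + N_B) and

    sigma_s^2 = p_0 (1 - p_0) (1/N_A + 1/N_B)
    z = (p_A - p_B) / sqrt(sigma_s^2 + s_e,A + s_e,B)

with z referred to the standard normal (two-sided throughout; the scan and
the printed tables report two-sided style P-values).  The terms s_e,A and
s_e,B are per-arm *estimation-error variances* in squared-frequency units:
the mean squared difference between pooled estimates and genotype-based
frequencies over a concordance set of SNPs typed on both platforms
(`estimate_estimation_error`).  Treating s_e as a variance added directly
to the sampling variance is the only reading that reproduces the printed
P = 0.86 for the 0.502/0.512 variant at N = 254/270 with
s_e = 0.00081/0.00032, which the test suite pins down.  With s_e = 0 the
statistic reduces exactly to the textbook pooled two-proportion Z-test
(property-tested to 1e-12 relative error).

The estimation error is assumed additive, homoscedastic across sites, and
Gaussian where a distribution is required (synthetic generator); only its
second moment enters the test itself.

## Pool-level quality semantics

- **Quality cutoffs** are calibrated from spike-in controls: the
  high-quality (specificity-maximizing) cutoff is the lowest
  positive-control score; the lower (sensitivity-maximizing) cutoff is the
  highest negative-control score.  When the two control distributions
  overlap the calibration is flagged `separable=False` rather than guessing
  a cutpoint.
- **Frequency rounding**: raw pooled estimates are rounded to the nearest
  multiple of one singleton allele, 1/2N for a pool of N individuals.
  Half-way ties round away from zero (a documented choice; the convention
  is otherwise arbitrary).  Rounding is idempotent and moves an estimate by
  at most 1/(4N) on average, which matters only for the rarest alleles.
- **Coverage QC** flags sites strictly below a detection-saturation
  threshold, default 30 reads per site per allele.

## Rare-variant burden

Rare variants (minor-allele frequency strictly below 1% in *both* arms) are
collapsed per arm into a single pseudo-allele: collapsed AF = summed
minor-allele count / arm allele total; the per-arm "number" column counts
distinct qualifying variants observed in that arm.  The burden comparison
is a one-tail Fisher exact test on carrier counts reconstructed as
round(f x 2N) — frequencies are the only pool-level observable, so integer
counts must be reconstructed.  The tail direction is an explicit parameter
defaulting to the observed direction (depletion when the case collapsed
frequency is lower).  Site filters restrict the collapse to candidate
regions, conserved sites within candidate regions (PhyloP P < 0.05,
strict), or the flanking-region control, which under the null generator is
statistically indistinguishable from the candidate set.

## Haplotype mapping

Chromosomes of a phased reference panel are clustered by exact
allele-vector identity over the fine-mapped interval; clusters at frequency
>= 5% are "major" (ties count as major).  For each major haplotype, tag
SNPs are the panel sites whose allele indicator has r^2 > 0.9 with the
haplotype-membership indicator; the linked allele orientation is recorded.
A haplotype's pool frequency is the arithmetic mean of its oriented
tag-SNP pool frequencies; the per-tag values and their spread are reported
so a caller can recognize (and exclude) an outlying tag — exclusion is
deliberately left to the caller.

Association per haplotype is a two-sided Fisher exact test on counts
reconstructed as round(freq x 2N), with the odds ratio from the table
cross-product and a Wald (log-OR normal approximation) 95% CI — the CI
method is a package choice, as is count reconstruction.  Independence of
two haplotype effects is tested conditionally: chromosomes carrying the
excluded haplotype are removed from both denominators and the Fisher test
recomputed.

Individual-level validation uses a tag-genotype table: individuals with a
missing tag dosage are dropped; an individual is *recombinant* when
dosages differ within the risk tag set or within the protective tag set
(an intact haplotype carries all of its tags together — this
discordant-dosage rule is a documented reconstruction of the study
procedure, which did not spell its rule out).  After exclusions, a
binomial-family GLM of case status on the two haplotype dosages yields
per-haplotype odds ratios with Wald CIs; complete separation is flagged
with no estimate.

LD between two loci uses gamete counts: D = p_AB - p_A p_B, D' = |D|/D_max
with the frequency-bound maximum, r^2 = D^2 / (p_A q_A p_B q_B); both are
verified against a brute-force oracle that expands gamete lists.

## Annotation

Intervals follow BED (0-based half-open) conventions.  Containment of a
variant position in an interval is centralized in one helper and uses
`start <= pos < end` with the end exclusive — the boundary semantics the
whole package (and its tests) share.  Conserved-element selection keeps
any element longer than 50 bp, plus every member of a cluster (gaps
< 200 bp) whose summed element length exceeds 50 bp.

"Binding energy" for a transcription-factor motif is operationalized as
the maximum windowed sum of per-position log-odds matrix scores over both
strands of the allele's sequence; the reported disruption is
(ancestral - derived)/ancestral x 100.  Variants scoring identically for
both alleles are excluded, as are motifs with more than 20 windows scoring
above 80% of the motif's maximum (a non-specificity filter; the exact
scanning thresholds of published web tools are version-dependent, so these
defaults are documented rather than claimed identical).  Scoring is
strand-symmetric by construction and tested as such.

Haplotype-private variants use strict privacy: a derived allele qualifies
for a major haplotype only if *every* carrier chromosome belongs to that
haplotype's group — one carrier on a rare chromosome disqualifies the
site.

## Synthetic data: what it emulates and what it does not

The generator reproduces the statistical structure the analysis assumes,
at the study's own scale:

| quantity | default | why |
| --- | --- | --- |
| panel chromosomes | 186 | 93 phased reference individuals |
| panel sites | 39 | common SNPs segregating in the fine-mapped interval |
| major haplotype frequencies | 0.29, 0.23, 0.13, 0.12 | four majors jointly covering 77% of chromosomes |
| risk / protective haplotype | majors 3 and 4 | low-frequency haplotypes (~13%, ~12%) carrying the effects |
| cohort | 127 cases / 135 controls | study arm sizes |
| baseline prevalence | 0.055 | population rate of the phenotype in the source population |
| haplotype odds ratios | 1.89 / 0.50 | per-dosage effects of the risk and protective haplotypes |
| pool allele counts | 192 + 62 case, 150 + 120 control | two sequencing pools per arm |
| s_e (case / control) | 0.00081 / 0.00032 | estimation-error variances |

Each major haplotype is planted with at least one private derived allele,
so a perfect tag (r^2 = 1) always exists and tag selection at r^2 > 0.9 is
guaranteed feasible; remaining chromosomes are mutated copies of majors
with all private alleles removed (they can never silently rejoin a major
group).  Cohorts are drawn retrospectively: individuals are pairs of panel
chromosomes sampled with replacement, case status is Bernoulli under
logit P(case) = logit(prevalence) + d_r ln(OR_r) + d_p ln(OR_p), and
rejection sampling fills the requested arm counts.  Pool estimates add
Gaussian noise with variance s_e (a maximum-entropy choice; only the
variance is specified by the design), truncate to [0, 1], and round to the
singleton grid.

Two caveats the tests make explicit.  First, the *allelic* (per-chromosome,
retrospective) odds ratio implied by this disease model is not exactly the
per-dosage logistic odds ratio: at 5.5% prevalence the analytic allelic OR
for the risk haplotype is ~2.02 versus the generating 1.89; the test suite
compares Monte-Carlo output to the closed-form value, not to 1.89.  Second,
the generator works at the pool-frequency level — no reads, no alignment,
no base-calling error, uniform noise across sites, no linkage decay within
the interval, and no genotyping error in the validation table beyond the
injected missing values.  Passing tests therefore demonstrate correctness
of the statistical machinery under the stated model, not robustness to
read-level artifacts of real pooled sequencing.

`replica_validation_genotypes` is a deterministic *synthetic* stand-in for
the study's individual-level genotype validation table (the original is
not redistributable).  It reproduces the table's structure — 3 risk and 3
protective tag columns, 4 low-quality individuals with missing dosages, 9
recombinants (2 cases, 7 controls) — and its covariate-pattern odds are
constructed to be exactly consistent with per-haplotype odds ratios 1.89
and 0.50, so the GLM procedure (exclusions included) recovers those values
when, and only when, it is implemented correctly.

## Numerical choices and degenerate inputs

- Integer reconstruction everywhere uses round-half-away-from-zero.
- Fisher tests with a zero margin return P = 1 and an undefined-OR flag;
  odds ratios at boundary frequencies raise rather than return infinities.
- The scan's "stronger than the tags" comparison is strict (P strictly
  below the least-significant tag P); a variant identical to a tag does not
  beat it.
- Clustering ties at the major-haplotype cutoff (exactly 5%) are kept as
  major; group order is deterministic (descending size, then first
  chromosome index).
- GLM separation is detected via the fitting warning plus a parameter-
  magnitude guard, and reported as a flag instead of an estimate.
- All generators take explicit integer seeds and are bit-reproducible; the
  pipeline writes JSON with sorted keys so re-runs are byte-identical.

## Problem sizes

The test suite runs entirely at desk scale: the null-calibration and
recovery studies use 200–250 cohort replicates at the default 127/135
arm sizes, type-I error uses 10,000 vectorized null pool replicates, the
Fisher-vs-enumeration sweep covers every achievable table exhaustively to
total 24 plus ~2,000 seeded larger tables (to total 60), and the GLM
coverage study fits 200 replicates of 262 individuals.  The full suite
completes in well under a minute on one CPU.

## Known limitations

- Haplotype identity is exact vector match; partially observed or
  imputed chromosomes are not assigned (the reference analysis likewise
  left some chromosomes untagged).
- No statistical phasing, no read simulation, no covariate adjustment or
  genomic control, and no weighted or dispersion-type burden tests — the
  reference design uses none of these.
- The Wald CI on the log odds ratio is anti-conservative for very sparse
  tables; the coverage study shows it is adequate at the study's size.
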