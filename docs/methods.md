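# Methods

## AEI calling

At a heterozygous SNP covered by `n = Rx + Ax` reads, balanced allelic
expression implies `Rx ~ Binomial(n, 0.5)`.  The two-sided p-value is
defined as `min(1, 2·P(X ≥ max(Rx, Ax)))`; at q = 0.5 the null is
symmetric, so this doubled-tail convention coincides with the equal-tail
and minimum-likelihood definitions — it is fixed here for reproducibility.
The AEI decision uses strict inequality p < 0.01.

Loci with `Rx < 4`, `Ax < 4` or `n < 20` are removed before testing.  These
cut-offs suppress false calls at low coverage and guarantee a non-zero
minor-allele count, so major/minor ratios are always finite.  Because the
test is discrete, its realized false-call rate at depths ≥ 20 is below the
nominal 1% (about 0.6–0.8% under the default depth distribution); the
acceptance script recomputes this rate and the exact enumerated power at
θ = 0.8, depth 50.

**Gene aggregation.** Phasing is unavailable, so counts cannot be summed
across a gene's SNPs.  A gene is testable in a sample when at least one SNP
survives the filters; it is called AEI when any surviving SNP is
significant (a per-representative-SNP-only mode is available via
`snp_mode="representative"`).  The representative SNP — deepest surviving
SNP, ties broken toward the smallest genomic coordinate — donates the
gene's p-value, reference fraction and ratio counts.

**Multiplicity.** No correction is applied by default; the 0.01 cut-off is
used as a fixed decision rule.  An optional Benjamini–Hochberg mode
(`fdr_mode`) adjusts across all gene-sample tests for users who want
error-rate control.

**DNA allele bias.** Copy-number imbalance skews DNA allele counts and can
mimic expression-level AEI.  DNA counts are pushed through the same
filters, test and representative rule; gene-sample pairs whose DNA rejects
50:50 at p < 0.01 are flagged, and optionally excluded from every
downstream denominator.  Flagging operates per gene-sample pair, not per
gene globally.

**Known variants.** Sites lacking the known-variant flag (a dbSNP-overlap
proxy that suppresses alignment artifacts, somatic mutations and RNA
editing) are dropped before filtering; this is on by default.

## Cohort statistics

* Per-sample AEI proportion = AEI genes / testable genes.  The denominator
  is testable genes (switchable in principle to all expressed genes, but
  expression is only observable here through covered SNPs, so "expressed"
  is operationalized as "testable").
* Per-unit (gene or SNP) AEI frequency = AEI samples / testable samples,
  reported only for units testable in ≥ `ceil(0.20 × cohort size)` samples
  of the tissue.  Untestable samples are unobserved, not balanced, so they
  leave the denominator.
* The high-frequency cut-off is the 75th percentile of the frequency
  distribution by linear interpolation of order statistics
  (`h = (n−1)·0.75 + 1`); the comparison is ≥.  "Fourth quartile" admits
  several conventions; this one is fixed and tested.
* The major allele of a gene is the allele with expression fraction > 0.5
  in strictly more adjacent samples than its counterpart; samples at
  exactly 0.5 count for neither side and exact ties resolve toward the
  reference allele.
* Ratio statistics (mean, CV of major/minor at the representative SNP) are
  computed per gene and tissue over all testable samples, for genes called
  AEI in at least one adjacent sample, and reported only with ≥ 10 usable
  samples.  CV uses the sample (n−1) standard deviation.  Ratios are
  averaged over all testable samples, not only AEI-positive ones, to avoid
  conditioning the noise measure on the test outcome.

## Association suite

Tumor-vs-adjacent and within-sample group contrasts use paired t-tests
(patients and genes are natural pairing units); Welch's unpaired variant is
available by flag.  Frequency-vs-conservation and frequency-vs-dN/dS
associations are simple OLS regressions whose two-sided slope test equals
the Pearson correlation test.  The consequence contrast assigns a gene to
the non-synonymous group when any surviving SNP changes the amino acid
(mixed genes are "exposed") and to the synonymous group when all surviving
SNPs are synonymous; genes with only other consequences are excluded.  No
multiplicity correction is applied across the suite's tests.

The RNA-editing filter removes SNPs whose allele pair, read on the
transcribed strand, is {A, G}: ref/alt ∈ {A/G, G/A} on + strand genes and
{T/C, C/T} on − strand genes.  Unknown strand retains the SNP with a
warning (conservative).

## Synthetic cohorts

The generator produces the minimal structure that makes every downstream
stage testable with known truth:

| parameter | default | meaning |
|---|---|---|
| `mean_snps_per_gene` | 1.2 | mean of the zero-truncated Poisson for heterozygous SNPs per gene (the truncated mean itself, so the realized average stays below 1.5) |
| `depth_mean`, `depth_dispersion` | 50, 5 | negative-binomial read depth per SNP (variance μ + μ²/k); depths are clipped at ≥ 1 |
| `alpha_aei`, `beta_cons`, `beta_nonsyn` | 0, −4, +1 | logistic model `P(AEI) = expit(α + β_c·conservation + β_n·1[nonsyn])`; defaults give ≈ 25% true-AEI genes, with conserved genes less and non-synonymous genes more often imbalanced |
| `theta_lo`, `theta_hi` | 0.65, 0.90 | uniform bounds for the major-allele fraction θ of true-AEI genes; non-AEI genes have θ = 0.5 exactly |
| `rho_adjacent`, `rho_tumor` | 0.005, 0.05 | beta-binomial intra-class correlation per tissue; ρ = 0 is the exact binomial limit, variance inflation `1 + (n−1)ρ` |
| `frac_nonsyn` | 0.4 | fraction of genes labelled non-synonymous (all SNPs of a gene share its class) |
| `frac_dna_bias`, `dna_theta` | 0, 0.7 | fraction of genes with tumor DNA allele bias, and the biased DNA fraction; adjacent DNA is always 50:50, and DNA counts carry no expression noise (ρ = 0) |
| `dnds_link_a/b/sd` | 0, 2, 0.3 | `dN/dS = exp(a − b·conservation + ε)`, tying gene-level and site-level selection signals together |
| `frac_artifact` | 0 | extra sites with `known_variant = 0`, for exercising the known-variant filter |

Conservation scores come from the bimodal mixture
`0.7·Beta(1,3) + 0.3·Beta(8,2)`, a phastCons-like shape with mass near 0
and near 1.  Overdispersion is parameterized as intra-class correlation so
ρ = 0 reduces exactly to binomial sampling (a clean oracle for tests).
Tumor and adjacent tissue share each gene's θ: the tissues differ only in
ρ and optional DNA bias, so any tumor/adjacent difference the pipeline
finds is attributable to noise, not to a shifted mean ratio.

All randomness flows from one `numpy` `default_rng(seed)`; identical
config and seed reproduce byte-identical output files.

### What the generator does not emulate

Counts are the atomic unit: no reads, no mapping bias, no somatic
mutations, and no RNA-editing events beyond the A/G labels needed to test
the filter.  There are no sample-level random effects (library size,
purity, immune infiltration) and no gene–gene correlation: every SNP ×
sample draw is independent given θ and ρ.  Passing tests therefore
demonstrate correctness of the statistical machinery and qualitative
recovery of the designed architecture, not realism of TCGA-like data —
real cohorts are substantially noisier between samples than this model.

### Two structural consequences worth knowing

Both follow from the shared-θ, unequal-ρ design and are computed by the
validation suite:

1. **Mean-ratio inflation under noise.** For a true-AEI gene the
   major/minor ratio `R = X/(n−X)` is convex in X, so `E[R]` grows with
   `Var(X)` (Jensen); the ≥ 4 minor-read filter truncates but does not
   cancel this.  At the default ρ contrast the tumor mean ratio exceeds
   the adjacent one by ≈ 0.1 on average, and with hundreds of paired genes
   the paired t-test reliably detects this small shift.  An equality check
   of mean ratios between tissues fails at study scale for this structural
   reason, even though θ is identical by construction.
2. **Residual consequence contrast in tumor.** Tumor overdispersion
   attenuates the nonsyn−syn AEI-proportion gap by roughly 30%, but
   without sample-level random effects the paired t-test across samples
   retains enough power to detect the residual gap in every replicate.
   Erasing the tumor contrast, as seen in real tumors, would require
   between-sample heterogeneity that this generator deliberately omits.

## Numerical choices

* Zero-truncated Poisson sampling solves `λ/(1−e^{−λ}) = m` by Brent's
  method and resamples zeros; `m = 1` degenerates to all ones.
* `alpha_aei = −inf` is an allowed sentinel (probability exactly 0) via
  `expit`.
* Binomial p-values use `scipy.stats.binom.sf(m−1, n, 0.5)`; the doubling
  is capped at 1.  Agreement with exact integer enumeration is verified to
  relative error 10⁻¹⁰ for all n ≤ 60.
* Representative-SNP ties (equal depth) break toward the smaller
  coordinate with a stable sort, making calls order-independent.
* Empty inputs: a sample with no testable gene raises an explicit
  undefined-proportion error; an empty frequency list raises on the
  quartile; degenerate paired differences (zero variance) raise rather
  than returning p = NaN.

## Problem sizes used in validation

Replicate-based checks run 20 seeded cohorts of 60 pairs × 2000 genes
(about 290k count records each); calibration checks use 10⁵ draws.  These
sizes give Monte-Carlo standard errors comfortably below the asserted
margins while keeping the whole suite fast.
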