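# Methods

This note documents the statistical models implemented in `grexlink`,
the assumptions behind them, the synthetic-data generator used to
validate them, and the numerical choices made where the design was
genuinely open.

## Summary-based association of predicted features

A cis weight model for a gene (or splice site, or protein) is a sparse
vector `w` over variants; applied to an individual's dosages it yields
the genetically regulated component of the feature (GReX). When only GWAS
summary statistics are available, the association between GReX and the
trait is computed without individual data as

    Z_g = Σ_l w_l (σ_l / σ_g) Z_l,

where `Z_l` are per-variant GWAS Wald statistics, `σ_l` per-variant
dosage standard deviations estimated in a reference panel, and
`σ_g = sqrt(wᵀ Σ w)` the SD of the predicted feature under the panel's
dosage covariance `Σ` (all with denominator n−1). The statistic is the
score of a regression of the trait on GReX; its accuracy rests on the
panel's LD matching the GWAS cohort's. Tests verify that on synthetic
cohorts the summary-based Z correlates r > 0.99 with the Z from
regressing the simulated trait on explicitly computed GReX.

**Missing variants.** Variants absent from the summary statistics are
dropped from both the numerator and the recomputation of `σ_g`. A model
losing more than half of its absolute weight mass is flagged
low-confidence rather than suppressed; this bounds silent power loss
while keeping the scan exhaustive. A model with no overlapping variants
produces an explicit non-testable record.

## Multi-tissue combination

Per-tissue Z-scores for one feature are correlated because the tissue
models overlap in variants and the panel has LD. The joint test
estimates the tissue–tissue correlation of the predicted feature from
per-sample scores in the panel, projects it to the nearest PSD
correlation matrix (eigenvalue clipping, unit-diagonal renormalization),
eigendecomposes it, and drops components whose condition number
`λ_max/λ_i` exceeds a limit (default 30 — the convention of published
multi-tissue TWAS regularization; configurable). The statistic
`Σ (u_iᵀ z)² / λ_i` is χ² with one degree of freedom per retained
component. With one tissue it reduces to `z²` on 1 df exactly;
perfectly correlated tissues collapse to a single component. The top
component is always retained, so the retention set is never empty.

## Harmonization

Variant identity is keyed by (chromosome, position); the variant id
column is advisory. Palindromic (A/T, C/G) pairs are removed outright —
no frequency-based rescue — because strand cannot be resolved for them.
Records whose alleles match the panel only after swapping effect/other
have `β`, `Z` negated and frequency reflected; records matching only
after base complementation are strand-corrected and re-checked.
Harmonizing an already-harmonized table is the identity, and downstream
association statistics are invariant to the input's storage coding (both
properties are tested). Indels are out of scope (the panel is SNP-only);
coordinates are 1-based throughout.

## Allelic imbalance

Per individual and gene, imbalance is `log2((a + 1)/(b + 1))` over the
two haplotypes' read counts (one pseudocount; base 2 is the allelic
fold-change convention — the base rescales reported values but cannot
affect a rank test). The coverage filter requires **raw** total reads
≥ 8; the pseudocount enters only the ratio. The scan compares |log aFC|
between heterozygous and homozygous carriers (both homozygous genotypes
pooled) of each GWAS variant with p < 5e-5 within 1 Mb of the gene,
one-sided with the heterozygous group hypothesized larger — the
direction implied by a cis-regulatory variant. The exact rank-sum null
distribution is used when the smaller group has ≤ 10 observations and
there are no ties; otherwise a midrank normal approximation with tie
correction (no continuity correction; agreement with the exact tail is
within 0.02 in tests). Per-gene significance uses 0.05 divided by the
number of genes tested (overridable to match an external denominator),
with a separate flag restricted to each gene's lead variant. Testing is
within one stratum; pooling across tissues is left to the caller.

## GReX phenome and lab scans

GReX is standardized before regression, so effects are per SD of
predicted expression and invariant to affine rescaling of the raw score.
The phenome scan is a logistic regression per phecode (≥ 100 cases) on
GReX plus age, sex, and ten principal components; fits that fail or do
not converge remain in the output flagged unreliable and count toward
the multiplicity denominator, since they were tested. The lab pipeline
per lab: per-person median over repeated measurements, with age taken at
the median-defining measurement (mean of the two central ages for even
counts); OLS residual on a natural cubic spline of age with 4 knots at
age quantiles 0.2/0.4/0.6/0.8 (quantile placement is the common
convention; a degenerate age distribution reduces the design to
mean-centering); then the rank-based inverse normal transform
`Φ⁻¹((r − 0.5)/n)` with midranks for ties. Constant covariate columns
are dropped from designs — they carry no information and would otherwise
make the fit singular. Phecode hierarchy (control exclusion ranges) is
not modeled; synthetic phecodes are independent, a documented divergence
from real phecode semantics.

## Category enrichment

Two estimators per clinical category. (1) Hypergeometric: upper-tail
probability of observing ≥ k significant items in the category given the
overall significant count, with fold
`(k/n_sig)/(n_category/n_total)`. (2) Bootstrap mean-χ²: each item's χ²
is its squared association z; the category mean is compared with 1 (the
null expectation) and scaled by the bootstrap SE of that mean (2000
within-category resamples by default). The mean is deterministic — only
the SE depends on the bootstrap seed. Reporting is two-sided, capturing
depletion as well as enrichment, with Bonferroni over the number of
categories. A category whose χ² values are all exactly 1 has a zero
numerator and zero SE and is reported as an exact null (z = 0); any
other zero-SE category is not evaluable. Calibration tests confirm a
~5% rejection rate at |z| > 1.96 under a standard-normal null.

## Cross-ancestry concordance

The model `β_A,i = α β_E,i + ε_i` with `ε_i ~ N(0, σ²·SE_A,i²)` is fit
by no-intercept weighted least squares with weights `1/SE_A²`:

    α̂ = Σ(β_E β_A / SE_A²) / Σ(β_E² / SE_A²),
    σ̂² = (1/(n−1)) Σ((β_A − α̂ β_E)/SE_A)²,
    SE(α̂) = sqrt(σ̂² / Σ(β_E²/SE_A²)),

with a normal 95% CI. `α` is the fraction of the discovery effect that
transfers to the replication ancestry; `σ²` is overdispersion relative
to replication sampling noise. Simulation at the replication-study size
(n = 32 pairs, α = 0.87, σ² = 1) shows ~95% CI coverage and unbiased
α̂ and σ̂². Per-pair heterogeneity uses
`z = (β_E − β_A)/sqrt(SE_E² + SE_A²)` — the standard two-estimate
difference test; the field usually reports per-pair heterogeneity
without naming a statistic, and this is the package's choice. FDR flags are Benjamini–Hochberg at
q = 0.05. LD clumping is greedy by ascending (p, chrom, pos): a variant
is accepted iff its squared dosage correlation with every accepted
variant within ±250 kb is ≤ 0.1; the result is independent of input row
order.

## Synthetic-data generator

The generator's purpose is statistical, not biological, realism: it
reproduces the first two moments that the statistics under test consume.

- **LD**: a latent Gaussian AR(1) on haplotypes, thresholded at each
  variant's frequency quantile and summed to dosages. One parameter
  (`ld_decay`) tunes adjacent-variant correlation; only LD's first two
  moments matter to the statistics under test. No recombination maps,
  realistic frequency spectra, or sex chromosomes.
- **Weight models**: contiguous cis windows tiled evenly along the
  variant axis (the way cis regions lie along a chromosome; windows are
  disjoint whenever the variant count allows, which keeps genes'
  statistics separable). Cross-tissue weight correlation is exact in
  expectation via a shared/specific Gaussian decomposition.
- **GWAS**: the trait is a liability — sum over causal genes of effect ×
  standardized GReX plus Gaussian noise scaled toward unit total
  variance, so an effect `b` explains `b²` of liability variance.
  Marginal statistics come from per-variant OLS on the liability rather
  than logistic regression on a dichotomized trait: downstream stages
  consume Z-scores, and case-control ascertainment machinery is
  irrelevant to what is being tested. Zero-variance variants are emitted
  with missing statistics and logged.
- **ASE**: per gene, the largest-|weight| variant acts as the regulatory
  variant; heterozygous carriers draw haplotype A counts binomially with
  ratio `2^a` (favoured haplotype randomized), homozygous carriers at
  1/2; totals are Poisson. Effect-size scale for the GWAS liability is
  chosen for testability — the source analyses give no scale.
- **EHR**: an independent cohort from the same LD process (mirroring the
  reference-panel/biobank separation); phecode status from a logistic
  model whose intercept hits a target prevalence; labs linear in GReX
  with a mild age trend, repeated dated measurements, and unit Gaussian
  noise; covariates are age ~ N(55, 15²) clipped to 18–90, sex ~
  Bernoulli(0.57), and ten standard-normal PCs.
- **Two-ancestry pairs**: drawn exactly under the concordance model.

All randomness flows from one seed with independent sub-streams keyed by
stage name, so outputs are byte-identical under a fixed config and
adding draws to one stage never perturbs another. Every generator
returns a truth record alongside its data.

Because the generator matches the models' assumptions by construction,
passing tests demonstrate correctness of the statistics and calibration
under those assumptions — not robustness to real-data violations
(population stratification, weight-model misspecification,
phecode hierarchy, EHR missingness).

## Problem sizes and numerical choices

Test and acceptance simulations are sized to keep the full suite fast on
one CPU while leaving Monte-Carlo error well inside the asserted
tolerances: null calibration uses ≥ 1000 tests per scan, parameter
recovery 200 replicates at the published n = 32, and end-to-end recovery
20 seeds of a 100-gene, 3-tissue, n = 10,000 GWAS. Note the joint
Bonferroni threshold controls family-wise error at 5%, so about one seed
in twenty is expected to show a single false positive by construction;
the end-to-end check therefore requires perfect precision and recall in
≥ 90% of seeds rather than all.

Other numerics: eigendecompositions use symmetric (`eigh`) routines;
degenerate inputs (zero-variance models, empty groups, singleton
enrichment categories) produce flagged, non-evaluable records rather
than exceptions wherever a scan should continue past them; ties in the
rank-sum and inverse-normal transforms are midranked; the
inverse-normal offset (r − 0.5)/n is the default and documented choice.
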