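# Methods

This note documents the statistical models behind `sumstat-mr`, the
default parameters and why they were chosen, what the synthetic-data
generator does and does not emulate, and the numerical conventions used
throughout. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Summary-statistic model and conventions

The unit of data is one variant's marginal association record: effect
and other allele, effect-allele frequency (EAF), per-allele effect β
with standard error SE, standardized statistic Z, two-sided p, sample
size N and imputation INFO. Coordinates are 1-based inclusive. Missing
statistics are reconstructed from identities (Z = β/SE, SE = |β/Z|, p
from the normal tail of Z); inconsistent Z (|Z − β/SE| ≥ 1e-6) is
recomputed from β/SE and reported. All p-values in the package are
two-sided **normal** tails: cohort sizes are in the tens of thousands,
where the t and normal references are indistinguishable, and summary
data carry no usable degrees of freedom anyway. Extreme statistics are
evaluated in log space (`norm.logsf`), so the magnitude of a p-value
like 10⁻³⁵² survives even though the double itself underflows.

Variant QC excludes records with SE > 10 **or SE ≤ 0** (a non-positive
SE would give an inverse-variance weight infinite mass), |β| > 5,
Hardy–Weinberg p < 10⁻⁶, or INFO below a per-study threshold (default
0.4; imputation pipelines differ between cohorts, so this is
configuration, not a constant). Rules apply independently: a row
failing two rules is counted under both, removed once.

Harmonisation aligns a second record's effect allele to a reference
record by direct match, allele swap (negating β and Z, mapping
EAF → 1−EAF), or strand complement. Palindromic variants (A/T, C/G)
whose minor-allele frequency exceeds 0.40 in either record cannot be
strand-resolved from frequency and are dropped — the common two-sample
MR convention; the 0.40 cut-off is configurable.

## Meta-analysis

Two fixed-effect schemes, reflecting the two situations that arise with
multi-platform metabolite GWAS:

* **Z-based** with weights √N (`z_meta = Σ√nᵢzᵢ/√Σnᵢ`), used when
  effect units differ across assay platforms; this is the documented
  default weighting of the standard meta-analysis software. A
  direction string (+/−/?) tracks per-study signs in registration
  order.
* **Inverse-variance** on effects sharing a unit scale:
  β̂ = Σwβ/Σw, SE = (Σw)^(−1/2), w = 1/SE².

Cochran's Q = Σw(βᵢ−β̂)² with a χ²(k−1) tail quantifies between-study
heterogeneity. A coverage filter keeps variants present in ≥ 2 studies,
covering > 50% of the grand total sample, with MAF ≥ 0.1% (MAF from the
sample-size-weighted mean EAF). No random-effects scheme is provided;
the workflows this package supports report Q rather than inflating SEs.

## Locus discovery

**Clumping** is greedy by ascending p: the most significant remaining
variant becomes a lead and absorbs everything within a half-window
(default ±0.5 Mb, i.e. a 1 Mb window; both readings of "1 Mb window"
are expressible since the half-width is a parameter) on the same
chromosome. Specific leads can carry wider windows (e.g. ±3 Mb for a
very strong, broad signal). Ties break by position then ID, for
determinism.

**Approximate joint analysis** reconstructs multiple regression from
marginal statistics plus an external LD correlation matrix R: with
dosage variance vⱼ = 2pⱼ(1−pⱼ) and per-variant sample sizes nⱼ (taken
from the summary rows, allowing differential coverage),

    (X'X)ⱼₖ ≈ √(nⱼvⱼ) √(nₖvₖ) R[j,k],   (X'y)ⱼ ≈ nⱼvⱼβⱼ,

joint β = (X'X)⁻¹X'y, and joint SEs from σ̂²(X'X)⁻¹. The residual
variance σ̂² is the median over members of vⱼβⱼ² + vⱼnⱼseⱼ² — each term
estimates the phenotypic variance implied by one marginal fit; the
median is robust to a few aberrant rows. This is one of several
conventions in this family of methods; the accuracy contract is
agreement with brute-force multiple regression on the generating
genotypes (tested at n = 5,000, 5 correlated variants, 20 seeds, max
relative error < 5%), not bit-compatibility with any external tool.
An LD submatrix with condition number above 1e8 raises a collinearity
error naming the worst pair.

**Stepwise selection** seeds with the lead, repeatedly adds the
candidate with the smallest conditional p when its joint p < 5×10⁻⁸ and
its r² with every selected variant is ≤ 0.9 (the collinearity guard of
the standard software), re-fits after each addition, and drops any
selected variant whose joint p rises above threshold. Candidates with
MAF < 1% are excluded up front. Selected signals are then pruned
greedily at r² > 0.05 (strict inequality; ties keep the more
significant variant), and low-frequency signals in high |D′| with the
locus's common sentinel can be removed. The D′ rule is deliberately
configurable (drop when |D′| exceeds a threshold, default 0.95):
published descriptions of this filter pair "high LD" with a low D′
cut-off, which is internally contradictory, so both readings are
accepted rather than guessed.

**Variance explained** by one biallelic variant on a standardized trait
is 2p(1−p)β²; it is invariant under allele relabelling
(p, β) → (1−p, −β), and cumulative sums over independent variants are
non-decreasing.

## Genetic scores

Scores are weighted allele counts with weights equal to meta-analysis
effect sizes oriented to the exposure-raising allele, so all weights
are ≥ 0 and a tier (pathway-specific subset) is unambiguously a subset
of its parent. `score_r2` is the squared Pearson correlation with the
phenotype. The phenome scan regresses each standardized trait on the
score plus covariates by least squares with normal p-values (no mixed
model at cohort scale) and flags significance at the exact Bonferroni
level α/m; thresholds are rounded to significant figures only for
display, never for decisions. Constant trait columns are skipped and do
not count toward m. Scan traits are standardized but not winsorised by
default.

## Sex-stratified comparison

Phenotypes are standardized within sex, per cohort, using the sample
SD (ddof = 1 — this makes standardization idempotent and the returned
raw SDs directly usable for unit conversion). The sex contrast for a
variant is z = (β_f − β_m)/√(se_f² + se_m²) against the two-sided
normal tail, evaluated in log space (finite for |z| far beyond 60).
Per-cohort sex-specific estimates pool by fixed-effect inverse variance
per sex before the contrast. The Bonferroni m defaults to the number
of lead variants tested.

## MR engine

Given harmonized instruments (γ, se_x; Γ, se_y):

* **Wald ratio** Γ/γ with first-order delta SE |se_y/γ|.
* **IVW**: weighted regression of Γ on γ through the origin, weights
  1/se_y²; fixed-effect SE by default, with an optional multiplicative
  random-effect inflation (never deflation). The paper-style workflow
  reports heterogeneity (Cochran's Q over per-instrument ratios,
  weights γ²/se_y²) separately rather than inflating SEs, hence the
  fixed-effect default.
* **MR-Egger**: weighted regression with a free intercept after
  orienting every instrument to γ ≥ 0 (required for the intercept to
  estimate average directional pleiotropy); intercept, its SE and
  two-sided p form the pleiotropy test. Valid under InSIDE.
* **Weighted median**: per-instrument ratios sorted ascending with
  normalized weights wⱼ = γⱼ²/se_yⱼ² (the leading-order inverse ratio
  variance, per the originating publication); cumulative midpoints
  sⱼ = Σ_{i≤j}wᵢ − wⱼ/2; the estimate interpolates θ across s at
  s = ½. SE by seeded parametric bootstrap: resample γ, Γ from
  N(observed, SE), recompute ratios, re-take the weighted median with
  the observed weights held fixed (the originating implementation's
  convention), SD over draws (default 5,000).
* **Penalized weighted median**: each instrument's heterogeneity
  contribution Qⱼ = wⱼ(θⱼ − θ_wm)² (unnormalized weights) gets a
  one-df χ² upper-tail qⱼ; penalized weight wⱼ·min(1, 20·qⱼ); the
  median rule re-runs with penalized weights. Penalty 20 and the
  bootstrap size follow the originating publication; both are
  parameters. Penalty → ∞ recovers the unpenalized estimate.
* **Multivariable MR**: weighted regression of Γ on several exposures'
  effect columns, no intercept, weights 1/se_y²; each coefficient is a
  direct effect adjusted for the co-exposures (the mediation
  adjustment). Identically-zero exposure columns are dropped and
  reported; collinear columns (condition > 1e8) are an error.

Estimates exponentiate to odds ratios when Γ is on the log-odds scale,
and rescale linearly between raw-unit and per-SD exposure effects
(rescaling commutes with estimation). Sex-specific MR is the same code
run on sex-specific γ, Γ and exposure SDs; comparing MR estimates
between sexes reuses the sex-difference contrast on (θ, se) pairs.

**Known calibration property.** The parametric-bootstrap SE of the
(penalized) weighted median is mildly conservative when the instruments
are exactly homogeneous: the bootstrap treats the sampling scatter of
the observed ratios as real spread, inflating the SD by roughly 5–12%
in the package's recovery experiments, so the 95% CI coverage of the
median methods sits near 0.97 rather than 0.95 (and their null
rejection rates slightly below 5%). This is a property of the canonical
estimator, documented rather than corrected; IVW and Egger are
calibrated at nominal level in the same experiments.

## Synthetic cohorts

The generator produces everything the pipeline consumes, with known
ground truth:

* **Genotypes**: diploid dosages as sums of two independent haplotypes;
  within a block, haplotype alleles share a latent Gaussian with
  equicorrelation ρ, thresholded at the MAF quantile. Blocks are
  independent. The realized dosage correlation is *attenuated* relative
  to ρ (the φ coefficient of thresholded indicators; ≈ 0.71 at
  ρ = 0.9) — this attenuation is characterised against a brute-force
  bivariate-normal orthant oracle in the tests, not assumed. The model
  was chosen over coalescent simulation for direct, analytic control of
  block LD at desk scale. The sample's dosage correlations, haplotype
  |D′| and EAFs form the emitted LD reference.
* **Metabolite**: latent = Xβ_sex + noise. Effects are in within-sex SD
  units; by default noise tops the within-sex variance to 1 (so the
  configured betas are directly the standardized effects; infeasible
  betas with genetic variance ≥ 1 raise an error), or, when a target
  h2 is given, the beta vector is rescaled per sex so the genetic
  fraction of within-sex variance equals h2 exactly. The latent maps
  through a log-normal with per-sex target mean and SD, so the
  pipeline's log → winsorise(5 SD) → z-score preparation is exercised
  on realistic raw values.
* **Outcome**: liability = θ·standardized(exposure) + Σαⱼ·dosageⱼ +
  N(0,1); direct effects α are zero (no pleiotropy), N(0, τ²)
  (balanced) or N(μ_α, τ²) (directional), on a configurable fraction of
  variants. Binary outcomes threshold the liability at the case
  fraction; per-variant logistic fits then give Γ on the log-odds
  scale. Exposure and outcome samples never share individuals.
* **Summary-level generator**: for estimator-scale experiments the
  instrument effects are simulated directly on the summary level with
  large-sample SEs 1/√(n·2p(1−p)), which keeps 500-replicate recovery
  studies fast. Default instrument strengths are uniform on
  0.08–0.5 SD/allele: a discovery-filtered instrument set at
  n = 20,000 requires roughly |γ| > 5.45·se_x ≈ 0.06–0.09 to reach
  genome-wide significance, and metabolite lead loci reach ~0.5.
* **Covariate-style utilities**: antihypertensive-treatment adjustment
  adds +15/+10 mmHg to measured systolic/diastolic pressure of treated
  individuals (raw inputs only; never re-applied).

Default study conditions: 24 common variants, MAF 0.1–0.5 with a
dominant locus at EAF 0.313 whose within-sex standardized effects are
0.69 (women) and 0.23 (men); background effects 0.070/0.095 bringing
the common-variant variance explained to roughly 25%/11% by sex; raw
log-normal SDs 0.321/0.195 around unit mean; causal effect θ = 0.2 on
the liability scale for recovery experiments; two samples of 20,000.

**What the generator does not emulate** — and therefore what passing
tests do not establish about real data: population structure and
relatedness, imputation error and INFO heterogeneity, recombination-map
LD (blocks are equicorrelated and independent), assortative mating,
selection bias in cohort recruitment, winner's-curse in instrument
selection, and case-control ascertainment beyond a simple liability
threshold. Per-variant least squares stands in for mixed-model GWAS;
with unrelated simulated individuals the two coincide, but mixed-model
behaviour under relatedness is untested by construction.

## Problem sizes used in validation

Recovery experiments run at 500 replicates of 24 instruments with two
samples of 20,000 (summary level); the full individual-level chain at
200 seeds with two samples of 10,000; the conditional-analysis oracle
at n = 5,000 × 5 variants × 20 seeds; null calibrations at 1,000–10,000
replicates. These sizes give Monte-Carlo SEs comfortably inside the
asserted tolerances while keeping the whole suite under a minute on one
CPU.

## Numerical choices

Weighted regressions use closed-form normal equations with fixed unit
scale (SEs are taken from the stated per-instrument variances, not an
estimated residual scale). Ties in clumping and pruning break by
p, then position, then ID. Bootstrap draws are generated by
`numpy.random.default_rng(seed)` and are bit-reproducible. Degenerate
inputs (empty instrument sets, zero instrument-exposure effects,
zero-variance strata or scores, EAF ∈ {0,1}, non-positive raw
metabolite values, singular LD submatrices) raise errors rather than
propagate NaNs.
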