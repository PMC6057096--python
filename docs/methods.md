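# Methods

`polyglia` implements a polygenic-score analysis pipeline for deeply
phenotyped aging-brain cohorts: construction of weighted genetic risk
scores (GRS), robust regression screening of scores against
neuropathological, microglial and cognitive phenotypes, deconstruction
of significant score associations into their driver variants, and a
signed −log10(P) concordance analysis linking variant effects on
microglial density to immune gene-module expression. Because the kind
of cohort this targets (postmortem brains with imputed genotypes,
immunohistochemical microglial counts and annual cognitive testing) is
access-controlled, the package ships a synthetic cohort generator with
planted, recoverable genetic effects; every pipeline stage is validated
against that known truth.

## Genetic risk scores

A score over M variants with published weights w_i (ln odds ratio or
standardized beta) and effect-allele dosages d_ij ∈ [0, 2] is the
average per-allele score

    score_j = Σ_i w_i · d̃_ij / (2M),

where d̃_ij is the observed dosage or, when missing, 2·f̂_i with f̂_i
the in-sample effect-allele frequency (mean(d)/2 over non-missing
entries; the weight table's frequency column is the fallback when a
variant is entirely missing). The fixed 2M denominator makes the
frequency substitution an exact mean imputation: the expected score is
unchanged under missingness completely at random (verified by Monte
Carlo in the tests). A sensitivity option divides by twice the
per-subject observed-variant count instead.

Harmonization aligns the genotype file's counted allele with the weight
table's effect allele, flipping d → 2 − d where the two are swapped and
dropping variants whose allele pairs match neither orientation.
Re-signing negative weights (so every weight is trait-increasing, with
the dosage flipped once more) shifts each subject's score by the
constant −Σ 2w_neg/(2M); all contrasts, correlations and regressions
are unchanged, and the tests assert score invariance after centering.
Strand-ambiguous (A/T, G/C) variants are kept with a warning by
default — the intended inputs are harmonized imputation outputs — and
can be dropped.

## Robust regression and inference

Every association is a Huber M-estimator fitted by iterated re-weighted
least squares: tuning constant c = 1.345 on standardized residuals
(95% Gaussian efficiency), residual scale median(|r|)/0.6745
re-estimated each iteration, convergence when the largest coefficient
change falls below 1e−8 (cap 50 iterations; a non-converged fit is
returned flagged with a warning). Standard errors use the Huber (1981)
small-sample-corrected M-estimator covariance

    K² · s² · [Σψ(u)²/(n−p)] / [mean ψ′(u)]² · (XᵀX)⁻¹,
    K = 1 + (p/n)·var(ψ′)/mean(ψ′)²,

which collapses exactly to the OLS covariance when no observation is
downweighted; tests confirm coefficient and SE agreement with
closed-form OLS at c → ∞ and cross-check coefficients against an
independent IRLS implementation. Two-sided p-values use a Student t
reference with residual degrees of freedom n − p; incomplete rows are
dropped listwise per model, which is why degrees of freedom vary across
phenotypes. Multiple testing is corrected by Benjamini–Hochberg within
each displayed grid (one FDR family per screen), significance meaning
q < 0.05.

The Huber loss protects against *gross errors* — blunders tens of SDs
out, e.g. values recorded in the wrong units. That matters for
calibration of the robustness checks: with symmetric contamination both
Huber and OLS remain unbiased, and the probability that Huber's slope
error beats OLS's in one replicate is roughly 1/2 + arctan(ρ/2)/π,
where ρ² ≈ 0.05·B²/1.15 for a 5% contamination of amplitude B residual
SDs. Huber wins ~60% of replicates at B = 5 but ≥90% only once B is in
the tens; the robustness suite therefore exercises B = 50 blunders, and
a win-rate criterion should not be expected to hold for mild outliers.

## Screening and the region × stage expansion

`screen_grid` fits one robust regression per (score, phenotype) cell —
phenotype on score plus that family's covariates — and BH-corrects the
cell p-values across the grid. Covariate sets mirror the intended
analyses: neuropathology models adjust for age at death, sex,
postmortem interval and three ancestry PCs (a no-PMI variant is
provided, since published analyses differ on its inclusion; both are
supported and neither asserted as canonical); cognition models swap PMI
for years of education. `posthoc_region_stage` reruns the machinery on
the 16-cell grid of four regions (midfrontal cortex, inferior temporal
gyrus, ventral medial caudate, posterior putamen) × four activation
aggregates (stage 1; 1+2+3; 2+3; 3).

Note that BH q-values are not pointwise monotone under family
enlargement — adding small p-values re-ranks the step-up minimum — so
only significance calls, not individual q-values, are stable when a
grid is extended; the tests encode exactly that.

## Driver deconstruction

Within a significantly associated score, every variant with MAF > 0.1
is tested individually (same covariates; uncorrected p by design — the
scan is exploratory). The top-ranked variant is removed, the score
recomputed over the remaining variants (denominator 2(M−1)), and the
score association refitted; this greedy loop stops when p ≥ 0.05
(verdict *driver-dominated*, removed variants = driver set) or after
k_max = 5 removals (verdict *polygenic*). The greedy rule is a
reconstruction — published analyses removed their "top variants"
without an explicit stopping criterion — and a `joint` mode removing
all nominally significant variants at once reproduces that literal
action. k_max = 5 operationally separates one-or-two-driver
architectures from diffuse ones; it is configurable.

## Longitudinal slopes

Domain composites are means of per-test z-scores (z-scored against the
baseline visit) per subject/visit/domain. Decline slopes come from a
linear mixed model of composite on time with fixed effects for time and
baseline covariates and a correlated random intercept + slope per
subject, variance components by REML (statsmodels MixedLM is the
engine). The per-subject slope is the fixed time effect plus the
subject's BLUP slope deviation — partially pooled, so Var(BLUP slopes)
≤ Var(per-subject OLS slopes) always. When REML fails to converge or
the residual variance degenerates (e.g. noise-free synthetic data), the
function falls back to per-subject OLS slopes with a warning, which is
also the exact answer in the zero-noise limit.

## Concordance and the min-rank test

Each variant's effect on a phenotype is summarized as
sign(β)·(−log10 p) (base 10 by convention; ranks — hence Spearman ρ —
are invariant to the base). Concordance between microglial density and
a module's expression is the Spearman correlation of the two signed
vectors over the score's variants, with average ranks for ties and an
exact permutation p-value when n ≤ 9 (t approximation otherwise).
Modules are ranked by descending ρ within a score, and the best rank
among the five designated immune modules is referred to the exact null
of the minimum of k ranks drawn without replacement from {1..M}:

    tail:  P(min ≤ r) = 1 − C(M−r, k)/C(M, k)
    point: P(min = r) = C(M−r, k−1)/C(M, k).

The tail form is the default significance measure — the point mass is
not a tail probability and cannot be read as a p-value — while the
point form preserves the literal "equal to the lowest observed rank"
reading; both are exposed and neither is asserted as the original
formulation. Because the tail statistic is discrete (43 atoms at
M = 47, k = 5), null calibration is checked through the randomized
probability integral transform P(min < r) + U·P(min = r), which is
exactly Uniform(0, 1) under the null; a naive KS test on the raw
discrete tail values would reject by construction at large n.

Immune flags can be re-derived from gene membership via the
hypergeometric upper tail P(X ≥ overlap) with threshold p < 0.0011;
module discovery itself is out of scope and memberships are inputs.

## Synthetic cohort generator

The generator emulates the data structure the pipeline assumes, not any
particular dataset:

- **Genotypes.** Independent loci, hard calls Binomial(2, f) — i.e.
  exact Hardy–Weinberg — with optional symmetric Beta(2,2) dosage
  jitter (imputation-like fractional dosages) and MCAR missingness.
  Linkage disequilibrium is deliberately absent.
- **Covariates.** age ~ N(89, 6) truncated to [65, 110]; sex ~
  Bernoulli(0.65, female); education ~ N(16, 3.5) years; postmortem
  interval lognormal (median ≈ 7 h); three ancestry PCs ~ N(0, 1).
  Covariate effects on phenotypes are small non-zero defaults so
  adjustment is exercised non-trivially.
- **Architectures.** `single_driver` plants one variant with a
  per-dosage effect (default 0.4 latent SD) *and* a large published
  weight (default 0.9 ≈ ln 2.5 against a ~0.1 background): a strongly
  upweighted variant with a real effect is precisely the regime in
  which a score association is an artifact of one locus. `diffuse`
  spreads the same total signal through the score
  (`polygenic_effect` = 0.26 latent SD per score SD, matching the
  variance of the default driver).
- **Microglial densities.** Per region, three stage components with
  means (115, 57, 19) counts/area and SD 30% of mean; subject-level
  region latents share an exchangeable correlation (default 0.5 — the
  empirical cross-region structure is unknown, so a single parameter is
  the honest default); aggregates are sums of components, so
  stage123 = stage1 + stage23 identically, and the brain-wide measure
  is the cross-region mean of stage 1+2+3. Densities are floored at 0
  (counts per area); the summation identity is exact whenever no
  component is truncated.
- **Outliers.** With probability 0.02 a phenotype value is displaced by
  5 column SDs — enough to make robust regression matter, mild relative
  to the gross-error regime discussed above.
- **Cognition.** True slopes ~ N(−0.05, 0.05) z/year plus covariate and
  optional genetic terms; visits are annual composites
  intercept + slope·t + N(0, 0.2) over 8 visits by default, with an
  optional per-visit dropout hazard (minimum two visits kept).
- **Modules.** 47 module summaries, standard normal noise plus planted
  (variant, module, β) eQTL effects; five designated immune modules.

Every generator is a pure function of (spec, seed): identical inputs
give identical outputs.

What the generator does *not* emulate — LD, ascertainment, informative
dropout, shared batch structure between modules, non-linear trajectories,
count noise in densities — bounds what passing tests show: they
demonstrate the estimators and decision rules are correct and
well-calibrated under the stated model, not that real cohorts satisfy
that model.

## Problem sizes and numerical choices

Simulation-based checks use n = 1000 subjects × 67 variants × 100
replicates for driver recovery, n = 500 × 8 visits for slope recovery,
200 replicates × 1000 tests for FDR control, and 10,000 draws for
min-rank calibration — large enough for the binomial error on a 90%
rate to sit near 3 percentage points. Convergence tolerances: IRLS
1e−8 on coefficients; an IRLS scale below 1e−12·max(1, max|y|) is
treated as an exact fit (zero residuals, unit weights). Rank-deficient
designs raise an error naming the offending columns (via pivoted QR).
p = 0 inputs to the signed score are capped at −log10 p = 300 with a
warning.

## Known limitations

- Huber M-estimation downweights residual outliers only; bad leverage
  points are outside its breakdown guarantees (no MM-estimation).
- The greedy driver rule can include one chance extra removal when two
  true drivers leave a borderline residual association.
- The mixed model assumes linear trajectories; terminal decline and
  practice effects are out of scope.
- Module memberships and immune designations are inputs; the package
  does not rediscover co-expression structure.
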