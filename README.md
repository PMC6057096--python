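# polyglia

Polygenic risk scores meet the aging brain: `polyglia` is a Python
library for asking whether the *cumulative* genetic liability for an
inflammatory or neurodegenerative disease leaves a footprint on brain
phenotypes — microglial density across regions and activation stages,
amyloid/tau pathology, longitudinal cognitive decline, gene
co-expression modules — and, crucially, whether such a footprint is
genuinely polygenic or an artifact of one or two strongly weighted
variants.

It is written for statistical geneticists and neuro-epidemiologists
working with deeply phenotyped autopsy cohorts, and for anyone who
wants a tested, simulation-validated reference implementation of this
analysis style.

## What it computes

**Genetic risk scores.** For a weight table of M variants (weights
w_i = ln OR or standardized beta) and effect-allele dosages
d_ij ∈ [0, 2],

    GRS_j = Σ_i w_i · d̃_ij / (2M),

with missing dosages contributing 2·f̂_i effect-allele copies (f̂_i =
in-sample effect-allele frequency). Allele harmonization (dosage
flipping, mismatch dropping, optional weight re-signing) is built in;
genotypes load from VCF (DS or GT) or TSV, weight tables accept
PGS-Catalog-style headers.

**Robust screening.** Every phenotype is regressed on every score with
a Huber M-estimator (IRLS, c = 1.345, MAD scale), covariate sets per
phenotype family, p-values from Student t with residual df, and
Benjamini–Hochberg FDR across each grid — plus a 4-region ×
4-activation-stage microglial expansion for significant scores.

**Driver deconstruction.** Variants with MAF > 0.1 are tested
individually; the top variant is removed, the score recomputed, and the
association refitted, iterating until the signal dies (verdict:
*driver-dominated*, with the removed set as drivers) or survives 5
removals (*polygenic*).

**Trajectories.** Per-visit domain composites from test z-scores and
per-subject decline slopes from a random intercept + slope REML mixed
model (BLUP slopes, with per-subject OLS fallback).

**Pleiotropy concordance.** Per-variant signed scores
sign(β)·(−log10 p) for two phenotypes, Spearman ρ per (score, module),
and an exact min-of-k-ranks null probability for whether the five
immune modules rank unusually high among 47; hypergeometric gene-set
enrichment re-derives immune flags from memberships.

**Synthetic cohorts.** A generator with Hardy–Weinberg genotypes,
realistic covariates, correlated regional microglial densities,
longitudinal cognition and module expression — with planted driver or
diffuse genetic architectures, so every claim above is testable against
known truth.

## Worked example

`examples/03_deconstruct_drivers.py` simulates two cohorts of 1,000
subjects with 67-variant scores whose score–phenotype associations are
equally strong but architecturally opposite, then deconstructs both:

```
driver-architecture: baseline t_992 = 8.42, p = 1.3e-16
  removed rs100033: p -> 0.87
  verdict: driver-dominated (drivers: ['rs100033'])

diffuse-architecture: baseline t_992 = 14.31, p = 2.3e-42
  removed rs100064: p -> 6.5e-38
  removed rs100050: p -> 1.5e-34
  removed rs100030: p -> 8.8e-34
  removed rs100027: p -> 4.9e-29
  removed rs100052: p -> 5.7e-26
  verdict: polygenic (drivers: [...])
```

Both baselines are decisively significant, yet removing a single
planted driver collapses the first association to null (p = 0.87),
while the second — the same total effect spread across all 67
variants — barely moves after five removals. That contrast is the
package's central diagnostic: a "polygenic" association that does not
survive leave-one-variant-out is really a single-locus finding wearing
a score.

The other examples cover cohort simulation and VCF round-tripping
(`01`), scoring + grid screening (`02`), mixed-model slope recovery
(`04`), and the immune-module concordance test (`05`).

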