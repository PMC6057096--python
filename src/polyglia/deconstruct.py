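"""Is a score-phenotype association polygenic or driver-dominated?

A significant polygenic-score association can reflect genuinely
cumulative small effects — or a single strongly weighted variant whose
own effect leaks through the score.  This module resolves the two:

1. every common variant in the score (MAF above a threshold, default
   0.1) is tested individually against the phenotype with the same
   robust regression and covariates as the originating screen cell;
2. the top-ranked variant is removed, the score is recomputed over the
   remaining variants (reduced denominator), and the score-phenotype
   fit is repeated;
3. step 2 iterates greedily until the association is gone
   (p >= alpha) or a removal cap ``k_max`` is hit.

Stopping within the cap yields the verdict ``driver-dominated`` with
the removed variants as the driver set; surviving all ``k_max``
removals yields ``polygenic``.  A ``joint`` mode instead removes, in
one step, every variant whose individual p-value is below alpha.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .scoring import GenotypeMatrix, WeightTable, compute_grs, recompute_excluding
from .screen import fit_score_association

__all__ = ["DeconstructionReport", "per_variant_scan", "find_drivers"]


@dataclass
class DeconstructionReport:
    """Outcome of deconstructing one score-phenotype association."""

    score_name: str
    phenotype_name: str
    scan: pd.DataFrame  # per-variant associations, ascending p
    baseline: dict  # score association before any removal (beta/t/df/p/n)
    trace: list[dict] = field(default_factory=list)  # one entry per removal step
    drivers: list[str] = field(default_factory=list)
    verdict: str = "indeterminate"  # driver-dominated | polygenic | indeterminate


SCAN_COLUMNS = ["variant_id", "maf", "weight", "beta", "se", "t", "df", "p", "direction", "n"]


def per_variant_scan(
    table: WeightTable,
    genotypes: GenotypeMatrix,
    phenotype: pd.Series,
    covariates: pd.DataFrame,
    covariate_names,
    *,
    maf_min: float = 0.1,
) -> pd.DataFrame:
    """Robust single-variant tests for every common variant in a score.

    Each passing variant's dosage is the predictor in a Huber fit with
    the same covariates as the originating screen cell (rows with
    missing dosage dropped listwise).  Weights are reported oriented
    positive (the published-effect orientation used when plotting
    driver scans).  Returns one row per variant, ranked by ascending p;
    constant-dosage variants are excluded with a warning.
    """
    maf = genotypes.maf()
    keep = np.where(maf > maf_min)[0]
    if keep.size == 0:
        raise ValueError(f"no variants pass the MAF > {maf_min} filter")
    v = table.variants.set_index("variant_id")
    rows = []
    for j in keep:
        vid = genotypes.variant_ids[j]
        dosage = pd.Series(genotypes.dosage[:, j], index=genotypes.subject_ids)
        obs = dosage.dropna()
        if obs.nunique() <= 1:
            warnings.warn(
                f"variant {vid} has constant dosage; excluded from scan",
                UserWarning,
                stacklevel=2,
            )
            continue
        cell = fit_score_association(dosage, phenotype, covariates, covariate_names)
        rows.append(
            {
                "variant_id": vid,
                "maf": float(maf[j]),
                "weight": float(abs(v.loc[vid, "weight"])),
                **cell,
                "direction": float(np.sign(cell["beta"])) if np.isfinite(cell["beta"]) else np.nan,
            }
        )
    if not rows:
        raise ValueError("every MAF-passing variant was degenerate")
    scan = pd.DataFrame(rows)[SCAN_COLUMNS]
    return scan.sort_values("p", kind="mergesort").reset_index(drop=True)


def _score_fit(
    table: WeightTable,
    genotypes: GenotypeMatrix,
    phenotype: pd.Series,
    covariates: pd.DataFrame,
    covariate_names,
    excluded: list[str],
) -> dict:
    if excluded:
        ss = recompute_excluding(table, genotypes, excluded)
    else:
        ss = compute_grs(table, genotypes)
    return fit_score_association(ss.scores, phenotype, covariates, covariate_names)


def find_drivers(
    table: WeightTable,
    genotypes: GenotypeMatrix,
    phenotype: pd.Series,
    covariates: pd.DataFrame,
    covariate_names,
    *,
    alpha: float = 0.05,
    k_max: int = 5,
    maf_min: float = 0.1,
    joint: bool = False,
    score_name: str | None = None,
    phenotype_name: str | None = None,
) -> DeconstructionReport:
    """Greedy leave-variant-out deconstruction of a score association.

    Requires the baseline score-phenotype association to be nominally
    significant (p < alpha); otherwise there is nothing to deconstruct
    and a ValueError is raised.  See the module docstring for the
    stopping rule and verdicts.
    """
    scan = per_variant_scan(
        table, genotypes, phenotype, covariates, covariate_names, maf_min=maf_min
    )
    baseline = _score_fit(table, genotypes, phenotype, covariates, covariate_names, [])
    report = DeconstructionReport(
        score_name=score_name or table.trait_name,
        phenotype_name=phenotype_name or str(phenotype.name or "phenotype"),
        scan=scan,
        baseline=baseline,
    )
    if not np.isfinite(baseline["p"]) or baseline["p"] >= alpha:
        raise ValueError(
            f"baseline score association is not significant "
            f"(p={baseline['p']:.3g} >= alpha={alpha}); nothing to deconstruct"
        )

    n_variants = len(table)
    if joint:
        hits = scan.loc[scan["p"] < alpha, "variant_id"].tolist()
        hits = hits[: n_variants - 1]  # at least one variant must remain
        if hits:
            fit = _score_fit(table, genotypes, phenotype, covariates, covariate_names, hits)
            report.trace.append({"removed": hits, **fit})
            report.drivers = hits
            report.verdict = "driver-dominated" if fit["p"] >= alpha else "polygenic"
        return report

    removed: list[str] = []
    for vid in scan["variant_id"]:
        if len(removed) >= min(k_max, n_variants - 1):
            break
        removed.append(vid)
        fit = _score_fit(table, genotypes, phenotype, covariates, covariate_names, removed)
        report.trace.append({"removed": vid, **fit})
        if fit["p"] >= alpha:
            report.drivers = list(removed)
            report.verdict = "driver-dominated"
            return report
    report.drivers = list(removed)
    report.verdict = "polygenic"
    return report
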