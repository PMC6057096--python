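"""Score x phenotype robust association screening with per-grid FDR.

One Huber regression per (score, phenotype) cell: the phenotype is
regressed on the score plus that phenotype family's covariate set, the
score term's (t, df, p) is extracted, and Benjamini-Hochberg correction
is applied across all estimable cells of the grid — mirroring the
per-figure asterisk convention of heatmap-style GRS screens.  A
post-hoc expansion re-runs the same machinery over the 4 regions x 4
activation-stage microglial density grid for a score of interest.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import REGIONS, STAGE_AGGREGATES
from .robust import bh_fdr, huber_fit
from .scoring import ScoreSet

__all__ = [
    "AssociationGrid",
    "COVARIATES_NEUROPATH",
    "COVARIATES_NEUROPATH_NO_PMI",
    "COVARIATES_COGNITION",
    "screen_grid",
    "posthoc_region_stage",
    "fit_score_association",
]

#: Covariate sets used in the original analyses: neuropathology models
#: adjust for age at death, sex, postmortem interval and 3 ancestry
#: PCs (a variant without PMI matches the figure captions); cognition
#: models adjust for baseline age, sex, education and the PCs.
COVARIATES_NEUROPATH = ("age", "sex", "pmi", "pc1", "pc2", "pc3")
COVARIATES_NEUROPATH_NO_PMI = ("age", "sex", "pc1", "pc2", "pc3")
COVARIATES_COGNITION = ("age", "sex", "educ", "pc1", "pc2", "pc3")

GRID_COLUMNS = ["score", "phenotype", "n", "beta", "se", "t", "df", "p", "q", "significant"]


@dataclass
class AssociationGrid:
    """Long-format grid of robust fits with FDR q-values.

    ``table`` has one row per (score, phenotype) cell with columns
    ``score, phenotype, n, beta, se, t, df, p, q, significant``.
    Cells with too few complete cases carry NaN statistics and are
    excluded from the FDR family.
    """

    table: pd.DataFrame

    def pivot(self, value: str = "t") -> pd.DataFrame:
        return self.table.pivot(index="score", columns="phenotype", values=value)

    def cell(self, score: str, phenotype: str) -> pd.Series:
        sel = self.table[(self.table["score"] == score) & (self.table["phenotype"] == phenotype)]
        if sel.empty:
            raise KeyError((score, phenotype))
        return sel.iloc[0]

    @property
    def significant_cells(self) -> pd.DataFrame:
        return self.table[self.table["significant"]]


def _scores_frame(scores) -> pd.DataFrame:
    """Accept {name: ScoreSet}, list of ScoreSet, or a subject x score frame."""
    if isinstance(scores, pd.DataFrame):
        return scores
    if isinstance(scores, pd.Series):
        return scores.to_frame(name=scores.name or "score")
    if isinstance(scores, ScoreSet):
        scores = [scores]
    if isinstance(scores, dict):
        return pd.DataFrame({name: s.scores for name, s in scores.items()})
    return pd.DataFrame({s.trait_name: s.scores for s in scores})


def fit_score_association(
    score: pd.Series,
    phenotype: pd.Series,
    covariates: pd.DataFrame,
    covariate_names,
) -> dict:
    """One cell: Huber fit of phenotype ~ score + covariates.

    Rows with any missing value are dropped listwise.  Returns the
    score term's summary plus the complete-case n; a cell with fewer
    complete cases than parameters + 2 is returned as not estimable
    (NaN statistics).
    """
    covariate_names = list(covariate_names)
    df = pd.DataFrame({"_score": score, "_y": phenotype}).join(
        covariates[covariate_names], how="inner"
    )
    df = df.dropna()
    n = len(df)
    p_params = 2 + len(covariate_names)
    if n < p_params + 2:
        return {"n": n, "beta": np.nan, "se": np.nan, "t": np.nan, "df": np.nan, "p": np.nan}
    design = np.column_stack(
        [np.ones(n), df["_score"].to_numpy()]
        + [df[c].to_numpy(dtype=float) for c in covariate_names]
    )
    fit = huber_fit(
        df["_y"].to_numpy(),
        design,
        names=["const", "score"] + covariate_names,
    )
    out = fit.term("score")
    out["n"] = n
    return out


def screen_grid(
    scores,
    phenotypes: pd.DataFrame,
    covariates: pd.DataFrame,
    covariate_map=COVARIATES_NEUROPATH,
    *,
    alpha: float = 0.05,
) -> AssociationGrid:
    """Regress every phenotype on every score; BH-correct the grid.

    Parameters
    ----------
    scores
        ``{name: ScoreSet}``, a list of ScoreSets, or a subject x score
        DataFrame.
    phenotypes, covariates
        Subject-indexed DataFrames (indices are intersected per cell
        with listwise deletion).
    covariate_map
        Either one covariate-name sequence for every phenotype, or a
        mapping ``phenotype -> sequence`` assigning each phenotype its
        family's covariate set.
    """
    sf = _scores_frame(scores)
    rows = []
    for pheno_name in phenotypes.columns:
        cov_names = (
            covariate_map[pheno_name]
            if isinstance(covariate_map, dict)
            else covariate_map
        )
        for score_name in sf.columns:
            cell = fit_score_association(
                sf[score_name], phenotypes[pheno_name], covariates, cov_names
            )
            cell.update({"score": score_name, "phenotype": pheno_name})
            rows.append(cell)
    table = pd.DataFrame(rows)
    est = table["p"].notna()
    q = np.full(len(table), np.nan)
    if est.any():
        q[est.to_numpy()] = bh_fdr(table.loc[est, "p"].to_numpy())
    table["q"] = q
    table["significant"] = table["q"] < alpha
    return AssociationGrid(table[GRID_COLUMNS].reset_index(drop=True))


def region_stage_columns() -> list[str]:
    return [f"microglia_{r}_{s}" for r in REGIONS for s in STAGE_AGGREGATES]


def posthoc_region_stage(
    score,
    microglial: pd.DataFrame,
    covariates: pd.DataFrame,
    covariate_map=COVARIATES_NEUROPATH,
    *,
    alpha: float = 0.05,
) -> AssociationGrid:
    """Region x activation-stage expansion for one score of interest.

    Runs the 16-cell grid (4 regions x stage aggregates {1, 1+2+3,
    2+3, 3}) through the same regression/FDR machinery.  ``score`` is a
    single ScoreSet (or named Series); ``microglial`` must contain the
    ``microglia_<region>_<stage>`` density columns.
    """
    cols = region_stage_columns()
    missing = [c for c in cols if c not in microglial.columns]
    if missing:
        raise ValueError(f"microglial table missing region/stage columns: {missing}")
    return screen_grid(score, microglial[cols], covariates, covariate_map, alpha=alpha)
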