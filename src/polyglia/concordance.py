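"""Pleiotropy concordance between microglial and transcriptomic effects.

Do the variants of one risk score push microglial density and immune
gene-module expression in the *same* direction?  Each variant's effect
on a phenotype is summarized as a signed score, ``sign(beta) *
(-log10 p)``; concordance between two phenotypes is then the Spearman
rank correlation of the two signed-score vectors over the score's
variants.  Computing one correlation per (score, module) and ranking
the 47 module coefficients within a score, the question becomes whether
the five designated immune modules sit unusually high: the minimum of
their ranks is compared with the exact null distribution of the minimum
of k ranks drawn without replacement from {1..M}.

The module also provides the hypergeometric enrichment test used to
flag modules as immune from gene membership, and a direct module
screen (module expression regressed on scores or density) built on the
same machinery as the main screening grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import permutations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .screen import AssociationGrid, screen_grid

__all__ = [
    "ModuleDefinition",
    "ConcordanceResult",
    "signed_scores",
    "concordance_rho",
    "module_concordance",
    "min_rank_probability",
    "module_enrichment",
    "direct_module_screen",
]

#: -log10 floor applied when an underflowing p-value of exactly 0 arrives.
NEGLOG10_CAP = 300.0


@dataclass
class ModuleDefinition:
    """A co-expression module's membership and immune flag."""

    module_id: str
    members: tuple[str, ...]
    microglial_overlap: int = 0
    immune: bool = False

    def __post_init__(self):
        if len(set(self.members)) != len(self.members):
            raise ValueError(f"module {self.module_id}: duplicate members")
        if self.microglial_overlap > len(self.members):
            raise ValueError(f"module {self.module_id}: overlap exceeds module size")


@dataclass
class ConcordanceResult:
    """Per-score concordance of variant effects across two phenotype sets."""

    score_name: str
    table: pd.DataFrame  # module_id, rho, p_rho, n_variants, rank, immune
    immune_min_rank: int
    min_rank_p: float  # null probability for the immune set's best rank
    mode: str  # "tail" or "point"


def signed_scores(scan: pd.DataFrame, *, cap: float = NEGLOG10_CAP) -> pd.Series:
    """Signed association scores ``sign(beta) * (-log10 p)`` per variant.

    ``scan`` needs columns ``variant_id, beta, p`` (a per-variant scan
    table).  ``p = 1`` maps to 0 regardless of sign; ``p = 0`` is
    capped at ``cap`` with a warning.
    """
    for col in ("variant_id", "beta", "p"):
        if col not in scan.columns:
            raise ValueError(f"scan table lacks column {col!r}")
    p = scan["p"].to_numpy(dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if np.any(p == 0):
        warnings.warn(
            f"p-value of 0 encountered; -log10 capped at {cap}", UserWarning, stacklevel=2
        )
    with np.errstate(divide="ignore"):
        mag = np.minimum(-np.log10(p), cap)
    vals = np.sign(scan["beta"].to_numpy(dtype=float)) * mag
    return pd.Series(vals, index=pd.Index(scan["variant_id"], name="variant_id"), name="signed")


def concordance_rho(
    a: pd.Series,
    b: pd.Series,
    *,
    exact_max_n: int = 9,
) -> tuple[float, float]:
    """Spearman correlation of two signed-score vectors over shared variants.

    Average ranks break ties.  The p-value is an exact permutation
    probability when n <= ``exact_max_n`` (all n! pairings enumerated),
    and the usual t approximation otherwise.  A constant vector leaves
    rho undefined: returns (nan, nan) with a warning.
    """
    joined = pd.concat([a, b], axis=1, join="inner").dropna()
    n = len(joined)
    if n < 4:
        raise ValueError(f"need at least 4 shared variants, got {n}")
    x, y = joined.iloc[:, 0].to_numpy(), joined.iloc[:, 1].to_numpy()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant signed-score vector; rho undefined", UserWarning, stacklevel=2)
        return float("nan"), float("nan")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= exact_max_n:
        ryc = ry - ry.mean()
        rxc = rx - rx.mean()
        denom = np.sqrt((rxc**2).sum() * (ryc**2).sum())
        observed = abs((rxc * ryc).sum() / denom)
        hits = total = 0
        for perm in permutations(ryc):
            r = abs(np.dot(rxc, perm) / denom)
            hits += r >= observed - 1e-12
            total += 1
        p = hits / total
    else:
        p = float(stats.spearmanr(x, y).pvalue)
    return rho, p


def module_concordance(
    density_scan: pd.DataFrame,
    module_scans: dict[str, pd.DataFrame],
    immune_modules,
    *,
    score_name: str = "score",
    mode: str = "tail",
) -> ConcordanceResult:
    """Concordance of one score's variant effects: density vs every module.

    ``density_scan`` is the per-variant scan against microglial
    density; ``module_scans`` maps module_id to the per-variant scan
    against that module's expression (same variant set).  Modules are
    ranked by descending rho (rank 1 = most concordant) and the best
    rank among ``immune_modules`` is tested against the exact
    min-of-k-ranks null.
    """
    sd = signed_scores(density_scan)
    rows = []
    for module_id, scan in module_scans.items():
        rho, p_rho = concordance_rho(sd, signed_scores(scan))
        rows.append(
            {
                "module_id": module_id,
                "rho": rho,
                "p_rho": p_rho,
                "n_variants": len(scan),
                "immune": module_id in set(immune_modules),
            }
        )
    table = pd.DataFrame(rows)
    # rank 1 = largest rho; average ranks on exact ties
    table["rank"] = stats.rankdata(-table["rho"].to_numpy(), method="average")
    immune_ranks = table.loc[table["immune"], "rank"]
    if immune_ranks.empty:
        raise ValueError("none of the designated immune modules present in module_scans")
    best = int(np.ceil(immune_ranks.min()))
    p = min_rank_probability(best, k=len(immune_ranks), n_modules=len(table), mode=mode)
    return ConcordanceResult(
        score_name=score_name,
        table=table.sort_values("rank").reset_index(drop=True),
        immune_min_rank=best,
        min_rank_p=p,
        mode=mode,
    )


def min_rank_probability(
    r_obs: int,
    k: int = 5,
    n_modules: int = 47,
    *,
    mode: str = "tail",
) -> float:
    """Null probability for the minimum of k ranks drawn from {1..M}.

    ``mode="tail"`` (default) returns ``P(min <= r_obs) =
    1 - C(M - r_obs, k)/C(M, k)`` — a proper p-value for "the best
    immune-module rank is at least this good".  ``mode="point"``
    returns the point mass ``P(min = r_obs) =
    C(M - r_obs, k - 1)/C(M, k)``, the literal "equal to the lowest
    observed rank" reading.
    """
    M = n_modules
    if not 1 <= k <= M:
        raise ValueError(f"need 1 <= k <= M, got k={k}, M={M}")
    if not 1 <= r_obs <= M - k + 1:
        raise ValueError(
            f"observed min rank must lie in [1, {M - k + 1}] for k={k}, M={M}; got {r_obs}"
        )
    if mode == "tail":
        return 1.0 - comb(M - r_obs, k) / comb(M, k)
    if mode == "point":
        return comb(M - r_obs, k - 1) / comb(M, k)
    raise ValueError("mode must be 'tail' or 'point'")


def module_enrichment(
    module_size: int,
    overlap: int,
    marked_total: int,
    universe_size: int,
    *,
    threshold: float = 0.0011,
) -> tuple[float, bool]:
    """Hypergeometric upper-tail enrichment of marked genes in a module.

    ``P(X >= overlap)`` for X ~ Hypergeometric(universe_size,
    marked_total, module_size); the immune flag is set when p falls
    below ``threshold``.  Counts must be mutually consistent.
    """
    if not (
        0 <= overlap <= min(module_size, marked_total)
        and module_size <= universe_size
        and marked_total <= universe_size
    ):
        raise ValueError(
            f"inconsistent counts: overlap={overlap}, module={module_size}, "
            f"marked={marked_total}, universe={universe_size}"
        )
    p = float(stats.hypergeom.sf(overlap - 1, universe_size, marked_total, module_size))
    return p, p < threshold


def direct_module_screen(
    predictors,
    module_expression: pd.DataFrame,
    covariates: pd.DataFrame,
    covariate_map,
    *,
    alpha: float = 0.05,
) -> AssociationGrid:
    """Module expression regressed directly on scores (or on density).

    Identical machinery to the main screening grid with modules as the
    phenotype family; ``predictors`` may be ScoreSets or any
    subject-indexed Series/DataFrame (e.g. a microglial density
    measure).
    """
    return screen_grid(predictors, module_expression, covariates, covariate_map, alpha=alpha)
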