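"""Cognitive composites and per-subject decline slopes.

Cognition is summarized per visit as the mean of available test
z-scores within a domain (episodic memory, semantic memory, working
memory, perceptual speed, visuospatial ability, or a global composite),
each test z-scored against the baseline visit.  Decline is then a
per-subject slope from a linear mixed model of composite score on time
— fixed effects for time and baseline covariates (age, education, sex),
correlated random intercept and slope per subject, variance components
by REML.  The reported slope is the fixed time effect plus the
subject's BLUP slope deviation, i.e. a partially pooled estimate shrunk
toward the population mean relative to per-subject OLS.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import ConvergenceWarning

__all__ = ["SlopeSet", "composite_score", "decline_slopes", "per_subject_ols_slopes"]

DOMAINS = (
    "episodic_memory",
    "semantic_memory",
    "working_memory",
    "perceptual_speed",
    "visuospatial",
    "global",
)


@dataclass
class SlopeSet:
    """Per-subject decline slopes plus model variance components."""

    slopes: pd.Series  # subject_id -> z units per year
    intercept_sd: float
    slope_sd: float
    residual_sd: float
    method: str  # "reml-blup" or "ols-fallback"
    fixed_time_effect: float


def composite_score(
    test_scores: pd.DataFrame,
    baseline_stats: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Average per-domain z-scores across a visit's test battery.

    ``test_scores`` is long format with columns ``subject_id, time,
    domain, test, value``.  Each test is z-scored against its baseline
    (earliest-visit) mean/SD, or against ``baseline_stats`` (indexed by
    test, columns ``mean, sd``) when supplied; the composite is the
    mean of available test z-scores per subject/visit/domain.  Missing
    tests are simply ignored; a domain-visit with no tests yields no
    row.
    """
    req = {"subject_id", "time", "domain", "test", "value"}
    if not req <= set(test_scores.columns):
        raise ValueError(f"test_scores must have columns {sorted(req)}")
    df = test_scores.dropna(subset=["value"]).copy()
    if baseline_stats is None:
        t0 = df["time"].min()
        base = df[df["time"] == t0].groupby("test")["value"].agg(["mean", "std"])
        base = base.rename(columns={"std": "sd"})
    else:
        base = baseline_stats
    stats = base.reindex(df["test"])
    sd = stats["sd"].to_numpy()
    sd = np.where((sd > 0) & np.isfinite(sd), sd, 1.0)
    df["z"] = (df["value"].to_numpy() - stats["mean"].to_numpy()) / sd
    out = (
        df.groupby(["subject_id", "time", "domain"], sort=True)["z"]
        .mean()
        .rename("score")
        .reset_index()
    )
    return out


def per_subject_ols_slopes(records: pd.DataFrame) -> pd.Series:
    """Unpooled least-squares slope of score on time, per subject."""
    def _slope(g):
        t = g["time"].to_numpy(dtype=float)
        y = g["score"].to_numpy(dtype=float)
        tc = t - t.mean()
        denom = (tc**2).sum()
        return np.nan if denom == 0 else float((tc * (y - y.mean())).sum() / denom)

    return records.groupby("subject_id").apply(_slope, include_groups=False).rename("slope")


def decline_slopes(
    records: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    *,
    min_visits: int = 2,
    reml: bool = True,
) -> SlopeSet:
    """Per-subject decline slopes from a random-intercept+slope model.

    Parameters
    ----------
    records : DataFrame
        Long format ``subject_id, time, score`` for one domain (years
        since baseline; composite z units).
    covariates : DataFrame, optional
        Indexed by subject_id with time-invariant columns (typically
        ``age, educ, sex``) entered as fixed effects.

    Returns per-subject slopes = fixed time effect + BLUP slope
    deviation, for exactly the subjects with >= ``min_visits`` visits.
    If REML does not converge (or the residual variance degenerates),
    falls back to per-subject OLS slopes with a warning.
    """
    req = {"subject_id", "time", "score"}
    if not req <= set(records.columns):
        raise ValueError(f"records must have columns {sorted(req)}")
    counts = records.groupby("subject_id")["time"].nunique()
    keep = counts[counts >= max(min_visits, 2)].index
    if keep.empty:
        raise ValueError("no subject has the minimum of 2 visits")
    dropped = counts.index.difference(keep)
    if len(dropped):
        warnings.warn(
            f"dropping {len(dropped)} subjects with < 2 visits", UserWarning, stacklevel=2
        )
    df = records[records["subject_id"].isin(keep)].copy()

    exog = pd.DataFrame({"const": 1.0, "time": df["time"].to_numpy()}, index=df.index)
    if covariates is not None:
        cov = covariates.reindex(df["subject_id"]).set_axis(df.index)
        for col in cov.columns:
            exog[col] = cov[col].astype(float) - float(cov[col].mean())
        if exog.isna().any().any():
            raise ValueError("covariates missing for some subjects in records")

    ols = per_subject_ols_slopes(df)

    def _fallback(reason: str) -> SlopeSet:
        warnings.warn(
            f"mixed model unavailable ({reason}); returning per-subject OLS slopes",
            RuntimeWarning,
            stacklevel=3,
        )
        resid_sd = _pooled_ols_resid_sd(df)
        return SlopeSet(
            slopes=ols,
            intercept_sd=float("nan"),
            slope_sd=float(ols.std(ddof=1)),
            residual_sd=resid_sd,
            method="ols-fallback",
            fixed_time_effect=float(ols.mean()),
        )

    # degenerate (near-interpolating) data: REML residual variance -> 0
    if _pooled_ols_resid_sd(df) < 1e-10:
        return _fallback("zero residual variance")

    try:
        with warnings.catch_warnings():
            # boundary-of-parameter-space warnings are advisory; judge the
            # fit by its convergence flag and estimate sanity instead
            warnings.simplefilter("ignore", ConvergenceWarning)
            model = sm.MixedLM(
                df["score"].to_numpy(dtype=float),
                exog.to_numpy(),
                groups=df["subject_id"].to_numpy(),
                exog_re=exog[["const", "time"]].to_numpy(),
            )
            fit = model.fit(reml=reml)
        if not fit.converged or not np.isfinite(fit.scale):
            raise RuntimeError("REML reported non-convergence")
    except Exception as exc:  # statsmodels raises several types here
        return _fallback(str(exc))

    fixed_time = float(fit.fe_params[1])
    re = fit.random_effects
    slopes = pd.Series(
        {sid: fixed_time + float(np.asarray(re[sid])[1]) for sid in re}, name="slope"
    ).sort_index()
    cov_re = np.asarray(fit.cov_re, dtype=float)
    return SlopeSet(
        slopes=slopes,
        intercept_sd=float(np.sqrt(max(cov_re[0, 0], 0.0))),
        slope_sd=float(np.sqrt(max(cov_re[1, 1], 0.0))),
        residual_sd=float(np.sqrt(fit.scale)),
        method="reml-blup",
        fixed_time_effect=fixed_time,
    )


def _pooled_ols_resid_sd(df: pd.DataFrame) -> float:
    """RMS residual of per-subject straight-line fits (df-unadjusted)."""
    sq, nobs = 0.0, 0
    for _, g in df.groupby("subject_id"):
        t = g["time"].to_numpy(dtype=float)
        y = g["score"].to_numpy(dtype=float)
        tc = t - t.mean()
        denom = (tc**2).sum()
        slope = 0.0 if denom == 0 else (tc * (y - y.mean())).sum() / denom
        resid = y - y.mean() - slope * tc
        sq += float((resid**2).sum())
        nobs += y.size
    return float(np.sqrt(sq / max(nobs, 1)))
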