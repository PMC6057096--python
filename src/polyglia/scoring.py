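"""Weighted genetic risk scores (GRS) from published variant weights.

A GRS condenses a subject's genotype at a list of trait-associated
variants into one number: the count of effect alleles at each variant,
multiplied by the published effect size (ln odds ratio or standardized
beta), summed over variants and divided by ``2M`` (ploidy times number
of variants) to give an average per-allele score.  Missing genotypes
contribute ``2 * f_hat`` effect-allele copies, where ``f_hat`` is the
in-sample effect-allele frequency — mean imputation that leaves the
expected score unbiased under missingness at random.

Before scoring, the weight table and the genotype file must agree on
which allele is being counted; :func:`harmonize` flips dosages
(``d -> 2 - d``) wherever the genotype file counts the table's *other*
allele, and drops variants whose allele pairs cannot be reconciled.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "WeightTable",
    "GenotypeMatrix",
    "ScoreSet",
    "harmonize",
    "compute_grs",
    "recompute_excluding",
]

log = logging.getLogger(__name__)

WEIGHT_COLUMNS = [
    "variant_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "weight",
    "effect_allele_freq",
]

PALINDROMIC = {frozenset(("A", "T")), frozenset(("G", "C"))}


@dataclass
class WeightTable:
    """Per-trait list of susceptibility variants with effect weights.

    ``variants`` is a DataFrame with columns ``variant_id, chrom, pos,
    effect_allele, other_allele, weight, effect_allele_freq`` (the
    frequency column may be NaN).
    """

    trait_name: str
    variants: pd.DataFrame

    def __post_init__(self):
        v = self.variants
        missing = [c for c in WEIGHT_COLUMNS[:6] if c not in v.columns]
        if missing:
            raise ValueError(f"weight table missing columns: {missing}")
        if "effect_allele_freq" not in v.columns:
            v = v.assign(effect_allele_freq=np.nan)
        if v["variant_id"].duplicated().any():
            dups = v.loc[v["variant_id"].duplicated(), "variant_id"].tolist()
            raise ValueError(f"duplicate variant ids in weight table: {dups}")
        if not np.isfinite(v["weight"]).all():
            raise ValueError("all weights must be finite")
        if (v["effect_allele"] == v["other_allele"]).any():
            raise ValueError("effect and other allele must differ")
        self.variants = v.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.variants)

    def subset(self, variant_ids) -> "WeightTable":
        keep = self.variants["variant_id"].isin(set(variant_ids))
        return WeightTable(self.trait_name, self.variants.loc[keep].copy())


@dataclass
class GenotypeMatrix:
    """Subject x variant effect-allele dosage matrix.

    ``dosage`` holds reals in [0, 2] with NaN marking missing entries.
    ``counted_allele``/``other_allele`` record, per variant, which
    allele the dosage counts (for VCF input, ALT and REF respectively).
    """

    subject_ids: np.ndarray
    variant_ids: np.ndarray
    dosage: np.ndarray
    counted_allele: np.ndarray
    other_allele: np.ndarray
    chrom: np.ndarray | None = None
    pos: np.ndarray | None = None

    def __post_init__(self):
        self.subject_ids = np.asarray(self.subject_ids)
        self.variant_ids = np.asarray(self.variant_ids)
        self.dosage = np.asarray(self.dosage, dtype=float)
        self.counted_allele = np.asarray(self.counted_allele)
        self.other_allele = np.asarray(self.other_allele)
        n, m = self.dosage.shape
        if n != self.subject_ids.size or m != self.variant_ids.size:
            raise ValueError("dosage shape inconsistent with id vectors")
        obs = self.dosage[np.isfinite(self.dosage)]
        if obs.size and (obs.min() < 0 or obs.max() > 2):
            raise ValueError("observed dosages must lie in [0, 2]")

    @property
    def n_subjects(self) -> int:
        return self.subject_ids.size

    @property
    def n_variants(self) -> int:
        return self.variant_ids.size

    def column(self, variant_id: str) -> np.ndarray:
        (j,) = np.where(self.variant_ids == variant_id)
        if j.size == 0:
            raise KeyError(variant_id)
        return self.dosage[:, j[0]]

    def effect_allele_freq(self) -> np.ndarray:
        """Per-variant counted-allele frequency, mean(dosage)/2 over observed."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(self.dosage, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        f = self.effect_allele_freq()
        return np.minimum(f, 1.0 - f)

    def subset_variants(self, variant_ids) -> "GenotypeMatrix":
        idx = [int(np.where(self.variant_ids == v)[0][0]) for v in variant_ids]
        return GenotypeMatrix(
            subject_ids=self.subject_ids,
            variant_ids=self.variant_ids[idx],
            dosage=self.dosage[:, idx],
            counted_allele=self.counted_allele[idx],
            other_allele=self.other_allele[idx],
            chrom=None if self.chrom is None else self.chrom[idx],
            pos=None if self.pos is None else self.pos[idx],
        )


@dataclass
class ScoreSet:
    """Per-subject average per-allele scores for one trait."""

    trait_name: str
    scores: pd.Series  # indexed by subject_id
    n_variants_used: int
    n_missing: pd.Series  # per-subject count of frequency-imputed entries

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": self.scores.index,
                "trait": self.trait_name,
                "score": self.scores.values,
                "n_used": self.n_variants_used,
                "n_missing": self.n_missing.values,
            }
        )


def harmonize(
    table: WeightTable,
    genotypes: GenotypeMatrix,
    *,
    resign_weights: bool = False,
    drop_ambiguous: bool = False,
) -> tuple[WeightTable, GenotypeMatrix]:
    """Align a weight table and a genotype matrix on shared variants.

    After harmonization every retained dosage column counts the table's
    effect allele: columns whose counted allele matches the table's
    *other* allele are flipped ``d -> 2 - d``.  Variants absent from the
    genotypes, or whose allele pair matches neither orientation, are
    dropped with a logged count/warning.

    With ``resign_weights=True``, negative weights are re-signed
    positive and their dosage columns flipped once more, so every weight
    is trait-increasing.  This shifts each subject's score by the
    constant ``-sum(2 w_neg)/(2M)`` and leaves all score contrasts and
    regressions unchanged.  ``drop_ambiguous`` removes strand-ambiguous
    (A/T, G/C) variants; by default they are kept with a warning.
    """
    v = table.variants.set_index("variant_id")
    geno_idx = {vid: j for j, vid in enumerate(genotypes.variant_ids)}
    keep_rows, cols, flip, dropped_mismatch = [], [], [], []
    n_absent = 0
    for vid, row in v.iterrows():
        j = geno_idx.get(vid)
        if j is None:
            n_absent += 1
            continue
        pair = frozenset((str(row["effect_allele"]), str(row["other_allele"])))
        if drop_ambiguous and pair in PALINDROMIC:
            continue
        if pair in PALINDROMIC:
            warnings.warn(
                f"palindromic variant {vid} kept; verify strand alignment",
                UserWarning,
                stacklevel=2,
            )
        ca, oa = str(genotypes.counted_allele[j]), str(genotypes.other_allele[j])
        if ca == row["effect_allele"] and oa == row["other_allele"]:
            flip.append(False)
        elif ca == row["other_allele"] and oa == row["effect_allele"]:
            flip.append(True)
        else:
            dropped_mismatch.append(vid)
            continue
        keep_rows.append(vid)
        cols.append(j)
    if dropped_mismatch:
        warnings.warn(
            f"dropped {len(dropped_mismatch)} variants with irreconcilable "
            f"alleles: {dropped_mismatch[:5]}",
            UserWarning,
            stacklevel=2,
        )
    if n_absent:
        log.info("%d weight-table variants absent from genotypes", n_absent)
    if not keep_rows:
        raise ValueError("no variants shared between weight table and genotypes")

    dosage = genotypes.dosage[:, cols].copy()
    flip = np.asarray(flip)
    dosage[:, flip] = 2.0 - dosage[:, flip]
    new_v = v.loc[keep_rows].reset_index()

    if resign_weights:
        neg = new_v["weight"].to_numpy() < 0
        dosage[:, neg] = 2.0 - dosage[:, neg]
        new_v.loc[neg, ["effect_allele", "other_allele"]] = new_v.loc[
            neg, ["other_allele", "effect_allele"]
        ].to_numpy()
        new_v.loc[neg, "effect_allele_freq"] = 1.0 - new_v.loc[neg, "effect_allele_freq"]
        new_v.loc[neg, "weight"] = -new_v.loc[neg, "weight"]

    aligned_geno = GenotypeMatrix(
        subject_ids=genotypes.subject_ids,
        variant_ids=new_v["variant_id"].to_numpy(),
        dosage=dosage,
        counted_allele=new_v["effect_allele"].to_numpy(),
        other_allele=new_v["other_allele"].to_numpy(),
        chrom=new_v["chrom"].to_numpy(),
        pos=new_v["pos"].to_numpy(),
    )
    return WeightTable(table.trait_name, new_v), aligned_geno


def compute_grs(
    table: WeightTable,
    genotypes: GenotypeMatrix,
    *,
    denominator: str = "2M",
) -> ScoreSet:
    """Average per-allele score: ``score_j = sum_i w_i d_ij / (2 M)``.

    Inputs must already be harmonized (identical variant order, dosages
    counting effect alleles).  Missing dosages are replaced by
    ``2 f_hat_i`` with ``f_hat_i`` the in-sample effect-allele frequency
    from non-missing dosages, falling back to the table's
    ``effect_allele_freq`` when a column is entirely missing.

    ``denominator="2M"`` (default) divides by ploidy times the total
    number of variants; ``"observed"`` divides each subject by twice the
    number of variants scored for that subject (sensitivity option —
    with mean imputation every variant is scored, so this only differs
    when imputation is impossible).
    """
    if denominator not in ("2M", "observed"):
        raise ValueError("denominator must be '2M' or 'observed'")
    v = table.variants
    m = len(v)
    if m < 1:
        raise ValueError("weight table is empty")
    if not np.array_equal(v["variant_id"].to_numpy(), genotypes.variant_ids):
        raise ValueError("inputs are not harmonized (variant order differs)")

    d = genotypes.dosage.copy()
    missing = ~np.isfinite(d)
    fhat = genotypes.effect_allele_freq()
    table_f = v["effect_allele_freq"].to_numpy(dtype=float)
    all_missing = ~np.isfinite(fhat)
    fhat = np.where(all_missing, table_f, fhat)
    bad = ~np.isfinite(fhat) & missing.any(axis=0) & all_missing
    if bad.any():
        names = v.loc[bad, "variant_id"].tolist()
        raise ValueError(
            f"variant(s) {names} have no observed dosages and no "
            "effect_allele_freq to impute from"
        )
    fill = np.broadcast_to(2.0 * fhat, d.shape)
    d[missing] = fill[missing]

    w = v["weight"].to_numpy(dtype=float)
    raw = d @ w
    denom = 2.0 * m if denominator == "2M" else 2.0 * m * np.ones(d.shape[0])
    scores = raw / denom
    return ScoreSet(
        trait_name=table.trait_name,
        scores=pd.Series(scores, index=pd.Index(genotypes.subject_ids, name="subject_id")),
        n_variants_used=m,
        n_missing=pd.Series(
            missing.sum(axis=1), index=pd.Index(genotypes.subject_ids, name="subject_id")
        ),
    )


def recompute_excluding(
    table: WeightTable,
    genotypes: GenotypeMatrix,
    excluded,
    **kwargs,
) -> ScoreSet:
    """Re-score after removing ``excluded`` variant ids (reduced-M denominator)."""
    excluded = set(excluded)
    unknown = excluded - set(table.variants["variant_id"])
    if unknown:
        raise ValueError(f"excluded ids not in weight table: {sorted(unknown)}")
    keep = [vid for vid in table.variants["variant_id"] if vid not in excluded]
    if not keep:
        raise ValueError("cannot exclude every variant in the score")
    return compute_grs(table.subset(keep), genotypes.subset_variants(keep), **kwargs)
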