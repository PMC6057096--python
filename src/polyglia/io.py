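"""Readers and writers for the package's tabular interchange formats.

Weight tables follow the PGS-Catalog scoring-file column convention
(``rsID/effect_allele/other_allele/effect_weight``) with common aliases
accepted.  Genotypes travel either as VCF (dosage ``DS`` FORMAT field
preferred, hard-call ``GT`` fallback) or as a plain subject x variant
TSV matrix.  All other tables (phenotypes, covariates, scores, module
expression) are ordinary TSVs with headers.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .scoring import WEIGHT_COLUMNS, GenotypeMatrix, ScoreSet, WeightTable

__all__ = [
    "read_weight_table",
    "write_weight_table",
    "read_genotypes_vcf",
    "write_genotypes_vcf",
    "read_genotypes_tsv",
    "write_genotypes_tsv",
    "write_scores",
]

# accepted header aliases -> canonical name (PGS-Catalog and PLINK usage)
_ALIASES = {
    "variant_id": "variant_id",
    "rsid": "variant_id",
    "id": "variant_id",
    "snp": "variant_id",
    "chrom": "chrom",
    "chr": "chrom",
    "chr_name": "chrom",
    "pos": "pos",
    "chr_position": "pos",
    "bp": "pos",
    "effect_allele": "effect_allele",
    "a1": "effect_allele",
    "other_allele": "other_allele",
    "a2": "other_allele",
    "reference_allele": "other_allele",
    "weight": "weight",
    "effect_weight": "weight",
    "beta": "weight",
    "ln_or": "weight",
    "effect_allele_freq": "effect_allele_freq",
    "eaf": "effect_allele_freq",
    "allelefrequency_effect": "effect_allele_freq",
    "freq": "effect_allele_freq",
}


def read_weight_table(path, trait_name: str | None = None) -> WeightTable:
    """Read a TSV scoring file, normalising PGS-Catalog-style headers."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#")
    renamed = {}
    for col in df.columns:
        canon = _ALIASES.get(col.strip().lower())
        if canon and canon not in renamed.values():
            renamed[col] = canon
    df = df.rename(columns=renamed)
    required = ["variant_id", "effect_allele", "other_allele", "weight"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    for optional, default in (("chrom", "1"), ("pos", 0), ("effect_allele_freq", np.nan)):
        if optional not in df.columns:
            df[optional] = default
    df["chrom"] = df["chrom"].astype(str)
    return WeightTable(trait_name or path.stem, df[WEIGHT_COLUMNS].copy())


def write_weight_table(table: WeightTable, path) -> None:
    table.variants[WEIGHT_COLUMNS].to_csv(path, sep="\t", index=False)


def read_genotypes_vcf(path) -> GenotypeMatrix:
    """Load a (plain or bgzipped) VCF as an effect-allele dosage matrix.

    The counted allele is ALT.  Per variant, the ``DS`` FORMAT field is
    used when present; otherwise dosage is the ALT-allele count from
    ``GT`` with missing calls as NaN.  Multi-allelic records are
    rejected.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    subjects = np.asarray(vcf.samples)
    ids, chroms, poss, alts, refs, cols = [], [], [], [], [], []
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise ValueError(f"multi-allelic record at {rec.CHROM}:{rec.POS} not supported")
        ids.append(rec.ID or f"{rec.CHROM}:{rec.POS}")
        chroms.append(rec.CHROM)
        poss.append(rec.POS)
        refs.append(rec.REF)
        alts.append(rec.ALT[0])
        ds = rec.format("DS")
        if ds is not None:
            col = np.asarray(ds, dtype=float).ravel()
            col[col < 0] = np.nan  # cyvcf2 encodes missing as negative sentinel
        else:
            gt = np.asarray(rec.genotype.array())[:, :2].astype(float)
            gt[gt < 0] = np.nan
            col = gt.sum(axis=1)
        cols.append(col)
    vcf.close()
    if not cols:
        raise ValueError(f"no variant records in {path}")
    return GenotypeMatrix(
        subject_ids=subjects,
        variant_ids=np.asarray(ids),
        dosage=np.column_stack(cols),
        counted_allele=np.asarray(alts),
        other_allele=np.asarray(refs),
        chrom=np.asarray(chroms),
        pos=np.asarray(poss),
    )


def write_genotypes_vcf(gm: GenotypeMatrix, path) -> None:
    """Write dosages as an uncompressed VCF with DS and GT FORMAT fields.

    GT carries the rounded hard call (``./.`` when missing); DS carries
    the dosage itself so a round trip preserves fractional values.
    """
    chrom = gm.chrom if gm.chrom is not None else np.repeat("1", gm.n_variants)
    pos = gm.pos if gm.pos is not None else np.arange(1, gm.n_variants + 1)
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DS,Number=1,Type=Float,Description="Estimated alternate allele dosage">',
    ]
    for c in pd.unique(np.asarray(chrom)):
        lines.append(f"##contig=<ID={c}>")
    header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
    lines.append("\t".join(header + [str(s) for s in gm.subject_ids]))
    gt_codes = {0: "0/0", 1: "0/1", 2: "1/1"}
    for j in range(gm.n_variants):
        fields = [
            str(chrom[j]),
            str(int(pos[j])),
            str(gm.variant_ids[j]),
            str(gm.other_allele[j]),
            str(gm.counted_allele[j]),
            ".",
            "PASS",
            ".",
            "GT:DS",
        ]
        for d in gm.dosage[:, j]:
            if np.isfinite(d):
                fields.append(f"{gt_codes.get(int(round(d)), './.')}:{d:g}")
            else:
                fields.append("./.:.")
        lines.append("\t".join(fields))
    Path(path).write_text("\n".join(lines) + "\n")


def read_genotypes_tsv(path, variant_info=None) -> GenotypeMatrix:
    """Read a subject x variant dosage TSV (first column ``subject_id``).

    ``variant_info`` may point to a TSV with ``variant_id,
    counted_allele, other_allele`` (plus optional chrom/pos); without
    it, the counted allele is recorded as ``A`` vs ``B`` placeholders
    and harmonization will treat the counted allele as the effect
    allele.
    """
    df = pd.read_csv(path, sep="\t")
    subjects = df.iloc[:, 0].astype(str).to_numpy()
    dosage = df.iloc[:, 1:].to_numpy(dtype=float)
    vids = np.asarray(df.columns[1:])
    if variant_info is not None:
        info = pd.read_csv(variant_info, sep="\t").set_index("variant_id")
        counted = info.loc[vids, "counted_allele"].to_numpy()
        other = info.loc[vids, "other_allele"].to_numpy()
        chrom = info["chrom"].loc[vids].to_numpy() if "chrom" in info else None
        pos = info["pos"].loc[vids].to_numpy() if "pos" in info else None
    else:
        counted = np.repeat("A", vids.size)
        other = np.repeat("B", vids.size)
        chrom = pos = None
    return GenotypeMatrix(subjects, vids, dosage, counted, other, chrom, pos)


def write_genotypes_tsv(gm: GenotypeMatrix, path) -> None:
    pd.DataFrame(gm.dosage, columns=gm.variant_ids).assign(
        subject_id=gm.subject_ids
    ).set_index("subject_id").to_csv(path, sep="\t")


def write_scores(scores: ScoreSet | list[ScoreSet], path) -> None:
    items = scores if isinstance(scores, list) else [scores]
    pd.concat([s.to_frame() for s in items]).to_csv(path, sep="\t", index=False)


def write_truth_json(truth, path) -> None:
    """Serialize a CohortTruth sidecar next to simulated outputs."""
    payload = {
        "seed": truth.seed,
        "true_scores": truth.true_scores.tolist(),
        "true_slopes": truth.true_slopes.tolist(),
        "variant_effects": truth.variant_effects.to_dict(orient="list"),
    }
    Path(path).write_text(json.dumps(payload, indent=1))
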