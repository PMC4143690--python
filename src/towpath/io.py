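"""Readers and writers for the pipeline's on-disk formats.

Formats: tab-separated tables with a header row for cohorts, genotypes,
annotations and result tables; GMT for gene sets (name, description, members);
BED (0-based half-open, converted to 1-based inclusive on read) or a 1-based
TSV for gene intervals; a minimal VCF 4.2 with a GT field as an optional
genotype carrier.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import ANNOTATION_COLUMNS, COHORT_COLUMNS, GeneSetCollection, GenotypeMatrix

# ---------------------------------------------------------------------------
# cohort


def write_cohort_tsv(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_cohort_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort table {path} lacks columns {missing}")
    return df


# ---------------------------------------------------------------------------
# genotypes (variants x individuals TSV; metadata columns first)

_GT_META = ["variant_id", "chrom", "pos", "maf_true"]


def write_genotype_tsv(genotypes: GenotypeMatrix, path) -> None:
    meta = genotypes.variants.copy()
    if "maf_true" not in meta.columns:
        meta["maf_true"] = np.nan
    body = pd.DataFrame(
        genotypes.dosages.T, columns=genotypes.individual_ids
    )
    out = pd.concat([meta[_GT_META].reset_index(drop=True), body], axis=1)
    out.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_genotype_tsv(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str},
                     float_precision="round_trip")
    meta_cols = [c for c in _GT_META if c in df.columns]
    if "variant_id" not in meta_cols or "pos" not in meta_cols:
        raise ValueError(f"genotype table {path} lacks variant_id/pos columns")
    individual_ids = [c for c in df.columns if c not in _GT_META]
    variants = df[meta_cols].copy()
    if variants.get("maf_true") is not None and variants["maf_true"].isna().all():
        variants = variants.drop(columns=["maf_true"])
    dosages = df[individual_ids].to_numpy(dtype=float).T
    return GenotypeMatrix(individual_ids=individual_ids, variants=variants, dosages=dosages)


# ---------------------------------------------------------------------------
# gene annotation


def write_annotation_tsv(annotation: pd.DataFrame, path) -> None:
    annotation[ANNOTATION_COLUMNS].to_csv(path, sep="\t", index=False)


def read_annotation_tsv(path) -> pd.DataFrame:
    """1-based inclusive gene intervals with a header row."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"annotation table {path} lacks columns {missing}")
    _check_annotation(df)
    return df[ANNOTATION_COLUMNS]


def read_annotation_bed(path) -> pd.DataFrame:
    """Headerless BED: chrom, start (0-based), end (half-open), gene_id.

    Converted on read to the package's 1-based inclusive convention:
    start_1 = start_0 + 1, end_1 = end_halfopen.
    """
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "gene_id"], dtype={"chrom": str},
    )
    df["start"] = df["start"].astype(int) + 1
    df["end"] = df["end"].astype(int)
    df = df[ANNOTATION_COLUMNS]
    _check_annotation(df)
    return df


def _check_annotation(df: pd.DataFrame) -> None:
    if (df["start"] > df["end"]).any():
        bad = df.loc[df["start"] > df["end"], "gene_id"].tolist()
        raise ValueError(f"annotation has start > end for genes {bad[:5]}")
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"]
        raise ValueError(f"duplicate gene ids in annotation: {sorted(set(dup))[:5]}")


# ---------------------------------------------------------------------------
# GMT gene sets


def write_gmt(sets: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name in sets:
            desc = sets.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *sets[name]]) + "\n")


def read_gmt(path) -> GeneSetCollection:
    names: dict[str, list[str]] = {}
    descs: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has <3 fields")
            name, desc, members = parts[0], parts[1], [g for g in parts[2:] if g]
            if name in names:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            names[name] = members
            descs[name] = desc
    return GeneSetCollection(sets=names, descriptions=descs)


# ---------------------------------------------------------------------------
# VCF (optional carrier for genotypes)

_DOSAGE_TO_GT = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def write_vcf(genotypes: GenotypeMatrix, path) -> None:
    """Minimal VCF 4.2 with a GT FORMAT field; REF/ALT are placeholders."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        chroms = genotypes.variants["chrom"].astype(str).unique()
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(genotypes.individual_ids)
            + "\n"
        )
        for j, rec in enumerate(genotypes.variants.itertuples(index=False)):
            col = genotypes.dosages[:, j]
            gts = "\t".join(
                "./." if np.isnan(d) else _DOSAGE_TO_GT[d] for d in col
            )
            fh.write(
                f"{rec.chrom}\t{int(rec.pos)}\t{rec.variant_id}\tA\tC\t.\tPASS\t.\tGT\t{gts}\n"
            )


def read_vcf(path) -> GenotypeMatrix:
    """Read GT dosages from a VCF via cyvcf2 (alt-allele copy count)."""
    from cyvcf2 import VCF  # optional dependency

    reader = VCF(str(path), gts012=True)
    individual_ids = list(reader.samples)
    ids, chroms, poss, rows = [], [], [], []
    for var in reader:
        ids.append(var.ID if var.ID else f"{var.CHROM}:{var.POS}")
        chroms.append(str(var.CHROM))
        poss.append(var.POS)
        gt = var.gt_types.astype(float)  # 0,1,2; 3 = unknown
        gt[gt == 3] = np.nan
        rows.append(gt)
    variants = pd.DataFrame({"variant_id": ids, "chrom": chroms, "pos": poss})
    dosages = np.vstack(rows).T if rows else np.empty((len(individual_ids), 0))
    return GenotypeMatrix(individual_ids=individual_ids, variants=variants, dosages=dosages)


# ---------------------------------------------------------------------------
# checksums / manifest


def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def file_manifest(paths: dict[str, Path]) -> dict:
    return {
        name: {"path": str(p), "sha256": sha256_of(p), "bytes": Path(p).stat().st_size}
        for name, p in paths.items()
    }


def write_json(obj: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
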