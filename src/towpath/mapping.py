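"""Variant-to-gene interval mapping and minor-allele-frequency classification.

MAF is computed from the analysis sample itself (no external reference
panel). A variant is *rare* when 0 < MAF < threshold (default 1%, strict),
*common* when MAF >= threshold, and *monomorphic* when no minor allele is
observed; monomorphic variants are excluded downstream. If a variant's
computed allele frequency exceeds 0.5 the dosage coding is flipped (x -> 2-x)
so the reported frequency is always the minor allele's.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .datatypes import GeneVariantMap, GenotypeMatrix

log = logging.getLogger(__name__)

RARE_MAF_THRESHOLD = 0.01


def compute_maf(genotypes: GenotypeMatrix, threshold: float = RARE_MAF_THRESHOLD) -> pd.DataFrame:
    """Per-variant sample MAF and rare/common/monomorphic class.

    Returns a DataFrame with columns variant_id, maf, n_missing, flipped,
    vclass. MAF = minor-allele count / (2 x non-missing individuals); flips
    needed to make the coded allele the minor one are recorded and logged.
    """
    X = genotypes.dosages
    n_missing = np.isnan(X).sum(axis=0)
    n_obs = X.shape[0] - n_missing
    with np.errstate(invalid="ignore"):
        freq = np.nansum(X, axis=0) / np.maximum(2 * n_obs, 1)
    flipped = freq > 0.5
    maf = np.where(flipped, 1.0 - freq, freq)
    maf[n_obs == 0] = 0.0

    vclass = np.where(maf == 0.0, "monomorphic", np.where(maf < threshold, "rare", "common"))
    if flipped.any():
        log.info(
            "flipped dosage coding to minor allele for %d variants: %s",
            int(flipped.sum()),
            genotypes.variants.loc[flipped, "variant_id"].tolist()[:10],
        )
    if (n_obs == 0).any():
        log.warning("%d variants have all dosages missing", int((n_obs == 0).sum()))
    return pd.DataFrame(
        {
            "variant_id": genotypes.variants["variant_id"].to_numpy(),
            "maf": maf,
            "n_missing": n_missing.astype(int),
            "flipped": flipped,
            "vclass": vclass,
        }
    )


def apply_minor_allele_coding(
    genotypes: GenotypeMatrix, classification: pd.DataFrame
) -> GenotypeMatrix:
    """Return a copy with flipped variants recoded as 2 - x."""
    X = genotypes.dosages.copy()
    flip = classification["flipped"].to_numpy()
    X[:, flip] = 2.0 - X[:, flip]
    return GenotypeMatrix(
        individual_ids=list(genotypes.individual_ids),
        variants=genotypes.variants.copy(),
        dosages=X,
    )


def impute_missing_mean(genotypes: GenotypeMatrix) -> np.ndarray:
    """Dosage matrix with per-variant mean imputation of missing entries.

    Keeps the closed-form association statistics defined; all-missing
    variants are filled with 0 (they are monomorphic and dropped downstream).
    """
    X = genotypes.dosages.copy()
    col_mean = np.nanmean(np.where(np.isnan(X), np.nan, X), axis=0)
    col_mean = np.nan_to_num(col_mean, nan=0.0)
    idx = np.where(np.isnan(X))
    X[idx] = col_mean[idx[1]]
    return X


def _norm_chrom(labels) -> np.ndarray:
    return np.array([str(c).removeprefix("chr") for c in labels])


def map_snps_to_genes(
    genotypes: GenotypeMatrix,
    annotation: pd.DataFrame,
    flank_bp: int = 0,
) -> GeneVariantMap:
    """Map each variant to every gene whose (flanked) interval contains it.

    A variant maps to gene G iff it is on the same chromosome and
    start - flank <= pos <= end + flank (1-based inclusive). Variants inside
    k overlapping genes appear in all k lists; unmapped variants are counted
    and reported.
    """
    if flank_bp < 0:
        raise ValueError("flank_bp must be >= 0")
    vchrom = _norm_chrom(genotypes.variants["chrom"])
    gchrom = _norm_chrom(annotation["chrom"])
    shared = set(vchrom) & set(gchrom)
    if not shared:
        raise ValueError(
            "no shared chromosome labels between genotypes "
            f"({sorted(set(vchrom.tolist()))}) and annotation "
            f"({sorted(set(gchrom.tolist()))})"
        )
    pos = genotypes.variants["pos"].to_numpy()
    mapped = np.zeros(len(pos), dtype=bool)
    gene_to_variants: dict[str, np.ndarray] = {}
    for gi, rec in enumerate(annotation.itertuples(index=False)):
        on_chrom = vchrom == gchrom[gi]
        lo = rec.start - flank_bp
        hi = rec.end + flank_bp
        hit = np.flatnonzero(on_chrom & (pos >= lo) & (pos <= hi))
        gene_to_variants[rec.gene_id] = hit
        mapped[hit] = True
    unmapped_ids = genotypes.variants.loc[~mapped, "variant_id"].tolist()
    log.info(
        "mapped %d/%d variants to %d genes (%d unmapped)",
        int(mapped.sum()), len(pos), len(annotation), len(unmapped_ids),
    )
    return GeneVariantMap(
        gene_to_variants=gene_to_variants,
        n_unmapped=len(unmapped_ids),
        unmapped_variant_ids=unmapped_ids,
    )
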