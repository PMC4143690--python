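"""Synthetic cohort, genotype, annotation and gene-set generator.

The generator produces fixtures with the statistical structure the analysis
assumes: a cohort of unrelated individuals with correlated SBP/DBP driven by
age, sex, smoking and medication use; Hardy-Weinberg genotypes at independent
variants whose population MAF spectrum straddles the 1% rare/common boundary;
non-overlapping gene intervals tiling one chromosome; and gene sets of
heterogeneous size, including sets that fall on either side of the downstream
size and chromosome filters.

Determinism contract: every operation derives its RNG from
(config.seed, fixed stream id), so identical configs give bit-identical
outputs, individually and as a bundle.
"""

from __future__ import annotations

import logging
import zlib
from pathlib import Path

import numpy as np
import pandas as pd

from .config import CausalGene, SimulationConfig
from .datatypes import GeneSetCollection, GenotypeMatrix
from . import io as tio

log = logging.getLogger(__name__)

# Fixed RNG stream ids per operation, so each op is deterministic standalone.
_STREAM_COHORT = 1
_STREAM_GENOTYPES = 2
_STREAM_INTERVALS = 31
_STREAM_SETS = 32
_STREAM_EFFECTS = 4

_OFF_CHROM_UNIVERSE = 2000
_INTERGENE_GAP = (1_000, 20_000)


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), stream]))


def _individual_ids(n: int) -> list[str]:
    return [f"IND{i:04d}" for i in range(n)]


def _gene_ids(n: int) -> list[str]:
    return [f"GENE{i:04d}" for i in range(n)]


# ---------------------------------------------------------------------------
# cohort


def simulate_cohort(config: SimulationConfig) -> pd.DataFrame:
    """Simulate the baseline visit of the cohort.

    SBP and DBP are linear models in (age, sex, smoking, medication_use) with
    a correlated bivariate-normal residual; the hypertension indicator is
    SBP >= 140 or DBP >= 90 or medication use (the standard clinical rule).
    Genetic effects, when a causal spec is present, are added afterwards by
    :func:`apply_genetic_effects` (they require the genotype matrix).
    """
    config.validate()
    rng = _rng(config, _STREAM_COHORT)
    n = config.n_individuals
    age = np.clip(rng.normal(config.age_mean, config.age_sd, n), 18.0, 95.0)
    sex = rng.binomial(1, config.p_female, n)
    smoking = rng.binomial(1, config.p_smoking, n)
    medication = rng.binomial(1, config.p_medication, n)

    tn = config.trait_noise
    u = rng.standard_normal((n, 2))
    rho = tn.residual_correlation
    eps_sbp = tn.sd_sbp * u[:, 0]
    eps_dbp = tn.sd_dbp * (rho * u[:, 0] + np.sqrt(1.0 - rho**2) * u[:, 1])

    covs = {"age": age, "sex": sex, "smoking": smoking, "medication_use": medication}
    sbp = config.sbp_intercept + eps_sbp
    dbp = config.dbp_intercept + eps_dbp
    for name, (b_s, b_d) in config.covariate_effects.items():
        if name not in covs:
            raise ValueError(f"unknown covariate {name!r} in covariate_effects")
        sbp = sbp + b_s * covs[name]
        dbp = dbp + b_d * covs[name]

    cohort = pd.DataFrame(
        {
            "individual_id": _individual_ids(n),
            "visit": 1,
            "SBP": sbp,
            "DBP": dbp,
            "hypertension": 0,
            "age": age,
            "sex": sex,
            "smoking": smoking,
            "medication_use": medication,
            "genotyped": (np.arange(n) < config.n_genotyped).astype(int),
        }
    )
    cohort["hypertension"] = hypertension_indicator(cohort)
    return cohort


def hypertension_indicator(cohort: pd.DataFrame) -> np.ndarray:
    """SBP >= 140 or DBP >= 90 or on antihypertensive medication."""
    return (
        (cohort["SBP"] >= 140.0)
        | (cohort["DBP"] >= 90.0)
        | (cohort["medication_use"] == 1)
    ).astype(int).to_numpy()


# ---------------------------------------------------------------------------
# gene intervals


def _gene_intervals(config: SimulationConfig) -> pd.DataFrame:
    """Non-overlapping 1-based inclusive intervals tiling the chromosome."""
    rng = _rng(config, _STREAM_INTERVALS)
    lo, hi = config.gene_length_range
    lengths = rng.integers(lo, hi + 1, config.n_genes)
    gaps = rng.integers(_INTERGENE_GAP[0], _INTERGENE_GAP[1] + 1, config.n_genes)
    starts = np.empty(config.n_genes, dtype=np.int64)
    pos = 1
    for i in range(config.n_genes):
        pos += gaps[i]
        starts[i] = pos
        pos += lengths[i]
    return pd.DataFrame(
        {
            "gene_id": _gene_ids(config.n_genes),
            "chrom": config.chromosome_label,
            "start": starts,
            "end": starts + lengths - 1,
        }
    )


# ---------------------------------------------------------------------------
# genotypes


def _draw_maf(rng: np.random.Generator, config: SimulationConfig, size: int) -> np.ndarray:
    """Population MAFs from the rare/common mixture (all strictly > 0)."""
    rare = rng.random(size) < config.fraction_rare
    maf = np.where(
        rare,
        rng.uniform(*config.rare_maf_range, size),
        rng.uniform(*config.common_maf_range, size),
    )
    return maf


def simulate_genotypes(config: SimulationConfig) -> GenotypeMatrix:
    """Hardy-Weinberg dosages at independent variants for the genotyped
    individuals.

    Each gene interval receives an equal share of the variants (at least one;
    the first forced rare and, when the share allows, the second forced
    common, so gene-level rare/common splits exist by construction); any
    remainder is scattered uniformly over the whole chromosome and may fall
    between genes.
    """
    config.validate()
    ann = _gene_intervals(config)
    rng = _rng(config, _STREAM_GENOTYPES)

    per_gene = config.n_variants // config.n_genes
    n_rem = config.n_variants - per_gene * config.n_genes
    chrom_end = int(ann["end"].max()) + _INTERGENE_GAP[1]

    positions: list[np.ndarray] = []
    mafs: list[np.ndarray] = []
    for rec in ann.itertuples(index=False):
        span = np.arange(rec.start, rec.end + 1)
        pos = np.sort(rng.choice(span, size=min(per_gene, span.size), replace=False))
        maf = _draw_maf(rng, config, pos.size)
        # guarantee one rare and (if room) one common variant per gene,
        # unless the mixture is degenerate at either end
        if config.fraction_rare > 0.0:
            maf[0] = rng.uniform(*config.rare_maf_range)
        if pos.size >= 2 and config.fraction_rare < 1.0:
            maf[1] = rng.uniform(*config.common_maf_range)
        positions.append(pos)
        mafs.append(maf)
    if n_rem:
        pos = rng.integers(1, chrom_end + 1, n_rem)
        positions.append(pos)
        mafs.append(_draw_maf(rng, config, n_rem))

    pos_all = np.concatenate(positions)
    maf_all = np.concatenate(mafs)
    order = np.argsort(pos_all, kind="stable")
    pos_all, maf_all = pos_all[order], maf_all[order]

    variants = pd.DataFrame(
        {
            "variant_id": [f"VAR{i:06d}" for i in range(pos_all.size)],
            "chrom": config.chromosome_label,
            "pos": pos_all,
            "maf_true": maf_all,
        }
    )
    dosages = rng.binomial(2, maf_all[None, :], size=(config.n_genotyped, pos_all.size))
    return GenotypeMatrix(
        individual_ids=_individual_ids(config.n_individuals)[: config.n_genotyped],
        variants=variants,
        dosages=dosages.astype(float),
    )


# ---------------------------------------------------------------------------
# annotation + gene sets


def simulate_annotation_and_sets(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, GeneSetCollection]:
    """Gene intervals plus curated-style gene sets.

    Set sizes on the target chromosome follow the heterogeneous mix observed
    in curated collections (mostly 1-5 genes, some 6-20, a few 21+), with a
    slice of sets having no gene on the chromosome at all; members beyond the
    chromosome are filled from an off-chromosome id universe absent from the
    annotation. When the config designates enriched sets, those sets contain
    the causal genes. Two sentinel sets are forced when n_sets allows: one
    with total size 9 (below the standard minimum-size-10 filter) and one
    with zero genes on the target chromosome.
    """
    config.validate()
    ann = _gene_intervals(config)
    rng = _rng(config, _STREAM_SETS)
    gene_ids = np.array(ann["gene_id"])
    off_ids = np.array([f"OFFCHR{i:04d}" for i in range(_OFF_CHROM_UNIVERSE)])
    lo, hi = config.set_size_range
    n_enriched = int(round(config.fraction_sets_enriched_for_causal_gene * config.n_sets))
    causal_ids = [c.gene_id for c in config.causal_spec]
    # In an enrichment experiment the background sets act as negative
    # controls: draw their on-chromosome members from non-causal genes so
    # enrichment is attributable to the constructed set alone.
    background_ids = (
        np.array([g for g in gene_ids if g not in causal_ids])
        if n_enriched > 0 and causal_ids else gene_ids
    )

    sets: dict[str, list[str]] = {}
    descs: dict[str, str] = {}
    for k in range(config.n_sets):
        name = f"SET{k:04d}"
        total = int(rng.integers(lo, hi + 1))
        enriched = k < n_enriched and bool(causal_ids)
        if enriched:
            # every on-chromosome member carries effects; off-chromosome
            # filler only pads the total size past the min-size filter
            on = list(causal_ids)
            total = max(total, 10, len(on))
            desc = "synthetic enriched set (contains causal genes)"
        else:
            u = rng.random()
            if u < 0.08:
                n_on = 0
            elif u < 0.72:
                n_on = int(rng.integers(1, 6))
            elif u < 0.94:
                n_on = int(rng.integers(6, 21))
            else:
                band_hi = min(140, len(gene_ids))
                n_on = int(rng.integers(21, band_hi + 1)) if band_hi >= 21 else len(gene_ids)
            n_on = min(n_on, total, len(background_ids))
            on = list(rng.choice(background_ids, size=n_on, replace=False))
            desc = "synthetic null set"
        # sentinels exercising both downstream filters
        if not enriched and k == config.n_sets - 2 and hi >= 9 and config.n_sets >= 3:
            total = 9
            on = on[: min(len(on), 4)] or list(rng.choice(background_ids, size=1))
            desc = "synthetic sentinel: total size 9 (below min-size filter)"
        if not enriched and k == config.n_sets - 1 and config.n_sets >= 3:
            on = []
            total = max(total, 10)
            desc = "synthetic sentinel: no gene on target chromosome"
        n_off = max(total - len(on), 0)
        off = list(rng.choice(off_ids, size=n_off, replace=False))
        sets[name] = on + off
        descs[name] = desc
    return ann, GeneSetCollection(sets=sets, descriptions=descs)


# ---------------------------------------------------------------------------
# genetic effects


def _residual_sd(config: SimulationConfig) -> tuple[float, float]:
    return config.trait_noise.sd_sbp, config.trait_noise.sd_dbp


def apply_genetic_effects(
    cohort: pd.DataFrame,
    genotypes: GenotypeMatrix,
    config: SimulationConfig,
) -> pd.DataFrame:
    """Add per-variant effects of the causal genes to SBP and DBP.

    Effect sizes are in units of each trait's residual SD (see
    :class:`~towpath.config.CausalGene` for the two scaling rules); effects
    apply to genotyped individuals only and the hypertension indicator is
    recomputed afterwards.
    """
    if not config.causal_spec:
        return cohort
    ann = _gene_intervals(config).set_index("gene_id")
    rng = _rng(config, _STREAM_EFFECTS)
    pos = genotypes.variants["pos"].to_numpy()
    maf = genotypes.variants["maf_true"].to_numpy()
    sd_s, sd_d = _residual_sd(config)

    cohort = cohort.copy()
    geno_rows = cohort["individual_id"].isin(genotypes.individual_ids)
    row_order = cohort.loc[geno_rows, "individual_id"].tolist()
    if row_order != genotypes.individual_ids:
        raise ValueError("cohort and genotype individual ids are inconsistent")

    add_s = np.zeros(genotypes.n_individuals)
    add_d = np.zeros(genotypes.n_individuals)
    for spec in config.causal_spec:
        if spec.gene_id not in ann.index:
            raise ValueError(f"causal gene {spec.gene_id!r} is not in the annotation")
        g = ann.loc[spec.gene_id]
        in_gene = np.flatnonzero((pos >= g["start"]) & (pos <= g["end"]))
        if in_gene.size == 0:
            log.warning("causal gene %s contains no variants", spec.gene_id)
            continue
        k = max(1, int(round(spec.fraction_causal * in_gene.size)))
        chosen = rng.choice(in_gene, size=k, replace=False)
        for j in chosen:
            if spec.rule == "standardized":
                scale = 1.0 / np.sqrt(2.0 * maf[j] * (1.0 - maf[j]))
            else:
                scale = 1.0
            x = genotypes.dosages[:, j]
            add_s += spec.effect_size * sd_s * scale * x
            add_d += spec.effect_size * sd_d * scale * x
    cohort.loc[geno_rows, "SBP"] = cohort.loc[geno_rows, "SBP"].to_numpy() + add_s
    cohort.loc[geno_rows, "DBP"] = cohort.loc[geno_rows, "DBP"].to_numpy() + add_d
    cohort["hypertension"] = hypertension_indicator(cohort)
    return cohort


# ---------------------------------------------------------------------------
# bundle


def simulate_bundle(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, GenotypeMatrix, pd.DataFrame, GeneSetCollection]:
    """Cohort, genotypes, annotation and sets in one deterministic call."""
    cohort = simulate_cohort(config)
    genotypes = simulate_genotypes(config)
    annotation, sets = simulate_annotation_and_sets(config)
    cohort = apply_genetic_effects(cohort, genotypes, config)
    return cohort, genotypes, annotation, sets


def write_fixture_bundle(
    cohort: pd.DataFrame,
    genotypes: GenotypeMatrix,
    annotation: pd.DataFrame,
    sets: GeneSetCollection,
    directory,
    config: SimulationConfig | None = None,
    write_vcf: bool = False,
) -> dict:
    """Write the four fixture files (+ optional VCF) and a checksum manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    missing = set(genotypes.individual_ids) - set(cohort["individual_id"])
    if missing:
        raise ValueError(
            f"genotyped individuals absent from cohort: {sorted(missing)[:5]}"
        )
    paths = {
        "cohort": directory / "cohort.tsv",
        "genotypes": directory / "genotypes.tsv",
        "annotation": directory / "annotation.tsv",
        "gene_sets": directory / "gene_sets.gmt",
    }
    tio.write_cohort_tsv(cohort, paths["cohort"])
    tio.write_genotype_tsv(genotypes, paths["genotypes"])
    tio.write_annotation_tsv(annotation, paths["annotation"])
    tio.write_gmt(sets, paths["gene_sets"])
    if write_vcf:
        paths["vcf"] = directory / "genotypes.vcf"
        tio.write_vcf(genotypes, paths["vcf"])
    manifest = {
        "files": tio.file_manifest(paths),
        "n_individuals": int(len(cohort)),
        "n_genotyped": int(genotypes.n_individuals),
        "n_variants": int(genotypes.n_variants),
        "n_genes": int(len(annotation)),
        "n_sets": int(len(sets)),
    }
    if config is not None:
        manifest["seed"] = int(config.seed)
    tio.write_json(manifest, directory / "manifest.json")
    return manifest


def gene_seed(master_seed: int, entity_id: str) -> np.random.SeedSequence:
    """Deterministic per-entity RNG seed: (master seed, CRC32 of the id)."""
    return np.random.SeedSequence([int(master_seed), zlib.crc32(entity_id.encode())])
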