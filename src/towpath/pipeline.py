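"""End-to-end orchestration: simulate (or load) -> derive -> map -> score -> enrich.

A run is fully described by a :class:`RunConfig`; the resolved config is
serialized next to the outputs together with a manifest of file checksums,
stage timings and the counts each stage retained, so two runs with the same
config and seed are byte-identical in their result tables.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as tio
from .association import score_all_genes
from .config import PHENOTYPES, SimulationConfig, default_lambda_grid
from .gsea import GseaConfig, run_gsea
from .mapping import apply_minor_allele_coding, compute_maf, map_snps_to_genes
from .phenotypes import derive_phenotypes, descriptive_stats, select_baseline
from .simulate import simulate_bundle, write_fixture_bundle

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All pipeline inputs and parameters for one reproducible run."""

    output_dir: str = "towpath_run"
    # either the four input paths ...
    cohort_path: str | None = None
    genotype_path: str | None = None
    annotation_path: str | None = None
    gene_sets_path: str | None = None
    # ... or a simulation in their place
    simulate: bool = True
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    phenotypes: tuple[str, ...] = PHENOTYPES
    maf_threshold: float = 0.01
    flank_bp: int = 0
    permutations: int = 1000
    lambda_step: float = 0.01
    min_set_size: int = 10
    gsea_permutations: int = 1000
    weight_exponent: float = 1.0
    fdr_threshold: float = 0.05
    target_chrom: str | None = None
    seed: int = 0

    def validate(self) -> None:
        unknown = [p for p in self.phenotypes if p not in PHENOTYPES]
        if unknown:
            raise ValueError(f"unknown phenotypes {unknown}; choose from {PHENOTYPES}")
        if not 0 < self.maf_threshold <= 0.5:
            raise ValueError("maf_threshold must lie in (0, 0.5]")
        if self.permutations < 100 or self.gsea_permutations < 100:
            raise ValueError("permutation counts must be >= 100")
        if not 0 < self.fdr_threshold < 1:
            raise ValueError("fdr_threshold must lie in (0, 1)")
        if self.flank_bp < 0:
            raise ValueError("flank_bp must be >= 0")
        if not self.simulate:
            for name in ("cohort_path", "genotype_path", "annotation_path", "gene_sets_path"):
                p = getattr(self, name)
                if p is None:
                    raise ValueError(f"{name} is required when simulate=False")
                if not Path(p).exists():
                    raise FileNotFoundError(f"{name}: no such file: {p}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("simulation", None)
        cfg = cls(**raw)
        if sim_raw:
            from .config import CausalGene, TraitNoise

            causal = tuple(CausalGene(**c) for c in sim_raw.pop("causal_spec", []))
            noise = TraitNoise(**sim_raw.pop("trait_noise", {}))
            for key in ("rare_maf_range", "common_maf_range",
                        "gene_length_range", "set_size_range"):
                if key in sim_raw:
                    sim_raw[key] = tuple(sim_raw[key])
            if "covariate_effects" in sim_raw:
                sim_raw["covariate_effects"] = {
                    k: tuple(v) for k, v in sim_raw["covariate_effects"].items()
                }
            cfg.simulation = SimulationConfig(
                **sim_raw, causal_spec=causal, trait_noise=noise
            )
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        def plain(obj):
            if isinstance(obj, dict):
                return {k: plain(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [plain(v) for v in obj]
            return obj

        raw = plain(dataclasses.asdict(self))
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=True)


def _load_inputs(config: RunConfig):
    if config.simulate:
        cohort, genotypes, annotation, sets = simulate_bundle(config.simulation)
        inputs_dir = Path(config.output_dir) / "inputs"
        write_fixture_bundle(cohort, genotypes, annotation, sets, inputs_dir,
                             config=config.simulation)
        return cohort, genotypes, annotation, sets
    cohort = tio.read_cohort_tsv(config.cohort_path)
    gp = str(config.genotype_path)
    genotypes = tio.read_vcf(gp) if gp.endswith((".vcf", ".vcf.gz")) else tio.read_genotype_tsv(gp)
    ap = str(config.annotation_path)
    annotation = tio.read_annotation_bed(ap) if ap.endswith(".bed") else tio.read_annotation_tsv(ap)
    sets = tio.read_gmt(config.gene_sets_path)
    return cohort, genotypes, annotation, sets


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage for each selected phenotype; returns the manifest."""
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    counts: dict[str, int] = {}

    t0 = time.perf_counter()
    cohort, genotypes, annotation, sets = _load_inputs(config)
    timings["load"] = time.perf_counter() - t0
    counts["individuals_in_cohort"] = int(cohort["individual_id"].nunique())

    t0 = time.perf_counter()
    baseline = select_baseline(cohort, require_genotyped=True)
    derived = derive_phenotypes(baseline)
    counts["individuals_retained"] = int(len(derived))
    stats = descriptive_stats(derived)
    stats.to_csv(outdir / "descriptives.tsv", sep="\t", index=False)
    timings["derive"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    classification = compute_maf(genotypes, threshold=config.maf_threshold)
    genotypes = apply_minor_allele_coding(genotypes, classification)
    classification.to_csv(outdir / "variant_classification.tsv", sep="\t", index=False)
    gene_map = map_snps_to_genes(genotypes, annotation, flank_bp=config.flank_bp)
    counts["variants_total"] = int(genotypes.n_variants)
    counts["variants_mapped"] = int(genotypes.n_variants - gene_map.n_unmapped)
    counts["genes_annotated"] = int(len(annotation))
    timings["map"] = time.perf_counter() - t0

    target_chrom = config.target_chrom or str(annotation["chrom"].iloc[0])
    lam = default_lambda_grid(config.lambda_step)
    result_files: dict[str, Path] = {}
    for phenotype in config.phenotypes:
        t0 = time.perf_counter()
        scores, drop_log = score_all_genes(
            derived, genotypes, gene_map, classification, phenotype,
            B=config.permutations, lambda_grid=lam, seed=config.seed,
            maf_threshold=config.maf_threshold,
        )
        tag = phenotype.replace("-", "_")
        scores_path = outdir / f"gene_scores_{tag}.tsv"
        scores.to_csv(scores_path, sep="\t", index=False)
        drop_log.to_csv(outdir / f"gene_drop_log_{tag}.tsv", sep="\t", index=False)
        counts[f"genes_scored_{tag}"] = int(len(scores))
        timings[f"score_{tag}"] = time.perf_counter() - t0

        t0 = time.perf_counter()
        gcfg = GseaConfig(
            min_set_size=config.min_set_size,
            n_permutations=config.gsea_permutations,
            weight_exponent=config.weight_exponent,
            fdr_threshold=config.fdr_threshold,
            seed=config.seed,
        )
        table, extras = run_gsea(scores, sets, annotation, target_chrom, gcfg)
        enrich_path = outdir / f"enrichment_{tag}.tsv"
        table.to_csv(enrich_path, sep="\t", index=False)
        extras["size_report"].to_csv(outdir / f"set_size_report_{tag}.tsv",
                                     sep="\t", index=False)
        counts[f"sets_kept_{tag}"] = int(len(table))
        counts[f"sets_enriched_{tag}"] = int(table["enriched"].sum()) if len(table) else 0
        timings[f"enrich_{tag}"] = time.perf_counter() - t0
        result_files[f"gene_scores_{tag}"] = scores_path
        result_files[f"enrichment_{tag}"] = enrich_path
        log.info("phenotype %s: %d genes scored, %d sets kept, %d enriched",
                 phenotype, len(scores), len(table), counts[f"sets_enriched_{tag}"])

    config.to_yaml(outdir / "run_config.yaml")
    manifest = {
        "seed": int(config.seed),
        "phenotypes": list(config.phenotypes),
        "counts": counts,
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
        "files": tio.file_manifest(result_files),
        "complete": True,
    }
    tio.write_json(manifest, outdir / "manifest.json")
    return manifest
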