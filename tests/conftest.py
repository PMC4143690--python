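import numpy as np
import pytest

import towpath as tp
from towpath.mapping import apply_minor_allele_coding, compute_maf, map_snps_to_genes
from towpath.phenotypes import derive_phenotypes, select_baseline


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale fixture: 80 individuals (70 genotyped, enough that singleton
    carriers fall below the 1% MAF threshold), 20 genes, 300 variants."""
    return tp.SimulationConfig(
        seed=20240917,
        n_individuals=80,
        n_genotyped=70,
        n_variants=300,
        n_genes=20,
        n_sets=40,
        set_size_range=(3, 25),
    )


@pytest.fixture(scope="session")
def bundle(small_config):
    return tp.simulate_bundle(small_config)


@pytest.fixture(scope="session")
def derived_cohort(bundle):
    cohort, *_ = bundle
    return derive_phenotypes(select_baseline(cohort, require_genotyped=True))


@pytest.fixture(scope="session")
def mapped(bundle):
    _, genotypes, annotation, _ = bundle
    classification = compute_maf(genotypes)
    genotypes = apply_minor_allele_coding(genotypes, classification)
    gene_map = map_snps_to_genes(genotypes, annotation)
    return genotypes, classification, gene_map


@pytest.fixture(scope="session")
def scored(bundle, derived_cohort, mapped):
    _, _, annotation, sets = bundle
    genotypes, classification, gene_map = mapped
    scores, drop_log = tp.score_all_genes(
        derived_cohort, genotypes, gene_map, classification,
        phenotype="MAP", B=150, seed=11,
    )
    return scores, drop_log


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
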