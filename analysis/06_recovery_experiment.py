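#!/usr/bin/env python
"""Enrichment-recovery demonstration.

Constructs a fixture in which one gene set's on-chromosome members all carry
strong per-allele effects on both pressure traits, runs the full
score-and-enrich pipeline on MAP, and shows that the causal set tops the NES
ranking while a matched effect-free fixture declares nothing. Also draws the
causal set's running-sum trace to results/figures/.
"""

import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

import matplotlib  # noqa: E402

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from towpath import CausalGene, GseaConfig, SimulationConfig, run_gsea, score_all_genes, simulate_bundle  # noqa: E402
from towpath.gsea import build_ranked_list, enrichment_score  # noqa: E402
from towpath.mapping import apply_minor_allele_coding, compute_maf, map_snps_to_genes  # noqa: E402
from towpath.phenotypes import derive_phenotypes, select_baseline  # noqa: E402

SEED = 107
RESULTS = ROOT / "results"

CAUSAL = tuple(
    CausalGene(f"GENE{i:04d}", effect_size=1.0, fraction_causal=0.75, rule="per_allele")
    for i in (5, 10, 15, 20, 25, 30, 35, 40)
)


def run_one(causal: bool):
    cfg = SimulationConfig(
        seed=SEED, n_individuals=129, n_genotyped=129, n_variants=600,
        n_genes=60, n_sets=60, set_size_range=(3, 30),
        causal_spec=CAUSAL if causal else (),
        fraction_sets_enriched_for_causal_gene=(1.0 / 60.0 if causal else 0.0),
    )
    cohort, geno, ann, sets = simulate_bundle(cfg)
    derived = derive_phenotypes(select_baseline(cohort))
    cls = compute_maf(geno)
    geno = apply_minor_allele_coding(geno, cls)
    gmap = map_snps_to_genes(geno, ann)
    scores, _ = score_all_genes(derived, geno, gmap, cls, "MAP", B=300, seed=SEED)
    table, extras = run_gsea(scores, sets, ann, "3",
                             GseaConfig(n_permutations=300, seed=SEED))
    return scores, sets, table, extras


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    scores, sets, table, extras = run_one(causal=True)
    table.to_csv(RESULTS / "06_enrichment_causal.tsv", sep="\t", index=False)
    top = table.iloc[0]
    print("causal fixture, top sets:")
    print(table.head(5)[["pathway", "n_genes_on_list", "ES", "NES", "p", "FDR_q"]]
          .to_string(index=False))
    print(f"-> top NES set is {top['pathway']} "
          f"({'the constructed causal set' if top['pathway'] == 'SET0000' else 'NOT the causal set'})")

    null_table = run_one(causal=False)[2]
    null_table.to_csv(RESULTS / "06_enrichment_null.tsv", sep="\t", index=False)
    print(f"null fixture: {int(null_table['enriched'].sum())} of "
          f"{len(null_table)} sets at q < 0.05")

    # running-sum trace of the causal set
    ranked = build_ranked_list(scores)
    members = [g for g in sets["SET0000"] if g in set(ranked["gene_id"])]
    es, run = enrichment_score(ranked, members)
    fig, ax = plt.subplots(figsize=(6, 3))
    ax.plot(range(1, len(run) + 1), run, lw=1.5)
    ax.axhline(0, color="grey", lw=0.5)
    ax.set_xlabel("gene rank (ascending association p)")
    ax.set_ylabel("running enrichment sum")
    ax.set_title(f"causal set SET0000: ES = {es:.3f}")
    fig.tight_layout()
    (RESULTS / "figures").mkdir(exist_ok=True)
    fig.savefig(RESULTS / "figures" / "06_running_sum_SET0000.png", dpi=120)
    print(f"running-sum trace saved (ES = {es:.3f})")


if __name__ == "__main__":
    main()
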