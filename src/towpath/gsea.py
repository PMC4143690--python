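"""Preranked gene-set enrichment over the gene-level association p-values.

Genes are ranked by ascending p-value and carry the nonnegative score
s_g = -log10(p_g). For a set S with N_H members on the N-gene list, the
reported enrichment score is the maximum of a weighted
Kolmogorov-Smirnov-like running sum that adds s_i^alpha / sum_{hits} s^alpha
at each member and subtracts 1/(N - N_H) at each non-member; with the
max-positive-deviation convention the reported ES lies in [0, 1].

Significance is calibrated by gene-set permutation: random same-size sets
drawn from the ranked list. The null keeps the SIGNED deviation (the running
sum's value at its largest absolute excursion, in [-1, 1]); a random set
whose members sit in the bottom half of the list scores negative. The test
of overrepresentation is then one-sided within the positive null:
NES = signed ES / mean(positive null ES), the add-one empirical p counts
positive null values at least as large, and the pooled FDR q compares
observed NES against the pooled positive null NES with the standard
two-fraction estimator, clipping and a monotone pass. Without the signed
null, a single-member set at rank 1 would saturate at NES = 2 (its floored
null mean is 1/2 regardless of the score distribution), drowning genuinely
enriched multi-gene sets; within-sign normalization is also what the
reference preranked-GSEA implementations do. Sets with q below the declared
threshold (default 0.05) and positive NES are flagged enriched.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import GeneSetCollection
from .mapping import _norm_chrom
from .simulate import gene_seed

log = logging.getLogger(__name__)


@dataclass
class GseaConfig:
    min_set_size: int = 10
    n_permutations: int = 1000
    weight_exponent: float = 1.0
    fdr_threshold: float = 0.05
    seed: int = 0
    top_k: int = 10


# ---------------------------------------------------------------------------
# ranking


def build_ranked_list(scores: pd.DataFrame) -> pd.DataFrame:
    """Order genes by ascending p (ties broken lexicographically by gene id)
    and attach the ranking score -log10(p)."""
    if (scores["p"] <= 0).any():
        bad = scores.loc[scores["p"] <= 0, "gene_id"].tolist()
        raise ValueError(
            f"non-positive p-values for {bad[:5]}; add-one permutation p-values "
            "cannot be 0 — this signals an upstream bug"
        )
    if (scores["p"] > 1).any():
        raise ValueError("p-values above 1 encountered")
    ranked = (
        scores[["gene_id", "p"]]
        .sort_values(["p", "gene_id"], kind="stable")
        .reset_index(drop=True)
    )
    ranked["score"] = -np.log10(ranked["p"])
    ranked["rank"] = np.arange(1, len(ranked) + 1)
    return ranked


# ---------------------------------------------------------------------------
# set filtering


def filter_gene_sets(
    sets: GeneSetCollection,
    ranked: pd.DataFrame,
    annotation: pd.DataFrame,
    target_chrom: str,
    min_total: int = 10,
) -> tuple[GeneSetCollection, pd.DataFrame, pd.DataFrame]:
    """Keep sets with >= min_total genes overall and >= 1 gene on the target
    chromosome that is present in the ranked list.

    Returns (kept sets, per-set filter log, size-distribution report). The
    report counts kept sets by their number of on-chromosome ranked genes in
    the bands 1-5, 6-20 and 21+, with percentages.
    """
    chrom_genes = set(
        annotation.loc[_norm_chrom(annotation["chrom"]) == str(target_chrom).removeprefix("chr"),
                       "gene_id"]
    )
    listed = set(ranked["gene_id"])
    usable = chrom_genes & listed

    rows = []
    kept_names = []
    n_on_list: dict[str, int] = {}
    for name in sets:
        members = set(sets[name])
        n_total = len(members)
        n_on = len(members & usable)
        keep = n_total >= min_total and n_on >= 1
        reason = (
            "kept" if keep
            else (f"fewer than {min_total} genes in total" if n_total < min_total
                  else "no gene on target chromosome in ranked list")
        )
        rows.append({"set": name, "n_total": n_total, "n_on_chrom_listed": n_on,
                     "kept": keep, "reason": reason})
        if keep:
            kept_names.append(name)
            n_on_list[name] = n_on
    filter_log = pd.DataFrame(rows)
    kept = sets.subset(kept_names)

    bands = {"1-5": (1, 5), "6-20": (6, 20), "21+": (21, np.inf)}
    counts = {
        label: sum(1 for v in n_on_list.values() if lo <= v <= hi)
        for label, (lo, hi) in bands.items()
    }
    total = max(len(kept_names), 1)
    report = pd.DataFrame(
        {
            "band_on_chrom_genes": list(counts),
            "n_sets": list(counts.values()),
            "percent": [100.0 * c / total for c in counts.values()],
        }
    )
    log.info(
        "set filtering: %d/%d kept; on-chromosome size bands %s",
        len(kept_names), len(sets),
        {k: f"{v} ({100.0 * v / total:.1f}%)" for k, v in counts.items()},
    )
    return kept, filter_log, report


# ---------------------------------------------------------------------------
# enrichment score


def enrichment_score(
    ranked: pd.DataFrame, gene_set, weight_exponent: float = 1.0
) -> tuple[float, np.ndarray]:
    """Weighted KS-like running sum; returns (ES, full running-sum trace).

    Requires 1 <= N_H < N members of the set on the list. If the weighted hit
    mass is zero (all hit scores zero), hit increments fall back to the
    unweighted 1/N_H.
    """
    genes = ranked["gene_id"].to_numpy()
    scores = ranked["score"].to_numpy(dtype=float)
    N = genes.size
    hit = np.isin(genes, list(gene_set))
    N_H = int(hit.sum())
    if N_H == 0:
        raise ValueError("gene set has no member on the ranked list")
    if N_H == N:
        raise ValueError("gene set covers the entire ranked list")
    weights = np.abs(scores) ** weight_exponent
    hit_mass = weights[hit].sum()
    inc = weights / hit_mass if hit_mass > 0 else np.full(N, 1.0 / N_H)
    step = np.where(hit, inc, -1.0 / (N - N_H))
    run = np.cumsum(step)
    return float(max(0.0, run.max())), run


def _signed_es_from_positions(sorted_pos: np.ndarray, weights: np.ndarray,
                              N: int) -> float:
    """Signed ES from hit positions only.

    The running sum peaks at a hit step and bottoms out just before one (it
    decays linearly between hits and ends at exactly 0), so both extrema are
    recovered from the N_H hit positions. Returns the value at the largest
    absolute excursion (peak wins ties), in [-1, 1].
    """
    N_H = sorted_pos.size
    w = weights[sorted_pos]
    mass = w.sum()
    inc = w / mass if mass > 0 else np.full(N_H, 1.0 / N_H)
    cum_hit = np.cumsum(inc)
    misses_before = (sorted_pos - np.arange(N_H)) / (N - N_H)  # 0-based
    peaks = cum_hit - misses_before
    dips = np.concatenate(([0.0], cum_hit[:-1])) - misses_before
    peak = float(max(peaks.max(), 0.0))
    dip = float(min(dips.min(), 0.0))
    return peak if peak >= -dip else dip


def signed_enrichment_score(
    ranked: pd.DataFrame, gene_set, weight_exponent: float = 1.0
) -> float:
    """Running-sum value at the largest absolute excursion, in [-1, 1]."""
    _, run = enrichment_score(ranked, gene_set, weight_exponent)
    mx, mn = float(run.max()), float(run.min())
    return mx if mx >= -mn else mn


def permutation_null(
    ranked: pd.DataFrame,
    gene_set,
    n_perm: int,
    weight_exponent: float = 1.0,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Signed null ES sample: each draw takes N_H gene labels uniformly
    without replacement from the ranked list and scores that random set."""
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(rng)
    genes = ranked["gene_id"].to_numpy()
    scores = ranked["score"].to_numpy(dtype=float)
    N = genes.size
    N_H = int(np.isin(genes, list(gene_set)).sum())
    if N_H == 0 or N_H == N:
        raise ValueError("set size on list must satisfy 1 <= N_H < N")
    weights = np.abs(scores) ** weight_exponent
    out = np.empty(n_perm)
    for b in range(n_perm):
        pos = np.sort(rng.choice(N, size=N_H, replace=False))
        out[b] = _signed_es_from_positions(pos, weights, N)
    return out


def normalize_and_test(es_observed: float, null_es: np.ndarray) -> tuple[float, float]:
    """One-sided normalization within the positive null.

    NES = ES / mean(positive null ES); the add-one empirical p counts the
    positive null values at least as large as the observed ES. Sets whose
    null has no positive mass are non-normalizable.
    """
    null_es = np.asarray(null_es, dtype=float)
    if null_es.size == 0:
        raise ValueError("empty null sample")
    pos = null_es[null_es > 0]
    if pos.size == 0 or pos.mean() <= 0:
        raise ValueError("null ES has no positive mass; set is non-normalizable")
    nes = es_observed / pos.mean()
    p = (1.0 + np.count_nonzero(pos >= es_observed)) / (pos.size + 1.0)
    return float(nes), float(p)


def fdr_q(observed_nes: np.ndarray, pooled_null_nes: np.ndarray) -> np.ndarray:
    """GSEA-style two-fraction FDR with clipping and a monotone pass.

    q_raw(S) = [fraction of pooled null NES >= NES(S)] /
               [fraction of observed NES >= NES(S)], clipped to [0, 1], then
    q(S) = min{ q_raw(S') : NES(S') <= NES(S) } so q is non-increasing in NES.
    """
    obs = np.asarray(observed_nes, dtype=float)
    null = np.asarray(pooled_null_nes, dtype=float)
    if obs.size == 0:
        return np.array([])
    if null.size == 0:
        raise ValueError("pooled null NES sample is empty")
    num = (null[None, :] >= obs[:, None]).mean(axis=1)
    den = (obs[None, :] >= obs[:, None]).mean(axis=1)
    q_raw = np.clip(num / den, 0.0, 1.0)
    # monotone pass: prefix-min along ascending NES order, so q at a high-NES
    # set never exceeds the q of any less significant set
    order = np.argsort(obs, kind="stable")
    q_sorted = q_raw[order]
    q_mono = np.minimum.accumulate(q_sorted)
    q = np.empty_like(q_raw)
    q[order] = q_mono
    return q


# ---------------------------------------------------------------------------
# end-to-end


def run_gsea(
    scores: pd.DataFrame,
    sets: GeneSetCollection,
    annotation: pd.DataFrame,
    target_chrom: str,
    config: GseaConfig | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Rank, filter, score and test every surviving gene set.

    Returns the enrichment table (pathway, n_genes_on_list, ES, NES, p,
    FDR_q, enriched; sorted by q then descending NES) and a dict of
    side-products (ranked list, filter log, size report, skipped sets).
    """
    cfg = config or GseaConfig()
    ranked = build_ranked_list(scores)
    kept, filter_log, size_report = filter_gene_sets(
        sets, ranked, annotation, target_chrom, min_total=cfg.min_set_size
    )
    if len(kept) == 0:
        log.warning("no gene sets survive filtering")
        empty = pd.DataFrame(
            columns=["pathway", "n_genes_on_list", "ES", "NES", "p", "FDR_q", "enriched"]
        )
        return empty, {"ranked": ranked, "filter_log": filter_log,
                       "size_report": size_report, "skipped": []}

    listed = set(ranked["gene_id"])
    rows = []
    skipped = []
    null_nes_pool = []
    for name in sorted(kept):
        members = [g for g in kept[name] if g in listed]
        try:
            es, run = enrichment_score(ranked, members, cfg.weight_exponent)
            mx, mn = float(run.max()), float(run.min())
            es_signed = mx if mx >= -mn else mn
            rng = np.random.default_rng(gene_seed(cfg.seed, name))
            null_es = permutation_null(
                ranked, members, cfg.n_permutations, cfg.weight_exponent, rng
            )
            nes, p = normalize_and_test(es_signed, null_es)
        except ValueError as exc:
            skipped.append({"set": name, "reason": str(exc)})
            continue
        null_pos = null_es[null_es > 0]
        null_nes_pool.append(null_pos / null_pos.mean())
        rows.append({"pathway": name, "n_genes_on_list": len(set(members)),
                     "ES": es, "NES": nes, "p": p})
    table = pd.DataFrame(rows)
    if len(table):
        pooled = np.concatenate(null_nes_pool)
        table["FDR_q"] = fdr_q(table["NES"].to_numpy(), pooled)
        table["enriched"] = (table["FDR_q"] < cfg.fdr_threshold) & (table["NES"] > 0)
        table = table.sort_values(
            ["FDR_q", "NES"], ascending=[True, False], kind="stable"
        ).reset_index(drop=True)
    else:
        table = pd.DataFrame(
            columns=["pathway", "n_genes_on_list", "ES", "NES", "p", "FDR_q", "enriched"]
        )
    if skipped:
        log.info("skipped %d sets: %s", len(skipped), [s["set"] for s in skipped][:5])
    return table, {"ranked": ranked, "filter_log": filter_log,
                   "size_report": size_report, "skipped": skipped}
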