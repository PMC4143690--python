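"""Ranked-list construction, set filtering, the weighted KS-like enrichment
score, permutation normalization and the pooled-null FDR."""

import numpy as np
import pandas as pd
import pytest

from towpath.datatypes import GeneSetCollection
from towpath.gsea import (
    GseaConfig,
    build_ranked_list,
    enrichment_score,
    fdr_q,
    filter_gene_sets,
    normalize_and_test,
    permutation_null,
    run_gsea,
)


def _scores(pairs):
    return pd.DataFrame(pairs, columns=["gene_id", "p"])


def _ranked(n=10, seed=3):
    rng = np.random.default_rng(seed)
    p = np.sort(rng.uniform(0.001, 1.0, n))
    return build_ranked_list(_scores(list(zip([f"G{i:03d}" for i in range(n)], p))))


class TestRankedList:
    def test_score_is_neg_log10_p(self):
        ranked = build_ranked_list(_scores([("A", 0.01)]))
        assert ranked.loc[0, "score"] == pytest.approx(2.0)

    def test_ties_break_lexicographically(self):
        ranked = build_ranked_list(_scores([("B", 0.5), ("A", 0.5), ("C", 0.1)]))
        assert ranked["gene_id"].tolist() == ["C", "A", "B"]

    def test_input_order_is_irrelevant(self):
        rows = [("A", 0.3), ("B", 0.1), ("C", 0.7), ("D", 0.05)]
        r1 = build_ranked_list(_scores(rows))
        r2 = build_ranked_list(_scores(rows[::-1]))
        pd.testing.assert_frame_equal(r1, r2)

    def test_zero_p_raises(self):
        with pytest.raises(ValueError, match="upstream bug"):
            build_ranked_list(_scores([("A", 0.0)]))

    def test_scores_non_increasing_down_the_list(self):
        ranked = _ranked(30)
        assert (np.diff(ranked["score"]) <= 1e-12).all()


class TestFilterGeneSets:
    @staticmethod
    def _fixture():
        ranked = _ranked(12)
        ann = pd.DataFrame({
            "gene_id": [f"G{i:03d}" for i in range(12)],
            "chrom": "3",
            "start": np.arange(12) * 1000 + 1,
            "end": np.arange(12) * 1000 + 500,
        })
        listed = [f"G{i:03d}" for i in range(12)]
        off = [f"OFF{i}" for i in range(60)]
        sets = GeneSetCollection(sets={
            "nine_total": listed[:4] + off[:5],                 # 9 genes -> dropped
            "fifty_off_chrom": off[:50],                        # no on-chrom gene -> dropped
            "boundary": [listed[0]] + off[:9],                  # 10 total, 1 on-chrom -> kept
            "big": listed[:6] + off[:10],
        })
        return sets, ranked, ann

    def test_both_filters_applied_at_boundaries(self):
        sets, ranked, ann = self._fixture()
        kept, log, _ = filter_gene_sets(sets, ranked, ann, "3", min_total=10)
        assert set(kept.sets) == {"boundary", "big"}
        reasons = log.set_index("set")["reason"]
        assert "fewer than 10" in reasons["nine_total"]
        assert "no gene on target chromosome" in reasons["fifty_off_chrom"]

    def test_size_report_bands(self):
        sets, ranked, ann = self._fixture()
        _, _, report = filter_gene_sets(sets, ranked, ann, "3", min_total=10)
        by_band = report.set_index("band_on_chrom_genes")["n_sets"]
        assert by_band["1-5"] == 1 and by_band["6-20"] == 1 and by_band["21+"] == 0


class TestEnrichmentScore:
    def test_single_member_at_top_scores_one(self):
        ranked = _ranked(10)
        es, _ = enrichment_score(ranked, [ranked["gene_id"].iloc[0]])
        assert es == pytest.approx(1.0)

    def test_single_member_at_bottom_scores_zero(self):
        ranked = _ranked(10)
        es, run = enrichment_score(ranked, [ranked["gene_id"].iloc[-1]])
        assert es == 0.0
        assert run[-1] == pytest.approx(0.0, abs=1e-12)

    def test_matches_step_by_step_oracle_on_ten_gene_fixture(self):
        """Independent running-sum trace: hits at ranks 1, 2 and 7."""
        ranked = _ranked(10)
        hits = ranked["gene_id"].iloc[[0, 1, 6]].tolist()
        s = ranked["score"].to_numpy()
        mass = s[0] + s[1] + s[6]
        run_oracle, cur, best = [], 0.0, 0.0
        for i in range(10):
            cur += (s[i] / mass) if i in (0, 1, 6) else -1.0 / 7.0
            run_oracle.append(cur)
            best = max(best, cur)
        es, run = enrichment_score(ranked, hits)
        assert np.allclose(run, run_oracle)
        assert es == pytest.approx(best)

    def test_running_sum_terminates_at_zero(self):
        ranked = _ranked(25, seed=9)
        hits = ranked["gene_id"].iloc[[2, 5, 11, 19]].tolist()
        for alpha in (0.0, 1.0):
            es, run = enrichment_score(ranked, hits, weight_exponent=alpha)
            assert run[-1] == pytest.approx(0.0, abs=1e-10)
            assert 0.0 <= es <= 1.0

    def test_degenerate_sets_rejected(self):
        ranked = _ranked(5)
        with pytest.raises(ValueError, match="no member"):
            enrichment_score(ranked, ["ABSENT"])
        with pytest.raises(ValueError, match="entire"):
            enrichment_score(ranked, ranked["gene_id"].tolist())

    def test_matches_gseapy_prerank(self):
        """Independent implementation cross-check on a top-loaded set."""
        import gseapy as gp

        ranked = _ranked(50, seed=12)
        S = ranked["gene_id"].iloc[[0, 2, 5, 9, 14]].tolist()
        es, _ = enrichment_score(ranked, S, weight_exponent=1.0)
        res = gp.prerank(rnk=ranked[["gene_id", "score"]], gene_sets={"S": S},
                         permutation_num=10, min_size=1, max_size=100,
                         outdir=None, seed=1, no_plot=True, weight=1.0)
        assert es == pytest.approx(res.results["S"]["es"], rel=1e-6)


class TestPermutationNull:
    def test_values_signed_in_unit_band_and_deterministic(self):
        ranked = _ranked(30, seed=4)
        S = ranked["gene_id"].iloc[[1, 3, 8]].tolist()
        a = permutation_null(ranked, S, 200, rng=7)
        b = permutation_null(ranked, S, 200, rng=7)
        assert np.array_equal(a, b)
        assert ((a >= -1) & (a <= 1)).all()
        assert (a > 0).any() and (a < 0).any()  # both tails populated

    def test_single_gene_null_matches_closed_form(self):
        """With equal ranking scores and N_H = 1, the signed ES for a hit at
        rank k is 1 - d when the peak dominates and -d otherwise, where
        d = (k-1)/(N-1) and k is uniform over ranks."""
        N = 40
        ranked = build_ranked_list(
            _scores([(f"G{i:03d}", 0.5) for i in range(N)])
        )
        null = permutation_null(ranked, [ranked["gene_id"].iloc[0]], 2000, rng=3)
        d = np.arange(N) / (N - 1)
        allowed = np.where(1.0 - d >= d, 1.0 - d, -d)
        assert all(np.isclose(v, allowed).any() for v in null)
        # means within ~3 MC standard errors at 2000 draws
        assert abs(null.mean() - allowed.mean()) < 0.04
        assert abs(null[null > 0].mean() - allowed[allowed > 0].mean()) < 0.04

    def test_agrees_with_full_trace_signed_score(self):
        """Hit-positions-only evaluation equals the full running-sum signed
        extremum for random sets."""
        from towpath.gsea import signed_enrichment_score, _signed_es_from_positions

        ranked = _ranked(35, seed=6)
        rng = np.random.default_rng(2)
        weights = np.abs(ranked["score"].to_numpy()) ** 1.0
        for _ in range(25):
            k = int(rng.integers(1, 12))
            pos = np.sort(rng.choice(35, size=k, replace=False))
            S = ranked["gene_id"].iloc[pos].tolist()
            assert _signed_es_from_positions(pos, weights, 35) == pytest.approx(
                signed_enrichment_score(ranked, S), abs=1e-12
            )

    def test_minimum_permutations_enforced(self):
        ranked = _ranked(10)
        with pytest.raises(ValueError, match="at least 100"):
            permutation_null(ranked, [ranked["gene_id"].iloc[0]], 10, rng=1)


class TestNormalizeAndFdr:
    def test_degenerate_null_gives_unit_nes_and_p_one(self):
        nes, p = normalize_and_test(0.4, np.full(100, 0.4))
        assert nes == pytest.approx(1.0)
        assert p == 1.0

    def test_extreme_observed_hits_add_one_bound(self):
        nes, p = normalize_and_test(0.9, np.full(1000, 0.3))
        assert p == pytest.approx(1.0 / 1001.0)
        assert nes == pytest.approx(3.0)

    def test_nes_is_direct_division_by_null_mean(self, rng):
        null = rng.uniform(0.1, 0.6, 500)
        nes, _ = normalize_and_test(0.5, null)
        assert nes == pytest.approx(0.5 / null.mean())

    def test_zero_null_mean_flags_non_normalizable(self):
        with pytest.raises(ValueError, match="non-normalizable"):
            normalize_and_test(0.2, np.zeros(100))

    def test_fdr_extreme_and_exchangeable_cases(self, rng):
        obs = np.array([3.0, 1.0, 0.9, 0.8])
        null = rng.uniform(0.5, 2.0, 1000)
        q = fdr_q(obs, null)
        assert q[0] == 0.0  # above every null and every other observed NES
        same = np.full(5, 1.2)
        assert np.allclose(fdr_q(same, same), 1.0)

    def test_fdr_matches_direct_two_fraction_oracle(self, rng):
        """5-set fixture against an independent loop implementation."""
        obs = rng.uniform(0.8, 2.5, 5)
        null = rng.uniform(0.3, 2.2, 800)
        q = fdr_q(obs, null)
        q_oracle = []
        for s in range(5):
            num = np.mean(null >= obs[s])
            den = np.mean(obs >= obs[s])
            q_oracle.append(min(1.0, num / den))
        for s in range(5):
            expect = min(q_oracle[t] for t in range(5) if obs[t] <= obs[s])
            assert q[s] == pytest.approx(expect)
        order = np.argsort(obs)
        assert (np.diff(q[order]) <= 1e-12).all()  # non-increasing in NES


class TestRunGsea:
    def test_one_row_per_surviving_set(self, bundle, scored):
        _, _, ann, sets = bundle
        scores, _ = scored
        cfg = GseaConfig(n_permutations=150, seed=2)
        table, extras = run_gsea(scores, sets, ann, "3", cfg)
        kept = extras["filter_log"]["kept"].sum()
        assert len(table) + len(extras["skipped"]) == kept
        assert table["pathway"].is_unique
        assert ((table["ES"] >= 0) & (table["ES"] <= 1)).all()
        assert ((table["FDR_q"] >= 0) & (table["FDR_q"] <= 1)).all()

    def test_mean_null_nes_is_one_by_construction(self, bundle, scored):
        """Random same-size sets with positive signed ES have NES centred at
        1 after within-sign normalization."""
        from towpath.gsea import signed_enrichment_score

        _, _, ann, sets = bundle
        scores, _ = scored
        ranked = build_ranked_list(scores)
        rng = np.random.default_rng(8)
        genes = ranked["gene_id"].to_numpy()
        nes_vals = []
        for _ in range(60):
            S = rng.choice(genes, size=5, replace=False).tolist()
            es_signed = signed_enrichment_score(ranked, S)
            if es_signed <= 0:
                continue
            null = permutation_null(ranked, S, 200, rng=rng)
            nes_vals.append(normalize_and_test(es_signed, null)[0])
        assert len(nes_vals) >= 15
        assert abs(np.mean(nes_vals) - 1.0) < 0.15

    def test_no_surviving_sets_yields_empty_table(self, bundle, scored):
        _, _, ann, _ = bundle
        scores, _ = scored
        tiny = GeneSetCollection(sets={"small": ["GENE0001", "GENE0002"]})
        table, _ = run_gsea(scores, tiny, ann, "3", GseaConfig(n_permutations=150))
        assert table.empty
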