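"""Residualization and the optimally weighted gene-level statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

import towpath as tp
from towpath.association import (
    DegenerateVarianceError,
    residualize,
    score_all_genes,
    tow_permutation_p,
    tow_statistic,
    vw_tow,
)


def _closed_form_tow(y, X):
    """Independent oracle: T = sum_m cov_m^2 / ss_m, computed term by term."""
    yc = y - y.mean()
    T = 0.0
    for m in range(X.shape[1]):
        xc = X[:, m] - X[:, m].mean()
        T += float(yc @ xc) ** 2 / float(xc @ xc)
    return T


class TestResidualize:
    def test_intercept_only_is_centering(self, rng):
        y = rng.normal(size=20)
        X = rng.binomial(2, 0.3, (20, 3)).astype(float)
        res = residualize(y, X, None)
        assert np.allclose(res.y_res, y - y.mean())
        assert np.allclose(res.X_res, X - X.mean(axis=0))

    def test_perfect_fit_gives_zero_residuals(self, rng):
        Z = rng.normal(size=(30, 2))
        y = 1.5 + 2.0 * Z[:, 0] - 0.7 * Z[:, 1]
        res = residualize(y, rng.binomial(2, 0.3, (30, 2)).astype(float), Z)
        assert np.max(np.abs(res.y_res)) < 1e-10

    def test_residuals_orthogonal_to_covariates(self, rng):
        Z = rng.normal(size=(50, 3))
        y = rng.normal(size=50)
        X = rng.binomial(2, 0.2, (50, 4)).astype(float)
        res = residualize(y, X, Z)
        for j in range(3):
            z = Z[:, j]
            assert abs(res.y_res @ z) <= 1e-8 * np.linalg.norm(y) * np.linalg.norm(z)
            for m in range(4):
                assert abs(res.X_res[:, m] @ z) <= 1e-8 * np.linalg.norm(X[:, m]) * np.linalg.norm(z) + 1e-12
        assert abs(res.y_res.sum()) < 1e-8 * np.linalg.norm(y)

    def test_coefficients_match_statsmodels(self, rng):
        import statsmodels.api as sm

        Z = rng.normal(size=(40, 2))
        y = rng.normal(size=40)
        res = residualize(y, rng.binomial(2, 0.3, (40, 1)).astype(float), Z,
                          covariate_names=["a", "b"])
        fit = sm.OLS(y, sm.add_constant(Z)).fit()
        assert np.allclose(res.coef_y, fit.params, atol=1e-10)

    def test_collinear_covariates_named(self, rng):
        Z = rng.normal(size=(25, 2))
        Z = np.column_stack([Z, Z[:, 0] * 2.0])
        with pytest.raises(ValueError, match="collinear"):
            residualize(rng.normal(size=25), rng.binomial(2, 0.3, (25, 1)).astype(float),
                        Z, covariate_names=["age", "sex", "age_times_two"])


class TestTowStatistic:
    def test_constant_phenotype_gives_zero(self):
        X = np.array([[0, 1, 2, 0, 1, 2], [1, 0, 1, 0, 1, 0]], dtype=float).T
        r = tow_statistic(np.zeros(6), X)
        assert r.statistic == 0.0
        assert np.allclose(r.weights, 0.0)

    def test_single_variant_closed_form(self, rng):
        y = rng.normal(size=15)
        x = rng.binomial(2, 0.3, (15, 1)).astype(float)
        r = tow_statistic(y, x)
        yc, xc = y - y.mean(), x[:, 0] - x.mean()
        assert r.statistic == pytest.approx(float(yc @ xc) ** 2 / float(xc @ xc), rel=1e-12)

    def test_small_integer_fixture_matches_brute_force(self):
        """6 individuals x 2 variants; oracle forms w, x0 and the sum explicitly."""
        y = np.array([3.0, 1.0, 4.0, 1.0, 5.0, 9.0])
        X = np.array([[0, 1, 2, 0, 1, 0], [1, 0, 0, 2, 1, 1]], dtype=float).T
        w = []
        for m in range(2):
            xc = X[:, m] - X[:, m].mean()
            w.append(float((y - y.mean()) @ xc) / float(xc @ xc))
        x0 = X @ np.array(w)
        T_oracle = float((y - y.mean()) @ (x0 - x0.mean()))
        r = tow_statistic(y, X)
        assert r.statistic == pytest.approx(T_oracle, rel=1e-12)
        assert np.allclose(r.weights, w)

    def test_zero_variance_column_rejected(self, rng):
        X = np.column_stack([np.ones(10), rng.binomial(2, 0.3, 10)]).astype(float)
        with pytest.raises(ValueError, match="zero-variance"):
            tow_statistic(rng.normal(size=10), X)

    def test_too_few_individuals_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            tow_statistic(np.array([1.0, 2.0]), np.array([[0.0], [1.0]]))


class TestTowPermutation:
    def test_p_respects_add_one_bounds(self, rng):
        y = rng.normal(size=40)
        X = rng.binomial(2, 0.3, (40, 3)).astype(float)
        r = tow_permutation_p(y, X, B=100, rng=rng)
        assert 1.0 / 101.0 <= r.p <= 1.0

    def test_null_p_values_uniform(self):
        ps = []
        for g in range(200):
            rng = np.random.default_rng(5000 + g)
            y = rng.standard_normal(60)
            X = rng.binomial(2, 0.25, (60, 4)).astype(float)
            ps.append(tow_permutation_p(y, X, B=150, rng=rng).p)
        assert kstest(ps, "uniform").pvalue > 0.01

    def test_power_against_strong_single_variant_effect(self):
        """Per-allele effect of 2 phenotype SDs at n = 129: the test should
        reject at 5% in most replicates."""
        ps = []
        for rep in range(100):
            rng = np.random.default_rng(9000 + rep)
            x = rng.binomial(2, 0.3, (129, 1)).astype(float)
            y = 2.0 * x[:, 0] + rng.standard_normal(129)
            ps.append(tow_permutation_p(y, x, B=1000, rng=rng).p)
        assert np.median(ps) < 0.05

    def test_p_invariant_under_increasing_affine_transform(self, rng):
        y = rng.normal(size=50)
        X = rng.binomial(2, 0.3, (50, 3)).astype(float)
        perms = np.array([rng.permutation(50) for _ in range(200)])
        p1 = tow_permutation_p(y, X, permutations=perms).p
        p2 = tow_permutation_p(3.0 + 2.0 * y, X, permutations=perms).p
        assert p1 == p2

    def test_minimum_permutation_count_enforced(self, rng):
        with pytest.raises(ValueError, match="at least 100"):
            tow_permutation_p(rng.normal(size=10),
                              rng.binomial(2, 0.3, (10, 1)).astype(float),
                              B=10, rng=rng)


class TestVwTow:
    def test_lambda_grid_validated(self, rng):
        y = rng.normal(size=30)
        Xr = rng.binomial(2, 0.05, (30, 2)).astype(float)
        Xc = rng.binomial(2, 0.3, (30, 2)).astype(float)
        Xr[0] = np.maximum(Xr[0], 1)
        with pytest.raises(ValueError, match="lambda grid"):
            vw_tow(y, Xr, Xc, B=100, lambda_grid=[-0.1, 0.5], rng=rng)

    def test_endpoints_reduce_to_single_class_tow(self, rng):
        y = rng.standard_normal(60)
        Xr = rng.binomial(2, 0.05, (60, 3)).astype(float)
        Xc = rng.binomial(2, 0.3, (60, 4)).astype(float)
        Xr[0] = np.maximum(Xr[0], 1)
        perms = np.array([rng.permutation(60) for _ in range(200)])
        assert vw_tow(y, Xr, Xc, lambda_grid=[1.0], permutations=perms).p == \
            tow_permutation_p(y, Xr, permutations=perms).p
        assert vw_tow(y, Xr, Xc, lambda_grid=[0.0], permutations=perms).p == \
            tow_permutation_p(y, Xc, permutations=perms).p

    def test_empty_class_rejected(self, rng):
        y = rng.normal(size=30)
        Xc = rng.binomial(2, 0.3, (30, 2)).astype(float)
        with pytest.raises(ValueError, match="non-empty"):
            vw_tow(y, np.empty((30, 0)), Xc, B=100, rng=rng)

    def test_p_invariant_under_increasing_affine_transform(self, rng):
        y = rng.standard_normal(50)
        Xr = rng.binomial(2, 0.08, (50, 2)).astype(float)
        Xc = rng.binomial(2, 0.3, (50, 3)).astype(float)
        Xr[0] = np.maximum(Xr[0], 1)
        perms = np.array([rng.permutation(50) for _ in range(150)])
        r1 = vw_tow(y, Xr, Xc, permutations=perms)
        r2 = vw_tow(10.0 + 0.5 * y, Xr, Xc, permutations=perms)
        assert r1.p == r2.p
        assert r1.min_p_observed == r2.min_p_observed

    def test_observed_min_p_is_grid_minimum(self, rng):
        y = rng.standard_normal(60)
        Xr = rng.binomial(2, 0.05, (60, 2)).astype(float)
        Xc = rng.binomial(2, 0.3, (60, 3)).astype(float)
        Xr[0] = np.maximum(Xr[0], 1)
        r = vw_tow(y, Xr, Xc, B=150, rng=rng)
        assert r.min_p_observed == pytest.approx(r.p_lambda_observed.min())
        assert r.p >= 1.0 / (r.n_permutations + 1)


class TestCovariateAdjustment:
    def test_adjustment_restores_null_calibration_under_confounding(self):
        """A covariate driving both the trait and the variant frequencies
        inflates the unadjusted test; residualization restores uniformity."""
        p_adj, p_raw = [], []
        for g in range(150):
            rng = np.random.default_rng(31000 + g)
            z = rng.standard_normal(100)
            prob = np.clip(0.3 + 0.15 * z, 0.02, 0.98)
            X = rng.binomial(2, prob[:, None], (100, 4)).astype(float)
            y = z + rng.standard_normal(100)
            perms = np.array([rng.permutation(100) for _ in range(150)])
            res = residualize(y, X, z[:, None])
            p_adj.append(tow_permutation_p(res.y_res, res.X_res, permutations=perms).p)
            res0 = residualize(y, X, None)
            p_raw.append(tow_permutation_p(res0.y_res, res0.X_res, permutations=perms).p)
        assert kstest(p_adj, "uniform").pvalue > 0.01
        assert kstest(p_raw, "uniform").pvalue < 1e-4


class TestScoreAllGenes:
    def test_unknown_phenotype_rejected(self, bundle, derived_cohort, mapped):
        genotypes, classification, gene_map = mapped
        with pytest.raises(ValueError, match="phenotype"):
            score_all_genes(derived_cohort, genotypes, gene_map, classification,
                            "BMI", B=100)

    def test_one_row_per_gene_with_polymorphic_variants(self, bundle, mapped, scored):
        _, geno, ann, _ = bundle
        genotypes, classification, gene_map = mapped
        scores, drop_log = scored
        vclass = classification["vclass"].to_numpy()
        expect = [
            g for g in gene_map
            if (vclass[gene_map[g]] != "monomorphic").any()
        ]
        assert sorted(scores["gene_id"]) == sorted(expect)
        assert len(scores) + len(set(drop_log["gene_id"])) >= len(gene_map)

    def test_kind_reflects_variant_classes(self, mapped, scored):
        genotypes, classification, gene_map = mapped
        scores, _ = scored
        vclass = classification["vclass"].to_numpy()
        for rec in scores.itertuples(index=False):
            cls = vclass[gene_map[rec.gene_id]]
            has_rare = (cls == "rare").any()
            has_common = (cls == "common").any()
            if rec.kind == "VW-TOW":
                assert has_rare and has_common
            elif rec.kind == "TOW-rare-only":
                assert has_rare
            else:
                assert has_common

    def test_monomorphic_gene_lands_in_drop_log(self, derived_cohort):
        from towpath.datatypes import GeneVariantMap, GenotypeMatrix
        from towpath.mapping import compute_maf

        n = len(derived_cohort)
        X = np.column_stack([np.zeros(n), np.random.default_rng(0).binomial(2, 0.3, n)])
        gm = GenotypeMatrix(
            individual_ids=derived_cohort["individual_id"].tolist(),
            variants=pd.DataFrame({"variant_id": ["V0", "V1"], "chrom": "3",
                                   "pos": [100, 200]}),
            dosages=X,
        )
        cls = compute_maf(gm)
        vmap = GeneVariantMap(gene_to_variants={"DEAD": np.array([0]),
                                                "LIVE": np.array([1])})
        scores, drops = score_all_genes(derived_cohort, gm, vmap, cls, "SBP",
                                        B=100, seed=1)
        assert scores["gene_id"].tolist() == ["LIVE"]
        assert drops["gene_id"].tolist() == ["DEAD"]
        assert "polymorphic" in drops["reason"].iloc[0]

    def test_results_reproducible_for_fixed_seed(self, derived_cohort, mapped):
        genotypes, classification, gene_map = mapped
        a, _ = score_all_genes(derived_cohort, genotypes, gene_map, classification,
                               "SBP", B=120, seed=42)
        b, _ = score_all_genes(derived_cohort, genotypes, gene_map, classification,
                               "SBP", B=120, seed=42)
        pd.testing.assert_frame_equal(a, b)
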