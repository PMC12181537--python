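"""Statistical inference: partial correlation, FDR, CCA, permutation tests,
MOCA stratification, t-tests and k-means classification."""

import numpy as np
import pytest
from scipy import stats as sps

import connage as ca


class TestPartialCorrelation:
    def test_no_covariates_equals_plain_correlation(self, rng):
        x, y = rng.standard_normal(50), rng.standard_normal(50)
        res = ca.partial_correlation(x, y, method="pearson")
        assert res.rho == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-12)

    def test_three_variable_closed_form(self, rng):
        """Partial r matches (r_xy - r_xz r_yz)/sqrt((1-r_xz^2)(1-r_yz^2))."""
        for _ in range(200):
            z = rng.standard_normal(40)
            x = 0.5 * z + rng.standard_normal(40)
            y = -0.3 * z + rng.standard_normal(40)
            res = ca.partial_correlation(x, y, z, method="pearson")
            rxy = np.corrcoef(x, y)[0, 1]
            rxz = np.corrcoef(x, z)[0, 1]
            ryz = np.corrcoef(y, z)[0, 1]
            expected = (rxy - rxz * ryz) / np.sqrt((1 - rxz**2) * (1 - ryz**2))
            assert res.rho == pytest.approx(expected, abs=1e-10)

    def test_perfect_linear_relationship(self, rng):
        x = rng.standard_normal(30)
        z = rng.standard_normal(30)
        res = ca.partial_correlation(x, 2 * x + 3, z, method="pearson")
        assert res.rho == pytest.approx(1.0)
        assert res.p_value == 0.0

    def test_symmetry_in_arguments(self, rng):
        x, y = rng.standard_normal(40), rng.standard_normal(40)
        Z = rng.standard_normal((40, 2))
        a = ca.partial_correlation(x, y, Z)
        b = ca.partial_correlation(y, x, Z)
        assert a.rho == pytest.approx(b.rho, abs=1e-12)
        assert a.p_value == pytest.approx(b.p_value, abs=1e-12)

    def test_listwise_deletion_of_missing(self, rng):
        x = rng.standard_normal(30)
        y = x + 0.1 * rng.standard_normal(30)
        x[3] = np.nan
        res = ca.partial_correlation(x, y, method="pearson")
        assert res.n_effective == 29

    def test_spearman_is_rank_based(self, rng):
        x = rng.standard_normal(50)
        y = np.exp(x)  # monotone, nonlinear
        res = ca.partial_correlation(x, y, method="spearman")
        assert res.rho == pytest.approx(1.0)

    def test_variable_in_covariate_span_rejected(self, rng):
        z = rng.standard_normal(30)
        with pytest.raises(ValueError, match="zero-variance"):
            ca.partial_correlation(2 * z + 1, rng.standard_normal(30), z,
                                   method="pearson")


class TestBHFDR:
    def test_hand_step_up_example(self):
        reject, adj = ca.bh_fdr(np.array([0.01, 0.02, 0.5]), q=0.05)
        # by hand: p_(1)=0.01 <= 1*0.05/3, p_(2)=0.02 <= 2*0.05/3, p_(3)=0.5 > 0.05
        assert reject.tolist() == [True, True, False]

    def test_all_ones_no_rejection(self):
        reject, _ = ca.bh_fdr(np.ones(5))
        assert not reject.any()

    def test_single_hypothesis(self):
        assert ca.bh_fdr(np.array([0.04]), q=0.05)[0][0]
        assert not ca.bh_fdr(np.array([0.06]), q=0.05)[0][0]

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(50):
            p = rng.random(int(rng.integers(1, 40)))
            reject, adj = ca.bh_fdr(p, q=0.05)
            sm_rej, sm_adj, *_ = multipletests(p, alpha=0.05, method="fdr_bh")
            np.testing.assert_array_equal(reject, sm_rej)
            np.testing.assert_allclose(adj, sm_adj, atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            ca.bh_fdr(np.array([0.5, 1.5]))


class TestCCA:
    def test_duplicate_sets_give_unit_correlation(self, rng):
        X = rng.standard_normal((50, 3))
        res = ca.cca_first_pair(X, X.copy())
        assert res.r == pytest.approx(1.0, abs=1e-10)

    def test_bivariate_reduction(self, rng):
        x = rng.standard_normal(60)
        y = 0.6 * x + rng.standard_normal(60)
        res = ca.cca_first_pair(x, y)
        assert res.r == pytest.approx(abs(np.corrcoef(x, y)[0, 1]), abs=1e-10)
        np.testing.assert_allclose(np.abs(res.structure_x), 1.0, atol=1e-10)
        np.testing.assert_allclose(np.abs(res.structure_y), 1.0, atol=1e-10)

    def test_eigen_oracle_on_two_by_two_sets(self, rng):
        """First canonical correlation equals the largest root of the
        generalized eigenproblem Sxx^-1 Sxy Syy^-1 Syx."""
        for _ in range(30):
            n = 80
            X = rng.standard_normal((n, 2))
            Y = 0.5 * X @ rng.standard_normal((2, 2)) + rng.standard_normal((n, 2))
            res = ca.cca_first_pair(X, Y)
            Xc = X - X.mean(0)
            Yc = Y - Y.mean(0)
            Sxx, Syy = Xc.T @ Xc, Yc.T @ Yc
            Sxy = Xc.T @ Yc
            M = np.linalg.solve(Sxx, Sxy) @ np.linalg.solve(Syy, Sxy.T)
            r_expected = np.sqrt(np.max(np.linalg.eigvals(M).real))
            assert res.r == pytest.approx(r_expected, abs=1e-8)

    def test_variates_unit_variance_and_structure_bounds(self, rng):
        X = rng.standard_normal((60, 3))
        Y = rng.standard_normal((60, 2))
        res = ca.cca_first_pair(X, Y)
        assert res.variates_u.std(ddof=1) == pytest.approx(1.0, abs=1e-10)
        assert res.variates_v.std(ddof=1) == pytest.approx(1.0, abs=1e-10)
        assert np.all(np.abs(res.structure_x) <= 1 + 1e-12)
        assert np.all(np.abs(res.structure_y) <= 1 + 1e-12)
        assert 0 <= res.r <= 1

    def test_affine_rescaling_invariance(self, rng):
        X = rng.standard_normal((60, 3))
        Y = rng.standard_normal((60, 2))
        r1 = ca.cca_first_pair(X, Y).r
        X2 = X * np.array([3.0, -0.5, 10.0]) + np.array([1.0, 2.0, -7.0])
        r2 = ca.cca_first_pair(X2, Y).r
        assert r1 == pytest.approx(r2, abs=1e-10)

    def test_rank_deficient_set_rejected(self, rng):
        X = rng.standard_normal((40, 2))
        X = np.column_stack([X, X[:, 0] + X[:, 1]])
        with pytest.raises(ValueError, match="rank-deficient|collinear"):
            ca.cca_first_pair(X, rng.standard_normal((40, 2)))


class TestPermutationPvalue:
    def test_identical_vectors_give_minimum_p(self, rng):
        u = rng.standard_normal(50)
        p = ca.permutation_pvalue(u, u, B=999, rng=1)
        assert p == pytest.approx(1 / 1000)

    def test_single_permutation_two_atom_support(self, rng):
        u, v = rng.standard_normal(20), rng.standard_normal(20)
        p = ca.permutation_pvalue(u, v, B=1, rng=2)
        assert p in (0.5, 1.0)

    def test_null_uniformity(self):
        """Under independence, permutation p-values are uniform (KS test)."""
        rng = np.random.default_rng(99)
        ps = [
            ca.permutation_pvalue(
                rng.standard_normal(40), rng.standard_normal(40), B=200, rng=rng
            )
            for _ in range(100)
        ]
        assert sps.kstest(ps, "uniform").pvalue > 0.01

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            ca.permutation_pvalue(np.ones(10), np.arange(10.0), B=10)


class TestStratifyMoca:
    def test_boundary_cases(self):
        labels = ca.stratify_moca(np.array([14, 18, 24, 25, 28], dtype=float))
        assert labels.tolist() == ["MOCA-", "excluded", "excluded", "MOCA+", "MOCA+"]

    def test_all_missing_all_excluded(self):
        labels = ca.stratify_moca(np.full(4, np.nan))
        assert labels.tolist() == ["excluded"] * 4

    def test_counts_match_comparison_loop(self, rng):
        scores = rng.integers(10, 31, 100).astype(float)
        scores[rng.random(100) < 0.1] = np.nan
        labels = ca.stratify_moca(scores)
        for s, lab in zip(scores, labels):
            if np.isnan(s):
                assert lab == "excluded"
            elif s < 18:
                assert lab == "MOCA-"
            elif s >= 25:
                assert lab == "MOCA+"
            else:
                assert lab == "excluded"


class TestIndependentTTest:
    def test_identical_groups(self):
        a = np.array([1.0, 2.0, 3.0])
        t, p = ca.independent_t_test(a, a)
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_textbook_pooled_formula(self):
        a, b = np.array([1.0, 2.0, 3.0]), np.array([4.0, 5.0, 6.0])
        t, p = ca.independent_t_test(a, b)
        # pooled s^2 = 1, se = sqrt(1*(1/3+1/3)), t = (2-5)/se
        expected = (2.0 - 5.0) / np.sqrt(2.0 / 3.0)
        assert t == pytest.approx(expected, abs=1e-12)

    def test_antisymmetry(self, rng):
        a, b = rng.standard_normal(10), rng.standard_normal(12) + 1
        t1, p1 = ca.independent_t_test(a, b)
        t2, p2 = ca.independent_t_test(b, a)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_zero_variance_unequal_means_rejected(self):
        with pytest.raises(ValueError, match="zero pooled variance"):
            ca.independent_t_test(np.ones(3), np.full(3, 2.0))


class TestKMeansClassification:
    def test_separable_clusters_perfect_accuracy(self, rng):
        n = 40
        X = np.vstack([rng.standard_normal((n, 2)) + 8, rng.standard_normal((n, 2)) - 8])
        labels = np.array(["MOCA+"] * n + ["MOCA-"] * n)
        acc, accs = ca.kmeans_classification_accuracy(X, labels, iterations=50, seed=3)
        assert acc == 1.0

    def test_label_swap_invariance(self, rng):
        X = rng.standard_normal((60, 2))
        X[:30] += 1.5
        labels = np.array(["MOCA+"] * 30 + ["MOCA-"] * 30)
        swapped = np.where(labels == "MOCA+", "MOCA-", "MOCA+")
        a, _ = ca.kmeans_classification_accuracy(X, labels, iterations=100, seed=4)
        b, _ = ca.kmeans_classification_accuracy(X, swapped, iterations=100, seed=4)
        assert a == b

    def test_random_labels_near_matching_null(self):
        """With random labels the modal accuracy sits near the optimal-
        matching null level for n = 200, computed by Monte Carlo."""
        rng = np.random.default_rng(12)
        n = 200
        X = rng.standard_normal((n, 2))
        labels = np.where(rng.random(n) < 0.5, "MOCA+", "MOCA-")
        acc, _ = ca.kmeans_classification_accuracy(X, labels, iterations=100, seed=rng)
        # Monte-Carlo null: accuracy of best-matched random split vs random labels
        null = []
        for _ in range(100):
            y = rng.random(n) < 0.5
            c = rng.random(n) < 0.5
            agree = np.mean(y == c)
            null.append(max(agree, 1 - agree))
        se = np.std(null)
        assert abs(acc - np.mean(null)) < 3 * se + 0.05

    def test_excluded_subjects_ignored(self, rng):
        X = rng.standard_normal((30, 1))
        labels = np.array(["MOCA+"] * 10 + ["MOCA-"] * 10 + ["excluded"] * 10)
        acc, _ = ca.kmeans_classification_accuracy(X, labels, iterations=10, seed=5)
        assert 0.5 <= acc <= 1.0

    def test_empty_group_rejected(self, rng):
        X = rng.standard_normal((10, 1))
        labels = np.array(["MOCA+"] * 10)
        with pytest.raises(ValueError, match="non-empty"):
            ca.kmeans_classification_accuracy(X, labels, iterations=5, seed=6)
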