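import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import special

from coabund._wilks import residualize, wilks_lambda_single
from coabund.manocca import (
    covariance_test,
    fit_product_pca,
    inverse_normal_transform,
    manocca_scan,
    multiple_testing_thresholds,
    pairwise_products,
    standardize_columns,
    transform_products,
)


class TestStandardize:
    def test_already_standardized_unchanged(self):
        out = standardize_columns(np.array([[1.0], [-1.0]]))
        np.testing.assert_allclose(out, [[1.0], [-1.0]])

    def test_affine_map(self):
        out = standardize_columns(np.array([[0.0], [2.0]]))
        np.testing.assert_allclose(out, [[-1.0], [1.0]])

    def test_output_contract(self, rng):
        out = standardize_columns(rng.random((50, 4)))
        assert np.abs(out.mean(axis=0)).max() < 1e-12
        assert np.abs(out.var(axis=0) - 1).max() < 1e-10

    def test_zero_variance_names_taxon(self):
        Y = np.ones((10, 2))
        Y[:, 0] = np.arange(10)
        with pytest.raises(ValueError, match="tB"):
            standardize_columns(Y, taxon_ids=["tA", "tB"])


class TestPairwiseProducts:
    def test_perfect_correlation(self):
        P = pairwise_products(np.array([[1.0, 1.0], [-1.0, -1.0]]))
        np.testing.assert_allclose(P.values[:, 0], [1.0, 1.0])
        assert P.values[:, 0].mean() == pytest.approx(1.0)

    def test_anti_correlation(self):
        P = pairwise_products(np.array([[1.0, -1.0], [-1.0, 1.0]]))
        assert P.values[:, 0].mean() == pytest.approx(-1.0)

    def test_column_means_equal_correlations(self, rng):
        """Product-column means reproduce the correlation matrix exactly
        (independent oracle: np.corrcoef)."""
        Y = standardize_columns(rng.random((50, 6)))
        P = pairwise_products(Y)
        R = np.corrcoef(Y.T)
        for m, (i, j) in zip(P.values.mean(axis=0), P.pair_index):
            assert abs(m - R[i, j]) < 1e-12

    def test_pair_index_lexicographic(self, rng):
        P = pairwise_products(standardize_columns(rng.random((10, 5))))
        assert P.pair_index == sorted(P.pair_index)
        assert P.n_pairs == 10

    def test_single_column_rejected(self):
        with pytest.raises(ValueError, match="K"):
            pairwise_products(np.ones((5, 1)))


class TestInverseNormalTransform:
    def test_three_distinct_values_match_blom_formula(self):
        # oracle: Phi^-1((rank - 3/8) / (n + 1/4)) evaluated directly
        out = inverse_normal_transform(np.array([10.0, 20.0, 30.0]))
        expected = special.ndtri((np.array([1, 2, 3]) - 0.375) / 3.25)
        np.testing.assert_allclose(out, expected)
        assert out[1] == pytest.approx(0.0)
        assert out[2] == pytest.approx(0.8694, abs=1e-4)

    def test_ties_share_one_value(self):
        v = np.array([0.0, 0.0, 0.0, 1.0, 2.0, 3.0])
        out = inverse_normal_transform(v)
        assert len(set(out[:3])) == 1

    @given(st.lists(st.floats(-1e6, 1e6), min_size=3, max_size=50, unique=True))
    @settings(max_examples=30, deadline=None)
    def test_strictly_monotone(self, values):
        v = np.array(values)
        out = inverse_normal_transform(v)
        order = np.argsort(v)
        assert np.all(np.diff(out[order]) > 0)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            inverse_normal_transform(np.ones(10))

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="length"):
            inverse_normal_transform(np.array([1.0, 2.0]))


class TestProductPCA:
    def test_single_varying_column_gives_indicator_loading(self, rng):
        P = pairwise_products(standardize_columns(rng.random((20, 3))))
        vals = np.zeros_like(P.values)
        vals[:, 1] = rng.standard_normal(20)
        P.values = vals
        proj, _ = fit_product_pca(P, 1)
        lead = np.abs(proj.loadings[:, 0])
        assert lead[1] == pytest.approx(1.0)
        assert lead[[0, 2]].max() < 1e-12

    def test_explained_variance_non_increasing(self, rng):
        P = pairwise_products(standardize_columns(rng.random((40, 6))))
        P_int, _ = transform_products(P)
        proj, _ = fit_product_pca(P_int, 8)
        assert np.all(np.diff(proj.explained_variance) <= 1e-12)

    def test_loadings_unit_norm(self, rng):
        P = pairwise_products(standardize_columns(rng.random((40, 6))))
        P_int, _ = transform_products(P)
        proj, _ = fit_product_pca(P_int, 5)
        np.testing.assert_allclose(
            np.linalg.norm(proj.loadings, axis=0), 1.0, atol=1e-12
        )

    def test_residual_orthogonal_to_loadings(self, rng):
        """Rank-p reconstruction leaves a residual orthogonal to the
        retained loadings (linear-algebra oracle)."""
        P = pairwise_products(standardize_columns(rng.random((30, 5))))
        P_int, _ = transform_products(P)
        proj, _ = fit_product_pca(P_int, 3)
        centered = P_int.values - proj.train_means
        scores = centered @ proj.loadings
        residual = centered - scores @ proj.loadings.T
        assert np.abs(residual @ proj.loadings).max() < 1e-8

    def test_p_out_of_range_rejected(self, rng):
        P = pairwise_products(standardize_columns(rng.random((10, 4))))
        P_int, _ = transform_products(P)
        with pytest.raises(ValueError, match="out of range"):
            fit_product_pca(P_int, 11)


class TestCovarianceTest:
    def test_perfect_association(self, rng):
        Q = rng.standard_normal((100, 5))
        res = covariance_test(Q, Q[:, 0], None)
        assert res.p_value < 1e-10

    def test_joint_permutation_invariance(self, rng):
        Q = rng.standard_normal((60, 4))
        x = rng.standard_normal(60)
        C = rng.standard_normal((60, 2))
        perm = rng.permutation(60)
        r1 = covariance_test(Q, x, C)
        r2 = covariance_test(Q[perm], x[perm], C[perm])
        assert r1.p_value == pytest.approx(r2.p_value, rel=1e-10)

    def test_rank_deficient_covariates_rejected(self, rng):
        Q = rng.standard_normal((30, 3))
        x = rng.standard_normal(30)
        C = np.column_stack([np.arange(30.0), 2 * np.arange(30.0)])
        with pytest.raises(ValueError):
            covariance_test(Q, x, C)

    def test_too_many_components_rejected(self, rng):
        Q = rng.standard_normal((10, 9))
        with pytest.raises(ValueError, match="components"):
            covariance_test(Q, rng.standard_normal(10), None)

    def test_betas_are_per_component_slopes(self, rng):
        Q = rng.standard_normal((80, 3))
        x = rng.standard_normal(80)
        res = covariance_test(Q, x, None)
        xs = (x - x.mean()) / x.std()
        x_res = residualize(xs, None).ravel()
        expected = residualize(Q, None).T @ x_res / (x_res @ x_res)
        np.testing.assert_allclose(res.betas, expected, atol=1e-12)


class TestWilksMachinery:
    def test_rank_one_identity_matches_determinant_form(self, rng):
        """1 - R^2 shortcut equals det(E)/det(E+H) (oracle: determinants)."""
        Y = rng.standard_normal((50, 6))
        x = rng.standard_normal(50)
        Y_res = residualize(Y, None)
        x_res = residualize(x, None).ravel()
        wt = wilks_lambda_single(Y_res, x_res)
        bhat = x_res @ Y_res / (x_res @ x_res)
        H = np.outer(bhat, bhat) * (x_res @ x_res)
        E = Y_res.T @ Y_res - H
        lam_det = np.linalg.det(E) / np.linalg.det(E + H)
        assert wt.lambda_ == pytest.approx(lam_det, abs=1e-12)


class TestScan:
    def test_grid_of_one_matches_covariance_test(self, rng):
        Y = rng.random((60, 5)) + 0.05
        Y = Y / Y.sum(axis=1, keepdims=True)
        x = rng.standard_normal(60)
        res = manocca_scan(Y, x, None, p_grid=[4])
        vals = np.column_stack(
            [inverse_normal_transform(Y[:, j]) for j in range(5)]
        )
        Z = standardize_columns(vals)
        P_int, _ = transform_products(pairwise_products(Z))
        _, Q = fit_product_pca(P_int, 4)
        direct = covariance_test(Q, x, None)
        assert res.p_value == pytest.approx(direct.p_value, rel=1e-10)
        assert res.optimal_p == 4

    def test_deterministic(self, rng):
        Y = rng.random((50, 5)) + 0.05
        x = rng.standard_normal(50)
        r1 = manocca_scan(Y, x, None, p_grid=[2, 3, 4])
        r2 = manocca_scan(Y, x, None, p_grid=[2, 3, 4])
        np.testing.assert_array_equal(r1.p_values, r2.p_values)
        assert r1.optimal_p == r2.optimal_p

    def test_infeasible_grid_truncated_with_warning(self, rng):
        Y = rng.random((40, 4)) + 0.05
        x = rng.standard_normal(40)
        with pytest.warns(UserWarning, match="truncating"):
            res = manocca_scan(Y, x, None, p_grid=[2, 3, 50])
        assert res.p_grid == [2, 3]

    def test_zero_variance_taxon_dropped_with_warning(self, rng):
        Y = rng.random((40, 4)) + 0.05
        Y[:, 2] = 0.3
        x = rng.standard_normal(40)
        with pytest.warns(UserWarning, match="zero-variance"):
            res = manocca_scan(Y, x, None, p_grid=[2])
        assert res.projection.loadings.shape[0] == 3  # 3 taxa -> 3 pairs


class TestThresholds:
    def test_published_screen_dimensions(self):
        stringent, suggestive = multiple_testing_thresholds(80, 100)
        assert stringent == pytest.approx(6.25e-6)
        assert suggestive == pytest.approx(6.25e-4)

    def test_no_correction_case(self):
        assert multiple_testing_thresholds(1, 1) == (0.05, 0.05)

    def test_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            multiple_testing_thresholds(0, 10)
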