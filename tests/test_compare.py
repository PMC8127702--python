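import numpy as np
import pytest
from hypothesis import given, strategies as st

from gmatkit.compare import (
    covariance_tensor,
    krzanowski_subspace,
    predict_response,
    r_metric,
    random_skewers,
)
from conftest import random_pd_matrix


def _draws(M, n=4):
    """Replicate a fixed matrix as a degenerate posterior."""
    return np.repeat(np.asarray(M, float)[None], n, axis=0)


class TestKrzanowski:
    def test_six_identical_matrices_reach_the_population_bound(self):
        M = random_pd_matrix(np.random.default_rng(0), 6)
        res = krzanowski_subspace({f"P{i}": _draws(M) for i in range(6)}, k=3)
        np.testing.assert_allclose(res.eigenvalue_mean, [6, 6, 6, 0, 0, 0],
                                   atol=1e-9)

    def test_orthogonal_leading_eigenvectors_give_unit_eigenvalues(self):
        # two 2-trait populations whose k=1 subspaces are e1 and e2
        A = np.diag([4.0, 1.0])
        B = np.diag([1.0, 4.0])
        res = krzanowski_subspace({"a": _draws(A), "b": _draws(B)}, k=1)
        np.testing.assert_allclose(res.eigenvalue_mean, [1.0, 1.0], atol=1e-12)

    @given(st.integers(0, 2**32 - 1))
    def test_eigenvalues_bounded_by_population_count(self, seed):
        rng = np.random.default_rng(seed)
        pops = {f"P{i}": _draws(random_pd_matrix(rng, 4), 2) for i in range(3)}
        res = krzanowski_subspace(pops, k=2)
        assert np.all(res.eigenvalue_draws >= -1e-12)
        assert np.all(res.eigenvalue_draws <= 3 + 1e-12)

    def test_k_out_of_range_rejected(self):
        M = np.eye(3)
        pops = {"a": _draws(M), "b": _draws(M)}
        with pytest.raises(ValueError):
            krzanowski_subspace(pops, k=0)
        with pytest.raises(ValueError):
            krzanowski_subspace(pops, k=4)

    def test_default_k_is_half_the_traits(self):
        M = random_pd_matrix(np.random.default_rng(1), 6)
        res = krzanowski_subspace({"a": _draws(M), "b": _draws(M)})
        assert res.k == 3


class TestTensor:
    def test_identical_populations_yield_no_variation(self):
        M = random_pd_matrix(np.random.default_rng(2), 4)
        res = covariance_tensor({f"P{i}": _draws(M) for i in range(3)})
        assert res.no_variation
        assert np.allclose(res.alpha, 0.0)

    def test_alphas_sum_to_one_and_are_nonnegative(self):
        rng = np.random.default_rng(3)
        pops = {f"P{i}": _draws(random_pd_matrix(rng, 4), 6)
                + 0.1 * rng.standard_normal((6, 1, 1)) * np.eye(4)
                for i in range(4)}
        res = covariance_tensor(pops)
        assert res.alpha.sum() == pytest.approx(1.0)
        assert np.all(res.alpha >= 0)
        np.testing.assert_allclose(res.alpha_draws.sum(axis=1), 1.0, atol=1e-8)

    def test_eigentensors_orthonormal_under_frobenius_product(self):
        rng = np.random.default_rng(4)
        pops = {f"P{i}": _draws(random_pd_matrix(rng, 3), 5) for i in range(4)}
        res = covariance_tensor(pops)
        E = res.eigentensors
        m = E.shape[0]
        gram = np.einsum("aij,bij->ab", E, E)
        np.testing.assert_allclose(gram, np.eye(m), atol=1e-8)

    def test_population_coordinates_are_centered(self):
        rng = np.random.default_rng(5)
        pops = {f"P{i}": _draws(random_pd_matrix(rng, 3), 4) for i in range(5)}
        res = covariance_tensor(pops)
        np.testing.assert_allclose(res.coordinates.sum(axis=0), 0.0, atol=1e-9)

    def test_single_axis_divergence_loads_on_the_divergent_trait(self):
        """Two populations differing only in trait-1 variance: the leading
        eigentensor's leading eigenvector points along trait 1."""
        base = np.diag([1.0, 2.0, 3.0])
        other = base.copy()
        other[0, 0] = 5.0
        res = covariance_tensor({"a": _draws(base), "b": _draws(other)})
        lead_vec = res.eigentensor_eigenvectors[0][:, 0]
        assert abs(lead_vec[0]) == pytest.approx(1.0, abs=1e-9)
        assert res.eigenvector_variance_share[0, 0] == pytest.approx(1.0, abs=1e-9)

    def test_single_population_rejected(self):
        with pytest.raises(ValueError):
            covariance_tensor({"a": _draws(np.eye(2))})


class TestResponse:
    def test_hand_computed_example(self):
        G = np.array([[1.0, 0.5], [0.5, 2.0]])
        res = predict_response(_draws(G), np.array([0.1, -0.2]))
        np.testing.assert_allclose(res.mean(), [0.0, -0.35], atol=1e-12)

    def test_diagonal_g_reduces_to_elementwise_product(self):
        G = np.diag([2.0, 3.0, 4.0])
        beta = np.array([0.5, -1.0, 0.25])
        res = predict_response(_draws(G), beta)
        np.testing.assert_allclose(res.mean(), np.diag(G) * beta)

    def test_zero_gradient_gives_zero_response(self):
        G = random_pd_matrix(np.random.default_rng(6), 4)
        res = predict_response(_draws(G), np.zeros(4))
        np.testing.assert_allclose(res.delta_z_draws, 0.0)

    def test_linearity_in_beta(self):
        rng = np.random.default_rng(7)
        Gd = np.stack([random_pd_matrix(rng, 3) for _ in range(5)])
        b1, b2 = rng.standard_normal(3), rng.standard_normal(3)
        r1 = predict_response(Gd, b1).delta_z_draws
        r2 = predict_response(Gd, b2).delta_z_draws
        r12 = predict_response(Gd, b1 + b2).delta_z_draws
        np.testing.assert_allclose(r12, r1 + r2, atol=1e-10)

    def test_sd_units_divide_by_global_sds(self):
        G = np.diag([4.0, 9.0])
        res = predict_response(_draws(G), np.array([1.0, 1.0]), sds=np.array([2.0, 3.0]))
        np.testing.assert_allclose(res.delta_z_sd_draws[0], [2.0, 3.0])

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            predict_response(_draws(np.eye(3)), np.ones(2))

    def test_posterior_beta_must_pair_with_draws(self):
        with pytest.raises(ValueError):
            predict_response(_draws(np.eye(2), n=4), np.ones((3, 2)))


class TestRMetric:
    @given(st.integers(0, 2**32 - 1))
    def test_diagonal_g_always_gives_unity(self, seed):
        rng = np.random.default_rng(seed)
        G = np.diag(rng.uniform(0.1, 5.0, 4))
        beta = rng.standard_normal(4)
        res = r_metric(_draws(G), beta)
        np.testing.assert_allclose(res.R_draws, 1.0)

    def test_concordant_covariance_accelerates(self):
        G = np.array([[1.0, 0.5], [0.5, 1.0]])
        assert r_metric(_draws(G), np.array([1.0, 1.0])).mean == pytest.approx(1.5)

    def test_antagonistic_selection_constrains(self):
        G = np.array([[1.0, 0.5], [0.5, 1.0]])
        assert r_metric(_draws(G), np.array([1.0, -1.0])).mean == pytest.approx(0.5)

    def test_invariant_to_positive_rescaling(self):
        rng = np.random.default_rng(8)
        G = random_pd_matrix(rng, 3)
        beta = rng.standard_normal(3)
        base = r_metric(_draws(G), beta).mean
        assert r_metric(_draws(7.0 * G), beta).mean == pytest.approx(base)
        assert r_metric(_draws(G), 3.0 * beta).mean == pytest.approx(base)

    def test_percentile_summaries_bracket_mean(self):
        rng = np.random.default_rng(9)
        Gd = np.stack([random_pd_matrix(rng, 3) for _ in range(200)])
        res = r_metric(Gd, np.array([1.0, -0.5, 0.25]))
        assert res.pct5 <= res.mean <= res.pct95


class TestSkewers:
    def test_identical_matrices_fully_correlated(self):
        M = random_pd_matrix(np.random.default_rng(10), 4)
        res = random_skewers({"a": _draws(M), "b": _draws(M)}, n_skewers=50, seed=0)
        corr, angle = res.lookup("a", "b")
        assert corr == pytest.approx(1.0)
        assert angle == pytest.approx(0.0, abs=1e-5)
        assert bool(res.pairs.similar.iloc[0])

    def test_scale_invariance_of_direction(self):
        M = random_pd_matrix(np.random.default_rng(11), 3)
        res = random_skewers({"a": _draws(M), "b": _draws(5.0 * M)},
                             n_skewers=50, seed=1)
        assert res.lookup("a", "b")[0] == pytest.approx(1.0)

    def test_anticorrelated_diagonals_match_monte_carlo_oracle(self):
        """diag(1,100) vs diag(100,1): brute-force oracle gives mean vector
        correlation 0.0675 (quadrature 0.06746)."""
        res = random_skewers({"a": _draws(np.diag([1.0, 100.0])),
                              "b": _draws(np.diag([100.0, 1.0]))},
                             n_skewers=20_000, seed=2)
        corr, _ = res.lookup("a", "b")
        assert corr == pytest.approx(0.0675, abs=0.02)
        assert not bool(res.pairs.similar.iloc[0])

    def test_seeded_reproducibility(self):
        M = random_pd_matrix(np.random.default_rng(12), 3)
        N = random_pd_matrix(np.random.default_rng(13), 3)
        a = random_skewers({"a": _draws(M), "b": _draws(N)}, n_skewers=100, seed=3)
        b = random_skewers({"a": _draws(M), "b": _draws(N)}, n_skewers=100, seed=3)
        assert a.pairs.equals(b.pairs)
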