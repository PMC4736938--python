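"""Smoothing matrix, reduced-rank ICAR effects and population realization."""

import numpy as np
import pytest
import scipy.stats

import icesurvey as isv
from icesurvey.population import TAU_ETA_DEFAULT
from icesurvey.scenario import DensitySurface


class TestSmoothingMatrix:
    def test_rows_sum_to_one(self, grid505):
        W = isv.build_smoothing_matrix(grid505).W
        assert np.abs(W.sum(axis=1) - 1.0).max() < 1e-12

    def test_interior_weights(self, grid3x3):
        W = isv.build_smoothing_matrix(grid3x3).W
        centre = 4  # row-major centre of a 3x3 lattice
        assert W[centre, centre] == pytest.approx(2.0 / 6.0)
        nb = grid3x3.adjacency[centre]
        np.testing.assert_allclose(W[centre, nb], 1.0 / 6.0)

    def test_isolated_unit_self_weight(self):
        g = isv.build_grid(1, 1)
        W = isv.build_smoothing_matrix(g).W
        assert W[0, 0] == 1.0

    def test_constant_field_is_fixed_point(self, grid3x3):
        W = isv.build_smoothing_matrix(grid3x3)
        d = DensitySurface("x", np.full(9, 3.7))
        np.testing.assert_allclose(isv.smooth_density(W, d), 3.7)

    def test_spike_smooths_to_self_weight(self, grid3x3):
        d = np.zeros(9)
        d[4] = 6.0
        W = isv.build_smoothing_matrix(grid3x3)
        out = isv.smooth_density(W, DensitySurface("x", d))
        assert out[4] == pytest.approx(2.0)  # (2 * 6) / 6

    def test_matches_dense_matvec_oracle(self):
        g = isv.build_grid(5, 5)
        W = isv.build_smoothing_matrix(g)
        rng = np.random.default_rng(0)
        d = rng.uniform(0, 10, g.n_units)
        expected = np.array(
            [sum(W.W[i, j] * d[j] for j in range(g.n_units)) for i in range(g.n_units)]
        )
        np.testing.assert_allclose(
            isv.smooth_density(W, DensitySurface("x", d)), expected
        )

    def test_dimension_mismatch(self, grid3x3):
        W = isv.build_smoothing_matrix(grid3x3)
        with pytest.raises(ValueError):
            isv.smooth_density(W, DensitySurface("x", np.ones(4)))


class TestRSRBasis:
    def test_orthonormal_columns(self, grid3x3):
        model = isv.build_rsr_basis(grid3x3, m=4)
        np.testing.assert_allclose(
            model.K.T @ model.K, np.eye(4), atol=1e-9
        )

    def test_intercept_restriction_zeroes_column_sums(self, grid3x3):
        model = isv.build_rsr_basis(grid3x3, X=np.ones((9, 1)), m=4)
        assert np.abs(model.K.sum(axis=0)).max() < 1e-9

    def test_moran_eigenvalues_match_dense_oracle(self, grid3x3):
        model = isv.build_rsr_basis(grid3x3, m=2)
        A = grid3x3.adjacency_matrix()
        evals = np.sort(np.linalg.eigvalsh(A))[::-1]
        np.testing.assert_allclose(model.moran_eigenvalues, evals[:2], atol=1e-9)

    def test_q_rows_sum_to_zero(self, grid505):
        model = isv.build_rsr_basis(grid505, m=10)
        assert np.abs(model.Q.sum(axis=1)).max() < 1e-12

    def test_full_rank_covariance_matches_icar_pseudoinverse(self, grid3x3):
        # with the intercept restriction and full remaining rank, the
        # implied covariance of eta equals pinv(tau * Q)
        tau = 5.0
        model = isv.build_rsr_basis(grid3x3, X=np.ones((9, 1)), m=8, tau_eta=tau)
        oracle = np.linalg.pinv(tau * model.Q)
        np.testing.assert_allclose(model.marginal_covariance(), oracle, atol=1e-6)

    def test_invalid_rank(self, grid3x3):
        with pytest.raises(ValueError):
            isv.build_rsr_basis(grid3x3, m=9)


class TestSpatialEffects:
    def test_seed_determinism(self, grid3x3):
        model = isv.build_rsr_basis(grid3x3, m=4)
        a = isv.draw_spatial_effects(model, seed=3)
        b = isv.draw_spatial_effects(model, seed=3)
        np.testing.assert_array_equal(a, b)

    def test_mean_zero_over_many_draws(self, grid3x3):
        model = isv.build_rsr_basis(
            grid3x3, X=np.ones((9, 1)), m=4, tau_eta=TAU_ETA_DEFAULT
        )
        rng = np.random.default_rng(11)
        draws = np.array([isv.draw_spatial_effects(model, rng) for _ in range(4000)])
        se = draws.std(axis=0) / np.sqrt(draws.shape[0])
        assert np.all(np.abs(draws.mean(axis=0)) < 4 * se)

    def test_high_precision_limit_shrinks_variance(self, grid3x3):
        tight = isv.build_rsr_basis(grid3x3, m=4, tau_eta=1e8)
        draw = isv.draw_spatial_effects(tight, seed=0)
        assert np.abs(draw).max() < 1e-2

    def test_empirical_covariance_matches_formula(self, grid3x3):
        model = isv.build_rsr_basis(grid3x3, X=np.ones((9, 1)), m=4, tau_eta=5.0)
        rng = np.random.default_rng(21)
        draws = np.array([isv.draw_spatial_effects(model, rng) for _ in range(6000)])
        emp = np.cov(draws.T)
        np.testing.assert_allclose(emp, model.marginal_covariance(), atol=0.05)


class TestIntensityAndRealization:
    def test_zero_noise_recovers_area_times_density(self, grid3x3):
        d_star = np.full(9, 2.0)
        out = isv.compute_lambda(
            grid3x3, d_star, np.zeros(9), seed=0, eps_variance=0.0
        )
        np.testing.assert_allclose(out.lam, grid3x3.a * 2.0)

    def test_negative_density_rejected(self, grid3x3):
        with pytest.raises(ValueError):
            isv.compute_lambda(grid3x3, np.full(9, -1.0), np.zeros(9))

    def test_lognormal_moment(self, grid3x3):
        # E[lambda] = a d* exp(var/2) for eta = 0
        d_star = np.full(9, 1.0)
        rng = np.random.default_rng(5)
        sums = [
            isv.compute_lambda(
                grid3x3, d_star, np.zeros(9), rng, eps_variance=0.1
            ).lam.mean()
            for _ in range(3000)
        ]
        expected = 625.0 * np.exp(0.05)
        assert np.mean(sums) == pytest.approx(expected, rel=0.01)

    def test_poisson_realization_moments_and_determinism(self, grid3x3):
        lam = isv.IntensitySurface("x", np.full(9, 10.0), None, None, None)
        rng_draws = [isv.draw_population(lam, seed=8).N_j for _ in range(2)]
        np.testing.assert_array_equal(*rng_draws)
        big = isv.IntensitySurface("x", np.full(10_000, 10.0), None, None, None)
        N = isv.draw_population(big, seed=1).N_j
        assert 9.9 <= N.mean() <= 10.1
        zero = isv.IntensitySurface("x", np.zeros(4), None, None, None)
        assert isv.draw_population(zero, seed=0).N == 0

    def test_binomial_thinning_matches_thinned_poisson(self):
        """Binomial(Poisson(lam), A) must be distributionally identical to
        Poisson(A lam) (the two-stage survey construction)."""
        rng = np.random.default_rng(42)
        lam, A = 8.0, 0.4
        n = rng.poisson(lam, size=100_000)
        thinned = rng.binomial(n, A)
        kmax = thinned.max()
        observed = np.bincount(thinned, minlength=kmax + 1)
        pmf = scipy.stats.poisson.pmf(np.arange(kmax + 1), lam * A)
        # pool the sparse upper tail before the goodness-of-fit test
        cut = np.searchsorted(pmf.cumsum(), 1 - 1e-4)
        obs = np.append(observed[:cut], observed[cut:].sum())
        exp = np.append(pmf[:cut], 1 - pmf[:cut].sum()) * thinned.size
        stat, pval = scipy.stats.chisquare(obs, exp)
        assert pval > 0.001
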