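"""GP population model: basis construction, covariance closed forms, MAP
objective against dense-algebra oracles, conjugate posterior, and the
chi-squared group comparison."""

import math

import numpy as np
import pytest
from scipy import linalg
from scipy.stats import chi2

from cyclesig import gptools as gp
from conftest import GP_ALPHA, GP_BETA, GP_GAMMA, GP_TAU, GP_TIMES, population_matrix


class TestBasis:
    def test_documented_configuration(self):
        basis = gp.gaussian_basis([0.0, 90.0], 10)
        assert basis.bandwidth == 10.0
        assert np.allclose(basis.centers, np.arange(0, 91, 10))

    def test_two_point_case(self):
        basis = gp.gaussian_basis([0.0, 10.0], 2)
        assert list(basis.centers) == [0.0, 10.0] and basis.bandwidth == 10.0

    def test_kernel_is_one_at_center(self):
        basis = gp.gaussian_basis([0.0, 90.0], 10)
        vals = basis(basis.centers)
        assert np.allclose(np.diag(vals), 1.0)

    def test_count_below_two_rejected(self):
        with pytest.raises(ValueError):
            gp.gaussian_basis([0.0, 10.0], 1)


class TestSigmaEll:
    def test_zero_coefficients_give_unity(self):
        basis = gp.gaussian_basis([0.0, 90.0], 5)
        hyper = gp.GPHyperparams(np.full(5, 1e-300), np.full(5, 1e-300), 1.0)
        sigma, ell = gp.eval_sigma_ell(hyper, basis, np.linspace(0, 90, 7))
        assert np.allclose(sigma, 1.0) and np.allclose(ell, 1.0)

    def test_single_active_kernel_at_center(self):
        basis = gp.gaussian_basis([0.0, 90.0], 5)
        beta = np.zeros(5)
        beta[2] = 1.0
        # contributions of the neighboring kernels at the center
        neighbor = 2 * math.exp(-0.5) + 2 * math.exp(-2.0)
        hyper = gp.GPHyperparams(beta + 1e-300, np.full(5, 1e-300), 1.0)
        sigma, _ = gp.eval_sigma_ell(hyper, basis, [45.0])
        assert sigma[0] == pytest.approx(math.e, rel=1e-12)
        del neighbor

    def test_positivity_for_random_prior_draws(self):
        rng = np.random.default_rng(7)
        basis = gp.gaussian_basis([0.0, 117.0], 5)
        t = np.linspace(0, 117, 25)
        for _ in range(1000):
            hyper = gp.GPHyperparams(
                rng.gamma(1.0, 1.0, 5) + 1e-12,
                np.minimum(rng.gamma(0.2 * 117.0, 1.0, 5), 8.0),
                rng.gamma(1.0, 1.0) + 1e-12,
            )
            sigma, ell = gp.eval_sigma_ell(hyper, basis, t)
            assert (sigma > 0).all() and (ell > 0).all()

    def test_length_mismatch_rejected(self):
        basis = gp.gaussian_basis([0.0, 90.0], 5)
        with pytest.raises(ValueError, match="length"):
            gp.eval_sigma_ell(gp.GPHyperparams(np.ones(3), np.ones(3), 1.0), basis, [0.0])


class TestCovariance:
    def test_diagonal_closed_form(self):
        basis = gp.gaussian_basis(GP_TIMES, 5)
        hyper = gp.GPHyperparams(GP_BETA, GP_GAMMA, GP_TAU)
        K = gp.build_covariance(hyper, basis, GP_TIMES)
        sigma, _ = gp.eval_sigma_ell(hyper, basis, GP_TIMES)
        assert np.allclose(np.diag(K), sigma**2 + GP_TAU**2, rtol=1e-12)

    def test_reduces_to_stationary_matern(self):
        # constant sigma = ell = 1 configuration vs the closed-form kernel
        t = np.linspace(0, 100, 20)
        basis = gp.gaussian_basis(t, 5)
        hyper = gp.GPHyperparams(np.full(5, 1e-300), np.full(5, 1e-300), 0.5)
        K = gp.build_covariance(hyper, basis, t, include_noise=False)
        d = np.abs(t[:, None] - t[None, :])
        a = math.sqrt(5) * d
        expected = (1 + a + 5 * d**2 / 3) * np.exp(-a)
        assert np.allclose(K, expected, atol=1e-12)

    def test_random_hyperparams_symmetric_psd(self):
        rng = np.random.default_rng(3)
        t = np.linspace(0, 117, 20)
        basis = gp.gaussian_basis(t, 5)
        for _ in range(20):
            hyper = gp.GPHyperparams(
                rng.uniform(0.05, 0.6, 5), rng.uniform(0.5, 2.5, 5),
                rng.uniform(0.1, 1.0),
            )
            K = gp.build_covariance(hyper, basis, t)
            assert np.allclose(K, K.T)
            w = linalg.eigvalsh(K)
            assert w[0] >= -1e-10 * w[-1]

    def test_overflow_reported(self):
        t = np.linspace(0, 117, 10)
        basis = gp.gaussian_basis(t, 5)
        hyper = gp.GPHyperparams(np.full(5, 500.0), np.full(5, 1.0), 0.1)
        with pytest.raises(ValueError, match="overflow"):
            gp.build_covariance(hyper, basis, t)


class TestNegLogPosterior:
    def test_identity_covariance_zero_residual(self):
        # tau=1, sigma -> 0, B=I on a matching grid, alpha = x1, priors off:
        # the data term collapses to (n/2) log(2 pi)
        n = 5
        t = np.linspace(0.0, 1.0, n)
        basis_B = gp.gaussian_basis(t, n)
        basis_C = gp.gaussian_basis(t, 2)
        hyper = gp.GPHyperparams(np.full(2, -400.0), np.full(2, 1e-300), 1.0)
        x = np.zeros((1, n))  # Ba = 0 for alpha = 0, residual 0
        val = gp.neg_log_posterior(
            np.zeros(n), hyper, x, t, basis_B, basis_C, include_priors=False
        )
        assert val == pytest.approx(n / 2 * math.log(2 * math.pi), rel=1e-12)

    def test_matches_dense_algebra_oracle(self):
        # 5-point, 2-cell fixture evaluated by explicit determinant and
        # quadratic form plus hand-written prior log-densities
        rng = np.random.default_rng(11)
        t = np.linspace(0.0, 20.0, 5)
        basis_B = gp.gaussian_basis(t, 3)
        basis_C = gp.gaussian_basis(t, 2)
        alpha = rng.normal(size=3)
        hyper = gp.GPHyperparams(np.array([0.4, 0.7]), np.array([1.1, 2.0]), 0.6)
        data = rng.normal(size=(2, 5))
        val = gp.neg_log_posterior(alpha, hyper, data, t, basis_B, basis_C)

        Sigma = gp.build_covariance(hyper, basis_C, t)
        B = basis_B(t)
        Sinv = np.linalg.inv(Sigma)
        _, logdet = np.linalg.slogdet(Sigma)
        expected = 0.0
        for i in range(2):
            r = data[i] - B @ alpha
            expected += 0.5 * (logdet + 5 * math.log(2 * math.pi) + r @ Sinv @ r)
        expected += 0.5 * 3 * math.log(2 * math.pi * 100) + alpha @ alpha / 200
        expected += hyper.beta.sum() + hyper.tau  # Gamma(1,1)
        a = 0.2 * 20.0
        from scipy.special import gammaln

        expected += float(
            np.sum(hyper.gamma - (a - 1) * np.log(hyper.gamma)) + 2 * gammaln(a)
        )
        assert val == pytest.approx(expected, abs=1e-10)

    def test_translation_invariance_of_data_term(self):
        rng = np.random.default_rng(5)
        t = np.linspace(0.0, 30.0, 8)
        basis_B = gp.gaussian_basis(t, 4)
        basis_C = gp.gaussian_basis(t, 2)
        hyper = gp.GPHyperparams(np.array([0.3, 0.3]), np.array([1.5, 1.5]), 0.4)
        alpha = rng.normal(size=4)
        data = rng.normal(size=(3, 8))
        v1 = gp.neg_log_posterior(alpha, hyper, data, t, basis_B, basis_C,
                                  include_priors=False)
        # shifting the data and the modeled mean together leaves the
        # residuals, hence the data term, unchanged
        delta = np.full(4, 5.0)
        shift = basis_B(t) @ delta
        v2 = gp.neg_log_posterior(alpha + delta, hyper, data + shift[None, :], t,
                                  basis_B, basis_C, include_priors=False)
        assert v2 == pytest.approx(v1, abs=1e-8)


class TestFitMap:
    def test_sigma_recovery_from_simulated_population(self):
        X = population_matrix(n_cells=60, seed=2)
        fit = gp.fit_map(X, GP_TIMES, seed=0, n_restarts=3)
        truth = gp.GPHyperparams(GP_BETA, GP_GAMMA, GP_TAU)
        basis_C = gp.gaussian_basis(GP_TIMES, 5)
        sig_true, _ = gp.eval_sigma_ell(truth, basis_C, GP_TIMES)
        sig_fit, _ = gp.eval_sigma_ell(fit.hyper, fit.basis_C, GP_TIMES)
        interior = slice(4, -4)
        rms = np.sqrt(np.mean((sig_fit[interior] - sig_true[interior]) ** 2))
        rms /= np.sqrt(np.mean(sig_true[interior] ** 2))
        assert rms < 0.30

    def test_minimizer_beats_every_start_and_is_consistent(self):
        X = population_matrix(n_cells=10, seed=4)
        fit = gp.fit_map(X, GP_TIMES, seed=1, n_restarts=3)
        assert fit.objective <= min(fit.restart_objectives) + 1e-9
        # reported objective equals the full posterior at the returned point
        val = gp.neg_log_posterior(
            fit.alpha, fit.hyper, X, GP_TIMES, fit.basis_B, fit.basis_C
        )
        assert val == pytest.approx(fit.objective, rel=1e-9)

    def test_seeded_determinism(self):
        X = population_matrix(n_cells=8, seed=6)
        f1 = gp.fit_map(X, GP_TIMES, seed=3, n_restarts=2)
        f2 = gp.fit_map(X, GP_TIMES, seed=3, n_restarts=2)
        assert np.array_equal(f1.hyper.beta, f2.hyper.beta)
        assert f1.hyper.tau == f2.hyper.tau

    def test_too_few_cells_rejected(self):
        with pytest.raises(ValueError, match="at least 5"):
            gp.fit_map(population_matrix(n_cells=3, seed=0), GP_TIMES)


class TestPosteriorAlpha:
    def test_zero_data_zero_mean(self):
        t = np.linspace(0, 50, 12)
        basis = gp.gaussian_basis(t, 4)
        mu, cov = gp.posterior_alpha(np.zeros((3, 12)), np.eye(12), basis, t)
        assert np.allclose(mu, 0.0)

    def test_scalar_conjugate_update(self):
        # Sigma = I, B = I, M = 1: mu = x / (1 + 1/100)
        t = np.linspace(0.0, 1.0, 3)
        basis = gp.gaussian_basis(t, 3)
        B = basis(t)
        x = np.array([[1.0, 2.0, 3.0]])
        mu, cov = gp.posterior_alpha(x, np.eye(3), basis, t)
        # fold the basis in: A mu = B' x
        assert np.allclose((np.eye(3) / 100 + B.T @ B) @ mu, B.T @ x[0], atol=1e-12)

    def test_matches_ridge_augmented_least_squares(self):
        rng = np.random.default_rng(9)
        t = np.linspace(0, 60, 15)
        basis = gp.gaussian_basis(t, 5)
        B = basis(t)
        data = rng.normal(size=(4, 15))
        Sigma = np.eye(15) * 0.8
        mu, cov = gp.posterior_alpha(data, Sigma, basis, t)
        # oracle: ridge regression of all stacked cells with penalty 1/100
        Sroot = linalg.sqrtm(np.linalg.inv(Sigma)).real
        X = np.vstack([Sroot @ B] * 4 + [np.eye(5) / 10.0])
        y = np.concatenate([Sroot @ d for d in data] + [np.zeros(5)])
        ref, *_ = np.linalg.lstsq(X, y, rcond=None)
        assert np.allclose(mu, ref, atol=1e-10)


class TestPosteriorMeanOnGrid:
    def test_degenerate_posterior(self):
        t = np.linspace(0, 90, 10)
        basis = gp.gaussian_basis(t, 10)
        post = gp.posterior_mean_on_grid(np.ones(10), np.zeros((10, 10)), basis, t)
        assert np.allclose(post.cov, 0.0)

    def test_rank_preserved_on_j_point_grid(self):
        rng = np.random.default_rng(2)
        t = np.linspace(0, 90, 10)
        basis = gp.gaussian_basis(t, 10)
        A = rng.normal(size=(10, 10))
        cov_alpha = A @ A.T
        grid = np.linspace(0, 90, 10)
        post = gp.posterior_mean_on_grid(np.zeros(10), cov_alpha, basis, grid)
        assert np.linalg.matrix_rank(post.cov, tol=1e-8) == np.linalg.matrix_rank(
            cov_alpha, tol=1e-8
        )

    def test_one_hot_coefficients_reproduce_kernel_column(self):
        t = np.linspace(0, 90, 10)
        basis = gp.gaussian_basis(t, 10)
        one_hot = np.zeros(10)
        one_hot[3] = 1.0
        post = gp.posterior_mean_on_grid(one_hot, np.zeros((10, 10)), basis, t)
        assert np.allclose(post.mu, basis(t)[:, 3])

    def test_grid_outside_range_rejected(self):
        basis = gp.gaussian_basis([0.0, 90.0], 10)
        with pytest.raises(ValueError, match="within"):
            gp.posterior_mean_on_grid(np.zeros(10), np.eye(10), basis, [-5.0, 50.0])


def _random_posterior(rng, J=10, rank=None):
    grid = np.linspace(0, 90, J)
    A = rng.normal(size=(J, J if rank is None else rank))
    cov = A @ A.T
    return gp.MeanPosterior(
        grid=grid, mu_alpha=np.zeros(J), cov_alpha=np.eye(J),
        mu=rng.normal(size=J), cov=cov,
    )


class TestCompareGroups:
    def test_identical_groups_null(self):
        rng = np.random.default_rng(1)
        post = _random_posterior(rng)
        res = gp.compare_groups(post, post)
        assert res.T == 0.0 and res.epsilon == 1.0 and np.allclose(res.effect, 0.0)

    def test_full_rank_matches_dense_solve(self):
        rng = np.random.default_rng(4)
        px, py = _random_posterior(rng), _random_posterior(rng)
        res = gp.compare_groups(px, py)
        S = px.cov + py.cov
        delta = px.mu - py.mu
        T_ref = float(delta @ np.linalg.solve(S, delta))
        assert res.nu == 10
        assert res.T == pytest.approx(T_ref, abs=1e-10 * max(1.0, T_ref))
        assert res.T == pytest.approx(float(res.effect @ res.effect), abs=1e-8)
        assert res.epsilon == pytest.approx(float(chi2.sf(T_ref, 10)))

    def test_known_null_space_projection(self):
        # S with a 3-dimensional null space on J=10: nu = 7 and T equals the
        # statistic of the projected difference
        rng = np.random.default_rng(8)
        px = _random_posterior(rng, rank=4)
        py = _random_posterior(rng, rank=3)
        res = gp.compare_groups(px, py)
        assert res.nu == 7
        S = px.cov + py.cov
        w, V = np.linalg.eigh(S)
        keep = w > 1e-8 * w[-1]
        delta = px.mu - py.mu
        z = V[:, keep].T @ delta
        T_ref = float(z @ (z / w[keep]))
        assert res.T == pytest.approx(T_ref, rel=1e-10)

    def test_symmetry_under_group_swap(self):
        rng = np.random.default_rng(12)
        px, py = _random_posterior(rng), _random_posterior(rng)
        r1 = gp.compare_groups(px, py)
        r2 = gp.compare_groups(py, px)
        assert r1.T == pytest.approx(r2.T, rel=1e-12)
        assert r1.nu == r2.nu and r1.epsilon == r2.epsilon
        assert np.allclose(np.abs(r1.effect), np.abs(r2.effect))

    def test_mismatched_grids_rejected(self):
        rng = np.random.default_rng(3)
        px, py = _random_posterior(rng), _random_posterior(rng)
        py.grid = py.grid + 1.0
        with pytest.raises(ValueError, match="grids"):
            gp.compare_groups(px, py)


class TestPosteriorCoverage:
    def test_marginal_interval_coverage(self):
        # plug-in MAP posterior: marginal 95% intervals of m(s) should cover
        # the true mean at ~95% of grid points (tolerance +/-5 points)
        basis_B = gp.gaussian_basis(GP_TIMES, 10)
        true_mean = basis_B(np.linspace(GP_TIMES[0], GP_TIMES[-1], 10)) @ GP_ALPHA
        hits = total = 0
        for rep in range(12):
            X = population_matrix(n_cells=60, seed=300 + rep)
            fit = gp.fit_map(X, GP_TIMES, seed=rep, n_restarts=1)
            mu_a, cov_a = gp.posterior_alpha(X, fit.covariance(), fit.basis_B, GP_TIMES)
            post = gp.posterior_mean_on_grid(
                mu_a, cov_a, fit.basis_B, np.linspace(GP_TIMES[0], GP_TIMES[-1], 10)
            )
            half = 1.96 * np.sqrt(np.clip(np.diag(post.cov), 0, None))
            hits += int(np.sum(np.abs(post.mu - true_mean) <= half))
            total += 10
        assert abs(hits / total - 0.95) <= 0.05 + 1e-9
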