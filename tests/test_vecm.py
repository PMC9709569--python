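"""Johansen estimation kernel: centering, sufficient statistics, the
generalized eigenproblem and the closed-form estimators."""

import numpy as np
import pytest

import cointnet as cn
from conftest import random_streams


class TestCentering:
    def test_constant_signal_gives_zero_streams(self):
        data = cn.EpochedData([np.ones((10, 3)) * 5.0], ["a", "b", "c"], 0.1)
        z = cn.center(data)
        assert np.abs(z.z0).max() == 0
        assert np.abs(z.z1).max() == 0

    def test_pooling_symmetry(self, rank2_data):
        one = rank2_data.select_trials([0])
        two = cn.EpochedData([one.values[0], one.values[0].copy()],
                             one.channel_labels, one.delta)
        S1 = cn.sufficient_stats(cn.center(one))
        S2 = cn.sufficient_stats(cn.center(two))
        assert np.allclose(S1.S00, S2.S00, atol=1e-12)
        assert np.allclose(S1.S01, S2.S01, atol=1e-12)
        assert np.allclose(S1.S11, S2.S11, atol=1e-12)

    def test_grand_means_removed(self, rank2_data):
        z = cn.center(rank2_data.select_trials(range(3)))
        assert np.abs(z.z0.mean(axis=0)).max() < 1e-12
        assert np.abs(z.z1.mean(axis=0)).max() < 1e-12

    def test_no_pairs_across_trials(self, rank2_data):
        z = cn.center(rank2_data)
        n_m = rank2_data.n_per_trial
        assert z.n_total == int((n_m - 1).sum())
        # trial boundaries: each trial contributes exactly N_m - 1 rows
        counts = np.bincount(z.trial_index)
        assert np.array_equal(counts, n_m - 1)

    def test_short_trial_rejected(self):
        data = cn.EpochedData([np.zeros((1, 2))], ["a", "b"], 0.1)
        with pytest.raises(ValueError, match="fewer than 2"):
            cn.center(data)


class TestSufficientStats:
    def test_duplicate_streams(self):
        z = random_streams(0)
        z_dup = cn.CenteredStreams(z0=z.z0, z1=z.z0, trial_index=z.trial_index,
                                   mean_dx=z.mean_dx, mean_lag=z.mean_lag)
        S = cn.sufficient_stats(z_dup)
        assert np.allclose(S.S00, S.S01)
        assert np.allclose(S.S00, S.S11)

    def test_orthogonal_streams(self):
        n = 10
        z0 = np.zeros((n, 2))
        z1 = np.zeros((n, 2))
        z0[: n // 2, 0] = [1, -1, 1, -1, 0]
        z1[n // 2:, 1] = [1, -1, 1, -1, 0]
        z = cn.CenteredStreams(z0=z0, z1=z1, trial_index=np.zeros(n, int),
                               mean_dx=np.zeros(2), mean_lag=np.zeros(2))
        assert np.abs(cn.sufficient_stats(z).S01).max() == 0

    def test_loop_oracle(self):
        z = random_streams(1, n=50, p=3)
        S = cn.sufficient_stats(z)
        S01 = np.zeros((3, 3))
        for n in range(50):
            S01 += np.outer(z.z0[n], z.z1[n])
        assert np.abs(S.S01 - S01 / 50).max() < 1e-10


class TestEigenproblem:
    def test_scalar_ar1_closed_form(self):
        # p=1: lambda_1 is the squared sample correlation of Dx and lag x
        rng = np.random.default_rng(11)
        x = np.zeros(300)
        for n in range(1, 300):
            x[n] = 0.7 * x[n - 1] + rng.standard_normal()
        data = cn.EpochedData([x[:, None]], ["x"], 0.1)
        z = cn.center(data)
        S = cn.sufficient_stats(z)
        eig = cn.solve_eigenproblem(S)
        rho2 = np.corrcoef(z.z0[:, 0], z.z1[:, 0])[0, 1] ** 2
        assert abs(eig.lambdas[0] - rho2) < 1e-10

    def test_uncorrelated_streams_zero_lambdas(self):
        S = cn.SufficientStats(S00=np.eye(2), S01=np.zeros((2, 2)),
                               S11=np.eye(2), n_total=6)
        eig = cn.solve_eigenproblem(S)
        assert np.abs(eig.lambdas).max() == 0

    @pytest.mark.parametrize("seed", range(4))
    def test_defining_equation_residual(self, seed):
        z = random_streams(seed, n=120, p=3)
        S = cn.sufficient_stats(z)
        eig = cn.solve_eigenproblem(S)
        M = S.S01.T @ np.linalg.solve(S.S00, S.S01)
        for lam, v in zip(eig.lambdas, eig.vectors.T):
            assert np.linalg.norm(lam * S.S11 @ v - M @ v) < 1e-8

    @pytest.mark.parametrize("seed", range(4))
    def test_characteristic_polynomial_oracle(self, seed):
        # roots of det(lambda S11 - S01' S00^{-1} S01) = 0, brute force p<=3
        z = random_streams(100 + seed, n=80, p=3)
        S = cn.sufficient_stats(z)
        M = S.S01.T @ np.linalg.solve(S.S00, S.S01)
        # det(lambda S11 - M) is a cubic in lambda; sample and fit coefficients
        grid = np.linspace(-0.5, 1.5, 7)
        dets = [np.linalg.det(lam * S.S11 - M) for lam in grid]
        coeffs = np.polyfit(grid, dets, 3)
        roots = np.sort(np.roots(coeffs).real)[::-1]
        eig = cn.solve_eigenproblem(S)
        assert np.abs(roots - eig.lambdas).max() < 1e-8

    def test_normalization_and_descending(self, stats_rank2):
        _, S = stats_rank2
        eig = cn.solve_eigenproblem(S)
        G = eig.vectors.T @ S.S11 @ eig.vectors
        assert np.abs(G - np.eye(S.p)).max() < 1e-8
        assert np.all(np.diff(eig.lambdas) <= 1e-12)
        assert eig.lambdas.min() >= 0 and eig.lambdas.max() <= 1

    def test_singular_s11_reports_condition(self, rank2_data):
        ca = cn.apply_common_average(rank2_data)
        z = cn.center(ca)
        S = cn.sufficient_stats(z)
        with pytest.raises(np.linalg.LinAlgError, match="S11"):
            cn.solve_eigenproblem(S)


class TestClosedFormEstimators:
    def test_alpha_with_normalized_beta(self, stats_rank2):
        _, S = stats_rank2
        eig = cn.solve_eigenproblem(S)
        beta = cn.estimate_beta(eig, 2)
        alpha = cn.estimate_alpha(S, beta)
        assert np.abs(alpha - S.S01 @ beta).max() < 1e-10

    @pytest.mark.parametrize("seed", range(10))
    def test_rotation_identity(self, stats_rank2, seed):
        _, S = stats_rank2
        eig = cn.solve_eigenproblem(S)
        beta = cn.estimate_beta(eig, 2)
        alpha = cn.estimate_alpha(S, beta)
        rng = np.random.default_rng(seed)
        Q = rng.standard_normal((2, 2)) + 2 * np.eye(2)
        betaQ = beta @ Q
        alphaQ = cn.estimate_alpha(S, betaQ)
        assert np.abs(alphaQ - alpha @ np.linalg.inv(Q).T).max() < 1e-8
        assert np.abs(alphaQ @ betaQ.T - alpha @ beta.T).max() < 1e-10

    def test_rank_zero(self, rank2_data, stats_rank2):
        z, S = stats_rank2
        fit = cn.fit_vecm(rank2_data, 0)
        assert fit.alpha.shape == (6, 0)
        assert np.abs(fit.Pi).max() == 0
        assert np.allclose(fit.Sigma, S.S00)
        assert np.allclose(fit.mu, z.mean_dx)

    def test_full_rank_matches_ols(self, rank2_data, stats_rank2):
        z, S = stats_rank2
        fit = cn.fit_vecm(rank2_data, 6)
        Pi_ols = np.linalg.solve(S.S11, S.S01.T).T
        resid = z.z0 - z.z1 @ Pi_ols.T
        Sigma_ols = resid.T @ resid / z.n_total
        assert np.abs(fit.Pi - Pi_ols).max() < 1e-8
        assert np.abs(fit.Sigma - Sigma_ols).max() < 1e-8

    def test_sigma_consistency(self, rank2_system):
        # Frobenius error roughly halves when Ntot quadruples
        _, var = rank2_system
        errs = []
        for M in (10, 40):
            data = cn.simulate_trials(var, M, 201, seed=77)
            fit = cn.fit_vecm(data, 2)
            errs.append(np.linalg.norm(fit.Sigma - var.Sigma))
        assert errs[1] < 0.7 * errs[0]


class TestLikelihood:
    def test_zero_residuals_identity_sigma(self):
        x = np.tile([1.0, 2.0], (5, 1)).T.reshape(2, 5).T  # constant trial
        data = cn.EpochedData([np.zeros((5, 2))], ["a", "b"], 0.1)
        params = cn.VECMParams(mu=np.zeros(2), alpha=np.zeros((2, 1)),
                               beta=np.zeros((2, 1)), Sigma=np.eye(2), rank=1)
        assert cn.log_likelihood(params, data) == 0.0

    def test_additivity_over_duplicated_trials(self, rank2_data, rank2_system):
        _, var = rank2_system
        params = cn.VECMParams(mu=var.mu, alpha=var.Pi[:, :2],
                               beta=np.eye(6)[:, :2], Sigma=var.Sigma, rank=2)
        one = rank2_data.select_trials([0])
        two = cn.EpochedData([one.values[0], one.values[0].copy()],
                             one.channel_labels, one.delta)
        l1 = cn.log_likelihood(params, one, include_constant=True)
        l2 = cn.log_likelihood(params, two, include_constant=True)
        assert np.isclose(l2, 2 * l1, rtol=1e-12)

    def test_value_at_mle_trace_identity(self, rank2_data):
        fit = cn.fit_vecm(rank2_data, 2)
        ll = cn.log_likelihood(fit, rank2_data)
        ll_closed = cn.max_log_likelihood(fit.Sigma, fit.info["n_total"])
        assert np.isclose(ll, ll_closed, rtol=1e-6)

    def test_monotone_in_rank(self, rank2_data):
        lls = []
        for r in range(7):
            fit = cn.fit_vecm(rank2_data, r)
            lls.append(cn.max_log_likelihood(fit.Sigma, fit.info["n_total"]))
        assert np.all(np.diff(lls) >= -1e-6)

    def test_singular_sigma_rejected(self, rank2_data):
        fit = cn.fit_vecm(rank2_data, 2)
        bad = cn.VECMParams(mu=fit.mu, alpha=fit.alpha, beta=fit.beta,
                            Sigma=np.zeros((6, 6)), rank=2)
        with pytest.raises(np.linalg.LinAlgError):
            cn.log_likelihood(bad, rank2_data)


class TestFitRecovery:
    def test_beta_subspace_recovery(self):
        # principal angle < 0.15 rad in >= 90% of 20 seeded replicates
        from scipy.linalg import subspace_angles

        ok = 0
        for i in range(20):
            ou = cn.random_cointegrated_ou(10, 3, seed=500 + i)
            var = cn.discretize_ou(ou)
            data = cn.simulate_trials(var, 50, 200, seed=i)
            fit = cn.fit_vecm(data, 3)
            ok += subspace_angles(fit.beta, ou.b).max() < 0.15
        assert ok >= 18

    def test_pi_error_decreases_with_data(self, rank2_system):
        _, var = rank2_system
        errs = []
        for M in (10, 80):
            data = cn.simulate_trials(var, M, 101, seed=13)
            fit = cn.fit_vecm(data, 2)
            errs.append(np.linalg.norm(fit.Pi - var.Pi))
        assert errs[1] < errs[0]


class TestEquilibriumDeviation:
    def test_rank_zero_empty(self, rank2_data):
        fit = cn.fit_vecm(rank2_data, 0)
        dev = cn.equilibrium_deviation(fit, rank2_data)
        assert dev.shape == (rank2_data.n_increments, 0)

    def test_mean_zero_and_direct_recomputation(self, rank2_data):
        fit = cn.fit_vecm(rank2_data, 2)
        dev = cn.equilibrium_deviation(fit, rank2_data)
        assert np.abs(dev.mean(axis=0)).max() < 1e-10
        lag = np.concatenate([t[:-1] for t in rank2_data.values])
        direct = lag @ fit.beta
        direct -= direct.mean(axis=0)
        assert np.abs(dev - direct).max() < 1e-10
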