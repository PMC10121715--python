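import numpy as np
import pytest

import pfpca
from pfpca.inference import (
    EMConfig,
    FPCAConfig,
    e_step,
    m_step,
    penalized_fpca,
    smooth_mean,
)
from pfpca.model import StimulusGrid


class TestEStep:
    def test_point_prior_returns_prior_mean_exactly(self):
        f = np.array([0.3, -0.1, 1.2])
        mean, cov, ess = e_step(
            np.array([1, 0, 4]), f, np.zeros((3, 3)), EMConfig(M=500, seed=0)
        )
        np.testing.assert_allclose(mean, f, atol=1e-6)
        np.testing.assert_allclose(cov, 0, atol=1e-6)
        assert ess == pytest.approx(500)

    def test_single_stimulus_matches_quadrature_oracle(self):
        # Poisson-log-normal posterior in 1-D, integrated on a fine grid
        f, s2, n, dt = np.log(3.0), 0.4, 5, 1.0
        grid = np.linspace(f - 6 * np.sqrt(s2), f + 6 * np.sqrt(s2), 20001)
        logpost = (
            -0.5 * (grid - f) ** 2 / s2 + n * grid - dt * np.exp(grid)
        )
        w = np.exp(logpost - logpost.max())
        w /= w.sum()
        oracle_mean = w @ grid
        oracle_var = w @ (grid - oracle_mean) ** 2

        mean, cov, ess = e_step(
            np.array([n]), np.array([f]), np.array([[s2]]),
            EMConfig(M=100_000, seed=1), dt=dt,
        )
        mc_se = np.sqrt(oracle_var / ess)
        assert abs(mean[0] - oracle_mean) < 3 * mc_se
        assert cov[0, 0] == pytest.approx(oracle_var, rel=0.1)

    def test_counts_at_prior_mode_keep_posterior_near_prior(self):
        f = np.log(np.array([2.0, 5.0, 3.0]))
        Sigma = 0.01 * np.eye(3)
        counts = np.round(np.exp(f)).astype(int)
        mean, _cov, _ess = e_step(counts, f, Sigma, EMConfig(M=20_000, seed=2))
        np.testing.assert_allclose(mean, f, atol=0.05)


class TestMStep:
    def test_identical_rows_zero_cov_give_zero_sigma(self):
        pm = np.tile([0.5, 1.0], (4, 1))
        post = pfpca.PosteriorLogRate(pm, np.zeros((4, 2, 2)), np.full(4, 100.0))
        f_hat, Sigma_hat = m_step(post)
        np.testing.assert_allclose(Sigma_hat, 0, atol=1e-15)
        np.testing.assert_allclose(f_hat, [0.5, 1.0])

    def test_two_opposite_blocks_give_outer_product(self):
        u = np.array([0.3, -0.7, 0.2])
        pm = np.vstack([u, -u])
        post = pfpca.PosteriorLogRate(pm, np.zeros((2, 3, 3)), np.full(2, 10.0))
        f_hat, Sigma_hat = m_step(post)
        np.testing.assert_allclose(f_hat, 0, atol=1e-15)
        np.testing.assert_allclose(Sigma_hat, np.outer(u, u), atol=1e-14)

    def test_f_hat_is_column_mean(self):
        rng = np.random.default_rng(0)
        pm = rng.normal(size=(7, 4))
        post = pfpca.PosteriorLogRate(
            pm, np.zeros((7, 4, 4)), np.full(7, 10.0)
        )
        f_hat, _ = m_step(post)
        np.testing.assert_allclose(f_hat, pm.mean(axis=0))

    def test_single_block_rejected(self):
        post = pfpca.PosteriorLogRate(
            np.zeros((1, 3)), np.zeros((1, 3, 3)), np.ones(1)
        )
        with pytest.raises(ValueError, match="two blocks"):
            m_step(post)


class TestRecoverLatentRates:
    def test_recovers_mean_log_rate_without_fluctuations(self, grid, mu0):
        """Fluctuation-free data: f_hat tracks the true mean log rate.

        The EM approaches the boundary MLE Sigma = 0 only at a third-order
        rate, so a small positive-variance floor (and the matching
        log-normal mean bias, ~ -Sigma_jj/2) remains after any practical
        number of iterations; the tolerances reflect that floor.
        """
        decomp = pfpca.TuningDecomposition(
            grid=grid, f=np.log(np.maximum(mu0, 2.0)), phis=np.eye(9)[:1],
            sigma_k2=np.zeros(1), sigma0_2=0.0, dt=1.0,
        )
        counts, _s, _l = pfpca.simulate_counts(decomp, 200, seed=9)
        _post, f_hat, Sigma_hat, _log = pfpca.recover_latent_rates(
            counts, EMConfig(M=2_000, seed=9)
        )
        err = np.abs(f_hat - decomp.f)
        assert np.mean(err) < 0.06
        assert np.max(err) < 0.15
        assert np.diag(Sigma_hat).max() < 0.2  # near the Sigma = 0 truth

    def test_all_zero_counts_warn_and_stay_finite(self, grid):
        counts = pfpca.SpikeCountMatrix(np.zeros((2, 9)), grid)
        with pytest.warns(RuntimeWarning, match="no spikes"):
            _post, f_hat, Sigma_hat, _log = pfpca.recover_latent_rates(
                counts, EMConfig(M=500, max_iter=5, seed=0)
            )
        assert np.all(np.isfinite(f_hat)) and np.all(f_hat < 0)
        assert np.all(np.isfinite(Sigma_hat))

    def test_same_seed_identical_posteriors(self, gain_dataset):
        counts, _t, _s = gain_dataset
        cfg = EMConfig(M=500, max_iter=5, seed=21)
        p1, f1, S1, _ = pfpca.recover_latent_rates(counts, cfg)
        p2, f2, S2, _ = pfpca.recover_latent_rates(counts, cfg)
        np.testing.assert_array_equal(p1.post_mean, p2.post_mean)
        np.testing.assert_array_equal(f1, f2)
        np.testing.assert_array_equal(S1, S2)

    def test_posterior_covariances_stay_psd(self, em_posterior):
        post, _f, _S, _log = em_posterior
        for C in post.post_cov:
            assert np.linalg.eigvalsh(C).min() > -1e-8


class TestSmoothMean:
    def test_zero_penalty_equals_column_mean(self, grid):
        rng = np.random.default_rng(3)
        pm = rng.normal(size=(12, 9))
        f = smooth_mean(pm, grid, FPCAConfig(lambda_mean=0.0))
        np.testing.assert_allclose(f, pm.mean(axis=0))

    def test_infinite_penalty_approaches_straight_line(self, grid):
        rng = np.random.default_rng(4)
        pm = rng.normal(size=(12, 9)) + np.linspace(0, 2, 9)
        f = smooth_mean(pm, grid, FPCAConfig(lambda_mean=1e12))
        # best-fit line to the column means
        ybar = pm.mean(axis=0)
        X = np.vstack([np.ones(9), grid.values]).T
        line = X @ np.linalg.lstsq(X, ybar, rcond=None)[0]
        np.testing.assert_allclose(f, line, atol=1e-3)

    def test_gcv_beats_raw_mean_on_noisy_quadratic(self, grid):
        s = grid.values
        truth = 0.5 + 1e-4 * s**2 - 2e-3 * s
        rng = np.random.default_rng(5)
        wins = 0
        for rep in range(10):
            pm = truth + rng.normal(scale=0.8, size=(20, 9))
            f = smooth_mean(pm, grid, FPCAConfig(lambda_mean=None))
            raw = pm.mean(axis=0)
            if np.mean((f - truth) ** 2) <= np.mean((raw - truth) ** 2):
                wins += 1
        assert wins >= 7

    def test_tiny_grid_falls_back_with_warning(self):
        g = StimulusGrid(np.array([0.0, 1.0, 2.0]))
        with pytest.warns(RuntimeWarning, match="4 grid points"):
            f = smooth_mean(np.ones((5, 3)), g)
        np.testing.assert_allclose(f, 1.0)


class TestPenalizedFpca:
    def test_zero_penalty_equals_brute_force_pca(self, grid):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(40, 9)) @ np.diag(np.linspace(2, 0.1, 9))
        f = X.mean(axis=0)
        phis, scores, shares = penalized_fpca(
            X, f, grid, FPCAConfig(K=4, lambda_pc=0.0)
        )
        Xc = X - f
        w, V = np.linalg.eigh((Xc.T @ Xc) / 40)
        V = V[:, np.argsort(w)[::-1]]
        for k in range(4):
            assert abs(phis[k] @ V[:, k]) == pytest.approx(1.0, abs=1e-8)
        assert shares.sum() == pytest.approx(1.0)

    def test_noiseless_rank_one_recovery(self, grid, mu0):
        phi = pfpca.make_fluctuation_fpc("shift", mu0, grid)
        rng = np.random.default_rng(7)
        a = rng.normal(size=30)
        X = np.log(mu0) + np.outer(a, phi)
        phis, scores, shares = penalized_fpca(
            X, np.log(mu0), grid, FPCAConfig(K=1, lambda_pc=0.0)
        )
        assert abs(phis[0] @ phi) > 0.999
        r = np.corrcoef(scores.scores[:, 0], a)[0, 1]
        assert abs(r) > 0.999
        assert shares[0] == pytest.approx(1.0)

    def test_rank_deficient_input_reduces_k_with_warning(self, grid):
        X = np.outer(np.arange(5.0), np.eye(9)[0])
        with pytest.warns(RuntimeWarning, match="reducing K"):
            phis, _s, _sh = penalized_fpca(
                X, X.mean(0), grid, FPCAConfig(K=5, lambda_pc=0.0)
            )
        assert phis.shape[0] < 5

    def test_penalty_smooths_the_leading_component(self, grid):
        rng = np.random.default_rng(8)
        smooth_dir = np.sin(np.linspace(0, np.pi, 9))
        smooth_dir /= np.linalg.norm(smooth_dir)
        X = np.outer(rng.normal(size=60), smooth_dir) + rng.normal(
            scale=0.4, size=(60, 9)
        )
        f = X.mean(axis=0)
        rough = penalized_fpca(X, f, grid, FPCAConfig(K=1, lambda_pc=0.0))[0][0]
        lam = grid.spacing**4  # strong curvature penalty
        smoothed = penalized_fpca(
            X, f, grid, FPCAConfig(K=1, lambda_pc=lam)
        )[0][0]
        P = np.diff(np.eye(9), 2, axis=0)
        assert np.sum((P @ smoothed) ** 2) <= np.sum((P @ rough) ** 2) + 1e-12
        assert abs(smoothed @ smooth_dir) > 0.9


class TestFitPfpca:
    def test_gain_benchmark_first_fpc_near_constant(self, gain_fit, gain_dataset):
        decomp, scores, _post = gain_fit
        _counts, truth, _true_scores = gain_dataset
        cos = abs(decomp.phis[0] @ truth.phis[0])
        assert cos > 0.8  # close to the constant (gain) direction
        assert 0.6 < scores.variance_shares[0] < 0.95  # truth: 0.8

    def test_sign_convention_nonnegative_sum(self, gain_fit):
        decomp, _scores, _post = gain_fit
        for phi in decomp.phis:
            s = phi.sum()
            assert s >= 0 or abs(s) < 1e-8

    def test_under_modeling_leaves_residual_variance(self, grid, mu0):
        phi1 = pfpca.make_fluctuation_fpc("gain", mu0, grid)
        phi2 = pfpca.make_fluctuation_fpc("shift", mu0, grid)
        phi2 -= phi1 * (phi1 @ phi2)
        phi2 /= np.linalg.norm(phi2)
        decomp = pfpca.TuningDecomposition(
            grid=grid, f=np.log(mu0), phis=np.vstack([phi1, phi2]),
            sigma_k2=np.array([1.3, 1.2]), sigma0_2=0.0, dt=1.0,
        )
        counts, _s, _l = pfpca.simulate_counts(decomp, 60, seed=13)
        fit, scores, _p = pfpca.fit_pfpca(
            counts, K=1, em_config=EMConfig(M=1_000, max_iter=40, seed=13)
        )
        assert scores.variance_shares[0] == pytest.approx(1.0)  # K=1
        assert fit.sigma0_2 > 0.05  # the second mode is left in the residual

    def test_four_type_fpc_shape_recovery(self):
        """The first fPC's shape tracks the generating direction for every
        fluctuation type.  Thresholds reflect what posterior-mean PCA can
        deliver at B=50: the antisymmetric shift direction is intrinsically
        hardest (Poisson-noise shrinkage tilts it most)."""
        floors = {"gain": 0.85, "additive": 0.9, "shift": 0.7, "sharpen": 0.75}
        for kind, floor in floors.items():
            cos = []
            for seed in (1, 2):
                spec = pfpca.BenchmarkSpec(kind=kind, seed=seed)
                counts, truth, _s = pfpca.build_benchmark(spec)
                fit, _sc, _p = pfpca.fit_pfpca(
                    counts, K=3,
                    em_config=EMConfig(M=2_000, seed=seed),
                )
                cos.append(abs(fit.phis[0] @ truth.phis[0]))
            assert np.mean(cos) > floor, (kind, cos)

    def test_score_recovery_improves_with_more_blocks(self, grid, mu0):
        """Pooled score correlation at B=150 should beat B=25 on average."""
        phi = pfpca.make_fluctuation_fpc("gain", mu0, grid)
        Sigma, c = pfpca.make_structured_covariance(phi, 1.25, 0.8)
        corrs = {25: [], 150: []}
        for seed in range(3):
            for B in corrs:
                decomp = pfpca.TuningDecomposition(
                    grid=grid, f=np.log(mu0), phis=phi[None, :],
                    sigma_k2=np.array([1.25]), sigma0_2=c, dt=1.0,
                )
                counts, true_s, _l = pfpca.simulate_counts(decomp, B, seed=seed)
                fit, scores, _p = pfpca.fit_pfpca(
                    counts, K=3,
                    em_config=EMConfig(M=1_000, max_iter=60, seed=seed),
                )
                sign = np.sign(fit.phis[0] @ phi)
                r = np.corrcoef(sign * scores.scores[:, 0],
                                true_s.scores[:, 0])[0, 1]
                corrs[B].append(r)
        assert np.mean(corrs[150]) >= np.mean(corrs[25])
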