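import numpy as np
import pytest

from ipolng import (
    CountMatrix,
    FactorConfig,
    GammaParams,
    LogitNormalParams,
    apply_observation_mask,
    estimate_alpha0,
    fit_ipolng,
    quantile_regression_slope,
    warm_start,
)
from ipolng.types import PoLNGFit


def _pinball_bruteforce(x, y, tau):
    """Exhaustive pinball-loss minimization over candidate slopes y_i/x_i."""
    candidates = y / x
    losses = []
    for b in candidates:
        u = y - b * x
        losses.append(np.sum(u * (tau - (u < 0))))
    return candidates[int(np.argmin(losses))]


class TestQuantileRegressionSlope:
    def test_exact_line_zero_loss(self):
        x = np.linspace(1, 5, 10)
        assert quantile_regression_slope(x, 2 * x, 0.9) == pytest.approx(2.0, abs=1e-12)

    def test_single_point(self):
        for tau in (0.1, 0.5, 0.9):
            assert quantile_regression_slope([1.0], [3.0], tau) == pytest.approx(3.0)

    @pytest.mark.parametrize("tau", [0.5, 0.9])
    def test_matches_bruteforce_oracle(self, tau, rng):
        for _ in range(20):
            x = rng.uniform(0.1, 5.0, 20)
            y = rng.uniform(0.0, 10.0, 20)
            got = quantile_regression_slope(x, y, tau)
            want = _pinball_bruteforce(x, y, tau)
            assert got == pytest.approx(want, abs=1e-9)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            quantile_regression_slope([], [], 0.9)
        with pytest.raises(ValueError):
            quantile_regression_slope([0.0, 1.0], [1.0, 2.0], 0.9)
        with pytest.raises(ValueError):
            quantile_regression_slope([1.0], [1.0], 1.5)


def _fit_with_moments(a, b, K=2, I=6):
    cfg = FactorConfig(K=K, epochs=10)
    J = 4
    return PoLNGFit(
        cell_loading_q=GammaParams(np.broadcast_to(a, (I, K)).copy(),
                                   np.broadcast_to(b, (I, K)).copy()),
        theta_q=LogitNormalParams(np.zeros((K, J)), np.full((K, J), 0.1)),
        L_hat=np.zeros((I, K)),
        Theta_hat=np.full((K, J), 0.25),
        elbo_trace=np.zeros(10),
        config=cfg,
    )


class TestEstimateAlpha0:
    def test_exact_linear_relation(self, rng):
        # Gamma variational moments satisfy var = mean^2 / shape exactly,
        # so constant shape a0 across entries gives alpha0 = a0.
        a0 = 7.0
        b = rng.uniform(0.5, 3.0, (6, 2))
        fit = _fit_with_moments(np.full((6, 2), a0), b)
        est = estimate_alpha0([fit])
        assert est[0] == pytest.approx(a0, rel=1e-9)

    def test_variance_scaling_halves_alpha0(self, rng):
        a = rng.uniform(2.0, 5.0, (6, 2))
        b = rng.uniform(0.5, 3.0, (6, 2))
        base = estimate_alpha0([_fit_with_moments(a, b)])[0]
        # halving shape and rate doubles var at fixed mean
        doubled = estimate_alpha0([_fit_with_moments(a / 2, b / 2)])[0]
        assert doubled == pytest.approx(base / 2, rel=1e-9)


class TestWarmStart:
    def _fits(self):
        f1 = _fit_with_moments(np.full((6, 2), 2.0), np.full((6, 2), 1.0))
        f2 = _fit_with_moments(np.full((6, 2), 5.0), np.full((6, 2), 3.0))
        f2.theta_q = LogitNormalParams(np.ones((2, 4)), np.full((2, 4), 0.3))
        return [f1, f2]

    def test_argmax_selection_and_gamma_broadcast(self):
        ws = warm_start(self._fits(), (10.0, 2.0))
        assert ws.m_tilde == 0
        # modality 2's Gamma init equals modality 1's fitted params
        np.testing.assert_array_equal(ws.modality_gamma[1].shape, 2.0)
        np.testing.assert_array_equal(ws.modality_gamma[1].rate, 1.0)

    def test_tie_breaks_to_lowest_index(self):
        assert warm_start(self._fits(), (5.0, 5.0)).m_tilde == 0

    def test_other_modality_theta_init_modes(self):
        fits = self._fits()
        own = warm_start(fits, (10.0, 2.0), other_theta_init="own")
        np.testing.assert_array_equal(own.theta[1].mean, 1.0)
        default = warm_start(fits, (10.0, 2.0), other_theta_init="default")
        np.testing.assert_array_equal(default.theta[1].mean, 0.0)
        np.testing.assert_array_equal(default.theta[1].diag_var, 0.1)

    def test_shared_embedding_uses_defaults(self):
        ws = warm_start(self._fits(), (2.0, 10.0))
        assert ws.m_tilde == 1
        np.testing.assert_array_equal(ws.shared.shape, 0.5)
        np.testing.assert_array_equal(ws.shared.scale, 0.5)

    def test_dimension_mismatch_rejected(self):
        f1 = _fit_with_moments(np.full((6, 2), 2.0), np.full((6, 2), 1.0))
        f2 = _fit_with_moments(np.full((5, 2), 2.0), np.full((5, 2), 1.0), I=5)
        with pytest.raises(ValueError):
            warm_start([f1, f2], (1.0, 2.0))


class TestObservationMask:
    def test_masked_cells_zeroed(self, rng):
        W = CountMatrix(rng.poisson(2.0, (10, 5)) + 1)
        out = apply_observation_mask(W, [1, 3])
        assert out.values[1].sum() == 0 and out.values[3].sum() == 0
        np.testing.assert_array_equal(out.values[0], W.values[0])

    def test_mask_all_zeroes_scaling(self, rng):
        from ipolng import scaling_factors

        W = CountMatrix(rng.poisson(2.0, (6, 5)) + 1)
        out = apply_observation_mask(W, np.arange(6))
        np.testing.assert_array_equal(scaling_factors(out), 0.0)

    def test_masked_cell_contributes_zero_likelihood(self, rng):
        from ipolng.polng import _poisson_loglik_and_grads

        W = np.vstack([rng.poisson(3.0, (3, 4)), np.zeros((1, 4))])
        s = W.sum(axis=1)
        lgw = np.zeros_like(W)
        l = rng.uniform(0.1, 1.0, (4, 2))
        theta = np.full((2, 4), 0.25)
        ll_all, g_l, _ = _poisson_loglik_and_grads(W, s, lgw, l, theta, s > 0)
        ll_obs, _, _ = _poisson_loglik_and_grads(W[:3], s[:3], lgw[:3], l[:3], theta, s[:3] > 0)
        assert ll_all == pytest.approx(ll_obs, rel=1e-12)
        np.testing.assert_array_equal(g_l[3], 0.0)

    def test_out_of_range_index_rejected(self, rng):
        W = CountMatrix(rng.poisson(2.0, (4, 3)))
        with pytest.raises(IndexError):
            apply_observation_mask(W, [7])


def _paired_counts(rng, I=80, J=60, depth=400.0):
    theta = rng.dirichlet(np.ones(J), size=3)
    l = rng.dirichlet(np.ones(3) * 0.5, size=I)
    W = rng.poisson(depth * (l @ theta)).astype(float)
    return CountMatrix(W, modality="RNA")


class TestFitIpolng:
    def test_cell_mismatch_rejected(self, rng):
        W1 = CountMatrix(rng.poisson(2.0, (5, 4)) + 1)
        W2 = CountMatrix(rng.poisson(2.0, (6, 4)) + 1)
        with pytest.raises(ValueError):
            fit_ipolng(W1, W2, FactorConfig(K=2, epochs=10))

    def test_fully_masked_cell_rejected(self, rng):
        W = CountMatrix(rng.poisson(2.0, (5, 4)) + 1)
        mask = np.zeros((5, 2), dtype=bool)
        mask[2] = True
        with pytest.raises(ValueError):
            fit_ipolng(W, W.copy(), FactorConfig(K=2, epochs=10), mask=mask)

    def test_contract_determinism_and_progress(self, rng):
        W1 = _paired_counts(rng)
        W2 = CountMatrix(W1.values.copy(), W1.cell_ids, None, "epigenome")
        cfg = FactorConfig(K=3, epochs=300, seed=4)
        fit = fit_ipolng(W1, W2, cfg, polng_epochs=150)
        for Th in fit.Theta_hat_m:
            np.testing.assert_allclose(Th.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(fit.L_hat > 0)
        assert all(a > 0 for a in fit.alpha0)
        assert fit.elbo_trace[-100:].mean() > fit.elbo_trace[:100].mean()
        fit2 = fit_ipolng(W1, W2, cfg, polng_epochs=150)
        np.testing.assert_array_equal(fit.elbo_trace, fit2.elbo_trace)

    def test_identical_modalities_give_similar_loadings(self, rng):
        """With W1 = W2 and equal alpha0, the modality loadings agree."""
        W1 = _paired_counts(rng, I=60, J=50, depth=8000.0)
        W2 = CountMatrix(W1.values.copy(), W1.cell_ids, None, "epigenome")
        cfg = FactorConfig(K=3, epochs=1500, seed=11)
        fit = fit_ipolng(W1, W2, cfg, alpha0=(20.0, 20.0), polng_epochs=750)
        num = np.linalg.norm(fit.L_hat_m[0] - fit.L_hat_m[1])
        den = np.linalg.norm(fit.L_hat_m[0])
        assert num / den < 0.1

    def test_masked_fit_returns_all_cells(self, rng):
        W1 = _paired_counts(rng, I=50, J=40)
        W2 = CountMatrix(W1.values.copy(), W1.cell_ids, None, "epigenome")
        mask = np.zeros((50, 2), dtype=bool)
        mask[np.arange(0, 50, 5), 1] = True  # 20% of modality-2 cells unobserved
        fit = fit_ipolng(W1, W2, FactorConfig(K=3, epochs=200, seed=0), mask=mask,
                         polng_epochs=100)
        assert fit.L_hat.shape == (50, 3)
        assert np.all(np.isfinite(fit.L_hat))
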