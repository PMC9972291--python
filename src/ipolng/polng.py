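"""Single-modality Poisson / Logit-Normal-Gamma factor model (PoLNG).

The generative model for one count matrix W (I cells x J features):

    l_ik   ~ Gamma(alpha_ik, beta_ik)            (shape-rate)
    theta_k = softmax(eta_k),  eta_k ~ N(mu_k, Sigma_k)   (diagonal)
    w_ij   ~ Poisson( s_i * sum_k l_ik theta_kj )

with s_i the total counts of cell i, which softly constrains the row sums
of the cell loading matrix L to be around 1.

Inference maximizes a single-Monte-Carlo-sample evidence lower bound with
Adam.  The Gaussian block uses the standard location-scale
reparameterization; the Gamma block uses implicit reparameterization
through the incomplete-gamma CDF; the KL terms against the priors are
closed-form, which keeps the gradient variance low enough for one sample
per step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special

from .math_core import (
    Adam,
    gamma_kl,
    gamma_mode,
    gaussian_kl,
    scaling_factors,
    softmax_backward,
    softmax_rows,
    standard_gamma_shape_grad,
)
from .types import CountMatrix, FactorConfig, GammaParams, LogitNormalParams, PoLNGFit

__all__ = [
    "PoLNGPrior",
    "init_polng",
    "polng_elbo",
    "fit_polng",
    "variational_moments",
]

# bounds on the log-scale optimizer variables, to keep shapes/rates/scales
# inside a numerically safe range
_LOG_LO, _LOG_HI = np.log(1e-4), np.log(1e6)
_LOG_SIG_LO, _LOG_SIG_HI = np.log(1e-6), np.log(1e3)
_LAM_FLOOR = 1e-12


@dataclass
class PoLNGPrior:
    """Prior hyperparameters of the single-modality model."""

    gamma_shape: np.ndarray  # (I, K)
    gamma_rate: np.ndarray  # (I, K)
    theta_mean: np.ndarray  # (K, J)
    theta_var: np.ndarray  # (K, J)


def init_polng(
    W: CountMatrix,
    cfg: FactorConfig,
    *,
    prior_shape: float = 0.1,
    prior_rate: float | None = None,
    init_shape: float = 0.5,
    init_rate: float = 0.5,
    init_theta_var: float = 0.1,
    init_gamma: GammaParams | None = None,
    init_theta: LogitNormalParams | None = None,
) -> tuple[PoLNGPrior, GammaParams, LogitNormalParams]:
    """Default priors and initial variational parameters.

    Defaults: prior Gamma(0.1, K*0.1) on each loading (prior mean 1/K, so
    loading rows softly sum to 1), standard-normal Logit-Normal prior on
    each theta row; variational init a=b=0.5, mu=0, variance 0.1.  Explicit
    ``init_gamma`` / ``init_theta`` override the defaults (used by the
    joint model's warm start).
    """
    I, J = W.shape
    K = cfg.K
    if prior_rate is None:
        prior_rate = K * prior_shape
    prior = PoLNGPrior(
        gamma_shape=np.full((I, K), prior_shape),
        gamma_rate=np.full((I, K), prior_rate),
        theta_mean=np.zeros((K, J)),
        theta_var=np.ones((K, J)),
    )
    if init_gamma is None:
        init_gamma = GammaParams(np.full((I, K), init_shape), np.full((I, K), init_rate))
    if init_theta is None:
        init_theta = LogitNormalParams(np.zeros((K, J)), np.full((K, J), init_theta_var))
    if init_gamma.shape.shape != (I, K):
        raise ValueError(f"initial Gamma parameters must be {I}x{K}")
    if init_theta.mean.shape != (K, J):
        raise ValueError(f"initial Logit-Normal parameters must be {K}x{J}")
    return prior, init_gamma, init_theta


def _poisson_loglik_and_grads(
    W: np.ndarray,
    s: np.ndarray,
    lgw: np.ndarray,
    l: np.ndarray,
    theta: np.ndarray,
    obs: np.ndarray,
):
    """Poisson log-likelihood sum over observed cells and its gradients
    w.r.t. the sampled loadings and simplex rows."""
    lam = (l @ theta) * s[:, None]
    lam = np.maximum(lam, _LAM_FLOOR)
    with np.errstate(divide="ignore", invalid="ignore"):
        ll_mat = W * np.log(lam) - lam - lgw
        G = (W / lam - 1.0) * s[:, None]
    ll_mat[~obs] = 0.0
    G[~obs] = 0.0
    loglik = float(ll_mat.sum())
    g_l = G @ theta.T
    g_theta = l.T @ G
    return loglik, g_l, g_theta


class _PoLNGEngine:
    """One-sample pathwise ELBO and gradients for PoLNG; drives Adam."""

    def __init__(
        self,
        W: CountMatrix,
        prior: PoLNGPrior,
        q_gamma: GammaParams,
        q_theta: LogitNormalParams,
    ):
        self.Wv = W.values
        self.s = scaling_factors(W)
        self.obs = self.s > 0
        self.lgw = special.gammaln(self.Wv + 1.0)
        self.prior = prior
        self.params = {
            "xa": np.log(q_gamma.shape.copy()),
            "xb": np.log(q_gamma.rate.copy()),
            "mu": q_theta.mean.copy(),
            "om": 0.5 * np.log(q_theta.diag_var.copy()),
        }

    # -- current constrained parameters -------------------------------------
    def gamma_q(self) -> GammaParams:
        return GammaParams(np.exp(self.params["xa"]), np.exp(self.params["xb"]))

    def theta_q(self) -> LogitNormalParams:
        sig = np.exp(self.params["om"])
        return LogitNormalParams(self.params["mu"].copy(), sig**2)

    def elbo_and_grads(self, rng: np.random.Generator):
        p = self.params
        a, b = np.exp(p["xa"]), np.exp(p["xb"])
        sig = np.exp(p["om"])

        u = np.maximum(rng.standard_gamma(a), 1e-30)
        l = u / b
        eps = rng.standard_normal(p["mu"].shape)
        eta = p["mu"] + sig * eps
        theta = softmax_rows(eta)

        loglik, g_l, g_theta = _poisson_loglik_and_grads(
            self.Wv, self.s, self.lgw, l, theta, self.obs
        )
        g_eta = softmax_backward(theta, g_theta)

        kl_g, dklg_da, dklg_db = gamma_kl(
            a, b, self.prior.gamma_shape, self.prior.gamma_rate, grads=True
        )
        kl_n, dkln_dmu, dkln_dsig = gaussian_kl(
            p["mu"], sig, self.prior.theta_mean, np.sqrt(self.prior.theta_var), grads=True
        )

        du_da = standard_gamma_shape_grad(a, u)
        g_a = g_l * (du_da / b) - dklg_da
        g_b = g_l * (-l / b) - dklg_db
        g_mu = g_eta - dkln_dmu
        g_sig = g_eta * eps - dkln_dsig

        elbo = loglik - float(kl_g.sum()) - float(kl_n.sum())
        grads = {
            "xa": g_a * a,
            "xb": g_b * b,
            "mu": g_mu,
            "om": g_sig * sig,
        }
        parts = {"loglik": loglik, "kl_gamma": float(kl_g.sum()), "kl_theta": float(kl_n.sum())}
        return elbo, grads, parts

    def clip(self) -> None:
        np.clip(self.params["xa"], _LOG_LO, _LOG_HI, out=self.params["xa"])
        np.clip(self.params["xb"], _LOG_LO, _LOG_HI, out=self.params["xb"])
        np.clip(self.params["om"], _LOG_SIG_LO, _LOG_SIG_HI, out=self.params["om"])


def polng_elbo(
    W: CountMatrix,
    prior: PoLNGPrior,
    variational: tuple[GammaParams, LogitNormalParams],
    rng: np.random.Generator,
    return_parts: bool = False,
):
    """Single-sample stochastic estimate of the evidence lower bound.

    Returns E_q[log p(W, L, theta) - log q] estimated with one draw from q;
    the KL terms are closed-form, only the Poisson likelihood is sampled.
    """
    q_gamma, q_theta = variational
    eng = _PoLNGEngine(W, prior, q_gamma, q_theta)
    elbo, _, parts = eng.elbo_and_grads(rng)
    if not np.isfinite(elbo):
        raise FloatingPointError("non-finite ELBO estimate")
    if return_parts:
        return elbo, parts
    return elbo


def fit_polng(
    W: CountMatrix,
    cfg: FactorConfig,
    init: tuple[GammaParams, LogitNormalParams] | None = None,
    prior: PoLNGPrior | None = None,
) -> PoLNGFit:
    """Fit PoLNG by stochastic variational inference.

    Full-batch Adam ascent on the one-sample pathwise ELBO for
    ``cfg.epochs`` steps at ``cfg.learning_rate``.  Deterministic given
    ``cfg.seed``.  Point estimates are the variational modes: L_hat from
    the Gamma mode (zero where shape <= 1), Theta_hat = softmax of the
    Logit-Normal means.
    """
    if W.values.sum() == 0:
        raise ValueError("cannot fit an all-zero count matrix")
    default_prior, g0, t0 = init_polng(W, cfg)
    if prior is None:
        prior = default_prior
    if init is not None:
        g0, t0 = init
    eng = _PoLNGEngine(W, prior, g0, t0)
    opt = Adam(eng.params, lr=cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed)

    trace = np.empty(cfg.epochs)
    bad = 0
    for epoch in range(cfg.epochs):
        if cfg.mc_samples == 1:
            elbo, grads, _ = eng.elbo_and_grads(rng)
        else:
            elbo = 0.0
            grads = None
            for _ in range(cfg.mc_samples):
                e1, g1, _ = eng.elbo_and_grads(rng)
                elbo += e1 / cfg.mc_samples
                if grads is None:
                    grads = {k: v / cfg.mc_samples for k, v in g1.items()}
                else:
                    for k in grads:
                        grads[k] += g1[k] / cfg.mc_samples
        trace[epoch] = elbo
        if not np.isfinite(elbo):
            bad += 1
            if bad > 10:
                raise FloatingPointError(
                    f"ELBO non-finite for {bad} consecutive epochs (epoch {epoch}); "
                    "check the input counts or lower the learning rate"
                )
            continue
        bad = 0
        opt.step(grads)
        eng.clip()

    q_gamma = eng.gamma_q()
    q_theta = eng.theta_q()
    return PoLNGFit(
        cell_loading_q=q_gamma,
        theta_q=q_theta,
        L_hat=gamma_mode(q_gamma),
        Theta_hat=softmax_rows(q_theta.mean),
        elbo_trace=trace,
        config=cfg,
        modality=W.modality,
    )


def variational_moments(fit: PoLNGFit) -> tuple[np.ndarray, np.ndarray]:
    """Mean and variance of the Gamma variational cell loadings.

    mean = shape/rate, variance = shape/rate^2 — the inputs to the
    noise-hyperparameter calibration of the joint model.
    """
    a, b = fit.cell_loading_q.shape, fit.cell_loading_q.rate
    return a / b, a / b**2
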