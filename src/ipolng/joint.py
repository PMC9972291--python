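"""Joint two-modality factor model (iPoLNG).

The two count matrices W^(1), W^(2) measure the same I cells.  A shared
cells-by-factors embedding L ties the modalities together:

    l_ik        ~ InverseGamma(alpha_ik, beta_ik)        (shape-scale)
    l_ik^(m) | l_ik ~ Gamma(alpha0^(m), alpha0^(m)/l_ik)
    theta_k^(m) = softmax(eta_k^(m)), eta ~ N(mu, Sigma) (diagonal)
    w_ij^(m)    ~ Poisson( s_i^(m) * sum_k l_ik^(m) theta_kj^(m) )

Conditional on l_ik the modality loadings satisfy E[l^(m)] = l and
var[l^(m)] = l^2/alpha0^(m): a large alpha0 marks a low-noise modality.
alpha0 is calibrated automatically from single-modality PoLNG fits by a
90% quantile regression of the variational variance on the squared
variational mean (no intercept); the reciprocal slope is alpha0.  The
joint fit is then warm-started from the PoLNG fit of the least-noisy
modality.
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
    inverse_gamma_mode,
    scaling_factors,
    softmax_backward,
    softmax_rows,
    standard_gamma_shape_grad,
)
from .polng import _LOG_HI, _LOG_LO, _LOG_SIG_HI, _LOG_SIG_LO, _poisson_loglik_and_grads, fit_polng
from .types import (
    CountMatrix,
    FactorConfig,
    GammaParams,
    InverseGammaParams,
    IPoLNGFit,
    LogitNormalParams,
    PoLNGFit,
)
from .polng import variational_moments

__all__ = [
    "quantile_regression_slope",
    "estimate_alpha0",
    "WarmStart",
    "warm_start",
    "apply_observation_mask",
    "fit_ipolng",
]


def quantile_regression_slope(x: np.ndarray, y: np.ndarray, tau: float = 0.9) -> float:
    """Slope of the no-intercept quantile regression of y on x.

    Minimizes the pinball loss sum_i rho_tau(y_i - b*x_i) with
    rho_tau(u) = u*(tau - 1{u<0}).  For a single positive covariate and no
    intercept the minimizer is a weighted tau-quantile of the ratios
    y_i/x_i with weights x_i: the smallest ratio r such that the x-weight
    of ratios <= r reaches tau of the total.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size == 0 or y.size == 0:
        raise ValueError("empty input")
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if np.any(x <= 0):
        raise ValueError("all x must be strictly positive")
    if not 0.0 < tau < 1.0:
        raise ValueError("tau must lie in (0, 1)")
    r = y / x
    order = np.argsort(r, kind="stable")
    cumw = np.cumsum(x[order])
    k = int(np.searchsorted(cumw, tau * cumw[-1]))
    return float(r[order[min(k, r.size - 1)]])


def estimate_alpha0(fits: list[PoLNGFit], tau: float = 0.9) -> tuple[float, ...]:
    """Per-modality noise hyperparameter from single-modality fits.

    For each modality, regress the variational variance of the cell
    loadings on their squared variational mean through the origin at
    quantile ``tau``; alpha0 is the reciprocal slope.  The high quantile
    compensates for the variational variance being under-estimated.
    """
    out = []
    for fit in fits:
        mean, var = variational_moments(fit)
        x = (mean**2).ravel()
        y = var.ravel()
        keep = x > 0
        slope = quantile_regression_slope(x[keep], y[keep], tau)
        if slope <= 0:
            raise ValueError(f"degenerate quantile-regression slope {slope}")
        out.append(1.0 / slope)
    return tuple(out)


@dataclass
class WarmStart:
    """Initial variational parameters for the joint fit."""

    shared: InverseGammaParams
    modality_gamma: list[GammaParams]
    theta: list[LogitNormalParams]
    m_tilde: int


def warm_start(
    fits: list[PoLNGFit],
    alpha0: tuple[float, ...],
    other_theta_init: str = "own",
    default_init: float = 0.5,
    default_theta_var: float = 0.1,
) -> WarmStart:
    """Warm-start rule: trust the least-noisy modality.

    m_tilde = argmax_m alpha0 (ties broken toward the lowest index).  The
    Gamma variational parameters (a, b) of modality m_tilde initialize the
    modality loadings for ALL modalities (this also pins down a common
    factor ordering, easing non-identifiability).  Theta parameters of
    m_tilde come from its own fit; the other modality's theta comes from
    its own fit too when ``other_theta_init="own"`` (default), or from the
    generic defaults when ``"default"``.  The shared embedding's
    Inverse-Gamma parameters start at the generic defaults.
    """
    if len(fits) != len(alpha0):
        raise ValueError("one alpha0 per fit required")
    shapes = {f.cell_loading_q.shape.shape for f in fits}
    if len(shapes) != 1:
        raise ValueError("PoLNG fits have mismatched cell/factor dimensions")
    if other_theta_init not in ("own", "default"):
        raise ValueError("other_theta_init must be 'own' or 'default'")
    m_t = int(np.argmax(alpha0))
    ref = fits[m_t].cell_loading_q
    I, K = ref.shape.shape
    shared = InverseGammaParams(np.full((I, K), default_init), np.full((I, K), default_init))
    gammas = [GammaParams(ref.shape.copy(), ref.rate.copy()) for _ in fits]
    thetas = []
    for m, f in enumerate(fits):
        if m == m_t or other_theta_init == "own":
            thetas.append(
                LogitNormalParams(f.theta_q.mean.copy(), f.theta_q.diag_var.copy())
            )
        else:
            K_, J_ = f.theta_q.mean.shape
            thetas.append(
                LogitNormalParams(np.zeros((K_, J_)), np.full((K_, J_), default_theta_var))
            )
    return WarmStart(shared=shared, modality_gamma=gammas, theta=thetas, m_tilde=m_t)


def apply_observation_mask(W: CountMatrix, masked_cells) -> CountMatrix:
    """Zero out all counts of the given cells in this modality.

    Setting an unobserved cell's counts to zero makes its scaling factor
    zero, which removes it from the likelihood (the fit additionally skips
    zero-depth cells explicitly, so no log(0) ever arises).
    """
    masked_cells = np.asarray(masked_cells, dtype=int)
    if masked_cells.size and (masked_cells.min() < 0 or masked_cells.max() >= W.n_cells):
        raise IndexError("masked cell index out of range")
    out = W.copy()
    out.values[masked_cells] = 0.0
    return out


def _shared_prior(I: int, K: int, parse: str) -> tuple[np.ndarray, np.ndarray]:
    alpha = 1.0
    beta = (alpha + 1.0) / K if parse == "ratio" else alpha + 1.0 / K
    return np.full((I, K), alpha), np.full((I, K), beta)


class _IPoLNGEngine:
    """Pathwise one-sample ELBO and gradients for the joint model."""

    def __init__(
        self,
        Ws: list[CountMatrix],
        alpha0: tuple[float, float],
        ws: WarmStart,
        cfg: FactorConfig,
    ):
        self.Wv = [W.values for W in Ws]
        self.s = [scaling_factors(W) for W in Ws]
        self.obs = [s > 0 for s in self.s]
        self.lgw = [special.gammaln(v + 1.0) for v in self.Wv]
        self.alpha0 = alpha0
        I = Ws[0].n_cells
        self.prior_shape, self.prior_scale = _shared_prior(I, cfg.K, cfg.prior_beta_parse)
        self.theta_prior_mean = [np.zeros((cfg.K, W.n_features)) for W in Ws]
        self.theta_prior_sd = [np.ones((cfg.K, W.n_features)) for W in Ws]
        self.params = {"xa_s": np.log(ws.shared.shape.copy()), "xb_s": np.log(ws.shared.scale.copy())}
        for m in range(2):
            self.params[f"xa{m}"] = np.log(ws.modality_gamma[m].shape.copy())
            self.params[f"xb{m}"] = np.log(ws.modality_gamma[m].rate.copy())
            self.params[f"mu{m}"] = ws.theta[m].mean.copy()
            self.params[f"om{m}"] = 0.5 * np.log(ws.theta[m].diag_var.copy())

    def shared_q(self) -> InverseGammaParams:
        return InverseGammaParams(np.exp(self.params["xa_s"]), np.exp(self.params["xb_s"]))

    def modality_q(self, m: int) -> GammaParams:
        return GammaParams(np.exp(self.params[f"xa{m}"]), np.exp(self.params[f"xb{m}"]))

    def theta_q(self, m: int) -> LogitNormalParams:
        sig = np.exp(self.params[f"om{m}"])
        return LogitNormalParams(self.params[f"mu{m}"].copy(), sig**2)

    def elbo_and_grads(self, rng: np.random.Generator):
        p = self.params
        a_s, b_s = np.exp(p["xa_s"]), np.exp(p["xb_s"])

        # shared embedding: l = scale / g, g ~ Gamma(shape, 1)
        g = np.maximum(rng.standard_gamma(a_s), 1e-30)
        l = b_s / g
        dg_da = standard_gamma_shape_grad(a_s, g)

        # KL of the shared block against its Inverse-Gamma prior (same
        # closed form as the Gamma-Gamma KL, scale playing the rate's role)
        klL, dklL_da, dklL_db = gamma_kl(a_s, b_s, self.prior_shape, self.prior_scale, grads=True)

        elbo = -float(klL.sum())
        g_l_total = np.zeros_like(l)
        grads = {}

        for m in range(2):
            a_m, b_m = np.exp(p[f"xa{m}"]), np.exp(p[f"xb{m}"])
            sig = np.exp(p[f"om{m}"])
            u = np.maximum(rng.standard_gamma(a_m), 1e-30)
            l_m = u / b_m
            eps = rng.standard_normal(p[f"mu{m}"].shape)
            theta = softmax_rows(p[f"mu{m}"] + sig * eps)

            loglik, g_lm, g_theta = _poisson_loglik_and_grads(
                self.Wv[m], self.s[m], self.lgw[m], l_m, theta, self.obs[m]
            )
            g_eta = softmax_backward(theta, g_theta)

            # conditional KL( q(l^m) || Gamma(alpha0, alpha0/l) ) at sampled l
            a0 = self.alpha0[m]
            beta_c = a0 / l
            ckl, dckl_da, dckl_db = gamma_kl(a_m, b_m, a0, beta_c, grads=True)
            # pathwise dependence on the sampled shared embedding
            dckl_dl = a0 / l - (a_m / b_m) * a0 / l**2

            kl_n, dkln_dmu, dkln_dsig = gaussian_kl(
                p[f"mu{m}"], sig, self.theta_prior_mean[m], self.theta_prior_sd[m], grads=True
            )

            du_da = standard_gamma_shape_grad(a_m, u)
            g_a = (g_lm * (du_da / b_m)) - dckl_da
            g_b = (g_lm * (-l_m / b_m)) - dckl_db
            grads[f"xa{m}"] = g_a * a_m
            grads[f"xb{m}"] = g_b * b_m
            grads[f"mu{m}"] = g_eta - dkln_dmu
            grads[f"om{m}"] = (g_eta * eps - dkln_dsig) * sig

            g_l_total += -dckl_dl
            elbo += loglik - float(ckl.sum()) - float(kl_n.sum())

        # chain shared-embedding gradient through l = b_s / g
        dl_da = -(b_s / g**2) * dg_da
        dl_db = 1.0 / g
        grads["xa_s"] = (g_l_total * dl_da - dklL_da) * a_s
        grads["xb_s"] = (g_l_total * dl_db - dklL_db) * b_s
        return elbo, grads

    def clip(self) -> None:
        for k, v in self.params.items():
            if k.startswith("om"):
                np.clip(v, _LOG_SIG_LO, _LOG_SIG_HI, out=v)
            elif k.startswith(("xa", "xb")):
                np.clip(v, _LOG_LO, _LOG_HI, out=v)


def fit_ipolng(
    W1: CountMatrix,
    W2: CountMatrix,
    cfg: FactorConfig,
    alpha0: tuple[float, float] | None = None,
    mask: np.ndarray | None = None,
    init: WarmStart | None = None,
    polng_epochs: int | None = None,
    tau: float = 0.9,
    keep_polng_fits: bool = False,
) -> IPoLNGFit:
    """Fit the joint model by stochastic variational inference.

    If ``alpha0`` is not given, the full pipeline runs first: a PoLNG fit
    per modality (``polng_epochs`` defaults to ``cfg.epochs``), alpha0
    calibration by quantile regression, and the warm start from the
    least-noisy modality.  ``mask`` is an optional (I, 2) boolean array
    marking unobserved cell/modality pairs, realized by zeroing those
    cells' counts (equivalently, dropping them from that modality's
    likelihood).  Deterministic given ``cfg.seed``.
    """
    if W1.n_cells != W2.n_cells:
        raise ValueError("both modalities must measure the same cells")
    if W1.cell_ids != W2.cell_ids:
        raise ValueError("cell identifiers disagree between modalities")
    Ws = [W1, W2]

    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (W1.n_cells, 2):
            raise ValueError("mask must be an (I, 2) boolean array")
        if np.any(mask.all(axis=1)):
            raise ValueError("some cells are masked in both modalities")
        Ws = [apply_observation_mask(W, np.flatnonzero(mask[:, m])) for m, W in enumerate(Ws)]

    polng_fits: list[PoLNGFit] | None = None
    if alpha0 is None or init is None:
        sub_epochs = polng_epochs if polng_epochs is not None else cfg.epochs
        polng_fits = [
            fit_polng(W, cfg.with_(epochs=sub_epochs, seed=cfg.seed + 1 + m))
            for m, W in enumerate(Ws)
        ]
    if alpha0 is None:
        alpha0 = estimate_alpha0(polng_fits, tau=tau)
    if init is None:
        init = warm_start(polng_fits, alpha0)

    eng = _IPoLNGEngine(Ws, alpha0, init, cfg)
    opt = Adam(eng.params, lr=cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed)

    trace = np.empty(cfg.epochs)
    bad = 0
    for epoch in range(cfg.epochs):
        elbo, grads = eng.elbo_and_grads(rng)
        trace[epoch] = elbo
        if not np.isfinite(elbo):
            bad += 1
            if bad > 10:
                raise FloatingPointError(
                    f"ELBO non-finite for {bad} consecutive epochs (epoch {epoch})"
                )
            continue
        bad = 0
        opt.step(grads)
        eng.clip()

    shared = eng.shared_q()
    mods = [eng.modality_q(m) for m in range(2)]
    thetas = [eng.theta_q(m) for m in range(2)]
    return IPoLNGFit(
        shared_q=shared,
        modality_q=mods,
        theta_q=thetas,
        alpha0=tuple(float(a) for a in alpha0),
        L_hat=inverse_gamma_mode(shared),
        L_hat_m=[gamma_mode(q) for q in mods],
        Theta_hat_m=[softmax_rows(t.mean) for t in thetas],
        elbo_trace=trace,
        config=cfg,
        modalities=(W1.modality, W2.modality),
        polng_fits=polng_fits if keep_polng_fits else None,
    )
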