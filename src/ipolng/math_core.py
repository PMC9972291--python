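"""Numeric primitives shared by both factor models.

Contains the softmax simplex map, sequencing-depth scaling factors, the
mode formulas used for point estimation, closed-form KL divergences with
their analytic gradients, and the implicit-reparameterization gradient of
a standard-Gamma sample with respect to its shape — the piece that lets a
plain numpy implementation run pathwise stochastic variational inference
through Gamma and Inverse-Gamma variational distributions.
"""

from __future__ import annotations

import numpy as np
from scipy import special

from .types import CountMatrix, GammaParams, InverseGammaParams

__all__ = [
    "softmax_rows",
    "softmax_backward",
    "scaling_factors",
    "gamma_mode",
    "inverse_gamma_mode",
    "gamma_kl",
    "gaussian_kl",
    "standard_gamma_shape_grad",
    "Adam",
]

_U_FLOOR = 1e-30


def softmax_rows(x: np.ndarray) -> np.ndarray:
    """Row-wise softmax: each row is mapped onto the probability simplex.

    Shift-invariant by construction (the row max is subtracted before
    exponentiation), so adding a constant to a row leaves the output
    unchanged.
    """
    x = np.asarray(x, dtype=np.float64)
    if not np.all(np.isfinite(x)):
        raise ValueError("softmax input must be finite")
    z = x - x.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_backward(theta: np.ndarray, grad_theta: np.ndarray) -> np.ndarray:
    """Pull a gradient w.r.t. softmax outputs back to the pre-softmax scores.

    For each row: g_eta = theta * (g_theta - <g_theta, theta>).
    """
    inner = (grad_theta * theta).sum(axis=-1, keepdims=True)
    return theta * (grad_theta - inner)


def scaling_factors(W: CountMatrix | np.ndarray) -> np.ndarray:
    """Per-cell sequencing depth s_i = total counts of cell i in this modality."""
    v = W.values if isinstance(W, CountMatrix) else np.asarray(W, dtype=np.float64)
    return v.sum(axis=1)


def gamma_mode(p: GammaParams) -> np.ndarray:
    """Mode of a shape-rate Gamma: (shape-1)/rate where shape > 1, else 0."""
    m = (p.shape - 1.0) / p.rate
    return np.where(p.shape > 1.0, m, 0.0)


def inverse_gamma_mode(p: InverseGammaParams) -> np.ndarray:
    """Mode of a shape-scale Inverse-Gamma: scale/(shape+1); always positive."""
    return p.scale / (p.shape + 1.0)


def gamma_kl(
    a: np.ndarray, b: np.ndarray, alpha: np.ndarray, beta: np.ndarray, grads: bool = False
):
    """KL( Gamma(a, b) || Gamma(alpha, beta) ) in shape-rate form, elementwise.

    The identical expression gives KL between shape-scale Inverse-Gammas,
    because x -> 1/x maps Gamma(a, rate=b) to InverseGamma(a, scale=b) and
    KL divergence is invariant under a common invertible transform.

    With ``grads=True`` also returns d/da and d/db.
    """
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    alpha, beta = np.asarray(alpha, dtype=float), np.asarray(beta, dtype=float)
    psi_a = special.digamma(a)
    kl = (
        (a - alpha) * psi_a
        - special.gammaln(a)
        + special.gammaln(alpha)
        + alpha * (np.log(b) - np.log(beta))
        + a * (beta - b) / b
    )
    if not grads:
        return kl
    d_a = (a - alpha) * special.polygamma(1, a) + beta / b - 1.0
    d_b = alpha / b - a * beta / b**2
    return kl, d_a, d_b


def gaussian_kl(
    mu: np.ndarray,
    sigma: np.ndarray,
    mu0: float | np.ndarray = 0.0,
    sigma0: float | np.ndarray = 1.0,
    grads: bool = False,
):
    """KL( N(mu, sigma^2) || N(mu0, sigma0^2) ) elementwise (diagonal case).

    With ``grads=True`` also returns d/dmu and d/dsigma.
    """
    var_ratio = (sigma / sigma0) ** 2
    kl = 0.5 * (var_ratio + ((mu - mu0) / sigma0) ** 2 - 1.0) - np.log(sigma / sigma0)
    if not grads:
        return kl
    d_mu = (mu - mu0) / np.asarray(sigma0, dtype=float) ** 2
    d_sigma = sigma / np.asarray(sigma0, dtype=float) ** 2 - 1.0 / sigma
    return kl, d_mu, d_sigma


def standard_gamma_shape_grad(a: np.ndarray, u: np.ndarray) -> np.ndarray:
    """du/da for a standard-Gamma draw u ~ Gamma(a, 1), holding the CDF level fixed.

    Implicit reparameterization: with F the regularized lower incomplete
    gamma function, du/da = -(dF/da) / pdf(u; a).  dF/da has no closed form
    and is evaluated by a central finite difference in the shape; the pdf is
    evaluated in log space.  Entries where the density underflows get a zero
    gradient rather than an overflow.
    """
    a = np.asarray(a, dtype=np.float64)
    u = np.maximum(np.asarray(u, dtype=np.float64), _U_FLOOR)
    h = 1e-4 * np.maximum(a, 1e-2)
    dF_da = (special.gammainc(a + h, u) - special.gammainc(a - h, u)) / (2.0 * h)
    log_pdf = (a - 1.0) * np.log(u) - u - special.gammaln(a)
    with np.errstate(over="ignore", under="ignore"):
        grad = -dF_da * np.exp(-log_pdf)
    return np.where(np.isfinite(grad), grad, 0.0)


class Adam:
    """Adam optimizer over a dict of named numpy arrays (gradient *ascent*)."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 0.1,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self._m = {k: np.zeros_like(v) for k, v in params.items()}
        self._v = {k: np.zeros_like(v) for k, v in params.items()}
        self._t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self._t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1**self._t
        bias2 = 1.0 - b2**self._t
        for k, g in grads.items():
            m = self._m[k] = b1 * self._m[k] + (1 - b1) * g
            v = self._v[k] = b2 * self._v[k] + (1 - b2) * g**2
            self.params[k] += self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)
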