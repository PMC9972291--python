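"""Domain types shared across the package.

The central container is :class:`CountMatrix`, a dense cells-by-features
matrix of non-negative integer counts with cell/feature identifiers and a
modality tag.  Variational-parameter containers (:class:`GammaParams`,
:class:`LogitNormalParams`, :class:`InverseGammaParams`) carry the fitted
distributions of the factor models, and the ``*Fit`` dataclasses bundle the
results of one inference run.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "CountMatrix",
    "FactorConfig",
    "GammaParams",
    "LogitNormalParams",
    "InverseGammaParams",
    "PoLNGFit",
    "IPoLNGFit",
    "SimulationTruth",
    "ClusteringResult",
]


def _as_ids(ids: Sequence[str] | None, n: int, prefix: str) -> list[str]:
    if ids is None:
        return [f"{prefix}{i}" for i in range(n)]
    out = [str(x) for x in ids]
    if len(out) != n:
        raise ValueError(f"expected {n} {prefix} identifiers, got {len(out)}")
    return out


@dataclass
class CountMatrix:
    """Cells x features non-negative integer count matrix for one modality.

    Counts are validated as integers but carried as float64 internally so
    that downstream linear algebra never re-casts.
    """

    values: np.ndarray
    cell_ids: list[str] = field(default_factory=list)
    feature_ids: list[str] = field(default_factory=list)
    modality: str = "modality"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2 or v.shape[0] < 1 or v.shape[1] < 1:
            raise ValueError("count matrix must be 2-D with at least one cell and feature")
        if not np.all(np.isfinite(v)):
            raise ValueError("count matrix contains non-finite entries")
        if np.any(v < 0):
            raise ValueError("count matrix contains negative entries")
        if not np.allclose(v, np.round(v)):
            raise ValueError("count matrix contains non-integer entries")
        self.values = np.round(v)
        self.cell_ids = _as_ids(self.cell_ids or None, v.shape[0], "cell")
        self.feature_ids = _as_ids(self.feature_ids or None, v.shape[1], "feature")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def cells_nonzero(self) -> np.ndarray:
        """Number of features with a nonzero count, per cell."""
        return np.count_nonzero(self.values, axis=1)

    def subset_cells(self, idx: np.ndarray) -> "CountMatrix":
        idx = np.asarray(idx)
        return CountMatrix(
            self.values[idx],
            [self.cell_ids[i] for i in np.atleast_1d(idx)],
            list(self.feature_ids),
            self.modality,
        )

    def subset_features(self, idx: np.ndarray) -> "CountMatrix":
        idx = np.asarray(idx)
        return CountMatrix(
            self.values[:, idx],
            list(self.cell_ids),
            [self.feature_ids[i] for i in np.atleast_1d(idx)],
            self.modality,
        )

    def copy(self) -> "CountMatrix":
        return CountMatrix(
            self.values.copy(), list(self.cell_ids), list(self.feature_ids), self.modality
        )


@dataclass
class FactorConfig:
    """Training configuration for the factor models.

    Defaults follow the published protocol: 3,000 epochs, learning rate 0.1
    with an Adam optimizer, one Monte-Carlo sample per step.
    """

    K: int
    epochs: int = 3000
    learning_rate: float = 0.1
    seed: int = 0
    mc_samples: int = 1
    #: parse of the shared-loading prior scale "alpha + 1 / K":
    #: "ratio" -> (alpha+1)/K (prior mode 1/K), "sum" -> alpha + (1/K).
    prior_beta_parse: str = "ratio"

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("number of latent factors K must be >= 1")
        if self.epochs < 1:
            raise ValueError("epochs must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if self.mc_samples < 1:
            raise ValueError("mc_samples must be >= 1")
        if self.prior_beta_parse not in ("ratio", "sum"):
            raise ValueError("prior_beta_parse must be 'ratio' or 'sum'")

    def with_(self, **kw) -> "FactorConfig":
        return replace(self, **kw)


def _check_positive(name: str, *arrays: np.ndarray) -> None:
    for a in arrays:
        if np.any(~np.isfinite(a)) or np.any(a <= 0):
            raise ValueError(f"{name} entries must be strictly positive and finite")


@dataclass
class GammaParams:
    """Shape-rate parameterization: density ∝ x^(shape-1) exp(-rate·x)."""

    shape: np.ndarray
    rate: np.ndarray

    def __post_init__(self) -> None:
        self.shape = np.asarray(self.shape, dtype=np.float64)
        self.rate = np.asarray(self.rate, dtype=np.float64)
        if self.shape.shape != self.rate.shape:
            raise ValueError("shape and rate must have identical dimensions")
        _check_positive("Gamma parameter", self.shape, self.rate)


@dataclass
class InverseGammaParams:
    """Shape-scale parameterization: density ∝ x^-(shape+1) exp(-scale/x)."""

    shape: np.ndarray
    scale: np.ndarray

    def __post_init__(self) -> None:
        self.shape = np.asarray(self.shape, dtype=np.float64)
        self.scale = np.asarray(self.scale, dtype=np.float64)
        if self.shape.shape != self.scale.shape:
            raise ValueError("shape and scale must have identical dimensions")
        _check_positive("Inverse-Gamma parameter", self.shape, self.scale)


@dataclass
class LogitNormalParams:
    """Per-factor diagonal Logit-Normal (softmax-basis Gaussian) parameters.

    ``mean`` holds the K x J Gaussian means and ``diag_var`` the diagonal of
    the per-factor covariance.  The induced simplex variable is
    softmax(row) of a Gaussian draw.
    """

    mean: np.ndarray
    diag_var: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=np.float64)
        self.diag_var = np.asarray(self.diag_var, dtype=np.float64)
        if self.mean.shape != self.diag_var.shape:
            raise ValueError("mean and diag_var must have identical dimensions")
        if np.any(~np.isfinite(self.mean)):
            raise ValueError("Logit-Normal mean must be finite")
        _check_positive("Logit-Normal variance", self.diag_var)


@dataclass
class PoLNGFit:
    """Result of fitting the single-modality model."""

    cell_loading_q: GammaParams
    theta_q: LogitNormalParams
    L_hat: np.ndarray
    Theta_hat: np.ndarray
    elbo_trace: np.ndarray
    config: FactorConfig
    modality: str = "modality"


@dataclass
class IPoLNGFit:
    """Result of fitting the joint two-modality model."""

    shared_q: InverseGammaParams
    modality_q: list[GammaParams]
    theta_q: list[LogitNormalParams]
    alpha0: tuple[float, float]
    L_hat: np.ndarray
    L_hat_m: list[np.ndarray]
    Theta_hat_m: list[np.ndarray]
    elbo_trace: np.ndarray
    config: FactorConfig
    modalities: tuple[str, str] = ("modality1", "modality2")
    polng_fits: list[PoLNGFit] | None = None


@dataclass
class SimulationTruth:
    """Ground truth of one simulated two-modality dataset."""

    labels: np.ndarray
    centers: np.ndarray
    theta_m: list[np.ndarray]
    alpha0_m: tuple[float, float]
    depths_m: list[np.ndarray]
    seed: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        self.centers = np.asarray(self.centers, dtype=np.float64)
        for th in self.theta_m:
            if not np.allclose(th.sum(axis=1), 1.0, atol=1e-10):
                raise ValueError("theta rows must sum to 1")
        if np.any(self.centers < 0):
            raise ValueError("cluster centers must be non-negative")


@dataclass
class ClusteringResult:
    """Leiden partition of a cell embedding at (approximately) a target K."""

    labels: np.ndarray
    resolution: float
    target_k: int
    n_clusters: int
    converged: bool = True
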