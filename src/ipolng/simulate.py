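"""Generative-model simulator for matched two-modality count data.

Produces paired count matrices with known cluster structure by sampling
the joint model's own generative chain: cluster-center loading rows on
the (soft) simplex, optional per-cell Gamma noise around the centers
controlled by per-modality alpha0, factor-specific feature loadings, and
per-cell sequencing depths.  Dividing the depths produces matched
datasets at increasing noise/sparsity — the dial used for the recovery
benchmarks.
"""

from __future__ import annotations

import numpy as np

from .math_core import softmax_rows
from .types import CountMatrix, SimulationTruth

__all__ = [
    "DEFAULT_CLUSTER_SIZES",
    "make_theta",
    "make_cluster_centers",
    "make_depths",
    "make_truth",
    "simulate_multiome",
    "mask_cells",
]

#: default cluster sizes: five neuronal cell types totalling 1,627 cells
DEFAULT_CLUSTER_SIZES = (403, 219, 396, 169, 440)


def make_theta(
    K: int, J: int, sparsity: float = 0.1, seed: int = 0, sigma: float = 1.0,
    boost: float = 3.0
) -> np.ndarray:
    """Random K x J feature-loading matrix with rows on the simplex.

    Rows are softmax-transformed Gaussian(0, sigma^2) scores; a fraction
    ``sparsity`` of coordinates per factor receives an additive boost
    before the softmax, creating factor-specific (marker-like) features.
    ``sparsity=0, sigma=0`` yields uniform rows.
    """
    if K < 1 or J < 1:
        raise ValueError("K and J must be >= 1")
    if not 0.0 <= sparsity < 1.0:
        raise ValueError("sparsity must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    scores = sigma * rng.standard_normal((K, J))
    n_marker = int(round(sparsity * J))
    for k in range(K):
        if n_marker:
            idx = rng.choice(J, size=n_marker, replace=False)
            scores[k, idx] += boost
    return softmax_rows(scores)


def make_cluster_centers(
    C: int, K: int, seed: int = 0, style: str = "one-hot-dominant", eps: float = 0.1
) -> np.ndarray:
    """C x K cluster-center loading rows, each summing to 1.

    ``one-hot-dominant`` puts mass 1-eps on one distinct factor per
    cluster and spreads eps over the rest; ``dirichlet`` draws rows from
    a sparse Dirichlet.
    """
    if style == "one-hot-dominant":
        if C > K:
            raise ValueError("one-hot-dominant centers require C <= K")
        centers = np.full((C, K), eps / (K - 1) if K > 1 else 0.0)
        for c in range(C):
            centers[c, c] = 1.0 - eps if K > 1 else 1.0
    elif style == "dirichlet":
        rng = np.random.default_rng(seed)
        centers = rng.dirichlet(np.full(K, 0.3), size=C)
    else:
        raise ValueError(f"unknown style {style!r}")
    return centers


def make_depths(I: int, median: float, seed: int = 0, sd_log: float = 0.3) -> np.ndarray:
    """Log-normal per-cell sequencing depths with the given median."""
    rng = np.random.default_rng(seed)
    return median * np.exp(sd_log * rng.standard_normal(I))


def make_truth(
    cluster_sizes: tuple[int, ...] = DEFAULT_CLUSTER_SIZES,
    K: int = 5,
    J_m: tuple[int, int] = (300, 500),
    alpha0_m: tuple[float, float] = (10.0, 10.0),
    depth_median_m: tuple[float, float] = (2000.0, 5000.0),
    theta_sparsity: float = 0.1,
    seed: int = 0,
) -> SimulationTruth:
    """Assemble a ground-truth configuration for :func:`simulate_multiome`.

    Defaults emulate the benchmark conditions: 5 clusters of sizes
    403/219/396/169/440 (1,627 cells), K=5 factors, RNA-like and
    epigenome-like modalities with log-normal depths of median 2,000 and
    5,000 counts per cell.
    """
    C = len(cluster_sizes)
    I = int(sum(cluster_sizes))
    labels = np.repeat(np.arange(C), cluster_sizes)
    centers = make_cluster_centers(C, K, seed=seed)
    theta_m = [
        make_theta(K, J, sparsity=theta_sparsity, seed=seed + 11 + m)
        for m, J in enumerate(J_m)
    ]
    depths_m = [
        make_depths(I, med, seed=seed + 101 + m) for m, med in enumerate(depth_median_m)
    ]
    return SimulationTruth(
        labels=labels,
        centers=centers,
        theta_m=theta_m,
        alpha0_m=tuple(float(a) for a in alpha0_m),
        depths_m=depths_m,
        seed=seed,
    )


def simulate_multiome(
    truth: SimulationTruth,
    depth_divisor_m: tuple[float, float] = (1.0, 1.0),
    hierarchical: bool = True,
) -> tuple[CountMatrix, CountMatrix, np.ndarray]:
    """Sample matched two-modality counts from the generative chain.

    For each cell i in cluster c: if ``hierarchical``, draw the modality
    loading l^(m)_ik ~ Gamma(alpha0^(m), alpha0^(m)/center_ck) — so its
    mean is the center and its variance center^2/alpha0 — otherwise use
    the center row directly.  Then draw
    w^(m)_ij ~ Poisson((depth_i/divisor_m) * sum_k l^(m)_ik theta^(m)_kj).
    Dividing the depth shrinks total counts and raises sparsity/noise.
    """
    for d in depth_divisor_m:
        if d <= 0:
            raise ValueError("depth divisors must be positive")
    rng = np.random.default_rng(truth.seed)
    labels = truth.labels
    I = labels.size
    mats = []
    names = ("RNA", "epigenome")
    for m, theta in enumerate(truth.theta_m):
        centers_per_cell = truth.centers[labels]  # (I, K)
        if hierarchical:
            a0 = truth.alpha0_m[m]
            l_m = rng.gamma(shape=a0, scale=centers_per_cell / a0)
        else:
            l_m = centers_per_cell
        depth = truth.depths_m[m] / depth_divisor_m[m]
        rates = (l_m @ theta) * depth[:, None]
        W = rng.poisson(rates).astype(np.float64)
        mats.append(
            CountMatrix(
                W,
                [f"cell{i}" for i in range(I)],
                [f"{names[m]}_feat{j}" for j in range(theta.shape[1])],
                modality=names[m],
            )
        )
    return mats[0], mats[1], labels.copy()


def mask_cells(
    W2: CountMatrix, fraction: float, seed: int = 0
) -> tuple[CountMatrix, np.ndarray]:
    """Zero out a uniformly random fraction of cells in one modality.

    Returns the masked matrix and the sorted masked cell indices
    (round-to-nearest count of cells).
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    n_mask = int(round(fraction * W2.n_cells))
    idx = np.sort(rng.choice(W2.n_cells, size=n_mask, replace=False))
    out = W2.copy()
    out.values[idx] = 0.0
    return out, idx
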