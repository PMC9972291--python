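"""Clustering of cell embeddings and clustering-quality metrics.

Leiden community detection on a k-nearest-neighbor graph of the embedding,
with a binary search over the resolution parameter to hit a requested
number of clusters; the adjusted Rand index against reference labels; and
the residual average Gini index (RAGI), which contrasts how concentrated
marker-gene expression is across clusters with how flat housekeeping-gene
expression is.
"""

from __future__ import annotations

import warnings

import igraph as ig
import leidenalg
import numpy as np
from sklearn.metrics import adjusted_rand_score
from sklearn.neighbors import NearestNeighbors

from .types import ClusteringResult, CountMatrix

__all__ = [
    "knn_graph",
    "leiden_cluster_to_k",
    "adjusted_rand_index",
    "gini_index",
    "ragi_score",
]


def knn_graph(embedding: np.ndarray, knn: int = 20) -> ig.Graph:
    """Undirected unweighted k-nearest-neighbor graph (Euclidean)."""
    X = np.asarray(embedding, dtype=float)
    n = X.shape[0]
    k = min(knn, n - 1)
    nbrs = NearestNeighbors(n_neighbors=k + 1).fit(X)
    idx = nbrs.kneighbors(X, return_distance=False)[:, 1:]  # drop self
    edges = {(min(i, j), max(i, j)) for i in range(n) for j in idx[i]}
    return ig.Graph(n=n, edges=sorted(edges))


def _leiden_at(graph: ig.Graph, resolution: float, seed: int) -> np.ndarray:
    part = leidenalg.find_partition(
        graph,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=2,
    )
    return np.asarray(part.membership)


def leiden_cluster_to_k(
    embedding: np.ndarray,
    target_k: int,
    seed: int = 0,
    knn: int = 20,
    resolution_bounds: tuple[float, float] = (1e-4, 10.0),
    max_iter: int = 30,
) -> ClusteringResult:
    """Leiden clustering tuned to a target number of clusters.

    Binary search on the resolution parameter (geometric midpoints over
    ``resolution_bounds``, at most ``max_iter`` probes), exploiting that
    the achieved cluster count grows with resolution.  The count is not
    strictly monotone, so if the target is never hit exactly the closest
    achieved partition over all probes is returned with ``converged=False``
    and a warning.
    """
    X = np.asarray(embedding, dtype=float)
    n = X.shape[0]
    if target_k < 2:
        raise ValueError("target_k must be >= 2")
    if target_k >= n:
        raise ValueError("target_k must be smaller than the number of cells")
    graph = knn_graph(X, knn=knn)

    lo, hi = resolution_bounds
    best: tuple[int, np.ndarray, float] | None = None
    for _ in range(max_iter):
        res = float(np.sqrt(lo * hi))
        labels = _leiden_at(graph, res, seed)
        k = labels.max() + 1
        if best is None or abs(k - target_k) < abs(best[0] - target_k):
            best = (k, labels, res)
        if k == target_k:
            return ClusteringResult(labels, res, target_k, int(k), converged=True)
        if k < target_k:
            lo = res
        else:
            hi = res
    k, labels, res = best
    warnings.warn(
        f"binary search did not reach exactly {target_k} clusters; "
        f"returning the closest achieved count {k}",
        stacklevel=2,
    )
    return ClusteringResult(labels, res, target_k, int(k), converged=False)


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Chance-corrected agreement of two partitions (permutation model)."""
    a = np.asarray(labels_a).ravel()
    b = np.asarray(labels_b).ravel()
    if a.size != b.size:
        raise ValueError("labelings must have equal length")
    return float(adjusted_rand_score(a, b))


def gini_index(x) -> float:
    """Gini coefficient of a non-negative vector, in [0, 1).

    With x sorted ascending, G = sum_i (2i - n - 1) x_i / (n sum_i x_i)
    (i is 1-based).  An all-zero vector returns 0 by convention.
    """
    v = np.sort(np.asarray(x, dtype=float).ravel())
    if np.any(v < 0):
        raise ValueError("gini_index requires non-negative entries")
    n = v.size
    total = v.sum()
    if total == 0:
        return 0.0
    i = np.arange(1, n + 1)
    return float(((2 * i - n - 1) * v).sum() / (n * total))


def _log_normalize(values: np.ndarray, scale: float = 1e4) -> np.ndarray:
    depth = values.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        norm = np.where(depth > 0, values / depth * scale, 0.0)
    return np.log1p(norm)


def _resolve_genes(feature_ids: list[str], genes, list_name: str) -> list[int]:
    lut = {g: j for j, g in enumerate(feature_ids)}
    idx = [lut[g] for g in genes if g in lut]
    missing = [g for g in genes if g not in lut]
    if missing:
        warnings.warn(
            f"{len(missing)} {list_name} gene(s) not found and dropped: "
            + ", ".join(missing[:5]),
            stacklevel=3,
        )
    if not idx:
        raise ValueError(f"no {list_name} genes resolvable against the feature identifiers")
    return idx


def ragi_score(
    expr: CountMatrix,
    labels,
    marker_genes,
    housekeeping_genes,
    scale: float = 1e4,
) -> float:
    """Residual average Gini index of a clustering.

    Counts are log-normalized (per-cell scaling to ``scale`` total, then
    log1p); for each gene the vector of per-cluster mean expressions is
    reduced to its Gini coefficient.  RAGI is the mean Gini over marker
    genes minus the mean over housekeeping genes: high when markers are
    concentrated in few clusters while housekeeping expression stays flat.
    """
    labels = np.asarray(labels).ravel()
    if labels.size != expr.n_cells:
        raise ValueError("labels length must equal the number of cells")
    m_idx = _resolve_genes(expr.feature_ids, marker_genes, "marker")
    h_idx = _resolve_genes(expr.feature_ids, housekeeping_genes, "housekeeping")
    X = _log_normalize(expr.values, scale)
    clusters = np.unique(labels)
    cluster_means = np.vstack([X[labels == c].mean(axis=0) for c in clusters])  # C x J
    gini_m = [gini_index(cluster_means[:, j]) for j in m_idx]
    gini_h = [gini_index(cluster_means[:, j]) for j in h_idx]
    return float(np.mean(gini_m) - np.mean(gini_h))
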