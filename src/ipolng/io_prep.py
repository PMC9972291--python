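"""Count-matrix I/O, preprocessing, and the end-to-end pipeline.

Readers accept 10x-style MatrixMarket triples (matrix.mtx[.gz] +
features.tsv[.gz] + barcodes.tsv[.gz], features-by-cells orientation) and
dense delimited text.  Preprocessing follows the standard single-cell
protocol: drop low-quality cells by per-modality nonzero-feature
thresholds, then select highly variable features by a vst-style
standardized variance computed on raw counts (log-normalization enters
only the selection, never the modeled counts).
"""

from __future__ import annotations

import gzip
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse
from statsmodels.nonparametric.smoothers_lowess import lowess

from .evaluate import leiden_cluster_to_k
from .joint import fit_ipolng
from .polng import fit_polng
from .types import ClusteringResult, CountMatrix, FactorConfig, IPoLNGFit, PoLNGFit

__all__ = [
    "PreprocessConfig",
    "read_count_matrix",
    "write_count_matrix",
    "filter_cells",
    "select_hvg",
    "run_pipeline",
    "save_ipolng_fit",
    "save_polng_fit",
]


@dataclass
class PreprocessConfig:
    """Cell-filtering and feature-selection thresholds.

    Defaults follow the common multiome protocol: keep cells expressing
    at least 500 genes and at least 200 epigenomic regions; keep the top
    5,000 variable genes and 20,000 variable regions; the selection's
    log-normalization uses a scale factor of 10,000.
    """

    min_genes_rna: int = 500
    min_regions_epi: int = 200
    n_hvg_rna: int = 5000
    n_hvg_epi: int = 20000
    norm_scale: float = 10000.0

    def __post_init__(self) -> None:
        for name, v in asdict(self).items():
            if v <= 0:
                raise ValueError(f"{name} must be positive")


def _open_maybe_gz(path: Path):
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def _find(dirpath: Path, stem: str) -> Path:
    for cand in (dirpath / stem, dirpath / f"{stem}.gz"):
        if cand.exists():
            return cand
    raise FileNotFoundError(f"missing {stem}[.gz] in {dirpath}")


def _read_ids(path: Path) -> list[str]:
    with _open_maybe_gz(path) as fh:
        return [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]


def read_count_matrix(
    path: str | Path,
    fmt: str = "auto",
    modality: str = "modality",
    orientation: str = "features-by-cells",
) -> CountMatrix:
    """Read counts from an MTX directory or a dense delimited file.

    MTX directories follow the 10x layout (matrix.mtx[.gz],
    features.tsv[.gz], barcodes.tsv[.gz]); the default orientation is the
    10x convention features-by-cells and is transposed to cells-by-features
    internally (1-based MTX coordinates are handled by the reader).  Dense
    files are cells-by-features with cell identifiers in the first column
    and feature identifiers in the header.
    """
    path = Path(path)
    if fmt == "auto":
        fmt = "mtx" if path.is_dir() else "dense"
    if fmt == "mtx":
        mtx_path = None
        for stem in ("matrix.mtx", "matrix.mtx.gz"):
            if (path / stem).exists():
                mtx_path = path / stem
                break
        if mtx_path is None:
            raise FileNotFoundError(f"no matrix.mtx[.gz] in {path}")
        if mtx_path.suffix == ".gz":
            with gzip.open(mtx_path, "rb") as fh:
                M = spio.mmread(fh)
        else:
            M = spio.mmread(mtx_path)
        M = sparse.coo_matrix(M).toarray()
        features = _read_ids(_find(path, "features.tsv"))
        barcodes = _read_ids(_find(path, "barcodes.tsv"))
        if orientation == "features-by-cells":
            M = M.T
        elif orientation != "cells-by-features":
            raise ValueError(f"unknown orientation {orientation!r}")
        if M.shape != (len(barcodes), len(features)):
            raise ValueError(
                f"matrix shape {M.shape} does not match {len(barcodes)} barcodes "
                f"x {len(features)} features"
            )
        return CountMatrix(M, barcodes, features, modality)
    if fmt == "dense":
        sep = "," if path.suffix.lower() == ".csv" else "\t"
        df = pd.read_csv(path, sep=sep, index_col=0)
        return CountMatrix(
            df.to_numpy(dtype=float),
            [str(x) for x in df.index],
            [str(x) for x in df.columns],
            modality,
        )
    raise ValueError(f"unknown format {fmt!r}")


def write_count_matrix(W: CountMatrix, path: str | Path, fmt: str = "mtx") -> None:
    """Write counts as an MTX directory (10x orientation) or dense TSV."""
    path = Path(path)
    if fmt == "mtx":
        path.mkdir(parents=True, exist_ok=True)
        spio.mmwrite(path / "matrix.mtx", sparse.csr_matrix(W.values.T.astype(int)))
        (path / "features.tsv").write_text("\n".join(W.feature_ids) + "\n")
        (path / "barcodes.tsv").write_text("\n".join(W.cell_ids) + "\n")
    elif fmt == "dense":
        df = pd.DataFrame(W.values.astype(int), index=W.cell_ids, columns=W.feature_ids)
        df.to_csv(path, sep="\t")
    else:
        raise ValueError(f"unknown format {fmt!r}")


def filter_cells(
    W_rna: CountMatrix, W_epi: CountMatrix, cfg: PreprocessConfig | None = None
) -> tuple[CountMatrix, CountMatrix, np.ndarray]:
    """Remove low-quality cells jointly across the two modalities.

    A cell survives iff it has nonzero counts in at least
    ``min_genes_rna`` genes AND at least ``min_regions_epi`` regions; both
    matrices are subset to the same surviving cells in input order.
    """
    cfg = cfg or PreprocessConfig()
    if W_rna.n_cells != W_epi.n_cells:
        raise ValueError("modalities must cover the same cells")
    keep = (W_rna.cells_nonzero() >= cfg.min_genes_rna) & (
        W_epi.cells_nonzero() >= cfg.min_regions_epi
    )
    idx = np.flatnonzero(keep)
    if idx.size == 0:
        raise ValueError("no cells survive the quality filters")
    return W_rna.subset_cells(idx), W_epi.subset_cells(idx), idx


def _vst_standardized_variance(values: np.ndarray, span: float = 0.3) -> np.ndarray:
    """Per-feature standardized variance, vst-style.

    Raw-count mean and variance per feature; a lowess smooth of
    log10(variance) on log10(mean) predicts each feature's expected
    standard deviation; counts are standardized by it, clipped at
    sqrt(n_cells), and the variance of the clipped values is the ranking
    statistic.  Features with zero variance score 0.
    """
    I = values.shape[0]
    mean = values.mean(axis=0)
    var = values.var(axis=0, ddof=1) if I > 1 else np.zeros(values.shape[1])
    out = np.zeros(values.shape[1])
    ok = (var > 0) & (mean > 0)
    if not np.any(ok):
        return out
    lx, ly = np.log10(mean[ok]), np.log10(var[ok])
    if np.unique(lx).size < 3:
        fitted = ly
    else:
        fitted = lowess(ly, lx, frac=span, return_sorted=False)
    exp_sd = np.sqrt(10.0**fitted)
    z = (values[:, ok] - mean[ok]) / exp_sd
    np.clip(z, None, np.sqrt(I), out=z)
    out[ok] = z.var(axis=0, ddof=1)
    return out


def select_hvg(
    W: CountMatrix, n_top: int, norm_scale: float = 10000.0, span: float = 0.3
) -> tuple[CountMatrix, np.ndarray]:
    """Keep the ``n_top`` most variable features by vst-style ranking.

    Returns the RAW counts of the selected features (normalization is used
    for ranking only) and the selected column indices; the surviving
    features keep their input order.
    """
    if n_top > W.n_features:
        raise ValueError(f"n_top={n_top} exceeds the {W.n_features} available features")
    std_var = _vst_standardized_variance(W.values, span=span)
    order = np.argsort(-std_var, kind="stable")[:n_top]
    idx = np.sort(order)
    return W.subset_features(idx), idx


def save_polng_fit(fit: PoLNGFit, out_dir: str | Path) -> None:
    """Write a single-modality fit: TSV point estimates + JSON archive."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _write_tsv(out / "L_hat.tsv", fit.L_hat, "factor")
    _write_tsv(out / "Theta_hat.tsv", fit.Theta_hat.T, "factor")
    archive = {
        "config": asdict(fit.config),
        "modality": fit.modality,
        "elbo_trace": fit.elbo_trace.tolist(),
        "gamma_shape": fit.cell_loading_q.shape.tolist(),
        "gamma_rate": fit.cell_loading_q.rate.tolist(),
        "theta_mean": fit.theta_q.mean.tolist(),
        "theta_diag_var": fit.theta_q.diag_var.tolist(),
    }
    (out / "fit.json").write_text(json.dumps(archive))


def _write_tsv(path: Path, mat: np.ndarray, colprefix: str) -> None:
    df = pd.DataFrame(mat, columns=[f"{colprefix}{k}" for k in range(mat.shape[1])])
    df.to_csv(path, sep="\t", index=False, float_format="%.8g")


def save_ipolng_fit(fit: IPoLNGFit, out_dir: str | Path) -> None:
    """Write a joint fit: per-matrix TSVs, alpha0.json, elbo.tsv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    names = ("rna", "epi")
    _write_tsv(out / "L_hat.tsv", fit.L_hat, "factor")
    for m in range(2):
        _write_tsv(out / f"L_hat_{names[m]}.tsv", fit.L_hat_m[m], "factor")
        _write_tsv(out / f"Theta_{names[m]}.tsv", fit.Theta_hat_m[m].T, "factor")
    (out / "alpha0.json").write_text(
        json.dumps({"alpha0_rna": fit.alpha0[0], "alpha0_epi": fit.alpha0[1]})
    )
    pd.DataFrame({"epoch": np.arange(fit.elbo_trace.size), "elbo": fit.elbo_trace}).to_csv(
        out / "elbo.tsv", sep="\t", index=False
    )


def run_pipeline(
    rna_path: str | Path,
    epi_path: str | Path | None,
    prep_cfg: PreprocessConfig,
    fit_cfg: FactorConfig,
    target_k: int | None = None,
    out_dir: str | Path | None = None,
    polng_epochs: int | None = None,
) -> tuple[IPoLNGFit | PoLNGFit, ClusteringResult | None]:
    """End-to-end run: read, filter, select features, fit, cluster.

    With ``epi_path=None`` the single-modality branch runs instead (read,
    feature selection, PoLNG).  ``target_k`` enables Leiden clustering of
    the fitted embedding; outputs are written under ``out_dir`` when
    given.  All randomness flows from ``fit_cfg.seed``.
    """
    W_rna = read_count_matrix(rna_path, modality="RNA")
    if epi_path is not None:
        W_epi = read_count_matrix(epi_path, modality="epigenome")
        W_rna, W_epi, _ = filter_cells(W_rna, W_epi, prep_cfg)
        W_rna, _ = select_hvg(
            W_rna, min(prep_cfg.n_hvg_rna, W_rna.n_features), prep_cfg.norm_scale
        )
        W_epi, _ = select_hvg(
            W_epi, min(prep_cfg.n_hvg_epi, W_epi.n_features), prep_cfg.norm_scale
        )
        fit = fit_ipolng(W_rna, W_epi, fit_cfg, polng_epochs=polng_epochs)
        embedding = fit.L_hat
    else:
        W_rna, _ = select_hvg(
            W_rna, min(prep_cfg.n_hvg_rna, W_rna.n_features), prep_cfg.norm_scale
        )
        fit = fit_polng(W_rna, fit_cfg)
        embedding = fit.L_hat

    clustering = None
    if target_k is not None:
        clustering = leiden_cluster_to_k(embedding, target_k, seed=fit_cfg.seed)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        if isinstance(fit, IPoLNGFit):
            save_ipolng_fit(fit, out)
        else:
            save_polng_fit(fit, out)
        if clustering is not None:
            pd.DataFrame({"cell": W_rna.cell_ids, "cluster": clustering.labels}).to_csv(
                out / "clusters.tsv", sep="\t", index=False
            )
            (out / "metrics.json").write_text(
                json.dumps(
                    {
                        "n_clusters": int(clustering.n_clusters),
                        "resolution": clustering.resolution,
                        "target_k": clustering.target_k,
                        "converged": clustering.converged,
                    }
                )
            )
    return fit, clustering
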