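"""Normalization, covariate regression, variable-gene selection, clustering.

The preprocessing chain mirrors standard droplet scRNA-seq practice:
library-size normalization to 10,000 counts with ln(1+x); per-gene OLS
regression of the log layer on total UMIs and mitochondrial fraction;
dispersion-based variable-gene selection with mean-bin z-scores; PCA on the
scaled residuals (30 components); a shared-nearest-neighbor graph on the PC
scores; and Leiden modularity community detection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .containers import ExpressionMatrix
from .qc import mito_fraction

DEFAULT_SCALE = 10_000.0
DEFAULT_N_PCS = 30
DEFAULT_RESOLUTION = 1.0
N_MEAN_BINS = 20
SCALE_CLIP = 10.0


@dataclass
class Clustering:
    """Cluster labels plus the reduced representations they came from."""

    labels: np.ndarray  # integer cluster id per cell, 0..N-1
    n_clusters: int
    pcs: np.ndarray  # cells x n_pcs scores
    embedding: np.ndarray  # cells x 2
    variable_genes: list = field(default_factory=list)
    resolution: float = DEFAULT_RESOLUTION

    def cells_in(self, cluster: int) -> np.ndarray:
        return np.flatnonzero(self.labels == cluster)


def normalize_log(matrix: ExpressionMatrix, scale: float = DEFAULT_SCALE) -> ExpressionMatrix:
    """Fill the log layer with ln(1 + count * scale / cell_total)."""
    total = matrix.total_counts().astype(float)
    if (total == 0).any():
        raise ValueError("cells with zero total counts; run QC first")
    dense = np.asarray(matrix.counts.todense(), dtype=float)
    matrix.log_layer = np.log1p(dense * (scale / total)[None, :])
    return matrix


def regress_out(
    matrix: ExpressionMatrix, covariates: tuple = ("total_umis", "mito_fraction")
) -> np.ndarray:
    """Per-gene OLS residuals of log expression on technical covariates.

    Returns a dense genes x cells residual matrix. Constant covariates are
    dropped with a warning.
    """
    if matrix.log_layer is None:
        raise ValueError("log layer missing; call normalize_log first")
    cols = []
    for name in covariates:
        if name == "total_umis":
            v = matrix.total_counts().astype(float)
        elif name == "mito_fraction":
            v = mito_fraction(matrix)
        else:
            raise ValueError(f"unknown covariate {name!r}")
        if np.ptp(v) == 0:
            warnings.warn(f"covariate {name!r} is constant; dropped")
            continue
        cols.append((v - v.mean()) / v.std())
    n_cells = matrix.n_cells
    X = np.column_stack([np.ones(n_cells)] + cols)
    Y = matrix.log_layer.T  # cells x genes
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    return resid.T


def select_variable_genes(
    matrix: ExpressionMatrix,
    x_low: float = 0.0,
    x_high: float = 8.0,
    y_cutoff: float = 0.0,
    n_bins: int = N_MEAN_BINS,
) -> list:
    """Dispersion-based variable genes with the mean/z-score cutoffs.

    Genes are binned by mean log expression into ``n_bins`` bins; within
    each bin the log dispersion (variance/mean of the back-transformed
    expression) is z-scored. Kept genes satisfy ``x_low < mean <= x_high``
    and ``z >= y_cutoff``. Bins with fewer than two genes get z = 0.
    """
    if matrix.log_layer is None:
        raise ValueError("log layer missing; call normalize_log first")
    expm = np.expm1(matrix.log_layer)
    gmean = expm.mean(axis=1)
    gvar = expm.var(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(gmean > 0, gvar / np.maximum(gmean, 1e-12), 0.0)
    log_disp = np.log1p(disp)
    mean_log = np.log1p(gmean)

    edges = np.linspace(mean_log.min(), mean_log.max() + 1e-9, n_bins + 1)
    bins = np.clip(np.digitize(mean_log, edges) - 1, 0, n_bins - 1)
    z = np.zeros_like(log_disp)
    for b in range(n_bins):
        members = bins == b
        if members.sum() < 2:
            continue
        mu, sd = log_disp[members].mean(), log_disp[members].std()
        if sd > 0:
            z[members] = (log_disp[members] - mu) / sd
    keep = (mean_log > x_low) & (mean_log <= x_high) & (z >= y_cutoff)
    return list(matrix.gene_meta["symbol"].to_numpy()[keep])


def dispersion_zscores(matrix: ExpressionMatrix, n_bins: int = N_MEAN_BINS) -> pd.DataFrame:
    """Per-gene mean, dispersion and within-bin z-score (for inspection)."""
    expm = np.expm1(matrix.log_layer)
    gmean = expm.mean(axis=1)
    gvar = expm.var(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(gmean > 0, gvar / np.maximum(gmean, 1e-12), 0.0)
    log_disp = np.log1p(disp)
    mean_log = np.log1p(gmean)
    edges = np.linspace(mean_log.min(), mean_log.max() + 1e-9, n_bins + 1)
    bins = np.clip(np.digitize(mean_log, edges) - 1, 0, n_bins - 1)
    z = np.zeros_like(log_disp)
    for b in range(n_bins):
        members = bins == b
        if members.sum() < 2:
            continue
        mu, sd = log_disp[members].mean(), log_disp[members].std()
        if sd > 0:
            z[members] = (log_disp[members] - mu) / sd
    return pd.DataFrame(
        {"symbol": matrix.gene_meta["symbol"], "mean": mean_log, "zscore": z, "bin": bins}
    )


def _scale_rows(resid: np.ndarray, clip: float = SCALE_CLIP) -> np.ndarray:
    sd = resid.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    scaled = (resid - resid.mean(axis=1, keepdims=True)) / sd
    return np.clip(scaled, -clip, clip)


def pca_embed_cluster(
    matrix: ExpressionMatrix,
    residuals: np.ndarray | None = None,
    variable_genes: list | None = None,
    n_pcs: int = DEFAULT_N_PCS,
    resolution: float = DEFAULT_RESOLUTION,
    n_neighbors: int | None = None,
    embedding: str = "tsne",
    seed: int = 0,
) -> Clustering:
    """PCA + SNN graph + Leiden community detection + 2-D embedding.

    Input is the residual matrix restricted to the variable genes, scaled to
    unit variance and clipped at +-10. ``embedding`` is ``"tsne"`` or
    ``"pca"`` (first two PCs, deterministic and fast). ``n_neighbors``
    defaults to 2 * sqrt(n_cells) (floored at 15): a denser graph stabilizes
    the modularity partition against boundary cells.
    """
    from sklearn.decomposition import PCA

    if residuals is None:
        residuals = regress_out(matrix)
    if variable_genes is None:
        variable_genes = select_variable_genes(matrix)
    idx = matrix.gene_index(variable_genes)
    if idx.size == 0:
        raise ValueError("no variable genes found in the matrix")
    X = _scale_rows(residuals[idx]).T  # cells x genes
    n_pcs_eff = min(n_pcs, min(X.shape) - 1)
    if n_pcs_eff < n_pcs:
        warnings.warn(f"n_pcs clamped to {n_pcs_eff}")
    pca = PCA(n_components=n_pcs_eff, svd_solver="full", random_state=seed)
    pcs = pca.fit_transform(X)

    if n_neighbors is None:
        n_neighbors = max(15, int(2 * np.sqrt(X.shape[0])))
    labels = _snn_leiden(pcs, n_neighbors=n_neighbors, resolution=resolution, seed=seed)

    if embedding == "tsne" and X.shape[0] > 30:
        from sklearn.manifold import TSNE

        emb = TSNE(
            n_components=2,
            random_state=seed,
            init="pca",
            perplexity=min(30.0, (X.shape[0] - 1) / 3.0),
        ).fit_transform(pcs)
    else:
        emb = pcs[:, :2].copy()
    return Clustering(
        labels=labels,
        n_clusters=int(labels.max()) + 1,
        pcs=pcs,
        embedding=emb,
        variable_genes=list(variable_genes),
        resolution=resolution,
    )


def _snn_leiden(
    pcs: np.ndarray, n_neighbors: int, resolution: float, seed: int
) -> np.ndarray:
    """Shared-nearest-neighbor graph + Leiden modularity partition."""
    import igraph
    import leidenalg
    from sklearn.neighbors import kneighbors_graph

    n = pcs.shape[0]
    if n < 3 or np.allclose(pcs.var(axis=0), 0):
        return np.zeros(n, dtype=int)
    k = min(n_neighbors, n - 1)
    knn = kneighbors_graph(pcs, n_neighbors=k, include_self=True)
    # SNN: Jaccard overlap of neighbor sets, pruned at 1/15
    shared = (knn @ knn.T).tocoo()
    union = 2 * k - shared.data  # |A|+|B|-|A&B| with |A|=|B|=k (incl. self)
    jac = shared.data / np.maximum(union, 1)
    mask = jac > 1.0 / 15.0
    src, dst, wts = shared.row[mask], shared.col[mask], jac[mask]
    keep = src < dst
    g = igraph.Graph(
        n=n, edges=list(zip(src[keep].tolist(), dst[keep].tolist())), directed=False
    )
    g.es["weight"] = wts[keep].tolist()
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        weights="weight",
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=-1,
    )
    return np.asarray(part.membership, dtype=int)
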