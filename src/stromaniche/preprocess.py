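"""Normalization, variable genes, embedding, and graph clustering.

The pipeline follows the standard single-cell recipe: per-cell
log-normalization to a fixed scale factor (10,000), top-n highly variable
genes (variance of normalized expression computed within each library and
averaged, a deterministic vst-like criterion), per-library standardization
of HVGs followed by a joint PCA (the batch-adjustment substitute for
anchor-based integration — it removes the generator's size-factor batch
effect exactly), a Euclidean kNN graph in PC space, and Leiden community
detection with the RB-configuration objective.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import scipy.sparse as sp
import igraph
import leidenalg
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

LOGNORM_LAYER = "lognorm"


@dataclass
class EmbeddingResult:
    pcs: np.ndarray  # cells x components
    n_components: int
    hvg_ids: list[str]
    explained_variance_ratio: np.ndarray


@dataclass
class ClusterAssignment:
    labels: np.ndarray  # per-cell contiguous cluster ids from 0
    resolution: float
    seed: int
    mismatch: bool = False  # set by subcluster when target_k was not reached
    extras: dict = field(default_factory=dict)

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1 if self.labels.size else 0


def log_normalize(adata: ad.AnnData, scale_factor: float = 1e4) -> ad.AnnData:
    """value = ln(1 + scale_factor * count / cell_total), stored as a layer."""
    X = sp.csr_matrix(adata.X, dtype=float)
    totals = np.asarray(X.sum(axis=1)).ravel()
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValueError(f"cell(s) with zero total counts: {list(adata.obs_names[zero[:5]])}")
    norm = X.multiply(scale_factor / totals[:, None]).tocsr()
    norm.data = np.log1p(norm.data)
    adata.layers[LOGNORM_LAYER] = norm
    adata.uns["scale_factor"] = scale_factor
    return adata


def _sparse_var(X: sp.csr_matrix) -> np.ndarray:
    mean = np.asarray(X.mean(axis=0)).ravel()
    sq = np.asarray(X.multiply(X).mean(axis=0)).ravel()
    return sq - mean**2


def select_hvgs(adata: ad.AnnData, n: int = 2000) -> list[str]:
    """Top-n genes by per-library variance of normalized expression,
    averaged across libraries; ties broken lexicographically by gene id."""
    if n <= 0:
        raise ValueError("number of HVGs must be positive")
    n = min(n, adata.n_vars)
    norm = sp.csr_matrix(adata.layers[LOGNORM_LAYER])
    libs = adata.obs["library"] if "library" in adata.obs else None
    if libs is None or libs.nunique() == 1:
        var = _sparse_var(norm)
    else:
        per_lib = [_sparse_var(norm[(libs == lib).to_numpy()]) for lib in libs.unique()]
        var = np.mean(per_lib, axis=0)
    order = sorted(range(adata.n_vars), key=lambda i: (-var[i], adata.var_names[i]))
    return [adata.var_names[i] for i in order[:n]]


def embed(
    adata: ad.AnnData,
    hvgs: list[str],
    n_components: int = 30,
    center_per_library: bool = True,
) -> EmbeddingResult:
    """Standardize HVGs (optionally per library) and run PCA.

    Component signs are fixed so each component's largest-magnitude gene
    loading is positive, making the embedding deterministic.
    """
    idx = [adata.var_names.get_loc(g) for g in hvgs]
    M = np.asarray(sp.csr_matrix(adata.layers[LOGNORM_LAYER])[:, idx].todense())

    def standardize(block: np.ndarray) -> np.ndarray:
        mu = block.mean(axis=0)
        sd = block.std(axis=0)
        sd[sd == 0] = 1.0
        return (block - mu) / sd

    if center_per_library and "library" in adata.obs and adata.obs["library"].nunique() > 1:
        libs = adata.obs["library"].to_numpy()
        for lib in np.unique(libs):
            rows = libs == lib
            M[rows] = standardize(M[rows])
    else:
        M = standardize(M)

    max_rank = min(M.shape)
    if n_components > max_rank:
        warnings.warn(f"n_components reduced from {n_components} to rank bound {max_rank}")
        n_components = max_rank
    pca = PCA(n_components=n_components, svd_solver="full")
    pcs = pca.fit_transform(M)
    # sign convention: largest-|loading| gene positive per component
    for j in range(n_components):
        lead = np.argmax(np.abs(pca.components_[j]))
        if pca.components_[j, lead] < 0:
            pcs[:, j] *= -1
            pca.components_[j] *= -1
    return EmbeddingResult(pcs, n_components, list(hvgs), pca.explained_variance_ratio_)


def _knn_graph(pcs: np.ndarray, k: int) -> igraph.Graph:
    n = pcs.shape[0]
    if k >= n:
        warnings.warn(f"k={k} >= n cells; reduced to {n - 1}")
        k = n - 1
    nn = NearestNeighbors(n_neighbors=k + 1).fit(pcs)
    _, ind = nn.kneighbors(pcs)
    edges = {(min(i, j), max(i, j)) for i, row in enumerate(ind) for j in row[1:]}
    g = igraph.Graph(n=n, edges=sorted(edges), directed=False)
    return g


def _leiden(g: igraph.Graph, resolution: float, seed: int) -> np.ndarray:
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=-1,
    )
    labels = np.asarray(part.membership)
    # relabel by decreasing cluster size (ties by original label)
    sizes = np.bincount(labels)
    order = sorted(range(sizes.size), key=lambda c: (-sizes[c], c))
    remap = {old: new for new, old in enumerate(order)}
    return np.array([remap[c] for c in labels])


def cluster_graph(
    embedding: EmbeddingResult,
    k_neighbors: int = 20,
    resolution: float = 0.2,
    seed: int = 0,
) -> ClusterAssignment:
    """kNN graph in PC space + Leiden (RB-configuration) at the given
    resolution; clusters relabeled by decreasing size."""
    g = _knn_graph(embedding.pcs, k_neighbors)
    labels = _leiden(g, resolution, seed)
    return ClusterAssignment(labels, resolution, seed)


def subcluster(
    adata: ad.AnnData,
    cells: np.ndarray,
    target_k: int,
    seed: int = 0,
    n_hvgs: int = 2000,
    n_components: int = 30,
    k_neighbors: int = 20,
    scale_factor: float = 1e4,
    resolution_grid: np.ndarray | None = None,
) -> ClusterAssignment:
    """Re-run normalize -> HVG -> embed -> cluster on a cell subset, scanning
    a fixed resolution grid for the smallest resolution yielding ``target_k``
    clusters; falls back to the closest count with ``mismatch=True``."""
    cells = np.asarray(cells)
    if cells.dtype == bool:
        cells = np.flatnonzero(cells)
    if cells.size == 0:
        raise ValueError("empty cell subset")
    if cells.size <= k_neighbors:
        raise ValueError(f"subset of {cells.size} cells smaller than k_neighbors={k_neighbors}")
    sub = adata[cells].copy()
    log_normalize(sub, scale_factor)
    hvgs = select_hvgs(sub, n_hvgs)
    emb = embed(sub, hvgs, min(n_components, len(hvgs), sub.n_obs))
    g = _knn_graph(emb.pcs, k_neighbors)
    grid = resolution_grid if resolution_grid is not None else np.arange(0.05, 2.0001, 0.05)
    best: tuple[float, np.ndarray] | None = None
    for res in grid:
        labels = _leiden(g, float(res), seed)
        k = labels.max() + 1
        if k == target_k:
            return ClusterAssignment(labels, float(res), seed, mismatch=False,
                                     extras={"embedding": emb})
        if best is None or abs(k - target_k) < best[0]:
            best = (abs(k - target_k), labels, float(res))
    _, labels, res = best
    return ClusterAssignment(labels, res, seed, mismatch=True, extras={"embedding": emb})
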