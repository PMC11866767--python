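"""Rooted pseudotime over a cluster-centroid minimum spanning tree.

A complete Euclidean graph over cluster centroids in PC space is reduced to
its MST; each cell is projected orthogonally onto its nearest tree edge and
its pseudotime is the geodesic distance along the tree from the root
centroid to the projection, shifted so the root cluster's minimum is zero.

This delivers the outputs downstream analyses use — a rooted per-cell
ordering and branch structure — as a deterministic substitute for a learned
principal graph; the claims it supports are ordinal (which direction
differentiation runs), not metric.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.csgraph as csgraph

from stromaniche.preprocess import ClusterAssignment, EmbeddingResult


@dataclass
class TrajectoryResult:
    root: int
    edges: list[tuple[int, int]]  # MST edges over cluster ids
    pseudotime: np.ndarray  # per cell, >= 0
    cell_edge: list[tuple[int, int]]  # per cell: assigned tree edge
    centroids: np.ndarray


def _project_to_segment(p: np.ndarray, a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """(distance to segment, arc-position t in [0,1] from a)."""
    ab = b - a
    denom = float(ab @ ab)
    t = 0.0 if denom == 0 else float(np.clip((p - a) @ ab / denom, 0.0, 1.0))
    proj = a + t * ab
    return float(np.linalg.norm(p - proj)), t


def fit_trajectory(
    embedding: EmbeddingResult, clusters: ClusterAssignment, root: int
) -> TrajectoryResult:
    labels = clusters.labels
    cluster_ids = sorted(set(labels.tolist()))
    if root not in cluster_ids:
        raise ValueError(f"root cluster {root} does not exist")
    centroids = np.stack([embedding.pcs[labels == c].mean(axis=0) for c in cluster_ids])
    id_of = {c: i for i, c in enumerate(cluster_ids)}

    if len(cluster_ids) == 1:
        warnings.warn("single cluster: all pseudotime values are 0")
        return TrajectoryResult(root, [], np.zeros(labels.size),
                                [(root, root)] * labels.size, centroids)

    D = np.linalg.norm(centroids[:, None] - centroids[None], axis=-1)
    mst = csgraph.minimum_spanning_tree(D)
    mst_sym = mst + mst.T
    ii, jj = mst.nonzero()
    edges = [(cluster_ids[i], cluster_ids[j]) for i, j in zip(ii, jj)]
    # geodesic distance from root to every centroid along the tree
    d_root = csgraph.dijkstra(mst_sym, indices=id_of[root])

    pseudotime = np.empty(labels.size)
    cell_edge: list[tuple[int, int]] = [None] * labels.size  # type: ignore[list-item]
    edge_geom = [
        (u, v, centroids[id_of[u]], centroids[id_of[v]],
         float(np.linalg.norm(centroids[id_of[u]] - centroids[id_of[v]])))
        for u, v in edges
    ]
    for i, p in enumerate(embedding.pcs):
        best = None
        for u, v, a, b, length in edge_geom:
            dist, t = _project_to_segment(p, a, b)
            if best is None or dist < best[0]:
                along = min(d_root[id_of[u]] + t * length,
                            d_root[id_of[v]] + (1 - t) * length)
                best = (dist, along, (u, v))
        pseudotime[i] = best[1]
        cell_edge[i] = best[2]

    # shift so the root cluster's minimum is 0; projections that land even
    # closer to the root centroid than any root cell clip at 0
    pseudotime = np.maximum(pseudotime - pseudotime[labels == root].min(), 0.0)
    return TrajectoryResult(root, edges, pseudotime, cell_edge, centroids)


def trajectory_table(result: TrajectoryResult, clusters: ClusterAssignment,
                     cell_names) -> pd.DataFrame:
    return pd.DataFrame({
        "cell": list(cell_names),
        "cluster": clusters.labels,
        "pseudotime": result.pseudotime,
        "edge": [f"{u}-{v}" for u, v in result.cell_edge],
    })
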