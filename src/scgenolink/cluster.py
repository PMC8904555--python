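"""Dimensionality reduction, graph clustering and cluster marker panels.

PCA on normalized expression with an algorithmic elbow rule picks the
number of informative components; cells are then clustered on a k-nearest-
neighbour graph in PC space with Leiden community detection, and embedded
in 2-D with t-SNE for visualization only.  The t-SNE layout is stochastic
(deterministic per seed) and never used for statistics.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE
from sklearn.neighbors import kneighbors_graph

from .errors import ParameterError
from .matrix import CellGeneMatrix
from .markers import NormalizationParams, wilcoxon_markers

log = logging.getLogger(__name__)

__all__ = ["pca_with_elbow", "graph_cluster", "tsne_embed", "cluster_marker_heatmap"]


def pca_with_elbow(
    normalized: np.ndarray, max_pcs: int = 30, tol: float = 1e-3, scale: bool = True
) -> tuple[np.ndarray, np.ndarray, int]:
    """PCA with an automatic elbow choice of component count.

    Genes are standardized to unit variance first (``scale=True``, the
    usual single-cell practice) so a few high-variance genes cannot mask
    sample structure.  The elbow is where the scree curve flattens for
    good: ``k`` is the last component whose explained-variance-ratio drop
    to its successor is at least ``tol`` — every component before the
    final substantial drop is kept, everything in the flat noise tail is
    not.  Pure-noise data yields ``k = 1``.

    Returns ``(scores, explained_variance_ratio, k)`` where ``scores`` has
    ``max_pcs`` columns; callers slice to ``k``.
    """
    X = np.asarray(normalized, dtype=float)
    if X.ndim != 2 or min(X.shape) < 2:
        raise ParameterError("need a 2-D matrix with at least 2 rows and columns")
    std = X.std(axis=0)
    if np.allclose(std, 0):
        raise ParameterError("constant matrix has no principal components")
    if scale:
        X = (X - X.mean(axis=0)) / np.where(std == 0, 1.0, std)
    n_comp = min(max_pcs, min(X.shape) - 1)
    pca = PCA(n_components=n_comp, svd_solver="full")
    scores = pca.fit_transform(X)
    evr = pca.explained_variance_ratio_
    drops = evr[:-1] - evr[1:]
    substantial = np.flatnonzero(drops >= tol)
    k = int(substantial[-1]) + 1 if substantial.size else 1
    return scores, evr, k


def graph_cluster(
    pcs: np.ndarray, n_neighbors: int = 15, resolution: float = 1.0, seed: int = 0
) -> np.ndarray:
    """Leiden community detection on a kNN graph in PC space.

    Returns integer cluster labels starting at 1, deterministic per seed.
    """
    import igraph
    import leidenalg

    pcs = np.asarray(pcs, dtype=float)
    n = pcs.shape[0]
    if n_neighbors >= n:
        raise ParameterError(f"n_neighbors={n_neighbors} must be < n_cells={n}")
    adj = kneighbors_graph(pcs, n_neighbors=n_neighbors, mode="connectivity")
    adj = adj.maximum(adj.T).tocoo()
    edges = [(i, j) for i, j in zip(adj.row, adj.col) if i < j]
    graph = igraph.Graph(n=n, edges=edges)
    partition = leidenalg.find_partition(
        graph,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=int(seed),
    )
    return np.asarray(partition.membership) + 1


def tsne_embed(pcs: np.ndarray, perplexity: float = 30.0, seed: int = 0) -> np.ndarray:
    """2-D t-SNE layout of cells from their PC coordinates."""
    pcs = np.asarray(pcs, dtype=float)
    n = pcs.shape[0]
    if perplexity >= (n - 1) / 3:
        raise ParameterError(f"perplexity={perplexity} too large for {n} cells")
    init = "pca" if pcs.shape[1] >= 2 else "random"
    tsne = TSNE(
        n_components=2, perplexity=perplexity, random_state=int(seed), init=init
    )
    return tsne.fit_transform(pcs)


def cluster_marker_heatmap(
    matrix: CellGeneMatrix,
    clusters: pd.Series,
    n: int = 30,
    params: NormalizationParams | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Rank-score matrix for the union of each cluster's top markers.

    For every cluster with at least 2 cells a cluster-vs-rest marker table
    is computed; its top ``n`` genes by rank score form that cluster's
    panel.  The emitted matrix holds the rank score of each panel gene
    (union, no duplicates) in each cluster.
    """
    clusters = clusters.reindex(matrix.cell_ids)
    labels = sorted(clusters.unique())
    tables = {}
    for c in labels:
        if (clusters == c).sum() < 2 or (clusters != c).sum() < 2:
            log.warning("cluster %s too small; skipped", c)
            continue
        tables[c] = wilcoxon_markers(matrix, c, labels=clusters, params=params)
    panel: list[str] = []
    for c, tab in tables.items():
        top = tab.sort_values(
            ["rank_score", "padj", "gene"], ascending=[False, True, True], kind="mergesort"
        )["gene"].head(n)
        panel.extend(g for g in top if g not in panel)
    scores = pd.DataFrame(
        {c: tab.set_index("gene")["rank_score"].reindex(panel) for c, tab in tables.items()},
        index=pd.Index(panel, name="gene"),
    )
    return scores, panel
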