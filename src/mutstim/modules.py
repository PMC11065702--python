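"""Effect-profile gene-module discovery and contrast-similarity mapping.

Strongly differential genes (adjusted p below 0.05 and absolute log2FC above
2 in at least one coefficient) form an effect matrix of log2 fold changes
(genes x coefficients).  A symmetrized k-nearest-neighbor graph on that
matrix is clustered with short-random-walk (walktrap) community detection,
cut at maximum modularity; module summaries report the mean log2FC per
coefficient.  Contrast similarity uses classical (Torgerson) multi-
dimensional scaling of one-minus-Spearman distances between contrast log2FC
profiles.  Any 2-D layout is visualization only — clustering depends solely
on the graph.
"""

from __future__ import annotations

import logging

import igraph as ig
import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import cdist

logger = logging.getLogger(__name__)


def effect_matrix(
    fits: dict[str, pd.DataFrame] | pd.DataFrame,
    padj_cut: float = 0.05,
    lfc_cut: float = 2.0,
) -> pd.DataFrame:
    """Aggregate log2FC profiles of strongly differential genes.

    ``fits`` is either a single long fit table or a mapping of contrast-set
    name -> long fit table (columns ``gene``, ``coefficient``, ``log2FC``,
    ``padj``); coefficient columns from different tables are prefixed with
    the mapping key.  A gene is retained when it passes ``padj < padj_cut``
    and ``|log2FC| > lfc_cut`` in at least one coefficient; missing entries
    are imputed as zero (absence of evidence of effect).
    """
    if isinstance(fits, pd.DataFrame):
        fits = {"": fits}
    lfc_frames, pass_frames = [], []
    for key, fit in fits.items():
        lfc = fit.pivot(index="gene", columns="coefficient", values="log2FC")
        padj = fit.pivot(index="gene", columns="coefficient", values="padj")
        if key:
            lfc.columns = [f"{key}:{c}" for c in lfc.columns]
            padj.columns = lfc.columns
        lfc_frames.append(lfc)
        pass_frames.append((padj < padj_cut) & (lfc.abs() > lfc_cut))
    matrix = pd.concat(lfc_frames, axis=1)
    passing = (
        pd.concat(pass_frames, axis=1)
        .reindex(index=matrix.index, columns=matrix.columns)
        .astype("boolean")
        .fillna(False)  # a gene untested in a contrast cannot pass there
        .astype(bool)
    )
    n_missing = int(matrix.isna().sum().sum())
    if n_missing:
        logger.info("imputed %d missing log2FC entries as 0", n_missing)
    matrix = matrix.fillna(0.0)
    keep = passing.any(axis=1)
    if not keep.any():
        raise ValueError(
            f"no gene passes padj < {padj_cut} and |log2FC| > {lfc_cut} in any coefficient"
        )
    out = matrix.loc[keep].sort_index()
    logger.info("effect matrix: %d genes x %d coefficients", *out.shape)
    return out


def knn_graph(matrix: pd.DataFrame, k: int = 15, metric: str = "euclidean") -> nx.Graph:
    """Symmetrized k-nearest-neighbor graph of the effect matrix.

    An edge joins i and j when either is among the other's k nearest
    neighbors (union symmetrization); edge weight is the distance.  Distance
    ties are broken by row order, so the graph is deterministic.
    """
    n = matrix.shape[0]
    if k >= n:
        raise ValueError(f"k ({k}) must be smaller than the number of genes ({n})")
    if k < 1:
        raise ValueError("k must be >= 1")
    D = cdist(matrix.to_numpy(), matrix.to_numpy(), metric=metric)
    graph = nx.Graph()
    graph.add_nodes_from(matrix.index)
    ids = list(matrix.index)
    order = np.argsort(D, axis=1, kind="stable")  # ties broken by row order
    for i in range(n):
        neighbors = [j for j in order[i] if j != i][:k]
        for j in neighbors:
            graph.add_edge(ids[i], ids[j], distance=float(D[i, j]))
    logger.info("kNN graph: %d nodes, %d edges (k=%d)", n, graph.number_of_edges(), k)
    return graph


def walktrap_communities(graph: nx.Graph, steps: int = 4) -> pd.Series:
    """Short-random-walk (walktrap) community detection, cut at maximum
    modularity.

    Vertices are agglomerated by similarity of their ``steps``-step random
    walk distributions and the merge tree is cut where modularity peaks.
    Isolated vertices form singleton communities.  Community ids are
    renumbered by first appearance in node order.
    """
    nodes = list(graph.nodes)
    if not nodes:
        raise ValueError("graph is empty")
    index = {v: i for i, v in enumerate(nodes)}
    g = ig.Graph(
        n=len(nodes), edges=[(index[u], index[v]) for u, v in graph.edges], directed=False
    )
    membership = g.community_walktrap(steps=steps).as_clustering().membership
    # renumber communities deterministically by first appearance
    remap: dict[int, int] = {}
    labels = []
    for m in membership:
        if m not in remap:
            remap[m] = len(remap)
        labels.append(remap[m])
    out = pd.Series(labels, index=nodes, name="community")
    logger.info("walktrap: %d communities over %d nodes", out.nunique(), len(nodes))
    return out


def module_mean_lfc(assignment: pd.Series, matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-module mean log2FC per coefficient, with module sizes."""
    missing = matrix.index.difference(assignment.index)
    if len(missing):
        raise ValueError(f"genes without a community assignment: {list(missing)[:5]}")
    means = matrix.groupby(assignment.loc[matrix.index]).mean()
    means.insert(0, "n_genes", assignment.loc[matrix.index].value_counts().sort_index())
    means.index.name = "community"
    return means


def classical_mds(distance: np.ndarray, n_components: int = 2) -> np.ndarray:
    """Classical (Torgerson) multidimensional scaling.

    Double-centers ``-d^2/2`` and embeds on the top eigenvectors scaled by
    the square root of their (non-negative) eigenvalues.  The configuration
    is defined up to rotation and reflection.
    """
    D2 = np.asarray(distance, dtype=float) ** 2
    n = D2.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    eigval, eigvec = np.linalg.eigh(B)
    idx = np.argsort(eigval)[::-1][:n_components]
    vals = np.maximum(eigval[idx], 0.0)
    return eigvec[:, idx] * np.sqrt(vals)


def contrast_similarity_mds(lfc_profiles: pd.DataFrame) -> pd.DataFrame:
    """Map contrasts into 2-D by similarity of their log2FC profiles.

    ``lfc_profiles`` is genes x contrasts.  Distances are one minus the
    Spearman correlation between contrast columns over the shared gene
    universe; the embedding is classical MDS (up to rotation/reflection).
    """
    if lfc_profiles.shape[1] < 3:
        raise ValueError("need at least 3 contrasts for the similarity map")
    rho = np.atleast_2d(stats.spearmanr(lfc_profiles.to_numpy(), axis=0).statistic)
    dist = 1.0 - rho
    np.fill_diagonal(dist, 0.0)
    coords = classical_mds(dist, n_components=2)
    return pd.DataFrame(coords, index=lfc_profiles.columns, columns=["dim1", "dim2"])


def embed_2d(matrix: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Optional 2-D layout of the effect matrix for visualization only.

    Uses UMAP when available, otherwise the first two principal components.
    Clustering never depends on this layout.
    """
    try:
        from umap import UMAP

        coords = UMAP(n_components=2, random_state=seed).fit_transform(
            matrix.to_numpy()
        )
    except ImportError:  # pragma: no cover - depends on optional extra
        centered = matrix.to_numpy() - matrix.to_numpy().mean(axis=0)
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        coords = centered @ vt[:2].T
    return pd.DataFrame(coords, index=matrix.index, columns=["x", "y"])
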