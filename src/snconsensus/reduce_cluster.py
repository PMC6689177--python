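"""PCA, PC selection, SNN graph clustering, tSNE and the cluster dendrogram.

The clustering stack is the standard graph-based recipe: PCA on the
scaled expression of the selected genes, a shared-nearest-neighbor
(SNN) graph with Jaccard edge weights in PC space, and
resolution-parameterized modularity community detection (Leiden),
seeded for determinism.  The number of informative PCs is chosen with a
jackstraw permutation test plus an elbow statistic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats
from scipy.cluster.hierarchy import linkage, to_tree
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE
from sklearn.neighbors import NearestNeighbors

from .containers import GeneExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass
class PCModel:
    loadings: np.ndarray  # genes x PCs
    scores: np.ndarray  # nuclei x PCs
    stdevs: np.ndarray
    gene_ids: List[str]
    jackstraw_p: Optional[np.ndarray] = None


@dataclass
class Clustering:
    """Nucleus -> cluster assignment, 0-based ids ordered by decreasing size."""

    assignment: pd.Series  # index=barcode, value=cluster id
    resolution: float
    k_neighbors: int
    seed: int

    def __post_init__(self) -> None:
        labels = np.asarray(self.assignment)
        uniq = np.unique(labels)
        if not np.array_equal(uniq, np.arange(len(uniq))):
            raise ValueError("cluster ids must be contiguous starting at 0")

    @property
    def n_clusters(self) -> int:
        return int(self.assignment.max()) + 1

    def members(self, cluster: int) -> set:
        return set(self.assignment.index[self.assignment == cluster])


@dataclass
class ClusterTree:
    linkage_matrix: np.ndarray
    labels: List[str]

    def to_newick(self) -> str:
        root = to_tree(self.linkage_matrix)

        def rec(node):
            if node.is_leaf():
                return self.labels[node.id]
            left, right = rec(node.left), rec(node.right)
            dl = node.dist - node.left.dist
            dr = node.dist - node.right.dist
            return f"({left}:{dl:.6g},{right}:{dr:.6g})"

        return rec(root) + ";"


# ---------------------------------------------------------------------------


def _restrict(m: GeneExpressionMatrix, genes: Sequence[str]) -> np.ndarray:
    """(cells x selected genes) dense array for the given gene ids."""
    idx = m.gene_index(genes)
    if len(idx) == 0:
        raise ValueError("none of the selected genes are present in the matrix")
    sub = m.csr()[idx, :]
    return np.asarray(sub.todense(), dtype=float).T


def run_pca(m: GeneExpressionMatrix, genes: Sequence[str], n: int = 100) -> PCModel:
    """PCA of the scaled matrix restricted to the selected genes.

    Deterministic: full SVD with the sign convention that each PC's
    largest-|loading| entry is positive.
    """
    X = _restrict(m, genes)
    n_cells, n_genes = X.shape
    if n > min(n_genes, n_cells) - 1:
        raise ValueError(
            f"n={n} PCs exceeds min(genes={n_genes}, cells={n_cells}) - 1"
        )
    pca = PCA(n_components=n, svd_solver="full")
    scores = pca.fit_transform(X)
    loadings = pca.components_.T  # genes x PCs
    flip = np.sign(loadings[np.argmax(np.abs(loadings), axis=0), np.arange(n)])
    flip[flip == 0] = 1.0
    loadings = loadings * flip
    scores = scores * flip
    stdevs = np.sqrt(pca.explained_variance_)
    idx = m.gene_index(genes)
    return PCModel(
        loadings=loadings,
        scores=scores,
        stdevs=stdevs,
        gene_ids=[m.gene_ids[i] for i in idx],
    )


def jackstraw(
    model: PCModel,
    m: GeneExpressionMatrix,
    genes: Sequence[str],
    replicates: int = 100,
    prop: float = 0.1,
    seed: int = 0,
) -> np.ndarray:
    """Permutation test for per-PC significance.

    Each replicate permutes a random fraction ``prop`` of the selected
    genes across nuclei, refits the PCA on the partially permuted
    matrix, and records the permuted genes' loadings; these refit
    loadings form the null (refitting matters: the eigen-decomposition
    inflates its own genes' loadings, so a null projected onto fixed
    scores would be anti-conservative).  The per-PC p-value is a
    one-sided rank test (Mann-Whitney U) of the observed |loading|
    distribution against the null.
    """
    if replicates < 20:
        raise ValueError("need at least 20 jackstraw replicates")
    X = _restrict(m, genes)  # cells x genes
    n_cells, n_genes = X.shape
    n_perm = int(np.floor(prop * n_genes))
    if n_perm < 1:
        raise ValueError(f"prop={prop} selects no genes out of {n_genes}")
    rng = np.random.default_rng(seed)

    n_pcs = model.scores.shape[1]
    observed = np.abs(model.loadings)  # genes x PCs

    null = np.empty((replicates * n_perm, n_pcs))
    for r in range(replicates):
        pick = rng.choice(n_genes, size=n_perm, replace=False)
        Xp = X.copy()
        for j in pick:
            Xp[:, j] = rng.permutation(Xp[:, j])
        refit = PCA(n_components=n_pcs, svd_solver="full").fit(Xp)
        null[r * n_perm : (r + 1) * n_perm] = np.abs(refit.components_.T[pick, :])

    pvals = np.empty(n_pcs)
    for k in range(n_pcs):
        res = scipy.stats.mannwhitneyu(
            observed[:, k], null[:, k], alternative="greater"
        )
        pvals[k] = res.pvalue
    model.jackstraw_p = pvals
    return pvals


def choose_n_pcs(model: PCModel, alpha: float = 0.05) -> int:
    """Largest m such that PCs 1..m are all jackstraw-significant.

    The elbow statistic (index of the largest drop in the stdev curve)
    is logged alongside for the run record.
    """
    if model.jackstraw_p is None:
        raise ValueError("run jackstraw before choosing the number of PCs")
    sig = model.jackstraw_p < alpha
    m = int(np.argmin(sig)) if not sig.all() else len(sig)
    drops = -np.diff(model.stdevs)
    elbow = int(np.argmax(drops)) + 1 if len(drops) else 1
    logger.info("jackstraw prefix rule: %d PCs (elbow statistic: %d)", m, elbow)
    if m == 0:
        logger.warning("no principal component is significant at alpha=%g", alpha)
    return m


# ---------------------------------------------------------------------------


def build_snn_graph(
    scores: np.ndarray, k: int = 20, prune: float = 1 / 15
) -> sp.csr_matrix:
    """Shared-nearest-neighbor graph in PC space.

    Each cell's neighborhood is its k nearest neighbors (Euclidean,
    self included); the edge weight between two cells is the Jaccard
    overlap of their neighborhoods.  Weights below ``prune`` are
    dropped.  Returns a symmetric sparse adjacency matrix.
    """
    scores = np.asarray(scores, dtype=float)
    n = scores.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be below the number of cells ({n})")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(scores)
    indices = nn.kneighbors(scores, return_distance=False)  # includes self
    rows = np.repeat(np.arange(n), k + 1)
    A = sp.csr_matrix(
        (np.ones(n * (k + 1)), (rows, indices.ravel())), shape=(n, n)
    )
    A.data[:] = 1.0  # guard duplicate entries
    inter = (A @ A.T).tocoo()
    union = 2.0 * (k + 1) - inter.data
    jac = inter.data / union
    keep = (jac >= prune) & (inter.row != inter.col)
    W = sp.csr_matrix((jac[keep], (inter.row[keep], inter.col[keep])), shape=(n, n))
    return W


class SNNLeidenClusterer(ClusterMixin, BaseEstimator):
    """SNN-graph Leiden clustering over an (n_cells, n_pcs) score matrix.

    fit stores ``labels_`` (0-based, ordered by decreasing cluster
    size).  Deterministic given ``random_state``.
    """

    def __init__(self, n_neighbors: int = 20, resolution: float = 0.6,
                 prune: float = 1 / 15, random_state: int = 0):
        self.n_neighbors = n_neighbors
        self.resolution = resolution
        self.prune = prune
        self.random_state = random_state

    def fit(self, X, y=None):
        W = build_snn_graph(np.asarray(X), k=self.n_neighbors, prune=self.prune)
        self.labels_ = cluster_snn_matrix(
            W, resolution=self.resolution, seed=self.random_state
        )
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def cluster_snn_matrix(W: sp.spmatrix, resolution: float = 0.6, seed: int = 0) -> np.ndarray:
    """Leiden community detection on a weighted adjacency matrix."""
    W = sp.coo_matrix(W)
    if W.shape[0] == 0:
        raise ValueError("empty graph")
    mask = W.row < W.col  # undirected, one edge per pair
    edges = list(zip(W.row[mask].tolist(), W.col[mask].tolist()))
    weights = W.data[mask].tolist()
    g = ig.Graph(n=W.shape[0], edges=edges)
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        weights=weights,
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=2,
    )
    raw = np.asarray(part.membership)
    return _relabel_by_size(raw)


def _relabel_by_size(labels: np.ndarray) -> np.ndarray:
    uniq, counts = np.unique(labels, return_counts=True)
    order = uniq[np.lexsort((uniq, -counts))]
    mapping = {old: new for new, old in enumerate(order)}
    return np.asarray([mapping[v] for v in labels])


def cluster_graph(
    W: sp.spmatrix,
    barcodes: Sequence[str],
    resolution: float = 0.6,
    k_neighbors: int = 20,
    seed: int = 0,
) -> Clustering:
    """Cluster an SNN graph and wrap the result with its provenance."""
    labels = cluster_snn_matrix(W, resolution=resolution, seed=seed)
    return Clustering(
        assignment=pd.Series(labels, index=list(barcodes)),
        resolution=resolution,
        k_neighbors=k_neighbors,
        seed=seed,
    )


def run_tsne(scores: np.ndarray, seed: int = 0, perplexity: float = 30.0) -> np.ndarray:
    """2-D tSNE embedding of the PC scores (visualization only)."""
    scores = np.asarray(scores, dtype=float)
    n = scores.shape[0]
    if n < 10:
        raise ValueError("tSNE needs at least 10 cells")
    if perplexity >= n:
        new = max(5.0, (n - 1) / 3.0)
        logger.warning("perplexity %.1f >= %d cells; reduced to %.1f", perplexity, n, new)
        perplexity = new
    emb = TSNE(
        n_components=2, perplexity=perplexity, random_state=seed, init="pca"
    ).fit_transform(scores)
    return np.asarray(emb)


def build_cluster_tree(
    m: GeneExpressionMatrix, c: Clustering, genes: Sequence[str]
) -> ClusterTree:
    """Average-linkage tree over Euclidean distances of cluster mean profiles."""
    if c.n_clusters < 2:
        raise ValueError("cluster tree needs at least 2 clusters")
    X = _restrict(m, genes)  # cells x genes
    labels = c.assignment.loc[list(m.barcodes)].to_numpy()
    means = np.vstack([X[labels == k].mean(axis=0) for k in range(c.n_clusters)])
    Z = linkage(means, method="average", metric="euclidean")
    return ClusterTree(linkage_matrix=Z, labels=[str(k) for k in range(c.n_clusters)])
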