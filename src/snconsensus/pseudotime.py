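"""MST pseudotime for a cell subset and gene-pseudotime association.

The ordering follows the classic cluster-then-tree recipe: expression is
filtered and log-transformed, cells are embedded in a low-dimensional PC
space and grouped with a Gaussian mixture (model size by BIC), a minimum
spanning tree is drawn over the mixture-component means, the longest
path through the tree defines the backbone, and every cell is projected
onto its component's incident backbone edge; pseudotime is cumulative
arc length along the backbone (orientation arbitrary but deterministic).

Association between a gene and pseudotime is a fixed-3-df cubic trend
fit tested against the intercept-only model by an F-test, with
Benjamini-Hochberg q-values.  The disease-associated-microglia (DAM)
scan runs the whole chain pooled and per donor and intersects the
per-donor significant sets.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats
from scipy.sparse.csgraph import minimum_spanning_tree, shortest_path
from sklearn.base import BaseEstimator
from sklearn.decomposition import PCA
from sklearn.mixture import GaussianMixture
from statsmodels.stats.multitest import multipletests

from .containers import GeneExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass
class ProcessedExpression:
    """Filtered, depth-normalized, log2-transformed expression for ordering."""

    values: np.ndarray  # cells x genes
    gene_symbols: List[str]
    barcodes: List[str]


@dataclass
class PseudotimeResult:
    states: np.ndarray  # per-cell mixture component
    mst_edges: List[tuple]
    path: List[int]  # ordered component sequence (backbone)
    pseudotime: np.ndarray
    barcodes: List[str]
    gene_stats: Optional[pd.DataFrame] = None  # gene, stat, p, q


@dataclass
class DamScanResult:
    input_genes: List[str]
    detected: List[str]
    per_stratum: Dict[str, List[str]]  # stratum -> significant genes (q < alpha)
    intersection: List[str]
    tables: Dict[str, pd.DataFrame] = field(default_factory=dict)


# ---------------------------------------------------------------------------


def tscan_preprocess(
    m: GeneExpressionMatrix, min_detect_fraction: float = 0.10
) -> ProcessedExpression:
    """Detection filter + log2 CPM transform of a counts subset.

    Genes detected in fewer than ``min_detect_fraction`` of the cells
    are dropped, counts are normalized to counts-per-million per cell,
    log2(x+1)-transformed, and zero-variance genes removed.
    """
    if m.n_cells < 20:
        raise ValueError(f"need at least 20 cells for ordering, got {m.n_cells}")
    X = np.asarray(m.csr().todense(), dtype=float).T  # cells x genes
    detect = (X > 0).mean(axis=0)
    keep = detect >= min_detect_fraction
    X = X[:, keep]
    symbols = [s for s, k in zip(m.gene_symbols, keep) if k]
    totals = X.sum(axis=1)
    if np.any(totals == 0):
        raise ValueError("cell with zero total count after gene filtering")
    X = np.log2(1.0 + 1e6 * X / totals[:, None])
    var = X.var(axis=0)
    X = X[:, var > 0]
    symbols = [s for s, v in zip(symbols, var > 0) if v]
    if X.shape[1] == 0:
        raise ValueError("no genes survive preprocessing")
    return ProcessedExpression(values=X, gene_symbols=symbols, barcodes=list(m.barcodes))


def fit_cell_states(
    processed: ProcessedExpression,
    max_k: int = 5,
    n_components: int = 2,
    seed: int = 0,
    min_k: int = 1,
) -> np.ndarray:
    """Gaussian-mixture states in a low-dimensional PC embedding; k by BIC.

    ``min_k`` defaults to 1 (a homogeneous cloud is one state); the
    ordering pipeline passes ``min_k=2`` because a spanning tree needs
    at least two vertices.
    """
    n = processed.values.shape[0]
    if n < 10 * max_k:
        raise ValueError(f"need at least {10 * max_k} cells for max_k={max_k}")
    dim = min(n_components, processed.values.shape[1], n - 1)
    emb = PCA(n_components=dim, svd_solver="full").fit_transform(processed.values)
    bics, fits = {}, {}
    for k in range(max(1, min_k), max_k + 1):
        gm = GaussianMixture(
            n_components=k, random_state=seed, n_init=3, reg_covar=1e-6,
            covariance_type="full",
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gm.fit(emb)
        if not gm.converged_:
            logger.warning("state mixture k=%d did not converge; excluded", k)
            continue
        bics[k] = gm.bic(emb)
        fits[k] = gm
    best = min(bics, key=bics.get)
    states = fits[best].predict(emb)
    processed.embedding_ = emb  # type: ignore[attr-defined]
    return states


def _longest_path(mst: sp.csr_matrix) -> List[int]:
    """Weighted diameter path of a tree (double sweep + predecessor trace)."""
    sym = mst.maximum(mst.T)
    d0, _ = shortest_path(sym, return_predecessors=True, indices=0)
    a = int(np.argmax(np.where(np.isinf(d0), -1, d0)))
    da, pred = shortest_path(sym, return_predecessors=True, indices=a)
    b = int(np.argmax(np.where(np.isinf(da), -1, da)))
    path = [b]
    while path[-1] != a:
        path.append(int(pred[path[-1]]))
    return path[::-1]


def order_cells(
    states: np.ndarray, processed: ProcessedExpression, seed: int = 0
) -> PseudotimeResult:
    """MST over state means, backbone = longest path, project cells onto it."""
    emb = getattr(processed, "embedding_", None)
    if emb is None:
        emb = PCA(
            n_components=min(2, processed.values.shape[1]), svd_solver="full"
        ).fit_transform(processed.values)
    states = np.asarray(states)
    ks = np.unique(states)
    means = np.vstack([emb[states == k].mean(axis=0) for k in ks])

    if len(ks) == 1:
        logger.warning("single state: ordering cells by PC1")
        pt = emb[:, 0] - emb[:, 0].min()
        return PseudotimeResult(
            states=states, mst_edges=[], path=[int(ks[0])],
            pseudotime=pt, barcodes=processed.barcodes,
        )

    dist = np.linalg.norm(means[:, None, :] - means[None, :, :], axis=2)
    mst = minimum_spanning_tree(dist)
    order = _longest_path(sp.csr_matrix(mst))
    coo = sp.coo_matrix(mst)
    edges = [(int(ks[i]), int(ks[j])) for i, j in zip(coo.row, coo.col)]

    # backbone geometry
    verts = means[order]
    seglen = np.linalg.norm(np.diff(verts, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seglen)])
    pos_on_path = {int(ks[v]): i for i, v in enumerate(order)}

    # off-backbone states attach to their nearest backbone vertex
    attach: Dict[int, int] = {}
    for ki, kk in enumerate(ks):
        kk = int(kk)
        if kk in pos_on_path:
            attach[kk] = pos_on_path[kk]
        else:
            attach[kk] = int(np.argmin(np.linalg.norm(verts - means[ki], axis=1)))

    def project(point: np.ndarray, vertex_idx: int) -> float:
        # terminal edges extrapolate beyond the end vertices so tail cells
        # keep distinct positions instead of collapsing onto the endpoint
        best = cum[vertex_idx]
        best_d = np.inf
        for e in (vertex_idx - 1, vertex_idx):
            if e < 0 or e >= len(seglen) or seglen[e] == 0:
                continue
            a, b = verts[e], verts[e + 1]
            t = np.dot(point - a, b - a) / seglen[e] ** 2
            lo = -np.inf if e == 0 else 0.0
            hi = np.inf if e == len(seglen) - 1 else 1.0
            t = np.clip(t, lo, hi)
            proj = a + t * (b - a)
            d = np.linalg.norm(point - proj)
            if d < best_d:
                best_d = d
                best = cum[e] + t * seglen[e]
        return float(best)

    pt_raw = np.asarray(
        [project(emb[i], attach[int(states[i])]) for i in range(len(states))]
    )
    pt_raw -= pt_raw.min()

    return PseudotimeResult(
        states=states, mst_edges=edges, path=[int(ks[v]) for v in order],
        pseudotime=pt_raw, barcodes=processed.barcodes,
    )


# ---------------------------------------------------------------------------


def _cubic_trend_test(y: np.ndarray, t: np.ndarray) -> tuple[float, float]:
    """F-test of a 3-df cubic trend in pseudotime against intercept-only."""
    n = len(y)
    if np.ptp(y) == 0 or np.ptp(t) == 0 or n < 6:
        return 0.0, 1.0
    ts = (t - t.mean()) / (t.std() or 1.0)
    D = np.column_stack([np.ones(n), ts, ts**2, ts**3])
    Q, _ = np.linalg.qr(D)
    fitted = Q @ (Q.T @ y)
    rss1 = float(((y - fitted) ** 2).sum())
    rss0 = float(((y - y.mean()) ** 2).sum())
    df_num, df_den = 3, n - 4
    if rss1 <= 0:
        return np.inf, 0.0
    F = ((rss0 - rss1) / df_num) / (rss1 / df_den)
    return float(F), float(scipy.stats.f.sf(F, df_num, df_den))


def pseudotime_association(
    result: PseudotimeResult,
    processed: ProcessedExpression,
    genes: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Per-gene pseudotime association (F statistic, p, BH q)."""
    if genes is None:
        genes = processed.gene_symbols
    cols = {g: i for i, g in enumerate(processed.gene_symbols)}
    rows = []
    for g in genes:
        if g not in cols:
            continue
        F, p = _cubic_trend_test(processed.values[:, cols[g]], result.pseudotime)
        rows.append(dict(gene=g, stat=F, p=p))
    table = pd.DataFrame(rows, columns=["gene", "stat", "p"])
    if len(table):
        table["q"] = multipletests(table["p"], method="fdr_bh")[1]
    else:
        table["q"] = pd.Series(dtype=float)
    result.gene_stats = table
    return table


class MSTPseudotime(BaseEstimator):
    """End-to-end pseudotime estimator over a (cells x genes) count block.

    fit computes ``states_``, ``pseudotime_`` and ``path_``; intended
    for an already-subset cell population (e.g. microglia).
    """

    def __init__(self, max_k: int = 5, n_components: int = 2,
                 min_detect_fraction: float = 0.10, random_state: int = 0):
        self.max_k = max_k
        self.n_components = n_components
        self.min_detect_fraction = min_detect_fraction
        self.random_state = random_state

    def fit(self, X, y=None, gene_symbols: Optional[Sequence[str]] = None):
        X = sp.csr_matrix(X)
        n_cells, n_genes = X.shape
        if gene_symbols is None:
            gene_symbols = [f"g{i}" for i in range(n_genes)]
        m = GeneExpressionMatrix(
            gene_ids=np.asarray(gene_symbols, dtype=object),
            gene_symbols=np.asarray(gene_symbols, dtype=object),
            barcodes=np.asarray([f"c{i}" for i in range(n_cells)], dtype=object),
            sample_labels=np.asarray([""] * n_cells, dtype=object),
            values=X.T,
            layer="counts",
        )
        processed = tscan_preprocess(m, self.min_detect_fraction)
        max_k = max(2, min(self.max_k, processed.values.shape[0] // 10))
        states = fit_cell_states(
            processed, max_k=max_k, n_components=self.n_components,
            seed=self.random_state, min_k=2,
        )
        result = order_cells(states, processed, seed=self.random_state)
        self.processed_ = processed
        self.states_ = result.states
        self.pseudotime_ = result.pseudotime
        self.path_ = result.path
        self.result_ = result
        return self


def run_ordering(
    m: GeneExpressionMatrix,
    max_k: int = 5,
    seed: int = 0,
    min_detect_fraction: float = 0.10,
) -> tuple[PseudotimeResult, ProcessedExpression]:
    """preprocess -> states -> order for a counts-layer cell subset."""
    processed = tscan_preprocess(m, min_detect_fraction)
    max_k = max(2, min(max_k, processed.values.shape[0] // 10))
    states = fit_cell_states(processed, max_k=max_k, seed=seed, min_k=2)
    result = order_cells(states, processed, seed=seed)
    return result, processed


def dam_scan(
    m: GeneExpressionMatrix,
    subset: Sequence,
    dam_genes: Sequence[str],
    alpha: float = 0.05,
    max_k: int = 5,
    seed: int = 0,
    min_cells: int = 20,
) -> DamScanResult:
    """Per-donor pseudotime scan of a marker gene list (e.g. DAM signature).

    ``subset`` is a boolean mask or barcode list naming the cell
    population (microglia in the motivating study).  The full
    preprocess -> states -> order -> association chain runs pooled and
    within each donor; per-stratum significant sets (q < alpha) and
    their cross-donor intersection are reported.
    """
    dam_genes = list(dam_genes)
    if not dam_genes:
        raise ValueError("empty gene list")
    subset = np.asarray(subset)
    if subset.dtype == bool:
        cells = m.subset_cells(subset)
    else:
        wanted = set(subset)
        cells = m.subset_cells(np.asarray([bc in wanted for bc in m.barcodes]))

    detected_all: set = set()
    per_stratum: Dict[str, List[str]] = {}
    tables: Dict[str, pd.DataFrame] = {}
    strata = [("pooled", np.ones(cells.n_cells, dtype=bool))] + [
        (str(s), cells.sample_labels == s) for s in cells.samples
    ]
    for name, mask in strata:
        if mask.sum() < min_cells:
            logger.warning("stratum %r has %d cells (<%d); skipped", name, mask.sum(), min_cells)
            continue
        sub = cells.subset_cells(mask)
        try:
            result, processed = run_ordering(sub, max_k=max_k, seed=seed)
        except ValueError as exc:
            logger.warning("stratum %r skipped: %s", name, exc)
            continue
        present = [g for g in dam_genes if g in processed.gene_symbols]
        detected_all.update(present)
        if not present:
            per_stratum[name] = []
            tables[name] = pd.DataFrame(columns=["gene", "stat", "p", "q"])
            continue
        table = pseudotime_association(result, processed, present)
        tables[name] = table
        per_stratum[name] = sorted(table.loc[table["q"] < alpha, "gene"])

    donor_sets = [set(v) for k, v in per_stratum.items() if k != "pooled"]
    inter = sorted(set.intersection(*donor_sets)) if donor_sets else []
    return DamScanResult(
        input_genes=dam_genes,
        detected=sorted(detected_all),
        per_stratum=per_stratum,
        intersection=inter,
        tables=tables,
    )
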