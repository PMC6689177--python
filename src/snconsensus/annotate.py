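"""Marker-based cluster annotation and cell-type differential expression.

Dot-plot statistics (per-cluster mean expression and detection fraction
of marker genes) drive an explicit argmax annotation rule: each cell
type's score in a cluster is the mean, over its panel genes, of the
cluster-standardized mean expression; the top-scoring type wins, with
the margin to the runner-up reported and ties flagged.  Layer spans for
excitatory clusters come from cortical-layer marker panels.  The
browser's precomputed tables are one-vs-rest Wilcoxon rank-sum tests per
cell type (neuronal clusters merged), filtered at logFC > 0.01 and
Bonferroni-corrected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .containers import GeneExpressionMatrix, MarkerPanel
from .reduce_cluster import Clustering

logger = logging.getLogger(__name__)

NEURONAL_TYPES = ("excitatory", "inhibitory", "neuron")


@dataclass
class DotPlotStats:
    """Per (cluster, gene): mean normalized expression and detection fraction."""

    mean: pd.DataFrame  # index=cluster, columns=gene
    fraction: pd.DataFrame


@dataclass
class CellTypeAnnotation:
    labels: Dict[int, str]
    margins: Dict[int, float] = field(default_factory=dict)
    ties: Dict[int, bool] = field(default_factory=dict)
    subclasses: Dict[int, str] = field(default_factory=dict)
    layer_spans: Dict[int, str] = field(default_factory=dict)

    def __getitem__(self, cluster: int) -> str:
        return self.labels[cluster]


def dotplot_stats(
    m: GeneExpressionMatrix, c: Clustering, genes: Sequence[str]
) -> DotPlotStats:
    """Group means and nonzero fractions of the given genes per cluster."""
    genes = list(genes)
    if not genes:
        raise ValueError("empty gene list")
    idx = m.gene_index(genes)
    present = {m.gene_symbols[i] for i in idx} | {m.gene_ids[i] for i in idx}
    absent = [g for g in genes if g not in present]
    if absent:
        logger.warning("dotplot: %d genes absent, skipped: %s", len(absent), absent[:10])
    if len(idx) == 0:
        raise ValueError("none of the requested genes are present")
    X = np.asarray(m.csr()[idx, :].todense(), dtype=float).T  # cells x genes
    names = [m.gene_symbols[i] for i in idx]
    labels = c.assignment.loc[list(m.barcodes)].to_numpy()
    means, fracs = {}, {}
    for k in range(c.n_clusters):
        sub = X[labels == k]
        means[k] = sub.mean(axis=0) if len(sub) else np.zeros(len(idx))
        fracs[k] = (sub > 0).mean(axis=0) if len(sub) else np.zeros(len(idx))
    return DotPlotStats(
        mean=pd.DataFrame.from_dict(means, orient="index", columns=names),
        fraction=pd.DataFrame.from_dict(fracs, orient="index", columns=names),
    )


def _standardize_columns(df: pd.DataFrame) -> pd.DataFrame:
    sd = df.std(axis=0, ddof=0).replace(0, 1.0)
    return (df - df.mean(axis=0)) / sd


def assign_cell_types(d: DotPlotStats, panel: MarkerPanel) -> CellTypeAnnotation:
    """Argmax cell-type call per cluster from standardized marker means."""
    if len(panel.cell_types) < 2:
        raise ValueError("panel must cover at least 2 cell types")
    z = _standardize_columns(d.mean)
    labels: Dict[int, str] = {}
    margins: Dict[int, float] = {}
    ties: Dict[int, bool] = {}
    for cluster in d.mean.index:
        if d.mean.loc[cluster].sum() == 0:
            labels[cluster] = "unassigned"
            margins[cluster] = 0.0
            ties[cluster] = False
            continue
        scores = []
        for ct in panel.cell_types:
            genes = [g for g in panel.genes_for(ct) if g in z.columns]
            if not genes:
                continue
            scores.append((ct, float(z.loc[cluster, genes].mean())))
        if not scores:
            labels[cluster] = "unassigned"
            margins[cluster] = 0.0
            ties[cluster] = False
            continue
        best = max(scores, key=lambda t: t[1])  # stable: first max in panel order
        rest = sorted((s for _, s in scores), reverse=True)
        margin = rest[0] - rest[1] if len(rest) > 1 else np.inf
        labels[cluster] = best[0]
        margins[cluster] = float(margin)
        ties[cluster] = bool(margin == 0)
        if ties[cluster]:
            logger.warning("cluster %s: tied cell-type scores; panel order used", cluster)
    return CellTypeAnnotation(labels=labels, margins=margins, ties=ties)


def annotate_layers(
    d: DotPlotStats, layer_panel: MarkerPanel, fraction: float = 0.5
) -> Dict[int, Optional[str]]:
    """Cortical-layer span per cluster from layer-tagged markers.

    A layer qualifies when its marker score (mean expression of its
    markers) exceeds ``fraction`` of the cluster's maximum layer score;
    the span runs from the lowest to the highest qualifying layer.
    """
    tagged = layer_panel.with_layers()
    if len(tagged) == 0:
        raise ValueError("layer panel carries no layer tags")
    layer_names = sorted(pd.unique(tagged.entries["layer"]))
    spans: Dict[int, Optional[str]] = {}
    for cluster in d.mean.index:
        scores = {}
        for layer in layer_names:
            genes = [
                g for g in tagged.entries.loc[tagged.entries["layer"] == layer, "gene_symbol"]
                if g in d.mean.columns
            ]
            if genes:
                scores[layer] = float(d.mean.loc[cluster, genes].mean())
        if not scores or max(scores.values()) <= 0:
            spans[cluster] = None
            continue
        top = max(scores.values())
        qual = sorted(l for l, s in scores.items() if s > fraction * top)
        spans[cluster] = f"{qual[0]}..{qual[-1]}"
        if len(qual) == len(scores) and len(scores) > 1:
            logger.info("cluster %s: uniform layer scores; full span reported", cluster)
    return spans


def merge_neuronal_clusters(
    c: Clustering, a: CellTypeAnnotation
) -> pd.Series:
    """Group clusters by cell type, merging all neuronal clusters into one."""
    def group_of(cluster: int) -> str:
        ct = a.labels[cluster]
        return "neuron" if ct in NEURONAL_TYPES else ct

    return c.assignment.map(group_of)


def celltype_de(
    m: GeneExpressionMatrix,
    c: Clustering,
    a: CellTypeAnnotation,
    logfc_min: float = 0.01,
    min_cells: int = 3,
) -> pd.DataFrame:
    """One-vs-rest Wilcoxon rank-sum DE per cell-type group.

    logFC is the difference of natural-log-scale mean normalized
    expression (in-group minus rest).  Only genes with logFC >
    ``logfc_min`` are retained; Bonferroni multiplicity is the number of
    retained tests.
    """
    if m.layer != "normalized":
        raise ValueError("celltype_de expects a normalized-layer matrix")
    groups = merge_neuronal_clusters(c, a)
    X = np.asarray(m.csr().todense(), dtype=float)  # genes x cells
    cell_groups = groups.loc[list(m.barcodes)].to_numpy()
    names = [g for g in pd.unique(cell_groups)]
    rows = []
    for g in names:
        sel = cell_groups == g
        if sel.sum() < min_cells:
            logger.warning("group %r has %d nuclei (<%d); excluded", g, sel.sum(), min_cells)
            continue
        in_mean = X[:, sel].mean(axis=1)
        out_mean = X[:, ~sel].mean(axis=1)
        logfc = in_mean - out_mean
        keep = np.flatnonzero(logfc > logfc_min)
        for i in keep:
            stat = scipy.stats.ranksums(X[i, sel], X[i, ~sel])
            rows.append(
                dict(gene=m.gene_symbols[i], cell_type=g,
                     log_fc=float(logfc[i]), p=float(stat.pvalue))
            )
    table = pd.DataFrame(rows, columns=["gene", "cell_type", "log_fc", "p"])
    n_tests = len(table)
    table["p_adj"] = np.minimum(1.0, table["p"] * max(n_tests, 1))
    table.attrs["bonferroni_m"] = n_tests
    return table
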