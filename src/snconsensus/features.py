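"""Gene selection for clustering: pooled HVGs, marker lists, and ConGen.

Three strategies are compared throughout the toolkit:

* **CGS** (Classic Gene Set): binned-dispersion highly-variable-gene
  selection on all nuclei pooled — the conventional approach, which is
  vulnerable to donor batch effects (a gene that merely shifts between
  donors looks highly variable in the pool).
* **Hicat markers**: a curated marker panel restricted to the genes
  present in the matrix.
* **ConGen** (Consensus Gene Set): HVGs are selected independently
  within each donor and the per-donor sets intersected, so every
  retained gene is variable *within* every donor; donor-private
  variability is excluded by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted

from .containers import GeneExpressionMatrix, MarkerPanel

logger = logging.getLogger(__name__)


@dataclass
class HVGParams:
    """Cutoffs for binned-dispersion HVG selection (mean/dispersion plot).

    ``x_low_cutoff``/``x_high_cutoff`` bound the log1p mean-expression
    axis; ``y_cutoff`` is the minimum within-bin dispersion z-score;
    ``n_bins`` equal-width bins are placed on the mean axis.
    """

    x_low_cutoff: float = 0.0125
    x_high_cutoff: float = 3.0
    y_cutoff: float = 0.8
    n_bins: int = 20

    def __post_init__(self) -> None:
        if not self.x_low_cutoff < self.x_high_cutoff:
            raise ValueError("x_low_cutoff must be below x_high_cutoff")
        if self.n_bins < 2:
            raise ValueError("n_bins must be at least 2")


@dataclass
class VariableGeneSelection:
    method: str  # cgs | hicat | congen
    selected: List[str]
    per_sample_sets: Dict[str, List[str]] = field(default_factory=dict)
    params: Optional[HVGParams] = None

    def __post_init__(self) -> None:
        if self.method == "congen":
            inter = set(self.selected)
            for sample, genes in self.per_sample_sets.items():
                if not inter <= set(genes):
                    raise ValueError(
                        f"consensus set is not a subset of sample {sample!r} set"
                    )

    def __len__(self) -> int:
        return len(self.selected)


class BinnedDispersionSelector(SelectorMixin, BaseEstimator):
    """Mean/dispersion HVG selection over an (n_cells, n_genes) normalized matrix.

    Per gene the statistics are computed on the expm1 (linear) scale:
    ``mean = log1p(mean(expm1 x))`` and ``dispersion = log(var/mean)``.
    Genes are binned into equal-width bins of the mean; dispersions are
    z-scored within each bin; a gene is selected iff its mean lies
    strictly inside (x_low, x_high) and its z-scored dispersion exceeds
    y_cutoff.
    """

    def __init__(self, x_low_cutoff: float = 0.0125, x_high_cutoff: float = 3.0,
                 y_cutoff: float = 0.8, n_bins: int = 20):
        self.x_low_cutoff = x_low_cutoff
        self.x_high_cutoff = x_high_cutoff
        self.y_cutoff = y_cutoff
        self.n_bins = n_bins

    def fit(self, X, y=None):
        if sp.issparse(X):
            E = np.asarray(X.todense(), dtype=float)
        else:
            E = np.asarray(X, dtype=float)
        lin = np.expm1(E)
        lin_mean = lin.mean(axis=0)
        lin_var = lin.var(axis=0, ddof=0)
        self.means_ = np.log1p(lin_mean)
        with np.errstate(divide="ignore", invalid="ignore"):
            disp = np.where(lin_mean > 0, lin_var / lin_mean, 0.0)
            self.dispersions_ = np.where(disp > 0, np.log(disp), -np.inf)

        finite = np.isfinite(self.dispersions_)
        z = np.full(E.shape[1], -np.inf)
        if finite.any():
            m = self.means_
            lo, hi = m.min(), m.max()
            if hi > lo:
                edges = np.linspace(lo, hi, self.n_bins + 1)
                # ties at edges fall into the lower bin
                bins = np.clip(np.searchsorted(edges, m, side="left") - 1, 0, self.n_bins - 1)
            else:
                bins = np.zeros(E.shape[1], dtype=int)
            for b in np.unique(bins):
                idx = np.flatnonzero((bins == b) & finite)
                if len(idx) == 0:
                    continue
                if len(idx) == 1:
                    logger.warning("mean bin %d holds a single gene; z-score set to 0", b)
                    z[idx] = 0.0
                    continue
                d = self.dispersions_[idx]
                sd = d.std(ddof=0)
                z[idx] = (d - d.mean()) / sd if sd > 0 else 0.0
        self.dispersions_z_ = z
        self.support_ = (
            (self.means_ > self.x_low_cutoff)
            & (self.means_ < self.x_high_cutoff)
            & (z > self.y_cutoff)
        )
        self.n_features_in_ = E.shape[1]
        return self

    def _get_support_mask(self):
        check_is_fitted(self)
        return self.support_


def find_variable_genes(
    m: GeneExpressionMatrix, p: HVGParams = HVGParams()
) -> List[str]:
    """Binned-dispersion HVG selection on one (stratum of a) normalized matrix.

    Returns selected gene identifiers ordered by decreasing within-bin
    dispersion z-score.
    """
    if m.layer != "normalized":
        raise ValueError("find_variable_genes expects a normalized-layer matrix")
    sel = BinnedDispersionSelector(
        x_low_cutoff=p.x_low_cutoff,
        x_high_cutoff=p.x_high_cutoff,
        y_cutoff=p.y_cutoff,
        n_bins=p.n_bins,
    ).fit(m.values.T)
    idx = np.flatnonzero(sel.support_)
    order = idx[np.argsort(-sel.dispersions_z_[idx], kind="stable")]
    return [m.gene_ids[i] for i in order]


def select_cgs(m: GeneExpressionMatrix, p: HVGParams = HVGParams()) -> VariableGeneSelection:
    """Classic Gene Set: HVGs over all nuclei pooled."""
    return VariableGeneSelection(method="cgs", selected=find_variable_genes(m, p), params=p)


def select_congen(m: GeneExpressionMatrix, p: HVGParams = HVGParams()) -> VariableGeneSelection:
    """Consensus Gene Set: intersect per-sample HVG sets.

    Each sample stratum is selected on its own normalized statistics;
    the consensus keeps the genes variable in *every* sample, ordered as
    in the first sample's ranking.
    """
    samples = m.samples
    if len(samples) < 2:
        raise ValueError("ConGen requires at least 2 samples")
    per_sample: Dict[str, List[str]] = {}
    for sample in samples:
        sub = m.subset_cells(m.sample_labels == sample)
        per_sample[sample] = find_variable_genes(sub, p)
    inter = set(per_sample[samples[0]])
    for sample in samples[1:]:
        inter &= set(per_sample[sample])
    if not inter:
        raise ValueError(
            "empty consensus gene set; relax the HVG cutoffs (lower y_cutoff or widen the mean window)"
        )
    selected = [g for g in per_sample[samples[0]] if g in inter]
    return VariableGeneSelection(
        method="congen", selected=selected, per_sample_sets=per_sample, params=p
    )


def select_markers(m: GeneExpressionMatrix, panel: MarkerPanel) -> VariableGeneSelection:
    """Marker-panel selection: panel genes present in the matrix, panel order.

    Matching is exact (case-sensitive) on gene symbol, falling back to
    identifier; absent genes are logged.
    """
    if len(panel) == 0:
        raise ValueError("marker panel is empty")
    present_syms = set(m.gene_symbols) | set(m.gene_ids)
    selected_syms = [g for g in panel.genes if g in present_syms]
    absent = [g for g in panel.genes if g not in present_syms]
    if absent:
        logger.warning("%d panel genes absent from the matrix: %s", len(absent), absent[:20])
    if not selected_syms:
        raise ValueError("no marker-panel genes present in the matrix")
    idx = m.gene_index(selected_syms)
    return VariableGeneSelection(method="hicat", selected=[m.gene_ids[i] for i in idx])
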