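"""Nucleus- and gene-level quality control.

The cleaning sequence mirrors common droplet snRNA-seq practice:
mitochondrial genes are removed (their count fraction per nucleus is
retained as a regression covariate), genes detected in too few nuclei
are dropped, nuclei with too few or too many detected genes are
discarded, and the extreme upper tail of the per-nucleus UMI total is
removed per sample as presumptive multiplets.  Summary statistics,
reference-comparison arithmetic, a Gaussian-mixture modality check on
genes-per-nucleus, and a pseudobulk-vs-bulk correlation round out the
module.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats
from sklearn.mixture import GaussianMixture

from .containers import GeneExpressionMatrix

logger = logging.getLogger(__name__)


class EmptyResultError(ValueError):
    """A filter removed every gene or every nucleus."""


@dataclass
class QCThresholds:
    """Cleaning thresholds.

    Defaults follow the frozen-brain snRNA-seq regime: nuclei with
    1800–8000 detected genes are plausible single nuclei, genes must be
    seen in at least 3 nuclei, and the top 0.5% of per-sample UMI totals
    is treated as multiplets.
    """

    min_genes_per_cell: int = 1800
    max_genes_per_cell: int = 8000
    min_cells_per_gene: int = 3
    multiplet_top_fraction: float = 0.005
    mito_prefix: str = "MT-"

    def __post_init__(self) -> None:
        if not 0 < self.min_genes_per_cell < self.max_genes_per_cell:
            raise ValueError("need 0 < min_genes_per_cell < max_genes_per_cell")
        if not 0 <= self.multiplet_top_fraction < 1:
            raise ValueError("multiplet_top_fraction must be in [0, 1)")


@dataclass
class QCSummary:
    """Per-sample and pooled post-QC summary statistics."""

    per_sample: pd.DataFrame  # index=sample; columns: n_nuclei, median_umi, median_genes, total_genes
    pooled: pd.Series  # same columns

    def to_frame(self) -> pd.DataFrame:
        out = self.per_sample.copy()
        out.loc["All"] = self.pooled
        return out


@dataclass
class ReferenceComparison:
    percent_increase_nuclei: float
    percent_increase_median_umi: float
    percent_increase_median_genes: float
    chi_square_p: float


@dataclass
class MixtureFit:
    n_components: int
    means: np.ndarray
    stds: np.ndarray
    weights: np.ndarray
    bic: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------


def remove_mito_genes(
    m: GeneExpressionMatrix, t: QCThresholds = QCThresholds()
) -> tuple[GeneExpressionMatrix, np.ndarray]:
    """Drop mitochondrial genes; return the matrix and per-nucleus mito fraction.

    The fraction is computed *before* removal so it can later be
    regressed out of the normalized expression.
    """
    is_mito = np.asarray(
        [str(s).startswith(t.mito_prefix) for s in m.gene_symbols], dtype=bool
    )
    totals = m.counts_per_cell().astype(float)
    if is_mito.any():
        mito_counts = np.asarray(m.csr()[is_mito, :].sum(axis=0)).ravel().astype(float)
    else:
        mito_counts = np.zeros(m.n_cells)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(totals > 0, mito_counts / totals, 0.0)
    return m.subset_genes(~is_mito), frac


def filter_genes_by_cell_count(
    m: GeneExpressionMatrix, t: QCThresholds = QCThresholds()
) -> GeneExpressionMatrix:
    """Keep genes detected (nonzero) in at least ``min_cells_per_gene`` nuclei."""
    keep = m.cells_per_gene() >= t.min_cells_per_gene
    if not keep.any():
        raise EmptyResultError("gene filter removed every gene")
    return m.subset_genes(keep)


def filter_cells_by_gene_count(
    m: GeneExpressionMatrix, t: QCThresholds = QCThresholds()
) -> GeneExpressionMatrix:
    """Keep nuclei whose detected-gene count lies in [min, max] inclusive."""
    g = m.genes_per_cell()
    keep = (g >= t.min_genes_per_cell) & (g <= t.max_genes_per_cell)
    if not keep.any():
        raise EmptyResultError("cell filter removed every nucleus")
    return m.subset_cells(keep)


def remove_multiplets(
    m: GeneExpressionMatrix, t: QCThresholds = QCThresholds()
) -> GeneExpressionMatrix:
    """Remove, per sample, nuclei strictly above the (1 - f) nUMI quantile.

    The quantile is the linearly interpolated empirical quantile; ties at
    the threshold are kept.  Samples with fewer than ``1/f`` nuclei are
    left untouched (the tail is not resolvable) with a warning.
    """
    if t.multiplet_top_fraction == 0:
        return m
    totals = m.counts_per_cell().astype(float)
    keep = np.ones(m.n_cells, dtype=bool)
    labels = m.sample_labels
    for sample in pd.unique(labels):
        idx = np.flatnonzero(labels == sample)
        if len(idx) < 1.0 / t.multiplet_top_fraction:
            logger.warning(
                "sample %r has only %d nuclei; multiplet tail not resolvable, skipping",
                sample, len(idx),
            )
            continue
        cutoff = np.quantile(totals[idx], 1.0 - t.multiplet_top_fraction)
        keep[idx[totals[idx] > cutoff]] = False
    if not keep.any():
        raise EmptyResultError("multiplet filter removed every nucleus")
    return m.subset_cells(keep)


def apply_qc(
    m: GeneExpressionMatrix, t: QCThresholds = QCThresholds()
) -> tuple[GeneExpressionMatrix, np.ndarray]:
    """Full cleaning chain: mito removal -> gene filter -> cell filter -> multiplets.

    Returns the cleaned matrix and the per-surviving-nucleus
    mitochondrial fraction.
    """
    m1, mito = remove_mito_genes(m, t)
    mito = pd.Series(mito, index=m1.barcodes)
    m2 = filter_genes_by_cell_count(m1, t)
    m3 = filter_cells_by_gene_count(m2, t)
    m4 = remove_multiplets(m3, t)
    return m4, mito.loc[m4.barcodes].to_numpy()


# ---------------------------------------------------------------------------


def qc_summary(m: GeneExpressionMatrix) -> QCSummary:
    """Nuclei count, median UMI, median detected genes, total genes detected."""
    totals = m.counts_per_cell()
    genes = m.genes_per_cell()
    rows = {}
    for sample in m.samples:
        sel = m.sample_labels == sample
        sub = m.subset_cells(sel)
        rows[sample] = {
            "n_nuclei": int(sel.sum()),
            "median_umi": float(np.median(totals[sel])),
            "median_genes": float(np.median(genes[sel])),
            "total_genes": int((sub.cells_per_gene() > 0).sum()),
        }
    per_sample = pd.DataFrame.from_dict(rows, orient="index")
    pooled = pd.Series(
        {
            "n_nuclei": int(m.n_cells),
            "median_umi": float(np.median(totals)),
            "median_genes": float(np.median(genes)),
            "total_genes": int((m.cells_per_gene() > 0).sum()),
        }
    )
    assert pooled["n_nuclei"] == per_sample["n_nuclei"].sum()
    return QCSummary(per_sample=per_sample, pooled=pooled)


def pooled_summary(
    n_nuclei: float, median_umi: float, median_genes: float, total_genes: float = np.nan
) -> pd.Series:
    """Build a pooled summary row from already-tabulated statistics."""
    return pd.Series(
        {
            "n_nuclei": n_nuclei,
            "median_umi": median_umi,
            "median_genes": median_genes,
            "total_genes": total_genes,
        }
    )


def compare_quantifications(a, b) -> ReferenceComparison:
    """Percent increases of a over b, plus a chi-square test on nuclei counts.

    ``a`` and ``b`` are pooled summary rows (or QCSummary objects) for
    the same nuclei under two quantification references.  Each percent
    increase is 100*(a - b)/b.  The chi-square statistic is a 1-df
    goodness-of-fit of the two nuclei counts against equal expectation.
    """
    sa = a.pooled if isinstance(a, QCSummary) else a
    sb = b.pooled if isinstance(b, QCSummary) else b

    def pct(x, y):
        if y == 0:
            raise ValueError("zero denominator in percent-increase computation")
        return 100.0 * (x - y) / y

    na, nb = float(sa["n_nuclei"]), float(sb["n_nuclei"])
    chi2 = ((na - nb) ** 2) / (na + nb) if (na + nb) > 0 else 0.0
    p = float(scipy.stats.chi2.sf(chi2, df=1)) if chi2 > 0 else 1.0
    return ReferenceComparison(
        percent_increase_nuclei=pct(na, nb),
        percent_increase_median_umi=pct(float(sa["median_umi"]), float(sb["median_umi"])),
        percent_increase_median_genes=pct(
            float(sa["median_genes"]), float(sb["median_genes"])
        ),
        chi_square_p=max(p, np.finfo(float).tiny),
    )


def fit_gene_count_mixture(
    genes_per_nucleus: np.ndarray, max_k: int = 3, seed: int = 0
) -> MixtureFit:
    """Fit 1-D Gaussian mixtures for k=1..max_k; pick k by minimum BIC.

    Used to ask whether genes-per-nucleus is multi-modal (e.g., glia
    expressing fewer genes than neurons).
    """
    x = np.asarray(genes_per_nucleus, dtype=float).reshape(-1, 1)
    if len(x) < 10 * max_k:
        raise ValueError(f"need at least {10 * max_k} observations for max_k={max_k}")
    if np.ptp(x) == 0:
        return MixtureFit(1, np.array([x[0, 0]]), np.array([0.0]), np.array([1.0]), {1: -np.inf})
    bics: dict = {}
    fits: dict = {}
    for k in range(1, max_k + 1):
        gm = GaussianMixture(n_components=k, random_state=seed, n_init=3, reg_covar=1e-6)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                gm.fit(x)
            if not gm.converged_:
                logger.warning("EM did not converge for k=%d; excluded", k)
                continue
        except Exception as exc:  # pragma: no cover - numerical corner
            logger.warning("mixture fit failed for k=%d: %s", k, exc)
            continue
        bics[k] = float(gm.bic(x))
        fits[k] = gm
    if not bics:
        raise RuntimeError("no mixture size converged")
    best = min(bics, key=bics.get)
    gm = fits[best]
    order = np.argsort(gm.means_.ravel())
    return MixtureFit(
        n_components=best,
        means=gm.means_.ravel()[order],
        stds=np.sqrt(gm.covariances_.ravel()[order]),
        weights=gm.weights_[order],
        bic=bics,
    )


def pseudobulk_correlation(
    m: GeneExpressionMatrix, bulk: Mapping[str, float] | pd.Series
) -> float:
    """Pearson r between log1p-CPM pseudobulk and an identically scaled bulk vector.

    Pseudobulk is the per-gene count sum over all nuclei, normalized to
    counts-per-million and log1p-transformed; the bulk vector gets the
    same CPM + log1p treatment over the shared genes.
    """
    bulk = pd.Series(bulk, dtype=float)
    pseudo = pd.Series(
        np.asarray(m.values.sum(axis=1)).ravel().astype(float), index=m.gene_symbols
    )
    pseudo = pseudo.groupby(level=0).sum()
    shared = pseudo.index.intersection(bulk.index)
    if len(shared) < 2:
        raise ValueError(f"only {len(shared)} shared genes; need at least 2")

    def log_cpm(v: pd.Series) -> np.ndarray:
        tot = v.sum()
        if tot <= 0:
            raise ValueError("non-positive library total")
        return np.log1p(1e6 * v.to_numpy() / tot)

    r, _ = scipy.stats.pearsonr(log_cpm(pseudo.loc[shared]), log_cpm(bulk.loc[shared]))
    return float(r)
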