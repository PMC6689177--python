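"""Core in-memory containers for the toolkit.

The central object is :class:`GeneExpressionMatrix`, a labeled sparse
genes x nuclei matrix carrying the sample (donor) of origin for every
nucleus and a ``layer`` tag recording which processing stage the values
represent (raw counts, log-normalized, or regressed-and-scaled).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

LAYERS = ("counts", "normalized", "scaled")


class FormatError(ValueError):
    """Raised when an on-disk file or container violates its format contract."""


@dataclass
class GeneExpressionMatrix:
    """Sparse genes x nuclei expression matrix with sample-of-origin labels.

    Parameters
    ----------
    gene_ids:
        Stable gene identifiers, unique.
    gene_symbols:
        Gene symbols, same length as ``gene_ids`` (may repeat).
    barcodes:
        Nucleus identifiers, unique.
    sample_labels:
        Sample-of-origin tag per nucleus.
    values:
        Sparse (n_genes, n_nuclei) matrix.
    layer:
        One of ``counts``, ``normalized``, ``scaled``.
    """

    gene_ids: np.ndarray
    gene_symbols: np.ndarray
    barcodes: np.ndarray
    sample_labels: np.ndarray
    values: sp.spmatrix
    layer: str = "counts"

    def __post_init__(self) -> None:
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.gene_symbols = np.asarray(self.gene_symbols, dtype=object)
        self.barcodes = np.asarray(self.barcodes, dtype=object)
        self.sample_labels = np.asarray(self.sample_labels, dtype=object)
        if self.layer not in LAYERS:
            raise ValueError(f"unknown layer {self.layer!r}; expected one of {LAYERS}")
        if len(self.gene_ids) != len(self.gene_symbols):
            raise FormatError("gene_ids and gene_symbols differ in length")
        if len(self.sample_labels) != len(self.barcodes):
            raise FormatError("sample_labels length must equal number of barcodes")
        if not sp.issparse(self.values):
            self.values = sp.csr_matrix(np.asarray(self.values))
        if self.values.shape != (len(self.gene_ids), len(self.barcodes)):
            raise FormatError(
                f"values shape {self.values.shape} does not match "
                f"({len(self.gene_ids)} genes, {len(self.barcodes)} barcodes)"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise FormatError("gene_ids are not unique")
        if len(set(self.barcodes)) != len(self.barcodes):
            raise FormatError("barcodes are not unique")

    # -- basic geometry -------------------------------------------------
    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.barcodes)

    @property
    def samples(self) -> list:
        """Distinct sample labels in first-appearance order."""
        return list(pd.unique(self.sample_labels))

    def csr(self) -> sp.csr_matrix:
        return sp.csr_matrix(self.values)

    def csc(self) -> sp.csc_matrix:
        return sp.csc_matrix(self.values)

    def dense(self) -> np.ndarray:
        return np.asarray(self.values.todense())

    # -- subsetting ------------------------------------------------------
    def subset_genes(self, mask_or_index) -> "GeneExpressionMatrix":
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return replace(
            self,
            gene_ids=self.gene_ids[idx],
            gene_symbols=self.gene_symbols[idx],
            values=self.csr()[idx, :],
        )

    def subset_cells(self, mask_or_index) -> "GeneExpressionMatrix":
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return replace(
            self,
            barcodes=self.barcodes[idx],
            sample_labels=self.sample_labels[idx],
            values=self.csc()[:, idx],
        )

    def with_values(self, values, layer: str) -> "GeneExpressionMatrix":
        if not sp.issparse(values):
            values = sp.csr_matrix(np.asarray(values))
        return replace(self, values=values, layer=layer)

    def gene_index(self, symbols_or_ids: Iterable[str]) -> np.ndarray:
        """Row indices for the given identifiers (ids matched first, then symbols)."""
        by_id = {g: i for i, g in enumerate(self.gene_ids)}
        by_sym: dict = {}
        for i, s in enumerate(self.gene_symbols):
            by_sym.setdefault(s, i)
        out = []
        for name in symbols_or_ids:
            if name in by_id:
                out.append(by_id[name])
            elif name in by_sym:
                out.append(by_sym[name])
        return np.asarray(out, dtype=int)

    # -- per-axis summaries ---------------------------------------------
    def counts_per_cell(self) -> np.ndarray:
        return np.asarray(self.values.sum(axis=0)).ravel()

    def genes_per_cell(self) -> np.ndarray:
        return np.asarray((self.csc() != 0).sum(axis=0)).ravel()

    def cells_per_gene(self) -> np.ndarray:
        return np.asarray((self.csr() != 0).sum(axis=1)).ravel()


@dataclass
class MarkerPanel:
    """Curated marker-gene panel: gene symbol -> cell type (+ optional tags)."""

    entries: pd.DataFrame = field(default_factory=pd.DataFrame)

    REQUIRED = ("gene_symbol", "cell_type")
    OPTIONAL = ("layer", "subclass")

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.entries)
        for col in self.REQUIRED:
            if col not in df.columns:
                raise FormatError(f"marker panel missing required column {col!r}")
        for col in self.OPTIONAL:
            if col not in df.columns:
                df[col] = pd.NA
        df = df.drop_duplicates(subset=["gene_symbol", "cell_type"]).reset_index(drop=True)
        self.entries = df[list(self.REQUIRED + self.OPTIONAL)]

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def genes(self) -> list:
        return list(pd.unique(self.entries["gene_symbol"]))

    @property
    def cell_types(self) -> list:
        return list(pd.unique(self.entries["cell_type"]))

    def genes_for(self, cell_type: str) -> list:
        sel = self.entries["cell_type"] == cell_type
        return list(self.entries.loc[sel, "gene_symbol"])

    def with_layers(self) -> "MarkerPanel":
        """Sub-panel of entries carrying a layer tag."""
        sel = self.entries["layer"].notna()
        return MarkerPanel(self.entries.loc[sel].reset_index(drop=True))
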