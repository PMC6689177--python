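"""Readers and writers for 10x-style sparse triplets and marker panels.

Counts live on disk as a Matrix Market coordinate file (1-based indices,
genes as rows) next to ``barcodes.tsv`` and ``features.tsv`` /
``genes.tsv``, the dialect emitted by droplet quantifiers.  All readers
are gzip-transparent.
"""

from __future__ import annotations

import gzip
import logging
import os
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .containers import FormatError, GeneExpressionMatrix, MarkerPanel

logger = logging.getLogger(__name__)

_MATRIX_NAMES = ("matrix.mtx", "matrix.mtx.gz")
_BARCODE_NAMES = ("barcodes.tsv", "barcodes.tsv.gz")
_FEATURE_NAMES = ("features.tsv", "features.tsv.gz", "genes.tsv", "genes.tsv.gz")


def _find(directory: Path, names: Sequence[str], what: str) -> Path:
    for name in names:
        p = directory / name
        if p.exists():
            return p
    raise FileNotFoundError(f"no {what} file in {directory} (looked for {', '.join(names)})")


def _read_tsv(path: Path) -> pd.DataFrame:
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        return pd.read_csv(fh, sep="\t", header=None, dtype=str)


def read_10x_matrix(directory: os.PathLike | str) -> GeneExpressionMatrix:
    """Read a 10x-style triplet directory into a counts-layer matrix.

    The feature table may carry one column (id only; symbols default to
    ids) or two or more (id, symbol[, type]).  Row/column counts in the
    Matrix Market header must match the table lengths.
    """
    directory = Path(directory)
    mtx_path = _find(directory, _MATRIX_NAMES, "Matrix Market")
    bc_path = _find(directory, _BARCODE_NAMES, "barcode")
    ft_path = _find(directory, _FEATURE_NAMES, "feature")

    values = sp.csr_matrix(scipy.io.mmread(str(mtx_path)))
    barcodes = _read_tsv(bc_path)[0].to_numpy(dtype=object)
    feats = _read_tsv(ft_path)
    gene_ids = feats[0].to_numpy(dtype=object)
    gene_symbols = feats[1].to_numpy(dtype=object) if feats.shape[1] >= 2 else gene_ids.copy()

    if values.shape != (len(gene_ids), len(barcodes)):
        raise FormatError(
            f"matrix header {values.shape} does not match tables "
            f"({len(gene_ids)} features, {len(barcodes)} barcodes) in {directory}"
        )
    return GeneExpressionMatrix(
        gene_ids=gene_ids,
        gene_symbols=gene_symbols,
        barcodes=barcodes,
        sample_labels=np.asarray([""] * len(barcodes), dtype=object),
        values=values,
        layer="counts",
    )


def write_10x_matrix(m: GeneExpressionMatrix, directory: os.PathLike | str) -> None:
    """Write a matrix in the same triplet dialect ``read_10x_matrix`` reads."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    coo = sp.coo_matrix(m.values)
    if m.layer == "counts":
        coo = coo.astype(np.int64)
    scipy.io.mmwrite(str(directory / "matrix.mtx"), coo)
    pd.Series(m.barcodes).to_csv(directory / "barcodes.tsv", sep="\t", header=False, index=False)
    pd.DataFrame({"id": m.gene_ids, "symbol": m.gene_symbols}).to_csv(
        directory / "features.tsv", sep="\t", header=False, index=False
    )


def merge_samples(
    matrices: Sequence[GeneExpressionMatrix], labels: Sequence[str]
) -> GeneExpressionMatrix:
    """Combine per-sample count matrices into one pooled, labeled matrix.

    Genes are unioned by identifier (absent entries are zero); barcodes
    are prefixed ``<label>_`` so the pooled barcode set is unique; total
    count mass is conserved.
    """
    if len(matrices) != len(labels):
        raise ValueError("one label per matrix required")
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate sample labels: {list(labels)}")
    for m in matrices:
        if m.layer != "counts":
            raise ValueError("merge_samples requires counts-layer inputs")

    # union of gene ids in first-appearance order; symbols must agree
    gene_order: list = []
    symbol_of: dict = {}
    for m in matrices:
        for gid, sym in zip(m.gene_ids, m.gene_symbols):
            if gid not in symbol_of:
                symbol_of[gid] = sym
                gene_order.append(gid)
            elif symbol_of[gid] != sym:
                raise FormatError(f"conflicting symbols for gene {gid!r}: "
                                  f"{symbol_of[gid]!r} vs {sym!r}")
    row_of = {gid: i for i, gid in enumerate(gene_order)}

    blocks = []
    barcodes: list = []
    sample_labels: list = []
    n_genes = len(gene_order)
    for m, label in zip(matrices, labels):
        rows = np.asarray([row_of[g] for g in m.gene_ids])
        coo = sp.coo_matrix(m.values)
        block = sp.coo_matrix(
            (coo.data, (rows[coo.row], coo.col)), shape=(n_genes, m.n_cells)
        )
        blocks.append(block)
        barcodes.extend(f"{label}_{bc}" for bc in m.barcodes)
        sample_labels.extend([label] * m.n_cells)

    values = sp.hstack(blocks, format="csr")
    return GeneExpressionMatrix(
        gene_ids=np.asarray(gene_order, dtype=object),
        gene_symbols=np.asarray([symbol_of[g] for g in gene_order], dtype=object),
        barcodes=np.asarray(barcodes, dtype=object),
        sample_labels=np.asarray(sample_labels, dtype=object),
        values=values,
        layer="counts",
    )


def read_marker_panel(path: os.PathLike | str) -> MarkerPanel:
    """Read a TSV marker panel (gene_symbol, cell_type[, layer, subclass])."""
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"empty marker panel file: {path}") from exc
    cols = {c.strip().lower(): c for c in df.columns}
    rename = {}
    for want, aliases in {
        "gene_symbol": ("gene_symbol", "gene", "symbol"),
        "cell_type": ("cell_type", "celltype", "type"),
        "layer": ("layer", "cortical_layer"),
        "subclass": ("subclass", "neuron_subclass"),
    }.items():
        for a in aliases:
            if a in cols:
                rename[cols[a]] = want
                break
    df = df.rename(columns=rename)
    for col in MarkerPanel.REQUIRED:
        if col not in df.columns:
            raise FormatError(f"marker panel {path} missing required column {col!r}")
    if df.empty:
        raise FormatError(f"marker panel {path} has a header but no rows")
    known = set(MarkerPanel.REQUIRED) | set(MarkerPanel.OPTIONAL)
    extra = [c for c in df.columns if c not in known]
    if extra:
        logger.warning("marker panel %s: ignoring unknown columns %s", path, extra)
    n_before = len(df)
    panel = MarkerPanel(df[[c for c in df.columns if c in known]])
    if len(panel) < n_before:
        logger.warning(
            "marker panel %s: %d duplicate (gene, cell_type) rows dropped",
            path, n_before - len(panel),
        )
    return panel


def write_marker_panel(panel: MarkerPanel, path: os.PathLike | str) -> None:
    panel.entries.to_csv(path, sep="\t", index=False)
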