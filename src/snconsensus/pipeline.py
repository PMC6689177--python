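"""End-to-end orchestration: merge -> QC -> normalize -> select -> cluster -> evaluate.

``cluster_workflow`` is the in-memory engine used by tests and the
acceptance machinery; ``run_pipeline`` is the file-based front end that
reads 10x triplet directories, writes every tabular artifact, and
records parameters, seeds and input checksums in a JSON run log.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import List, Optional

import numpy as np
import pandas as pd

from . import annotate as ann
from . import evaluate as ev
from . import features as ft
from . import io as sn_io
from . import normalize as nm
from . import qc as qcmod
from . import reduce_cluster as rc
from .containers import GeneExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    input_dirs: List[str]
    labels: List[str]
    output_dir: str
    method: str = "congen"  # cgs | hicat | congen
    marker_panel: Optional[str] = None
    qc: qcmod.QCThresholds = field(default_factory=qcmod.QCThresholds)
    norm: nm.NormalizationParams = field(default_factory=nm.NormalizationParams)
    hvg: ft.HVGParams = field(default_factory=ft.HVGParams)
    n_pcs: int = 30
    use_jackstraw: bool = False
    jackstraw_replicates: int = 100
    jackstraw_prop: float = 0.1
    resolution: float = 0.6
    k_neighbors: int = 20
    entropy_threshold: float = 1.2
    compute_tsne: bool = False
    seed: int = 0


@dataclass
class WorkflowResult:
    matrix: GeneExpressionMatrix  # cleaned counts
    normalized: GeneExpressionMatrix
    scaled: GeneExpressionMatrix
    selection: ft.VariableGeneSelection
    pcs: rc.PCModel
    n_pcs_used: int
    clustering: rc.Clustering
    donor_table: ev.DonorClusterTable
    entropy: ev.ClusterEntropyReport
    mito_fraction: np.ndarray
    embedding: Optional[np.ndarray] = None


def cluster_workflow(
    matrix: GeneExpressionMatrix,
    method: str = "congen",
    marker_panel=None,
    qc_thresholds: Optional[qcmod.QCThresholds] = None,
    norm_params: Optional[nm.NormalizationParams] = None,
    hvg_params: Optional[ft.HVGParams] = None,
    n_pcs: int = 30,
    use_jackstraw: bool = False,
    jackstraw_replicates: int = 100,
    jackstraw_prop: float = 0.1,
    resolution: float = 0.6,
    k_neighbors: int = 20,
    entropy_threshold: float = 1.2,
    compute_tsne: bool = False,
    seed: int = 0,
    skip_qc: bool = False,
) -> WorkflowResult:
    """Run the clustering stack on an in-memory pooled counts matrix."""
    qc_thresholds = qc_thresholds or qcmod.QCThresholds()
    norm_params = norm_params or nm.NormalizationParams()
    hvg_params = hvg_params or ft.HVGParams()

    if skip_qc:
        cleaned, mito = qcmod.remove_mito_genes(matrix, qc_thresholds)
    else:
        cleaned, mito = qcmod.apply_qc(matrix, qc_thresholds)
    normalized = nm.log_normalize(cleaned, norm_params)
    cov = nm.Covariates(
        n_umi=cleaned.counts_per_cell().astype(float),
        mito_fraction=mito,
        sample_label=cleaned.sample_labels,
    )
    scaled = nm.regress_and_scale(normalized, cov, norm_params)

    if method == "cgs":
        selection = ft.select_cgs(normalized, hvg_params)
    elif method == "congen":
        selection = ft.select_congen(normalized, hvg_params)
    elif method == "hicat":
        if marker_panel is None:
            raise ValueError("method='hicat' requires a marker panel")
        selection = ft.select_markers(normalized, marker_panel)
    else:
        raise ValueError(f"unknown method {method!r}")

    max_pcs = min(len(selection.selected), scaled.n_cells) - 1
    n_comp = min(n_pcs, max_pcs)
    pcs = rc.run_pca(scaled, selection.selected, n=n_comp)
    if use_jackstraw:
        rc.jackstraw(
            pcs, scaled, selection.selected,
            replicates=jackstraw_replicates, prop=jackstraw_prop, seed=seed,
        )
        n_used = max(rc.choose_n_pcs(pcs), 2)
    else:
        n_used = n_comp
    scores = pcs.scores[:, :n_used]

    graph = rc.build_snn_graph(scores, k=min(k_neighbors, scaled.n_cells - 1))
    clustering = rc.cluster_graph(
        graph, scaled.barcodes, resolution=resolution,
        k_neighbors=k_neighbors, seed=seed,
    )
    donor_table = ev.donor_cluster_table(clustering, scaled.sample_labels)
    entropy = ev.cluster_entropy(donor_table, threshold=entropy_threshold)
    embedding = rc.run_tsne(scores, seed=seed) if compute_tsne else None

    return WorkflowResult(
        matrix=cleaned, normalized=normalized, scaled=scaled,
        selection=selection, pcs=pcs, n_pcs_used=n_used,
        clustering=clustering, donor_table=donor_table, entropy=entropy,
        mito_fraction=mito, embedding=embedding,
    )


def _checksum(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """File-based pipeline run; returns the artifact paths."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    matrices = [sn_io.read_10x_matrix(d) for d in config.input_dirs]
    pooled = sn_io.merge_samples(matrices, config.labels)
    panel = sn_io.read_marker_panel(config.marker_panel) if config.marker_panel else None

    result = cluster_workflow(
        pooled,
        method=config.method,
        marker_panel=panel,
        qc_thresholds=config.qc,
        norm_params=config.norm,
        hvg_params=config.hvg,
        n_pcs=config.n_pcs,
        use_jackstraw=config.use_jackstraw,
        jackstraw_replicates=config.jackstraw_replicates,
        jackstraw_prop=config.jackstraw_prop,
        resolution=config.resolution,
        k_neighbors=config.k_neighbors,
        entropy_threshold=config.entropy_threshold,
        compute_tsne=config.compute_tsne,
        seed=config.seed,
    )

    artifacts = {}

    summary = qcmod.qc_summary(result.matrix)
    p = out / "qc_summary.tsv"
    summary.to_frame().to_csv(p, sep="\t")
    artifacts["qc_summary"] = p

    p = out / "mito_fraction.tsv"
    pd.DataFrame(
        {"barcode": result.matrix.barcodes, "mito_fraction": result.mito_fraction}
    ).to_csv(p, sep="\t", index=False)
    artifacts["mito_fraction"] = p

    p = out / "selected_genes.tsv"
    pd.Series(result.selection.selected, name="gene").to_csv(p, sep="\t", index=False)
    artifacts["selected_genes"] = p
    if result.selection.per_sample_sets:
        p = out / "per_sample_genes.tsv"
        pd.DataFrame(
            [(s, g) for s, genes in result.selection.per_sample_sets.items() for g in genes],
            columns=["sample", "gene"],
        ).to_csv(p, sep="\t", index=False)
        artifacts["per_sample_genes"] = p

    p = out / "clusters.tsv"
    pd.DataFrame(
        {
            "barcode": result.clustering.assignment.index,
            "sample": result.scaled.sample_labels,
            "cluster": result.clustering.assignment.to_numpy(),
        }
    ).to_csv(p, sep="\t", index=False)
    artifacts["clusters"] = p

    p = out / "entropy.tsv"
    table4 = result.donor_table.percentages.copy()
    table4["entropy"] = result.entropy.entropy
    table4.to_csv(p, sep="\t")
    artifacts["entropy"] = p

    if result.embedding is not None:
        p = out / "tsne.tsv"
        pd.DataFrame(
            {
                "barcode": result.scaled.barcodes,
                "tsne1": result.embedding[:, 0],
                "tsne2": result.embedding[:, 1],
            }
        ).to_csv(p, sep="\t", index=False)
        artifacts["tsne"] = p

    if result.clustering.n_clusters >= 2:
        tree = rc.build_cluster_tree(
            result.normalized, result.clustering, result.selection.selected
        )
        p = out / "cluster_tree.nwk"
        p.write_text(tree.to_newick() + "\n")
        artifacts["cluster_tree"] = p

    if panel is not None:
        stats = ann.dotplot_stats(result.normalized, result.clustering, panel.genes)
        annotation = ann.assign_cell_types(stats, panel)
        p = out / "annotation.tsv"
        pd.DataFrame(
            {
                "cluster": list(annotation.labels),
                "cell_type": list(annotation.labels.values()),
                "margin": [annotation.margins[c] for c in annotation.labels],
                "tie": [annotation.ties[c] for c in annotation.labels],
            }
        ).to_csv(p, sep="\t", index=False)
        artifacts["annotation"] = p
        p = out / "dotplot.tsv"
        long = (
            stats.mean.stack().rename("mean").to_frame()
            .join(stats.fraction.stack().rename("fraction"))
            .reset_index(names=["cluster", "gene"])
        )
        long.to_csv(p, sep="\t", index=False)
        artifacts["dotplot"] = p

    runlog = {
        "config": _jsonable(asdict(config)),
        "inputs": {
            str(d): {
                f.name: _checksum(f)
                for f in sorted(Path(d).iterdir())
                if f.is_file()
            }
            for d in config.input_dirs
        },
        "n_cells_after_qc": int(result.matrix.n_cells),
        "n_genes_after_qc": int(result.matrix.n_genes),
        "n_selected_genes": len(result.selection.selected),
        "n_pcs_used": result.n_pcs_used,
        "n_clusters": result.clustering.n_clusters,
        "n_uneven_clusters": result.entropy.n_uneven,
    }
    p = out / "runlog.json"
    p.write_text(json.dumps(runlog, indent=2, sort_keys=True) + "\n")
    artifacts["runlog"] = p
    return artifacts


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
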