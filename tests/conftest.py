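import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from snconsensus import GeneExpressionMatrix, MarkerPanel


def make_matrix(counts, gene_symbols=None, samples=None, layer="counts"):
    """Build a GeneExpressionMatrix from a dense genes x cells array."""
    counts = np.asarray(counts)
    g, c = counts.shape
    gene_ids = [f"ENSG{i:03d}" for i in range(g)]
    if gene_symbols is None:
        gene_symbols = [f"GENE{i}" for i in range(g)]
    if samples is None:
        samples = ["S1"] * c
    return GeneExpressionMatrix(
        gene_ids=np.asarray(gene_ids, dtype=object),
        gene_symbols=np.asarray(gene_symbols, dtype=object),
        barcodes=np.asarray([f"BC{j:04d}" for j in range(c)], dtype=object),
        sample_labels=np.asarray(samples, dtype=object),
        values=sp.csr_matrix(counts),
        layer=layer,
    )


@pytest.fixture
def toy_counts():
    """5 genes x 4 nuclei with two mitochondrial genes and two samples."""
    counts = np.array(
        [
            [5, 0, 2, 1],   # MT-CO1
            [1, 1, 0, 0],   # MT-ND1
            [4, 2, 3, 1],
            [0, 3, 1, 2],
            [2, 0, 0, 4],
        ]
    )
    return make_matrix(
        counts,
        gene_symbols=["MT-CO1", "MT-ND1", "GAD1", "AQP4", "SLC17A7"],
        samples=["A", "A", "B", "B"],
    )


@pytest.fixture
def marker_panel():
    return MarkerPanel(
        pd.DataFrame(
            {
                "gene_symbol": ["GAD1", "SLC17A7", "AQP4"],
                "cell_type": ["inhibitory", "excitatory", "astrocyte"],
            }
        )
    )


@pytest.fixture(scope="session")
def small_fixture(tmp_path_factory):
    """Deterministic 200x300 fixture written in the 10x triplet dialect."""
    from snconsensus import make_fixture_small

    path = tmp_path_factory.mktemp("fixture10x")
    matrix, truth = make_fixture_small(path)
    return path, matrix, truth
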