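import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score, silhouette_score

import snconsensus as sc
from snconsensus.reduce_cluster import PCModel, cluster_snn_matrix

from conftest import make_matrix


def _scaled_matrix(X):
    """Wrap a cells x genes array as a scaled-layer container."""
    return make_matrix(X.T, layer="scaled")


class TestPCA:
    def test_rank_two_data(self):
        rng = np.random.default_rng(0)
        basis = rng.normal(size=(2, 12))
        X = rng.normal(size=(40, 2)) @ basis  # cells x genes, rank 2
        m = _scaled_matrix(X)
        model = sc.run_pca(m, list(m.gene_ids), n=6)
        assert model.stdevs[2:] == pytest.approx(0.0, abs=1e-8)

    def test_variance_conservation(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(30, 10))
        X[:, -1] = X[:, 0]  # rank <= 9, so 9 PCs carry all the variance
        m = _scaled_matrix(X)
        model = sc.run_pca(m, list(m.gene_ids), n=9)
        total = X.var(axis=0, ddof=1).sum()
        assert (model.stdevs**2).sum() == pytest.approx(total, rel=1e-6)

    def test_matches_eigendecomposition_up_to_sign(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(10, 8))
        m = _scaled_matrix(X)
        model = sc.run_pca(m, list(m.gene_ids), n=5)
        C = np.cov((X - X.mean(axis=0)).T)
        w, v = np.linalg.eigh(C)
        order = np.argsort(w)[::-1][:5]
        expected = (X - X.mean(axis=0)) @ v[:, order]
        for k in range(5):
            s = np.sign(np.dot(expected[:, k], model.scores[:, k]))
            np.testing.assert_allclose(
                s * expected[:, k], model.scores[:, k], atol=1e-8
            )

    def test_scores_orthogonal_and_n_too_large(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(20, 10))
        m = _scaled_matrix(X)
        model = sc.run_pca(m, list(m.gene_ids), n=5)
        G = model.scores.T @ model.scores
        off = G - np.diag(np.diag(G))
        assert np.abs(off).max() / np.abs(np.diag(G)).max() < 1e-6
        with pytest.raises(ValueError, match="exceeds"):
            sc.run_pca(m, list(m.gene_ids), n=10)


class TestJackstraw:
    def test_planted_factor_significant_only_on_pc1(self):
        rng = np.random.default_rng(4)
        factor = rng.normal(size=100)
        loadings = rng.normal(size=30)
        X = np.outer(factor, loadings) * 3 + rng.normal(size=(100, 30))
        X = (X - X.mean(axis=0)) / X.std(axis=0)  # scaled layer: unit variance
        m = _scaled_matrix(X)
        model = sc.run_pca(m, list(m.gene_ids), n=5)
        p = sc.jackstraw(model, m, list(m.gene_ids), replicates=50, prop=0.2, seed=0)
        assert p[0] < 0.01
        assert (p[1:] > 0.05).all()
        assert sc.choose_n_pcs(model, alpha=0.05) == 1

    def test_pure_noise_rarely_significant(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(80, 40))
        m = _scaled_matrix(X)
        model = sc.run_pca(m, list(m.gene_ids), n=6)
        p = sc.jackstraw(model, m, list(m.gene_ids), replicates=50, prop=0.2, seed=1)
        # Bonferroni across 6 PCs: none should survive
        assert (p * 6 > 0.05).all()

    def test_argument_errors(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(30, 10))
        m = _scaled_matrix(X)
        model = sc.run_pca(m, list(m.gene_ids), n=3)
        with pytest.raises(ValueError, match="replicates"):
            sc.jackstraw(model, m, list(m.gene_ids), replicates=0)
        with pytest.raises(ValueError, match="selects no genes"):
            sc.jackstraw(model, m, list(m.gene_ids), replicates=20, prop=0.001)


class TestChooseNPcs:
    def _model(self, pvals):
        k = len(pvals)
        return PCModel(
            loadings=np.zeros((5, k)), scores=np.zeros((5, k)),
            stdevs=np.linspace(2, 1, k), gene_ids=[],
            jackstraw_p=np.asarray(pvals),
        )

    def test_prefix_rule(self):
        assert sc.choose_n_pcs(self._model([0.001, 0.002, 0.3, 0.001])) == 2

    def test_all_significant(self):
        assert sc.choose_n_pcs(self._model([0.01] * 4)) == 4

    def test_none_significant_returns_zero(self):
        assert sc.choose_n_pcs(self._model([0.5, 0.9])) == 0


class TestSNNGraph:
    def test_two_blobs_no_cross_edges(self):
        rng = np.random.default_rng(7)
        pts = np.vstack([rng.normal(0, 0.1, (25, 2)), rng.normal(50, 0.1, (25, 2))])
        W = sc.build_snn_graph(pts, k=5)
        W = W.tocoo()
        assert not any((r < 25) != (c < 25) for r, c in zip(W.row, W.col))
        assert W.data.min() >= 0 and W.data.max() <= 1

    def test_full_k_gives_complete_graph_before_pruning(self):
        rng = np.random.default_rng(8)
        pts = rng.normal(size=(12, 3))
        W = sc.build_snn_graph(pts, k=11, prune=0.0)
        assert (W > 0).sum() == 12 * 11  # every ordered pair

    def test_k_must_be_below_n(self):
        with pytest.raises(ValueError):
            sc.build_snn_graph(np.zeros((5, 2)), k=5)


class TestClustering:
    def test_two_disconnected_cliques(self):
        import scipy.sparse as spm

        block = np.ones((6, 6)) - np.eye(6)
        W = spm.block_diag([block, block]).tocsr()
        for res in (0.2, 0.6, 1.0):
            labels = cluster_snn_matrix(W, resolution=res, seed=0)
            assert len(set(labels)) == 2
            assert len(set(labels[:6])) == 1 and len(set(labels[6:])) == 1

    def test_resolution_sweep_non_decreasing_endpoints(self, small_fixture):
        _, matrix, _ = small_fixture
        qc = sc.QCThresholds(min_genes_per_cell=10, max_genes_per_cell=10_000)
        res = sc.cluster_workflow(matrix, method="cgs", qc_thresholds=qc, seed=0)
        W = sc.build_snn_graph(res.pcs.scores[:, : res.n_pcs_used], k=20)
        k_low = len(set(cluster_snn_matrix(W, resolution=0.2, seed=0)))
        k_high = len(set(cluster_snn_matrix(W, resolution=1.2, seed=0)))
        assert k_high >= k_low

    def test_assignment_invariant_to_barcode_order(self):
        rng = np.random.default_rng(9)
        pts = np.vstack(
            [rng.normal(c, 0.3, (30, 3)) for c in ((0, 0, 0), (8, 0, 0), (0, 8, 0))]
        )
        model = sc.SNNLeidenClusterer(n_neighbors=10, random_state=0)
        base = model.fit_predict(pts)
        perm = rng.permutation(len(pts))
        permuted = sc.SNNLeidenClusterer(n_neighbors=10, random_state=0).fit_predict(
            pts[perm]
        )
        assert adjusted_rand_score(base[perm], permuted) == 1.0

    def test_clusterer_is_sklearn_compatible(self):
        model = sc.SNNLeidenClusterer(resolution=0.8)
        assert model.get_params()["resolution"] == 0.8
        model.set_params(resolution=0.4)
        assert model.resolution == 0.4


class TestTSNE:
    def test_deterministic_and_separates_blobs(self):
        rng = np.random.default_rng(10)
        pts = np.vstack([rng.normal(0, 0.5, (40, 5)), rng.normal(12, 0.5, (40, 5))])
        e1 = sc.run_tsne(pts, seed=3)
        e2 = sc.run_tsne(pts, seed=3)
        np.testing.assert_array_equal(e1, e2)
        labels = np.repeat([0, 1], 40)
        assert silhouette_score(e1, labels) > 0.5

    def test_small_n_auto_reduces_perplexity(self):
        rng = np.random.default_rng(11)
        emb = sc.run_tsne(rng.normal(size=(10, 4)), seed=0)
        assert emb.shape == (10, 2)


class TestClusterTree:
    def _clustering(self, labels):
        return sc.Clustering(
            assignment=pd.Series(labels, index=[f"BC{j:04d}" for j in range(len(labels))]),
            resolution=0.6, k_neighbors=20, seed=0,
        )

    def test_duplicated_clusters_merge_at_height_zero(self):
        X = np.tile(np.arange(5.0), (8, 1))  # 8 cells, identical profiles
        m = make_matrix(X.T, layer="normalized")
        tree = sc.build_cluster_tree(m, self._clustering([0] * 4 + [1] * 4), list(m.gene_ids))
        assert tree.linkage_matrix[0, 2] == pytest.approx(0.0)

    def test_hand_set_means(self):
        # cluster means at 0, 1, 10 on one gene: 0 and 1 merge first
        vals = np.array([[0.0, 0.0, 1.0, 1.0, 10.0, 10.0]])
        m = make_matrix(vals, layer="normalized")
        tree = sc.build_cluster_tree(m, self._clustering([0, 0, 1, 1, 2, 2]), list(m.gene_ids))
        first = sorted(tree.linkage_matrix[0, :2].astype(int))
        assert first == [0, 1]
        assert tree.linkage_matrix[0, 2] == pytest.approx(1.0)
        nwk = tree.to_newick()
        assert nwk.endswith(";") and "2" in nwk

    def test_single_cluster_error(self):
        m = make_matrix(np.ones((2, 3)), layer="normalized")
        with pytest.raises(ValueError, match="at least 2"):
            sc.build_cluster_tree(m, self._clustering([0, 0, 0]), list(m.gene_ids))
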