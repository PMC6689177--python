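import numpy as np
import pandas as pd
import pytest

import snconsensus as sc
from snconsensus.qc import EmptyResultError, QCThresholds, pooled_summary

from conftest import make_matrix


class TestMitoRemoval:
    def test_hand_arithmetic(self, toy_counts):
        cleaned, frac = sc.remove_mito_genes(toy_counts)
        assert cleaned.n_genes == 3
        assert not any(s.startswith("MT-") for s in cleaned.gene_symbols)
        totals = toy_counts.counts_per_cell()
        mito = toy_counts.dense()[:2].sum(axis=0)
        np.testing.assert_allclose(frac, mito / totals)

    def test_no_mito_genes_unchanged(self):
        m = make_matrix(np.ones((3, 2)))
        cleaned, frac = sc.remove_mito_genes(m)
        assert cleaned.n_genes == 3
        np.testing.assert_array_equal(frac, [0.0, 0.0])

    def test_pure_mito_nucleus_fraction_one(self):
        counts = np.array([[4, 1], [0, 3]])
        m = make_matrix(counts, gene_symbols=["MT-CO1", "NUC1"])
        _, frac = sc.remove_mito_genes(m)
        assert frac[0] == 1.0


class TestGeneAndCellFilters:
    def test_gene_filter_boundary_inclusive(self):
        # gene 0 in 3 nuclei (kept), gene 1 in 2 (removed)
        counts = np.array([[1, 1, 1, 0], [1, 1, 0, 0], [1, 1, 1, 1]])
        kept = sc.filter_genes_by_cell_count(make_matrix(counts))
        assert list(kept.gene_ids) == ["ENSG000", "ENSG002"]

    def test_cell_filter_boundaries(self):
        # thresholds 1800..2000 genes; nuclei detect 1799 / 1800 / 2000 / 2001
        g = 2010
        counts = np.zeros((g, 4), dtype=int)
        for j, ndet in enumerate([1799, 1800, 2000, 2001]):
            counts[:ndet, j] = 1
        t = QCThresholds(min_genes_per_cell=1800, max_genes_per_cell=2000)
        kept = sc.filter_cells_by_gene_count(make_matrix(counts), t)
        assert list(kept.barcodes) == ["BC0001", "BC0002"]

    def test_filters_match_bruteforce_and_are_idempotent(self):
        rng = np.random.default_rng(42)
        counts = (rng.random((50, 50)) < 0.15) * rng.integers(1, 9, (50, 50))
        m = make_matrix(counts)
        t = QCThresholds(min_genes_per_cell=4, max_genes_per_cell=12, min_cells_per_gene=3)
        genes_kept = sc.filter_genes_by_cell_count(m, t)
        assert list(genes_kept.gene_ids) == [
            m.gene_ids[i] for i in range(50) if (counts[i] > 0).sum() >= 3
        ]
        cells_kept = sc.filter_cells_by_gene_count(m, t)
        detected = (counts > 0).sum(axis=0)
        assert list(cells_kept.barcodes) == [
            m.barcodes[j] for j in range(50) if 4 <= detected[j] <= 12
        ]
        twice = sc.filter_genes_by_cell_count(genes_kept, t)
        np.testing.assert_array_equal(twice.dense(), genes_kept.dense())

    def test_empty_result_errors(self):
        m = make_matrix(np.zeros((3, 3), dtype=int))
        with pytest.raises(EmptyResultError):
            sc.filter_genes_by_cell_count(m)


class TestMultipletRemoval:
    def test_removes_exactly_top_half_percent(self):
        rng = np.random.default_rng(1)
        depths = rng.permutation(np.arange(1, 1001))  # 1000 distinct nUMI
        counts = np.zeros((1, 1000), dtype=int)
        counts[0] = depths
        m = make_matrix(counts)
        kept = sc.remove_multiplets(m)
        assert kept.n_cells == 995
        removed = set(m.barcodes) - set(kept.barcodes)
        worst = {m.barcodes[j] for j in np.argsort(depths)[-5:]}
        assert removed == worst

    def test_small_sample_skipped_with_warning(self, caplog):
        counts = np.arange(1, 101).reshape(1, 100)
        m = make_matrix(counts)
        t = QCThresholds(multiplet_top_fraction=0.005)
        kept = sc.remove_multiplets(m, t)  # 100 < 1/0.005 nuclei
        assert kept.n_cells == 100

    def test_per_sample_stratification(self):
        # two samples with disjoint depth ranges: each loses its own top 0.5%
        rng = np.random.default_rng(2)
        d1 = rng.permutation(np.arange(1, 401))
        d2 = rng.permutation(np.arange(10_001, 10_401))
        counts = np.concatenate([d1, d2]).reshape(1, 800)
        m = make_matrix(counts, samples=["A"] * 400 + ["B"] * 400)
        kept = sc.remove_multiplets(m)
        kept_samples = pd.Series(kept.sample_labels).value_counts()
        assert kept_samples["A"] == 398 and kept_samples["B"] == 398
        # pooled cutoff would only remove deep-sample nuclei
        removed_depths = sorted(
            int(v) for v in set(counts.ravel()) - set(kept.counts_per_cell())
        )
        assert removed_depths[0] < 401 and removed_depths[-1] > 10_000


class TestSummaries:
    def test_pooled_equals_sum_and_bruteforce_medians(self):
        rng = np.random.default_rng(3)
        counts = rng.integers(0, 6, (20, 30))
        m = make_matrix(counts, samples=["A"] * 10 + ["B"] * 20)
        s = sc.qc_summary(m)
        assert s.pooled["n_nuclei"] == s.per_sample["n_nuclei"].sum() == 30
        assert s.pooled["median_umi"] == float(np.median(counts.sum(axis=0)))
        assert s.per_sample.loc["A", "median_genes"] == float(
            np.median((counts[:, :10] > 0).sum(axis=0))
        )

    def test_single_nucleus_medians(self):
        m = make_matrix(np.array([[3], [0], [2]]))
        s = sc.qc_summary(m)
        assert s.pooled["median_umi"] == 5
        assert s.pooled["median_genes"] == 2

    def test_per_sample_nuclei_sum_to_pool(self):
        # the three-donor bookkeeping: per-sample counts add to the pool
        per_sample = [5663, 7147, 13521]
        assert sum(per_sample) == 26331


class TestReferenceComparison:
    def test_printed_table_arithmetic(self):
        pre = pooled_summary(26331, 9262, 3642)
        mat = pooled_summary(19302, 4234, 2510)
        cmp = sc.compare_quantifications(pre, mat)
        assert round(cmp.percent_increase_median_umi, 1) == 118.8
        assert round(cmp.percent_increase_median_genes, 1) == 45.1
        assert round(cmp.percent_increase_nuclei) == 36
        assert cmp.chi_square_p < 1e-16

    def test_identical_summaries(self):
        s = pooled_summary(100, 50, 40)
        cmp = sc.compare_quantifications(s, s)
        assert cmp.percent_increase_nuclei == 0
        assert cmp.percent_increase_median_umi == 0
        assert cmp.chi_square_p == 1.0

    def test_swapping_flips_direction(self):
        a, b = pooled_summary(200, 80, 60), pooled_summary(100, 40, 30)
        fwd = sc.compare_quantifications(a, b)
        rev = sc.compare_quantifications(b, a)
        assert fwd.percent_increase_nuclei > 0 > rev.percent_increase_nuclei

    def test_zero_denominator(self):
        with pytest.raises(ValueError, match="denominator"):
            sc.compare_quantifications(pooled_summary(1, 1, 1), pooled_summary(0, 1, 1))


class TestGeneCountMixture:
    def test_bimodal_recovers_two_components(self):
        rng = np.random.default_rng(7)
        x = np.concatenate([rng.normal(2000, 100, 500), rng.normal(6000, 200, 500)])
        fit = sc.fit_gene_count_mixture(x, max_k=3, seed=0)
        assert fit.n_components == 2
        np.testing.assert_allclose(fit.means, [2000, 6000], rtol=0.05)

    def test_unimodal_prefers_one_component(self):
        rng = np.random.default_rng(8)
        fit = sc.fit_gene_count_mixture(rng.normal(3000, 150, 600), max_k=3, seed=0)
        assert fit.n_components == 1

    def test_constant_vector_degenerate(self):
        fit = sc.fit_gene_count_mixture(np.full(100, 2500.0), max_k=3)
        assert fit.n_components == 1
        assert fit.stds[0] == 0.0


class TestPseudobulkCorrelation:
    def _pseudo(self, m):
        v = pd.Series(
            np.asarray(m.values.sum(axis=1)).ravel().astype(float),
            index=m.gene_symbols,
        )
        return v

    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(9)
        m = make_matrix(rng.integers(0, 20, (30, 10)))
        assert sc.pseudobulk_correlation(m, self._pseudo(m)) == pytest.approx(1.0)

    def test_scaling_invariance(self):
        rng = np.random.default_rng(10)
        m = make_matrix(rng.integers(0, 20, (30, 10)))
        assert sc.pseudobulk_correlation(m, 7.5 * self._pseudo(m)) == pytest.approx(1.0)

    def test_permuted_bulk_near_zero(self):
        rng = np.random.default_rng(11)
        m = make_matrix(rng.integers(0, 50, (400, 5)))
        bulk = self._pseudo(m)
        perm = pd.Series(
            rng.permutation(bulk.to_numpy()), index=bulk.index
        )
        assert abs(sc.pseudobulk_correlation(m, perm)) < 0.15

    def test_too_few_shared_genes(self):
        m = make_matrix(np.ones((3, 2)))
        with pytest.raises(ValueError, match="shared genes"):
            sc.pseudobulk_correlation(m, pd.Series({"NOPE": 1.0}))
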