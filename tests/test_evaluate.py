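import itertools

import numpy as np
import pandas as pd
import pytest

import snconsensus as sc
from snconsensus import DonorClusterTable, entropy_from_percentages

# Donor-by-cluster percentage table of the three-donor reference study
# (within-donor percentages; printed entropies in the last column).
TABLE4 = {
    0: ([17.36, 27.16, 18.76], 1.56),
    1: ([18.68, 17.01, 9.99], 1.54),
    2: ([9.27, 11.70, 10.69], 1.58),
    3: ([8.83, 3.86, 14.28], 1.41),
    4: ([9.34, 7.51, 8.65], 1.58),
    5: ([10.10, 7.43, 6.96], 1.56),
    6: ([7.77, 8.17, 6.69], 1.58),
    7: ([6.29, 6.95, 7.49], 1.58),
    8: ([6.20, 6.91, 3.78], 1.54),
    9: ([1.08, 0.74, 7.66], 0.89),
    10: ([2.95, 1.53, 1.96], 1.53),
    11: ([0.71, 0.53, 1.52], 1.43),
    12: ([1.32, 0.14, 1.38], 1.23),
    13: ([0.11, 0.35, 0.18], 1.42),
}

CLUSTER_TYPES = {
    0: "excitatory", 1: "excitatory", 2: "excitatory", 3: "excitatory",
    4: "excitatory", 8: "excitatory", 10: "excitatory",
    6: "inhibitory", 7: "inhibitory",
    5: "oligodendrocyte", 9: "astrocyte", 11: "microglia",
    12: "OPC", 13: "endothelial",
}


def _clustering(labels, barcodes=None):
    barcodes = barcodes or [f"c{j}" for j in range(len(labels))]
    return sc.Clustering(
        assignment=pd.Series(labels, index=barcodes),
        resolution=0.6, k_neighbors=20, seed=0,
    )


class TestDonorClusterTable:
    def test_single_cluster_percentages_are_hundred(self):
        labels = [0] * 100
        donors = ["A"] * 10 + ["B"] * 30 + ["C"] * 60
        t = sc.donor_cluster_table(_clustering(labels), donors)
        np.testing.assert_allclose(t.percentages.loc[0], [100.0, 100.0, 100.0])

    def test_columns_sum_to_hundred(self):
        rng = np.random.default_rng(0)
        labels = rng.integers(0, 4, 200)
        donors = rng.choice(["A", "B", "C"], 200)
        t = sc.donor_cluster_table(_clustering(labels), donors)
        np.testing.assert_allclose(t.percentages.sum(axis=0), [100.0] * 3)

    def test_matches_bruteforce_crosstab(self):
        rng = np.random.default_rng(1)
        labels = rng.integers(0, 3, 60)
        donors = rng.choice(["A", "B"], 60)
        t = sc.donor_cluster_table(_clustering(labels), donors)
        for k in range(3):
            for d in ("A", "B"):
                expect = sum(
                    1 for l, dn in zip(labels, donors) if l == k and dn == d
                )
                assert t.counts.loc[k, d] == expect


class TestClusterEntropy:
    @pytest.mark.parametrize(
        "pcts,printed",
        [(TABLE4[0][0], 1.56), (TABLE4[3][0], 1.41), (TABLE4[9][0], 0.89)],
    )
    def test_reproduces_printed_entropies(self, pcts, printed):
        assert round(entropy_from_percentages(pcts), 2) == printed

    def test_whole_reference_table_within_rounding(self):
        # inputs are printed at 2 d.p., so allow one unit in the last place
        for pcts, printed in TABLE4.values():
            assert abs(entropy_from_percentages(pcts) - printed) <= 0.011

    def test_extremes(self):
        assert entropy_from_percentages([10.0, 0.0, 0.0]) == 0.0
        assert entropy_from_percentages([5.5, 5.5, 5.5]) == pytest.approx(
            np.log2(3)
        )
        assert round(np.log2(3), 2) == 1.58

    def test_report_flags_and_bounds(self):
        pct = pd.DataFrame(
            {d: [TABLE4[c][0][i] for c in TABLE4] for i, d in enumerate("ABC")},
            index=list(TABLE4),
        )
        t = DonorClusterTable.from_percentages(pct)
        report = sc.cluster_entropy(t, threshold=1.2)
        assert report.h_max == pytest.approx(np.log2(3))
        assert (report.entropy <= report.h_max + 1e-12).all()
        assert report.uneven_clusters == [9]

    def test_donor_permutation_invariance_and_empty_stratum(self):
        base = [12.0, 3.0, 7.0]
        h = entropy_from_percentages(base)
        for perm in itertools.permutations(base):
            assert entropy_from_percentages(list(perm)) == pytest.approx(h)
        assert entropy_from_percentages(base + [0.0]) == pytest.approx(h)

    def test_uniform_maximizes(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            pcts = rng.uniform(0.1, 30, 3)
            assert entropy_from_percentages(pcts) <= np.log2(3) + 1e-12


class TestCoincidence:
    def test_identical_clusterings(self):
        rng = np.random.default_rng(3)
        labels = rng.integers(0, 4, 80)
        a = _clustering(labels)
        res = sc.coincidence(a, a)
        diag = res.pairs[res.pairs.cluster_a == res.pairs.cluster_b]
        assert (diag.jaccard == 1.0).all()
        np.testing.assert_allclose(diag.npmi, 1.0)
        off = res.pairs[res.pairs.cluster_a != res.pairs.cluster_b]
        assert (off.jaccard == 0.0).all()

    def test_independence_gives_zero_pmi(self):
        # x = half of N, y = half, overlap N/4
        labels_a = [0] * 50 + [1] * 50
        labels_b = ([0] * 25 + [1] * 25) * 2
        res = sc.coincidence(_clustering(labels_a), _clustering(labels_b))
        row = res.pairs.query("cluster_a == 0 and cluster_b == 0").iloc[0]
        assert row.pmi == pytest.approx(0.0, abs=1e-12)

    def test_hand_arithmetic_n12(self):
        # |x|=6, |y|=4, |x & y|=3 over N=12
        labels_a = [0] * 6 + [1] * 6
        labels_b = [0] * 3 + [1] * 3 + [1] * 5 + [0] * 1
        res = sc.coincidence(_clustering(labels_a), _clustering(labels_b))
        row = res.pairs.query("cluster_a == 0 and cluster_b == 0").iloc[0]
        assert row.n_both == 3
        assert row.jaccard == pytest.approx(3 / 7)
        assert row.pmi == pytest.approx(np.log(1.5))

    def test_symmetry_transposes(self):
        rng = np.random.default_rng(4)
        a = _clustering(rng.integers(0, 3, 60))
        b = _clustering(rng.integers(0, 4, 60))
        ab = sc.coincidence(a, b).matrix("jaccard")
        ba = sc.coincidence(b, a).matrix("jaccard")
        pd.testing.assert_frame_equal(
            ab, ba.T, check_names=False
        )

    def test_matches_set_enumeration_oracle(self):
        rng = np.random.default_rng(5)
        barcodes = [f"c{j}" for j in range(30)]
        la = rng.integers(0, 3, 30)
        lb = rng.integers(0, 4, 30)
        res = sc.coincidence(_clustering(la, barcodes), _clustering(lb, barcodes))
        for _, row in res.pairs.iterrows():
            x = {bc for bc, l in zip(barcodes, la) if l == row.cluster_a}
            y = {bc for bc, l in zip(barcodes, lb) if l == row.cluster_b}
            assert row.n_both == len(x & y)
            expect_j = len(x & y) / len(x | y)
            assert row.jaccard == pytest.approx(expect_j)
            if x & y:
                expect_pmi = np.log(
                    (len(x & y) / 30) / ((len(x) / 30) * (len(y) / 30))
                )
                assert row.pmi == pytest.approx(expect_pmi)
            else:
                assert np.isnan(row.pmi)

    def test_disjoint_universes_error(self):
        a = _clustering([0, 1], ["x1", "x2"])
        b = _clustering([0, 1], ["y1", "y2"])
        with pytest.raises(ValueError, match="share no barcodes"):
            sc.coincidence(a, b)


class TestCelltypeComposition:
    @pytest.fixture
    def table(self):
        pct = pd.DataFrame(
            {
                d: [TABLE4[c][0][i] for c in TABLE4]
                for i, d in enumerate(["Sample1", "Sample2", "Sample3"])
            },
            index=list(TABLE4),
        )
        return DonorClusterTable.from_percentages(pct)

    def test_reference_study_compositions(self, table):
        comp = sc.celltype_composition(table, CLUSTER_TYPES)
        assert comp.loc["inhibitory", "Sample1"] == pytest.approx(14.06)
        assert comp.loc["excitatory", "Sample2"] == pytest.approx(75.68)

    def test_single_type_gives_hundred(self):
        labels = [0] * 20 + [1] * 20
        donors = ["A", "B"] * 20
        t = sc.donor_cluster_table(_clustering(labels), donors)
        comp = sc.celltype_composition(t, {0: "neuron", 1: "neuron"})
        np.testing.assert_allclose(comp.loc["neuron"], [100.0, 100.0])

    def test_unannotated_cluster_error(self, table):
        partial = {k: v for k, v in CLUSTER_TYPES.items() if k != 13}
        with pytest.raises(ValueError, match="13"):
            sc.celltype_composition(table, partial)
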