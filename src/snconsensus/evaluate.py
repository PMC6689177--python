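"""Donor-evenness entropy and clustering coincidence analysis.

A cluster driven by biology should contain nuclei from every donor in
proportion to each donor's contribution; a cluster driven by a donor
batch effect is dominated by one donor.  The evenness of a cluster is
scored by the Shannon entropy (bits) of its donor-normalized membership
proportions: 0 when a single donor owns the cluster, log2(D) when the D
donors are evenly represented after correcting for their library sizes.
Clusters with entropy below a cutoff (default 1.2, against a 3-donor
maximum of log2 3 = 1.58) are flagged as uneven.

Two clusterings are compared pairwise with pointwise mutual information
(co-membership enrichment over independence) and the Jaccard index
(overlap fraction).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .reduce_cluster import Clustering


@dataclass
class DonorClusterTable:
    """Per-(cluster, donor) nucleus counts and within-donor percentages."""

    counts: pd.DataFrame  # index=cluster, columns=donor
    donor_totals: pd.Series

    @property
    def percentages(self) -> pd.DataFrame:
        """100 * n_dc / N_d: percentage of donor d's nuclei that sit in cluster c."""
        return 100.0 * self.counts / self.donor_totals

    @classmethod
    def from_percentages(
        cls, percentages: pd.DataFrame, donor_totals: Optional[pd.Series] = None
    ) -> "DonorClusterTable":
        """Rebuild a table from already-tabulated within-donor percentages."""
        pct = pd.DataFrame(percentages, dtype=float)
        if donor_totals is None:
            donor_totals = pd.Series(100.0, index=pct.columns)
        counts = pct * donor_totals / 100.0
        return cls(counts=counts, donor_totals=pd.Series(donor_totals, dtype=float))


@dataclass
class ClusterEntropyReport:
    """Per-cluster donor-evenness entropies and flags."""

    table: pd.DataFrame  # index=cluster; donor-normalized p columns + entropy columns
    threshold: float
    h_max: float

    @property
    def entropy(self) -> pd.Series:
        return self.table["entropy"]

    @property
    def uneven_clusters(self) -> list:
        return list(self.table.index[~self.table["even"]])

    @property
    def n_uneven(self) -> int:
        return int((~self.table["even"]).sum())


@dataclass
class CoincidenceResult:
    pairs: pd.DataFrame  # cluster_a, cluster_b, n_a, n_b, n_both, jaccard, pmi, npmi
    n_shared: int

    def matrix(self, value: str = "jaccard") -> pd.DataFrame:
        return self.pairs.pivot(index="cluster_a", columns="cluster_b", values=value)


# ---------------------------------------------------------------------------


def donor_cluster_table(
    c: Clustering, sample_labels: Optional[Mapping | Sequence] = None
) -> DonorClusterTable:
    """Cross-tabulate cluster membership against donor of origin."""
    if sample_labels is None:
        raise ValueError("sample labels are required")
    labels = pd.Series(np.asarray(sample_labels, dtype=object), index=c.assignment.index)
    counts = (
        pd.crosstab(c.assignment, labels)
        .reindex(range(c.n_clusters), fill_value=0)
        .rename_axis(index="cluster", columns="donor")
    )
    return DonorClusterTable(counts=counts, donor_totals=counts.sum(axis=0).astype(float))


def shannon_entropy_bits(p: np.ndarray) -> float:
    """-sum p log2 p with 0 log 0 := 0."""
    p = np.asarray(p, dtype=float)
    p = p[p > 0]
    return float(max(0.0, -(p * np.log2(p)).sum()))


def cluster_entropy(
    t: DonorClusterTable, threshold: float = 1.2
) -> ClusterEntropyReport:
    """Donor-evenness entropy per cluster.

    The probability of donor i in a cluster is its within-donor
    percentage renormalized over donors, so a donor contributing few
    nuclei overall is not penalized for being small.  The raw-fraction
    entropy (share of the cluster's nuclei per donor, unnormalized for
    donor size) is reported as a secondary column.
    """
    pct = t.percentages
    if pct.shape[1] < 2:
        raise ValueError("entropy needs at least 2 donors")
    h_max = float(np.log2(pct.shape[1]))
    rows = {}
    for cluster, row in pct.iterrows():
        s = row.sum()
        if s == 0:
            rows[cluster] = dict.fromkeys(
                [f"p[{d}]" for d in pct.columns] + ["entropy", "entropy_raw"], np.nan
            )
            rows[cluster]["even"] = False
            continue
        p = (row / s).to_numpy()
        raw_counts = t.counts.loc[cluster].to_numpy(dtype=float)
        raw = raw_counts / raw_counts.sum() if raw_counts.sum() > 0 else p
        h = shannon_entropy_bits(p)
        rows[cluster] = {f"p[{d}]": p[i] for i, d in enumerate(pct.columns)}
        rows[cluster]["entropy"] = h
        rows[cluster]["entropy_raw"] = shannon_entropy_bits(raw)
        rows[cluster]["even"] = bool(h > threshold)
    table = pd.DataFrame.from_dict(rows, orient="index")
    return ClusterEntropyReport(table=table, threshold=threshold, h_max=h_max)


def entropy_from_percentages(percentages: Sequence[float]) -> float:
    """Entropy (bits) of one cluster row of within-donor percentages."""
    p = np.asarray(percentages, dtype=float)
    if p.sum() <= 0:
        raise ValueError("percentages sum to zero")
    return shannon_entropy_bits(p / p.sum())


# ---------------------------------------------------------------------------


def coincidence(a: Clustering, b: Clustering) -> CoincidenceResult:
    """Exhaustive pairwise cluster comparison between two clusterings.

    Over the shared barcode universe N: pmi(x, y) = log(p(x,y) /
    (p(x) p(y))) with natural log, npmi = pmi / (-log p(x,y)), and the
    Jaccard index |x n y| / |x u y|.  Pairs with empty intersection get
    jaccard 0 and missing pmi/npmi.
    """
    shared = a.assignment.index.intersection(b.assignment.index)
    n = len(shared)
    if n == 0:
        raise ValueError("the two clusterings share no barcodes")
    la = a.assignment.loc[shared]
    lb = b.assignment.loc[shared]
    ct = pd.crosstab(la, lb)
    rows = []
    for x in range(a.n_clusters):
        nx = int((la == x).sum())
        for y in range(b.n_clusters):
            ny = int((lb == y).sum())
            nxy = int(ct.loc[x, y]) if (x in ct.index and y in ct.columns) else 0
            union = nx + ny - nxy
            jac = nxy / union if union > 0 else 0.0
            if nxy > 0:
                pxy, px, py = nxy / n, nx / n, ny / n
                pmi = float(np.log(pxy / (px * py)))
                npmi = float(pmi / (-np.log(pxy))) if pxy < 1 else 1.0
            else:
                pmi = np.nan
                npmi = np.nan
            rows.append(
                dict(cluster_a=x, cluster_b=y, n_a=nx, n_b=ny, n_both=nxy,
                     jaccard=jac, pmi=pmi, npmi=npmi)
            )
    return CoincidenceResult(pairs=pd.DataFrame(rows), n_shared=n)


def celltype_composition(
    t: DonorClusterTable, annotation: Mapping[int, str]
) -> pd.DataFrame:
    """Within-donor percentages summed over clusters sharing a cell-type label."""
    missing = [c for c in t.counts.index if c not in annotation]
    if missing:
        raise ValueError(f"unannotated clusters: {missing}")
    pct = t.percentages.copy()
    pct["cell_type"] = [annotation[c] for c in pct.index]
    return pct.groupby("cell_type").sum()
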