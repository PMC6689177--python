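# snconsensus

A toolkit for clustering pooled **single-nuclei RNA-seq** data from
multiple donors without letting donor identity drive the clusters.

When nuclei from several brains are pooled and clustered with the
standard recipe — highly-variable-gene (HVG) selection, PCA, shared
nearest-neighbor (SNN) graph, modularity communities — some clusters
routinely turn out to be donor artifacts: a gene that merely *shifts*
between donors looks highly variable in the pool, gets selected as a
clustering feature, and splits a real cell type by donor. This package
implements a donor-aware alternative and the diagnostics to measure the
problem:

- **ConGen (Consensus Gene Set)** — HVGs are selected independently
  within each donor (binned-dispersion selection; cutoffs
  `x.low = 0.0125`, `x.high = 3`, `y = 0.8`) and the per-donor sets are
  intersected, so every clustering feature is variable *within* every
  donor. Pooled selection (**CGS**) and curated marker panels
  (**Hicat**-style) are provided for comparison.
- **Donor-evenness entropy** — for each cluster, the Shannon entropy
  (bits) of its donor-normalized membership proportions,

  &nbsp;&nbsp;&nbsp;&nbsp;*Ĥ = −Σᵢ p(i) log₂ p(i)*,

  where *p(i)* is donor *i*'s within-donor percentage renormalized over
  donors. *Ĥ* = 0 means a single-donor cluster; log₂ *D* (1.58 for three
  donors) means perfect evenness; clusters with *Ĥ* ≤ 1.2 are flagged
  as donor-biased.
- **Coincidence analysis** — exhaustive pairwise comparison of two
  clusterings by pointwise mutual information,
  *pmi(x,y) = log p(x,y)/(p(x)p(y))* (with its normalized variant), and
  the Jaccard index |x∩y|/|x∪y|.
- The full supporting stack: 10x triplet IO, QC filters (mito removal,
  ≥3-cell gene filter, 1800–8000 genes/cell, per-sample top-0.5% nUMI
  multiplet removal), log-normalization with covariate regression,
  seeded SNN/Leiden clustering and tSNE, dot-plot-based cell-type and
  cortical-layer annotation, one-vs-rest Wilcoxon differential
  expression with Bonferroni correction, and MST pseudotime with
  per-donor gene-association scans (for disease-associated microglia
  signatures and the like).
- A **synthetic-data generator** that plants cell types, donor batch
  effects, donor-private cell states, library-size variation, dropout
  and latent trajectories, so every stage is testable without access to
  tissue data.

The numeric stages are scikit-learn estimators (`LogNormalizer`,
`CovariateScaler`, `BinnedDispersionSelector`, `SNNLeidenClusterer`,
`MSTPseudotime`) and compose with sklearn pipelines; the module-level
functions wrap them around a labeled sparse `GeneExpressionMatrix`.

## Worked example

```python
import snconsensus as snc

# three donors, 8 planted cell types, donor batch effects switched on
matrix, truth = snc.simulate_counts(snc.reference_spec(seed=0))

qc = snc.QCThresholds(min_genes_per_cell=50, max_genes_per_cell=100_000)
cgs    = snc.cluster_workflow(matrix, method="cgs",    qc_thresholds=qc, seed=0)
congen = snc.cluster_workflow(matrix, method="congen", qc_thresholds=qc, seed=0)

for name, res in [("CGS", cgs), ("ConGen", congen)]:
    print(f"{name}: {res.clustering.n_clusters} clusters, "
          f"{res.entropy.n_uneven} with entropy < 1.2, "
          f"min entropy {res.entropy.entropy.min():.2f}")
```

prints

```
CGS: 11 clusters, 6 with entropy < 1.2, min entropy 0.00
ConGen: 8 clusters, 0 with entropy < 1.2, min entropy 1.54
```

Eight cell types were planted. Pooled HVG selection picks up
donor-variable genes and splits types by donor — six of its eleven
clusters fail the evenness cutoff, the worst being a pure single-donor
cluster (entropy 0.00 bits against a maximum of 1.58). The consensus
intersection recovers exactly the eight planted types, all donor-even.

A command-line interface exposes each stage (`snconsensus simulate`,
`qc`, `select-genes`, `run`, `entropy`, `coincide`, `dam-scan`); every
run writes its parameters, seeds and input checksums to a JSON run log.

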