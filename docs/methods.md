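# Methods

This note documents the models, conventions and numerical choices behind
`snconsensus`, in the order the pipeline runs them, followed by the
synthetic-data model used for validation and the limitations of both.

## Quality control

Cleaning runs in a fixed order: mitochondrial-gene removal → gene filter
→ cell filter → multiplet removal. Each step is idempotent.

- **Mitochondrial genes** are identified by the `MT-` symbol prefix and
  removed from the matrix; the per-nucleus mitochondrial count
  *fraction* is computed before removal and kept as a regression
  covariate. Removing the genes is treated as a feature operation, not
  a cell filter.
- **Gene filter**: a gene is kept iff it is detected (nonzero) in at
  least `min_cells_per_gene` nuclei (default 3, inclusive).
- **Cell filter**: a nucleus is kept iff its detected-gene count lies in
  `[min_genes_per_cell, max_genes_per_cell]` (defaults 1800 and 8000,
  both inclusive — "fewer than 1800" and "more than 8000" are
  discarded). These defaults suit deeply sequenced frozen-brain nuclei
  and must be lowered for shallow or simulated libraries.
- **Multiplet removal** drops, *within each sample*, nuclei whose total
  UMI count is strictly above the empirical
  (1 − `multiplet_top_fraction`) quantile (default top 0.5%; linear
  interpolation; ties at the threshold kept). Per-sample stratification
  matters because donors can differ several-fold in depth: a pooled
  cutoff would remove nuclei only from the deepest donor. A sample with
  fewer than `1/fraction` nuclei is left untouched — the tail is not
  resolvable — with a warning.

A Gaussian-mixture modality check (`fit_gene_count_mixture`, EM for
k = 1..max_k, minimum BIC, seeded) asks whether genes-per-nucleus is
multi-modal, as expected when glia express fewer genes than neurons.
Pseudobulk-vs-bulk agreement is Pearson correlation of log1p CPM of the
per-gene count sums against an identically transformed bulk vector over
shared gene symbols.

The comparison between two quantification references reports percent
increases 100·(a−b)/b of nuclei count and median UMI/genes, plus a 1-df
chi-square goodness-of-fit of the two nuclei counts against equal
expectation. No test on medians is offered: a t-test on a pair of
medians is not a defined procedure, so that quantity is reported
descriptively only.

## Normalization and covariate regression

`LogNormalizer` computes x′ = log(1 + x·s/T_c), with T_c the nucleus
total and s the scale factor — by default the **median of per-nucleus
totals** (a per-gene median would be ≈0 in sparse data and break the
rescaling semantics). Natural log throughout, so downstream fold
changes are in natural-log units.

`CovariateScaler` then regresses each gene (OLS) on intercept, nUMI
(raw, not log), mitochondrial fraction and one-hot sample indicators
(reference level dropped; collinear columns dropped with a warning),
and z-scores the residuals with clipping at ±10. Clipping bounds the
leverage of outlier nuclei on PCA; genes with numerically zero residual
variance are set to 0. The scaler stores coefficients and residual
moments, so it can transform held-out cells given their covariates.

## Variable-gene selection

`BinnedDispersionSelector` reproduces the classic mean/dispersion
selection: per gene, mean = log1p(mean of expm1(x)) and dispersion =
log(variance/mean of the expm1-scale values); genes are split into
`n_bins = 20` equal-width bins of the mean (ties at edges fall to the
lower bin); dispersions are z-scored within bins (a single-gene bin
gets z = 0 with a warning); a gene is selected iff
`x_low < mean < x_high` and z > `y_cutoff` (defaults 0.0125, 3, 0.8).

Three strategies share this primitive:

- **CGS** runs it on all nuclei pooled.
- **Hicat markers** bypasses it: the selection is the marker panel's
  genes present in the matrix, in panel order, matched exactly
  (case-sensitive) on symbol with identifier fallback.
- **ConGen** runs it per donor stratum — each donor normalized within
  itself — and intersects the per-donor sets, matching on gene
  identifier. The consensus is ordered by the first donor's ranking.
  An empty intersection raises an error advising relaxed cutoffs.

## PCA, PC selection, clustering

PCA (full SVD, deterministic) runs on the scaled submatrix of selected
genes, with the sign convention that each PC's largest-|loading| entry
is positive. The jackstraw test permutes a fraction (default 10%) of
the selected genes across nuclei, **refits** the PCA, and uses the
permuted genes' refit loadings as the per-PC null; refitting matters
because an eigendecomposition inflates its own genes' loadings, so a
null projected onto fixed scores is anti-conservative. Observed vs
null |loadings| are compared per PC by a one-sided Mann-Whitney test,
and the number of PCs retained is the longest prefix with p < α (the
elbow statistic — the largest drop in the stdev curve — is logged
alongside).

The SNN graph connects each cell to its k = 20 nearest neighbors in PC
space (Euclidean, self included); edge weights are Jaccard overlaps of
neighborhoods, pruned below 1/15. Communities come from seeded Leiden
optimization of resolution-parameterized modularity (RBConfiguration,
resolution 0.6 by default); clusters are relabeled by decreasing size.
tSNE embeddings (seeded, perplexity auto-reduced for tiny inputs) are
for visualization only. The cluster dendrogram is average-linkage
agglomeration of Euclidean distances between cluster mean-expression
profiles over the selected genes, exportable as Newick.

## Donor-evenness entropy

For cluster c with donor counts n_dc and donor totals N_d, the
within-donor percentage is 100·n_dc/N_d. The entropy uses the
**donor-size-normalized convention**: p(i) is donor i's within-donor
percentage renormalized to sum to 1 over donors, and
Ĥ = −Σ p(i) log₂ p(i), in bits, with 0·log 0 = 0. This convention —
rather than the raw share of the cluster's nuclei per donor — is what
reproduces the reference study's printed per-cluster entropies (e.g., a
cluster at percentages 1.08/0.74/7.66 gives 0.89 bits; raw fractions
would give ≈0.57). The raw-fraction entropy is exported as a secondary
column so either reading is available. The evenness flag is Ĥ > 1.2
against a three-donor maximum of log₂ 3 ≈ 1.58.

## Coincidence analysis

Over the shared barcode universe of two clusterings (size N, logged),
each cluster pair (x, y) gets pmi = ln(p(x,y)/(p(x)p(y))),
npmi = pmi/(−ln p(x,y)) ∈ [−1, 1], and Jaccard |x∩y|/|x∪y|, with
counts. Empty intersections report Jaccard 0 and missing pmi/npmi.
Natural log for pmi (the base only rescales); npmi is exported because
its boundedness aids cross-pair comparison (color = npmi, size =
Jaccard in the plot-data export).

## Annotation and differential expression

Dot-plot statistics are per-(cluster, gene) mean normalized expression
and detection fraction. Cell-type calls use an explicit argmax rule:
each type's score in a cluster is the mean over its panel genes of the
cluster-standardized mean expression (standardization makes the call
invariant to per-gene affine rescaling); the margin to the runner-up is
reported, exact ties go to panel order and are flagged, all-zero
clusters are "unassigned". Manual dot-plot reading is the field's
practice; the argmax rule is its auditable formalization. Layer spans
take all layers whose marker score exceeds half the cluster's maximum
layer score, reported as min..max.

For the browser tables, clusters are grouped by cell type with all
neuronal clusters merged into one group; per group, one-vs-rest
two-sided Wilcoxon rank-sum tests are computed for genes whose logFC
(difference of natural-log-scale means, in-group minus rest) exceeds
0.01, and Bonferroni correction uses the number of retained tests
(recorded in the table metadata). One-vs-rest (rather than all-pairs)
is the reading consistent with per-group marker tables.

## Pseudotime and the marker scan

Preprocessing drops genes detected in < 10% of the subset's cells,
transforms to log₂(CPM + 1), and drops zero-variance genes. Cells are
embedded in 2 PCs; Gaussian mixtures with k = 1..max_k (full
covariance, seeded, BIC-selected) define states — the ordering chain
constrains k ≥ 2, since a spanning tree needs two vertices. The MST
over state means (Euclidean) is reduced to its longest (diameter) path;
each cell is projected orthogonally onto its state's incident path
edges (off-path states attach to their nearest path vertex), and
pseudotime is cumulative arc length. Terminal edges extrapolate beyond
the end vertices so tail cells keep distinct positions; orientation is
arbitrary but deterministic given the seed.

Gene-pseudotime association is a fixed-3-df cubic trend (orthogonalized
1, t, t², t³ basis) tested against intercept-only by an F-test —
a deterministic stand-in for a free-knot smoother, adequate for
monotone or single-bump profiles — with Benjamini-Hochberg q-values.
Constant genes get p = 1.

Two caveats govern interpretation of the association p-values. First,
testing a gene against an ordering that was *built from that gene* is
circular and anti-conservative; calibration is guaranteed only for
genes that did not drive the ordering, which is the regime of a marker
scan (a short list against a transcriptome-wide ordering). Second, any
cell-level technical factor — library-size variation being the
canonical one — induces a genome-wide detection trend in log-CPM space;
if the ordering aligns with it, essentially every gene is *truly*
associated. That is a property of the data, not a test error, which is
why the calibration check in the test suite uses a depth-homogeneous
null simulation with held-out genes.

The marker scan (`dam_scan`, after the disease-associated-microglia use
case) runs preprocess → states → ordering → association pooled and
within each donor, reports per-stratum significant sets at q < 0.05,
and intersects the donor sets; the intersection is the donor-replicated
signal. Strata under 20 cells are skipped with a warning.

## Synthetic-data model

Counts are negative binomial: cell c of donor d and type t has gene
means μ_g · fold_g(t) · m_{g,d} · state/trajectory factors, normalized
to sum to the cell's library size L_c ~ lognormal, drawn with NB size
`dispersion`, then zeroed with probability `dropout`. Planted
structure:

- **Types**: disjoint marker blocks (default 10 genes/type, fold 8).
- **Donor batch effects**, two components. Per-(gene, donor) lognormal
  mean multipliers (`donor_effect_sd`) emulate global donor shifts;
  they inflate pooled dispersion (so CGS selects them) but are *exactly
  removed* by the per-gene donor regression, so alone they cannot bias
  clusters. Donor-private cell states (`donor_private_genes`,
  `donor_private_fold`) upregulate a gene block in one donor's cells of
  one type — the way a single donor's activated astrocytes form a
  donor-exclusive cluster; such within-donor structure is invisible to
  a donor-mean regression, and per-donor HVG selection sees it in one
  donor only, so the consensus intersection drops it.
- **Trajectory**: latent τ_c ~ U(0,1) scales trajectory-gene means by
  exp(β·τ); trajectory genes get low baselines (activation genes start
  low), and donor-private trajectory genes respond in one donor only.

Reference conditions are frozen as constructors: `reference_spec` (3
donors, 8 types, 1000 genes, 3000 nuclei, mildly unequal compositions,
mean-shift sd 0.6 + 25-gene private states at fold 8),
`trajectory_spec` (strong 60-gene program, β = 4, NB size 50 — the
"large effect, low noise" recovery regime), `dam_scan_spec` (750 cells,
1000 genes, 60-gene shared backbone at β = 2.5 plus 5 donor-private
responsive genes per donor; the 1000-gene library keeps the program a
realistic fraction of each cell's output, since in a small gene universe
compositional renormalization couples every gene to the trajectory),
and `null_association_spec` (no trajectory, no depth variation, no
dropout — the genuine null). The deterministic test fixture is 200
genes × 300 nuclei, 3 donors, 5 types, written in the 10x triplet
dialect and byte-stable under its seed.

What the simulator does **not** model: gene-gene correlation beyond the
planted programs, ambient RNA, doublet expression profiles, UMI-level
saturation, batch effects on dropout rates. Passing tests therefore
demonstrate correctness of the algorithms under the stated generative
assumptions, not performance on arbitrary real tissue.

## Problem sizes and known limitations

Validation runs use 300–3000 cells and 200–1000 genes; at these sizes
the full pipeline runs in seconds and the property checks (5-seed
evenness contrast, planted-type recovery ARI > 0.8, pseudotime rank
correlation > 0.9, marker-scan intersection) complete in well under a
minute each.

- Per-donor consensus selection needs a few hundred cells per donor:
  on the 300-cell fixture (~100 cells/donor) the intersection keeps
  too few genes for reliable clustering, so that fixture's recovery
  checks use pooled selection; consensus recovery is validated at the
  3000-cell reference condition.
- Dense intermediates are used inside the scaling, PCA and DE steps;
  matrices beyond ~10⁵ cells would need chunked or sparse-path
  variants.
- The pseudotime model is a single linear path; branching topologies
  are out of scope, and orientation is reported up to reversal.
- The entropy diagnostic flags unevenness but does not correct it; the
  package deliberately contains no embedding-space batch integration —
  feature selection *is* the correction under test.
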