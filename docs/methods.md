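# Methods

## Model and assumptions

`scmoc` addresses clustering of paired single-cell RNA + ATAC data. Its
central assumption is that a cell's local neighbourhood estimated from
the less-sparse modality (RNA) approximates its true neighbourhood in
the sparser modality (ATAC), because both are measurements of the same
cell. Under that assumption, averaging each cell's normalized ATAC
profile over its k nearest RNA-space neighbours recovers accessibility
structure that is unreadable in the raw sparse matrix, and the two
modalities can then be clustered independently and reconciled.

The merge is deliberately asymmetric: the RNA clustering is trusted, and
ATAC evidence may only *split* RNA clusters, never merge or reshape
them. The output therefore refines the RNA partition — a property the
test suite asserts on random inputs.

## Pipeline stages and parameters

| stage | parameter | default | rationale |
|---|---|---|---|
| normalization | scale factor | 1e4 | counts per 10k, the standard single-cell convention |
| HVG (vst) | n_hvg | 6000 | generous cut that keeps all informative genes at co-assay depths |
| HVG (vst) | loess span / degree | 0.3 / 2 | published defaults of the vst procedure this ranking follows |
| scaling | clip | ±10 | prevents outlier cells from dominating PCA |
| PCA / LSI | components | 20 | standard working dimensionality for both modalities |
| imputation | k | 50 | neighbourhood size; the k-sensitivity sweep shows a flat response over 10–100 with a mild optimum near 50 |
| kNN graph | k | 50 | same neighbourhood scale as imputation |
| Louvain | resolution γ | 0.8 | modularity resolution (RB-configuration form) |
| merge | window | (0.10, 0.90), strict | an ATAC overlap qualifies when it covers >10% and <90% of the RNA cluster |

Processing order for ATAC: normalize → impute → renormalize → LSI. LSI
is applied to the renormalized imputed matrix with the log folded into
the TF-IDF weighting (`log(1 + TF·IDF·1e4)`), the common scATAC
formulation; applying a separate log/scale before the SVD is not done.
All 20 LSI components are kept by default; a `drop_first` flag exists
for chromatin data whose leading component tracks sequencing depth.

## Numerical and determinism choices

- **vst ranking.** Per-gene mean/variance on raw counts; loess (tricube
  weights, local quadratic, span 0.3) of log10 variance on log10 mean
  over genes with positive variance; standardized counts clipped at
  √n_cells; genes ranked by the variance (ddof = 1) of the clipped
  values, ties broken by feature id. The degenerate all-constant matrix
  returns the first n features with a warning.
- **Scaling** uses the population (ddof = 0) standard deviation;
  zero-variance features map to zero columns.
- **Sign convention.** Each PCA/LSI component is flipped so its
  largest-magnitude loading is positive, making embeddings reproducible
  across linear-algebra backends. The LSI truncated SVD uses a seeded
  start vector.
- **kNN.** Exact blockwise search with squared Euclidean distances
  (`cdist`), ties broken toward the smaller cell index; a cell is not
  its own neighbour by default (`include_self` exists). With self
  included the cell's own sparse row would dilute the mean by 1/k —
  negligible at k = 50, but exclusion is the cleaner contract.
- **Imputation output** is stored sparse; magnitudes below 1e-12 are
  truncated to keep memory bounded. Every imputed entry is a uniform
  mean of observed values, so it lies inside the neighbours' value range
  and density can only grow.
- **Louvain** runs on an unweighted symmetrized-union kNN graph (edge if
  either endpoint lists the other); an opt-in shared-neighbour (Jaccard)
  edge weighting and an opt-in Leiden backend exist but are off by
  default, since the published method specifies plain Euclidean kNN with
  Louvain. The igraph RNG is seeded and labels are size-ordered, making
  runs bit-reproducible.
- **Merge details.** "Overlaps more than one ATAC cluster" is
  operationalized as ≥ 2 qualifying overlaps under the strict (0.10,
  0.90) window — a single qualifying overlap cannot split a cluster
  (a one-part split is a no-op). Reassignment candidates are restricted
  to sub-clusters carved from the cell's own original RNA cluster, and
  distances are computed against pre-reassignment memberships so the
  result does not depend on processing order; ties go to the smaller
  sub-cluster label. Reassignment uses the full 20-component RNA PCA
  space.
- **Seeding.** One root seed is expanded into independent per-stage
  seeds (PCA, LSI, per-modality Louvain) via `SeedSequence`; all derived
  seeds stay below 2³¹ and are echoed in the run's configuration record.
- Cells with a zero total in either modality after downsampling are
  dropped with a warning before normalization; evaluation metrics are
  computed over the intersection of surviving cells.

## Evaluation machinery

Downsampling uses per-entry binomial thinning (each count unit retained
independently with probability f) — distributionally equivalent to
depth-downsampling tools, without chasing bit-identity with any specific
RNG stream. Silhouette is computed in each branch's own LSI space
(recorded in the curve metadata), with singleton clusters contributing
0. ARI is the standard permutation-model adjusted Rand index; the 50-NN
Jaccard compares each cell's neighbour set before and after a
perturbation. RMSE is computed over all entries of normalized matrices,
zeros included.

## Synthetic data: what it emulates, and what it does not

The generator draws RNA counts from a negative binomial (gene-level
lognormal base means, sigma 1; per-cell lognormal depth factors, sigma
0.3; NB size r = 0.5, i.e. variance μ + μ²/r) with a fold-change of 8 on
50 marker genes per major group, and ATAC counts from a Poisson with low
per-peak lognormal rates (sigma 0.5) and an enrichment of 6 on 100
marker peaks per fine subgroup. A scalar rate multiplier per modality is
calibrated by bisection on the analytic expected density
(NB: 1 − (r/(r+μ))^r; Poisson: 1 − e^(−μ)), so realized densities land
within ±10% of their targets; presets reproduce the density regimes of
the three co-assay protocols studied (RNA 1.05/2.87/7.06%, ATAC
0.28/1.01/6.49%).

Fine subgroups differ in ATAC marker peaks only, unless `rna_leak > 0`
adds a fold-change of (1 + rna_leak) on 50 dedicated genes — the regime
in which sibling subpopulations show expression-level differences too
weak for RNA-only clustering to act on. ATAC counts are Poisson rather
than binary so thinning and normalization act naturally; binarization is
not part of the pipeline.

The generator does *not* emulate: batch effects, doublets, genomic
coordinates or peak–gene linkage, zero inflation beyond what the count
models produce, or cross-modality technical correlation. Passing tests
on this data therefore demonstrate the pipeline's mechanics and the
conditions under which RNA-guided imputation helps, not performance on
any particular real dataset.

## The operating regime of the merge — a known limitation

RNA-guided imputation replaces each cell's ATAC row by an average over
RNA-space neighbours. If two subpopulations are *strictly*
indistinguishable in RNA, their members' neighbourhoods are
statistically identical, so the imputed profiles carry no information
about the cell's own subgroup and no downstream clustering can recover
the split — the equal-neighbourhood assumption is load-bearing. The test
suite demonstrates this regime explicitly (`TestKnownLimitation`). The
regime in which the merge earns its keep — and the one the label-recovery
test instantiates (`rna_leak = 4`, i.e. fold 5 on 50 of 2000 genes) — is
weak-but-nonzero RNA signal: enough to bias the 50-NN neighbourhoods
toward the cell's own subgroup, not enough for RNA-only Louvain to split
the cluster.

## Problem sizes

The shipped tests and the acceptance script run the full method at 2000
cells × 2000 genes × 5000 peaks (the label-recovery and downsampling
conditions) and smaller instances elsewhere; oracle-equivalence checks
(exhaustive kNN, pair-counting ARI, direct silhouette, dense SVD) use
≤ 200-cell instances where the brute-force reference is exact.

## Open choices made

- Whether the original imputation averaged raw or normalized peak
  values is ambiguous; the stated processing order (normalize → impute →
  renormalize) is followed, so normalized values are averaged.
- The silhouette space for branch comparisons is each branch's own LSI
  embedding (not a shared space), recorded in curve metadata.
- RMSE is computed on normalized matrices.
- QC cell thresholds apply jointly (a cell must pass both modalities),
  since the paired invariant requires a single shared cell set; exact
  cut-offs are dataset-dependent configuration, not constants.
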