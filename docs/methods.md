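# Methods

This note documents the statistical procedures implemented in `ssbench`,
the choices made where the design was genuinely open, and what the
synthetic test fixtures do and do not establish about real data.

## Data model and preprocessing

A dataset is a non-negative gene × spot UMI count matrix `Y` with 2D spot
coordinates, optional spatial-domain labels and optional per-spot
cell-type proportions. Orientation is fixed as genes × spots everywhere;
readers normalize and reject (never truncate) dimension mismatches.
Coordinates are continuous and their units are never interpreted.

* **log2-CPM**: `log2(1e6 · Y_gk / N_k + 1)` with `N_k` the spot library
  size; the pseudocount of 1 keeps zeros at zero on the log scale. Spots
  with zero library size are an error, not a silent drop.
* **Single-cell QC** retains cells with 200–2500 detected features and a
  mitochondrial count fraction ≤ 5% (gene-prefix configurable,
  default `MT-`); both bounds are inclusive, so a cell with exactly 2500
  features is kept and one with 2501 removed.
* **Gene selection** keeps the 1000 most spatially variable genes when a
  dataset has more, ranked by univariate Moran's I of log2-CPM on the
  spot neighbor graph, ties broken lexicographically by gene id, original
  gene order preserved. The operation is idempotent.
* **Neighbor graph**: symmetrized (union) k-nearest-neighbor adjacency
  with k = 6 by default — the coordination number of a hexagonal Visium
  lattice — with distance ties broken by the lower spot index so the
  graph is a deterministic function of the coordinates. Delaunay
  triangulation is available where a parameter-free graph is preferred.
  Note that union symmetrization of asymmetric mutual picks can give a
  spot more than k neighbors (on a 2×2 unit square with k = 1 the
  lower-index tie rule produces 3 undirected edges, not 2).

## Property metrics

Spot-level (8): library size, TMM factor, effective library size
(`N_k · TMM_k`), scaled mean and scaled variance of log2-CPM (per-spot
moments z-scored across spots, sample sd), per-spot zero fraction, the
(library size, zero fraction) pair, and Pearson correlations between
sampled spot pairs. Gene-level (6): the per-gene analogues plus the
(mean, variance) and (mean, zero fraction) pairs. The higher-order
relationship pairs use raw-count per-gene moments — that is the scale on
which the count mean–variance law lives (Poisson data falls on the
identity line) — while the scaled-moment metrics use log2-CPM as defined.

**TMM.** The per-spot normalization factor is the doubly trimmed weighted
mean of per-gene log ratios against a reference spot:
`M_g = log2(Y_gk/N_k) − log2(Y_gr/N_r)`,
`A_g = ½·[log2(Y_gk/N_k) + log2(Y_gr/N_r)]`, genes with a zero count in
either library excluded, per-tail rank trimming of 30% on M and 5% on A,
weights `w_g = (N_k−Y_gk)/(N_k·Y_gk) + (N_r−Y_gr)/(N_r·Y_gr)`, and
`TMM_k = 2^(Σ w M / Σ w)` over the kept genes. The reference spot is the
one whose upper-quartile relative abundance is closest to the mean
upper-quartile. An `as_printed=True` audit mode replaces the difference
of logs by their ratio for comparison against sources that typeset the
M-value that way. If every kept weight is zero the unweighted trimmed
mean is used.

**Pair correlations** are computed over all C(n,2) unit pairs up to a cap
(default 5000), beyond which a seeded uniform without-replacement sample
of pairs is used; constant units are skipped and tallied. The subsample
is unbiased for the full-enumeration mean.

## Spatial metrics

Let `w_ij` be the neighbor adjacency and `W = Σ w_ij` over ordered pairs.

* **Moran's I** `(N/W)·Σ w_ij (x_i−x̄)(x_j−x̄) / Σ (x_i−x̄)²`; a constant
  vector returns 0 with a warning (the formula is 0/0 there). The
  per-gene vector over log2-CPM is the spatial-level Moran sample.
* **Transition matrix (TM)**: row-stochastic domain transition
  frequencies over ordered neighbor pairs; empty rows become uniform with
  a warning.
* **Neighborhood enrichment (NEM)**: z-scores of inter-domain ordered
  edge counts against a seeded label-permutation null (default 1000
  permutations). A permutation null is used because it is assumption-free
  and matches the behavior of the upstream tools that popularized the
  statistic; `σ = 0` cells get z = 0 with a warning.
* **Centrality scores (CSM)**, per domain: group degree centrality
  `|N(C_k)|/(N−|C_k|)`, mean local clustering coefficient over members
  (degree < 2 contributes 0), and group closeness
  `|V−C_k| / Σ_{v∉C_k} dist(v, C_k)` with unweighted shortest paths;
  spots unreachable from the domain are excluded with a logged count.
* **Nearest-neighbor correlation**: per gene, the Pearson correlation
  between each spot's log2-CPM value and its single nearest neighbor's
  (smallest Euclidean distance, lowest index on ties).
* **Cell-type interaction**: for each unordered type pair (a, b), the
  average over ordered neighbor spot pairs of `p_ia · p_jb`; a single
  type gives exactly 1.
* **L statistic**: proportion-weighted Ripley cross-K,
  `K_ab(r) = |A| · Σ_{i≠j} p_ia p_jb 1[d_ij ≤ r] / (W_a W_b)` with `|A|`
  the bounding-box area, variance-stabilized as `L = sqrt(K/π)`, flattened
  over type pairs × radii (default radii 5–25% of the bounding-box
  diameter). No edge correction is applied; under complete spatial
  randomness the small-radius bias is a few percent, which the tests
  bound at ±15%. The cell-type interaction and L statistics are explicit
  concretizations of summary features whose upstream definitions are
  informal; they are isolated behind this module boundary.

## KDE two-sample comparison

For samples `x (n₁)` and `y (n₂)` with per-sample, per-dimension
Silverman bandwidths `h = (4/(d+2))^{1/(d+4)} n^{-1/(d+4)} σ` (tiny
positive fallback for zero-variance dimensions), the integrated squared
error between the two Gaussian KDEs reduces exactly to three pairwise
Gaussian sums — the convolution of two normal kernels is a normal density
at the center difference with summed variances — so no grid is involved:

```
T = mean_ij φ(x_i−x_j; 2h₁²) + mean_ij φ(y_i−y_j; 2h₂²) − 2·mean_ij φ(x_i−y_j; h₁²+h₂²).
```

Relationship metrics use the 2D product kernel. `T` is standardized
against a seeded permutation null (default 200 relabelings of the pooled
sample, bandwidths recomputed per permutation); the null moments are
estimated rather than taken from an asymptotic formula, which keeps the
statistic assumption-free at the sample sizes benchmarks use. Samples are
capped at 2000 points (seeded subsample) before the quadratic-cost
statistic. Per metric, z values across all compared methods are min-max
mapped to [0, 1]; a degenerate (constant) set maps to 0.

Because `z` standardizes each comparison against its own permutation
null, two simulations that are both statistically indistinguishable from
the real data can swap z-order by null noise; `T` itself is the stable
quantity in that regime (an exact copy scores `T = 0` identically).

## Metric registry and score table

The registry enumerates 35 metric identifiers: 8 spot + 6 gene + 7
spatial data properties, 8 downstream agreement metrics (4 tasks × 2),
and 6 scalability identifiers ({runtime, memory} × {spot scaling, gene
scaling, overall}). Wall-clock/memory profiling is environment-bound and
not scored by `score_table`; the identifiers exist so evaluation ledgers
(method × dataset × metric) are complete — 13 × 10 × 35 = 4550 rows.
`score_table` records every (method, metric) row with an explicit status;
failures carry reasons and are never silently dropped.

The label-dependent spatial metrics (TM, NEM, CSM, cell-type
interaction) are computed from the annotation a dataset carries. A
simulation produced by the adaptor inherits the real labels, making those
comparisons trivially tight; the structure comparison below re-clusters
the simulated counts instead, which is the analysis a benchmark of
unlabeled simulator output performs.

## Downstream tasks

Truth for each task is the output of the same (pluggable) analysis
applied to the real dataset; synthetic fixtures may substitute planted
truth. Built-in baselines:

* **Clustering**: k-means (10 seeded restarts) on the top principal
  components of per-gene standardized log2-CPM (unit total variance)
  concatenated with min-max-scaled coordinates weighted by
  `smooth_weight` (default 0.5; 0 = expression only). Gene
  standardization before PCA is what lets minority marker genes drive
  the components. Agreement by ARI and NMI (arithmetic-mean
  normalization); two single-cluster partitions agree perfectly (1) by
  convention.
* **Deconvolution**: non-negative least squares of spot CPM profiles on
  per-type mean CPM signatures (≥ 50 shared genes required), rows
  renormalized. RMSE is per-type normalized by the true column sums
  `S_k`; JSD normalizes each type's proportion column into a
  distribution over spots and uses natural-log KL to the midpoint
  (maximum ln 2; 0·ln 0 = 0).
* **SVG detection**: per-gene Moran's I on square-root-CPM (variance
  stabilizing for counts — the log transform's zero/non-zero jump
  otherwise swamps the autocorrelation signal of mid-abundance genes)
  with a joint spot-permutation null, one-sided p-values,
  Benjamini–Hochberg at 5% FDR. Scored by precision/recall against the
  real-data detections.
* **Cross-correlation**: gene × gene bivariate Moran's I on log2-CPM
  (diagonal = univariate I), by default over the 50 most autocorrelated
  real genes (the full matrix is quadratic); matrices compared by cosine
  similarity of the flattened entries and the Mantel centered
  cross-product correlation over all entries.

## Cluster-then-simulate adaptor

Any simulator obeying the contract *(counts submatrix, seed) → same-shape
counts* can be adapted: spots are partitioned by provided labels, the
dataset's own domains, or the baseline clustering (cluster count required
explicitly — there is no safe default); each cluster's submatrix is
simulated independently and real coordinates/labels are reattached.
Per-cluster seeds are `(master + CRC32(label)) mod 2³¹−1`, so output is
invariant to cluster order and distinct per label. Clusters below a
simulator's minimum size pass through with a warning. `mode="whole"`
bypasses the split for head-to-head comparison.

The built-in reference simulator fits each gene by method of moments —
NB(mean m, dispersion r = m²/(v−m)) when v > m, Poisson otherwise — and
resamples i.i.d. per spot. It deliberately models no gene–gene or
spot–spot dependence: whatever spatial structure its adapted output shows
is injected by the adaptor, which is exactly what the structure
comparison isolates. `structure_comparison` re-clusters each simulated
dataset (expression-only k-means, K = the real domain count), computes
the domain transition matrix on the shared graph, and compares the
flattened matrix against the real one with the KDE test; the comparison
is reported on `T` (see the z-noise caveat above).

## Aggregation

Per-metric method ranks use the raw KDE z, ascending (lower = closer),
average ranks on ties; a level's overall score is the unweighted mean
rank — equivalent under any monotone transform of z, so ranking on z or
on the [0, 1] transform is the same ordering. Dataset consistency is the
mean raw z per (method, dataset, level). The concordance index counts,
over pairs with distinct true outcomes, the fraction predicted in the
same order, with predicted ties credited 0.5. Method-effect regression is
OLS of the score on method indicators (reference level = first method
alphabetically) with coefficient/SE/p-value output. The downsampling grid
draws one spot and one gene permutation per seed and takes prefixes, so
smaller subsamples are nested in larger ones; the default grids
(200, 500, 1000, 3000, 5000 spots × 200, 500, 1000 genes) yield 15
datasets.

## Synthetic fixtures

The generator produces a square integer lattice partitioned into K
contiguous vertical bands, NB(mean, dispersion) expression with variance
`μ + μ²/r`, per-domain marker genes up-regulated by a fold-change, and
per-spot Dirichlet cell-type proportions with domain-specific
concentrations. Defaults — 16×16 spots, 200 genes, K = 4, baseline means
uniform on [0.5, 10], dispersion 2, 10 markers per domain at 4-fold,
3 cell types with a 5:1 domain-skewed Dirichlet — describe a small
Visium-like tissue region with strong overdispersion and clear regional
identity. Bands (rather than random blobs) make domain contiguity and
the sign of marker spatial autocorrelation provable. All draws come from
one `default_rng` stream per generator call, seeded from the
configuration, so outputs are bit-reproducible.

What the fixtures do *not* emulate: gene–gene correlation, within-domain
expression gradients, platform artifacts (spot swapping, segmentation
error), irregular tissue boundaries, or library-size covariation with
domain identity beyond what markers induce. Tests passing on these
fixtures establish the statistics and the pipeline plumbing, not that any
particular simulator is adequate for a given real tissue.

## Problem sizes and numerical conventions

Tests and the acceptance script run on lattices up to side 20 (400
spots; 5000 spots for moment-recovery checks, 5200 × 1100 for the
downsampling grid), with 50–1000 permutations depending on the null being
estimated — sizes at which every stochastic assertion holds with wide
margin under the fixed seeds. Variance and z-scoring use the sample
convention (ddof = 1) throughout. Ties are broken deterministically
(lexicographic ids, lowest index) wherever an order matters. Degenerate
inputs follow the conventions stated above (constant vectors, σ = 0
nulls, single-cluster partitions, zero-probability JSD cells), each with
a warning rather than silence.

## Known limitations

* The KDE z statistic is permutation-standardized, not the closed-form
  moment standardization of the R `ks::kde.test` implementation; the
  ordering of methods and the [0, 1] transform behavior are the
  reproducible quantities, not the third decimal of z.
* Ripley statistics use no edge correction; radii beyond ~25% of the
  domain size underestimate K near boundaries.
* The built-in baselines are deliberately simple stand-ins for the
  external tools a production benchmark would plug in through the
  callable/`exec:` interfaces; their absolute task performance is not a
  statement about those tools.
* Scalability (runtime/memory) is enumerated but not measured.
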