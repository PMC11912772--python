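# ssbench

Benchmarking framework for spatial transcriptomics count simulators.

Simulated spot-level expression data underpins the validation of most
spatial analysis tools (clustering, deconvolution, spatially variable gene
detection), but a simulator is only useful if its output behaves like real
tissue data. `ssbench` quantifies that: given a real gene × spot dataset
and one or more simulated versions of it, the package scores how faithfully
each simulation reproduces the real data's **spot-level**, **gene-level**
and **spatial-level** distributional properties and how well it supports
four **downstream tasks**, then aggregates the scores into per-method
ranks. It also ships the **cluster-then-simulate adaptor**: a procedure
that turns any single-cell count simulator into a spatially structured one
by partitioning spots into spatial domains, simulating each domain
independently, and reattaching the real coordinates.

It is intended for developers of spatial simulators (to benchmark a new
method against existing ones on their own reference data) and for analysts
choosing a simulator for a specific tissue/protocol.

## The statistics at the core

Each data property (library size, TMM factor, zero fractions, scaled
moments, Moran's I per gene, domain transition frequencies, ...) is a
distribution over spots, genes or domain pairs. Real and simulated
distributions are compared by the integrated squared error between their
Gaussian kernel density estimates,

```
T = ∫ [f₁(x) − f₂(x)]² dx ,    z = (T − μ_T) / σ_T ,
```

where `T` is evaluated in closed form through the Gaussian convolution
identity and `(μ_T, σ_T)` come from a seeded permutation null that pools
the two samples. Lower `T`/`z` means the simulation is closer to the real
data; per metric, `z` values across all compared methods are min-max
mapped to a [0, 1] dissimilarity. Spatial autocorrelation uses Moran's I

```
I = (N/W) · Σᵢⱼ wᵢⱼ (xᵢ − x̄)(xⱼ − x̄) / Σᵢ (xᵢ − x̄)² ,
```

with `w` a symmetrized k-nearest-neighbor spot adjacency (k = 6 by
default, matching the hexagonal Visium lattice), and its bivariate form
for spatial cross-correlation between genes. Downstream agreement uses
ARI/NMI (clustering), per-type-normalized RMSE and Jensen–Shannon
divergence (deconvolution), precision/recall (SVG detection) and
cosine/Mantel similarity (cross-correlation matrices). Method ranks are
averaged per level into an overall score; ranking consistency between real
and simulated analyses is summarized by the concordance index.

## Worked example

Every metric is testable without downloads: the `fixtures` module
generates lattices of spots partitioned into contiguous spatial domains
with negative-binomial expression, planted domain-marker genes and
Dirichlet cell-type composition.

```python
import ssbench as sb

cfg = sb.SyntheticConfig(n_spots_side=16, n_genes=200, n_domains=4, seed=0)
real, info = sb.generate_dataset(cfg)
graph = sb.build_neighbor_graph(real.coords)

nb = sb.BUILTIN_SIMULATORS["builtin-nb"]          # moment-matched NB resampler
sims = {
    "nb-adaptor": sb.adapt_simulator(real, nb, seed=0),               # per-domain
    "nb-whole":   sb.adapt_simulator(real, nb, mode="whole", seed=0), # one pass
}
table = sb.score_table(real, sims, graph=graph, n_perm=100, seed=0)
print(sb.overall_rank_score(table, "spot").round(2))
```

Selected rows of the score table this prints (KDE statistic and z for
property metrics, agreement values for downstream tasks):

```
    method            metric      level  statistic  raw_z  value
nb-adaptor          morans_i    spatial      0.226  1.828    NaN
nb-adaptor    clustering_ari downstream        NaN    NaN  0.712
nb-adaptor        svg_recall downstream        NaN    NaN  0.952
  nb-whole          morans_i    spatial      0.992 11.271    NaN
  nb-whole    clustering_ari downstream        NaN    NaN  0.001
  nb-whole        svg_recall downstream        NaN    NaN  0.000
```

Reading it: simulating each spatial domain separately (`nb-adaptor`)
keeps the per-gene spatial autocorrelation distribution close to the real
one (z = 1.8 vs 11.3), recovers the real clustering structure
(ARI 0.71 vs 0.00) and preserves 95% of the real spatially variable
genes, while the same simulator run on the whole matrix destroys all
three — the adaptor is what injects the spatial signal. The spot-level
rank table averages per-metric ranks (1 = best) into an overall score per
method.

The same pipeline is scriptable from a shell:

```sh
ssbench fixtures --side 16 --genes 200 --domains 4 --seed 0 --out real/
ssbench simulate --in real/ --out sim/ --simulator builtin-nb --mode adaptor --seed 0
ssbench score    --real real/ --sims sim/ --out scores.csv
ssbench report   --scores scores.csv --out report/
```

Datasets on disk use plain-text standard formats: Matrix Market counts
with `features.tsv`/`barcodes.tsv`, plus CSV tables for coordinates,
domain labels and cell-type proportions.

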