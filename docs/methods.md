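# Methods

This note documents the models, conventions and design choices behind
`damlink`: what each stage computes, why the defaults are what they are,
what the synthetic generator does and does not emulate, and the numerical
edge rules.

## Quality control

A single simultaneous pass over the raw count matrix:

| parameter | default | meaning |
|---|---|---|
| `min_cells_per_gene` | 3 | gene kept iff detected (count > 0) in ≥ 3 cells of the input matrix |
| `min_genes_per_cell` | 200 | cell kept iff it detects ≥ 200 genes of the input matrix |
| `max_mito_fraction` | 0.05 | cell removed iff mito counts / total counts is **strictly greater** than the bound (high-mito cells treated as dying) |
| `umi_bounds`, `genes_per_cell_upper` | off | dataset-specific depth filters; values belong to whoever produced the data, so they are config, never defaults |
| `exclude_barcodes` | empty | hook for multiplets detected by an external method |

Both axes are evaluated on the input matrix and applied at once, matching
common droplet-workflow practice; consequently a kept gene may fall below
the detection threshold among surviving cells. `iterate=True` repeats the
pass to a fixed point for users who want the stricter semantics. A cell
with zero total counts gets mito fraction 0 by definition, so it is removed
by the gene-count rule rather than by a division error.

The 200-gene floor presumes transcriptome-scale gene panels (~20k genes).
Configurations aimed at the synthetic generator's few-hundred-gene datasets
scale it down (the shipped examples use 40–50), which is a property of the
panel size, not of the filtering rule.

## Normalization, embedding, clustering, annotation

* **Normalization**: counts scaled per cell to a common library size
  (median by default) and log1p-transformed, natural log. Zeros map to
  zeros, so detection frequencies agree between raw and normalized layers.
  The layer is dense in memory; the package targets desk-scale matrices
  (10^3–10^4 cells), not atlas-scale ones.
* **HVG**: the `n_hvg` (default 2000) genes with the largest variance of
  the log layer; exact ties broken by ascending gene index, so selection is
  deterministic. Variance is the simplest monotone dispersion statistic
  satisfying the contract; nothing downstream depends on the flavor.
* **PCA**: per-gene z-scoring with |z| clipped at `scale_clip` (default 10,
  the common practice value), full-SVD PCA to `n_pcs` (default 20)
  components. Each component is oriented so its largest-magnitude loading
  is positive, making embeddings machine-independent. The component count
  is taken as configuration; no automated elbow detection.
* **Clustering**: Leiden (RB-configuration quality) on the undirected
  k-nearest-neighbor graph (`n_neighbors` default 15), seeded, run to
  convergence. Resolution is per-dataset configuration (the example config
  carries 0.32 / 0.2 / 0.06 for the three study datasets). The
  resolution → 0 limit yields one cluster per connected component; merging
  across disconnected components is impossible by construction.
* **Annotation**: for each cluster, every gene's within-cluster mean log
  expression is mapped to its rank-quantile among all genes (same half-tie
  rule as below); a panel's score is the mean quantile of its genes present
  in the data, and the argmax panel annotates the cluster, ties falling to
  panel order. This deterministic rank score replaces external annotation
  tools while keeping the same interface contract (one cell type per
  cluster, with a score). A panel none of whose genes are present is a
  configuration error and is reported as such.

## Consensus score

For a cell type with cells C and genes G, gene g gets

```
freq(g)       = #{c ∈ C : count[c,g] > 0} / |C|
expr(g)       = mean over C of lognorm[c,g]
ratio(v, g)   = (#{h≠g : v_h < v_g} + ½·#{h≠g : v_h = v_g}) / (G−1)
consensus(g)  = ratio(freq, g) + ratio(expr, g)
```

The half-tie rule over denominator G−1 is the normative formula of this
package: a strict unique maximum gets exactly 1, a strict unique minimum
exactly 0, an all-equal vector 0.5 everywhere, and the mean of each ratio
over genes is exactly 0.5 within every cell type (average-rank
conservation), so the consensus always spans [0, 2] in the advertised way.
Detection is computed on raw counts; expression on the log-normalized
layer, which is robust to depth. Because normalization preserves zeros,
computing frequency on either layer is equivalent. Scores are computed on
post-QC genes only, and increasing a gene's count in one cell never lowers
that gene's consensus in that cell's type.

## Marker selection

Parameters (`CorrelationFilterParams`): `target_gene` (default `Piezo1`),
`corr_threshold` 0.7, `presence_threshold` 0.70, per-dataset subcluster
name lists, `require_all_datasets` true, `correlation_kind`
`pearson_on_lognorm` (Spearman available for sensitivity analysis).

Two distinct criteria, mirroring their distinct definitions:

* **Correlation** is computed over *all* cells of the pooled named
  subclusters on the log-normalized layer — target-positivity plays no
  role here. Up-class markers must reach r ≤ −0.7, down-class r ≥ +0.7,
  boundaries inclusive.
* **Presence** is the fraction of target-positive cells (raw target count
  > 0) in which the marker is detected (raw count > 0); it must reach the
  threshold, inclusive.

A marker is finally kept iff it passes both criteria in every configured
dataset. Markers absent from a dataset, constant markers, and datasets
without target-positive cells fail with an explicit reason rather than a
silent NaN. Pooling the named subclusters is the default; per-subcluster
evaluation exists behind an experimental flag. Subcluster names match
per-cell labels exactly (annotated cell type or cluster id), so the
study-specific labels are configuration, not code. The cell set entering
each correlation is logged per run. Selection is monotone in both
thresholds and invariant to cell and marker ordering.

## Bulk harmonization

`log2(x + 1)` (pseudocount configurable), quantile normalization, per-gene
batch centering. Quantile normalization forces every sample onto the
vector of cross-sample rank means; entries tied within a sample receive
the mean of the reference values their rank span covers (for pairs and
tie-free data this coincides with limma's `normalizeQuantiles`, which the
test suite uses as an independent reference; for ties of three or more
limma instead interpolates at the average rank). The operation is
idempotent on tie-free data; tie averaging perturbs the shared
distribution once, after which it is stable. Batch centering removes each
batch's per-gene mean and restores the grand mean — the no-covariate
special case of linear-model batch-effect removal — and therefore
preserves every gene's grand mean exactly.

## Study-design statistics

Two-group sample size uses the normal-approximation closed form
`n = ceil(2 (z₁₋α/₂ + z_power)² / d²)` with `d = (fold_change − 1) / sd`
over a unit baseline, floored at 2. Defaults (power 0.80, two-sided α
0.05, 1.5-fold, sd 0.3 ⇒ d = 1.667) give n = 6 per group. A noncentral-t
iteration (statsmodels) is available via `method="t"`; it is stricter and
returns 7 at the default design. The qPCR helper returns `2^ΔΔCt` for a
*signed* ΔΔCt: orient ΔΔCt so that enrichment (lower target Ct than
control) is positive, or negate it to get the textbook `2^(−ΔΔCt)` form —
the two conventions differ only in the sign the caller feeds in.

## Synthetic data generator

The generator plants the statistical structure the analysis assumes:

* cells drawn from configured type proportions (default Microglia /
  Astrocyte / Neuron at 0.4 / 0.3 / 0.3, 3000 cells);
* each type has its own marker genes (30 per type, 8× baseline fold);
* microglial cells carry a latent DAM activation `a ~ N(3·is_dam, 1)`
  with a DAM fraction of 0.4;
* gene means are `exp(log base + loading·a)` times a log-normal library
  factor (σ = 0.25, unit mean); counts are gamma–Poisson with dispersion
  θ = 6;
* the target gene (mean 12 in microglia) has loading −1.3, so activation
  suppresses it; 7 up-markers load positively (anticorrelating with the
  target), 13 down-markers negatively (correlating positively), 50 null
  candidates are microglia-enriched but load zero; DAM-class genes default
  to a microglial mean of 15 — deliberately highly expressed, as the
  canonical down-regulated DAM genes (ribosomal subunits, *Malat1*,
  *Fth1*-class genes) are;
* 10 mitochondrial genes whose means are solved per cell type so the
  expected mito fraction matches `mito_mean_fraction` (default 3%).

Count noise attenuates latent correlations, so up/down loadings are not
set directly: a calibration routine simulates the generative model itself
over a loading grid (fixed internal seed; memoized), builds the
monotone attenuation curve |r|(loading) for Pearson on the log-normalized
layer over the microglial mixture, and inverts it at the requested value.
A request beyond the curve's ceiling — the product of the two genes'
count-noise reliabilities bounds it — raises an error stating the maximum
attainable |r|. The default noise regime was chosen so that the default
requests (−0.85 / +0.8) sit on the rising part of the curve with headroom
(ceiling ≈ 0.88 up / 0.92 down); at 3000 cells the empirical correlations
land within a few hundredths of the request.

`simulate_dataset_pair` derives two child seeds from one parent seed and
draws two datasets sharing gene roles and requested correlations with
independent noise, emulating replication across studies. Everything is
bit-reproducible from `(params, seed)`.

**What the generator does not emulate**: ambient RNA, doublets, batch
chemistry effects, gene–gene correlation beyond the single DAM factor,
transcriptome-scale gene panels, or the compositional coupling structure
of real data beyond what library-size normalization itself induces (null
markers pick up a mild positive correlation with the target through the
shared library denominator, as they would in real data; it stays far from
the ±0.7 bounds). Passing tests on generated data therefore demonstrate
the correctness and power of the *procedure* under the planted model, not
that any particular real dataset satisfies the model.

## Pipeline and reproducibility

`run_pipeline` validates the configuration before any compute (missing
subcluster names, empty panels and overlapping marker classes fail fast),
then runs qc → normalize → HVG → PCA → Leiden → annotate → consensus →
marker evaluation per dataset and intersects the selection. Stages never
mutate their inputs; every run emits a record with the config snapshot,
seed, package version and SHA-256 hashes of all inputs and outputs, and
identical config + seed reproduce identical hashes. Stage failures abort
with the dataset id and underlying cause.

Problem sizes used by the test suite — paired 3000-cell × 500-gene
datasets for recovery and null-control checks (10 and 100 seeded
replicates respectively), 600–700-cell datasets for clustering checks —
are the generator defaults and keep the whole suite in the low minutes on
one CPU.

## Known limitations

* Dense normalized layer: memory scales as cells × genes × 8 bytes.
* The annotation score assumes panels discriminate at the mean-expression
  level; it has no notion of negative markers.
* Batch centering has no covariate protection; confounded designs need a
  proper linear model.
* Real-data gene identifier matching (symbols vs Ensembl ids) is a
  configuration concern; the readers expose both columns of 10x feature
  files but matching policy is the caller's.
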