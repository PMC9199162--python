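# damlink

Cross-dataset single-cell analysis linking a target gene to
disease-associated-microglia (DAM) markers.

In Alzheimer's disease models, microglia near amyloid plaques shift from a
homeostatic state into a DAM state with a characteristic transcriptional
signature: AD-risk genes up, homeostatic genes down. `damlink` implements a
reusable pipeline for asking how a target gene of interest — canonically the
mechanosensitive channel gene *Piezo1* — relates to that signature across
independent single-cell/single-nucleus RNA-seq datasets:

1. **QC**: a gene is kept if detected in ≥ 3 cells, a cell if it detects
   ≥ 200 genes and has a mitochondrial count fraction ≤ 5% (strictly above
   is treated as dying), plus optional dataset-specific depth bounds and a
   hook for externally detected multiplets.
2. **Clustering**: depth normalization and log1p, the 2000 most variable
   genes, 20 principal components, Leiden community detection on a kNN
   graph at a per-dataset resolution, and cluster annotation by marker-panel
   scoring (mean rank-quantile of within-cluster mean expression).
3. **Consensus score**: for each gene *g* and cell type, with *G* genes,

   ```
   freq_ratio(g) = (#{h≠g: freq_h < freq_g} + ½·#{h≠g: freq_h = freq_g}) / (G−1)
   expr_ratio(g) =  same, on mean log-normalized expression
   consensus(g)  =  freq_ratio(g) + expr_ratio(g)        ∈ [0, 2]
   ```

   where `freq` is the detection frequency (fraction of the type's cells
   with a nonzero count). A gene strictly top in both scores exactly 2,
   strictly bottom exactly 0; a frequency ratio of 0.6 means the gene is
   detected in more cells than 60% of the other genes of that cell type.
4. **Marker selection**: within named microglial subclusters, each candidate
   DAM marker is correlated with the target (Pearson on the log-normalized
   layer, over all pooled subcluster cells) and checked for presence among
   target-positive cells. An up-class marker passes in a dataset iff
   r ≤ −0.7 **and** presence ≥ 70%; a down-class marker iff r ≥ +0.7 and the
   same presence bound (all bounds inclusive). The final set is the
   intersection across datasets.

It also ships bulk RNA-seq harmonization helpers (log2, quantile
normalization, batch centering), two study-design statistics (two-group
sample size; qPCR 2^ΔΔCt fold change), and a seeded negative-binomial
simulator that plants the entire structure — cell types, a DAM subcluster,
a target gene with requested marker correlations, null decoys,
mitochondrial content, library-size variation — so every stage is testable
without downloading any dataset.

## Worked example

```python
import damlink as dl

# two datasets sharing planted truth, independent noise
pair = dl.simulate_dataset_pair(dl.SimParams(seed=1))
truth = pair[0][1]
cands = truth.candidate_marker_set()          # 7 up + 13 down + 50 decoys

cfg = dl.AnalysisConfig(
    qc=dl.QCParams(min_genes_per_cell=50),    # generator draws 500 genes
    cluster=dl.ClusterParams(n_hvg=500, resolution=0.3),
    corr_filter=dl.CorrelationFilterParams(
        subclusters_per_dataset={"ds1": ["Microglia"], "ds2": ["Microglia"]}),
    seed=1,
    panels=dict(truth.type_panels().panels),
    markers={"up": cands.up_markers, "down": cands.down_markers},
)
result = dl.run_pipeline(cfg, [d for d, _ in pair])

kept = result.selection.loc[result.selection.final_kept, "marker"].unique()
print(sorted(kept))
print(result.scores.query("gene == 'Piezo1' and dataset_id == 'ds1'")
      [["cell_type", "consensus"]].to_string(index=False))
```

prints

```
['DnDam1', 'DnDam10', 'DnDam11', 'DnDam12', 'DnDam13', 'DnDam2', 'DnDam3',
 'DnDam4', 'DnDam5', 'DnDam6', 'DnDam7', 'DnDam8', 'DnDam9', 'UpDam1',
 'UpDam2', 'UpDam3', 'UpDam4', 'UpDam5', 'UpDam6', 'UpDam7']
cell_type  consensus
   Neuron   1.275551
Microglia   1.639279
Astrocyte   0.361723
```

The selection recovered exactly the 20 planted DAM markers (none of the 50
decoys), and the target gene's consensus score is highest in microglia —
detected in more cells *and* expressed higher, relative to the other genes,
than in any other planted type.

The same stages are available from a shell (`damlink qc | cluster | score |
correlate | harmonize | simulate | power | ddct | run`); see
`examples/config.yaml` for a fully annotated configuration with the standard
thresholds.

```sh
damlink power --power 0.8 --alpha 0.05 --fold-change 1.5 --sd 0.3   # -> 6
damlink simulate --seed 4 --out sim1/
```

## Documentation

`docs/methods.md` describes the model and its assumptions, what the
synthetic generator does and does not emulate, every tunable parameter with
its default, and the numerical conventions (tie rules, sign conventions,
degenerate inputs).
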