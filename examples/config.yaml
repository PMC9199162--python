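# Example pipeline configuration with the standard analysis parameters.
# Dataset ids, subcluster names, panels and marker candidates are study
# choices; every numeric threshold the stages use is named here, never
# hard-coded.
qc:
  min_cells_per_gene: 3        # gene kept if detected in >= 3 cells
  min_genes_per_cell: 200      # cell kept if it detects >= 200 genes
  max_mito_fraction: 0.05      # strictly above 5% mito counts = dying cell
  umi_bounds: null             # dataset-specific; off by default
  genes_per_cell_upper: null
  exclude_barcodes: []         # hook for externally detected multiplets
  iterate: false
cluster:
  target_library_size: median
  n_hvg: 2000
  n_pcs: 20
  n_neighbors: 15
  resolution: 0.32             # fallback when no per-dataset value is given
  scale_clip: 10.0
  seed: 0
corr_filter:
  target_gene: Piezo1
  corr_threshold: 0.7          # inclusive: r <= -0.7 (up class), >= +0.7 (down)
  presence_threshold: 0.70     # inclusive: detected in >= 70% of target+ cells
  subclusters_per_dataset:
    mouse_sc: ["Microglia 1", "Microglia 2", "Microglia 3"]
    mouse_sn: ["microglia 0", "microglia 2"]
  require_all_datasets: true
  correlation_kind: pearson_on_lognorm
  per_subcluster: false
power:
  power: 0.80
  alpha: 0.05
  fold_change: 1.5
  sd: 0.3
seed: 0
per_dataset_resolution:
  human_sn: 0.32
  mouse_sc: 0.2
  mouse_sn: 0.06
panels:
  Microglia: [Hexb, Cst3, Cx3cr1, Ctss, P2ry12, Tmem119]
  Astrocyte: [Gfap, Aqp4, Slc1a3, Aldoc]
  Neuron: [Snap25, Syt1, Rbfox3, Meg3]
markers:
  # candidate DAM signature genes to test against the target; the kept
  # subset is the analysis output, not this list
  up: [Cd9, Ctsb, Ctsd, Ctsl, Ctsz, Fth1, Rplp2, Apoe, Trem2, Cst7]
  down: [Cd164, Cox6a1, Glul, Malat1, Marcks, Npm1, Rpl22l1, Rpl35a, Rpl5,
         Rps11, Rpsa, Serinc3, Tmem173, P2ry12, Tmem119]
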