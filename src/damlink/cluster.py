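"""Normalization, dimensionality reduction, graph clustering and annotation.

The chain mirrors the standard droplet workflow: depth-normalize and
log1p-transform, keep the most variable genes, embed with PCA on the scaled
layer, cluster a k-nearest-neighbor graph with the Leiden algorithm at a
given resolution, and annotate each cluster by scoring marker panels with a
mean rank-quantile of within-cluster mean expression. Every step is
deterministic under a fixed seed (PCA uses a full SVD with a fixed sign
convention; Leiden is seeded).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import igraph
import leidenalg
import numpy as np
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .io import ExpressionDataset, GenePanel
from .score import rank_ratio

__all__ = [
    "ClusterParams",
    "ClusterAssignment",
    "normalize_log",
    "select_hvg",
    "embed_pca",
    "cluster_graph",
    "annotate_clusters",
]


@dataclass
class ClusterParams:
    """Parameters for the embed/cluster/annotate chain.

    ``target_library_size`` may be a positive number or ``"median"`` (median
    raw library size of the dataset). ``resolution`` is the Leiden
    resolution; per-dataset values belong in the pipeline config.
    ``scale_clip`` bounds per-gene z-scores before PCA.
    """

    target_library_size: float | str = "median"
    n_hvg: int = 2000
    n_pcs: int = 20
    n_neighbors: int = 15
    resolution: float = 0.32
    scale_clip: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        if self.n_pcs > self.n_hvg:
            raise ValueError("n_pcs must not exceed n_hvg")
        if self.scale_clip <= 0:
            raise ValueError("scale_clip must be positive")
        if isinstance(self.target_library_size, str):
            if self.target_library_size != "median":
                raise ValueError("target_library_size must be a number or 'median'")
        elif self.target_library_size <= 0:
            raise ValueError("target_library_size must be positive")


@dataclass
class ClusterAssignment:
    """Per-cell cluster ids plus one annotated cell type per cluster."""

    cluster_ids: np.ndarray  # per-cell small integers
    cluster_to_type: dict[int, str]
    cluster_to_score: dict[int, float]

    def cell_types(self) -> np.ndarray:
        return np.asarray([self.cluster_to_type[c] for c in self.cluster_ids], dtype=object)


def normalize_log(
    dataset: ExpressionDataset, params: ClusterParams | None = None
) -> np.ndarray:
    """Scale each cell to the target library size and log1p-transform.

    Returns a dense cells × genes float layer; the raw counts stay untouched
    on the dataset. Natural log. Zeros are preserved (a zero count maps to a
    zero normalized value), which keeps detection frequencies identical
    between the raw and normalized layers.
    """
    params = params or ClusterParams()
    lib = np.asarray(dataset.counts.sum(axis=1)).ravel().astype(float)
    if (lib == 0).any():
        raise ValueError(
            "dataset contains zero-count cells; apply QC before normalization"
        )
    target = (
        float(np.median(lib))
        if params.target_library_size == "median"
        else float(params.target_library_size)
    )
    scale = target / lib
    layer = dataset.counts.multiply(scale[:, None]).toarray()
    return np.log1p(layer)


def select_hvg(layer: np.ndarray, n_hvg: int) -> np.ndarray:
    """Indices of the ``n_hvg`` genes with the largest variance of the
    normalized layer, in decreasing order; ties broken by ascending gene
    index. If fewer genes are available all are used, with a warning."""
    layer = np.asarray(layer)
    G = layer.shape[1]
    if n_hvg > G:
        warnings.warn(
            f"n_hvg={n_hvg} exceeds the {G} available genes; using all genes"
        )
        n_hvg = G
    var = layer.var(axis=0)
    order = np.lexsort((np.arange(G), -var))
    return order[:n_hvg]


def _scale_genes(X: np.ndarray, clip: float) -> np.ndarray:
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return np.clip((X - mean) / sd, -clip, clip)


def embed_pca(
    layer: np.ndarray, hvg: np.ndarray, params: ClusterParams | None = None
) -> np.ndarray:
    """PCA embedding of the scaled HVG sub-layer, cells × n_pcs.

    Deterministic: full SVD, and each component is oriented so its largest-
    magnitude gene loading is positive.
    """
    params = params or ClusterParams()
    X = _scale_genes(np.asarray(layer)[:, np.asarray(hvg)], params.scale_clip)
    n_cells = X.shape[0]
    if n_cells < params.n_pcs:
        raise ValueError(f"need at least n_pcs={params.n_pcs} cells, got {n_cells}")
    n_comp = min(params.n_pcs, X.shape[1])
    pca = PCA(n_components=n_comp, svd_solver="full", random_state=params.seed)
    emb = pca.fit_transform(X)
    flip = np.sign(
        pca.components_[np.arange(n_comp), np.abs(pca.components_).argmax(axis=1)]
    )
    flip = np.where(flip == 0, 1.0, flip)
    return emb * flip


def cluster_graph(
    embedding: np.ndarray, params: ClusterParams | None = None
) -> np.ndarray:
    """Leiden community detection on the kNN graph of the embedding."""
    params = params or ClusterParams()
    emb = np.asarray(embedding, dtype=float)
    n_cells = emb.shape[0]
    if params.n_neighbors >= n_cells:
        raise ValueError(
            f"n_neighbors={params.n_neighbors} must be smaller than the "
            f"{n_cells} cells"
        )
    nn = NearestNeighbors(n_neighbors=params.n_neighbors + 1).fit(emb)
    _, idx = nn.kneighbors(emb)
    edges = set()
    for i in range(n_cells):
        for j in idx[i, 1:]:
            edges.add((min(i, int(j)), max(i, int(j))))
    graph = igraph.Graph(n=n_cells, edges=sorted(edges), directed=False)
    part = leidenalg.find_partition(
        graph,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=params.resolution,
        seed=params.seed,
        n_iterations=-1,
    )
    return np.asarray(part.membership, dtype=int)


def annotate_clusters(
    dataset: ExpressionDataset,
    clusters: np.ndarray,
    panels: GenePanel,
    layer: np.ndarray | None = None,
    params: ClusterParams | None = None,
) -> ClusterAssignment:
    """Assign one cell type per cluster by a mean rank-quantile panel score.

    For a cluster, each gene's within-cluster mean (log-normalized) expression
    is converted to its rank-quantile among all genes; a panel's score is the
    mean quantile of its genes that are present in the dataset. The cluster
    is annotated with the argmax panel; exact ties fall to the first panel in
    insertion order.
    """
    if layer is None:
        layer = normalize_log(dataset, params)
    clusters = np.asarray(clusters)
    symbols = dataset.gene_meta["symbol"]
    sym_to_idx = {s: i for i, s in enumerate(symbols)}
    panel_idx: dict[str, list[int]] = {}
    for cell_type, genes in panels:
        present = [sym_to_idx[g] for g in genes if g in sym_to_idx]
        if not present:
            missing = [g for g in genes if g not in sym_to_idx]
            raise ValueError(
                f"no gene of panel {cell_type!r} is present in the dataset; "
                f"missing: {missing}"
            )
        panel_idx[cell_type] = present

    cluster_to_type: dict[int, str] = {}
    cluster_to_score: dict[int, float] = {}
    for c in np.unique(clusters):
        mask = clusters == c
        quantiles = rank_ratio(layer[mask].mean(axis=0))
        best_type, best_score = None, -np.inf
        for cell_type, idx in panel_idx.items():  # insertion order breaks ties
            s = float(np.mean(quantiles[idx]))
            if s > best_score:
                best_type, best_score = cell_type, s
        cluster_to_type[int(c)] = best_type
        cluster_to_score[int(c)] = best_score
    return ClusterAssignment(clusters.astype(int), cluster_to_type, cluster_to_score)
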