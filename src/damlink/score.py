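"""Per-cell-type gene consensus score.

For each cell type, every gene gets two rank-quantiles relative to the other
genes of the same cell type: one for its detection frequency (fraction of the
type's cells with a nonzero raw count) and one for its mean expression on the
log-normalized layer. The consensus score is their sum, ranging from 0 (a
gene that is both the least frequent and the least expressed) to 2 (strictly
the most frequent and the most expressed).

The normative rank-quantile of this package is, for gene ``g`` among ``G``
genes with values ``v``::

    ratio(g) = (#{h != g : v_h < v_g} + 0.5 * #{h != g : v_h = v_g}) / (G - 1)

i.e. a strict comparison against the *other* genes, with ties counted at
half weight so that an all-equal vector scores 0.5 everywhere and the
quantiles average to exactly 0.5 within every cell type. A frequency ratio
of 0.6 therefore reads: the gene is detected in more cells than 60% of the
other genes of that cell type.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io import ExpressionDataset

__all__ = [
    "detection_frequency",
    "mean_expression",
    "rank_ratio",
    "consensus_scores",
]


def _cell_type_labels(dataset: ExpressionDataset, labels=None) -> np.ndarray:
    if labels is not None:
        labels = np.asarray(labels, dtype=object)
        if labels.shape[0] != dataset.n_cells:
            raise ValueError("labels length does not match number of cells")
        return labels
    if "cell_type" not in dataset.cell_meta.columns:
        raise ValueError(
            "dataset has no 'cell_type' annotation; run annotate_clusters first "
            "or pass labels explicitly"
        )
    return dataset.cell_meta["cell_type"].to_numpy(dtype=object)


def detection_frequency(
    dataset: ExpressionDataset, cell_type_label: str, labels=None
) -> np.ndarray:
    """Per-gene fraction of the cell type's cells with raw count > 0."""
    labels = _cell_type_labels(dataset, labels)
    mask = labels == cell_type_label
    if not mask.any():
        available = sorted(set(labels.tolist()))
        raise KeyError(
            f"unknown cell type {cell_type_label!r}; available: {available}"
        )
    sub = dataset.counts[np.flatnonzero(mask)]
    detected = sub.copy()
    detected.data = (detected.data > 0).astype(np.int64)
    return np.asarray(detected.sum(axis=0)).ravel() / mask.sum()


def mean_expression(layer: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Per-gene mean of the (log-normalized) layer over the masked cells."""
    return np.asarray(layer[mask]).mean(axis=0)


def rank_ratio(values) -> np.ndarray:
    """Half-tie rank quantile of each value relative to the others, in [0, 1].

    A strict unique maximum maps to exactly 1, a strict unique minimum to
    exactly 0, and an all-equal vector to 0.5 everywhere.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1:
        raise ValueError("rank_ratio expects a 1-D vector")
    G = v.shape[0]
    if G < 2:
        raise ValueError("rank ratio is undefined for fewer than 2 genes")
    # average rank = 1 + #{v_h < v_g} + 0.5 * #{ties among others}
    return (rankdata(v, method="average") - 1.0) / (G - 1.0)


def consensus_scores(
    dataset: ExpressionDataset,
    layer: np.ndarray,
    labels=None,
) -> pd.DataFrame:
    """Consensus score table for every (gene, cell type).

    Parameters
    ----------
    dataset
        Annotated dataset (post-QC) providing raw counts for detection.
    layer
        Log-normalized expression, cells × genes (see
        :func:`damlink.cluster.normalize_log`).
    labels
        Per-cell cell-type labels; defaults to ``cell_meta['cell_type']``.

    Returns
    -------
    DataFrame with columns cell_type, gene, detection_frequency,
    mean_expression, freq_ratio, expr_ratio, consensus — sorted by
    descending consensus within each cell type.
    """
    if dataset.n_genes < 2:
        raise ValueError("consensus score requires at least 2 genes")
    labels = _cell_type_labels(dataset, labels)
    layer = np.asarray(layer)
    if layer.shape != (dataset.n_cells, dataset.n_genes):
        raise ValueError("layer shape does not match dataset")
    blocks = []
    for cell_type in pd.unique(labels):
        mask = labels == cell_type
        if not mask.any():  # pragma: no cover - unique() precludes this
            warnings.warn(f"cell type {cell_type!r} has 0 cells; omitted")
            continue
        freq = detection_frequency(dataset, cell_type, labels)
        expr = mean_expression(layer, mask)
        fr = rank_ratio(freq)
        er = rank_ratio(expr)
        block = pd.DataFrame(
            {
                "cell_type": cell_type,
                "gene": dataset.gene_meta["symbol"].to_numpy(),
                "detection_frequency": freq,
                "mean_expression": expr,
                "freq_ratio": fr,
                "expr_ratio": er,
                "consensus": fr + er,
            }
        )
        blocks.append(
            block.sort_values(
                ["consensus", "gene"], ascending=[False, True], kind="mergesort"
            )
        )
    return pd.concat(blocks, ignore_index=True)
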