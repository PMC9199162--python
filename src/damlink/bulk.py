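"""Cross-study bulk RNA-seq harmonization.

Three small, composable steps applied to a gene × sample matrix:
``log2(x + pseudocount)``, quantile normalization (every sample is forced
onto the vector of cross-sample rank means; tied values within a sample
receive the mean of their reference values, the same rule limma's
``normalizeQuantiles`` uses), and a no-covariate batch centering (per gene,
each batch's mean is replaced by the grand mean — the special case of
linear-model batch-effect removal with no other covariates).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["BulkMatrix", "log2_shift", "quantile_normalize", "batch_center"]


@dataclass
class BulkMatrix:
    """Gene × sample expression values with a batch label per sample."""

    values: pd.DataFrame  # genes (rows) × samples (columns)
    batches: pd.Series  # indexed by sample id

    def __post_init__(self) -> None:
        if self.values.isna().to_numpy().any():
            raise ValueError("bulk matrix contains missing values")
        missing = [s for s in self.values.columns if s not in self.batches.index]
        if missing:
            raise ValueError(f"samples without a batch label: {missing}")
        self.batches = self.batches.loc[self.values.columns]


def log2_shift(matrix: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """Elementwise ``log2(x + pseudocount)``; x must be non-negative."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    values = matrix.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("negative values cannot be log2-transformed")
    return pd.DataFrame(
        np.log2(values + pseudocount), index=matrix.index, columns=matrix.columns
    )


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force all samples (columns) onto the vector of cross-sample rank means."""
    X = matrix.to_numpy(dtype=float)
    n_genes, n_samples = X.shape
    if n_samples < 2:
        warnings.warn("quantile normalization of a single sample is the identity")
        return matrix.copy()
    ref = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    for j in range(n_samples):
        x = X[:, j]
        order = np.argsort(x, kind="stable")
        col = np.empty(n_genes)
        col[order] = ref
        # ties: average the reference values assigned within each tie group
        uniq, inverse, counts = np.unique(x, return_inverse=True, return_counts=True)
        if len(uniq) < n_genes:
            sums = np.bincount(inverse, weights=col)
            col = (sums / counts)[inverse]
        out[:, j] = col
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def batch_center(matrix: pd.DataFrame, batches) -> pd.DataFrame:
    """Per gene, remove each batch's mean and restore the grand mean."""
    batches = pd.Series(batches)
    if set(batches.index) >= set(matrix.columns):
        batches = batches.loc[matrix.columns]
    elif len(batches) == matrix.shape[1]:
        batches = pd.Series(batches.to_numpy(), index=matrix.columns)
    else:
        raise ValueError("batch labels do not align with samples")
    X = matrix.to_numpy(dtype=float)
    grand = X.mean(axis=1, keepdims=True)
    out = X.copy()
    for b in pd.unique(batches):
        cols = np.flatnonzero((batches == b).to_numpy())
        if cols.size == 0:
            raise ValueError(f"batch {b!r} has no samples")
        out[:, cols] += grand - X[:, cols].mean(axis=1, keepdims=True)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
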