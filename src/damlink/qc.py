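"""Quality-control filtering of single-cell count matrices.

A single simultaneous pass over the raw matrix: a gene is kept iff it is
detected (count > 0) in at least ``min_cells_per_gene`` cells of the INPUT
matrix; a cell is kept iff it detects at least ``min_genes_per_cell`` genes
of the INPUT matrix, its mitochondrial count fraction does not exceed
``max_mito_fraction`` (strictly greater is removed — high-mito cells are
treated as dying), and any optional depth bounds hold. The filters are not
iterated to a fixed point, so after filtering a kept gene may fall below the
detection threshold among surviving cells; iteration is available as a
non-default option.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .io import ExpressionDataset

__all__ = ["QCParams", "QCReport", "apply_qc"]


@dataclass
class QCParams:
    """Thresholds for :func:`apply_qc`.

    Defaults are the standard droplet-QC values: gene present in ≥ 3 cells,
    cell expressing ≥ 200 genes, mitochondrial fraction ≤ 5%. UMI and
    genes-per-cell upper bounds default to off; they are dataset-specific
    (set them following the recommendations of whoever generated the data).
    ``exclude_barcodes`` is a hook for externally identified multiplets.
    """

    min_cells_per_gene: int = 3
    min_genes_per_cell: int = 200
    max_mito_fraction: float = 0.05
    umi_bounds: tuple[int, int] | None = None
    genes_per_cell_upper: int | None = None
    exclude_barcodes: tuple[str, ...] = field(default_factory=tuple)
    iterate: bool = False

    def __post_init__(self) -> None:
        if self.min_cells_per_gene < 0 or self.min_genes_per_cell < 0:
            raise ValueError("QC count thresholds must be non-negative")
        if not 0.0 <= self.max_mito_fraction <= 1.0:
            raise ValueError("max_mito_fraction must be a proportion")
        if self.umi_bounds is not None:
            lo, hi = self.umi_bounds
            if lo < 0 or hi < lo:
                raise ValueError("umi_bounds must satisfy 0 <= low <= high")
        self.exclude_barcodes = tuple(self.exclude_barcodes)


@dataclass
class QCReport:
    """Per-criterion removal bookkeeping. A cell can fail several criteria,
    so per-criterion counts can sum to more than the total removed."""

    n_cells_in: int
    n_cells_out: int
    n_genes_in: int
    n_genes_out: int
    cells_failed_gene_count: int
    cells_failed_mito: int
    cells_failed_depth: int
    cells_excluded_barcode: int
    genes_failed_min_cells: int

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"count": vars(self)}
        ).rename_axis("metric")


def _qc_masks(dataset: ExpressionDataset, params: QCParams):
    counts = dataset.counts.tocsr()
    detected = counts.copy()
    detected.data = (detected.data > 0).astype(np.int64)
    genes_per_cell = np.asarray(detected.sum(axis=1)).ravel()
    cells_per_gene = np.asarray(detected.sum(axis=0)).ravel()
    total = np.asarray(counts.sum(axis=1)).ravel().astype(float)
    mito_idx = dataset.gene_meta["is_mito"].to_numpy()
    mito_total = (
        np.asarray(counts[:, mito_idx].sum(axis=1)).ravel().astype(float)
        if mito_idx.any()
        else np.zeros_like(total)
    )
    # zero-count cells: define mito fraction 0 so they fall to the
    # gene-count rule rather than a division error
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(total > 0, mito_total / np.maximum(total, 1e-300), 0.0)

    ok_gene_count = genes_per_cell >= params.min_genes_per_cell
    if params.genes_per_cell_upper is not None:
        ok_gene_count &= genes_per_cell <= params.genes_per_cell_upper
    ok_mito = mito_frac <= params.max_mito_fraction
    if params.umi_bounds is not None:
        lo, hi = params.umi_bounds
        ok_depth = (total >= lo) & (total <= hi)
    else:
        ok_depth = np.ones_like(ok_mito)
    ok_barcode = ~dataset.cell_meta["barcode"].isin(params.exclude_barcodes).to_numpy()
    keep_cells = ok_gene_count & ok_mito & ok_depth & ok_barcode
    keep_genes = cells_per_gene >= params.min_cells_per_gene
    fails = {
        "gene_count": int((~ok_gene_count).sum()),
        "mito": int((~ok_mito).sum()),
        "depth": int((~ok_depth).sum()),
        "barcode": int((~ok_barcode).sum()),
    }
    return keep_cells, keep_genes, fails


def apply_qc(
    dataset: ExpressionDataset, params: QCParams | None = None
) -> tuple[ExpressionDataset, QCReport]:
    """Filter genes and cells in one simultaneous pass on the raw matrix."""
    params = params or QCParams()
    n_cells_in, n_genes_in = dataset.n_cells, dataset.n_genes
    if n_cells_in == 0:
        report = QCReport(0, 0, n_genes_in, n_genes_in, 0, 0, 0, 0, 0)
        return dataset.copy(), report

    keep_cells, keep_genes, fails = _qc_masks(dataset, params)
    out = dataset.subset(cells=keep_cells, genes=keep_genes)
    if params.iterate:
        while True:
            kc, kg, _ = _qc_masks(out, params)
            if kc.all() and kg.all():
                break
            out = out.subset(cells=kc, genes=kg)
    report = QCReport(
        n_cells_in=n_cells_in,
        n_cells_out=out.n_cells,
        n_genes_in=n_genes_in,
        n_genes_out=out.n_genes,
        cells_failed_gene_count=fails["gene_count"],
        cells_failed_mito=fails["mito"],
        cells_failed_depth=fails["depth"],
        cells_excluded_barcode=fails["barcode"],
        genes_failed_min_cells=int((~keep_genes).sum()),
    )
    return out, report
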