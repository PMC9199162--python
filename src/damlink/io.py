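"""Dataset container and readers/writers for standard single-cell matrix formats.

The in-memory convention is fixed: ``counts`` is always cells × genes,
whatever the on-disk orientation (10x-style Matrix Market files store
genes × cells; a dialect flag on the reader controls transposition).
All internal coordinates are 0-based; the 1-based triplet convention of
Matrix Market stays at the file boundary, handled by :mod:`scipy.io`.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "FormatError",
    "ExpressionDataset",
    "GenePanel",
    "read_sparse_triplet",
    "write_sparse_triplet",
    "read_dense_table",
    "read_gene_panels",
]

#: Case-insensitive gene-symbol prefixes flagged as mitochondrial
#: ("MT-" human, "mt-" mouse). Overridable by an explicit symbol list.
MITO_PREFIXES = ("mt-",)


class FormatError(ValueError):
    """A file does not conform to its declared format."""


def _is_mito(symbols: pd.Series, mito_symbols=None) -> np.ndarray:
    if mito_symbols is not None:
        wanted = set(mito_symbols)
        return symbols.isin(wanted).to_numpy()
    low = symbols.str.lower()
    mask = np.zeros(len(symbols), dtype=bool)
    for pref in MITO_PREFIXES:
        mask |= low.str.startswith(pref).to_numpy()
    return mask


@dataclass
class ExpressionDataset:
    """Sparse UMI count matrix (cells × genes) with aligned metadata.

    Parameters
    ----------
    counts
        Non-negative integer sparse matrix, shape ``(n_cells, n_genes)``.
    cell_meta
        One row per cell; columns ``barcode`` (unique), ``dataset_id`` and
        optionally ``group_label``, ``cluster``, ``cell_type``.
    gene_meta
        One row per gene; columns ``symbol`` (unique) and ``is_mito``.
    """

    counts: sp.csr_matrix
    cell_meta: pd.DataFrame
    gene_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.cell_meta = self.cell_meta.reset_index(drop=True)
        self.gene_meta = self.gene_meta.reset_index(drop=True)
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        n_cells, n_genes = self.counts.shape
        if len(self.cell_meta) != n_cells:
            raise FormatError(
                f"cell metadata has {len(self.cell_meta)} rows for {n_cells} cells"
            )
        if len(self.gene_meta) != n_genes:
            raise FormatError(
                f"gene metadata has {len(self.gene_meta)} rows for {n_genes} genes"
            )
        data = self.counts.data
        if data.size:
            if data.min() < 0:
                raise ValueError("counts contain negative entries")
            if not np.allclose(data, np.round(data)):
                raise ValueError("counts contain non-integer entries")
        if self.cell_meta["barcode"].duplicated().any():
            dup = self.cell_meta["barcode"][self.cell_meta["barcode"].duplicated()]
            raise ValueError(f"duplicate cell barcodes: {sorted(set(dup))[:5]}")
        if self.gene_meta["symbol"].duplicated().any():
            dup = self.gene_meta["symbol"][self.gene_meta["symbol"].duplicated()]
            raise ValueError(f"duplicate gene symbols: {sorted(set(dup))[:5]}")

    # -- conveniences -----------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    @property
    def gene_symbols(self) -> pd.Series:
        return self.gene_meta["symbol"]

    def gene_index(self, symbol: str) -> int:
        idx = np.flatnonzero((self.gene_meta["symbol"] == symbol).to_numpy())
        if idx.size == 0:
            raise KeyError(f"gene {symbol!r} not in dataset")
        return int(idx[0])

    def copy(self) -> "ExpressionDataset":
        return ExpressionDataset(
            self.counts.copy(), self.cell_meta.copy(), self.gene_meta.copy()
        )

    def subset(self, cells=None, genes=None) -> "ExpressionDataset":
        """Return a new dataset restricted to the given cell/gene indices or masks."""
        cells = np.arange(self.n_cells) if cells is None else np.asarray(cells)
        genes = np.arange(self.n_genes) if genes is None else np.asarray(genes)
        if cells.dtype == bool:
            cells = np.flatnonzero(cells)
        if genes.dtype == bool:
            genes = np.flatnonzero(genes)
        return ExpressionDataset(
            self.counts[cells][:, genes],
            self.cell_meta.iloc[cells],
            self.gene_meta.iloc[genes],
        )

    def content_hash(self) -> str:
        """SHA-256 over counts and both metadata tables (stable serialization)."""
        import hashlib

        h = hashlib.sha256()
        m = self.counts.tocsr()
        m.sum_duplicates()
        h.update(np.ascontiguousarray(m.indptr).tobytes())
        h.update(np.ascontiguousarray(m.indices).tobytes())
        h.update(np.ascontiguousarray(np.asarray(m.data, dtype=np.int64)).tobytes())
        h.update(self.cell_meta.to_csv(index=False).encode())
        h.update(self.gene_meta.to_csv(index=False).encode())
        return h.hexdigest()


@dataclass
class GenePanel:
    """Ordered marker-gene lists keyed by cell-type name."""

    panels: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[str, list[str]] = {}
        for cell_type, genes in self.panels.items():
            seen: list[str] = []
            for g in genes:
                if g not in seen:
                    seen.append(g)
            if not seen:
                raise ValueError(f"empty marker panel for cell type {cell_type!r}")
            clean[cell_type] = seen
        if not clean:
            raise ValueError("gene panel file defines no panels")
        self.panels = clean

    def __iter__(self):
        return iter(self.panels.items())


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _read_lines(path) -> list[str]:
    with open(path) as fh:
        return [ln.rstrip("\n") for ln in fh if ln.strip()]


def read_sparse_triplet(
    matrix_path,
    barcodes_path,
    features_path,
    *,
    orientation: str = "genes_rows",
    dataset_id: str | None = None,
    mito_symbols=None,
) -> ExpressionDataset:
    """Read a 10x-style Matrix Market triplet with barcode/feature sidecars.

    ``orientation`` names what the matrix rows are on disk; the returned
    container is always cells × genes. Features files with the symbol in
    column 2 (10x: id, symbol, type) are tolerated; single-column files are
    treated as symbols.
    """
    if orientation not in ("genes_rows", "cells_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    try:
        mat = scipy.io.mmread(os.fspath(matrix_path))
    except ValueError as exc:
        raise FormatError(f"{matrix_path}: not a Matrix Market file ({exc})") from exc
    mat = sp.coo_matrix(mat)
    if orientation == "genes_rows":
        mat = mat.T
    barcodes = _read_lines(barcodes_path)
    feat_lines = _read_lines(features_path)
    if len(barcodes) != mat.shape[0]:
        raise FormatError(
            f"{barcodes_path}: {len(barcodes)} barcodes for {mat.shape[0]} matrix cells"
        )
    if len(feat_lines) != mat.shape[1]:
        raise FormatError(
            f"{features_path}: {len(feat_lines)} features for {mat.shape[1]} matrix genes"
        )
    if mat.data.size and mat.data.min() < 0:
        raise ValueError(f"{matrix_path}: negative count entries")
    if mat.data.size and not np.allclose(mat.data, np.round(mat.data)):
        raise ValueError(f"{matrix_path}: non-integer count entries")

    fields = [ln.split("\t") for ln in feat_lines]
    symbols = pd.Series(
        [f[1] if len(f) >= 2 else f[0] for f in fields], name="symbol", dtype=object
    )
    gene_meta = pd.DataFrame(
        {"symbol": symbols, "is_mito": _is_mito(symbols, mito_symbols)}
    )
    cell_meta = pd.DataFrame(
        {
            "barcode": pd.Series(barcodes, dtype=object),
            "dataset_id": dataset_id or Path(matrix_path).stem,
        }
    )
    return ExpressionDataset(
        sp.csr_matrix(mat.astype(np.int64)), cell_meta, gene_meta
    )


def write_sparse_triplet(dataset: ExpressionDataset, out_dir) -> None:
    """Write ``matrix.mtx`` + ``barcodes.tsv`` + ``features.tsv`` (10x dialect:
    the matrix is stored genes × cells)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(
        os.fspath(out / "matrix.mtx"),
        sp.coo_matrix(dataset.counts.T.astype(np.int64)),
        field="integer",
    )
    (out / "barcodes.tsv").write_text(
        "".join(f"{b}\n" for b in dataset.cell_meta["barcode"])
    )
    (out / "features.tsv").write_text(
        "".join(f"{s}\t{s}\n" for s in dataset.gene_meta["symbol"])
    )


def read_dense_table(
    path,
    orientation: str = "cells_rows",
    *,
    dataset_id: str | None = None,
    mito_symbols=None,
) -> ExpressionDataset:
    """Read a dense TSV/CSV count table (header row + index column)."""
    if orientation not in ("cells_rows", "genes_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    sep = "," if str(path).endswith(".csv") else "\t"
    try:
        df = pd.read_csv(path, sep=sep, index_col=0, on_bad_lines="error")
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: ragged table ({exc})") from exc
    bad = df.isna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise FormatError(
            f"{path}: missing/non-numeric value at row {df.index[r]!r}, "
            f"column {df.columns[c]!r}"
        )
    if orientation == "genes_rows":
        df = df.T
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise FormatError(f"{path}: non-numeric entries")
    symbols = pd.Series(df.columns.astype(str), name="symbol", dtype=object)
    gene_meta = pd.DataFrame(
        {"symbol": symbols, "is_mito": _is_mito(symbols, mito_symbols)}
    )
    cell_meta = pd.DataFrame(
        {
            "barcode": pd.Series(df.index.astype(str), dtype=object),
            "dataset_id": dataset_id or Path(path).stem,
        }
    )
    return ExpressionDataset(sp.csr_matrix(values.astype(np.int64)), cell_meta, gene_meta)


def read_gene_panels(path) -> GenePanel:
    """Read marker panels from a two-column (cell_type, gene_symbol) TSV.

    A header row ``cell_type<TAB>gene_symbol`` is tolerated. Order of first
    appearance is preserved; duplicates within a panel are dropped.
    """
    rows = []
    for i, ln in enumerate(_read_lines(path), start=1):
        parts = ln.split("\t")
        if len(parts) != 2:
            raise FormatError(f"{path}: line {i}: expected 2 columns, got {len(parts)}")
        rows.append(parts)
    if rows and [p.lower() for p in rows[0]] == ["cell_type", "gene_symbol"]:
        rows = rows[1:]
    if not rows:
        raise ValueError(f"{path}: gene panel file has no data rows")
    panels: dict[str, list[str]] = {}
    for cell_type, gene in rows:
        panels.setdefault(cell_type, []).append(gene)
    return GenePanel(panels)
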