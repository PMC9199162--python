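"""Target-gene / DAM-marker correlation-and-presence selection.

Within the named microglial subclusters of each dataset, every candidate
marker is (1) correlated with the target gene over *all* cells of the pooled
subclusters on the log-normalized layer, and (2) checked for presence (raw
count > 0) among the target-positive cells (raw target count > 0). A marker
of the up-in-DAM class is kept in a dataset iff r <= -corr_threshold and
presence >= presence_threshold; a down-in-DAM marker needs r >= +corr_threshold
and the same presence bound. All bounds are inclusive. The final kept set is
the intersection across the configured datasets (when ``require_all_datasets``).

Target-positivity enters only the presence criterion, never the correlation;
the cells used for each are logged per run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import pearsonr, spearmanr

from .io import ExpressionDataset

__all__ = [
    "CorrelationFilterParams",
    "MarkerSet",
    "subcluster_mask",
    "target_positive_presence",
    "marker_target_correlation",
    "evaluate_dataset_markers",
    "select_markers",
]

logger = logging.getLogger(__name__)


@dataclass
class MarkerSet:
    """Up- and down-regulated DAM marker candidates (disjoint symbol lists)."""

    up_markers: list[str]
    down_markers: list[str]

    def __post_init__(self) -> None:
        overlap = set(self.up_markers) & set(self.down_markers)
        if overlap:
            raise ValueError(f"markers in both classes: {sorted(overlap)}")

    def classes(self) -> list[tuple[str, str]]:
        return [("up", m) for m in self.up_markers] + [
            ("down", m) for m in self.down_markers
        ]


@dataclass
class CorrelationFilterParams:
    """Thresholds and per-dataset subcluster names for marker selection."""

    target_gene: str = "Piezo1"
    corr_threshold: float = 0.7
    presence_threshold: float = 0.70
    subclusters_per_dataset: dict[str, list[str]] = field(default_factory=dict)
    require_all_datasets: bool = True
    correlation_kind: str = "pearson_on_lognorm"
    per_subcluster: bool = False  # experimental: evaluate each subcluster alone

    def __post_init__(self) -> None:
        for name, v in (
            ("corr_threshold", self.corr_threshold),
            ("presence_threshold", self.presence_threshold),
        ):
            if not 0 < v <= 1:
                raise ValueError(f"{name} must lie in (0, 1]")
        if self.correlation_kind not in ("pearson_on_lognorm", "spearman_on_lognorm"):
            raise ValueError(f"unknown correlation_kind {self.correlation_kind!r}")


def subcluster_mask(
    dataset: ExpressionDataset, subclusters, labels=None
) -> np.ndarray:
    """Cells belonging to the named subclusters.

    Names are matched exactly against per-cell labels: the ``labels``
    argument if given, else the dataset's ``cell_type`` then ``cluster``
    metadata columns (a cell matches if either does).
    """
    wanted = set(subclusters)
    mask = np.zeros(dataset.n_cells, dtype=bool)
    if labels is not None:
        mask |= np.isin(np.asarray(labels, dtype=object), list(wanted))
    else:
        for col in ("cell_type", "cluster"):
            if col in dataset.cell_meta.columns:
                mask |= dataset.cell_meta[col].isin(wanted).to_numpy()
    return mask


def target_positive_presence(
    dataset: ExpressionDataset,
    subclusters,
    target: str,
    marker: str,
    labels=None,
) -> float:
    """Among subcluster cells with raw target count > 0, the fraction with a
    raw marker count > 0. NaN if there are no target-positive cells."""
    mask = subcluster_mask(dataset, subclusters, labels)
    cells = np.flatnonzero(mask)
    if cells.size == 0:
        raise ValueError(f"no cells in subclusters {list(subclusters)}")
    t = np.asarray(
        dataset.counts[cells, dataset.gene_index(target)].todense()
    ).ravel()
    positive = cells[t > 0]
    if positive.size == 0:
        return float("nan")
    m = np.asarray(
        dataset.counts[positive, dataset.gene_index(marker)].todense()
    ).ravel()
    return float((m > 0).mean())


def _corr(x: np.ndarray, y: np.ndarray, kind: str) -> float:
    if kind == "pearson_on_lognorm":
        return float(pearsonr(x, y).statistic)
    return float(spearmanr(x, y).statistic)


def marker_target_correlation(
    dataset: ExpressionDataset,
    layer: np.ndarray,
    subclusters,
    target: str,
    markers,
    kind: str = "pearson_on_lognorm",
    labels=None,
) -> pd.Series:
    """Correlation of each marker with the target over all cells of the
    pooled named subclusters, on the log-normalized layer.

    A zero-variance marker yields NaN (it cannot satisfy any threshold).
    """
    mask = subcluster_mask(dataset, subclusters, labels)
    n = int(mask.sum())
    if n < 3:
        raise ValueError(
            f"need at least 3 cells in subclusters {list(subclusters)}, got {n}"
        )
    t = np.asarray(layer)[mask, dataset.gene_index(target)]
    if np.ptp(t) == 0:
        raise ValueError(f"target {target!r} has zero variance in the subclusters")
    logger.info(
        "correlation over %d pooled cells of subclusters %s", n, list(subclusters)
    )
    out = {}
    for m in markers:
        x = np.asarray(layer)[mask, dataset.gene_index(m)]
        out[m] = float("nan") if np.ptp(x) == 0 else _corr(t, x, kind)
    return pd.Series(out, name="r")


def evaluate_dataset_markers(
    dataset: ExpressionDataset,
    layer: np.ndarray,
    markers: MarkerSet,
    params: CorrelationFilterParams,
    dataset_id: str | None = None,
    labels=None,
) -> pd.DataFrame:
    """Per-marker correlation and presence within one dataset.

    Returns one row per marker: marker, class, r, presence, reason (why a
    value is undefined, if it is). Absent markers get reason "absent".
    """
    dataset_id = dataset_id or str(dataset.cell_meta["dataset_id"].iloc[0])
    subclusters = params.subclusters_per_dataset.get(dataset_id)
    if not subclusters:
        raise ValueError(f"no subclusters configured for dataset {dataset_id!r}")
    symbols = set(dataset.gene_meta["symbol"])
    rows = []
    present = [
        m for _, m in markers.classes() if m in symbols
    ]
    rs = marker_target_correlation(
        dataset, layer, subclusters, params.target_gene, present,
        params.correlation_kind, labels,
    )
    mask = subcluster_mask(dataset, subclusters, labels)
    cells = np.flatnonzero(mask)
    t = np.asarray(
        dataset.counts[cells, dataset.gene_index(params.target_gene)].todense()
    ).ravel()
    n_positive = int((t > 0).sum())
    for cls, m in markers.classes():
        if m not in symbols:
            rows.append((m, cls, np.nan, np.nan, "absent"))
            continue
        r = rs[m]
        if n_positive == 0:
            rows.append((m, cls, r, np.nan, "no target-positive cells"))
            continue
        presence = target_positive_presence(
            dataset, subclusters, params.target_gene, m, labels
        )
        reason = "constant expression" if np.isnan(r) else ""
        rows.append((m, cls, r, presence, reason))
    df = pd.DataFrame(
        rows, columns=["marker", "class", "r", "presence", "reason"]
    )
    df.insert(0, "dataset_id", dataset_id)
    return df


def _passes(cls: str, r: float, presence: float, params: CorrelationFilterParams) -> bool:
    if np.isnan(r) or np.isnan(presence):
        return False
    if presence < params.presence_threshold:
        return False
    if cls == "up":
        return r <= -params.corr_threshold
    return r >= params.corr_threshold


def select_markers(
    results_per_dataset: dict[str, pd.DataFrame],
    markers: MarkerSet,
    params: CorrelationFilterParams,
) -> pd.DataFrame:
    """Combine per-dataset evaluations into the final keep/drop table.

    One row per (marker, dataset) with a ``passed`` flag, plus a
    ``final_kept`` column equal to the AND (or OR when
    ``require_all_datasets=False``) over the configured datasets.
    """
    required = list(params.subclusters_per_dataset)
    missing = [d for d in required if d not in results_per_dataset]
    if missing:
        raise ValueError(f"datasets not evaluated: {missing}")
    frames = []
    for ds in required:
        df = results_per_dataset[ds].copy()
        df["passed"] = [
            _passes(c, r, p, params)
            for c, r, p in zip(df["class"], df["r"], df["presence"])
        ]
        frames.append(df)
    combined = pd.concat(frames, ignore_index=True)
    agg = combined.groupby("marker")["passed"]
    final = agg.all() if params.require_all_datasets else agg.any()
    combined["final_kept"] = combined["marker"].map(final)
    order = {m: i for i, (_, m) in enumerate(markers.classes())}
    combined["_o"] = combined["marker"].map(order)
    combined = combined.sort_values(["_o", "dataset_id"], kind="mergesort")
    return combined.drop(columns="_o").reset_index(drop=True)
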