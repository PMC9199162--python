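"""End-to-end orchestration: QC -> normalize -> embed -> cluster -> annotate
-> consensus scores -> cross-dataset marker selection.

Stages are pure with respect to their inputs (the input datasets are never
mutated) and the whole chain is deterministic under a fixed config + seed;
every run emits a :class:`PipelineRunRecord` with content hashes of all
inputs and outputs so reruns can be compared byte-for-byte.
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import dataclass, field, replace

import pandas as pd

from . import __version__
from .cluster import (
    annotate_clusters,
    cluster_graph,
    embed_pca,
    normalize_log,
    select_hvg,
)
from .config import AnalysisConfig
from .io import ExpressionDataset, GenePanel
from .markers import evaluate_dataset_markers, select_markers
from .qc import apply_qc
from .score import consensus_scores

__all__ = ["PipelineRunRecord", "PipelineResult", "run_pipeline"]

logger = logging.getLogger(__name__)


def _frame_hash(df: pd.DataFrame) -> str:
    return hashlib.sha256(
        df.to_csv(index=False, float_format="%.12g").encode()
    ).hexdigest()


@dataclass
class PipelineRunRecord:
    config: dict
    seed: int
    version: str
    input_hashes: dict[str, str]
    output_hashes: dict[str, str] = field(default_factory=dict)
    qc_reports: dict[str, dict] = field(default_factory=dict)
    started: float = 0.0
    finished: float = 0.0


@dataclass
class PipelineResult:
    scores: pd.DataFrame
    selection: pd.DataFrame
    record: PipelineRunRecord
    annotated: dict[str, ExpressionDataset] = field(default_factory=dict)


def _validate(config: AnalysisConfig, dataset_ids: list[str]) -> None:
    """Fail fast, before any compute."""
    if not dataset_ids:
        raise ValueError("at least one dataset is required")
    if len(set(dataset_ids)) != len(dataset_ids):
        raise ValueError(f"duplicate dataset ids: {dataset_ids}")
    if not config.panels:
        raise ValueError("config defines no annotation panels")
    missing = [
        d for d in dataset_ids if not config.corr_filter.subclusters_per_dataset.get(d)
    ]
    if missing:
        raise ValueError(
            f"config names no subclusters for dataset(s) {missing}; "
            "set corr_filter.subclusters_per_dataset"
        )
    config.marker_set()  # validates disjointness


def run_pipeline(
    config: AnalysisConfig, datasets: list[ExpressionDataset]
) -> PipelineResult:
    """Run the full analysis over one or more datasets.

    Returns the concatenated per-dataset consensus-score table, the final
    marker-selection table (intersection across datasets), and the run
    record. Input datasets are left untouched.
    """
    dataset_ids = [str(d.cell_meta["dataset_id"].iloc[0]) for d in datasets]
    _validate(config, dataset_ids)
    panels = GenePanel(dict(config.panels))
    markers = config.marker_set()

    record = PipelineRunRecord(
        config=config.to_dict(),
        seed=config.seed,
        version=__version__,
        input_hashes={i: d.content_hash() for i, d in zip(dataset_ids, datasets)},
        started=time.time(),
    )

    score_blocks = []
    per_dataset_results = {}
    annotated_out = {}
    for ds_id, dataset in zip(dataset_ids, datasets):
        try:
            logger.info("[%s] QC on %d cells x %d genes", ds_id, dataset.n_cells, dataset.n_genes)
            clean, report = apply_qc(dataset, config.qc)
            record.qc_reports[ds_id] = vars(report)
            cparams = replace(
                config.cluster,
                seed=config.seed,
                resolution=config.per_dataset_resolution.get(
                    ds_id, config.cluster.resolution
                ),
            )
            layer = normalize_log(clean, cparams)
            hvg = select_hvg(layer, cparams.n_hvg)
            embedding = embed_pca(layer, hvg, cparams)
            clusters = cluster_graph(embedding, cparams)
            assignment = annotate_clusters(clean, clusters, panels, layer, cparams)
            annotated = clean.copy()
            annotated.cell_meta["cluster"] = [str(c) for c in clusters]
            annotated.cell_meta["cell_type"] = assignment.cell_types()
            logger.info(
                "[%s] %d clusters -> types %s", ds_id,
                len(assignment.cluster_to_type),
                sorted(set(assignment.cluster_to_type.values())),
            )
            scores = consensus_scores(annotated, layer)
            scores.insert(0, "dataset_id", ds_id)
            score_blocks.append(scores)
            per_dataset_results[ds_id] = evaluate_dataset_markers(
                annotated, layer, markers, config.corr_filter, ds_id
            )
            annotated_out[ds_id] = annotated
        except Exception as exc:
            raise RuntimeError(f"pipeline failed on dataset {ds_id!r}: {exc}") from exc

    selection = select_markers(per_dataset_results, markers, config.corr_filter)
    all_scores = pd.concat(score_blocks, ignore_index=True)
    record.output_hashes = {
        "scores": _frame_hash(all_scores),
        "selection": _frame_hash(selection),
        **{f"annotated:{k}": v.content_hash() for k, v in annotated_out.items()},
    }
    record.finished = time.time()
    return PipelineResult(all_scores, selection, record, annotated_out)
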