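"""One validated configuration structure for the whole pipeline.

Every threshold the analysis uses (gene/cell/mito QC cut-offs, HVG and PC
counts, per-dataset clustering resolutions, the ±0.7 correlation and 70%
presence bounds, power-analysis assumptions) lives here as data, never as a
literal in stage code. The structure serializes to YAML and round-trips
losslessly.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

from .cluster import ClusterParams
from .markers import CorrelationFilterParams, MarkerSet
from .qc import QCParams
from .stats import PowerParams

__all__ = ["AnalysisConfig"]


@dataclass
class AnalysisConfig:
    qc: QCParams = field(default_factory=QCParams)
    cluster: ClusterParams = field(default_factory=ClusterParams)
    corr_filter: CorrelationFilterParams = field(default_factory=CorrelationFilterParams)
    power: PowerParams = field(default_factory=PowerParams)
    seed: int = 0
    #: per-dataset Leiden resolution overrides, dataset_id -> resolution
    per_dataset_resolution: dict[str, float] = field(default_factory=dict)
    #: annotation panels, cell type -> gene symbols
    panels: dict[str, list[str]] = field(default_factory=dict)
    #: candidate DAM markers, {"up": [...], "down": [...]}
    markers: dict[str, list[str]] = field(default_factory=lambda: {"up": [], "down": []})

    def marker_set(self) -> MarkerSet:
        return MarkerSet(list(self.markers.get("up", [])), list(self.markers.get("down", [])))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["qc"]["umi_bounds"] = (
            list(self.qc.umi_bounds) if self.qc.umi_bounds is not None else None
        )
        d["qc"]["exclude_barcodes"] = list(self.qc.exclude_barcodes)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        d = dict(d)
        qc = dict(d.get("qc", {}))
        if qc.get("umi_bounds") is not None:
            qc["umi_bounds"] = tuple(qc["umi_bounds"])
        if "exclude_barcodes" in qc:
            qc["exclude_barcodes"] = tuple(qc["exclude_barcodes"])
        return cls(
            qc=QCParams(**qc),
            cluster=ClusterParams(**d.get("cluster", {})),
            corr_filter=CorrelationFilterParams(**d.get("corr_filter", {})),
            power=PowerParams(**d.get("power", {})),
            seed=int(d.get("seed", 0)),
            per_dataset_resolution=dict(d.get("per_dataset_resolution", {})),
            panels={k: list(v) for k, v in d.get("panels", {}).items()},
            markers={k: list(v) for k, v in d.get("markers", {"up": [], "down": []}).items()},
        )

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "AnalysisConfig":
        if hasattr(source, "read"):
            data = yaml.safe_load(source)
        else:
            with open(source) as fh:
                data = yaml.safe_load(fh)
        return cls.from_dict(data or {})
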