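"""Seeded synthetic single-cell count generator with a planted DAM structure.

The generator emulates the statistical shape the analysis assumes: several
cell types with their own marker panels; a microglial population containing
a disease-associated (DAM) subpopulation driven by a latent activation
factor; a target gene ("Piezo1-like") whose expression falls with activation;
up-regulated DAM markers that rise with activation (hence anticorrelate with
the target) and down-regulated DAM markers that fall with it (hence
correlate positively); null candidate markers that are microglia-enriched
but independent of the target; mitochondrial genes at a controllable
expected fraction; and log-normal library-size variation.

Mechanism: cell type is drawn from the configured proportions; microglial
cells get a latent activation ``a ~ N(dam_shift * is_dam, 1)`` (zero
elsewhere); gene ``g`` in cell ``c`` has mean
``exp(log base(type_c, g) + loading_g * a_c) * L_c`` with ``L_c`` a
log-normal library factor of unit mean; counts are negative-binomial
(gamma–Poisson) with dispersion ``nb_dispersion``. Count-level correlations
are attenuated relative to the latent ones, so the up/down loadings are
calibrated against a pre-computed attenuation curve (Monte-Carlo on the
generative model itself) such that the model correlation between target and
each marker class, measured as Pearson on the log-normalized layer over the
microglial population, equals the requested value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import ExpressionDataset, GenePanel
from .markers import MarkerSet

__all__ = [
    "SimParams",
    "SimulationTruth",
    "calibrate_loading",
    "simulate_dataset",
    "simulate_dataset_pair",
    "make_toy_fixtures",
]

_CALIBRATION_SEED = 987654321  # internal; calibration is a pure function
_calibration_memo: dict[tuple, float] = {}  # pure-function memo, safe to share


@dataclass
class SimParams:
    """Generator settings. Defaults plant the study-shaped structure:
    3000 cells, 7 up-markers at model r = -0.85 with the target, 13
    down-markers at r = +0.8, 50 null candidates."""

    n_cells: int = 3000
    n_genes: int = 500
    cell_types: tuple[str, ...] = ("Microglia", "Astrocyte", "Neuron")
    cell_type_proportions: tuple[float, ...] = (0.4, 0.3, 0.3)
    markers_per_type: int = 30
    marker_fold: float = 8.0
    dam_fraction_of_microglia: float = 0.4
    dam_shift: float = 3.0
    up_markers: int = 7
    down_markers: int = 13
    n_null_markers: int = 50
    target_up_corr: float = -0.85
    target_down_corr: float = 0.8
    target_gene: str = "Piezo1"
    target_mean: float = 12.0
    target_loading: float = 1.3
    dam_marker_mean: float = 15.0
    baseline_mean: float = 0.3
    nb_dispersion: float = 6.0
    libsize_sigma: float = 0.25
    mito_genes: int = 10
    mito_mean_fraction: float = 0.03
    seed: int = 0
    dataset_id: str = "sim"

    def __post_init__(self) -> None:
        props = np.asarray(self.cell_type_proportions, dtype=float)
        if len(props) != len(self.cell_types):
            raise ValueError("one proportion per cell type required")
        if not np.isclose(props.sum(), 1.0):
            raise ValueError("cell_type_proportions must sum to 1")
        if not (-1 < self.target_up_corr <= 0):
            raise ValueError("target_up_corr must lie in (-1, 0]")
        if not (0 <= self.target_down_corr < 1):
            raise ValueError("target_down_corr must lie in [0, 1)")
        for name in (
            "n_cells", "n_genes", "baseline_mean", "nb_dispersion",
            "dam_marker_mean", "target_mean", "marker_fold",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.mito_mean_fraction < 1:
            raise ValueError("mito_mean_fraction must be a proportion below 1")
        core = (
            len(self.cell_types) * self.markers_per_type
            + self.up_markers + self.down_markers + self.n_null_markers
            + 1 + self.mito_genes
        )
        if self.n_genes < core:
            raise ValueError(
                f"n_genes={self.n_genes} too small for the planted structure "
                f"({core} structural genes)"
            )


@dataclass
class SimulationTruth:
    """Planted labels, gene roles and requested correlations for one dataset."""

    cell_types: np.ndarray
    is_dam: np.ndarray
    gene_roles: pd.DataFrame  # columns: symbol, role, loading
    requested: dict[str, float]
    seed: int

    def type_panels(self, genes_per_panel: int = 10) -> GenePanel:
        """Marker panels for cluster annotation, from the planted type markers."""
        panels: dict[str, list[str]] = {}
        for _, row in self.gene_roles.iterrows():
            role = row["role"]
            if role.startswith("type_marker:"):
                panels.setdefault(role.split(":", 1)[1], []).append(row["symbol"])
        return GenePanel({t: g[:genes_per_panel] for t, g in panels.items()})

    def planted_marker_set(self) -> MarkerSet:
        r = self.gene_roles
        return MarkerSet(
            list(r.loc[r.role == "up", "symbol"]),
            list(r.loc[r.role == "down", "symbol"]),
        )

    def candidate_marker_set(self) -> MarkerSet:
        """Planted markers plus the null decoys, split over the two classes
        (a null candidate has to be nominated as one or the other)."""
        planted = self.planted_marker_set()
        nulls = list(self.gene_roles.loc[self.gene_roles.role == "null_marker", "symbol"])
        return MarkerSet(
            planted.up_markers + nulls[0::2],
            planted.down_markers + nulls[1::2],
        )


# ---------------------------------------------------------------------------
# gene layout and loading calibration
# ---------------------------------------------------------------------------

def _gene_layout(params: SimParams) -> pd.DataFrame:
    rows: list[tuple[str, str]] = []
    for t in params.cell_types:
        rows += [(f"{t}_mk{j + 1}", f"type_marker:{t}") for j in range(params.markers_per_type)]
    rows += [(f"UpDam{j + 1}", "up") for j in range(params.up_markers)]
    rows += [(f"DnDam{j + 1}", "down") for j in range(params.down_markers)]
    rows += [(f"NullMk{j + 1}", "null_marker") for j in range(params.n_null_markers)]
    rows += [(params.target_gene, "target")]
    rows += [(f"mt-Nd{j + 1}", "mito") for j in range(params.mito_genes)]
    rows += [(f"Bg{j + 1}", "background") for j in range(params.n_genes - len(rows))]
    return pd.DataFrame(rows, columns=["symbol", "role"])


def _draw_counts(rng: np.random.Generator, mu: np.ndarray, theta: float) -> np.ndarray:
    lam = rng.gamma(shape=theta, scale=mu / theta)
    return rng.poisson(lam)


def _microglia_latent(rng, n, dam_fraction, dam_shift):
    is_dam = rng.random(n) < dam_fraction
    a = rng.standard_normal(n) + dam_shift * is_dam
    return a, is_dam


def calibrate_loading(
    requested_r: float,
    marker_sign: float,
    params: SimParams,
    n_cells: int = 6000,
    grid_max: float = 3.0,
    grid_size: int = 31,
) -> float:
    """Solve the marker loading whose model correlation with the target
    (Pearson on the log-normalized layer, microglial population) matches
    ``requested_r``.

    The attenuation curve |r|(loading) is estimated by Monte-Carlo on the
    generative model with an internal fixed seed, then inverted by linear
    interpolation. Raises if the request exceeds the maximum attainable
    magnitude (the target's own count-noise reliability bounds it).
    """
    want = abs(requested_r)
    if want == 0:
        return 0.0
    key = (
        round(want, 12), marker_sign, n_cells, grid_max, grid_size,
        params.dam_fraction_of_microglia, params.dam_shift,
        params.libsize_sigma, params.target_mean, params.target_loading,
        params.dam_marker_mean, params.nb_dispersion,
    )
    if key in _calibration_memo:
        return _calibration_memo[key]
    rng = np.random.default_rng(_CALIBRATION_SEED)
    a, _ = _microglia_latent(
        rng, n_cells, params.dam_fraction_of_microglia, params.dam_shift
    )
    L = np.exp(
        rng.normal(0.0, params.libsize_sigma, n_cells) - params.libsize_sigma**2 / 2
    )
    mu_t = np.exp(np.log(params.target_mean) - params.target_loading * a) * L
    ct = _draw_counts(rng, mu_t, params.nb_dispersion)
    xt = np.log1p(ct / L)
    if np.ptp(xt) == 0:  # pragma: no cover - degenerate params only
        raise ValueError("target counts are constant; cannot calibrate")
    grid = np.linspace(0.0, grid_max, grid_size)
    curve = np.empty(grid_size)
    for i, lam in enumerate(grid):
        mu_m = np.exp(np.log(params.dam_marker_mean) + marker_sign * lam * a) * L
        cm = _draw_counts(rng, mu_m, params.nb_dispersion)
        xm = np.log1p(cm / L)
        curve[i] = 0.0 if np.ptp(xm) == 0 else abs(np.corrcoef(xt, xm)[0, 1])
    curve = np.maximum.accumulate(curve)  # enforce monotonicity for inversion
    if want > curve[-1]:
        raise ValueError(
            f"requested |r|={want:.3f} unattainable under this dispersion/"
            f"noise; max attainable |r| ~= {curve[-1]:.3f}"
        )
    solved = float(np.interp(want, curve, grid))
    _calibration_memo[key] = solved
    return solved


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def simulate_dataset(
    params: SimParams | None = None,
    seed: int | None = None,
    dataset_id: str | None = None,
) -> tuple[ExpressionDataset, SimulationTruth]:
    """Draw one dataset; bit-reproducible from (params, seed)."""
    params = params or SimParams()
    seed = params.seed if seed is None else int(seed)
    dataset_id = dataset_id or params.dataset_id
    rng = np.random.default_rng(seed)

    layout = _gene_layout(params)
    roles = layout["role"].to_numpy()
    G = params.n_genes
    types = np.asarray(params.cell_types, dtype=object)
    mg = 0  # microglia are always the first configured type

    lam_up = calibrate_loading(params.target_up_corr, +1.0, params)
    lam_dn = calibrate_loading(params.target_down_corr, -1.0, params)
    loading = np.zeros(G)
    loading[roles == "target"] = -params.target_loading
    loading[roles == "up"] = +lam_up
    loading[roles == "down"] = -lam_dn

    # per-(type, gene) base means
    base = np.full((len(types), G), params.baseline_mean)
    for ti, t in enumerate(types):
        base[ti, roles == f"type_marker:{t}"] = params.baseline_mean * params.marker_fold
    for role, mean in (
        ("up", params.dam_marker_mean),
        ("down", params.dam_marker_mean),
        ("null_marker", params.dam_marker_mean),
        ("target", params.target_mean),
    ):
        base[mg, roles == role] = mean

    # mitochondrial means per type, set so the expected mito fraction matches
    mito = roles == "mito"
    if params.mito_genes and params.mito_mean_fraction > 0:
        p = params.dam_fraction_of_microglia
        s = params.dam_shift
        ea = (1 - p) * np.exp(loading**2 / 2) + p * np.exp(
            loading * s + loading**2 / 2
        )  # E[exp(loading * a)] over the microglial mixture
        for ti in range(len(types)):
            factor = ea if ti == mg else np.ones(G)
            t_total = float((base[ti, ~mito] * factor[~mito]).sum())
            f = params.mito_mean_fraction
            base[ti, mito] = f / (1 - f) * t_total / params.mito_genes

    cell_type_idx = rng.choice(
        len(types), size=params.n_cells, p=np.asarray(params.cell_type_proportions)
    )
    is_mg = cell_type_idx == mg
    a = np.zeros(params.n_cells)
    is_dam = np.zeros(params.n_cells, dtype=bool)
    a_mg, dam_mg = _microglia_latent(
        rng, int(is_mg.sum()), params.dam_fraction_of_microglia, params.dam_shift
    )
    a[is_mg] = a_mg
    is_dam[is_mg] = dam_mg
    L = np.exp(
        rng.normal(0.0, params.libsize_sigma, params.n_cells)
        - params.libsize_sigma**2 / 2
    )
    mu = base[cell_type_idx] * np.exp(np.outer(a, loading)) * L[:, None]
    counts = _draw_counts(rng, mu, params.nb_dispersion)

    gene_meta = pd.DataFrame({"symbol": layout["symbol"], "is_mito": mito})
    cell_meta = pd.DataFrame(
        {
            "barcode": [f"{dataset_id}-c{i:05d}" for i in range(params.n_cells)],
            "dataset_id": dataset_id,
        }
    )
    dataset = ExpressionDataset(sp.csr_matrix(counts), cell_meta, gene_meta)
    truth = SimulationTruth(
        cell_types=types[cell_type_idx],
        is_dam=is_dam,
        gene_roles=layout.assign(loading=loading),
        requested={
            "target_up_corr": params.target_up_corr,
            "target_down_corr": params.target_down_corr,
        },
        seed=seed,
    )
    return dataset, truth


def simulate_dataset_pair(
    params: SimParams | None = None,
) -> list[tuple[ExpressionDataset, SimulationTruth]]:
    """Two datasets sharing gene roles and requested correlations but drawn
    with independent noise (seeds derived from ``params.seed``)."""
    params = params or SimParams()
    child = np.random.SeedSequence(params.seed).generate_state(2) % (2**31)
    return [
        simulate_dataset(params, seed=int(child[i]), dataset_id=f"ds{i + 1}")
        for i in range(2)
    ]


# ---------------------------------------------------------------------------
# deterministic toy fixtures
# ---------------------------------------------------------------------------

def _dataset_from_dense(counts, symbols, barcodes, dataset_id="toy"):
    symbols = pd.Series(symbols, dtype=object)
    is_mito = symbols.str.lower().str.startswith("mt-").to_numpy()
    return ExpressionDataset(
        sp.csr_matrix(np.asarray(counts, dtype=np.int64)),
        pd.DataFrame({"barcode": list(barcodes), "dataset_id": dataset_id}),
        pd.DataFrame({"symbol": symbols, "is_mito": is_mito}),
    )


def make_toy_fixtures() -> dict:
    """Small deterministic fixtures used across the test suite.

    ``qc_small``: 6 cells × 5 genes with hand-enumerated QC survivors.
    ``qc_boundary``: 6 cells × 203 genes engineered to sit exactly on the
    default QC thresholds (199/200 detected genes, mito fraction
    0.05/0.0501, gene in 2/3 cells).
    ``consensus_extremes``: 10 cells × 5 genes where the target is strictly
    top in both detection and expression and one gene strictly bottom.
    ``score``: seeded 200 cells × 50 genes for oracle comparisons.
    ``blobs``: two well-separated Gaussian blobs in 5 dimensions.
    """
    from .qc import QCParams

    fixtures: dict = {}

    counts = np.array(
        [
            [1, 5, 2, 0, 0],
            [0, 3, 1, 2, 0],
            [6, 1, 0, 1, 0],
            [0, 0, 0, 4, 3],
            [0, 2, 0, 0, 0],
            [1, 1, 1, 1, 1],
        ]
    )
    fixtures["qc_small"] = {
        "dataset": _dataset_from_dense(
            counts, ["mt-Co1", "G2", "G3", "G4", "G5"],
            [f"c{i + 1}" for i in range(6)],
        ),
        "params": QCParams(
            min_cells_per_gene=3, min_genes_per_cell=2, max_mito_fraction=0.5
        ),
        # hand enumeration: c3 fails mito (6/8 > 0.5), c5 detects 1 gene,
        # G5 is detected in only 2 cells
        "expected": {
            "kept_barcodes": ["c1", "c2", "c4", "c6"],
            "kept_genes": ["mt-Co1", "G2", "G3", "G4"],
            "cells_failed_mito": 1,
            "cells_failed_gene_count": 1,
            "genes_failed_min_cells": 1,
        },
    }

    G = 203
    symbols = [f"G{j:03d}" for j in range(200)] + ["MT-ND4", "PAIR", "TRIO"]
    m = np.zeros((6, G), dtype=np.int64)
    m[0, :199] = 1                       # 199 genes -> removed
    m[1, :200] = 1; m[1, 202] = 1        # 201 genes -> kept
    m[2, :200] = 1; m[2, 0] = 29; m[2, 200] = 12    # mito 12/240 = 0.05 -> kept
    m[3, :200] = 1; m[3, 0] = 9300; m[3, 200] = 501  # 501/10000 = 0.0501 -> removed
    m[4, :200] = 1; m[4, 201] = 1; m[4, 202] = 1     # kept
    m[5, :200] = 1; m[5, 201] = 1; m[5, 202] = 1     # kept
    fixtures["qc_boundary"] = {
        "dataset": _dataset_from_dense(
            m, symbols, [f"b{i}" for i in range(6)]
        ),
        "params": QCParams(),
        "expected": {
            "kept_barcodes": ["b1", "b2", "b4", "b5"],
            "n_genes_out": 201,          # MT-ND4 (2 cells) and PAIR (2 cells) drop
            "cells_failed_mito": 1,
            "cells_failed_gene_count": 1,
            "genes_failed_min_cells": 2,
        },
    }

    ext = np.array(
        [
            [5, 3, 2, 1, 1],
            [5, 3, 2, 1, 1],
            [5, 3, 2, 1, 0],
            [5, 3, 2, 1, 0],
            [5, 3, 2, 0, 0],
            [5, 3, 2, 0, 0],
            [5, 3, 0, 0, 0],
            [5, 3, 0, 0, 0],
            [5, 0, 0, 0, 0],
            [5, 0, 0, 0, 0],
        ]
    )
    ds = _dataset_from_dense(
        ext, ["Piezo1", "G1", "G2", "G3", "G4"], [f"e{i}" for i in range(10)]
    )
    ds.cell_meta["cell_type"] = "Microglia"
    fixtures["consensus_extremes"] = {"dataset": ds, "top": "Piezo1", "bottom": "G4"}

    rng = np.random.default_rng(20240)
    mu = rng.uniform(0.2, 5.0, size=50)
    counts = rng.poisson(rng.gamma(2.0, np.broadcast_to(mu / 2.0, (200, 50))))
    ds = _dataset_from_dense(
        counts, [f"S{j:02d}" for j in range(50)], [f"s{i:03d}" for i in range(200)]
    )
    ds.cell_meta["cell_type"] = "MG"
    fixtures["score"] = {"dataset": ds}

    rng = np.random.default_rng(7)
    blob1 = rng.standard_normal((100, 5))
    blob2 = rng.standard_normal((100, 5))
    blob2[:, 0] += 12.0
    fixtures["blobs"] = {
        "embedding": np.vstack([blob1, blob2]),
        "labels": np.repeat([0, 1], 100),
    }
    return fixtures
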