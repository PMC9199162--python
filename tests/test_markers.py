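import numpy as np
import pandas as pd
import pytest

from damlink import (
    ClusterParams,
    CorrelationFilterParams,
    MarkerSet,
    evaluate_dataset_markers,
    marker_target_correlation,
    normalize_log,
    select_markers,
    simulate_dataset,
    SimParams,
    target_positive_presence,
)

from test_qc import make_dataset


def _mg_dataset(counts):
    ds = make_dataset(counts)
    ds.cell_meta["cell_type"] = "MG"
    return ds


class TestPresence:
    def test_always_and_never_detected(self):
        # gene g0 = target, g1 detected everywhere, g2 never
        counts = np.array([[2, 1, 0], [1, 3, 0], [0, 1, 0], [4, 2, 0]])
        ds = _mg_dataset(counts)
        assert target_positive_presence(ds, ["MG"], "g0", "g1") == 1.0
        assert target_positive_presence(ds, ["MG"], "g0", "g2") == 0.0

    def test_seven_of_ten_hits_the_inclusive_boundary(self):
        counts = np.zeros((10, 2), dtype=int)
        counts[:, 0] = 1          # all cells target-positive
        counts[:7, 1] = 1         # marker in exactly 7
        ds = _mg_dataset(counts)
        presence = target_positive_presence(ds, ["MG"], "g0", "g1")
        assert presence == 0.7
        assert presence >= CorrelationFilterParams().presence_threshold

    def test_no_target_positive_cells_is_nan(self):
        counts = np.array([[0, 1], [0, 1], [0, 1]])
        ds = _mg_dataset(counts)
        assert np.isnan(target_positive_presence(ds, ["MG"], "g0", "g1"))


class TestCorrelation:
    def test_identical_and_affine_decreasing(self):
        rng = np.random.default_rng(0)
        base = rng.poisson(8, size=20) + 1
        counts = np.column_stack([base, base, base.max() + 1 - base])
        ds = _mg_dataset(counts)
        layer = np.column_stack([base, base, -2.0 * base + 50])  # affine in target
        rs = marker_target_correlation(ds, layer, ["MG"], "g0", ["g1", "g2"])
        assert rs["g1"] == pytest.approx(1.0)
        assert rs["g2"] == pytest.approx(-1.0)

    def test_constant_marker_is_nan(self):
        counts = np.array([[1, 5], [2, 5], [3, 5]])
        ds = _mg_dataset(counts)
        layer = counts.astype(float)
        rs = marker_target_correlation(ds, layer, ["MG"], "g0", ["g1"])
        assert np.isnan(rs["g1"])

    def test_constant_target_rejected(self):
        counts = np.array([[5, 1], [5, 2], [5, 3]])
        ds = _mg_dataset(counts)
        with pytest.raises(ValueError, match="variance"):
            marker_target_correlation(ds, counts.astype(float), ["MG"], "g0", ["g1"])

    def test_generator_latent_correlation_recovered(self):
        params = SimParams(seed=21)
        ds, truth = simulate_dataset(params)
        ds.cell_meta["cell_type"] = truth.cell_types
        layer = normalize_log(ds, ClusterParams(n_hvg=params.n_genes))
        up = truth.planted_marker_set().up_markers
        rs = marker_target_correlation(ds, layer, ["Microglia"], "Piezo1", up)
        assert ((rs >= -0.95) & (rs <= -0.75)).all()


def _result_frame(ds_id, rows):
    return pd.DataFrame(
        [(ds_id, m, c, r, p, "") for m, c, r, p in rows],
        columns=["dataset_id", "marker", "class", "r", "presence", "reason"],
    )


class TestSelect:
    def setup_method(self):
        self.markers = MarkerSet(["u1", "u2"], ["d1"])
        self.params = CorrelationFilterParams(
            subclusters_per_dataset={"a": ["m0"], "b": ["m0"]}
        )

    def test_exact_boundaries_inclusive_in_both_datasets(self):
        rows_a = [("u1", "up", -0.70, 0.70), ("u2", "up", -0.69, 0.99),
                  ("d1", "down", 0.70, 0.70)]
        rows_b = [("u1", "up", -0.70, 0.70), ("u2", "up", -0.90, 0.99),
                  ("d1", "down", 0.70, 0.70)]
        table = select_markers(
            {"a": _result_frame("a", rows_a), "b": _result_frame("b", rows_b)},
            self.markers, self.params,
        )
        kept = set(table.loc[table.final_kept, "marker"])
        assert kept == {"u1", "d1"}  # u2 fails r in dataset a only

    def test_wrong_sign_fails(self):
        rows = [("u1", "up", +0.9, 1.0), ("u2", "up", -0.9, 1.0),
                ("d1", "down", -0.9, 1.0)]
        table = select_markers(
            {"a": _result_frame("a", rows), "b": _result_frame("b", rows)},
            self.markers, self.params,
        )
        assert set(table.loc[table.final_kept, "marker"]) == {"u2"}

    def test_monotone_in_thresholds(self):
        rng = np.random.default_rng(5)
        rows = [
            (f"u{i}", "up", -rng.random(), rng.random()) for i in range(1, 6)
        ] + [(f"d{i}", "down", rng.random(), rng.random()) for i in range(1, 6)]
        markers = MarkerSet([f"u{i}" for i in range(1, 6)], [f"d{i}" for i in range(1, 6)])
        results = {"a": _result_frame("a", rows)}
        kept_sets = []
        for thr in (0.9, 0.7, 0.5, 0.3):
            params = CorrelationFilterParams(
                corr_threshold=thr, presence_threshold=thr,
                subclusters_per_dataset={"a": ["m0"]},
            )
            table = select_markers(results, markers, params)
            kept_sets.append(frozenset(table.loc[table.final_kept, "marker"]))
        for tight, loose in zip(kept_sets, kept_sets[1:]):
            assert tight <= loose

    def test_missing_dataset_rejected(self):
        with pytest.raises(ValueError, match="not evaluated"):
            select_markers({"a": _result_frame("a", [])}, self.markers, self.params)


class TestEvaluateDataset:
    def test_absent_marker_flagged(self, small_sim):
        dataset, truth, params = small_sim
        ds = dataset.copy()
        ds.cell_meta["cell_type"] = truth.cell_types
        layer = normalize_log(ds, ClusterParams(n_hvg=params.n_genes))
        markers = MarkerSet(["UpDam1", "NotAGene"], ["DnDam1"])
        cf = CorrelationFilterParams(subclusters_per_dataset={"sim": ["Microglia"]})
        out = evaluate_dataset_markers(ds, layer, markers, cf, "sim")
        row = out.set_index("marker").loc["NotAGene"]
        assert row["reason"] == "absent" and np.isnan(row["r"])

    def test_kept_set_invariant_to_cell_and_marker_order(self, small_sim):
        dataset, truth, params = small_sim
        ds = dataset.copy()
        ds.cell_meta["cell_type"] = truth.cell_types
        cf = CorrelationFilterParams(subclusters_per_dataset={"sim": ["Microglia"]})
        cands = truth.candidate_marker_set()

        def kept(d, marker_set):
            layer = normalize_log(d, ClusterParams(n_hvg=params.n_genes))
            res = evaluate_dataset_markers(d, layer, marker_set, cf, "sim")
            table = select_markers({"sim": res}, marker_set, cf)
            return set(table.loc[table.final_kept, "marker"])

        base = kept(ds, cands)
        perm = np.random.default_rng(3).permutation(ds.n_cells)
        shuffled = ds.subset(cells=perm)
        reordered = MarkerSet(cands.up_markers[::-1], cands.down_markers[::-1])
        assert kept(shuffled, cands) == base
        assert kept(ds, reordered) == base
        planted = truth.planted_marker_set()
        assert base == set(planted.up_markers) | set(planted.down_markers)
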