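"""Positivity calling, intracellularity geometry, densities, neighborhoods."""

import numpy as np
import pandas as pd
import pytest

from lowbiome import spatial as sp
from lowbiome import synthetic as syn
from lowbiome.errors import GeometryError, ThresholdError

from oracles import pairwise_within, quartile_membership


def cells_frame(rows):
    df = pd.DataFrame(
        rows,
        columns=["cell_id", "fov", "x_um", "y_um", "area_um2", "cell_type", "is_tumor", "total_counts"],
    )
    return df


class TestBackground:
    def test_uniform_case_floor_inactive(self):
        # every cell identical: negprobes exactly 1% of counts -> b = 0.01 * total
        cells = cells_frame(
            [(f"c{i}", 0, 0, 0, 50.0, "tumor", True, 100) for i in range(10)]
        )
        tr = []
        for i in range(10):
            tr += [("NegPrb", "negprobe_host", 0, 0, 0, 0, f"c{i}")] * 1
            tr += [("G", "host", 0, 0, 0, 0, f"c{i}")] * 99
        transcripts = pd.DataFrame(
            tr, columns=["target", "probe_class", "x_um", "y_um", "z_um", "fov", "cell_id"]
        )
        b = sp.estimate_background(cells, transcripts)
        assert np.allclose(b.values, 1.0)

    def test_floor_applies_fifth_percentile(self):
        cells = cells_frame(
            [(f"c{i}", 0, 0, 0, 50.0, "tumor", True, t) for i, t in enumerate([1000] * 9 + [10])]
        )
        tr = [("NegPrb", "negprobe_bact", 0, 0, 0, 0, "c0")] * 90
        transcripts = pd.DataFrame(
            tr, columns=["target", "probe_class", "x_um", "y_um", "z_um", "fov", "cell_id"]
        )
        b = sp.estimate_background(cells, transcripts)
        raw = 90 / (9 * 1000 + 10) * np.array([1000] * 9 + [10])
        q05 = np.percentile(raw[raw > 0], 5)
        assert b["c9"] == pytest.approx(q05)

    def test_matches_two_pass_recomputation(self, spatial_dataset):
        transcripts, cells, _ = spatial_dataset
        cells = sp.qc_cells(cells)
        b = sp.estimate_background(cells, transcripts)
        neg = transcripts[
            transcripts["probe_class"].isin(("negprobe_host", "negprobe_bact"))
            & transcripts["cell_id"].notna()
        ]
        neg_per_cell = neg.groupby("cell_id").size().reindex(cells["cell_id"], fill_value=0)
        p = neg_per_cell.sum() / cells["total_counts"].sum()
        raw = (p * cells["total_counts"]).to_numpy(float)
        q05 = np.percentile(raw[raw > 0], 5)
        expected = np.maximum(raw, q05)
        assert np.allclose(b.reindex(cells["cell_id"]).values, expected)


class TestThresholdAndCalling:
    def test_single_positive_yields_unique_midpoint(self):
        norm = pd.Series({"a": 0.0, "b": 0.0, "c": 25.0})
        raw = pd.Series({"a": 0, "b": 0, "c": 5})
        assert sp.roc_threshold(norm, raw) == pytest.approx(12.5)

    def test_youden_maximum_found_by_candidate_scan(self):
        norm = pd.Series({"a": 0.0, "b": 0.0, "c": 21.0, "d": 30.0, "e": 40.0})
        raw = pd.Series({"a": 0, "b": 0, "c": 3, "d": 4, "e": 5})
        t = sp.roc_threshold(norm, raw)
        assert t == pytest.approx(10.5)
        # exhaustive candidate scan oracle
        vals = np.array([0.0, 0.0, 21.0, 30.0, 40.0])
        labels = np.array([0, 0, 1, 1, 1])
        uniq = np.unique(vals)
        cands = (uniq[:-1] + uniq[1:]) / 2
        js = [( (vals[labels == 1] > c).mean() + (vals[labels == 0] <= c).mean() - 1, -c) for c in cands]
        best = cands[int(np.argmax([j for j, _ in js]))]
        assert t == pytest.approx(best)

    def test_missing_pseudo_class_raises(self):
        norm = pd.Series({"a": 0.0, "b": 2.0})
        raw = pd.Series({"a": 0, "b": 2})
        with pytest.raises(ThresholdError, match="pseudo-positive"):
            sp.roc_threshold(norm, raw)

    def test_strict_boundary_call(self):
        norm = pd.Series({"a": 10.0, "b": 10.02})
        called = sp.call_positive(norm, 10.01)
        assert not called["a"] and called["b"]

    def test_raising_pseudo_positive_cutoff_shrinks_positives(self, spatial_dataset):
        transcripts, cells, _ = spatial_dataset
        out20, _ = sp.run_spatial_calling(transcripts, cells, pseudo_positive_cutoff=20.0)
        n20 = (out20["norm_bact"] > 20).sum()
        n30 = (out20["norm_bact"] > 30).sum()
        assert n30 <= n20


class TestCentrality:
    def make_cell(self, bact_xyz, host_n=40, spread=5.0, seed=0):
        rng = np.random.default_rng(seed)
        rows = [
            ("G", "host", *rng.uniform(-spread, spread, size=3), 0, "c0")
            for _ in range(host_n)
        ]
        rows += [("B", "bacterial", x, y, z, 0, "c0") for x, y, z in bact_xyz]
        return pd.DataFrame(
            rows, columns=["target", "probe_class", "x_um", "y_um", "z_um", "fov", "cell_id"]
        )

    def test_centered_bacterial_transcript_is_high_confidence(self):
        tr = self.make_cell([(0.0, 0.0, 0.0)])
        flag, reason = sp.central50_intracellular(tr)
        assert flag, reason

    def test_peripheral_bacterial_cloud_rejected(self):
        tr = self.make_cell([(100.0, 0.0, 0.0)] * 3)
        flag, reason = sp.central50_intracellular(tr)
        assert not flag and "x_um" in reason

    def test_degenerate_small_cell_rejected_with_reason(self):
        tr = self.make_cell([(0, 0, 0)], host_n=1)
        flag, reason = sp.central50_intracellular(tr)
        assert not flag and "fewer than 4" in reason

    def test_500_random_cells_match_bruteforce_percentiles(self):
        rng = np.random.default_rng(2)
        for i in range(500):
            n_host = int(rng.integers(4, 30))
            n_bact = int(rng.integers(1, 5))
            tr = self.make_cell(
                rng.normal(0, rng.uniform(0.5, 8), size=(n_bact, 3)),
                host_n=n_host, seed=i,
            )
            flag, _ = sp.central50_intracellular(tr)
            bact = tr[tr["probe_class"] == "bacterial"]
            expected = all(
                quartile_membership(tr[ax], bact[ax]) for ax in ("x_um", "y_um", "z_um")
            )
            assert flag == expected, i

    def test_flags_invariant_to_rigid_translation(self, spatial_dataset):
        transcripts, cells, _ = spatial_dataset
        out, _ = sp.run_spatial_calling(transcripts, cells)
        shifted = transcripts.copy()
        for ax in ("x_um", "y_um", "z_um"):
            shifted[ax] = shifted[ax] + 137.0
        cells2 = cells.copy()
        cells2["x_um"] += 137.0
        cells2["y_um"] += 137.0
        out2, _ = sp.run_spatial_calling(shifted, cells2)
        assert (out["high_confidence"].values == out2["high_confidence"].values).all()
        assert (out["positive"].values == out2["positive"].values).all()


class TestDensity:
    def test_arithmetic_example(self):
        cells = cells_frame(
            [("c0", 0, 10, 10, 100.0, "tumor", True, 50), ("c1", 0, 30, 30, 150.0, "tumor", True, 50)]
        )
        rows = [("B", "bacterial", 1, 1, 0, 0, "c0")] * 5
        tr = pd.DataFrame(rows, columns=["target", "probe_class", "x_um", "y_um", "z_um", "fov", "cell_id"])
        d = sp.fov_density(tr, cells)
        assert d.loc[0, "intracellular_density"] == pytest.approx(5 / 250.0)
        assert d.loc[0, "extracellular_density"] == 0.0

    def test_fov_area_from_pixel_geometry(self):
        geom = sp.FovGeometry()
        assert geom.area_um2 == pytest.approx((4256 * 0.12) ** 2)
        assert geom.area_um2 == pytest.approx(260834.92, abs=0.01)

    def test_cell_area_exceeding_fov_raises(self):
        cells = cells_frame([("c0", 0, 0, 0, 1e9, "tumor", True, 50)])
        tr = pd.DataFrame([], columns=["target", "probe_class", "x_um", "y_um", "z_um", "fov", "cell_id"])
        with pytest.raises(GeometryError):
            sp.fov_density(tr, cells)

    def test_transcript_conservation_per_fov(self, spatial_dataset):
        transcripts, cells, _ = spatial_dataset
        d = sp.fov_density(transcripts, cells)
        bact = transcripts[transcripts["probe_class"] == "bacterial"]
        for fov, grp in bact.groupby("fov"):
            assert d.loc[fov, "n_intracellular"] + d.loc[fov, "n_extracellular"] == len(grp)


class TestNeighborhoods:
    def grid(self):
        # anchor tumor cells: positive at origin, negative far away
        rows = [
            ("p", 0, 0.0, 0.0, 50.0, "tumor", True, 100),     # positive tumor
            ("n", 0, 500.0, 0.0, 50.0, "tumor", True, 100),   # negative tumor
            ("a", 0, 29.0, 0.0, 50.0, "myeloid", False, 100),  # 29 um from p
            ("b", 0, 200.0, 0.0, 50.0, "myeloid", False, 100),  # >30 from any tumor
            ("c", 0, 475.0, 0.0, 50.0, "myeloid", False, 100),  # 25 from n, 475 from p
            ("d", 0, 80.0, 0.0, 50.0, "myeloid", False, 100),  # within 100 of p
        ]
        return cells_frame(rows)

    def test_label_rules(self):
        cells = self.grid()
        positive = pd.Series({"p": True, "n": False, "a": False, "b": False, "c": False, "d": False})
        labels = sp.annotate_neighborhoods(cells, positive)
        assert labels["a"] == "positive_nh"
        assert labels["b"] == "excluded"
        assert labels["c"] == "negative_nh"  # 475 um from the positive cell
        assert labels["d"] == "excluded"  # candidate negative within 100 um of positive

    def test_exclusion_radius_disqualifies_near_negatives(self):
        cells = self.grid()
        # move the negative anchor close: candidate negatives fall inside 100 um
        cells.loc[cells["cell_id"] == "n", "x_um"] = 60.0
        cells.loc[cells["cell_id"] == "c", "x_um"] = 85.0
        positive = pd.Series({"p": True, "n": False, "a": False, "b": False, "c": False, "d": False})
        labels = sp.annotate_neighborhoods(cells, positive)
        assert labels["c"] == "excluded"

    def test_300_random_cells_match_distance_oracle(self):
        rng = np.random.default_rng(3)
        n = 300
        cells = cells_frame([
            (f"c{i}", 0, rng.uniform(0, 400), rng.uniform(0, 400), 50.0,
             "tumor" if rng.random() < 0.4 else "other", rng.random() < 0.4, 100)
            for i in range(n)
        ])
        cells["is_tumor"] = cells["cell_type"] == "tumor"
        positive = pd.Series(rng.random(n) < 0.1, index=cells["cell_id"].values)
        labels = sp.annotate_neighborhoods(cells, positive)
        xy = cells[["x_um", "y_um"]].to_numpy()
        is_tumor = cells["is_tumor"].to_numpy()
        pos = positive.values
        near_pt = pairwise_within(xy, xy[is_tumor & pos], 30.0)
        near_nt = pairwise_within(xy, xy[is_tumor & ~pos], 30.0)
        near_p100 = pairwise_within(xy, xy[pos], 100.0)
        for i, cid in enumerate(cells["cell_id"]):
            if near_pt[i]:
                expected = "positive_nh"
            elif near_nt[i] and not near_p100[i]:
                expected = "negative_nh"
            else:
                expected = "excluded"
            assert labels[cid] == expected, cid


class TestCovariate:
    def test_no_dissimilar_neighbors_gives_zero(self):
        cells = cells_frame([
            ("c0", 0, 0, 0, 50.0, "tumor", True, 100),
            ("c1", 0, 10, 0, 50.0, "tumor", True, 100),
        ])
        cov = sp.neighbor_expression_covariate(cells, pd.Series({"c0": 5.0, "c1": 7.0}))
        assert cov["c0"] == 0.0 and cov["c1"] == 0.0

    def test_single_dissimilar_neighbor_contributes_its_total(self):
        cells = cells_frame([
            ("c0", 0, 0, 0, 50.0, "tumor", True, 100),
            ("c1", 0, 10, 0, 50.0, "myeloid", False, 100),
        ])
        cov = sp.neighbor_expression_covariate(cells, pd.Series({"c0": 5.0, "c1": 42.0}))
        assert cov["c0"] == 42.0 and cov["c1"] == 5.0

    def test_random_config_matches_nested_loop_oracle(self):
        rng = np.random.default_rng(4)
        n = 80
        cells = cells_frame([
            (f"c{i}", int(rng.integers(2)), rng.uniform(0, 200), rng.uniform(0, 200),
             50.0, rng.choice(["tumor", "myeloid", "lymphoid"]), False, 100)
            for i in range(n)
        ])
        totals = pd.Series(rng.uniform(0, 100, size=n), index=cells["cell_id"].values)
        cov = sp.neighbor_expression_covariate(cells, totals, radius_um=30.0)
        for i in range(n):
            s = 0.0
            for j in range(n):
                if i == j or cells["fov"][i] != cells["fov"][j]:
                    continue
                if cells["cell_type"][i] == cells["cell_type"][j]:
                    continue
                d = np.hypot(
                    cells["x_um"][i] - cells["x_um"][j], cells["y_um"][i] - cells["y_um"][j]
                )
                if d <= 30.0:
                    s += totals.iloc[j]
            assert cov[f"c{i}"] == pytest.approx(s)


class TestRecovery:
    def test_planted_cells_recovered_without_false_calls(self, spatial_dataset):
        transcripts, cells, truth = spatial_dataset
        out, summary = sp.run_spatial_calling(transcripts, cells)
        merged = out.merge(truth, on="cell_id")
        planted = merged[merged["planted_positive"]]
        assert planted["high_confidence"].mean() >= 0.9
        assert merged.loc[~merged["planted_positive"], "positive"].sum() == 0
        # flag hierarchy: high confidence implies positive
        assert (merged.loc[merged["high_confidence"], "positive"]).all()

    def test_positivity_percent_precision(self):
        assert sp.positivity_percent(182, 28177) == 0.65
        assert sp.positivity_percent(198, 65993) == 0.3
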