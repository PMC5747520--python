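"""Cell graph construction, conduction speeds, shape, pacemakers, 2D maps."""

import numpy as np
import networkx as nx
import pandas as pd
import pytest
from scipy.spatial import Delaunay

from conftest import make_small_config
from cardiomap.metrics import compute_activation_map
from cardiomap.network import (biological_speed, build_graph,
                               identify_pacemakers, map_conduction_2d,
                               metric_speed, shape_estimate)
from cardiomap.synthetic import make_activation, make_geometry, make_transients

FRAME = 2.5  # ms


def star_graph(dts_ms, lengths_um=None):
    """Focal node 0 with one neighbor per entry; neighbor j activated dt later."""
    g = nx.Graph()
    g.add_node(0, pos=np.zeros(3))
    t = {0: 100.0}
    lengths = lengths_um or [10.0] * len(dts_ms)
    for j, (dt, d) in enumerate(zip(dts_ms, lengths), start=1):
        g.add_node(j, pos=np.array([d, 0, 0.1 * j]))
        g.add_edge(0, j, length_um=float(d))
        t[j] = 100.0 + dt
    return g, pd.Series(t)


class TestBuildGraph:
    def test_flat_grid_contains_axis_edges(self):
        s = 3.0
        xs, ys = np.meshgrid(np.arange(6) * s, np.arange(6) * s)
        pts = np.column_stack([xs.ravel(), ys.ravel(), np.zeros(36)])
        g = build_graph(pts)
        # oracle: full planar Delaunay contains every 4-neighbor axis edge
        oracle = Delaunay(pts[:, :2] + np.random.default_rng(0).normal(0, 1e-9, (36, 2)))
        oracle_edges = set()
        for simplex in oracle.simplices:
            for k in range(3):
                a, b = sorted((int(simplex[k]), int(simplex[(k + 1) % 3])))
                oracle_edges.add((a, b))
        for i in range(36):
            x, y = i % 6, i // 6
            if x < 5:
                assert (i, i + 1) in oracle_edges
                assert g.has_edge(i, i + 1)
                assert g.edges[i, i + 1]["length_um"] == pytest.approx(s)
            if y < 5:
                assert g.has_edge(i, i + 6)
        # with an edge cap, everything beyond the second shell is pruned
        g_cap = build_graph(pts, max_edge_um=2 * s)
        for a, b in g_cap.edges:
            assert np.linalg.norm(pts[a] - pts[b]) <= 2 * s + 1e-6
        for i in range(36):
            if i % 6 < 5:
                assert g_cap.has_edge(i, i + 1)

    def test_square_has_exactly_one_diagonal(self):
        pts = np.array([[0, 0, 0], [10, 0, 0], [10, 10, 0], [0, 10, 0]], float)
        g = build_graph(pts)
        sides = [(0, 1), (1, 2), (2, 3), (0, 3)]
        for a, b in sides:
            assert g.has_edge(a, b)
        diagonals = [e for e in g.edges if e in ((0, 2), (1, 3))]
        assert len(diagonals) == 1

    def test_cylinder_surface_connected_bounded_degree(self, small_dataset):
        g = build_graph(small_dataset.truth.cells[["x_um", "y_um", "z_um"]])
        assert nx.is_connected(g)
        assert max(d for _, d in g.degree) <= 12

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(8)
        pts = rng.uniform(0, 30, (60, 3))
        from scipy.spatial.transform import Rotation
        R = Rotation.random(random_state=1).as_matrix()
        g0 = build_graph(pts)
        g1 = build_graph(pts @ R.T + np.array([5.0, -3.0, 11.0]))
        assert set(g0.edges) == set(g1.edges)

    def test_max_edge_pruning(self):
        pts = np.array([[0, 0, 0], [3, 0, 0], [6, 0, 0], [50, 0.1, 0.2]], float)
        g = build_graph(pts, max_edge_um=10.0)
        assert g.degree[3] == 0

    def test_too_few_cells_rejected(self):
        with pytest.raises(ValueError, match="at least 4"):
            build_graph(np.zeros((3, 3)))


class TestSpeeds:
    def test_four_equal_neighbors(self):
        g, t = star_graph([10.0, 10.0, 10.0, -10.0])
        bio = biological_speed(g, t, FRAME)
        assert bio.loc[0, "cs_cells_s"] == pytest.approx(100.0)

    def test_two_unequal_neighbors_hand_computed(self):
        # dt = {5, 20} ms: cs = 2 / (0.005 + 0.020) = 80 cells/s
        g, t = star_graph([5.0, 20.0])
        bio = biological_speed(g, t, FRAME)
        assert bio.loc[0, "cs_cells_s"] == pytest.approx(80.0)

    def test_metric_speed_hand_computed(self):
        g, t = star_graph([10.0] * 3, [10.0] * 3)
        met = metric_speed(g, t, FRAME)
        assert met.loc[0, "cs_um_s"] == pytest.approx(1000.0)

    def test_doubling_lengths_doubles_metric_only(self):
        g1, t = star_graph([5.0, 20.0], [8.0, 12.0])
        g2, _ = star_graph([5.0, 20.0], [16.0, 24.0])
        assert (metric_speed(g2, t, FRAME).loc[0, "cs_um_s"]
                == pytest.approx(2 * metric_speed(g1, t, FRAME).loc[0, "cs_um_s"]))
        assert (biological_speed(g2, t, FRAME).loc[0, "cs_cells_s"]
                == pytest.approx(biological_speed(g1, t, FRAME).loc[0, "cs_cells_s"]))

    def test_time_scaling_divides_speeds(self):
        g, t = star_graph([10.0, 25.0, 40.0])
        c = 2.0
        b1 = biological_speed(g, t, FRAME).loc[0, "cs_cells_s"]
        b2 = biological_speed(g, 100.0 + (t - 100.0) * c, FRAME).loc[0, "cs_cells_s"]
        assert b2 == pytest.approx(b1 / c)

    def test_tied_neighbors_clamped_and_flagged(self):
        g, t = star_graph([0.0, 10.0])
        bio = biological_speed(g, t, FRAME)
        assert bool(bio.loc[0, "tie_clamped"])
        assert bio.loc[0, "cs_cells_s"] == pytest.approx(2 / ((FRAME + 10.0) / 1000))

    def test_isolated_node_flagged(self):
        g, t = star_graph([10.0])
        g.add_node(99, pos=np.array([50.0, 50, 50]))
        t.loc[99] = 0.0
        bio = biological_speed(g, t, FRAME)
        assert bool(bio.loc[99, "isolated_or_missing"])
        assert np.isnan(bio.loc[99, "cs_cells_s"])

    def test_brute_force_oracle_exact_on_small_instances(self):
        # direct evaluation of the printed formulas on random <=30-cell graphs
        rng = np.random.default_rng(42)
        for trial in range(5):
            n = int(rng.integers(8, 30))
            pts = rng.uniform(0, 40, (n, 3))
            g = build_graph(pts, k_neighbors=6)
            t = pd.Series(rng.uniform(0, 200, n))
            bio = biological_speed(g, t, FRAME)
            met = metric_speed(g, t, FRAME)
            for i in g.nodes:
                nbrs = list(g.neighbors(i))
                if not nbrs:
                    continue
                dts = np.array([max(abs(t[j] - t[i]), FRAME) / 1000 for j in nbrs])
                ds = np.array([g.edges[i, j]["length_um"] for j in nbrs])
                assert bio.loc[i, "cs_cells_s"] == pytest.approx(len(nbrs) / dts.sum())
                assert met.loc[i, "cs_um_s"] == pytest.approx(len(nbrs) / (dts / ds).sum())


class TestShapeEstimate:
    def axis_star(self, p, q, r):
        g = nx.Graph()
        g.add_node(0, pos=np.zeros(3))
        offs = [(p, 0, 0), (-p, 0, 0), (0, q, 0), (0, -q, 0), (0, 0, r), (0, 0, -r)]
        for j, o in enumerate(offs, 1):
            g.add_node(j, pos=np.array(o, float))
            g.add_edge(0, j)
        return g

    def test_isotropic_neighbors_zero_fa(self):
        g = self.axis_star(2.0, 2.0, 2.0)
        s = shape_estimate(g)
        assert s.loc[0, "fa"] == pytest.approx(0.0, abs=1e-12)

    def test_collinear_neighbors_fa_one(self):
        g = nx.Graph()
        g.add_node(0, pos=np.zeros(3))
        for j, x in enumerate([-2.0, -1.0, 1.0, 2.0], 1):
            g.add_node(j, pos=np.array([x, 0, 0]))
            g.add_edge(0, j)
        s = shape_estimate(g)
        assert s.loc[0, "fa"] == pytest.approx(1.0)

    def test_eigenvalues_2_1_1_give_fa_one_over_sqrt6(self):
        # second moments diag(2, 1, 1): p^2/3 = 2 etc.
        g = self.axis_star(np.sqrt(6.0), np.sqrt(3.0), np.sqrt(3.0))
        s = shape_estimate(g)
        assert s.loc[0, "lambda1"] == pytest.approx(2.0)
        assert s.loc[0, "lambda2"] == pytest.approx(1.0)
        assert s.loc[0, "fa"] == pytest.approx(1.0 / np.sqrt(6.0))
        assert s.loc[0, "volume"] == pytest.approx(4.0 / 3.0 * np.pi * 2.0)

    def test_sqrt_axes_option(self):
        g = self.axis_star(np.sqrt(6.0), np.sqrt(3.0), np.sqrt(3.0))
        s = shape_estimate(g, use_sqrt_axes=True)
        assert s.loc[0, "volume"] == pytest.approx(
            4.0 / 3.0 * np.pi * np.sqrt(2.0))

    def test_few_neighbors_flagged(self):
        g, t = star_graph([10.0, 12.0])
        s = shape_estimate(g)
        assert bool(s.loc[0, "flagged"])


class TestIdentifyPacemakers:
    def frame(self, t, cs):
        n = len(t)
        act = pd.DataFrame({"cell_id": np.arange(n), "t_act_ms": t,
                            "flagged": False}).set_index("cell_id")
        cond = pd.DataFrame({"cell_id": np.arange(n),
                             "cs_cells_s": cs}).set_index("cell_id")
        return act, cond

    def test_all_equal_times_empty(self):
        act, cond = self.frame(np.full(50, 10.0), np.linspace(10, 100, 50))
        assert len(identify_pacemakers(act, cond)) == 0

    def test_q_one_without_speed_filter_selects_all_below_max(self):
        act, cond = self.frame(np.arange(50.0), np.linspace(10, 100, 50))
        sel = identify_pacemakers(act, cond, q=1.0, use_speed_filter=False)
        assert len(sel) == 49  # strict inequality excludes the latest cell

    def test_too_few_cells_rejected(self):
        act, cond = self.frame(np.arange(10.0), np.ones(10))
        with pytest.raises(ValueError, match="fewer than 20"):
            identify_pacemakers(act, cond)

    def test_origin_ring_recovery_from_noiseless_truth(self):
        # 240 cells, 0.05 quantile -> a 12-cell origin ring
        cfg = make_small_config(seed=21, n_cells=240)
        geom = make_geometry(cfg)
        truth = make_activation(geom, cfg)
        ts = make_transients(truth, cfg)
        amap = compute_activation_map(ts)
        g = build_graph(geom.cells[["x_um", "y_um", "z_um"]])
        bio = biological_speed(g, amap["t_act_ms"], cfg.frame_period_ms)
        pred = set(identify_pacemakers(amap, bio))
        true_origin = set(truth.origin_ids)
        assert len(true_origin) == pytest.approx(12, abs=1)
        tp = len(pred & true_origin)
        assert tp / max(len(pred), 1) >= 0.8       # precision
        assert tp / len(true_origin) >= 0.8        # recall


class TestMapConduction2d:
    def cylinder_coords(self, n=400, seed=0):
        rng = np.random.default_rng(seed)
        tau = rng.uniform(0, 1, n)
        phi = rng.uniform(-np.pi, np.pi, n)
        coords = pd.DataFrame({"cell_id": np.arange(n), "tau": tau, "phi": phi,
                               "inner": phi > 0}).set_index("cell_id")
        return coords

    def cond(self, speeds):
        n = len(speeds)
        return pd.DataFrame({"cell_id": np.arange(n),
                             "cs_cells_s": speeds}).set_index("cell_id")

    def test_constant_field_has_no_isolines(self):
        coords = self.cylinder_coords()
        out = map_conduction_2d(self.cond(np.full(400, 97.0)), coords)
        assert len(out["isolines"]) == 0
        finite = out["field"][np.isfinite(out["field"])]
        assert np.allclose(finite, 97.0)

    def test_step_field_isolines_concentrate_at_boundary(self):
        coords = self.cylinder_coords(1600, seed=2)
        speeds = np.where(coords["tau"] < 0.5, 90.0, 210.0)
        out = map_conduction_2d(self.cond(speeds), coords, iso_step=50.0)
        assert len(out["isolines"]) > 0
        total = near = 0.0
        for iso in out["isolines"]:
            seg = np.linalg.norm(np.diff(iso["path"], axis=0), axis=1)
            total += seg.sum()
            mid = 0.5 * (iso["path"][1:, 0] + iso["path"][:-1, 0])
            near += seg[np.abs(mid - 0.5) < 0.1].sum()
        assert near / total >= 0.8

    def test_phi_seam_continuity(self):
        coords = self.cylinder_coords(600, seed=3)
        speeds = 100.0 + 50.0 * np.sin(coords["phi"])  # smooth in angle
        out = map_conduction_2d(self.cond(speeds.to_numpy()), coords)
        field = out["field"]
        top = field[:, -2]     # phi ~ +pi
        bottom = field[:, 1]   # phi ~ -pi
        ok = np.isfinite(top) & np.isfinite(bottom)
        assert np.abs(top[ok] - bottom[ok]).max() < 10.0

    def test_too_few_cells_rejected(self):
        coords = self.cylinder_coords(2)
        with pytest.raises(ValueError, match="at least 3"):
            map_conduction_2d(self.cond(np.ones(2)), coords)

    def test_region_summary_table(self):
        coords = self.cylinder_coords(300, seed=4)
        labels = pd.Series(np.where(coords["tau"] < 0.5, "atrium", "ventricle"),
                           index=coords.index)
        out = map_conduction_2d(self.cond(np.full(300, 120.0)), coords,
                                region_labels=labels)
        assert set(out["summary"].index) <= {"atrium", "ventricle"}
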