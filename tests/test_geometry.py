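"""Midline spline, Frenet-Serret frames, and curved-cylinder coordinates.

The helix is the module's analytic oracle: for r(t) = (a cos t, a sin t, b t),
curvature = a/(a^2+b^2), torsion = b/(a^2+b^2), with closed-form frames.
"""

import numpy as np
import pandas as pd
import pytest

from cardiomap.geometry import (assign_coordinates, circular_delta_phi,
                                fit_midline, frenet_frame,
                                rotation_minimizing_frames, unroll,
                                untwist_straighten)

A, B = 10.0, 2.0  # helix radius and pitch parameters (um)


def helix_points(n=160, turns=2.0):
    t = np.linspace(0, 2 * np.pi * turns, n)
    return np.column_stack([A * np.cos(t), A * np.sin(t), B * t])


@pytest.fixture(scope="module")
def helix_frames():
    return frenet_frame(fit_midline(helix_points()))


def trim(x, frac=0.1):
    k = int(len(x) * frac)
    return x[k:-k]


class TestFitMidline:
    def test_interpolates_control_points(self):
        cp = helix_points(n=40)
        mf = fit_midline(cp)
        # the spline must pass through every control point
        chord = np.concatenate([[0.0], np.cumsum(
            np.linalg.norm(np.diff(cp, axis=0), axis=1))])
        err = np.linalg.norm(np.asarray(mf.spline(chord)) - cp, axis=1)
        assert err.max() < 1e-6

    def test_collinear_points_give_straight_spline(self):
        cp = np.column_stack([np.linspace(0, 50, 8), np.zeros(8), np.zeros(8)])
        mf = frenet_frame(fit_midline(cp))
        assert np.all(mf.curvature <= 1e-6)
        assert np.all(mf.provenance == "transported")
        # transported frames on a straight line are mutually parallel
        assert np.allclose(mf.N, mf.N[0], atol=1e-9)

    def test_duplicate_consecutive_points_rejected(self):
        cp = helix_points(n=10)
        cp[4] = cp[3]
        with pytest.raises(ValueError, match="duplicate"):
            fit_midline(cp)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="at least 5"):
            fit_midline(helix_points(n=4))

    def test_unit_speed_parameterization(self, helix_frames):
        seg = np.linalg.norm(np.diff(helix_frames.points, axis=0), axis=1)
        assert np.allclose(seg, seg.mean(), rtol=1e-3)


class TestFrenetFrame:
    def test_helix_curvature_and_torsion(self, helix_frames):
        kappa = A / (A**2 + B**2)
        tau_t = B / (A**2 + B**2)
        assert np.allclose(trim(helix_frames.curvature), kappa, rtol=0.01)
        assert np.allclose(trim(helix_frames.torsion), tau_t, rtol=0.01)

    def test_helix_frames_match_closed_form(self, helix_frames):
        mf = helix_frames
        t = np.arctan2(mf.points[:, 1], mf.points[:, 0])
        t = np.unwrap(t)
        c = np.sqrt(A**2 + B**2)
        T_true = np.column_stack([-A * np.sin(t), A * np.cos(t), np.full_like(t, B)]) / c
        N_true = np.column_stack([-np.cos(t), -np.sin(t), np.zeros_like(t)])
        B_true = np.column_stack([B * np.sin(t), -B * np.cos(t), np.full_like(t, A)]) / c
        for est, true in ((mf.T, T_true), (mf.N, N_true), (mf.B, B_true)):
            assert np.abs(trim(est) - trim(true)).max() < 1e-3

    def test_orthonormal_right_handed_everywhere(self, helix_frames):
        mf = helix_frames
        for V in (mf.T, mf.N, mf.B):
            assert np.abs(np.linalg.norm(V, axis=1) - 1).max() < 1e-9
        assert np.abs(np.einsum("ij,ij->i", mf.T, mf.N)).max() < 1e-9
        assert np.abs(np.einsum("ij,ij->i", mf.T, mf.B)).max() < 1e-9
        assert np.abs(np.einsum("ij,ij->i", mf.N, mf.B)).max() < 1e-9
        assert np.abs(np.cross(mf.T, mf.N) - mf.B).max() < 1e-9

    def test_planar_circle_has_no_torsion_constant_binormal(self):
        t = np.linspace(0, 1.5 * np.pi, 100)
        mf = frenet_frame(fit_midline(
            np.column_stack([20 * np.cos(t), 20 * np.sin(t), np.zeros_like(t)])))
        assert np.abs(trim(mf.torsion)).max() < 1e-6
        assert np.abs(trim(mf.B) - np.array([0, 0, 1.0])).max() < 1e-6

    def test_sign_continuity_across_inflection(self):
        # planar S-curve: raw Frenet N flips across the inflection point
        x = np.linspace(0, 4 * np.pi, 120)
        mf = frenet_frame(fit_midline(
            np.column_stack([x, 5 * np.sin(x), np.zeros_like(x)])))
        dots = np.einsum("ij,ij->i", mf.N[:-1], mf.N[1:])
        assert dots.min() > 0.0


class TestAssignCoordinates:
    def straight_frames(self, length=60.0):
        cp = np.column_stack([np.linspace(0, length, 9), np.zeros(9), np.zeros(9)])
        return frenet_frame(fit_midline(cp))

    def test_phi_zero_along_binormal(self):
        mf = self.straight_frames()
        j = len(mf.points) // 2
        cell = mf.points[j] + 5.0 * mf.B[j]
        c = assign_coordinates(cell[None, :], mf)
        assert abs(c["phi"].iloc[0]) < 1e-6
        assert abs(c["z_um"].iloc[0] - 5.0) < 1e-6

    def test_phi_quarter_turn_along_normal(self):
        mf = self.straight_frames()
        j = len(mf.points) // 2
        cell = mf.points[j] + 5.0 * mf.N[j]
        c = assign_coordinates(cell[None, :], mf)
        assert abs(c["phi"].iloc[0] - np.pi / 2) < 1e-6

    def test_phi_convention_flippable(self):
        mf = self.straight_frames()
        j = len(mf.points) // 2
        cell = mf.points[j] + 5.0 * mf.N[j]
        c = assign_coordinates(cell[None, :], mf, phi_from="normal")
        assert abs(c["phi"].iloc[0]) < 1e-6

    def test_cylinder_radius_and_tau_recovery(self):
        mf = self.straight_frames(length=80.0)
        rng = np.random.default_rng(5)
        tau = rng.uniform(0.05, 0.95, 300)
        phi = rng.uniform(-np.pi, np.pi, 300)
        r = 6.0
        base = np.column_stack([tau * 80.0, np.zeros(300), np.zeros(300)])
        cells = base + r * (np.cos(phi)[:, None] * mf.B[0]
                            + np.sin(phi)[:, None] * mf.N[0])
        c = assign_coordinates(cells, mf)
        assert np.abs(c["z_um"] - r).max() < 1e-3
        assert np.sqrt(np.mean((c["tau"] - tau) ** 2)) < 0.01
        dphi = circular_delta_phi(c["phi"].to_numpy(), phi)
        assert dphi.max() < 1e-6

    def test_rigid_motion_tau_z_invariant_phi_equivariant(self):
        mf = frenet_frame(fit_midline(helix_points()))
        rng = np.random.default_rng(11)
        idx = rng.integers(100, len(mf.points) - 100, 40)
        phi = rng.uniform(-np.pi, np.pi, 40)
        cells = mf.points[idx] + 4.0 * (np.cos(phi)[:, None] * mf.B[idx]
                                        + np.sin(phi)[:, None] * mf.N[idx])
        c0 = assign_coordinates(cells, mf)

        # random rotation + translation applied to the whole dataset
        from scipy.spatial.transform import Rotation
        R = Rotation.random(random_state=3).as_matrix()
        shift = np.array([12.0, -5.0, 30.0])
        mf2 = frenet_frame(fit_midline(helix_points() @ R.T + shift))
        c1 = assign_coordinates(cells @ R.T + shift, mf2)
        assert np.abs(c0["tau"] - c1["tau"]).max() < 1e-4
        assert np.abs(c0["z_um"] - c1["z_um"]).max() < 1e-4
        # phi measured in the intrinsic (Frenet) frame is rigid-motion invariant
        assert circular_delta_phi(c0["phi"].to_numpy(), c1["phi"].to_numpy()).max() < 1e-3

    def test_hairpin_ambiguity_flagged(self):
        # U-shape with parallel legs: a point midway between the legs has two
        # near-equal distance minima at distant tau
        leg1 = np.column_stack([np.linspace(0, 40, 9), np.zeros(9), np.zeros(9)])
        t = np.linspace(0.25 * np.pi, 0.75 * np.pi, 5)
        arc = np.column_stack([40 + 5 * np.sin(t), 5 - 5 * np.cos(t), np.zeros(5)])
        leg2 = np.column_stack([np.linspace(40, 0, 9), np.full(9, 10.0), np.zeros(9)])
        mf = frenet_frame(fit_midline(np.vstack([leg1, arc, leg2])))
        probe = np.array([[10.0, 5.0, 0.0]])  # equidistant from both legs
        c = assign_coordinates(probe, mf)
        assert bool(c["ambiguous"].iloc[0])


class TestUnroll:
    def test_uniform_grid_on_straight_cylinder(self):
        mf = TestAssignCoordinates().straight_frames()
        taus = np.repeat(np.linspace(0.1, 0.9, 9), 8)
        phis = np.tile(np.linspace(-np.pi, np.pi, 8, endpoint=False), 9)
        cells = (np.column_stack([taus * 60.0, np.zeros_like(taus), np.zeros_like(taus)])
                 + 5.0 * (np.cos(phis)[:, None] * mf.B[0]
                          + np.sin(phis)[:, None] * mf.N[0]))
        m = unroll(assign_coordinates(cells, mf))
        assert np.allclose(np.sort(np.unique(np.round(m["tau"], 6))),
                           np.linspace(0.1, 0.9, 9), atol=1e-4)

    def test_seam_distance(self):
        eps = 0.01
        assert np.isclose(circular_delta_phi(np.pi - eps, -np.pi + eps), 2 * eps)
        assert np.isclose(circular_delta_phi(0.0, np.pi), np.pi)

    def test_total_on_synthetic_heart(self, small_dataset):
        from cardiomap.geometry import fit_midline, frenet_frame
        cfg = small_dataset.config
        mf = frenet_frame(fit_midline(cfg.midline_control_points))
        coords = assign_coordinates(small_dataset.truth.cells, mf)
        m = unroll(coords)
        assert len(m) == cfg.n_cells
        assert m["tau"].between(0, 1).all()
        assert m["phi"].between(-np.pi, np.pi).all()


class TestUntwistStraighten:
    def kabsch_rmsd(self, X, Y):
        Xc, Yc = X - X.mean(0), Y - Y.mean(0)
        U, _, Vt = np.linalg.svd(Xc.T @ Yc)
        d = np.sign(np.linalg.det(U @ Vt))
        R = U @ np.diag([1, 1, d]) @ Vt
        return float(np.sqrt(np.mean(np.sum((Xc @ R - Yc) ** 2, axis=1))))

    def test_straight_cylinder_is_fixed_point(self):
        mf = TestAssignCoordinates().straight_frames()
        rng = np.random.default_rng(2)
        tau = rng.uniform(0.1, 0.9, 100)
        phi = rng.uniform(-np.pi, np.pi, 100)
        cells = (np.column_stack([tau * 60.0, np.zeros(100), np.zeros(100)])
                 + 5.0 * (np.cos(phi)[:, None] * mf.B[0]
                          + np.sin(phi)[:, None] * mf.N[0]))
        out = untwist_straighten(cells, mf)
        scale = np.linalg.norm(cells - cells.mean(0), axis=1).mean()
        assert self.kabsch_rmsd(cells, out) / scale < 1e-6

    def test_helix_tube_straightens(self):
        mf = frenet_frame(fit_midline(helix_points()))
        rng = np.random.default_rng(4)
        idx = rng.integers(100, len(mf.points) - 100, 200)
        phi = rng.uniform(-np.pi, np.pi, 200)
        r = 3.0
        cells = mf.points[idx] + r * (np.cos(phi)[:, None] * mf.B[idx]
                                      + np.sin(phi)[:, None] * mf.N[idx])
        out = untwist_straighten(cells, mf)
        radial = np.linalg.norm(out[:, 1:], axis=1)
        assert np.abs(radial - r).max() < 1e-2          # same tube radius
        # arc length preserved: axial positions span the sampled tau range
        assert np.isclose(out[:, 0].max() - out[:, 0].min(),
                          (mf.tau[idx].max() - mf.tau[idx].min()) * mf.length_um,
                          rtol=1e-6)

    def test_antipodal_cells_stay_antipodal(self):
        mf = TestAssignCoordinates().straight_frames()
        j = len(mf.points) // 2
        c1 = mf.points[j] + 5.0 * mf.B[j]
        c2 = mf.points[j] - 5.0 * mf.B[j]
        out = untwist_straighten(np.stack([c1, c2]), mf)
        assert np.allclose(out[0, 1:], -out[1, 1:], atol=1e-6)
        assert np.isclose(out[0, 0], out[1, 0], atol=1e-6)


def test_rmf_frames_are_orthonormal_and_twist_free():
    mf = fit_midline(helix_points())
    E1, E2 = rotation_minimizing_frames(mf)
    d1 = np.asarray(mf.spline(mf.u, 1))
    T = d1 / np.linalg.norm(d1, axis=1)[:, None]
    assert np.abs(np.einsum("ij,ij->i", E1, T)).max() < 1e-8
    assert np.abs(np.einsum("ij,ij->i", E1, E2)).max() < 1e-8
    # rotation-minimizing: angular step between consecutive frames about T ~ 0
    proj = np.einsum("ij,ij->i", E1[:-1], E1[1:])
    assert proj.min() > 1 - 1e-4
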