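"""Midline splines, moving frames, and curved-cylinder coordinates.

The embryonic heart tube is modelled as a curved cylinder around a midline
running from the venous inflow to the arterial outflow.  A cubic
(order-4) interpolating B-spline through user-traced control points gives
the midline ``r(u)``; dense arc-length resampling yields the normalized
position parameter ``tau`` in [0, 1].  The Frenet-Serret frame (tangent
``T``, normal ``N``, binormal ``B``) provides the local cross-sectional
plane, so every cell centroid maps to intrinsic coordinates

    tau  - normalized arc-length position of the nearest midline point,
    phi  - angle of the radial offset in the N-B plane, measured from B
           toward N with the two-argument arctangent,
    z    - radial distance from the midline in micrometres.

On straight segments the Frenet normal is undefined; there the frame is
continued by rotation-minimizing (double-reflection) parallel transport
and flagged ``transported``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.interpolate import make_interp_spline
from scipy.optimize import minimize_scalar

__all__ = [
    "MidlineFrameField",
    "fit_midline",
    "frenet_frame",
    "rotation_minimizing_frames",
    "assign_coordinates",
    "unroll",
    "circular_delta_phi",
    "untwist_straighten",
]


@dataclass
class MidlineFrameField:
    """Sampled midline with arc-length parameter and per-sample frames."""

    spline: object                 # vector-valued cubic BSpline over chord parameter u
    u: np.ndarray                  # (n,) spline parameter at unit-speed samples
    tau: np.ndarray                # (n,) normalized arc length in [0, 1]
    points: np.ndarray             # (n, 3) midline samples, um
    length_um: float
    T: np.ndarray | None = None    # (n, 3) unit tangents
    N: np.ndarray | None = None    # (n, 3) unit normals
    B: np.ndarray | None = None    # (n, 3) unit binormals
    curvature: np.ndarray | None = None   # (n,), 1/um
    torsion: np.ndarray | None = None     # (n,), 1/um
    provenance: np.ndarray | None = None  # (n,) "frenet" | "transported"

    @property
    def has_frames(self) -> bool:
        return self.T is not None

    def point_at(self, u: float) -> np.ndarray:
        return np.asarray(self.spline(u), dtype=float)

    def tau_of_u(self, u):
        return np.interp(u, self.u, self.tau)

    def u_of_tau(self, tau):
        return np.interp(tau, self.tau, self.u)


def fit_midline(control_points, n_samples: int = 2048) -> MidlineFrameField:
    """Interpolating cubic B-spline midline, reparameterized to unit speed.

    Parameters
    ----------
    control_points : (k, 3) array-like
        Ordered midline control points in micrometres, inflow first.
    n_samples : int
        Number of uniform-arc-length samples kept on the field.
    """
    cp = np.asarray(control_points, dtype=float)
    if cp.ndim != 2 or cp.shape[1] != 3:
        raise ValueError("control points must be an (k, 3) array of 3D points")
    if cp.shape[0] < 5:
        raise ValueError("need at least 5 ordered control points")
    seg = np.linalg.norm(np.diff(cp, axis=0), axis=1)
    if np.any(seg == 0):
        dup = int(np.flatnonzero(seg == 0)[0])
        raise ValueError(f"duplicate consecutive control points at index {dup}")

    # chordal parameterization, then dense arc-length inversion
    u_knots = np.concatenate([[0.0], np.cumsum(seg)])
    spline = make_interp_spline(u_knots, cp, k=3, axis=0)

    u_fine = np.linspace(0.0, u_knots[-1], max(8 * n_samples, 4096))
    speed = np.linalg.norm(spline(u_fine, 1), axis=1)
    s_fine = np.concatenate([[0.0], np.cumsum(0.5 * (speed[1:] + speed[:-1]) * np.diff(u_fine))])
    length = float(s_fine[-1])

    s_targets = np.linspace(0.0, length, n_samples)
    u_grid = np.interp(s_targets, s_fine, u_fine)
    u_grid[0], u_grid[-1] = 0.0, u_knots[-1]

    return MidlineFrameField(
        spline=spline,
        u=u_grid,
        tau=np.linspace(0.0, 1.0, n_samples),
        points=np.asarray(spline(u_grid), dtype=float),
        length_um=length,
    )


def _double_reflection_step(x0, t0, r0, x1, t1):
    """One rotation-minimizing frame step (double reflection method)."""
    v1 = x1 - x0
    c1 = float(v1 @ v1)
    if c1 < 1e-300:
        rl, tl = r0, t0
    else:
        rl = r0 - (2.0 / c1) * (v1 @ r0) * v1
        tl = t0 - (2.0 / c1) * (v1 @ t0) * v1
    v2 = t1 - tl
    c2 = float(v2 @ v2)
    if c2 < 1e-300:
        r1 = rl
    else:
        r1 = rl - (2.0 / c2) * (v2 @ rl) * v2
    # guard orthogonality against accumulated rounding
    r1 = r1 - (r1 @ t1) * t1
    return r1 / np.linalg.norm(r1)


def _seed_normal(t):
    """An arbitrary but deterministic unit vector orthogonal to ``t``."""
    axis = np.zeros(3)
    axis[int(np.argmin(np.abs(t)))] = 1.0
    n = np.cross(t, axis)
    return n / np.linalg.norm(n)


def _spline_derivatives(mf: MidlineFrameField):
    d1 = np.asarray(mf.spline(mf.u, 1), dtype=float)
    d2 = np.asarray(mf.spline(mf.u, 2), dtype=float)
    d3 = np.asarray(mf.spline(mf.u, 3), dtype=float)
    return d1, d2, d3


def frenet_frame(mf: MidlineFrameField, curvature_tol: float = 1e-6) -> MidlineFrameField:
    """Attach Frenet-Serret frames, curvature and torsion to a midline.

    ``T = r'/|r'|``, ``N = T'/|T'|``, ``B = T x N``.  Samples whose
    curvature falls below ``curvature_tol`` (per micrometre) get a
    rotation-minimizing frame transported from the last valid sample and
    are flagged ``"transported"``.  Sign continuity of N is enforced along
    the curve so the frame does not flip across inflection points.
    """
    d1, d2, d3 = _spline_derivatives(mf)
    speed = np.linalg.norm(d1, axis=1)
    T = d1 / speed[:, None]

    cross12 = np.cross(d1, d2)
    cross_norm = np.linalg.norm(cross12, axis=1)
    curvature = cross_norm / speed**3
    torsion = np.zeros_like(curvature)
    ok = cross_norm > 1e-30
    torsion[ok] = np.einsum("ij,ij->i", cross12[ok], d3[ok]) / cross_norm[ok] ** 2

    # derivative of T with respect to the spline parameter (direction of N)
    dT = d2 / speed[:, None] - d1 * np.einsum("ij,ij->i", d1, d2)[:, None] / speed[:, None] ** 3
    valid = curvature >= curvature_tol

    n = len(mf.u)
    N = np.zeros((n, 3))
    provenance = np.full(n, "transported", dtype="<U11")

    if not np.any(valid):
        warnings.warn("midline is straight everywhere; frame seeded from an arbitrary normal")
        N[0] = _seed_normal(T[0])
        for i in range(1, n):
            N[i] = _double_reflection_step(mf.points[i - 1], T[i - 1], N[i - 1], mf.points[i], T[i])
    else:
        i0 = int(np.flatnonzero(valid)[0])
        N[i0] = dT[i0] / np.linalg.norm(dT[i0])
        provenance[i0] = "frenet"
        for direction in (range(i0 + 1, n), range(i0 - 1, -1, -1)):
            for i in direction:
                prev = i - 1 if i > i0 else i + 1
                if valid[i]:
                    cand = dT[i] / np.linalg.norm(dT[i])
                    if cand @ N[prev] < 0:
                        cand = -cand
                    N[i] = cand
                    provenance[i] = "frenet"
                else:
                    N[i] = _double_reflection_step(
                        mf.points[prev], T[prev], N[prev], mf.points[i], T[i]
                    )

    # exact orthonormalization (numerical safety for the 1e-9 invariant)
    N = N - np.einsum("ij,ij->i", N, T)[:, None] * T
    N /= np.linalg.norm(N, axis=1)[:, None]
    B = np.cross(T, N)

    return replace(mf, T=T, N=N, B=B, curvature=curvature, torsion=torsion, provenance=provenance)


def rotation_minimizing_frames(mf: MidlineFrameField, seed_normal=None):
    """Torsion-free (rotation-minimizing) frame field ``(E1, E2)`` along the midline.

    ``E1`` plays the role of the normal, ``E2 = T x E1`` of the binormal.
    """
    d1 = np.asarray(mf.spline(mf.u, 1), dtype=float)
    T = d1 / np.linalg.norm(d1, axis=1)[:, None]
    n = len(mf.u)
    E1 = np.zeros((n, 3))
    if seed_normal is None:
        E1[0] = _seed_normal(T[0])
    else:
        s = np.asarray(seed_normal, dtype=float)
        s = s - (s @ T[0]) * T[0]
        E1[0] = s / np.linalg.norm(s)
    for i in range(1, n):
        E1[i] = _double_reflection_step(mf.points[i - 1], T[i - 1], E1[i - 1], mf.points[i], T[i])
    E2 = np.cross(T, E1)
    return E1, E2


def _nearest_u(mf: MidlineFrameField, point: np.ndarray, j: int) -> float:
    """Refine the nearest midline parameter around dense sample ``j``."""
    lo = mf.u[max(j - 1, 0)]
    hi = mf.u[min(j + 1, len(mf.u) - 1)]
    if hi <= lo:
        return float(mf.u[j])

    def sqdist(u):
        d = np.asarray(mf.spline(u)) - point
        return float(d @ d)

    res = minimize_scalar(sqdist, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-10 * max(mf.length_um, 1.0)})
    return float(res.x)


def assign_coordinates(
    cells,
    mf: MidlineFrameField,
    ambiguity_rel: float = 0.01,
    ambiguity_dtau: float = 0.05,
    phi_from: str = "binormal",
) -> pd.DataFrame:
    """Map cell centroids to curved-cylinder coordinates (tau, phi, z).

    Parameters
    ----------
    cells : (n, 3) array or DataFrame with columns x_um, y_um, z_um
    mf : midline with frames attached
    ambiguity_rel, ambiguity_dtau :
        A cell is flagged ``ambiguous`` when a second local minimum of the
        distance-to-midline profile lies within ``ambiguity_rel`` of the
        global minimum but more than ``ambiguity_dtau`` away in tau.
    phi_from : "binormal" (paper reading, phi = atan2(d.N, d.B)) or "normal"
        (phi = atan2(d.B, d.N)), the alternative sign convention.

    Returns
    -------
    DataFrame with columns ``tau, phi, z_um, inner, ambiguous`` indexed like
    the input cells.
    """
    if not mf.has_frames:
        raise ValueError("midline has no frames; call frenet_frame first")
    if phi_from not in ("binormal", "normal"):
        raise ValueError("phi_from must be 'binormal' or 'normal'")
    if isinstance(cells, pd.DataFrame):
        xyz = cells[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)
        index = cells.index
    else:
        xyz = np.asarray(cells, dtype=float)
        index = pd.RangeIndex(len(xyz))

    # dense distance profiles, chunked to bound memory
    n_cells = len(xyz)
    out = np.zeros((n_cells, 5))
    ambiguous = np.zeros(n_cells, dtype=bool)
    inner = np.zeros(n_cells, dtype=bool)
    taus = np.zeros(n_cells)
    phis = np.zeros(n_cells)
    zs = np.zeros(n_cells)

    for start in range(0, n_cells, 512):
        block = xyz[start:start + 512]
        d2 = ((block[:, None, :] - mf.points[None, :, :]) ** 2).sum(axis=2)
        jmin = np.argmin(d2, axis=1)
        for bi, (point, j) in enumerate(zip(block, jmin)):
            i = start + bi
            u_star = _nearest_u(mf, point, int(j))
            tau_star = float(mf.tau_of_u(u_star))
            foot = np.asarray(mf.spline(u_star), dtype=float)
            d = point - foot
            z = float(np.linalg.norm(d))

            prof = d2[bi]
            interior = prof[1:-1]
            mins = 1 + np.flatnonzero((interior < prof[:-2]) & (interior <= prof[2:]))
            dmin = np.sqrt(prof[j])
            for m in mins:
                if abs(mf.tau[m] - tau_star) > ambiguity_dtau and \
                        np.sqrt(prof[m]) <= dmin * (1.0 + ambiguity_rel):
                    ambiguous[i] = True
                    break

            js = int(np.argmin(np.abs(mf.u - u_star)))
            dN = float(d @ mf.N[js])
            dB = float(d @ mf.B[js])
            phi = np.arctan2(dN, dB) if phi_from == "binormal" else np.arctan2(dB, dN)
            taus[i], phis[i], zs[i] = tau_star, phi, z
            inner[i] = dN > 0

    del out
    return pd.DataFrame(
        {"tau": taus, "phi": phis, "z_um": zs, "inner": inner, "ambiguous": ambiguous},
        index=index,
    )


def unroll(coords: pd.DataFrame) -> pd.DataFrame:
    """Project (tau, phi, z) -> (tau, phi), the flat cylinder map.

    The radial distance is discarded; the cylinder is cut at phi = +/- pi.
    Use :func:`circular_delta_phi` for distances across the seam.
    """
    return coords[["tau", "phi"]].copy()


def circular_delta_phi(a, b):
    """Circular distance between angles, respecting the phi = +/-pi seam."""
    d = np.abs(np.asarray(a) - np.asarray(b)) % (2.0 * np.pi)
    return np.minimum(d, 2.0 * np.pi - d)


def untwist_straighten(cells, mf: MidlineFrameField, coords: pd.DataFrame | None = None) -> np.ndarray:
    """Map cells to the fully untwisted, straightened tube configuration.

    Each cell goes to ``(tau * L, z cos phi', z sin phi')`` on a straight
    axis of the midline's total length L, where ``phi'`` is the cell's
    angle measured in a torsion-free rotation-minimizing frame.  This is
    the endpoint of successively removing the midline's torsion and then
    its curvature.
    """
    if coords is None:
        coords = assign_coordinates(cells, mf)
    E1, E2 = rotation_minimizing_frames(mf, seed_normal=mf.N[0] if mf.has_frames else None)
    # twist angle of the Frenet normal relative to the torsion-free frame
    psi = np.arctan2(np.einsum("ij,ij->i", mf.N, E2), np.einsum("ij,ij->i", mf.N, E1))
    psi_unwrapped = np.unwrap(psi)
    psi_cell = np.interp(coords["tau"].to_numpy(), mf.tau, psi_unwrapped)
    phi_prime = coords["phi"].to_numpy() - psi_cell
    z = coords["z_um"].to_numpy()
    # axes chosen so the map is orientation-preserving (a proper rigid
    # motion on straight untwisted input): N -> y, B -> z, T -> x
    return np.column_stack([
        coords["tau"].to_numpy() * mf.length_um,
        z * np.sin(phi_prime),
        z * np.cos(phi_prime),
    ])
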