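"""Synthetic looped-heart generator for end-to-end pipeline testing.

Emulates the acquisition geometry of high-speed light-sheet optical
mapping of the embryonic zebrafish heart: a looped two-chambered tube
(sinus venosus -> atrium -> atrio-ventricular canal -> ventricle ->
outflow tract) populated with cells on its surface, a region-dependent
activation wave travelling from an inflow pacemaker ring, per-cell
calcium transients with region-specific 10-90% rise times, and rendered
two-channel image data: a z-stack of per-plane high-speed calcium movies
(each plane starting at an independent random cardiac phase, as in
unsynchronized plane-by-plane acquisition) plus a static nuclear-marker
z-stack.

All randomness flows from ``SyntheticHeartConfig.rng_seed``; identical
configs give bit-identical output.

The default geometry is a desk-scale model (midline ~150 um, radii
7-15 um, 600 cells) rather than a full-size heart; see docs/methods.md.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, dijkstra
from scipy.spatial import Delaunay, cKDTree

from .containers import MovieStack, TransientSet
from .geometry import MidlineFrameField, fit_midline, rotation_minimizing_frames

__all__ = [
    "SyntheticHeartConfig",
    "NoiseModel",
    "HeartGeometry",
    "GroundTruth",
    "default_midline_control_points",
    "make_geometry",
    "make_activation",
    "make_transients",
    "render_movies",
    "generate",
]

REGION_NAMES = ("sinus", "atrium", "avc", "ventricle", "outflow")

# logit(0.9) - logit(0.1): width of a logistic 10-90% rise in units of its scale
_LOGISTIC_1090 = 2.0 * np.log(9.0)


def default_midline_control_points() -> np.ndarray:
    """An s-looped midline with torsion, spanning roughly 100 x 36 x 10 um."""
    u = np.linspace(0.0, 1.0, 11)
    x = 98.0 * u
    y = 30.0 + 18.0 * np.sin(2.0 * np.pi * u)
    z = 22.0 + 6.0 * u + 3.0 * np.sin(2.0 * np.pi * u + 0.5 * np.pi)
    return np.column_stack([x, y, z])


@dataclass
class NoiseModel:
    """Poisson-Gaussian camera noise surrogate."""

    gaussian_sigma: float = 3.0
    poisson: bool = True

    def apply(self, image: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        out = image
        if self.poisson:
            out = rng.poisson(np.clip(out, 0, None)).astype(np.float32)
        if self.gaussian_sigma > 0:
            out = out + rng.normal(0.0, self.gaussian_sigma, size=out.shape).astype(np.float32)
        return out


@dataclass
class SyntheticHeartConfig:
    """Study conditions of the synthetic heart.

    Acquisition constants default to the experimental setup (400 Hz frame
    rate i.e. 2.5 ms frames, 0.5 um xy pixels, 1 um z-steps, 2 Hz heart
    rate i.e. a 500 ms cycle).
    """

    midline_control_points: np.ndarray = field(default_factory=default_midline_control_points)
    # (tau, radius_um) knots; two bulges (atrium, ventricle) with an AVC constriction
    radius_knots: tuple = (
        (0.0, 7.0), (0.10, 11.0), (0.22, 14.5), (0.38, 13.5), (0.50, 7.5),
        (0.60, 10.5), (0.75, 15.0), (0.88, 11.5), (1.0, 7.5),
    )
    n_cells: int = 600
    # tau cut points between sinus / atrium / AVC / ventricle / outflow
    region_boundaries: tuple = (0.09, 0.42, 0.60, 0.91)
    region_speeds: dict = field(default_factory=lambda: {
        "sinus": 75.0, "atrium": 160.0, "avc": 65.0, "ventricle": 190.0, "outflow": 130.0,
    })  # cells/s
    region_rise_times: dict = field(default_factory=lambda: {
        "sinus": 120.0, "atrium": 135.0, "avc": 170.0, "ventricle": 200.0, "outflow": 210.0,
    })  # ms, 10-90%
    cycle_period_ms: float = 500.0
    frame_period_ms: float = 2.5
    n_record_cycles: float = 2.25
    pixel_size_xy_um: float = 0.5
    z_step_um: float = 1.0
    # cell placement
    min_separation_um: float = 3.0
    radial_jitter_um: float = 0.4
    # rendering
    calcium_sigma_um: float = 1.6
    nuclear_sigma_um: float = 1.1
    calcium_amplitude: float = 700.0
    nuclear_amplitude: float = 600.0
    baseline: float = 100.0
    render_margin_um: float = 6.0
    render_z_margin_um: float = 2.0  # tighter: keeps every plane inside the tissue
    fov_um: tuple | None = None  # optional (x, y) field-of-view override
    noise_model: NoiseModel = field(default_factory=NoiseModel)
    phase_offsets: str = "random"  # "random" | "zero"
    # activation
    activation_model: str = "front"  # "front" | "links"
    rise_jitter_frac: float = 0.03
    origin_quantile: float = 0.05
    rng_seed: int = 0

    def __post_init__(self):
        self.validate()

    def validate(self):
        b = np.asarray(self.region_boundaries, dtype=float)
        if not (np.all(np.diff(b) > 0) and b[0] > 0 and b[-1] < 1):
            raise ValueError("region_boundaries must be strictly increasing within (0, 1)")
        for name in REGION_NAMES:
            if self.region_speeds[name] <= 0:
                raise ValueError(f"region speed for {name} must be > 0")
            if self.region_rise_times[name] <= 0:
                raise ValueError(f"region rise time for {name} must be > 0")
        ratio = self.cycle_period_ms / self.frame_period_ms
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError("cycle_period_ms must be an integer multiple of frame_period_ms")
        if self.activation_model not in ("front", "links"):
            raise ValueError("activation_model must be 'front' or 'links'")
        if self.phase_offsets not in ("random", "zero"):
            raise ValueError("phase_offsets must be 'random' or 'zero'")

    @property
    def cycle_frames(self) -> int:
        return int(round(self.cycle_period_ms / self.frame_period_ms))

    @property
    def record_frames(self) -> int:
        return int(round(self.n_record_cycles * self.cycle_frames))

    def radius_profile(self) -> PchipInterpolator:
        knots = np.asarray(self.radius_knots, dtype=float)
        return PchipInterpolator(knots[:, 0], knots[:, 1])

    def region_of_tau(self, tau):
        """Region label per tau value."""
        idx = np.searchsorted(np.asarray(self.region_boundaries), np.asarray(tau), side="right")
        return np.asarray(REGION_NAMES)[idx]

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["midline_control_points"] = np.asarray(self.midline_control_points).tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticHeartConfig":
        d = dict(d)
        if "noise_model" in d and isinstance(d["noise_model"], dict):
            d["noise_model"] = NoiseModel(**d["noise_model"])
        if "midline_control_points" in d:
            d["midline_control_points"] = np.asarray(d["midline_control_points"], dtype=float)
        if "radius_knots" in d:
            d["radius_knots"] = tuple(tuple(k) for k in d["radius_knots"])
        if "region_boundaries" in d:
            d["region_boundaries"] = tuple(d["region_boundaries"])
        if "fov_um" in d and d["fov_um"] is not None:
            d["fov_um"] = tuple(d["fov_um"])
        return cls(**d)


@dataclass
class HeartGeometry:
    """Midline plus cells placed on the tube surface (ground-truth geometry)."""

    midline: MidlineFrameField
    cells: pd.DataFrame      # x_um, y_um, z_um, tau, phi, radius_um, region
    config: SyntheticHeartConfig


@dataclass
class GroundTruth:
    """Per-cell ground truth plus acquisition-level truth (plane phase offsets)."""

    cells: pd.DataFrame      # geometry columns + t_act_ms, rise_ms, speed_cells_s, is_origin
    midline_samples: np.ndarray
    adjacency: list          # true neighbor edges [(i, j), ...]
    mean_link_um: float
    plane_offsets: np.ndarray | None = None   # frames, in [0, cycle_frames)
    origin_ids: np.ndarray | None = None

    def to_json_dict(self) -> dict:
        return {
            "plane_offsets": None if self.plane_offsets is None else self.plane_offsets.tolist(),
            "mean_link_um": self.mean_link_um,
            "origin_ids": None if self.origin_ids is None else self.origin_ids.tolist(),
        }


def _check_self_intersection(mf: MidlineFrameField, radius):
    """Reject midlines that pass within one tube diameter of themselves."""
    pts = mf.points[::8]
    tau = mf.tau[::8]
    r = radius(tau)
    tree = cKDTree(pts)
    pairs = tree.query_pairs(float(2.0 * r.max()), output_type="ndarray")
    if len(pairs) == 0:
        return
    d = np.linalg.norm(pts[pairs[:, 0]] - pts[pairs[:, 1]], axis=1)
    arc = np.abs(tau[pairs[:, 0]] - tau[pairs[:, 1]]) * mf.length_um
    rsum = r[pairs[:, 0]] + r[pairs[:, 1]]
    # only distant-along-the-curve segments can collide; adjacent bends are fine
    bad = (arc > 2.0 * rsum) & (d < 0.9 * rsum)
    if np.any(bad):
        k = int(np.flatnonzero(bad)[0])
        raise ValueError(
            "degenerate midline: self-intersects within the tube radius near "
            f"tau={tau[pairs[k, 0]]:.3f} and tau={tau[pairs[k, 1]]:.3f}"
        )


def make_geometry(config: SyntheticHeartConfig) -> HeartGeometry:
    """Place ``n_cells`` on the tube surface with a minimum-separation thinning.

    Longitudinal positions are drawn with density proportional to the local
    circumference (i.e. uniformly per unit surface area), angles uniformly;
    radial jitter emulates myocardial wall thickness.
    """
    if len(np.asarray(config.midline_control_points)) < 4:
        raise ValueError("need at least 4 midline control points")
    if config.n_cells < 20:
        raise ValueError("n_cells must be at least 20")

    rng = np.random.default_rng(np.random.SeedSequence([config.rng_seed, 101]))
    mf = fit_midline(config.midline_control_points)
    radius = config.radius_profile()
    _check_self_intersection(mf, radius)

    # inverse-CDF sampling of tau with area density  ~ r(tau) (unit-speed midline)
    tau_grid = np.linspace(0.0, 1.0, 4096)
    w = radius(tau_grid)
    cdf = np.concatenate([[0.0], np.cumsum(0.5 * (w[1:] + w[:-1]) * np.diff(tau_grid))])
    cdf /= cdf[-1]

    E1, E2 = rotation_minimizing_frames(mf)

    accepted = np.empty((0, 3))
    rows = []
    max_candidates = 200 * config.n_cells
    batch = 4 * config.n_cells
    n_drawn = 0
    while len(rows) < config.n_cells and n_drawn < max_candidates:
        taus = np.interp(rng.random(batch), cdf, tau_grid)
        phis = rng.uniform(-np.pi, np.pi, batch)
        r_eff = radius(taus) + rng.normal(0.0, config.radial_jitter_um, batch)
        n_drawn += batch
        e1 = np.column_stack([np.interp(taus, mf.tau, E1[:, k]) for k in range(3)])
        e2 = np.column_stack([np.interp(taus, mf.tau, E2[:, k]) for k in range(3)])
        base = np.column_stack([np.interp(taus, mf.tau, mf.points[:, k]) for k in range(3)])
        pos = base + r_eff[:, None] * (np.cos(phis)[:, None] * e2 + np.sin(phis)[:, None] * e1)
        for cand, t_, p_, r_ in zip(pos, taus, phis, r_eff):
            if len(accepted) and np.min(np.linalg.norm(accepted - cand, axis=1)) < config.min_separation_um:
                continue
            accepted = np.vstack([accepted, cand])
            rows.append((cand[0], cand[1], cand[2], t_, p_, r_))
            if len(rows) == config.n_cells:
                break
    if len(rows) < config.n_cells:
        raise ValueError(
            f"could only place {len(rows)} of {config.n_cells} cells at "
            f"min separation {config.min_separation_um} um; reduce density"
        )

    cells = pd.DataFrame(rows, columns=["x_um", "y_um", "z_um", "tau", "phi", "radius_um"])
    cells.index.name = "cell_id"
    cells["region"] = config.region_of_tau(cells["tau"].to_numpy())
    return HeartGeometry(midline=mf, cells=cells, config=config)


def region_area_fractions(config: SyntheticHeartConfig, n_quad: int = 20000) -> dict:
    """Surface-area fraction per region by dense quadrature of 2*pi*r(tau)*L dtau."""
    radius = config.radius_profile()
    tau = np.linspace(0.0, 1.0, n_quad)
    w = radius(tau)
    regions = config.region_of_tau(tau)
    total = np.trapezoid(w, tau)
    out = {}
    for name in REGION_NAMES:
        mask = regions == name
        out[name] = float(np.trapezoid(np.where(mask, w, 0.0), tau) / total)
    return out


def _surface_delaunay_edges(cells: pd.DataFrame, length_um: float) -> np.ndarray:
    """True cell adjacency: Delaunay triangulation on the developed surface.

    The tube surface is developed to (s, a) = (tau * L, phi * r); the seam at
    phi = +/-pi is handled by triplicating cells at a +/- 2*pi*r.
    """
    n = len(cells)
    s = cells["tau"].to_numpy() * length_um
    r = cells["radius_um"].to_numpy()
    a = cells["phi"].to_numpy() * r
    pts = np.concatenate([
        np.column_stack([s, a]),
        np.column_stack([s, a + 2.0 * np.pi * r]),
        np.column_stack([s, a - 2.0 * np.pi * r]),
    ])
    tri = Delaunay(pts)
    edges = set()
    for simplex in tri.simplices:
        for k in range(3):
            i, j = int(simplex[k]), int(simplex[(k + 1) % 3])
            oi, oj = i % n, j % n
            if oi == oj:
                continue
            if i < n or j < n:  # keep edges touching an original (non-copy) cell
                edges.add((min(oi, oj), max(oi, oj)))
    edges = np.asarray(sorted(edges))
    # guard: drop rare spurious long edges from the development approximation
    xyz = cells[["x_um", "y_um", "z_um"]].to_numpy()
    d3 = np.linalg.norm(xyz[edges[:, 0]] - xyz[edges[:, 1]], axis=1)
    nn = cKDTree(xyz).query(xyz, k=2)[0][:, 1]
    cap = 3.0 * np.median(nn)
    return edges[d3 <= cap]


def make_activation(geometry: HeartGeometry, config: SyntheticHeartConfig | None = None) -> GroundTruth:
    """Ground-truth activation times from an inflow-to-outflow wave.

    Two models:

    ``"front"`` (default): a smooth front travels along the tube; its local
    longitudinal rate is calibrated on the true adjacency so that the
    neighborhood harmonic speed measure (cells/s) equals the configured
    region speed.  t_act is then a function of tau only.

    ``"links"``: per-link delay 1/region_speed; t_act is the multi-source
    shortest-path (Dijkstra) time from the inflow ring.  This is the
    literal links-traversed-per-second reading, kept for oracle tests.
    """
    config = config or geometry.config
    cells = geometry.cells.copy()
    n = len(cells)
    L = geometry.midline.length_um
    edges = _surface_delaunay_edges(cells, L)

    adj = csr_matrix(
        (np.ones(len(edges)), (edges[:, 0], edges[:, 1])), shape=(n, n)
    )
    adj = adj + adj.T
    n_comp, _ = connected_components(adj, directed=False)
    if n_comp != 1:
        raise ValueError(f"true cell adjacency is disconnected ({n_comp} components)")

    xyz = cells[["x_um", "y_um", "z_um"]].to_numpy()
    elen = np.linalg.norm(xyz[edges[:, 0]] - xyz[edges[:, 1]], axis=1)
    mean_link = float(np.mean(elen))

    s = cells["tau"].to_numpy() * L
    speeds = np.asarray([config.region_speeds[r] for r in cells["region"]])

    if config.activation_model == "front":
        # The front's longitudinal rate is calibrated per region so that the
        # neighborhood harmonic speed measure, evaluated on the true
        # adjacency, has the configured value as its regional median:
        # cs_i = V / mean_j|ds_ij|, so V_r = v_r * median_i(mean_j |ds_ij|).
        ds = np.abs(s[edges[:, 0]] - s[edges[:, 1]])
        percell_sum = np.zeros(n)
        percell_cnt = np.zeros(n)
        for (a, b), v in zip(edges, ds):
            percell_sum[a] += v
            percell_cnt[a] += 1
            percell_sum[b] += v
            percell_cnt[b] += 1
        percell_mean = percell_sum / np.maximum(percell_cnt, 1)
        regions = cells["region"].to_numpy()
        bounds = (0.0,) + tuple(config.region_boundaries) + (1.0,)
        s_nodes = [0.0]
        t_nodes = [0.0]
        t_accum = 0.0
        for k, name in enumerate(REGION_NAMES):
            in_r = regions == name
            m_r = np.median(percell_mean[in_r]) if np.any(in_r) else mean_link * 0.55
            v_um = config.region_speeds[name] * m_r  # um/s front rate in this region
            seg = (bounds[k + 1] - bounds[k]) * L
            t_accum += seg / v_um * 1000.0  # ms
            s_nodes.append(bounds[k + 1] * L)
            t_nodes.append(t_accum)
        t_act = np.interp(s, s_nodes, t_nodes)
    else:
        # shortest-path time with per-link delay 1/region_speed (seconds per link)
        delays = 0.5 * (1.0 / speeds[edges[:, 0]] + 1.0 / speeds[edges[:, 1]]) * 1000.0  # ms
        g = csr_matrix((delays, (edges[:, 0], edges[:, 1])), shape=(n, n))
        g = g + g.T
        ring = np.flatnonzero(s - s.min() < mean_link)
        t_all = dijkstra(g, directed=False, indices=ring)
        t_act = t_all.min(axis=0)
        if np.any(~np.isfinite(t_act)):
            raise ValueError("activation did not reach every cell (disconnected adjacency)")

    rng = np.random.default_rng(np.random.SeedSequence([config.rng_seed, 202]))
    base_rise = np.asarray([config.region_rise_times[r] for r in cells["region"]])
    rise = base_rise * (1.0 + config.rise_jitter_frac * rng.standard_normal(n))
    rise = np.clip(rise, 2.0 * config.frame_period_ms, None)

    cells["t_act_ms"] = t_act
    cells["rise_ms"] = rise
    cells["speed_cells_s"] = speeds

    q = np.quantile(t_act, config.origin_quantile)
    is_origin = (t_act < q) & (speeds < np.median(speeds))
    cells["is_origin"] = is_origin

    return GroundTruth(
        cells=cells,
        midline_samples=geometry.midline.points.copy(),
        adjacency=[tuple(e) for e in edges],
        mean_link_um=mean_link,
        origin_ids=np.flatnonzero(is_origin),
    )


def _waveform_matrix(t_act, rise, F: int, dt: float, P: float) -> np.ndarray:
    """Noiseless periodic transients, (n_cells, F), exactly min-max normalized.

    Logistic upstroke whose continuous 10% crossing sits at t_act and 90%
    crossing at t_act + rise, a short plateau, then an exponential decay
    reaching exactly zero at the next onset.
    """
    t_act = np.asarray(t_act, dtype=float)[:, None]
    rise = np.asarray(rise, dtype=float)[:, None]
    if np.any(rise < 2.0 * dt):
        raise ValueError("rise time below two frame periods is unresolvable")
    t = (np.arange(F) * dt - t_act) % P
    s = rise / _LOGISTIC_1090  # logistic scale: 10-90% span = 2*ln(9)*s
    c = 0.5 * rise
    x_peak = c + 5.49 * s
    x_peak = np.minimum(x_peak, 0.92 * P)
    peak = 1.0 / (1.0 + np.exp(-(x_peak - c) / s))
    rem = P - x_peak
    tau_d = np.maximum(rem / 5.0, 15.0)
    upstroke = 1.0 / (1.0 + np.exp(-(t - c) / s))
    d = t - x_peak
    decay = peak * (np.exp(-d / tau_d) - np.exp(-rem / tau_d)) / (1.0 - np.exp(-rem / tau_d))
    w = np.where(t <= x_peak, upstroke, decay)
    w = w - w.min(axis=1, keepdims=True)
    w = w / w.max(axis=1, keepdims=True)
    return w


def make_transients(truth: GroundTruth, config: SyntheticHeartConfig) -> TransientSet:
    """Noiseless normalized per-cell transients over one cardiac cycle."""
    F = config.cycle_frames
    w = _waveform_matrix(
        truth.cells["t_act_ms"].to_numpy(),
        truth.cells["rise_ms"].to_numpy(),
        F, config.frame_period_ms, config.cycle_period_ms,
    )
    return TransientSet(
        data=w,
        frame_period_ms=config.frame_period_ms,
        cell_ids=truth.cells.index.to_numpy(),
        state="normalized",
    )


def render_movies(truth: GroundTruth, transients: TransientSet,
                  config: SyntheticHeartConfig):
    """Render the calcium movie z-stack and the static nuclear z-stack.

    Returns ``(stack, nuclear, truth)`` where ``truth`` now carries the
    per-plane phase offsets.  Cells are additive 3D Gaussian blobs sectioned
    by each plane; each plane's movie starts at an independent uniformly
    drawn cardiac phase (in frames).
    """
    cells = truth.cells
    xyz = cells[["x_um", "y_um", "z_um"]].to_numpy()
    margin = np.array([config.render_margin_um, config.render_margin_um,
                       config.render_z_margin_um])
    lo = xyz.min(axis=0) - margin
    hi = xyz.max(axis=0) + margin
    if config.fov_um is not None:
        fx, fy = config.fov_um
        if fx < hi[0] - lo[0] or fy < hi[1] - lo[1]:
            raise ValueError(
                f"field of view {config.fov_um} um is smaller than the geometry "
                f"bounding box ({hi[0] - lo[0]:.1f} x {hi[1] - lo[1]:.1f} um)"
            )
    px = config.pixel_size_xy_um
    dz = config.z_step_um
    nx = int(np.ceil((hi[0] - lo[0]) / px)) + 1
    ny = int(np.ceil((hi[1] - lo[1]) / px)) + 1
    nz = int(np.ceil((hi[2] - lo[2]) / dz)) + 1
    origin = (float(lo[0]), float(lo[1]), float(lo[2]))

    F = config.cycle_frames
    T = config.record_frames
    ss = np.random.SeedSequence([config.rng_seed, 303])
    rng_off, rng_noise_ca, rng_noise_nuc = [np.random.default_rng(s) for s in ss.spawn(3)]

    if config.phase_offsets == "zero":
        offsets = np.zeros(nz, dtype=int)
    else:
        offsets = rng_off.integers(0, F, size=nz)

    amp = config.calcium_amplitude * transients.data  # (n, F)
    sig = config.calcium_sigma_um
    xs = lo[0] + px * np.arange(nx)
    ys = lo[1] + px * np.arange(ny)

    # per-cell xy footprint patch (shared across planes)
    half = int(np.ceil(3.5 * sig / px))
    movies = np.empty((nz, T, ny, nx), dtype=np.uint16)
    frame_idx = np.arange(T)
    for iz in range(nz):
        zc = lo[2] + dz * iz
        zfac = np.exp(-((xyz[:, 2] - zc) ** 2) / (2.0 * sig ** 2))
        near = np.flatnonzero(zfac > 1e-3)
        plane = np.full((T, ny, nx), config.baseline, dtype=np.float32)
        phases = (frame_idx + offsets[iz]) % F
        for i in near:
            cx = int(round((xyz[i, 0] - lo[0]) / px))
            cy = int(round((xyz[i, 1] - lo[1]) / px))
            x0, x1 = max(cx - half, 0), min(cx + half + 1, nx)
            y0, y1 = max(cy - half, 0), min(cy + half + 1, ny)
            gx = np.exp(-((xs[x0:x1] - xyz[i, 0]) ** 2) / (2.0 * sig ** 2))
            gy = np.exp(-((ys[y0:y1] - xyz[i, 1]) ** 2) / (2.0 * sig ** 2))
            patch = (zfac[i] * np.outer(gy, gx)).astype(np.float32)
            plane[:, y0:y1, x0:x1] += amp[i, phases][:, None, None].astype(np.float32) * patch
        plane = config.noise_model.apply(plane, rng_noise_ca)
        movies[iz] = np.clip(plane, 0, 65535).astype(np.uint16)

    # static nuclear stack
    nsig = config.nuclear_sigma_um
    nuclear = np.full((nz, ny, nx), config.baseline, dtype=np.float32)
    nhalf = int(np.ceil(3.5 * nsig / px))
    for i in range(len(xyz)):
        cx = int(round((xyz[i, 0] - lo[0]) / px))
        cy = int(round((xyz[i, 1] - lo[1]) / px))
        x0, x1 = max(cx - nhalf, 0), min(cx + nhalf + 1, nx)
        y0, y1 = max(cy - nhalf, 0), min(cy + nhalf + 1, ny)
        gx = np.exp(-((xs[x0:x1] - xyz[i, 0]) ** 2) / (2.0 * nsig ** 2))
        gy = np.exp(-((ys[y0:y1] - xyz[i, 1]) ** 2) / (2.0 * nsig ** 2))
        zs = lo[2] + dz * np.arange(nz)
        gz = np.exp(-((zs - xyz[i, 2]) ** 2) / (2.0 * nsig ** 2))
        nuclear[:, y0:y1, x0:x1] += (
            config.nuclear_amplitude
            * gz[:, None, None]
            * np.outer(gy, gx)[None, :, :]
        ).astype(np.float32)
    nuclear = config.noise_model.apply(nuclear, rng_noise_nuc)
    nuclear = np.clip(nuclear, 0, 65535).astype(np.uint16)

    stack = MovieStack(
        movies=movies,
        frame_period_ms=config.frame_period_ms,
        pixel_size_xy_um=px,
        z_step_um=dz,
        origin_um=origin,
    )
    truth.plane_offsets = offsets
    return stack, nuclear, truth


@dataclass
class SyntheticDataset:
    config: SyntheticHeartConfig
    geometry: HeartGeometry
    truth: GroundTruth
    transients: TransientSet
    stack: MovieStack
    nuclear: np.ndarray


def generate(config: SyntheticHeartConfig) -> SyntheticDataset:
    """Full synthetic dataset: geometry, truth, transients, rendered channels."""
    geom = make_geometry(config)
    truth = make_activation(geom, config)
    transients = make_transients(truth, config)
    stack, nuclear, truth = render_movies(truth, transients, config)
    return SyntheticDataset(config, geom, truth, transients, stack, nuclear)
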