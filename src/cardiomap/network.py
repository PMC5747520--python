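"""Cell-neighborhood graph and conduction analysis.

The myocardium is represented as an undirected graph G = (V, E): per cell,
its k nearest neighbors are projected onto the local tangent plane (top-2
right singular vectors of the centered neighborhood), the 2D Delaunay
triangulation is computed, and the edges incident to the focal cell join
the global graph.

Two local conduction speed measures are computed per cell i over its
direct neighbors j, with dt(i,j) the absolute activation-time difference
(floored at one frame period to keep ties finite, flagged):

* biological speed, cells/s:  cs_i = n * (sum_j dt(i,j) / e(i,j))^-1
  with e(i,j) = 1 for direct neighbors (links traversed per second);
* metric speed, um/s:         cs_i = n * (sum_j dt(i,j) / d(i,j))^-1
  with d(i,j) the 3D Euclidean edge length.

Cell shape is estimated from the principal components of the neighboring
nuclei distribution (eigenvalues l1 >= l2 >= l3): fractional anisotropy
FA = sqrt(3/2) * ||l - mean(l)|| / ||l|| and ellipsoid volume
(4/3) pi l1 l2 l3.  Pacemaker cells are those activating before the
0.05 quantile of activation times while conducting slower than the median.
"""

from __future__ import annotations

import numpy as np
import networkx as nx
import pandas as pd
from scipy.interpolate import griddata
from scipy.spatial import Delaunay, cKDTree

__all__ = [
    "build_graph",
    "biological_speed",
    "metric_speed",
    "shape_estimate",
    "identify_pacemakers",
    "map_conduction_2d",
]


def build_graph(cells, k_neighbors: int = 10, max_edge_um: float | None = None,
                jitter_seed: int = 0) -> nx.Graph:
    """Local-SVD-projected Delaunay neighborhood graph.

    ``cells`` is an (n, 3) centroid array or a DataFrame with x_um/y_um/z_um.
    A deterministic seeded jitter (1e-6 of the bounding-box diagonal) is
    applied to the coordinates used for triangulation only, resolving
    cocircular/coplanar degeneracies consistently across all local patches.
    Edge lengths come from the unjittered 3D positions.
    """
    if isinstance(cells, pd.DataFrame):
        xyz = cells[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)
        ids = cells.index.to_numpy()
    else:
        xyz = np.asarray(cells, dtype=float)
        ids = np.arange(len(xyz))
    n = len(xyz)
    if n < 4:
        raise ValueError("need at least 4 cells to build a neighborhood graph")
    k = min(k_neighbors, n - 1)

    diag = float(np.linalg.norm(xyz.max(axis=0) - xyz.min(axis=0))) or 1.0
    rng = np.random.default_rng(jitter_seed)
    jittered = xyz + rng.normal(0.0, 1e-6 * diag, size=xyz.shape)

    tree = cKDTree(jittered)
    _, nn = tree.query(jittered, k=k + 1)  # includes self at column 0

    edges: set[tuple[int, int]] = set()
    for i in range(n):
        local_idx = nn[i]
        pts = jittered[local_idx]
        centered = pts - pts.mean(axis=0)
        # top-2 right singular directions span the local tangent plane
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        flat = centered @ vt[:2].T
        try:
            tri = Delaunay(flat)
        except Exception:
            # rank-deficient local patch (collinear): chain consecutive points
            order = np.argsort(flat[:, 0])
            for a, b in zip(order[:-1], order[1:]):
                ia, ib = int(local_idx[a]), int(local_idx[b])
                if 0 in (a, b) and ia != ib:
                    edges.add((min(ia, ib), max(ia, ib)))
            continue
        indptr, indices = tri.vertex_neighbor_vertices
        for local_j in indices[indptr[0]:indptr[1]]:  # neighbors of focal (index 0)
            j = int(local_idx[local_j])
            if j != i:
                edges.add((min(i, j), max(i, j)))

    g = nx.Graph()
    for i in range(n):
        g.add_node(ids[i], pos=xyz[i])
    for a, b in sorted(edges):
        length = float(np.linalg.norm(xyz[a] - xyz[b]))
        if max_edge_um is not None and length > max_edge_um:
            continue
        if length <= 0:
            continue
        g.add_edge(ids[a], ids[b], length_um=length)
    return g


def _speeds(graph: nx.Graph, t_act: pd.Series, frame_period_ms: float, metric: bool):
    rows = []
    for node in graph.nodes:
        t_i = t_act.get(node, np.nan)
        nbrs = [j for j in graph.neighbors(node)]
        if len(nbrs) == 0:
            rows.append((node, np.nan, 0, True, True))
            continue
        if not np.isfinite(t_i):
            rows.append((node, np.nan, len(nbrs), False, True))
            continue
        total = 0.0
        tie = False
        valid = 0
        for j in nbrs:
            t_j = t_act.get(j, np.nan)
            if not np.isfinite(t_j):
                continue
            dt = abs(t_j - t_i)
            if dt < frame_period_ms:
                dt = frame_period_ms
                tie = True
            dt_s = dt / 1000.0
            if metric:
                total += dt_s / graph.edges[node, j]["length_um"]
            else:
                total += dt_s  # e(i, j) = 1 for direct neighbors
            valid += 1
        if valid == 0:
            rows.append((node, np.nan, len(nbrs), tie, True))
            continue
        rows.append((node, valid / total, valid, tie, False))
    cols = ["cell_id", "speed", "n_neighbors", "tie_clamped", "isolated_or_missing"]
    return pd.DataFrame(rows, columns=cols).set_index("cell_id")


def biological_speed(graph: nx.Graph, t_act: pd.Series,
                     frame_period_ms: float = 2.5) -> pd.DataFrame:
    """Per-cell biological conduction speed in cells (links) per second."""
    df = _speeds(graph, t_act, frame_period_ms, metric=False)
    return df.rename(columns={"speed": "cs_cells_s"})


def metric_speed(graph: nx.Graph, t_act: pd.Series,
                 frame_period_ms: float = 2.5) -> pd.DataFrame:
    """Per-cell metric (biophysical) conduction speed in um per second."""
    df = _speeds(graph, t_act, frame_period_ms, metric=True)
    return df.rename(columns={"speed": "cs_um_s"})


def shape_estimate(graph: nx.Graph, use_sqrt_axes: bool = False) -> pd.DataFrame:
    """Ellipsoidal cell shape/size from the neighbor distribution.

    Second moments of neighbor centroid offsets about the focal centroid
    give eigenvalues l1 >= l2 >= l3; FA and the ellipsoid volume
    (4/3) pi l1 l2 l3 follow.  ``use_sqrt_axes`` switches the volume to
    sqrt-eigenvalue semi-axes (standard-deviation ellipsoid).  Cells with
    fewer than 3 neighbors are flagged.
    """
    rows = []
    for node in graph.nodes:
        nbrs = list(graph.neighbors(node))
        if len(nbrs) < 3:
            rows.append((node, *[np.nan] * 5, True))
            continue
        p0 = graph.nodes[node]["pos"]
        offsets = np.array([graph.nodes[j]["pos"] for j in nbrs]) - p0
        cov = offsets.T @ offsets / len(nbrs)
        lam = np.sort(np.linalg.eigvalsh(cov))[::-1]
        lam = np.clip(lam, 0.0, None)
        lam_bar = lam.mean()
        denom = float(np.sqrt((lam ** 2).sum()))
        fa = 0.0 if denom == 0 else float(np.sqrt(1.5 * ((lam - lam_bar) ** 2).sum()) / denom)
        axes = np.sqrt(lam) if use_sqrt_axes else lam
        vol = float(4.0 / 3.0 * np.pi * axes[0] * axes[1] * axes[2])
        rows.append((node, lam[0], lam[1], lam[2], min(fa, 1.0), vol, False))
    cols = ["cell_id", "lambda1", "lambda2", "lambda3", "fa", "volume", "flagged"]
    return pd.DataFrame(rows, columns=cols).set_index("cell_id")


def identify_pacemakers(activation: pd.DataFrame, conduction: pd.DataFrame,
                        q: float = 0.05, use_speed_filter: bool = True) -> np.ndarray:
    """Pacemaker cells: earliest-activating (t_act below the q-quantile,
    linear-interpolation quantile) AND slow-conducting (speed below the
    population median).  Strict inequalities; flagged cells are excluded
    from both distributions.  Returns the selected cell ids.
    """
    speed_col = "cs_cells_s" if "cs_cells_s" in conduction.columns else "cs_um_s"
    df = activation.join(conduction, how="inner", lsuffix="", rsuffix="_cond")
    ok = np.isfinite(df["t_act_ms"]) & np.isfinite(df[speed_col])
    if "flagged" in df.columns:
        ok &= ~df["flagged"].astype(bool)
    df = df[ok]
    if len(df) < 20:
        raise ValueError("fewer than 20 valid cells; quantile rule is meaningless")
    thr_t = np.quantile(df["t_act_ms"], q)
    sel = df["t_act_ms"] < thr_t
    if use_speed_filter:
        sel &= df[speed_col] < df[speed_col].median()
    return df.index[sel].to_numpy()


def map_conduction_2d(conduction: pd.DataFrame, coords: pd.DataFrame,
                      iso_step: float = 50.0, grid_shape=(200, 120),
                      region_labels: pd.Series | None = None) -> dict:
    """Conduction speeds on the unrolled (tau, phi) rectangle with
    iso-velocity line levels every ``iso_step`` (cells/s by default).

    phi is treated circularly: the point cloud is replicated at phi +/- 2 pi
    before linear interpolation, so values are seam-continuous.  Returns a
    dict with the grid, the interpolated field, isoline levels/paths and a
    per-region / inner-outer curvature summary table.
    """
    speed_col = "cs_cells_s" if "cs_cells_s" in conduction.columns else "cs_um_s"
    df = conduction.join(coords, how="inner")
    df = df[np.isfinite(df[speed_col])]
    if len(df) < 3:
        raise ValueError("need at least 3 cells with finite speeds")

    tau = df["tau"].to_numpy()
    phi = df["phi"].to_numpy()
    val = df[speed_col].to_numpy()
    pts = np.concatenate([
        np.column_stack([tau, phi]),
        np.column_stack([tau, phi + 2 * np.pi]),
        np.column_stack([tau, phi - 2 * np.pi]),
    ])
    vals3 = np.concatenate([val, val, val])

    n_tau, n_phi = grid_shape
    g_tau = np.linspace(0.0, 1.0, n_tau)
    g_phi = np.linspace(-np.pi, np.pi, n_phi)
    gt, gp = np.meshgrid(g_tau, g_phi, indexing="ij")
    field = griddata(pts, vals3, (gt, gp), method="linear")

    lo = np.ceil(np.nanmin(field) / iso_step) * iso_step
    hi = np.nanmax(field)
    levels = np.arange(lo, hi + 0.5 * iso_step, iso_step) if np.isfinite(lo) else np.array([])

    isolines = []
    try:
        from skimage import measure
        # continue the field outside the convex hull with nearest values so
        # the hull boundary does not spawn spurious contours
        nearest = griddata(pts, vals3, (gt, gp), method="nearest")
        filled = np.where(np.isfinite(field), field, nearest)
        for lev in levels:
            for contour in measure.find_contours(filled, lev):
                c_tau = np.interp(contour[:, 0], np.arange(n_tau), g_tau)
                c_phi = np.interp(contour[:, 1], np.arange(n_phi), g_phi)
                isolines.append({"level": float(lev),
                                 "path": np.column_stack([c_tau, c_phi])})
    except ImportError:  # pragma: no cover
        pass

    summary = None
    side = np.where(df["inner"].to_numpy(), "inner", "outer") if "inner" in df.columns \
        else np.full(len(df), "all")
    sdf = pd.DataFrame({"speed": val, "side": side})
    if region_labels is not None:
        sdf["region"] = region_labels.reindex(df.index).to_numpy()
        summary = sdf.groupby(["region", "side"], observed=False)["speed"].median().unstack()
    else:
        summary = sdf.groupby("side")["speed"].median().to_frame().T

    return {
        "grid_tau": g_tau,
        "grid_phi": g_phi,
        "field": field,
        "iso_levels": levels,
        "isolines": isolines,
        "summary": summary,
    }
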