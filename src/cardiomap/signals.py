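"""Nucleus detection, per-cell reference volumes, and transient extraction.

Nuclei are detected in the static nuclear-marker channel with multi-scale
Laplacian-of-Gaussian blob detection in physical units.  Each cell's
reference volume is the set of voxels within ``radius_voxels`` of its
centroid (Euclidean distance in index space) that are closer to it than to
any other centroid, i.e. Voronoi-restricted balls; transients are the mean
intensity over that volume per time point, low-pass filtered at 5 Hz
(zero-phase, circular over the cardiac cycle) and min-max normalized to
[0, 1].
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.feature import blob_log

from .containers import MovieStack, TransientSet, new_cell_table

__all__ = [
    "detect_nuclei",
    "apply_curation",
    "build_cell_volumes",
    "extract_transients",
    "filter_and_normalize",
]


def detect_nuclei(
    nuclear_stack: np.ndarray,
    voxel_size_zyx_um,
    origin_um=(0.0, 0.0, 0.0),
    min_radius_um: float = 2.0,
    max_radius_um: float = 5.0,
    n_scales: int = 5,
    threshold_rel: float = 0.05,
    exclusion_radius_um: float = 2.0,
    overlap: float = 0.95,
) -> pd.DataFrame:
    """Grayscale blob detection of nuclei in a static 3D stack.

    The LoG scale range corresponds to nuclear radii of
    ``min_radius_um``..``max_radius_um`` (radius = sigma * sqrt(3) in 3D);
    anisotropic voxel sizes are handled by per-axis sigmas.  LoG overlap
    pruning is kept permissive (``overlap``); suppression of doubled
    detections is instead handled by ``exclusion_radius_um``, keeping the
    brighter of two detections closer than that radius (epithelia are
    dense, so scale-space overlap alone over-merges).  Returns a cell
    table sorted deterministically by (z, y, x).
    """
    vol = np.asarray(nuclear_stack, dtype=float)
    if vol.ndim != 3:
        raise ValueError("nuclear stack must be 3D (z, y, x)")
    voxel = np.asarray(voxel_size_zyx_um, dtype=float)
    vmin, vmax = float(vol.min()), float(vol.max())
    if vmax - vmin < 1e-12:
        warnings.warn("nuclear stack has no contrast; returning empty cell table")
        return new_cell_table(np.empty((0, 3)), voxel, origin_um)
    norm = (vol - vmin) / (vmax - vmin)

    sig_lo = (min_radius_um / np.sqrt(3.0)) / voxel
    sig_hi = (max_radius_um / np.sqrt(3.0)) / voxel
    blobs = blob_log(
        norm,
        min_sigma=sig_lo,
        max_sigma=sig_hi,
        num_sigma=n_scales,
        threshold=None,
        threshold_rel=threshold_rel,
        overlap=overlap,
    )
    if len(blobs) == 0:
        warnings.warn("no nuclei detected")
        return new_cell_table(np.empty((0, 3)), voxel, origin_um)

    zyx_vox = blobs[:, :3]
    zyx_um = zyx_vox * voxel[None, :]
    # brightness proxy for exclusion-radius suppression
    idx = np.clip(np.round(zyx_vox).astype(int), 0, np.array(vol.shape) - 1)
    brightness = vol[idx[:, 0], idx[:, 1], idx[:, 2]]

    order = np.argsort(-brightness)
    kept: list[int] = []
    kept_pos = np.empty((0, 3))
    for i in order:
        p = zyx_um[i]
        if len(kept) and np.min(np.linalg.norm(kept_pos - p, axis=1)) < exclusion_radius_um:
            continue
        kept.append(i)
        kept_pos = np.vstack([kept_pos, p])
    kept = np.asarray(kept)

    zyx_um = zyx_um[kept]
    # deterministic order: (z, y, x)
    order = np.lexsort((zyx_um[:, 2], zyx_um[:, 1], zyx_um[:, 0]))
    zyx_um = zyx_um[order]
    x0, y0, z0 = origin_um
    xyz_um = np.column_stack([zyx_um[:, 2] + x0, zyx_um[:, 1] + y0, zyx_um[:, 0] + z0])
    return new_cell_table(xyz_um, voxel, origin_um)


def apply_curation(table: pd.DataFrame, edits: pd.DataFrame,
                   match_radius_um: float = 3.0) -> pd.DataFrame:
    """Apply file-based curation edits (add/delete) to a cell table.

    ``edits`` has columns ``action`` ("add" | "delete") and
    ``x_um, y_um, z_um``.  A delete removes the nearest detection within
    ``match_radius_um`` and raises if none is found.
    """
    out = table.copy()
    bad = []
    for k, edit in edits.iterrows():
        p = np.array([edit["x_um"], edit["y_um"], edit["z_um"]], dtype=float)
        if edit["action"] == "add":
            new_id = int(out["cell_id"].max()) + 1 if len(out) else 0
            row = {"cell_id": new_id, "x_um": p[0], "y_um": p[1], "z_um": p[2],
                   "status": "added"}
            for c in ("x_vox", "y_vox", "z_vox"):
                if c in out.columns:
                    row[c] = np.nan
            out = pd.concat([out, pd.DataFrame([row])], ignore_index=True)
        elif edit["action"] == "delete":
            if len(out) == 0:
                bad.append(k)
                continue
            d = np.linalg.norm(out[["x_um", "y_um", "z_um"]].to_numpy() - p, axis=1)
            j = int(np.argmin(d))
            if d[j] > match_radius_um:
                bad.append(k)
            else:
                out = out.drop(out.index[j]).reset_index(drop=True)
        else:
            raise ValueError(f"unknown curation action {edit['action']!r} in row {k}")
    if bad:
        raise ValueError(
            f"deletion edits {bad} have no detection within {match_radius_um} um"
        )
    return out.reset_index(drop=True)


def build_cell_volumes(table: pd.DataFrame, volume_shape, radius_voxels: int = 5) -> np.ndarray:
    """Label volume of per-cell reference regions.

    A voxel belongs to cell i iff i has the nearest centroid (Euclidean in
    index space) and the distance is at most ``radius_voxels``; the regions
    are disjoint Voronoi-restricted balls.  Labels are ``cell_id + 1``;
    0 is background.
    """
    if radius_voxels <= 0:
        raise ValueError("radius_voxels must be positive")
    shape = tuple(int(s) for s in volume_shape)
    seeds = np.zeros(shape, dtype=np.int32)
    zyx = np.round(table[["z_vox", "y_vox", "x_vox"]].to_numpy(dtype=float)).astype(int)
    zyx = np.clip(zyx, 0, np.array(shape) - 1)
    for cid, (z, y, x) in zip(table["cell_id"].to_numpy(), zyx):
        seeds[z, y, x] = int(cid) + 1
    dist, (iz, iy, ix) = ndimage.distance_transform_edt(seeds == 0, return_indices=True)
    labels = seeds[iz, iy, ix]
    labels[dist > radius_voxels] = 0
    return labels


def extract_transients(volumes: np.ndarray, labels: np.ndarray,
                       frame_period_ms: float, n_cells: int | None = None) -> TransientSet:
    """Raw per-cell transients: mean intensity over each reference volume.

    ``volumes`` is the synchronized (time, z, y, x) series; ``labels`` the
    output of :func:`build_cell_volumes`.  Cells with zero labeled voxels
    yield NaN series and are flagged.  ``n_cells`` fixes the number of
    expected cells (default: the largest label present).
    """
    if volumes.shape[1:] != labels.shape:
        raise ValueError("label volume shape does not match the 3D frames")
    flat_labels = labels.ravel()
    if n_cells is None:
        n_cells = int(flat_labels.max())
    n_labels = n_cells + 1
    counts = np.bincount(flat_labels, minlength=n_labels)[:n_labels]

    T = volumes.shape[0]
    present = np.arange(1, n_labels)
    data = np.empty((len(present), T))
    for t in range(T):
        sums = np.bincount(flat_labels, weights=volumes[t].ravel().astype(np.float64),
                           minlength=n_labels)[:n_labels]
        with np.errstate(invalid="ignore", divide="ignore"):
            means = sums[1:] / counts[1:]
        data[:, t] = means
    flagged = counts[1:] == 0
    if np.any(flagged):
        warnings.warn(f"{int(flagged.sum())} cell(s) have zero labeled voxels")
    return TransientSet(
        data=data,
        frame_period_ms=frame_period_ms,
        cell_ids=present - 1,
        state="raw",
        flagged=flagged,
    )


def _butterworth_gain_sq(freqs_hz: np.ndarray, cutoff_hz: float, order: int) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth magnitude response."""
    return 1.0 / (1.0 + (freqs_hz / cutoff_hz) ** (2 * order))


def filter_and_normalize(ts: TransientSet, cutoff_hz: float = 5.0,
                         order: int = 4) -> TransientSet:
    """Low-pass filter (5 Hz default) and min-max normalize each transient.

    The filter is the zero-phase circular equivalent of a forward-backward
    4th-order Butterworth: the cycle is treated as periodic and each
    harmonic is scaled by the squared Butterworth magnitude, so activation
    timing (the pipeline's core readout) is not shifted.  Constant series
    are set to zero and flagged.
    """
    fs = 1000.0 / ts.frame_period_ms
    freqs = np.fft.rfftfreq(ts.n_frames, 1.0 / fs)
    gain = _butterworth_gain_sq(freqs, cutoff_hz, order)

    data = np.array(ts.data, dtype=float)
    flagged = np.array(ts.flagged, dtype=bool)
    ok = ~np.any(~np.isfinite(data), axis=1)
    out = np.zeros_like(data)

    spectra = np.fft.rfft(data[ok], axis=1) * gain[None, :]
    filt = np.fft.irfft(spectra, ts.n_frames, axis=1)
    lo = filt.min(axis=1, keepdims=True)
    hi = filt.max(axis=1, keepdims=True)
    span = (hi - lo).ravel()
    constant = span < 1e-12 * np.maximum(1.0, np.abs(hi).ravel())
    norm = np.where(constant[:, None], 0.0, (filt - lo) / np.where(span[:, None] == 0, 1.0, hi - lo))
    out[ok] = norm

    new_flagged = flagged.copy()
    new_flagged[~ok] = True
    ok_idx = np.flatnonzero(ok)
    new_flagged[ok_idx[constant]] = True
    return TransientSet(
        data=out,
        frame_period_ms=ts.frame_period_ms,
        cell_ids=ts.cell_ids,
        state="normalized",
        flagged=new_flagged,
    )
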