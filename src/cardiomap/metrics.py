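"""Per-cell calcium-transient metrics: activation time, rise time, alignment.

Activation time (t_act) is the time point at which the normalized transient
reaches 10% of its amplitude on the upstroke; rise time is the interval
between the interpolated 10% and 90% upward crossings of the same
upstroke.  The cardiac cycle has no absolute zero, so each transient is
unwrapped at its global minimum (the diastolic baseline) before crossings
are searched, and the per-cell times are reported on the common cycle
clock and re-zeroed fleet-wide to the earliest-activated cell.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .containers import TransientSet

__all__ = [
    "activation_time",
    "compute_activation_map",
    "rise_time",
    "align_transients",
    "rise_time_vs_midline",
]


def _first_upward_crossing(x: np.ndarray, threshold: float, start: int = 0):
    """Index (float, linear sub-frame interpolation) of the first upward
    crossing of ``threshold`` at or after ``start``; None if absent."""
    for k in range(start, len(x) - 1):
        if x[k] <= threshold < x[k + 1]:
            return k + (threshold - x[k]) / (x[k + 1] - x[k])
    return None


def _cell_crossings(x: np.ndarray, thresholds=(0.1, 0.9)):
    """Crossing positions (frames, on the common cycle clock) after unwrapping
    at the global minimum.  Returns a dict threshold -> absolute frame."""
    i_min = int(np.argmin(x))
    rot = np.roll(x, -i_min)
    out = {}
    start = 0
    for th in thresholds:
        c = _first_upward_crossing(rot, th, start=start)
        if c is None:
            out[th] = None
            continue
        out[th] = (i_min + c) % len(x)
        start = int(np.floor(c))
    return out


def activation_time(transient: np.ndarray, frame_period_ms: float,
                    threshold: float = 0.10):
    """10%-amplitude activation time of one normalized transient, in ms on
    the cycle clock (no fleet re-zeroing); NaN if degenerate."""
    x = np.asarray(transient, dtype=float)
    if not np.all(np.isfinite(x)) or x.max() - x.min() < 1e-12:
        return np.nan
    c = _cell_crossings(x, (threshold,))[threshold]
    return np.nan if c is None else float(c * frame_period_ms)


def rise_time(transient: np.ndarray, frame_period_ms: float,
              lo: float = 0.10, hi: float = 0.90):
    """10-90% rise time of one normalized transient in ms; NaN when the 90%
    level is never reached after the 10% crossing within the cycle."""
    x = np.asarray(transient, dtype=float)
    if not np.all(np.isfinite(x)) or x.max() - x.min() < 1e-12:
        return np.nan
    i_min = int(np.argmin(x))
    rot = np.roll(x, -i_min)
    c_lo = _first_upward_crossing(rot, lo)
    if c_lo is None:
        return np.nan
    c_hi = _first_upward_crossing(rot, hi, start=int(np.floor(c_lo)))
    if c_hi is None:
        return np.nan
    return float((c_hi - c_lo) * frame_period_ms)


def _circular_zero(times_ms: np.ndarray, cycle_ms: float) -> float:
    """Fleet-wide zero: the cycle phase just after the largest circular gap
    in the activation-time distribution (robust to cycles whose arbitrary
    start frame bisects the activation sequence)."""
    finite = np.sort(times_ms[np.isfinite(times_ms)])
    if len(finite) == 0:
        return 0.0
    gaps = np.diff(np.concatenate([finite, [finite[0] + cycle_ms]]))
    k = int(np.argmax(gaps))
    return float(finite[(k + 1) % len(finite)])


def compute_activation_map(ts: TransientSet, threshold: float = 0.10) -> pd.DataFrame:
    """Activation map for a whole TransientSet.

    Columns: ``t_act_ms`` (re-zeroed to the earliest cell, ties resolved by
    cell id through the stable ordering), ``rise_ms``, ``peak_frame``,
    ``flagged``.  Flagged/degenerate transients get NaN metrics.
    """
    F, dt = ts.n_frames, ts.frame_period_ms
    cycle = ts.cycle_ms
    raw_t = np.full(ts.n_cells, np.nan)
    rises = np.full(ts.n_cells, np.nan)
    peaks = np.zeros(ts.n_cells, dtype=int)
    flagged = np.array(ts.flagged, dtype=bool)

    for i in range(ts.n_cells):
        x = ts.data[i]
        if flagged[i] or not np.all(np.isfinite(x)) or x.max() - x.min() < 1e-12:
            flagged[i] = True
            continue
        peaks[i] = int(np.argmax(x))
        raw_t[i] = activation_time(x, dt, threshold)
        rises[i] = rise_time(x, dt)

    zero = _circular_zero(raw_t, cycle)
    t_act = np.where(np.isfinite(raw_t), (raw_t - zero) % cycle, np.nan)
    return pd.DataFrame({
        "cell_id": ts.cell_ids,
        "t_act_ms": t_act,
        "rise_ms": rises,
        "peak_frame": peaks,
        "flagged": flagged,
    }).set_index("cell_id")


def align_transients(ts: TransientSet, band: float = 0.05, sustain: int = 2):
    """Circularly shift each transient so its onset maps to t = 0.

    The onset is the first run of ``sustain`` consecutive frames above a
    baseline band (``band`` of amplitude above the minimum) - the point of
    first sustained deviation from minimal fluorescence, which is distinct
    from (earlier than) the 10% activation threshold.

    Returns ``(aligned_matrix, onset_frames, excluded_ids)``.
    """
    F = ts.n_frames
    aligned = np.zeros_like(ts.data)
    onsets = np.full(ts.n_cells, -1, dtype=int)
    excluded = []
    for i in range(ts.n_cells):
        x = ts.data[i]
        if ts.flagged[i] or not np.all(np.isfinite(x)) or x.max() - x.min() < 1e-12:
            excluded.append(ts.cell_ids[i])
            continue
        i_min = int(np.argmin(x))
        rot = np.roll(x, -i_min)
        above = rot > band
        onset_rot = None
        for k in range(F - sustain + 1):
            if np.all(above[k:k + sustain]):
                onset_rot = k
                break
        if onset_rot is None:
            excluded.append(ts.cell_ids[i])
            continue
        onset = (i_min + onset_rot) % F
        onsets[i] = onset
        aligned[i] = np.roll(x, -onset)
    return aligned, onsets, excluded


def rise_time_vs_midline(activation: pd.DataFrame, coords: pd.DataFrame,
                         region_labels: pd.Series | None = None,
                         avc_boundary_tau: float | None = None,
                         window: float = 0.08) -> dict:
    """Spearman correlation of rise time with midline position, plus
    per-region medians and a change-point score at the AVC boundary.

    The change-point score is the jump of the median rise time across the
    boundary, in units of the overall median absolute deviation.
    """
    df = activation.join(coords, how="inner")
    df = df[np.isfinite(df["rise_ms"])]
    if len(df) < 10:
        raise ValueError("need at least 10 cells with valid rise times")
    rho, pval = spearmanr(df["tau"], df["rise_ms"])

    out = {"spearman_rho": float(rho), "p_value": float(pval)}
    if region_labels is not None:
        med = df.join(region_labels.rename("region"), how="inner") \
                .groupby("region", observed=False)["rise_ms"].median()
        out["region_medians_ms"] = med.to_dict()
    if avc_boundary_tau is not None:
        before = df[(df["tau"] >= avc_boundary_tau - window) & (df["tau"] < avc_boundary_tau)]
        after = df[(df["tau"] >= avc_boundary_tau) & (df["tau"] < avc_boundary_tau + window)]
        mad = float(np.median(np.abs(df["rise_ms"] - df["rise_ms"].median()))) or 1.0
        if len(before) and len(after):
            out["avc_changepoint_score"] = float(
                (after["rise_ms"].median() - before["rise_ms"].median()) / mad
            )
        else:
            out["avc_changepoint_score"] = np.nan
    return out
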