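"""Static figures: transient rasters and unrolled conduction maps."""

from __future__ import annotations

import numpy as np

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt


def plot_transient_raster(aligned: np.ndarray, t_act_ms: np.ndarray,
                          frame_period_ms: float, path=None):
    """All transients overlaid, colored by activation time."""
    fig, ax = plt.subplots(figsize=(6, 4))
    finite = np.isfinite(t_act_ms)
    order = np.argsort(t_act_ms[finite])
    cmap = plt.get_cmap("viridis")
    span = np.ptp(t_act_ms[finite]) or 1.0
    t = np.arange(aligned.shape[1]) * frame_period_ms
    for i in np.flatnonzero(finite)[order]:
        ax.plot(t, aligned[i], lw=0.4,
                color=cmap((t_act_ms[i] - np.nanmin(t_act_ms)) / span))
    ax.set_xlabel("time (ms)")
    ax.set_ylabel("normalized fluorescence")
    sm = plt.cm.ScalarMappable(cmap=cmap,
                               norm=plt.Normalize(np.nanmin(t_act_ms), np.nanmax(t_act_ms)))
    fig.colorbar(sm, ax=ax, label="activation time (ms)")
    if path:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig


def plot_map2d(m2d: dict, path=None, cmap="turbo"):
    """Unrolled (tau, phi) conduction-speed field with iso-velocity lines."""
    fig, ax = plt.subplots(figsize=(7, 4))
    pm = ax.pcolormesh(m2d["grid_tau"], m2d["grid_phi"], m2d["field"].T,
                       shading="auto", cmap=cmap)
    for iso in m2d["isolines"]:
        ax.plot(iso["path"][:, 0], iso["path"][:, 1], "k-", lw=0.6)
    ax.set_xlabel(r"midline position $\tau$")
    ax.set_ylabel(r"angle $\phi$ (rad)")
    ax.set_ylim(-np.pi, np.pi)
    fig.colorbar(pm, ax=ax, label="conduction speed")
    if path:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig
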