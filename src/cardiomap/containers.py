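"""Shared in-memory containers for the pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class MovieStack:
    """A z-indexed set of single-plane 2D movies.

    ``movies`` has shape (n_planes, n_frames, height, width); all planes
    share the frame count, frame period and image shape.  ``origin_um`` is
    the physical position of voxel (0, 0, 0) so centroids in micrometres
    and voxel indices stay interconvertible.
    """

    movies: np.ndarray
    frame_period_ms: float
    pixel_size_xy_um: float
    z_step_um: float
    origin_um: tuple[float, float, float] = (0.0, 0.0, 0.0)  # (x0, y0, z0)
    z_indices: np.ndarray | None = None

    def __post_init__(self):
        m = np.asarray(self.movies)
        if m.ndim != 4:
            raise ValueError("movies must have shape (planes, frames, height, width)")
        if np.issubdtype(m.dtype, np.floating) and np.any(m < 0):
            raise ValueError("intensities must be non-negative")
        self.movies = m
        if self.z_indices is None:
            self.z_indices = np.arange(m.shape[0])

    @property
    def n_planes(self) -> int:
        return self.movies.shape[0]

    @property
    def n_frames(self) -> int:
        return self.movies.shape[1]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.movies.shape[2], self.movies.shape[3]


@dataclass
class TransientSet:
    """Per-cell fluorescence time series over one cardiac cycle.

    ``data`` is (n_cells, n_frames).  ``state`` tracks processing:
    raw -> filtered -> normalized.  Normalized series span exactly [0, 1]
    per cell; constant (degenerate) series are set to zero and flagged.
    """

    data: np.ndarray
    frame_period_ms: float
    cell_ids: np.ndarray
    state: str = "raw"
    flagged: np.ndarray | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be (n_cells, n_frames)")
        self.cell_ids = np.asarray(self.cell_ids)
        if len(self.cell_ids) != self.data.shape[0]:
            raise ValueError("cell_ids length must match data rows")
        if self.flagged is None:
            self.flagged = np.zeros(self.data.shape[0], dtype=bool)

    @property
    def n_cells(self) -> int:
        return self.data.shape[0]

    @property
    def n_frames(self) -> int:
        return self.data.shape[1]

    @property
    def cycle_ms(self) -> float:
        return self.n_frames * self.frame_period_ms

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, index=pd.Index(self.cell_ids, name="cell_id"))


def new_cell_table(xyz_um: np.ndarray, voxel_size_zyx_um, origin_um=(0.0, 0.0, 0.0),
                   status: str = "auto") -> pd.DataFrame:
    """Build a cell table from centroids in micrometres.

    Columns: cell_id, x_um, y_um, z_um, x_vox, y_vox, z_vox, status.
    Voxel indices are 0-based; physical coordinates are micrometres.
    """
    xyz_um = np.asarray(xyz_um, dtype=float).reshape(-1, 3)
    dz, dy, dx = voxel_size_zyx_um
    x0, y0, z0 = origin_um
    df = pd.DataFrame({
        "cell_id": np.arange(len(xyz_um)),
        "x_um": xyz_um[:, 0],
        "y_um": xyz_um[:, 1],
        "z_um": xyz_um[:, 2],
        "x_vox": (xyz_um[:, 0] - x0) / dx,
        "y_vox": (xyz_um[:, 1] - y0) / dy,
        "z_vox": (xyz_um[:, 2] - z0) / dz,
        "status": status,
    })
    return df
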