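"""On-disk formats: TIFF movie stacks, CSV tables with unit sidecars, configs.

Conventions (also written to every sidecar): voxel indices are 0-based;
physical coordinates are micrometres; tau is dimensionless in [0, 1];
angles are radians in [-pi, pi]; times are milliseconds.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .containers import MovieStack
from .synthetic import GroundTruth, SyntheticHeartConfig

__all__ = [
    "PipelineConfig",
    "write_movie_stack",
    "read_movie_stack",
    "write_volumes",
    "read_volumes",
    "write_table",
    "read_table",
    "write_synthetic_dataset",
    "config_hash",
]

MANIFEST_NAME = "stack_manifest.json"


def write_table(df: pd.DataFrame, path, units: dict | None = None):
    """CSV with header plus a sidecar JSON declaring column units."""
    path = Path(path)
    df.to_csv(path, index=False)
    sidecar = {
        "columns": list(df.columns),
        "units": units or {},
        "conventions": {
            "voxel_indices": "0-based",
            "coordinates": "micrometres",
            "tau": "dimensionless [0,1]",
            "phi": "radians [-pi, pi]",
            "time": "milliseconds",
        },
    }
    path.with_suffix(path.suffix + ".units.json").write_text(json.dumps(sidecar, indent=2))
    return path


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_movie_stack(stack: MovieStack, outdir) -> Path:
    """One multi-page TIFF per z-plane (`calcium_z####.tif`) plus a manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    planes = []
    for z in range(stack.n_planes):
        name = f"calcium_z{z:04d}.tif"
        tifffile.imwrite(outdir / name, stack.movies[z])
        planes.append({"file": name, "z_index": int(stack.z_indices[z])})
    manifest = {
        "planes": planes,
        "frame_period_ms": stack.frame_period_ms,
        "pixel_size_xy_um": stack.pixel_size_xy_um,
        "z_step_um": stack.z_step_um,
        "origin_um": list(stack.origin_um),
    }
    (outdir / MANIFEST_NAME).write_text(json.dumps(manifest, indent=2))
    return outdir


def read_movie_stack(path) -> MovieStack:
    """Read a movie stack from a manifest JSON or a directory containing one.

    Planes are sorted by their declared z index; inconsistent frame counts
    or image shapes raise with the offending planes listed; missing
    metadata is an explicit error, never a silent default.
    """
    path = Path(path)
    manifest_path = path if path.is_file() else path / MANIFEST_NAME
    if not manifest_path.exists():
        raise FileNotFoundError(f"no stack manifest found at {manifest_path}")
    manifest = json.loads(manifest_path.read_text())
    for key in ("planes", "frame_period_ms", "pixel_size_xy_um", "z_step_um"):
        if key not in manifest:
            raise ValueError(f"stack manifest is missing required metadata {key!r}")

    root = manifest_path.parent
    planes = sorted(manifest["planes"], key=lambda p: p["z_index"])
    movies, shapes = [], []
    for p in planes:
        arr = tifffile.imread(root / p["file"])
        if arr.ndim == 2:
            arr = arr[None]
        movies.append(arr)
        shapes.append(arr.shape)
    frames = {s[0] for s in shapes}
    if len(frames) > 1:
        offenders = [p["file"] for p, s in zip(planes, shapes)
                     if s[0] != max(frames)]
        raise ValueError(f"inconsistent frame counts across planes; offenders: {offenders}")
    if len({s[1:] for s in shapes}) > 1:
        raise ValueError("inconsistent image shapes across planes")

    return MovieStack(
        movies=np.stack(movies),
        frame_period_ms=float(manifest["frame_period_ms"]),
        pixel_size_xy_um=float(manifest["pixel_size_xy_um"]),
        z_step_um=float(manifest["z_step_um"]),
        origin_um=tuple(manifest.get("origin_um", (0.0, 0.0, 0.0))),
        z_indices=np.array([p["z_index"] for p in planes]),
    )


def write_volumes(volumes: np.ndarray, outdir, meta: dict) -> Path:
    """Synchronized cycle as one multi-page TIFF per time point."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for t in range(volumes.shape[0]):
        tifffile.imwrite(outdir / f"vol_t{t:04d}.tif", volumes[t])
    (outdir / "volumes_meta.json").write_text(json.dumps(
        {**meta, "n_timepoints": int(volumes.shape[0])}, indent=2))
    return outdir


def read_volumes(indir) -> tuple[np.ndarray, dict]:
    indir = Path(indir)
    meta = json.loads((indir / "volumes_meta.json").read_text())
    files = sorted(indir.glob("vol_t*.tif"))
    vols = np.stack([tifffile.imread(f) for f in files])
    return vols, meta


def write_nuclear(nuclear: np.ndarray, path):
    tifffile.imwrite(Path(path), nuclear)


def write_synthetic_dataset(dataset, outdir) -> Path:
    """Write the rendered channels, ground truth and config echo to disk."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_movie_stack(dataset.stack, outdir)
    tifffile.imwrite(outdir / "nuclear.tif", dataset.nuclear)
    truth: GroundTruth = dataset.truth
    write_table(truth.cells.reset_index(), outdir / "truth_cells.csv", units={
        "x_um": "um", "y_um": "um", "z_um": "um", "t_act_ms": "ms",
        "rise_ms": "ms", "speed_cells_s": "cells/s",
    })
    info = truth.to_json_dict()
    info["config"] = dataset.config.to_dict()
    info["config"]["noise_model"] = dataclasses.asdict(dataset.config.noise_model)
    (outdir / "truth.json").write_text(json.dumps(info, indent=2))
    np.savetxt(outdir / "midline_samples.csv",
               truth.midline_samples[::16], delimiter=",",
               header="x_um,y_um,z_um", comments="")
    return outdir


# ---------------------------------------------------------------------------
# pipeline configuration

_STAGES = ("synth", "sync", "detect", "extract", "metrics", "geometry", "network")


@dataclass
class PipelineConfig:
    """Bundled stage parameters; round-trips losslessly through JSON."""

    input_dir: str = ""
    output_dir: str = ""
    seed: int = 0
    synthetic: dict | None = None          # SyntheticHeartConfig dict, optional
    corr_floor: float = 0.5
    sync_downsample: int = 2
    detect_min_radius_um: float = 1.5
    detect_max_radius_um: float = 3.5
    detect_threshold_rel: float = 0.05
    exclusion_radius_um: float = 2.0
    cell_radius_voxels: int = 5
    lowpass_cutoff_hz: float = 5.0
    activation_threshold: float = 0.10
    k_neighbors: int = 10
    max_edge_um: float | None = None
    pacemaker_quantile: float = 0.05
    iso_step: float = 50.0
    midline_control_points: list | None = None   # user-supplied trace, inflow first
    curation_file: str | None = None

    def validate(self):
        if not (0 < self.corr_floor < 1):
            raise ValueError("corr_floor must be in (0, 1)")
        if self.cell_radius_voxels <= 0:
            raise ValueError("cell_radius_voxels must be positive")
        if self.lowpass_cutoff_hz <= 0:
            raise ValueError("lowpass_cutoff_hz must be positive")
        if not (0 < self.pacemaker_quantile < 1):
            raise ValueError("pacemaker_quantile must be in (0, 1)")
        if not (0 < self.activation_threshold < 1):
            raise ValueError("activation_threshold must be in (0, 1)")
        if self.k_neighbors < 3:
            raise ValueError("k_neighbors must be at least 3")
        return self

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        return cls(**json.loads(text)).validate()

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        return cls.from_json(Path(path).read_text())

    def synthetic_config(self) -> SyntheticHeartConfig | None:
        if self.synthetic is None:
            return None
        d = dict(self.synthetic)
        d.setdefault("rng_seed", self.seed)
        return SyntheticHeartConfig.from_dict(d)


def config_hash(config: PipelineConfig) -> str:
    """Hash of the scientific parameters (I/O paths excluded)."""
    d = dataclasses.asdict(config)
    d.pop("input_dir", None)
    d.pop("output_dir", None)
    return hashlib.sha256(json.dumps(d, sort_keys=True).encode()).hexdigest()[:16]
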