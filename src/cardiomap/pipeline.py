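"""End-to-end pipeline orchestration.

Runs synth (optional) -> sync -> detect -> extract -> metrics -> geometry
-> network on a dataset directory, writing each stage's artifacts plus a
provenance manifest (config hash, seed, package version, per-file SHA-256).
All randomness flows from the single config seed, so two runs with the
same config produce bit-identical outputs.  Stage timings go to a separate
run log so the determinism of scientific outputs is not polluted.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .io import (PipelineConfig, config_hash, read_movie_stack, read_table,
                 write_movie_stack, write_synthetic_dataset, write_table,
                 write_volumes, read_volumes)
from .containers import new_cell_table
from .geometry import assign_coordinates, fit_midline, frenet_frame, unroll
from .metrics import align_transients, compute_activation_map, rise_time_vs_midline
from .network import (biological_speed, build_graph, identify_pacemakers,
                      map_conduction_2d, metric_speed, shape_estimate)
from .signals import (build_cell_volumes, detect_nuclei, extract_transients,
                      filter_and_normalize, apply_curation)
from .sync import synchronize_stack
from .synthetic import SyntheticHeartConfig, generate

__all__ = ["run_pipeline", "PipelineError"]

ALL_STAGES = ("synth", "sync", "detect", "extract", "metrics", "geometry", "network")


class PipelineError(RuntimeError):
    """A stage failure, tagged with the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, stages=None) -> dict:
    """Execute the pipeline; returns the output manifest dict."""
    config.validate()
    stages = tuple(stages) if stages is not None else ALL_STAGES
    for s in stages:
        if s not in ALL_STAGES:
            raise ValueError(f"unknown stage {s!r}")
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings = {}
    artifacts: list[str] = []

    def _stage(name):
        return name in stages

    data_dir = Path(config.input_dir) if config.input_dir else out / "dataset"

    try:
        if _stage("synth") and config.synthetic is not None:
            t0 = time.perf_counter()
            ds = generate(config.synthetic_config())
            data_dir = out / "dataset"
            write_synthetic_dataset(ds, data_dir)
            artifacts += [str(p.relative_to(out)) for p in sorted(data_dir.rglob("*")) if p.is_file()]
            timings["synth"] = time.perf_counter() - t0
    except PipelineError:
        raise
    except Exception as e:
        raise PipelineError("synth", str(e)) from e

    sync_dir = out / "synced"
    try:
        if _stage("sync"):
            t0 = time.perf_counter()
            stack = read_movie_stack(data_dir)
            volumes, res = synchronize_stack(
                stack, corr_floor=config.corr_floor, seed=config.seed,
                downsample=config.sync_downsample)
            write_volumes(volumes, sync_dir, meta={
                "frame_period_ms": stack.frame_period_ms,
                "pixel_size_xy_um": stack.pixel_size_xy_um,
                "z_step_um": stack.z_step_um,
                "origin_um": list(stack.origin_um),
            })
            (sync_dir / "sync_result.json").write_text(json.dumps({
                "start_frames": res.start_frames.tolist(),
                "correlations": res.correlations.tolist(),
                "cycle_length": res.cycle_length,
                "reference_plane": res.reference_plane,
                "reference_start": res.reference_start,
                "flagged_planes": res.flagged_planes.tolist(),
            }, indent=2))
            artifacts += [str(p.relative_to(out)) for p in sorted(sync_dir.rglob("*")) if p.is_file()]
            timings["sync"] = time.perf_counter() - t0
    except PipelineError:
        raise
    except Exception as e:
        raise PipelineError("sync", str(e)) from e

    cells_csv = out / "cells.csv"
    try:
        if _stage("detect"):
            t0 = time.perf_counter()
            nuclear = tifffile.imread(data_dir / "nuclear.tif")
            manifest = json.loads((data_dir / "stack_manifest.json").read_text())
            voxel = (manifest["z_step_um"], manifest["pixel_size_xy_um"],
                     manifest["pixel_size_xy_um"])
            origin = tuple(manifest.get("origin_um", (0.0, 0.0, 0.0)))
            table = detect_nuclei(
                nuclear, voxel, origin_um=origin,
                min_radius_um=config.detect_min_radius_um,
                max_radius_um=config.detect_max_radius_um,
                threshold_rel=config.detect_threshold_rel,
                exclusion_radius_um=config.exclusion_radius_um,
            )
            if config.curation_file:
                edits = read_table(config.curation_file)
                table = apply_curation(table, edits)
            write_table(table, cells_csv, units={"x_um": "um", "y_um": "um", "z_um": "um",
                                                 "x_vox": "voxel", "y_vox": "voxel",
                                                 "z_vox": "voxel"})
            artifacts += ["cells.csv", "cells.csv.units.json"]
            timings["detect"] = time.perf_counter() - t0
    except PipelineError:
        raise
    except Exception as e:
        raise PipelineError("detect", str(e)) from e

    transients_csv = out / "transients.csv"
    try:
        if _stage("extract"):
            t0 = time.perf_counter()
            volumes, meta = read_volumes(sync_dir)
            table = read_table(cells_csv)
            labels = build_cell_volumes(table, volumes.shape[1:],
                                        radius_voxels=config.cell_radius_voxels)
            raw = extract_transients(volumes, labels, meta["frame_period_ms"],
                                     n_cells=len(table))
            norm = filter_and_normalize(raw, cutoff_hz=config.lowpass_cutoff_hz)
            df = norm.to_frame().reset_index()
            df.insert(1, "flagged", norm.flagged)
            write_table(df, transients_csv, units={"values": "normalized [0,1]"})
            (out / "transients_meta.json").write_text(json.dumps({
                "frame_period_ms": norm.frame_period_ms,
                "n_frames": norm.n_frames, "state": norm.state}, indent=2))
            artifacts += ["transients.csv", "transients.csv.units.json",
                          "transients_meta.json"]
            timings["extract"] = time.perf_counter() - t0
    except PipelineError:
        raise
    except Exception as e:
        raise PipelineError("extract", str(e)) from e

    metrics_csv = out / "activation.csv"
    try:
        if _stage("metrics"):
            t0 = time.perf_counter()
            ts = _load_transients(out)
            amap = compute_activation_map(ts, threshold=config.activation_threshold)
            write_table(amap.reset_index(), metrics_csv,
                        units={"t_act_ms": "ms", "rise_ms": "ms"})
            artifacts += ["activation.csv", "activation.csv.units.json"]
            timings["metrics"] = time.perf_counter() - t0
    except PipelineError:
        raise
    except Exception as e:
        raise PipelineError("metrics", str(e)) from e

    coords_csv = out / "coords.csv"
    try:
        if _stage("geometry"):
            t0 = time.perf_counter()
            cp = _midline_control_points(config, data_dir)
            mf = frenet_frame(fit_midline(cp))
            table = read_table(cells_csv)
            coords = assign_coordinates(table, mf)
            coords.insert(0, "cell_id", table["cell_id"].to_numpy())
            write_table(coords, coords_csv, units={"tau": "[0,1]", "phi": "rad",
                                                   "z_um": "um"})
            artifacts += ["coords.csv", "coords.csv.units.json"]
            timings["geometry"] = time.perf_counter() - t0
    except PipelineError:
        raise
    except Exception as e:
        raise PipelineError("geometry", str(e)) from e

    try:
        if _stage("network"):
            t0 = time.perf_counter()
            table = read_table(cells_csv)
            amap = read_table(metrics_csv).set_index("cell_id")
            meta = json.loads((out / "transients_meta.json").read_text())
            graph = build_graph(table.set_index("cell_id"),
                                k_neighbors=config.k_neighbors,
                                max_edge_um=config.max_edge_um,
                                jitter_seed=config.seed)
            bio = biological_speed(graph, amap["t_act_ms"],
                                   frame_period_ms=meta["frame_period_ms"])
            met = metric_speed(graph, amap["t_act_ms"],
                               frame_period_ms=meta["frame_period_ms"])
            shape = shape_estimate(graph)
            cond = bio.join(met["cs_um_s"]).join(shape[["fa", "volume"]])
            write_table(cond.reset_index(), out / "conduction.csv",
                        units={"cs_cells_s": "cells/s", "cs_um_s": "um/s",
                               "volume": "um^3 (eigenvalue ellipsoid)"})
            edges = pd.DataFrame(
                [(a, b, d["length_um"]) for a, b, d in graph.edges(data=True)],
                columns=["src", "dst", "length_um"])
            write_table(edges, out / "graph_edges.csv", units={"length_um": "um"})
            pm = identify_pacemakers(amap, bio, q=config.pacemaker_quantile)
            (out / "pacemakers.json").write_text(json.dumps(
                {"pacemaker_cell_ids": [int(i) for i in pm]}, indent=2))
            if coords_csv.exists():
                coords = read_table(coords_csv).set_index("cell_id")
                m2d = map_conduction_2d(bio, coords, iso_step=config.iso_step)
                np.savetxt(out / "map2d_field.csv", m2d["field"], delimiter=",")
                artifacts.append("map2d_field.csv")
            artifacts += ["conduction.csv", "conduction.csv.units.json",
                          "graph_edges.csv", "graph_edges.csv.units.json",
                          "pacemakers.json"]
            timings["network"] = time.perf_counter() - t0
    except PipelineError:
        raise
    except Exception as e:
        raise PipelineError("network", str(e)) from e

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config_sha256": config_hash(config),
        "stages": list(stages),
        "artifacts": sorted(set(artifacts)),
        "hashes": {a: _sha256(out / a) for a in sorted(set(artifacts))
                   if (out / a).is_file()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    (out / "run_log.json").write_text(json.dumps(
        {"timings_s": timings}, indent=2))
    return manifest


def _load_transients(out: Path):
    from .containers import TransientSet
    meta = json.loads((out / "transients_meta.json").read_text())
    df = read_table(out / "transients.csv")
    flagged = df["flagged"].to_numpy(dtype=bool)
    cell_ids = df["cell_id"].to_numpy()
    data = df.drop(columns=["cell_id", "flagged"]).to_numpy(dtype=float)
    return TransientSet(data=data, frame_period_ms=meta["frame_period_ms"],
                        cell_ids=cell_ids, state="normalized", flagged=flagged)


def _midline_control_points(config: PipelineConfig, data_dir: Path) -> np.ndarray:
    if config.midline_control_points is not None:
        return np.asarray(config.midline_control_points, dtype=float)
    truth_json = data_dir / "truth.json"
    if truth_json.exists():
        info = json.loads(truth_json.read_text())
        cp = info.get("config", {}).get("midline_control_points")
        if cp is not None:
            return np.asarray(cp, dtype=float)
    raise ValueError("no midline control points: supply midline_control_points "
                     "in the pipeline config or a dataset truth.json")
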