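"""Shared fixtures: scaled-down synthetic hearts and truth-matching helpers."""

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

from cardiomap.synthetic import SyntheticHeartConfig, NoiseModel, generate


def make_small_config(seed=0, **kw):
    """A ~200-cell heart small enough for second-scale rendering."""
    u = np.linspace(0, 1, 9)
    cp = np.column_stack([
        55 * u,
        20 + 10 * np.sin(2 * np.pi * u),
        14 + 4 * u + 2 * np.sin(2 * np.pi * u + np.pi / 2),
    ])
    d = dict(
        midline_control_points=cp,
        radius_knots=((0, 4.5), (0.1, 7), (0.22, 9.5), (0.38, 9), (0.5, 5),
                      (0.6, 7), (0.75, 10), (0.88, 7.5), (1, 5)),
        n_cells=200,
        cycle_period_ms=300.0,
        region_rise_times={"sinus": 60.0, "atrium": 70.0, "avc": 90.0,
                           "ventricle": 110.0, "outflow": 115.0},
        rng_seed=seed,
    )
    d.update(kw)
    return SyntheticHeartConfig(**d)


def make_tiny_config(seed=0, **kw):
    """A ~60-cell heart for fast pipeline/determinism tests."""
    u = np.linspace(0, 1, 7)
    cp = np.column_stack([
        38 * u,
        12 + 6 * np.sin(2 * np.pi * u),
        10 + 3 * u,
    ])
    d = dict(
        midline_control_points=cp,
        radius_knots=((0, 3.5), (0.25, 6.0), (0.5, 4.0), (0.75, 6.5), (1, 4.0)),
        n_cells=60,
        cycle_period_ms=150.0,
        region_rise_times={"sinus": 30.0, "atrium": 35.0, "avc": 45.0,
                           "ventricle": 55.0, "outflow": 60.0},
        rng_seed=seed,
    )
    d.update(kw)
    return SyntheticHeartConfig(**d)


def match_to_truth(truth_cells, table, radius_um=3.0):
    """Hungarian assignment of detections to ground-truth centroids.

    Returns (truth_idx, detected_idx) for pairs within ``radius_um``.
    """
    txyz = truth_cells[["x_um", "y_um", "z_um"]].to_numpy()
    dxyz = table[["x_um", "y_um", "z_um"]].to_numpy()
    D = cdist(txyz, dxyz)
    ri, ci = linear_sum_assignment(D)
    ok = D[ri, ci] < radius_um
    return ri[ok], ci[ok]


@pytest.fixture(scope="session")
def small_config():
    return make_small_config(seed=1)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate(small_config)


@pytest.fixture(scope="session")
def noiseless_config():
    return make_small_config(
        seed=3, n_cells=150,
        noise_model=NoiseModel(gaussian_sigma=0.0, poisson=False),
    )


@pytest.fixture(scope="session")
def noiseless_dataset(noiseless_config):
    return generate(noiseless_config)


@pytest.fixture(scope="session")
def small_sync(small_dataset):
    from cardiomap.sync import synchronize_stack
    volumes, result = synchronize_stack(small_dataset.stack, seed=7)
    return volumes, result


@pytest.fixture(scope="session")
def small_cells(small_dataset):
    from cardiomap.signals import detect_nuclei
    cfg = small_dataset.config
    return detect_nuclei(
        small_dataset.nuclear,
        (cfg.z_step_um, cfg.pixel_size_xy_um, cfg.pixel_size_xy_um),
        origin_um=small_dataset.stack.origin_um,
        min_radius_um=1.5, max_radius_um=3.5,
    )


@pytest.fixture(scope="session")
def small_transients(small_dataset, small_sync, small_cells):
    from cardiomap.signals import (build_cell_volumes, extract_transients,
                                   filter_and_normalize)
    volumes, _ = small_sync
    labels = build_cell_volumes(small_cells, volumes.shape[1:])
    raw = extract_transients(volumes, labels,
                             small_dataset.config.frame_period_ms,
                             n_cells=len(small_cells))
    return filter_and_normalize(raw)
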