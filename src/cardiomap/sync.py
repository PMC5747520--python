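"""Post-acquisition synchronization of a z-stack of per-plane movies.

Each plane of the heart is recorded as an independent high-speed movie, so
planes start at arbitrary cardiac phases.  Synchronization picks one full
cardiac cycle in the middle plane (start frame drawn by a seeded RNG) and
iterates outward toward the first and last plane, matching every plane
against its already-synchronized neighbor by scanning all candidate start
frames and maximizing the Pearson correlation of the two cycle-long frame
blocks (flattened over frames and pixels).  The chained reference tolerates
the gradual appearance change with depth; the presence of both chambers in
most planes keeps the matching well conditioned.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .containers import MovieStack

__all__ = ["SyncResult", "estimate_cycle_length", "match_cycle", "synchronize_stack"]


@dataclass
class SyncResult:
    """Per-plane chosen cycle start frames and match quality."""

    start_frames: np.ndarray          # (n_planes,) chosen cycle start per plane
    correlations: np.ndarray          # (n_planes,) best Pearson r (1.0 at reference)
    cycle_length: int                 # frames
    reference_plane: int
    reference_start: int
    flagged_planes: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    def __post_init__(self):
        if self.cycle_length < 2:
            raise ValueError("cycle length must be at least 2 frames")


def estimate_cycle_length(movie: np.ndarray, min_lag: int = 2,
                          significance: float = 0.2) -> int:
    """Cardiac cycle length in frames from one plane's movie.

    The first dominant peak (beyond lag 0) of the temporal autocorrelation
    of the frame-mean intensity trace gives a candidate period, which is
    then refined to the integer lag maximizing the full-frame lag
    correlation in a +/-2 frame window (the frame mean alone can be off by
    one frame in noise).  The movie must span at least two cycles.
    """
    movie = np.asarray(movie)
    trace = movie.reshape(movie.shape[0], -1).mean(axis=1).astype(float)
    t = len(trace)
    x = trace - trace.mean()
    var = float(x @ x) / t
    if var < 1e-12 * max(1.0, trace.mean() ** 2):
        raise ValueError("no periodicity detected: frame-mean trace is constant")
    # normalize by overlap count (mildly unbiased estimate)
    ac_full = np.correlate(x, x, mode="full")[t - 1:]
    counts = t - np.arange(t)
    ac = ac_full / counts / var
    search = ac[min_lag:]
    peaks, _ = find_peaks(search, height=significance, prominence=0.05)
    if len(peaks) == 0:
        raise ValueError("no periodicity detected: autocorrelation has no significant peak")
    p0 = int(peaks[0] + min_lag)

    # refine on full frames (spatially downsampled) around the candidate lag
    flat = movie[:, ::2, ::2].reshape(t, -1).astype(np.float64)
    flat -= flat.mean()
    best_p, best_r = p0, -np.inf
    for p in range(max(min_lag, p0 - 2), min(t - 1, p0 + 2) + 1):
        a = flat[: t - p].ravel()
        b = flat[p:].ravel()
        am, bm = a - a.mean(), b - b.mean()
        denom = np.sqrt((am @ am) * (bm @ bm))
        r = float(am @ bm / denom) if denom > 0 else 0.0
        if r > best_r:
            best_p, best_r = p, r
    return best_p


def _window_stats(movie2d: np.ndarray, L: int):
    """Sliding sums and sums of squares of L-frame windows, flattened over pixels."""
    per_frame = movie2d.sum(axis=1, dtype=np.float64)
    per_frame_sq = (movie2d ** 2).sum(axis=1, dtype=np.float64)
    c1 = np.concatenate([[0.0], np.cumsum(per_frame)])
    c2 = np.concatenate([[0.0], np.cumsum(per_frame_sq)])
    sy = c1[L:] - c1[:-L]
    syy = c2[L:] - c2[:-L]
    return sy, syy


def match_cycle(reference_cycle: np.ndarray, target_movie: np.ndarray,
                downsample: int = 1):
    """Best-matching cycle start in ``target_movie`` for ``reference_cycle``.

    Scans every candidate start frame, computing the Pearson correlation
    between the reference block and the candidate block flattened over
    (frame, pixel).  Ties break toward the smallest start frame;
    zero-variance candidate blocks score 0.

    Returns ``(best_start, best_correlation)``.
    """
    ref = np.asarray(reference_cycle)
    tgt = np.asarray(target_movie)
    if ref.ndim != 3 or tgt.ndim != 3:
        raise ValueError("expected (frames, height, width) arrays")
    L, T = ref.shape[0], tgt.shape[0]
    if L > T:
        raise ValueError("reference block is longer than the target movie")
    if downsample > 1:
        ref = ref[:, ::downsample, ::downsample]
        tgt = tgt[:, ::downsample, ::downsample]

    # pre-center by the target's global mean (Pearson is shift invariant);
    # float64 keeps the matched-pair correlation exact to ~1e-12
    center = float(np.asarray(tgt, dtype=np.float64).mean())
    r2 = ref.reshape(L, -1).astype(np.float64) - center
    t2 = tgt.reshape(T, -1).astype(np.float64) - center
    npx = r2.shape[1]
    n = float(L * npx)

    sx = float(r2.sum())
    sxx = float((r2 ** 2).sum())
    vx = sxx - sx * sx / n

    cross_ft = r2 @ t2.T                       # (L, T) frame-by-frame dot products
    n_cand = T - L + 1
    cross = np.zeros(n_cand)
    for f in range(L):                          # sum of the f-th shifted diagonal
        cross += cross_ft[f, f:f + n_cand]

    sy, syy = _window_stats(t2, L)
    vy = syy - sy * sy / n
    cov = cross - sx * sy / n

    denom = np.sqrt(np.clip(vx, 0, None) * np.clip(vy, 0, None))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, cov / denom, 0.0)
    # ties (within float tolerance) break toward the smallest start frame
    best = int(np.flatnonzero(r >= r.max() - 1e-9)[0])
    return best, float(r[best])


def synchronize_stack(stack: MovieStack, corr_floor: float = 0.5, seed: int = 0,
                      downsample: int = 2):
    """Synchronize all planes into a single 3D+time cardiac cycle.

    Returns ``(volumes, result)`` where ``volumes`` has shape
    (cycle_frames, n_planes, height, width) and ``result`` is a
    :class:`SyncResult`.  Planes whose best correlation falls below
    ``corr_floor`` are flagged and reported with a warning.
    """
    Z, T = stack.n_planes, stack.n_frames
    if Z < 3:
        raise ValueError("need at least 3 planes to synchronize")
    mid = Z // 2
    L = estimate_cycle_length(stack.movies[mid])
    if T < 2 * L:
        raise ValueError("each plane must span at least two cardiac cycles")

    rng = np.random.default_rng(seed)
    s_mid = int(rng.integers(0, T - L + 1))

    starts = np.zeros(Z, dtype=int)
    corrs = np.zeros(Z)
    starts[mid], corrs[mid] = s_mid, 1.0

    # two independent passes outward from the middle plane, chained reference
    for sequence in (range(mid + 1, Z), range(mid - 1, -1, -1)):
        for z in sequence:
            prev = z - 1 if z > mid else z + 1
            ref_block = stack.movies[prev, starts[prev]:starts[prev] + L]
            starts[z], corrs[z] = match_cycle(ref_block, stack.movies[z],
                                              downsample=downsample)

    flagged = np.flatnonzero(corrs < corr_floor)
    if len(flagged):
        warnings.warn(
            f"{len(flagged)} plane(s) below correlation floor {corr_floor}: "
            f"{flagged.tolist()}"
        )

    volumes = np.empty((L, Z) + stack.frame_shape, dtype=stack.movies.dtype)
    for z in range(Z):
        volumes[:, z] = stack.movies[z, starts[z]:starts[z] + L]

    result = SyncResult(
        start_frames=starts,
        correlations=corrs,
        cycle_length=L,
        reference_plane=mid,
        reference_start=s_mid,
        flagged_planes=flagged,
    )
    return volumes, result
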