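"""Post-inference diffusion analysis and track-comparison metrics.

Converts posterior MSD samples to diffusion-coefficient estimates with
credible intervals (``D = MSD / (2 dt)`` per axis), computes jump-distance
distributions with their theoretical Rayleigh prediction for free 2D
diffusion, aligns tracks by centre of mass for direct comparison, matches
inferred tracks to ground truth, and segments piezo-protocol tracks into
dwells for step-size recovery.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import median_filter
from scipy.optimize import linear_sum_assignment

__all__ = [
    "DiffusionEstimate",
    "msd_to_d",
    "jump_distances",
    "rayleigh_prediction",
    "align_and_compare",
    "match_tracks",
    "segment_dwells",
]

#: nm²/s per μm²/s
_NM2_PER_UM2 = 1.0e6


@dataclass(frozen=True)
class DiffusionEstimate:
    """Posterior summary of the diffusion coefficient, in μm²/s."""

    mean: float
    low: float
    high: float
    level: float
    frame_interval: float

    def __post_init__(self) -> None:
        if not (self.low <= self.mean <= self.high):
            raise ValueError("expected low <= mean <= high")
        if self.low < 0:
            raise ValueError("diffusion coefficient cannot be negative")


def msd_to_d(
    msd_samples, frame_interval: float, dims: int = 2, level: float = 0.95
) -> DiffusionEstimate:
    """Diffusion-coefficient estimate from posterior MSD samples.

    ``msd_samples`` are per-axis displacement variances per frame interval
    (nm²); each converts elementwise as ``D = MSD / (2 dt)``, reported in
    μm²/s with empirical mean and quantile bounds at ``level``.  ``dims`` is
    accepted for interface symmetry; the per-axis convention makes the
    conversion dimension-independent.
    """
    if frame_interval <= 0:
        raise ValueError("frame_interval must be positive")
    samples = np.asarray(msd_samples, dtype=float)
    if samples.size == 0:
        raise ValueError("no MSD samples given")
    if np.any(samples < 0):
        raise ValueError("MSD samples must be non-negative")
    d = samples / (2.0 * frame_interval) / _NM2_PER_UM2
    lo_q, hi_q = 0.5 - level / 2.0, 0.5 + level / 2.0
    return DiffusionEstimate(
        mean=float(d.mean()),
        low=float(np.quantile(d, lo_q)),
        high=float(np.quantile(d, hi_q)),
        level=level,
        frame_interval=frame_interval,
    )


def jump_distances(track: np.ndarray) -> np.ndarray:
    """Euclidean displacement magnitudes between consecutive frames, in nm.

    ``track`` has shape ``(N, 2)`` with ``N >= 2``; returns ``N - 1`` values.
    """
    track = np.asarray(track, dtype=float)
    if track.ndim != 2 or track.shape[1] != 2:
        raise ValueError("track must have shape (N, 2)")
    if track.shape[0] < 2:
        raise ValueError("need at least two frames")
    return np.linalg.norm(np.diff(track, axis=0), axis=1)


def rayleigh_prediction(
    d: float, frame_interval: float, r: np.ndarray, dims: int = 2
) -> np.ndarray:
    """Jump-distance density for free 2D diffusion — a prediction, not a fit.

    For per-axis displacement variance ``2 D dt`` the jump distance is
    Rayleigh distributed:

        p(r) = r / (2 D dt) * exp(-r² / (4 D dt)),

    with ``d`` in μm²/s, ``frame_interval`` in s, and ``r`` in nm; returns the
    density per nm.  ``d`` is taken as given (e.g. a posterior mean) and never
    fitted to the jump histogram.  Only the 2D form is implemented; 3D motion
    needs the Maxwell–Boltzmann analogue and raises.
    """
    if dims != 2:
        raise NotImplementedError("Rayleigh jump-distance prediction is 2D only")
    if d <= 0 or frame_interval <= 0:
        raise ValueError("d and frame_interval must be positive")
    r = np.asarray(r, dtype=float)
    two_d_dt = 2.0 * d * _NM2_PER_UM2 * frame_interval  # nm²
    return r / two_d_dt * np.exp(-(r**2) / (2.0 * two_d_dt))


def align_and_compare(tracks) -> dict:
    """Centre-of-mass alignment and pairwise distance statistics.

    Each track ``(N, 2)`` is translated so its centre of mass is at the
    origin; per-frame Euclidean distances are reported for every pair.
    Returns ``aligned`` (list of arrays), ``pair_distances`` of shape
    ``(n_pairs, N)``, ``pairs`` (index tuples), and scalar ``max`` / ``mean``.
    """
    arrays = [np.asarray(t, dtype=float) for t in tracks]
    if not arrays:
        raise ValueError("need at least one track")
    n = arrays[0].shape[0]
    for t in arrays:
        if t.ndim != 2 or t.shape[1] != 2:
            raise ValueError("tracks must have shape (N, 2)")
        if t.shape[0] != n:
            raise ValueError("all tracks must have equal length")
    aligned = [t - t.mean(axis=0) for t in arrays]
    pairs = [
        (i, j) for i in range(len(aligned)) for j in range(i + 1, len(aligned))
    ]
    if pairs:
        dist = np.stack(
            [np.linalg.norm(aligned[i] - aligned[j], axis=1) for i, j in pairs]
        )
        dist_max, dist_mean = float(dist.max()), float(dist.mean())
    else:
        dist = np.zeros((0, n))
        dist_max = dist_mean = 0.0
    return {
        "aligned": aligned,
        "pairs": pairs,
        "pair_distances": dist,
        "max": dist_max,
        "mean": dist_mean,
    }


def match_tracks(inferred: np.ndarray, truth: np.ndarray) -> dict:
    """Match inferred tracks to ground truth by minimum mean distance.

    Both arguments have shape ``(M, N, 2)``.  Uses the Hungarian assignment
    on the matrix of mean per-frame distances and reports the per-frame
    distances for the matched pairs.
    """
    inferred = np.asarray(inferred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if inferred.shape != truth.shape:
        raise ValueError("inferred and truth must have identical shapes")
    cost = np.linalg.norm(
        inferred[:, None, :, :] - truth[None, :, :, :], axis=-1
    ).mean(axis=-1)
    rows, cols = linear_sum_assignment(cost)
    per_frame = np.linalg.norm(inferred[rows] - truth[cols], axis=-1)
    return {
        "assignment": list(zip(rows.tolist(), cols.tolist())),
        "per_frame_distance": per_frame,
        "max": float(per_frame.max()),
        "mean": float(per_frame.mean()),
    }


def segment_dwells(
    track: np.ndarray,
    min_dwell: int,
    jump_threshold: float,
    smooth_window: int | None = None,
) -> dict:
    """Change-point segmentation of a stepping (piezo-protocol) track.

    Median-filters the track (window ``smooth_window``, default
    ``min_dwell // 4 | 1``), measures the displacement magnitude across a
    ``min_dwell // 2``-frame window at every frame, and takes local maxima
    above ``jump_threshold`` (nm) separated by at least ``min_dwell`` frames
    as change points.  Dwell positions are means over the central half of
    each segment, keeping clear of the transition ramps.

    Returns ``change_points``, ``dwell_positions`` of shape ``(n_dwell, 2)``,
    and ``step_magnitudes`` between consecutive dwells.
    """
    track = np.asarray(track, dtype=float)
    if track.ndim != 2 or track.shape[1] != 2:
        raise ValueError("track must have shape (N, 2)")
    n = track.shape[0]
    if min_dwell < 2 or n < 2 * min_dwell:
        raise ValueError("track too short for the requested minimum dwell")
    if smooth_window is None:
        smooth_window = max(3, (min_dwell // 4) | 1)
    smooth = np.column_stack(
        [median_filter(track[:, k], size=smooth_window, mode="nearest") for k in (0, 1)]
    )
    half = max(1, min_dwell // 2)
    jump = np.zeros(n)
    idx = np.arange(half, n - half)
    jump[idx] = np.linalg.norm(smooth[idx + half - 1] - smooth[idx - half], axis=1)
    candidates = np.nonzero(jump > jump_threshold)[0]
    change_points: list[int] = []
    for c in candidates[np.argsort(jump[candidates])[::-1]]:
        if all(abs(c - prev) >= min_dwell for prev in change_points):
            change_points.append(int(c))
    change_points.sort()
    bounds = [0] + change_points + [n]
    dwell_positions = []
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        span = hi - lo
        core = slice(lo + span // 4, hi - span // 4)
        dwell_positions.append(track[core].mean(axis=0))
    dwell_positions = np.asarray(dwell_positions)
    steps = (
        np.linalg.norm(np.diff(dwell_positions, axis=0), axis=1)
        if len(dwell_positions) > 1
        else np.zeros(0)
    )
    return {
        "change_points": change_points,
        "dwell_positions": dwell_positions,
        "step_magnitudes": steps,
    }
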