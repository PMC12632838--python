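"""Observation model for single-photon-detector frame stacks.

A single-photon pixel reports, per exposure, only whether at least one photon
(signal or dark count) was registered.  With ``u_np`` the expected number of
photons at pixel ``p`` during frame ``n``,

    w_np ~ Bernoulli(1 - exp(-u_np)),

and the expected count decomposes as

    u_np = DC_p + h * sum_m f_nm * (PSF mass of emitter m inside pixel p),

where ``DC_p`` is the per-pixel dark-count expectation per exposure, ``h`` the
emitter brightness (expected photons per exposure), and ``f_nm`` a fixed 0/1
photophysical (bright/dark) state.  Defective pixels carry a boolean usable
flag ``F_p`` and contribute exactly zero to the likelihood.

Frames produced by summing ``k`` consecutive binary exposures are handled by
the exact consequence of the same generative model: each summed count is
Binomial(k, 1 - exp(-u)) with ``u`` per constituent binary exposure.

The full log-likelihood factorizes over frames and pixels, which is what makes
chunked/parallel evaluation exact (see :func:`chunked_log_likelihood`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .psf import PixelGrid, PsfModel, _axis_fractions

__all__ = [
    "Calibration",
    "FrameStack",
    "TrackSet",
    "expected_photons",
    "log_likelihood",
    "binned_log_likelihood",
    "chunked_log_likelihood",
    "estimate_dark_counts",
    "log1mexp",
    "post_frame_emission_probability",
]

#: detection-rate at or above which a pixel is declared hot and masked out
HOT_PIXEL_RATE = 1.0 - 1e-6


def log1mexp(u: np.ndarray) -> np.ndarray:
    """Stable ``log(1 - exp(-u))`` for ``u >= 0``.

    Branches at ``u = ln 2``: ``log(-expm1(-u))`` below (accurate for the
    dark-count regime ``u ~ 1e-3``), ``log1p(-exp(-u))`` above.  ``u = 0``
    yields ``-inf``.
    """
    u = np.asarray(u, dtype=float)
    with np.errstate(divide="ignore"):
        small = np.log(-np.expm1(-np.minimum(u, np.log(2.0))))
        large = np.log1p(-np.exp(-np.maximum(u, np.log(2.0))))
    return np.where(u < np.log(2.0), small, large)


def post_frame_emission_probability(
    lifetime: float, exposure: float, excitation_fraction: float = 0.5
) -> float:
    """Probability that a fluorophore excited during one exposure emits after it.

    With an exponential excited-state lifetime ``tau`` and excitation at
    ``excitation_fraction`` of the way through an exposure of length ``T``
    (both in seconds), the photon falls outside the frame with probability
    ``exp(-(1 - excitation_fraction) * T / tau)``.  For microsecond exposures
    and nanosecond lifetimes this is negligible, which is what justifies
    treating frames as independent in the likelihood.
    """
    if lifetime <= 0 or exposure <= 0:
        raise ValueError("lifetime and exposure must be positive")
    if not 0.0 <= excitation_fraction <= 1.0:
        raise ValueError("excitation_fraction must lie in [0, 1]")
    return float(np.exp(-(1.0 - excitation_fraction) * exposure / lifetime))


@dataclass(frozen=True)
class Calibration:
    """Per-pixel detector calibration plus optical parameters.

    Attributes
    ----------
    dc
        Expected dark counts per binary exposure, shape ``(n_rows, n_cols)``.
        Hot pixels are represented by large entries.
    mask
        Boolean usable flag per pixel (``False`` = defective, excluded from
        the likelihood).
    h
        Emitter brightness: expected photons per binary exposure delivered by
        one in-focus bright emitter (its PSF mass sums to 1 over the plane).
    psf
        PSF model used to spread emitter photons over pixels.
    """

    dc: np.ndarray
    mask: np.ndarray
    h: float
    psf: PsfModel

    def __post_init__(self) -> None:
        dc = np.asarray(self.dc, dtype=float)
        mask = np.asarray(self.mask, dtype=bool)
        if dc.ndim != 2 or mask.shape != dc.shape:
            raise ValueError("dc and mask must be 2D arrays of identical shape")
        if np.any(dc < 0) or not np.all(np.isfinite(dc)):
            raise ValueError("dark counts must be finite and non-negative")
        if not np.isfinite(self.h) or self.h <= 0:
            raise ValueError("brightness h must be positive")
        object.__setattr__(self, "dc", dc)
        object.__setattr__(self, "mask", mask)

    @property
    def shape(self) -> tuple[int, int]:
        return self.dc.shape


@dataclass(frozen=True)
class FrameStack:
    """Stack of photon-count frames from a single-photon detector.

    Attributes
    ----------
    counts
        ``(N, n_rows, n_cols)`` non-negative integers, each at most
        ``bin_count``.
    bin_count
        Number of binary exposures summed into each stored frame (1 = raw
        binary data).
    exposure
        Duration of one constituent binary exposure, seconds.  The effective
        exposure of a stored frame is ``bin_count * exposure``.
    frame_interval
        Time between consecutive stored frames, seconds.  Equals
        ``bin_count * exposure`` unless frames were subsampled
        (stroboscopic subsetting lengthens the interval at fixed exposure).
    grid
        Pixel geometry.
    """

    counts: np.ndarray
    exposure: float
    grid: PixelGrid
    bin_count: int = 1
    frame_interval: float | None = None

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 3:
            raise ValueError("counts must have shape (N, n_rows, n_cols)")
        if counts.shape[1:] != self.grid.shape:
            raise ValueError(
                f"counts shape {counts.shape[1:]} does not match grid {self.grid.shape}"
            )
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.array_equal(counts, counts.astype(np.int64)):
                raise ValueError("counts must be integers")
            counts = counts.astype(np.int64)
        if self.bin_count < 1:
            raise ValueError("bin_count must be >= 1")
        if counts.min(initial=0) < 0 or counts.max(initial=0) > self.bin_count:
            raise ValueError("counts must lie in [0, bin_count]")
        if self.exposure <= 0:
            raise ValueError("exposure must be positive")
        object.__setattr__(self, "counts", counts)
        if self.frame_interval is None:
            object.__setattr__(self, "frame_interval", self.bin_count * self.exposure)
        elif self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")

    @property
    def n_frames(self) -> int:
        return self.counts.shape[0]

    @property
    def effective_exposure(self) -> float:
        """Total photon-collection time per stored frame, seconds."""
        return self.bin_count * self.exposure


@dataclass(frozen=True)
class TrackSet:
    """M particle trajectories over N frames with photophysical states.

    ``positions`` has shape ``(M, N, 2)`` in nm (x, y); ``states`` is the
    ``(M, N)`` 0/1 bright-state indicator (default: all bright).
    """

    positions: np.ndarray
    states: np.ndarray | None = None

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 3 or pos.shape[2] != 2:
            raise ValueError("positions must have shape (M, N, 2)")
        if not np.all(np.isfinite(pos)):
            raise ValueError("positions must be finite")
        states = self.states
        if states is None:
            states = np.ones(pos.shape[:2], dtype=np.uint8)
        else:
            states = np.asarray(states)
            if states.shape != pos.shape[:2]:
                raise ValueError("states must have shape (M, N)")
            if not np.isin(states, (0, 1)).all():
                raise ValueError("states must be 0/1")
            states = states.astype(np.uint8)
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "states", states)

    @property
    def n_particles(self) -> int:
        return self.positions.shape[0]

    @property
    def n_frames(self) -> int:
        return self.positions.shape[1]

    @classmethod
    def empty(cls, n_frames: int) -> "TrackSet":
        return cls(np.zeros((0, n_frames, 2)), np.zeros((0, n_frames), dtype=np.uint8))


def expected_photons(
    tracks: TrackSet, cal: Calibration, grid: PixelGrid
) -> np.ndarray:
    """Expected photons per pixel per binary exposure, shape ``(N, rows, cols)``.

    ``u_np = DC_p + h * sum_m f_nm * (PSF mass of particle m in pixel p)``.
    The PSF integral is separable, so each particle contributes an outer
    product of 1D CDF differences per frame.
    """
    if cal.shape != grid.shape:
        raise ValueError("calibration and grid shapes differ")
    n = tracks.n_frames
    u = np.broadcast_to(cal.dc, (n,) + grid.shape).copy()
    sigma = cal.psf.sigma
    for m in range(tracks.n_particles):
        f = tracks.states[m].astype(float)
        if not f.any():
            continue
        fx = _axis_fractions(grid.x_edges, tracks.positions[m, :, 0], sigma)
        fy = _axis_fractions(grid.y_edges, tracks.positions[m, :, 1], sigma)
        u += cal.h * f[:, None, None] * fy[:, :, None] * fx[:, None, :]
    return u


def _check_shapes(stack: FrameStack, u: np.ndarray, cal: Calibration) -> None:
    if u.shape != stack.counts.shape:
        raise ValueError(f"u shape {u.shape} != counts shape {stack.counts.shape}")
    if cal.shape != stack.grid.shape:
        raise ValueError("calibration shape does not match stack grid")


def log_likelihood(stack: FrameStack, u: np.ndarray, cal: Calibration) -> float:
    """Bernoulli log-likelihood of a binary stack given the expected field.

    Returns ``sum_np F_p * log Bernoulli(w_np; 1 - exp(-u_np))``.  Pixels with
    ``F_p = 0`` contribute exactly 0.  An observed detection where ``u = 0``
    yields ``-inf`` (an impossible configuration, returned rather than raised
    so samplers can reject uniformly).
    """
    if stack.bin_count != 1:
        raise ValueError("log_likelihood requires binary data (bin_count == 1)")
    return binned_log_likelihood(stack, u, cal)


def binned_log_likelihood(stack: FrameStack, u: np.ndarray, cal: Calibration) -> float:
    """Binomial log-likelihood for frames formed by summing binary exposures.

    ``sum_np F_p * log Binomial(w_np; k, 1 - exp(-u_np))`` with ``u`` the
    expectation per constituent binary exposure.  Reduces exactly to
    :func:`log_likelihood` at ``k = 1``.
    """
    u = np.asarray(u, dtype=float)
    _check_shapes(stack, u, cal)
    if np.any(u < 0):
        raise ValueError("expected photon field must be non-negative")
    k = stack.bin_count
    w = stack.counts
    mask = cal.mask
    wm = w[:, mask]
    um = u[:, mask]
    # log pmf = log C(k, w) + w*log(1-e^-u) + (k-w)*(-u)
    #         = log C(k, w) - k*u + w*(u + log(1-e^-u))
    total = -k * um.sum()
    fired = wm > 0
    if np.any(fired):
        wf = wm[fired].astype(float)
        uf = um[fired]
        with np.errstate(invalid="ignore"):
            g = uf + log1mexp(uf)  # == log(e^u - 1); -inf when u == 0
        total += float(np.sum(wf * g))
    if k > 1:
        total += float(
            np.sum(gammaln(k + 1) - gammaln(wm + 1.0) - gammaln(k - wm + 1.0))
        )
    return total


def chunked_log_likelihood(
    stack: FrameStack,
    tracks: TrackSet,
    cal: Calibration,
    grid: PixelGrid,
    chunks: list[tuple[np.ndarray, np.ndarray]] | None = None,
) -> float:
    """Log-likelihood evaluated as a sum over an arbitrary (frame, pixel) partition.

    ``chunks`` is a list of ``(frame_indices, flat_pixel_indices)`` rectangles
    whose cartesian products must tile the full (frame, pixel) index set
    exactly once.  Each chunk term is a pure function of its inputs; the sum
    equals the unchunked value up to floating-point summation order.  With
    ``chunks=None`` a single whole-stack chunk is used.
    """
    n, (rows, cols) = stack.n_frames, grid.shape
    npix = rows * cols
    if chunks is None:
        chunks = [(np.arange(n), np.arange(npix))]
    cover = np.zeros((n, npix), dtype=np.int32)
    for frames, pixels in chunks:
        frames = np.asarray(frames, dtype=np.intp)
        pixels = np.asarray(pixels, dtype=np.intp)
        cover[np.ix_(frames, pixels)] += 1
    if not np.all(cover == 1):
        raise ValueError("chunks must partition the (frame, pixel) index set exactly")

    k = stack.bin_count
    total = 0.0
    flat_counts = stack.counts.reshape(n, npix)
    flat_mask = cal.mask.reshape(npix)
    for frames, pixels in chunks:
        frames = np.asarray(frames, dtype=np.intp)
        pixels = np.asarray(pixels, dtype=np.intp)
        sub = TrackSet(tracks.positions[:, frames], tracks.states[:, frames])
        u = expected_photons(sub, cal, grid).reshape(len(frames), npix)[:, pixels]
        w = flat_counts[np.ix_(frames, pixels)]
        msk = flat_mask[pixels]
        um, wm = u[:, msk], w[:, msk]
        term = -k * um.sum()
        fired = wm > 0
        if np.any(fired):
            with np.errstate(invalid="ignore"):
                g = um[fired] + log1mexp(um[fired])
            term += float(np.sum(wm[fired] * g))
        if k > 1:
            term += float(
                np.sum(gammaln(k + 1) - gammaln(wm + 1.0) - gammaln(k - wm + 1.0))
            )
        total += term
    return float(total)


def estimate_dark_counts(
    dark_stack: FrameStack,
    hot_threshold: float = HOT_PIXEL_RATE,
    ceiling: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel dark-count map from an emitter-free (dark) binary stack.

    Inverts the Bernoulli detection rate: ``DC_p = -ln(1 - mean_n w_np)``.
    Pixels whose empirical rate reaches ``hot_threshold`` are flagged
    defective (``mask = False``); their DC is set to ``ceiling`` if given,
    else to the inversion at the threshold — never infinity.

    Returns ``(dc, mask)``.
    """
    if dark_stack.bin_count != 1:
        raise ValueError("dark-count estimation expects a binary stack")
    if dark_stack.n_frames == 0:
        raise ValueError("dark stack is empty")
    rate = dark_stack.counts.mean(axis=0)
    hot = rate >= hot_threshold
    capped = np.minimum(rate, hot_threshold)
    dc = -np.log1p(-capped)
    if ceiling is not None:
        dc = np.minimum(dc, ceiling)
        dc[hot] = ceiling
    mask = ~hot
    return dc, mask
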