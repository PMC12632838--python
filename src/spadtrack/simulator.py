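"""Forward simulator matched to the likelihood's generative model.

Generates ground-truth trajectories (free diffusion or piezo-stage stepping),
renders them to binary frame stacks by drawing each pixel-frame independently
from Bernoulli(1 - exp(-u)), and provides the frame manipulations used in the
diffusion-bias experiments: summing consecutive binary frames into
higher-bit-depth stacks and stroboscopic subsetting.

Because rendering uses exactly the expected-photon field of
:func:`spadtrack.likelihood.expected_photons`, agreement between empirical
firing rates and the likelihood's success probability is an identity of the
implementation, and every inference claim can be tested end to end.

Motion blur within one exposure is not simulated: the position is sampled once
per binary frame, matching the single-position-per-frame observation model.
At the 10-50 microsecond exposures studied here intra-frame displacement is
small against the pixel size; the residual effect is a documented limitation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .likelihood import Calibration, FrameStack, TrackSet, expected_photons
from .psf import PixelGrid, PsfModel

__all__ = [
    "SimConfig",
    "simulate_brownian",
    "simulate_piezo",
    "simulate_tracks",
    "render_frames",
    "bin_frames",
    "stroboscopic_subset",
    "sample_dark_counts",
    "make_calibration",
]

logger = logging.getLogger(__name__)

#: nm² per μm²
_UM2_TO_NM2 = 1.0e6


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic acquisition.

    Defaults follow the synthetic robustness conditions used throughout the
    package tests: NA 1.45, refractive-index-1.515 oil objective, 665 nm
    emission, 100 nm pixels, 10 us binary exposure, and a uniform
    1e-3-counts-per-exposure dark-count floor (a realistic room-temperature
    SPAD rate of ~100 counts/s/pixel).

    ``kind`` selects the trajectory model: ``"brownian"`` (supply exactly one
    of ``d`` in um²/s or ``msd`` in nm² per frame), ``"piezo"`` (stationary
    dwells of ``dwell`` seconds separated by instantaneous axis-aligned steps
    of ``step_size`` nm in a uniformly random direction), or ``"fixed"``
    (immobile emitters).

    Brightness is given either as ``h`` (expected photons per binary exposure)
    or ``photon_rate`` (photons/s, converted as ``h = photon_rate * exposure``).
    """

    kind: str = "brownian"
    n_frames: int = 1000
    exposure: float = 10e-6
    n_particles: int = 1
    # trajectory parameters
    d: float | None = None            # um^2/s
    msd: float | None = None          # nm^2 per frame interval
    dwell: float | None = None        # s (piezo)
    step_size: float | None = None    # nm (piezo)
    start: str | np.ndarray = "center"  # "center", "uniform", or (M, 2) nm
    # optics / detector
    numerical_aperture: float = 1.45
    wavelength: float = 665.0         # nm
    pixel_size: float = 100.0         # nm
    n_rows: int = 32
    n_cols: int = 32
    psf_sigma: float | None = None    # nm; overrides the optics-derived width
    # brightness
    h: float | None = None
    photon_rate: float | None = None  # photons/s
    # dark counts / defects
    dc: float = 1e-3                  # constant map unless dc_mode says otherwise
    dc_mode: str = "constant"         # "constant" | "lognormal"
    dc_sigma: float = 0.5             # lognormal sigma (log-space)
    hot_fraction: float = 0.002       # fraction of 100x hot pixels (lognormal mode)
    dead_fraction: float = 0.0        # fraction of masked (dead) pixels
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("brownian", "piezo", "fixed"):
            raise ValueError(f"unknown trajectory kind {self.kind!r}")
        if self.n_frames < 1 or self.n_particles < 0:
            raise ValueError("n_frames must be >= 1 and n_particles >= 0")
        if self.exposure <= 0:
            raise ValueError("exposure must be positive")
        if self.kind == "brownian":
            if (self.d is None) == (self.msd is None):
                raise ValueError("brownian motion needs exactly one of d or msd")
            value = self.d if self.d is not None else self.msd
            if value <= 0:
                raise ValueError("diffusion parameter must be positive")
        if self.kind == "piezo":
            if self.dwell is None or self.step_size is None:
                raise ValueError("piezo motion needs dwell and step_size")
            if self.step_size <= 0:
                raise ValueError("step size must be positive")
            if self.dwell < self.exposure:
                raise ValueError("dwell must be at least one exposure")
        if (self.h is None) == (self.photon_rate is None):
            raise ValueError("specify exactly one of h or photon_rate")

    @property
    def grid(self) -> PixelGrid:
        return PixelGrid(self.n_rows, self.n_cols, self.pixel_size)

    @property
    def psf(self) -> PsfModel:
        if self.psf_sigma is not None:
            return PsfModel(self.psf_sigma)
        return PsfModel.from_optics(self.numerical_aperture, self.wavelength)

    @property
    def brightness(self) -> float:
        if self.h is not None:
            return self.h
        return self.photon_rate * self.exposure

    @property
    def msd_per_frame(self) -> float:
        """Per-axis displacement variance per binary frame, nm² (brownian)."""
        if self.msd is not None:
            return self.msd
        return 2.0 * self.d * _UM2_TO_NM2 * self.exposure


def _start_positions(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    grid = cfg.grid
    if isinstance(cfg.start, str):
        if cfg.start == "center":
            centre = np.array([grid.width / 2.0, grid.height / 2.0])
            return np.tile(centre, (cfg.n_particles, 1))
        if cfg.start == "uniform":
            return rng.uniform(
                [0.0, 0.0], [grid.width, grid.height], size=(cfg.n_particles, 2)
            )
        raise ValueError(f"unknown start spec {cfg.start!r}")
    start = np.asarray(cfg.start, dtype=float)
    if start.shape != (cfg.n_particles, 2):
        raise ValueError("explicit start must have shape (n_particles, 2)")
    return start


def simulate_brownian(cfg: SimConfig, rng: np.random.Generator) -> TrackSet:
    """Free-diffusion trajectories: i.i.d. Gaussian per-axis increments.

    Per-axis increment variance is ``2 D dt`` (equivalently the configured MSD
    per frame).
    """
    if cfg.kind != "brownian":
        raise ValueError("config kind must be 'brownian'")
    sd = np.sqrt(cfg.msd_per_frame)
    start = _start_positions(cfg, rng)
    steps = rng.normal(0.0, sd, size=(cfg.n_particles, cfg.n_frames - 1, 2))
    positions = np.concatenate(
        [start[:, None, :], start[:, None, :] + np.cumsum(steps, axis=1)], axis=1
    )
    return TrackSet(positions)


def simulate_piezo(cfg: SimConfig, rng: np.random.Generator) -> TrackSet:
    """Piezo-stage protocol: constant dwells separated by axis-aligned jumps.

    The stage holds for ``dwell`` seconds (rounded down to a whole number of
    frames, logged if inexact), then moves instantaneously by ``step_size`` nm
    in one of the four axis directions chosen uniformly.
    """
    if cfg.kind != "piezo":
        raise ValueError("config kind must be 'piezo'")
    ratio = cfg.dwell / cfg.exposure
    frames_per_dwell = int(np.floor(ratio + 1e-9))  # tolerate float round-off
    if abs(ratio - frames_per_dwell) > 1e-6:
        logger.info(
            "dwell %.3g s is not a whole number of frames; using %d frames per dwell",
            cfg.dwell,
            frames_per_dwell,
        )
    start = _start_positions(cfg, rng)
    directions = np.array([[1.0, 0.0], [-1.0, 0.0], [0.0, 1.0], [0.0, -1.0]])
    positions = np.empty((cfg.n_particles, cfg.n_frames, 2))
    for m in range(cfg.n_particles):
        pos = start[m].copy()
        for n in range(cfg.n_frames):
            if n > 0 and n % frames_per_dwell == 0:
                pos = pos + cfg.step_size * directions[rng.integers(4)]
            positions[m, n] = pos
    return TrackSet(positions)


def simulate_tracks(cfg: SimConfig, rng: np.random.Generator) -> TrackSet:
    """Dispatch on ``cfg.kind``."""
    if cfg.kind == "brownian":
        return simulate_brownian(cfg, rng)
    if cfg.kind == "piezo":
        return simulate_piezo(cfg, rng)
    start = _start_positions(cfg, rng)
    return TrackSet(np.repeat(start[:, None, :], cfg.n_frames, axis=1))


def sample_dark_counts(
    shape: tuple[int, int],
    rng: np.random.Generator,
    base: float = 1e-3,
    mode: str = "constant",
    sigma: float = 0.5,
    hot_fraction: float = 0.002,
    hot_factor: float = 100.0,
    dead_fraction: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel dark-count map and usable mask.

    ``mode="constant"`` gives a uniform map at ``base``.  ``mode="lognormal"``
    draws log-normal pixel-to-pixel variation around ``base`` and promotes a
    ``hot_fraction`` of pixels to ``hot_factor`` times their rate, emulating
    the heavy-tailed dark-count distributions of real SPAD arrays.  A
    ``dead_fraction`` of pixels is masked out (defective).
    """
    if base < 0:
        raise ValueError("base dark-count rate must be non-negative")
    if mode == "constant":
        dc = np.full(shape, float(base))
    elif mode == "lognormal":
        dc = base * rng.lognormal(-0.5 * sigma**2, sigma, size=shape)
        hot = rng.random(shape) < hot_fraction
        dc[hot] *= hot_factor
    else:
        raise ValueError(f"unknown dark-count mode {mode!r}")
    mask = np.ones(shape, dtype=bool)
    if dead_fraction > 0:
        mask &= rng.random(shape) >= dead_fraction
    return dc, mask


def make_calibration(cfg: SimConfig, rng: np.random.Generator) -> Calibration:
    """Calibration implied by the simulation config (DC map, mask, h, PSF)."""
    dc, mask = sample_dark_counts(
        (cfg.n_rows, cfg.n_cols),
        rng,
        base=cfg.dc,
        mode=cfg.dc_mode,
        sigma=cfg.dc_sigma,
        hot_fraction=cfg.hot_fraction,
        dead_fraction=cfg.dead_fraction,
    )
    return Calibration(dc=dc, mask=mask, h=cfg.brightness, psf=cfg.psf)


def render_frames(
    tracks: TrackSet,
    cal: Calibration,
    grid: PixelGrid,
    exposure: float,
    rng: np.random.Generator,
    chunk_frames: int = 2000,
) -> FrameStack:
    """Draw a binary stack from the generative model.

    Each pixel-frame is an independent Bernoulli(1 - exp(-u)) draw with ``u``
    from :func:`spadtrack.likelihood.expected_photons`; defective pixels
    output 0.  Frames are rendered in chunks to bound memory.
    """
    n = tracks.n_frames
    counts = np.empty((n, *grid.shape), dtype=np.uint8)
    for lo in range(0, n, chunk_frames):
        hi = min(lo + chunk_frames, n)
        sub = TrackSet(tracks.positions[:, lo:hi], tracks.states[:, lo:hi])
        u = expected_photons(sub, cal, grid)
        p = -np.expm1(-u)
        counts[lo:hi] = (rng.random(u.shape) < p).astype(np.uint8)
    counts[:, ~cal.mask] = 0
    return FrameStack(counts=counts, exposure=exposure, grid=grid, bin_count=1)


def bin_frames(stack: FrameStack, k: int) -> FrameStack:
    """Sum each run of ``k`` consecutive frames into one higher-depth frame.

    The bin count multiplies by ``k`` (255 binary frames at 50 us collapse to
    one 8-bit frame with a 12.75 ms effective exposure), as does the frame
    interval.  A trailing remainder of fewer than ``k`` frames is dropped and
    logged.  ``k = 1`` returns the stack unchanged.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k == 1:
        return stack
    n_keep = (stack.n_frames // k) * k
    if n_keep < stack.n_frames:
        logger.info("dropping %d trailing frames not filling a bin", stack.n_frames - n_keep)
    if n_keep == 0:
        raise ValueError(f"stack has fewer than k={k} frames")
    rows, cols = stack.grid.shape
    summed = (
        stack.counts[:n_keep]
        .reshape(n_keep // k, k, rows, cols)
        .sum(axis=1)
        .astype(np.int64)
    )
    return FrameStack(
        counts=summed,
        exposure=stack.exposure,
        grid=stack.grid,
        bin_count=stack.bin_count * k,
        frame_interval=stack.frame_interval * k,
    )


def stroboscopic_subset(stack: FrameStack, keep_every: int, offset: int = 0) -> FrameStack:
    """Keep frames ``offset, offset + keep_every, ...``.

    Emulates stroboscopic illumination: the frame interval multiplies by
    ``keep_every`` while the per-frame exposure is unchanged.
    """
    if keep_every < 1:
        raise ValueError("keep_every must be >= 1")
    if not 0 <= offset < keep_every:
        raise ValueError("offset must lie in [0, keep_every)")
    if keep_every == 1:
        return stack
    return FrameStack(
        counts=stack.counts[offset::keep_every].copy(),
        exposure=stack.exposure,
        grid=stack.grid,
        bin_count=stack.bin_count,
        frame_interval=stack.frame_interval * keep_every,
    )
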