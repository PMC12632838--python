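"""Priors over trajectories, particle number, and mean squared displacement.

The motion model is free diffusion discretized at the frame interval: each
per-axis displacement is an independent zero-mean Gaussian with variance MSD,

    x_n ~ Normal(x_{n-1}, MSD * I),   n = 2..N,

where MSD is the per-axis displacement variance over one frame interval (nm²).
The diffusion coefficient follows as ``D = MSD / (2 * dt)``; this single
convention is used consistently throughout the package.

The remaining priors are weakly informative and primarily fix the support of
each variable: initial positions are uniform over the field of view, the
particle count is Poisson (mean ``m_mean``) truncated at ``m_max``, and MSD
carries an inverse-gamma prior (strictly positive support, conjugate to the
Gaussian increments, which gives the sampler an exact Gibbs update).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .likelihood import TrackSet

__all__ = [
    "MotionParams",
    "PriorConfig",
    "motion_log_prior",
    "number_and_static_log_prior",
    "msd_log_prior",
    "truncated_poisson_logpmf",
    "sample_msd_prior",
]


@dataclass(frozen=True)
class MotionParams:
    """Diffusive motion parameters.

    ``msd``: per-axis displacement variance per frame interval, nm².
    ``frame_interval``: seconds between consecutive frames.
    ``dims``: spatial dimensionality of the motion model (2 for the planar
    tracking done here; 3 is accepted for the prior computations).
    """

    msd: float
    frame_interval: float
    dims: int = 2

    def __post_init__(self) -> None:
        if not np.isfinite(self.msd) or self.msd <= 0:
            raise ValueError("MSD must be positive")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if self.dims not in (2, 3):
            raise ValueError("dims must be 2 or 3")

    @property
    def diffusion_coefficient(self) -> float:
        """D in nm²/s, from D = MSD / (2 dt)."""
        return self.msd / (2.0 * self.frame_interval)


@dataclass(frozen=True)
class PriorConfig:
    """Hyperparameters of the static priors.

    ``fov``: ``((x_min, x_max), (y_min, y_max))`` bounds in nm of the uniform
    initial-position prior; must enclose the pixel grid in use.
    ``m_max`` / ``m_mean``: truncation and mean of the Poisson prior on the
    particle count.
    ``msd_shape`` / ``msd_mean``: inverse-gamma prior on MSD with the given
    shape; the scale is set so the prior mean equals ``msd_mean`` (nm²),
    i.e. ``scale = msd_mean * (msd_shape - 1)``.
    """

    fov: tuple[tuple[float, float], tuple[float, float]]
    m_max: int = 20
    m_mean: float = 1.0
    msd_shape: float = 2.0
    msd_mean: float = 1000.0

    def __post_init__(self) -> None:
        (x0, x1), (y0, y1) = self.fov
        if not (x1 > x0 and y1 > y0):
            raise ValueError("FOV bounds must be non-degenerate")
        if self.m_max < 1:
            raise ValueError("m_max must be >= 1")
        if self.m_mean <= 0:
            raise ValueError("m_mean must be positive")
        if self.msd_shape <= 1 or self.msd_mean <= 0:
            raise ValueError("msd_shape must exceed 1 and msd_mean be positive")

    @property
    def fov_area(self) -> float:
        (x0, x1), (y0, y1) = self.fov
        return (x1 - x0) * (y1 - y0)

    @property
    def msd_scale(self) -> float:
        return self.msd_mean * (self.msd_shape - 1.0)

    def positions_in_fov(self, positions: np.ndarray) -> np.ndarray:
        p = np.asarray(positions, dtype=float)
        (x0, x1), (y0, y1) = self.fov
        return (
            (p[..., 0] >= x0) & (p[..., 0] <= x1)
            & (p[..., 1] >= y0) & (p[..., 1] <= y1)
        )


def motion_log_prior(tracks: TrackSet, params: MotionParams) -> float:
    """Log-density of all displacements under the diffusive motion prior.

    Sum over particles and frames ``n >= 2`` of independent per-axis Gaussian
    log-densities with variance MSD; depends only on displacements, hence
    translation-invariant.  A single-frame track contributes 0 (empty
    product).  Decomposes additively over particles.
    """
    if tracks.n_frames < 1:
        raise ValueError("tracks must span at least one frame")
    if tracks.n_particles == 0 or tracks.n_frames == 1:
        return 0.0
    inc = np.diff(tracks.positions[..., : params.dims], axis=1)
    n_terms = inc.size
    ss = float(np.sum(inc * inc))
    return -0.5 * n_terms * np.log(2.0 * np.pi * params.msd) - ss / (2.0 * params.msd)


def truncated_poisson_logpmf(m: int, mean: float, m_max: int) -> float:
    """Log pmf of a Poisson(mean) truncated to ``{0, ..., m_max}``."""
    if not 0 <= m <= m_max:
        return -np.inf
    support = np.arange(m_max + 1)
    log_terms = stats.poisson.logpmf(support, mean)
    log_z = float(np.logaddexp.reduce(log_terms))
    return float(stats.poisson.logpmf(m, mean) - log_z)


def msd_log_prior(msd: float, cfg: PriorConfig) -> float:
    """Inverse-gamma log-density of MSD (support ``(0, inf)``)."""
    if msd <= 0:
        return -np.inf
    return float(stats.invgamma.logpdf(msd, a=cfg.msd_shape, scale=cfg.msd_scale))


def number_and_static_log_prior(
    tracks: TrackSet, params: MotionParams, cfg: PriorConfig
) -> float:
    """Joint log-prior of the particle count, initial positions, and MSD.

    Uniform initial positions over the FOV (``-inf`` outside), truncated
    Poisson on the particle count, inverse-gamma on MSD.
    """
    m = tracks.n_particles
    if m > cfg.m_max:
        return -np.inf
    total = truncated_poisson_logpmf(m, cfg.m_mean, cfg.m_max)
    if m > 0:
        first = tracks.positions[:, 0, :]
        if not np.all(cfg.positions_in_fov(first)):
            return -np.inf
        total += -m * np.log(cfg.fov_area)
    total += msd_log_prior(params.msd, cfg)
    return float(total)


def sample_msd_prior(cfg: PriorConfig, rng: np.random.Generator, size=None):
    """Draw MSD values from the inverse-gamma prior."""
    return cfg.msd_scale / rng.gamma(cfg.msd_shape, 1.0, size=size)
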