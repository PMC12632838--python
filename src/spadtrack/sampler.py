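"""Posterior sampling over particle number, trajectories, and MSD.

The joint posterior over ``(M, tracks, MSD)`` combines the Bernoulli/binomial
photon-detection likelihood, the Gaussian-increment motion prior, a uniform
initial-position prior over the field of view, a truncated-Poisson prior on
the particle count, and an inverse-gamma prior on MSD.  It is explored by
Metropolis-within-Gibbs:

* **positions** — Gaussian random-walk proposals applied to all even-index
  frames of one particle at once, then all odd-index frames (frames of equal
  parity are conditionally independent given the complementary parity, so the
  block update is an exact Metropolis move), plus a whole-track translation;
* **MSD** — an exact conjugate inverse-gamma Gibbs draw given displacements;
* **particle count** (nonparametric mode) — reversible-jump birth/death:
  births anchor a new track at a position drawn from a smoothed residual
  detection image (with a uniform floor so the proposal density is bounded
  away from zero) and extend it with motion-prior increments, whose density
  cancels analytically in the acceptance ratio.

Likelihood deltas exploit the structure of single-photon data: per frame the
log-likelihood is ``-k * sum_p u + sum_{w>0} w * (u + log(1 - e^-u))`` plus
binomial constants, so a position change touches only (a) the closed-form
total PSF mass captured by the (unmasked) grid and (b) the sparse set of
pixels that actually fired.  Deltas are exact; a periodic full recomputation
bounds floating-point drift and is reported as a diagnostic.

All randomness flows through one seeded generator in a fixed draw order, so
identical configuration and data reproduce identical ensembles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.optimize import linear_sum_assignment

from .likelihood import (
    Calibration,
    FrameStack,
    TrackSet,
    binned_log_likelihood,
    expected_photons,
    log1mexp,
)
from .priors import (
    MotionParams,
    PriorConfig,
    motion_log_prior,
    msd_log_prior,
    number_and_static_log_prior,
    sample_msd_prior,
    truncated_poisson_logpmf,
)
from .psf import captured_fraction, psf_fraction_at

__all__ = [
    "SamplerConfig",
    "PosteriorSample",
    "PosteriorEnsemble",
    "Chain",
    "run",
    "update_tracks",
    "update_msd",
    "birth_death_move",
    "credible_intervals",
    "upsample_tracks",
]

logger = logging.getLogger(__name__)

_MOVE_NAMES = (
    "single_frame",
    "frame_jump",
    "block_shift",
    "track_shift",
    "birth",
    "death",
    "msd",
    "msd_rescale",
)


@dataclass
class SamplerConfig:
    """Controls for one MCMC run.

    ``mode`` is ``"nonparametric"`` (particle count inferred by birth/death
    moves) or ``"parametric"`` (count fixed to ``n_particles``; birth/death
    never attempted).  ``n_samples`` posterior samples are retained after
    ``burn_in`` sweeps, one every ``thin`` sweeps.  The position step is
    adapted toward ``target_accept`` during burn-in only, then frozen so the
    stationary target is preserved.  MSD Gibbs updates start after
    ``msd_delay`` sweeps (default: a third of burn-in) so a cold
    initialization cannot collapse the step size.
    """

    mode: str = "nonparametric"
    n_particles: Optional[int] = None
    n_samples: int = 500
    burn_in: int = 300
    thin: int = 1
    step_nm: float = 30.0
    shift_nm: float = 10.0
    block_scales: tuple[int, ...] = (16, 64)
    birth_death_prob: float = 0.5
    seed: int = 0
    adapt: bool = True
    adapt_interval: int = 25
    target_accept: float = 0.3
    msd_init: Optional[float] = None
    msd_delay: Optional[int] = None
    update_msd: bool = True
    update_positions: bool = True
    use_frame_jumps: bool = True
    residual_floor: float = 0.1
    jump_floor: float = 0.25
    msd_rescale_step: float = 0.3
    n_msd_rescale: int = 2
    recompute_every: int = 1000
    max_init_retries: int = 10

    def __post_init__(self) -> None:
        if self.mode not in ("parametric", "nonparametric"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "parametric" and not self.n_particles and self.n_particles != 0:
            raise ValueError("parametric mode requires n_particles")
        if self.n_samples < 1 or self.burn_in < 0 or self.thin < 1:
            raise ValueError("n_samples >= 1, burn_in >= 0, thin >= 1 required")
        if self.step_nm < 0 or self.shift_nm < 0:
            raise ValueError("proposal steps must be non-negative")
        if not 0.0 <= self.birth_death_prob <= 1.0:
            raise ValueError("birth_death_prob must lie in [0, 1]")
        if not 0.0 < self.residual_floor <= 1.0:
            raise ValueError("residual_floor must lie in (0, 1]")


@dataclass(frozen=True)
class PosteriorSample:
    """One retained draw of (particle count, tracks, MSD) with its log-posterior."""

    n_particles: int
    tracks: TrackSet
    msd: float
    log_posterior: float


@dataclass
class PosteriorEnsemble:
    """Ordered posterior samples plus per-move acceptance diagnostics."""

    samples: list[PosteriorSample]
    acceptance: dict[str, dict[str, int]]
    diagnostics: dict
    frame_interval: float

    @property
    def map_sample(self) -> PosteriorSample:
        """Sample with the highest log-posterior; earliest index on ties."""
        if not self.samples:
            raise ValueError("ensemble is empty")
        values = np.array([s.log_posterior for s in self.samples])
        return self.samples[int(np.argmax(values))]

    @property
    def msd_samples(self) -> np.ndarray:
        return np.array([s.msd for s in self.samples])

    @property
    def m_samples(self) -> np.ndarray:
        return np.array([s.n_particles for s in self.samples])

    @property
    def modal_m(self) -> int:
        counts = np.bincount(self.m_samples)
        return int(np.argmax(counts))

    def acceptance_rate(self, move: str) -> float:
        rec = self.acceptance[move]
        return rec["accepted"] / rec["attempted"] if rec["attempted"] else np.nan

    def credible_intervals(self, level: float = 0.95) -> dict:
        return credible_intervals(self, level)


def _g(u: np.ndarray) -> np.ndarray:
    """``log(e^u - 1) = u + log(1 - e^-u)``; the firing-pixel likelihood term."""
    with np.errstate(invalid="ignore"):
        return u + log1mexp(u)


class Chain:
    """Markov-chain state and transition kernels for one dataset.

    Construct once per run; the constructor precomputes the sparse firing-
    pixel layout.  :meth:`sweep` applies one full update cycle; :func:`run`
    drives burn-in, thinning, recording, and adaptation.
    """

    def __init__(
        self,
        stack: FrameStack,
        cal: Calibration,
        prior_cfg: Optional[PriorConfig] = None,
        sampler_cfg: Optional[SamplerConfig] = None,
        init_tracks: Optional[TrackSet] = None,
    ) -> None:
        self.stack = stack
        self.cal = cal
        self.grid = stack.grid
        self.cfg = sampler_cfg if sampler_cfg is not None else SamplerConfig()
        if prior_cfg is None:
            prior_cfg = PriorConfig(
                fov=((0.0, self.grid.width), (0.0, self.grid.height))
            )
        self.prior_cfg = prior_cfg
        self.rng = np.random.default_rng(self.cfg.seed)
        self.h = cal.h
        self.k = stack.bin_count
        self.sigma = cal.psf.sigma
        self.n_frames = stack.n_frames

        rows, cols = self.grid.shape
        npix = rows * cols
        counts_flat = stack.counts.reshape(self.n_frames, npix)
        mask_flat = cal.mask.reshape(npix)
        self._dc_flat = cal.dc.reshape(npix)
        self._masked_pix = np.nonzero(~mask_flat)[0]
        self._n_unmasked = int(mask_flat.sum())

        frame_idx, pix_idx = np.nonzero((counts_flat > 0) & mask_flat[None, :])
        self._hits_frame = frame_idx.astype(np.intp)
        self._hits_pix = pix_idx.astype(np.intp)
        self._hits_w = counts_flat[frame_idx, pix_idx].astype(float)
        self._parity_sel = []
        for parity in (0, 1):
            sel = np.nonzero(self._hits_frame % 2 == parity)[0]
            local = (self._hits_frame[sel] - parity) // 2
            self._parity_sel.append((sel, local))
        # mean detection rate per binary exposure per pixel (proposal map input)
        with np.errstate(invalid="ignore"):
            self._mean_rate = counts_flat.sum(axis=0) / (self.n_frames * self.k)

        # frame-jump proposal structures: CSR over hits, dark-subtracted
        # weights, pixel centres, and the Gaussian jitter scale
        self._frame_ptr = np.searchsorted(
            self._hits_frame, np.arange(self.n_frames + 1)
        )
        expected_dark = self.k * (-np.expm1(-self._dc_flat[self._hits_pix]))
        self._jump_w = np.clip(self._hits_w - expected_dark, 0.0, None)
        self._jump_W = np.bincount(
            self._hits_frame, weights=self._jump_w, minlength=self.n_frames
        )
        self._jump_cum = np.cumsum(self._jump_w)
        self._cum0 = np.concatenate([[0.0], self._jump_cum])
        a = self.grid.pixel_size
        self._hit_centers = np.column_stack(
            [
                (self._hits_pix % self.grid.n_cols + 0.5) * a,
                (self._hits_pix // self.grid.n_cols + 0.5) * a,
            ]
        )
        self._jump_sigma = float(np.sqrt(self.sigma**2 + a**2 / 12.0))

        # state
        self.positions = np.zeros((0, self.n_frames, 2))
        self.states = np.zeros((0, self.n_frames), dtype=np.uint8)
        self.msd = (
            self.cfg.msd_init if self.cfg.msd_init is not None else prior_cfg.msd_mean
        )
        self.loglik = -np.inf
        self.step_nm = self.cfg.step_nm
        self.shift_nm = self.cfg.shift_nm
        self.block_steps = {s: self.cfg.step_nm for s in self.cfg.block_scales}
        self._block_windows = {
            s: {"accepted": 0, "attempted": 0} for s in self.cfg.block_scales
        }
        self.acceptance = {
            name: {"accepted": 0, "attempted": 0} for name in _MOVE_NAMES
        }
        self._adapt_window = {"accepted": 0, "attempted": 0}
        self.diagnostics = {"loglik_delta_max_error": 0.0, "n_recomputes": 0}
        self._frozen = False
        self._initialize(init_tracks)

    # ------------------------------------------------------------------ state

    @property
    def n_particles(self) -> int:
        return self.positions.shape[0]

    def tracks(self) -> TrackSet:
        return TrackSet(self.positions.copy(), self.states.copy())

    def motion_params(self) -> MotionParams:
        return MotionParams(
            msd=self.msd, frame_interval=self.stack.frame_interval, dims=2
        )

    def log_posterior(self) -> float:
        t = TrackSet(self.positions, self.states)
        lp = self.loglik
        if self.n_particles > 0 and self.n_frames > 1:
            lp += motion_log_prior(t, self.motion_params())
        lp += number_and_static_log_prior(t, self.motion_params(), self.prior_cfg)
        return float(lp)

    # ------------------------------------------------------------- likelihood

    def full_log_likelihood(self, chunk_frames: int = 1024) -> float:
        """Exact recomputation through the likelihood module (frame-chunked)."""
        total = 0.0
        for lo in range(0, self.n_frames, chunk_frames):
            hi = min(lo + chunk_frames, self.n_frames)
            sub_tracks = TrackSet(self.positions[:, lo:hi], self.states[:, lo:hi])
            sub_stack = FrameStack(
                counts=self.stack.counts[lo:hi],
                exposure=self.stack.exposure,
                grid=self.grid,
                bin_count=self.k,
            )
            u = expected_photons(sub_tracks, self.cal, self.grid)
            total += binned_log_likelihood(sub_stack, u, self.cal)
        return total

    def _capture_eff(self, positions: np.ndarray) -> np.ndarray:
        """PSF mass over the *unmasked* grid for positions ``(..., 2)``."""
        cap = captured_fraction(positions, self.cal.psf, self.grid)
        if self._masked_pix.size:
            corr = psf_fraction_at(
                self._masked_pix, positions[..., None, :], self.cal.psf, self.grid
            ).sum(axis=-1)
            cap = cap - corr
        return cap

    def _u_at_hits(self, sel: np.ndarray) -> np.ndarray:
        """Expected photons per binary exposure at the selected hits."""
        pix = self._hits_pix[sel]
        frames = self._hits_frame[sel]
        u = self._dc_flat[pix].copy()
        for m in range(self.n_particles):
            fm = self.states[m, frames].astype(float)
            if not fm.any():
                continue
            u += self.h * fm * psf_fraction_at(
                pix, self.positions[m, frames], self.cal.psf, self.grid
            )
        return u

    def _track_delta_loglik(
        self, positions: np.ndarray, states: np.ndarray, sign: float
    ) -> float:
        """Likelihood change from adding (+1) or removing (-1) a whole track."""
        f = states.astype(float)
        cap = self._capture_eff(positions)
        delta = -sign * self.k * self.h * float(np.sum(f * cap))
        if self._hits_pix.size:
            sel = np.arange(self._hits_pix.size)
            u_cur = self._u_at_hits(sel)
            frames = self._hits_frame
            c = self.h * f[frames] * psf_fraction_at(
                self._hits_pix, positions[frames], self.cal.psf, self.grid
            )
            u_new = u_cur + sign * c
            delta += float(np.sum(self._hits_w * (_g(u_new) - _g(u_cur))))
        return delta

    # ---------------------------------------------------------------- updates

    def _frames_delta(
        self, m: int, parity: int, x_cur: np.ndarray, x_new: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        """Per-frame (prior, likelihood) log-density changes for one parity block."""
        n = self.n_frames
        S = np.arange(parity, n, 2)
        K = S.size
        # motion-prior delta over the edges touching each updated frame
        dlp = np.zeros(K)
        has_prev = S > 0
        if has_prev.any():
            prev = self.positions[m, S[has_prev] - 1]
            dlp[has_prev] += (
                np.sum((x_cur[has_prev] - prev) ** 2, axis=1)
                - np.sum((x_new[has_prev] - prev) ** 2, axis=1)
            ) / (2.0 * self.msd)
        has_next = S < n - 1
        if has_next.any():
            nxt = self.positions[m, S[has_next] + 1]
            dlp[has_next] += (
                np.sum((x_cur[has_next] - nxt) ** 2, axis=1)
                - np.sum((x_new[has_next] - nxt) ** 2, axis=1)
            ) / (2.0 * self.msd)
        if parity == 0:  # frame 0 carries the uniform initial-position prior
            if not self.prior_cfg.positions_in_fov(x_new[0]):
                dlp[0] = -np.inf

        # likelihood delta: captured-mass term plus sparse firing-pixel term
        f_m = self.states[m, S].astype(float)
        dll = -self.k * self.h * f_m * (
            self._capture_eff(x_new) - self._capture_eff(x_cur)
        )
        sel, local = self._parity_sel[parity]
        if sel.size:
            pix = self._hits_pix[sel]
            frames = self._hits_frame[sel]
            u_cur = self._u_at_hits(sel)
            fh = self.states[m, frames].astype(float)
            c_cur = self.h * fh * psf_fraction_at(
                pix, x_cur[local], self.cal.psf, self.grid
            )
            c_new = self.h * fh * psf_fraction_at(
                pix, x_new[local], self.cal.psf, self.grid
            )
            u_new = u_cur - c_cur + c_new
            dg = self._hits_w[sel] * (_g(u_new) - _g(u_cur))
            dll += np.bincount(local, weights=dg, minlength=K)
        return dlp, dll

    def _accept_frames(
        self,
        m: int,
        parity: int,
        x_new: np.ndarray,
        delta: np.ndarray,
        dll: np.ndarray,
        move: str,
    ) -> None:
        S = np.arange(parity, self.n_frames, 2)
        delta = np.where(np.isnan(delta), -np.inf, delta)
        accept = np.log(self.rng.random(S.size)) < delta
        if accept.any():
            self.positions[m, S[accept]] = x_new[accept]
            self.loglik += float(dll[accept].sum())
        self.acceptance[move]["attempted"] += S.size
        self.acceptance[move]["accepted"] += int(accept.sum())
        if move == "single_frame":
            self._adapt_window["attempted"] += S.size
            self._adapt_window["accepted"] += int(accept.sum())

    def update_positions_half(self, m: int, parity: int) -> None:
        """Random-walk Metropolis update of all parity-``parity`` frames."""
        S = np.arange(parity, self.n_frames, 2)
        if S.size == 0:
            return
        x_cur = self.positions[m, S]
        x_new = x_cur + self.step_nm * self.rng.standard_normal((S.size, 2))
        dlp, dll = self._frames_delta(m, parity, x_cur, x_new)
        self._accept_frames(m, parity, x_new, dlp + dll, dll, "single_frame")

    # -- per-frame independence ("jump") proposals ---------------------------
    #
    # Local random-walk moves cannot find an emitter far from the current
    # track.  Each frame therefore also receives an independence proposal
    # drawn from that frame's own detection image: with probability
    # ``jump_floor`` a uniform position in the FOV, otherwise a firing pixel
    # chosen with probability proportional to its dark-count-subtracted
    # count, jittered by a Gaussian of the PSF scale.  The proposal density
    # is an explicit mixture, so the Metropolis-Hastings correction is exact.

    def _jump_density(self, parity: int, positions: np.ndarray) -> np.ndarray:
        S = np.arange(parity, self.n_frames, 2)
        K = S.size
        floor_n = np.where(self._jump_W[S] > 0, self.cfg.jump_floor, 1.0)
        in_fov = self.prior_cfg.positions_in_fov(positions)
        dens = np.where(in_fov, floor_n / self.prior_cfg.fov_area, 0.0)
        sel, local = self._parity_sel[parity]
        if sel.size:
            s2 = self._jump_sigma**2
            diff = positions[local] - self._hit_centers[sel]
            kernel = np.exp(-np.sum(diff * diff, axis=1) / (2.0 * s2)) / (
                2.0 * np.pi * s2
            )
            mix = np.bincount(
                local, weights=self._jump_w[sel] * kernel, minlength=K
            )
            with np.errstate(invalid="ignore", divide="ignore"):
                mix = np.where(self._jump_W[S] > 0, mix / self._jump_W[S], 0.0)
            dens = dens + (1.0 - floor_n) * mix
        return dens

    def _sample_jump(self, parity: int) -> np.ndarray:
        S = np.arange(parity, self.n_frames, 2)
        K = S.size
        (x0, x1), (y0, y1) = self.prior_cfg.fov
        uniform = np.column_stack(
            [self.rng.uniform(x0, x1, K), self.rng.uniform(y0, y1, K)]
        )
        floor_n = np.where(self._jump_W[S] > 0, self.cfg.jump_floor, 1.0)
        take_uniform = self.rng.random(K) < floor_n
        pickpos = self._cum0[self._frame_ptr[S]] + self.rng.random(K) * self._jump_W[S]
        idx = np.searchsorted(self._jump_cum, pickpos, side="right")
        idx = np.clip(idx, 0, max(self._hit_centers.shape[0] - 1, 0))
        jitter = self._jump_sigma * self.rng.standard_normal((K, 2))
        if self._hit_centers.shape[0]:
            targeted = self._hit_centers[idx] + jitter
        else:
            targeted = uniform
        return np.where(take_uniform[:, None], uniform, targeted)

    def update_positions_jump(self, m: int, parity: int) -> None:
        """Independence-proposal update of all parity-``parity`` frames."""
        S = np.arange(parity, self.n_frames, 2)
        if S.size == 0:
            return
        x_cur = self.positions[m, S]
        x_new = self._sample_jump(parity)
        dlp, dll = self._frames_delta(m, parity, x_cur, x_new)
        with np.errstate(divide="ignore"):
            log_q_ratio = np.log(self._jump_density(parity, x_cur)) - np.log(
                self._jump_density(parity, x_new)
            )
        self._accept_frames(
            m, parity, x_new, dlp + dll + log_q_ratio, dll, "frame_jump"
        )

    def update_block_shift(self, m: int, scale: int) -> None:
        """Joint translation of contiguous ``scale``-frame blocks.

        Collective track modes (smoothed wiggles) decorrelate slowly under
        single-frame moves; translating a whole block pays the motion prior
        only at its two boundary edges, so intermediate-scale modes mix
        directly.  Blocks have a random phase each call and are updated in
        alternating parity (even block indices, then odd) so simultaneous
        updates never share an edge.
        """
        n = self.n_frames
        if scale >= n or scale < 2:
            return
        phase = int(self.rng.integers(scale))
        bid = (np.arange(n) + (scale - phase)) // scale
        n_blocks = int(bid[-1]) + 1
        step = self.block_steps[scale]
        delta = step * self.rng.standard_normal((n_blocks, 2))
        hits_bid = bid[self._hits_frame] if self._hits_pix.size else None
        for par in (0, 1):
            frames = np.nonzero((bid % 2) == par)[0]
            if frames.size == 0:
                continue
            fb = bid[frames]
            x_cur = self.positions[m, frames]
            x_new = x_cur + delta[fb]

            dlp_b = np.zeros(n_blocks)
            starts = frames[frames > 0]
            starts = starts[bid[starts - 1] != bid[starts]]
            if starts.size:
                prev = self.positions[m, starts - 1]
                xc = self.positions[m, starts]
                xn = xc + delta[bid[starts]]
                term = (
                    np.sum((xc - prev) ** 2, axis=1)
                    - np.sum((xn - prev) ** 2, axis=1)
                ) / (2.0 * self.msd)
                np.add.at(dlp_b, bid[starts], term)
            ends = frames[frames < n - 1]
            ends = ends[bid[ends + 1] != bid[ends]]
            if ends.size:
                nxt = self.positions[m, ends + 1]
                xc = self.positions[m, ends]
                xn = xc + delta[bid[ends]]
                term = (
                    np.sum((xc - nxt) ** 2, axis=1)
                    - np.sum((xn - nxt) ** 2, axis=1)
                ) / (2.0 * self.msd)
                np.add.at(dlp_b, bid[ends], term)
            if bid[0] % 2 == par:  # frame 0 carries the initial-position prior
                if not self.prior_cfg.positions_in_fov(
                    self.positions[m, 0] + delta[bid[0]]
                ):
                    dlp_b[bid[0]] = -np.inf

            f_m = self.states[m, frames].astype(float)
            dll_f = -self.k * self.h * f_m * (
                self._capture_eff(x_new) - self._capture_eff(x_cur)
            )
            dll_b = np.bincount(fb, weights=dll_f, minlength=n_blocks)
            if self._hits_pix.size:
                hsel = np.nonzero((hits_bid % 2) == par)[0]
                if hsel.size:
                    pix = self._hits_pix[hsel]
                    hframes = self._hits_frame[hsel]
                    u_cur = self._u_at_hits(hsel)
                    fh = self.states[m, hframes].astype(float)
                    c_cur = self.h * fh * psf_fraction_at(
                        pix, self.positions[m, hframes], self.cal.psf, self.grid
                    )
                    c_new = self.h * fh * psf_fraction_at(
                        pix,
                        self.positions[m, hframes] + delta[hits_bid[hsel]],
                        self.cal.psf,
                        self.grid,
                    )
                    u_new = u_cur - c_cur + c_new
                    dg = self._hits_w[hsel] * (_g(u_new) - _g(u_cur))
                    dll_b += np.bincount(
                        hits_bid[hsel], weights=dg, minlength=n_blocks
                    )

            blocks = np.arange(par, n_blocks, 2)
            total = dlp_b[blocks] + dll_b[blocks]
            total = np.where(np.isnan(total), -np.inf, total)
            accept = np.log(self.rng.random(blocks.size)) < total
            acc_blocks = blocks[accept]
            if acc_blocks.size:
                upd = frames[np.isin(fb, acc_blocks)]
                self.positions[m, upd] += delta[bid[upd]]
                self.loglik += float(dll_b[acc_blocks].sum())
            self.acceptance["block_shift"]["attempted"] += blocks.size
            self.acceptance["block_shift"]["accepted"] += int(accept.sum())
            self._block_windows[scale]["attempted"] += blocks.size
            self._block_windows[scale]["accepted"] += int(accept.sum())

    def update_track_shift(self, m: int) -> None:
        """Metropolis translation of an entire track (motion prior invariant)."""
        if self.shift_nm == 0:
            return
        shift = self.shift_nm * self.rng.standard_normal(2)
        x_new = self.positions[m] + shift
        self.acceptance["track_shift"]["attempted"] += 1
        if not self.prior_cfg.positions_in_fov(x_new[0]):
            return
        dll = self._shift_delta(m, x_new)
        if np.isnan(dll):
            return
        if np.log(self.rng.random()) < dll:
            self.positions[m] = x_new
            self.loglik += dll
            self.acceptance["track_shift"]["accepted"] += 1

    def _shift_delta(self, m: int, x_new: np.ndarray) -> float:
        f = self.states[m].astype(float)
        cap_delta = self._capture_eff(x_new) - self._capture_eff(self.positions[m])
        delta = -self.k * self.h * float(np.sum(f * cap_delta))
        if self._hits_pix.size:
            sel = np.arange(self._hits_pix.size)
            frames = self._hits_frame
            u_cur = self._u_at_hits(sel)
            fh = f[frames]
            c_cur = self.h * fh * psf_fraction_at(
                self._hits_pix, self.positions[m, frames], self.cal.psf, self.grid
            )
            c_new = self.h * fh * psf_fraction_at(
                self._hits_pix, x_new[frames], self.cal.psf, self.grid
            )
            u_prop = u_cur - c_cur + c_new
            delta += float(np.sum(self._hits_w * (_g(u_prop) - _g(u_cur))))
        return delta

    def update_tracks(self) -> None:
        """One position sweep per particle: random-walk and independence
        updates of both parities, plus a whole-track translation."""
        for m in range(self.n_particles):
            self.update_positions_half(m, 0)
            self.update_positions_half(m, 1)
            if self.cfg.use_frame_jumps:
                self.update_positions_jump(m, 0)
                self.update_positions_jump(m, 1)
            for scale in self.cfg.block_scales:
                self.update_block_shift(m, scale)
            self.update_track_shift(m)

    def update_msd(self) -> None:
        """Conjugate Gibbs draw of MSD given current displacements.

        With no particles (or a single frame) the draw falls back to the
        inverse-gamma prior.
        """
        self.acceptance["msd"]["attempted"] += 1
        if self.n_particles == 0 or self.n_frames < 2:
            self.msd = float(sample_msd_prior(self.prior_cfg, self.rng))
        else:
            inc = np.diff(self.positions, axis=1)
            ss = float(np.sum(inc * inc))
            shape = self.prior_cfg.msd_shape + inc.size / 2.0
            scale = self.prior_cfg.msd_scale + ss / 2.0
            self.msd = scale / self.rng.gamma(shape)
        self.acceptance["msd"]["accepted"] += 1

    def update_msd_rescale(self) -> None:
        """Joint non-centered move on (MSD, tracks): rescale all increments.

        The centered Gibbs draw mixes slowly when positions and MSD are
        strongly coupled (the sampled increments always mirror the current
        MSD).  Interweaving this move solves that: propose
        ``MSD' = MSD * exp(eps)`` and rescale every track's increments by
        ``sqrt(MSD'/MSD)`` about its first frame.  In the non-centered
        parameterization (standardized increments held fixed) the motion
        prior cancels exactly, leaving the MSD prior (with the log-scale
        Jacobian) and the likelihood ratio.
        """
        self.acceptance["msd_rescale"]["attempted"] += 1
        msd_new = self.msd * float(
            np.exp(self.cfg.msd_rescale_step * self.rng.standard_normal())
        )
        dlp = (
            msd_log_prior(msd_new, self.prior_cfg)
            + np.log(msd_new)
            - msd_log_prior(self.msd, self.prior_cfg)
            - np.log(self.msd)
        )
        if self.n_particles == 0 or self.n_frames < 2:
            if np.log(self.rng.random()) < dlp:
                self.msd = msd_new
                self.acceptance["msd_rescale"]["accepted"] += 1
            return
        s = np.sqrt(msd_new / self.msd)
        anchor = self.positions[:, :1, :]
        new_pos = anchor + s * (self.positions - anchor)
        dll = self._replace_all_delta(new_pos)
        delta = dlp + dll
        if np.isnan(delta):
            return
        if np.log(self.rng.random()) < delta:
            self.positions = new_pos
            self.msd = msd_new
            self.loglik += dll
            self.acceptance["msd_rescale"]["accepted"] += 1

    def _replace_all_delta(self, new_positions: np.ndarray) -> float:
        """Likelihood change from replacing every particle's positions."""
        delta = 0.0
        for m in range(self.n_particles):
            f = self.states[m].astype(float)
            cap_delta = self._capture_eff(new_positions[m]) - self._capture_eff(
                self.positions[m]
            )
            delta += -self.k * self.h * float(np.sum(f * cap_delta))
        if self._hits_pix.size:
            sel = np.arange(self._hits_pix.size)
            frames = self._hits_frame
            u_cur = self._u_at_hits(sel)
            u_new = self._dc_flat[self._hits_pix].copy()
            for m in range(self.n_particles):
                fh = self.states[m, frames].astype(float)
                u_new += self.h * fh * psf_fraction_at(
                    self._hits_pix, new_positions[m, frames], self.cal.psf, self.grid
                )
            delta += float(np.sum(self._hits_w * (_g(u_new) - _g(u_cur))))
        return delta

    # ----------------------------------------------------------- birth/death

    def _expected_rate_map(self, exclude: Optional[int] = None) -> np.ndarray:
        """Mean detection probability per binary exposure per pixel."""
        keep = [m for m in range(self.n_particles) if m != exclude]
        if not keep:
            return -np.expm1(-self.cal.dc)
        total = np.zeros(self.grid.shape)
        chunk = max(1, int(2_000_000 // max(self.grid.n_pixels, 1)))
        for lo in range(0, self.n_frames, chunk):
            hi = min(lo + chunk, self.n_frames)
            sub = TrackSet(
                self.positions[keep, lo:hi], self.states[keep, lo:hi]
            )
            u = expected_photons(sub, self.cal, self.grid)
            total += (-np.expm1(-u)).sum(axis=0)
        return total / self.n_frames

    def _proposal_map(self, exclude: Optional[int] = None) -> Optional[np.ndarray]:
        """Smoothed excess-detection image, normalized; None means uniform."""
        if self._n_unmasked == 0:
            return None
        obs = self._mean_rate.reshape(self.grid.shape)
        resid = np.clip(obs - self._expected_rate_map(exclude), 0.0, None)
        resid[~self.cal.mask] = 0.0
        resid = gaussian_filter(resid, sigma=self.sigma / self.grid.pixel_size)
        resid = np.clip(resid, 0.0, None)
        resid[~self.cal.mask] = 0.0
        total = resid.sum()
        if not np.isfinite(total) or total <= 0:
            return None
        return resid / total

    def _anchor_density(
        self, qmap: Optional[np.ndarray], positions: np.ndarray
    ) -> np.ndarray:
        """Birth anchor proposal density (per nm²) at positions ``(..., 2)``."""
        p = np.asarray(positions, dtype=float)
        in_fov = self.prior_cfg.positions_in_fov(p)
        floor = self.cfg.residual_floor if qmap is not None else 1.0
        dens = np.where(in_fov, floor / self.prior_cfg.fov_area, 0.0)
        if qmap is not None:
            a = self.grid.pixel_size
            j = np.clip((p[..., 0] // a).astype(np.intp), 0, self.grid.n_cols - 1)
            i = np.clip((p[..., 1] // a).astype(np.intp), 0, self.grid.n_rows - 1)
            on_grid = self.grid.contains(p)
            dens = dens + np.where(
                on_grid & in_fov, (1.0 - self.cfg.residual_floor) * qmap[i, j] / a**2, 0.0
            )
        return dens

    def _sample_anchor(
        self, qmap: Optional[np.ndarray], floor: Optional[float] = None
    ) -> np.ndarray:
        (x0, x1), (y0, y1) = self.prior_cfg.fov
        if floor is None:
            floor = self.cfg.residual_floor
        if qmap is None or self.rng.random() < floor:
            return np.array(
                [self.rng.uniform(x0, x1), self.rng.uniform(y0, y1)]
            )
        flat = self.rng.choice(qmap.size, p=qmap.ravel())
        i, j = divmod(int(flat), self.grid.n_cols)
        a = self.grid.pixel_size
        return np.array(
            [(j + self.rng.random()) * a, (i + self.rng.random()) * a]
        )

    def _propose_track(self, qmap: Optional[np.ndarray]) -> np.ndarray:
        n = self.n_frames
        anchor_frame = int(self.rng.integers(n))
        anchor = self._sample_anchor(qmap)
        sd = np.sqrt(self.msd)
        y = np.empty((n, 2))
        y[anchor_frame] = anchor
        if anchor_frame + 1 < n:
            steps = self.rng.normal(0.0, sd, size=(n - anchor_frame - 1, 2))
            y[anchor_frame + 1 :] = anchor + np.cumsum(steps, axis=0)
        if anchor_frame > 0:
            steps = self.rng.normal(0.0, sd, size=(anchor_frame, 2))
            y[:anchor_frame] = anchor - np.cumsum(steps, axis=0)[::-1]
        return y

    def _p_birth(self, m: int) -> float:
        if m >= self.prior_cfg.m_max:
            return 0.0
        if m == 0:
            return 1.0
        return 0.5

    def birth_death_move(self) -> None:
        """One reversible-jump move over the particle count."""
        m = self.n_particles
        p_b = self._p_birth(m)
        if self.rng.random() < p_b:
            self._birth_move(m)
        elif m > 0:
            self._death_move(m)

    def _birth_move(self, m: int) -> None:
        self.acceptance["birth"]["attempted"] += 1
        qmap = self._proposal_map()
        y = self._propose_track(qmap)
        if not self.prior_cfg.positions_in_fov(y[0]):
            return
        dens = self._anchor_density(qmap, y)
        mean_dens = float(dens.mean())  # (1/N) * sum over anchor frames
        if mean_dens <= 0:
            return
        f_new = np.ones(self.n_frames, dtype=np.uint8)
        dll = self._track_delta_loglik(y, f_new, +1.0)
        log_alpha = (
            dll
            + truncated_poisson_logpmf(m + 1, self.prior_cfg.m_mean, self.prior_cfg.m_max)
            - truncated_poisson_logpmf(m, self.prior_cfg.m_mean, self.prior_cfg.m_max)
            - np.log(self.prior_cfg.fov_area)
            - np.log(mean_dens)
            + np.log(1.0 - self._p_birth(m + 1))  # reverse move selection
            - np.log(self._p_birth(m))
        )
        # no 1/(M+1) particle-selection factor: with an exchangeable target
        # the reverse death of any insertion position returns the same state
        if np.isnan(log_alpha):
            return
        if np.log(self.rng.random()) < log_alpha:
            self.positions = np.concatenate([self.positions, y[None]], axis=0)
            self.states = np.concatenate([self.states, f_new[None]], axis=0)
            self.loglik += dll
            self.acceptance["birth"]["accepted"] += 1

    def _death_move(self, m: int) -> None:
        self.acceptance["death"]["attempted"] += 1
        j = int(self.rng.integers(m))
        qmap = self._proposal_map(exclude=j)
        y = self.positions[j]
        dens = self._anchor_density(qmap, y)
        mean_dens = float(dens.mean())
        dll = self._track_delta_loglik(y, self.states[j], -1.0)
        if mean_dens <= 0:
            return
        log_alpha = (
            dll
            + truncated_poisson_logpmf(m - 1, self.prior_cfg.m_mean, self.prior_cfg.m_max)
            - truncated_poisson_logpmf(m, self.prior_cfg.m_mean, self.prior_cfg.m_max)
            + np.log(self.prior_cfg.fov_area)
            + np.log(mean_dens)
            + np.log(self._p_birth(m - 1))  # reverse move selection
            - np.log(1.0 - self._p_birth(m))
        )
        if np.isnan(log_alpha):
            return
        if np.log(self.rng.random()) < log_alpha:
            self.positions = np.delete(self.positions, j, axis=0)
            self.states = np.delete(self.states, j, axis=0)
            self.loglik += dll
            self.acceptance["death"]["accepted"] += 1

    # ------------------------------------------------------------------ setup

    def _initialize(self, init_tracks: Optional[TrackSet]) -> None:
        cfg = self.cfg
        for attempt in range(cfg.max_init_retries):
            if init_tracks is not None:
                self.positions = init_tracks.positions.copy()
                self.states = init_tracks.states.copy()
            elif cfg.mode == "parametric" and cfg.n_particles:
                # initial anchors come purely from the detection image: the
                # uniform exploration floor is an MCMC-reversibility device
                # and would strand a cold start away from the data
                qmap = self._empty_state_map()
                anchors = np.stack(
                    [
                        self._sample_anchor(qmap, floor=0.0)
                        for _ in range(cfg.n_particles)
                    ]
                )
                self.positions = np.repeat(
                    anchors[:, None, :], self.n_frames, axis=1
                )
                self.states = np.ones(
                    (cfg.n_particles, self.n_frames), dtype=np.uint8
                )
            else:
                self.positions = np.zeros((0, self.n_frames, 2))
                self.states = np.zeros((0, self.n_frames), dtype=np.uint8)
            self.loglik = self.full_log_likelihood()
            if np.isfinite(self.log_posterior()):
                return
            if init_tracks is not None or self.n_particles == 0:
                break  # retrying cannot change anything
        raise RuntimeError(
            "initialization produced a non-finite log-posterior "
            f"(log-likelihood {self.loglik}); detections on pixels with zero "
            "expected rate usually indicate a missing dark-count calibration"
        )

    def _empty_state_map(self) -> Optional[np.ndarray]:
        saved = (self.positions, self.states)
        self.positions = np.zeros((0, self.n_frames, 2))
        self.states = np.zeros((0, self.n_frames), dtype=np.uint8)
        try:
            return self._proposal_map()
        finally:
            self.positions, self.states = saved

    # -------------------------------------------------------------- main loop

    def sweep(self, sweep_index: int) -> None:
        cfg = self.cfg
        if cfg.update_positions:
            self.update_tracks()
        if cfg.mode == "nonparametric" and (
            self.rng.random() < cfg.birth_death_prob
        ):
            self.birth_death_move()
        delay = (
            cfg.msd_delay if cfg.msd_delay is not None else cfg.burn_in // 3
        )
        # the conjugate Gibbs draw starts only after the early burn-in: from
        # a cold (constant-track) initialization the increments carry no
        # information and the draw would collapse MSD and freeze the chain;
        # the likelihood-informed rescale move runs from the start so the
        # chain can descend the position-MSD funnel while positions adapt
        if cfg.update_msd:
            if sweep_index >= delay:
                self.update_msd()
            for _ in range(cfg.n_msd_rescale):
                self.update_msd_rescale()

    def _adapt_step(self) -> None:
        win = self._adapt_window
        if win["attempted"]:
            rate = win["accepted"] / win["attempted"]
            self.step_nm = float(
                np.clip(self.step_nm * np.exp(rate - self.cfg.target_accept), 1e-3, 1e6)
            )
            self.shift_nm = float(
                np.clip(self.shift_nm * np.exp(rate - self.cfg.target_accept), 1e-3, 1e6)
            )
            win["accepted"] = 0
            win["attempted"] = 0
        for scale, bwin in self._block_windows.items():
            if bwin["attempted"]:
                rate = bwin["accepted"] / bwin["attempted"]
                self.block_steps[scale] = float(
                    np.clip(
                        self.block_steps[scale]
                        * np.exp(rate - self.cfg.target_accept),
                        1e-3,
                        1e6,
                    )
                )
                bwin["accepted"] = 0
                bwin["attempted"] = 0

    def _check_drift(self) -> None:
        full = self.full_log_likelihood()
        err = abs(full - self.loglik)
        denom = max(1.0, abs(full))
        self.diagnostics["loglik_delta_max_error"] = max(
            self.diagnostics["loglik_delta_max_error"], err / denom
        )
        self.diagnostics["n_recomputes"] += 1
        self.loglik = full

    def run(self) -> PosteriorEnsemble:
        cfg = self.cfg
        total = cfg.burn_in + cfg.n_samples * cfg.thin
        samples: list[PosteriorSample] = []
        for sweep_index in range(total):
            self.sweep(sweep_index)
            if cfg.adapt and sweep_index < cfg.burn_in:
                if (sweep_index + 1) % cfg.adapt_interval == 0:
                    self._adapt_step()
            if cfg.recompute_every and (sweep_index + 1) % cfg.recompute_every == 0:
                self._check_drift()
            if sweep_index >= cfg.burn_in:
                if (sweep_index - cfg.burn_in) % cfg.thin == cfg.thin - 1:
                    samples.append(
                        PosteriorSample(
                            n_particles=self.n_particles,
                            tracks=self.tracks(),
                            msd=float(self.msd),
                            log_posterior=self.log_posterior(),
                        )
                    )
        self._check_drift()
        diagnostics = dict(self.diagnostics)
        diagnostics["final_step_nm"] = self.step_nm
        return PosteriorEnsemble(
            samples=samples,
            acceptance={k: dict(v) for k, v in self.acceptance.items()},
            diagnostics=diagnostics,
            frame_interval=self.stack.frame_interval,
        )


# ------------------------------------------------------------------ wrappers


def run(
    stack: FrameStack,
    cal: Calibration,
    prior_cfg: Optional[PriorConfig] = None,
    sampler_cfg: Optional[SamplerConfig] = None,
    init_tracks: Optional[TrackSet] = None,
) -> PosteriorEnsemble:
    """Draw a posterior ensemble for one frame stack.

    Runs burn-in (with step adaptation), then records ``n_samples`` thinned
    samples with per-move acceptance diagnostics.  Identical configuration,
    data, and seed reproduce the ensemble exactly.
    """
    chain = Chain(stack, cal, prior_cfg, sampler_cfg, init_tracks)
    return chain.run()


def update_tracks(chain: Chain) -> None:
    """One Metropolis position sweep (both parities + translation) per particle."""
    chain.update_tracks()


def update_msd(chain: Chain) -> None:
    """One conjugate Gibbs draw of MSD (prior draw when no particles)."""
    chain.update_msd()


def birth_death_move(chain: Chain) -> None:
    """One reversible-jump birth/death attempt over the particle count."""
    chain.birth_death_move()


def upsample_tracks(tracks: TrackSet, factor: int, n_frames: int | None = None) -> TrackSet:
    """Linearly interpolate coarse (e.g. binned-frame) tracks to a finer grid.

    Each coarse frame is taken to represent the centre of its ``factor``
    constituent fine frames.  Used to warm-start inference on native binary
    frames from tracks obtained on longer effective exposures, which is the
    recommended workflow when the per-frame signal is far below one photon.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    n_coarse = tracks.n_frames
    if n_frames is None:
        n_frames = n_coarse * factor
    coarse_t = (np.arange(n_coarse) + 0.5) * factor
    fine_t = np.arange(n_frames) + 0.5
    m = tracks.n_particles
    fine = np.empty((m, n_frames, 2))
    for i in range(m):
        for axis in (0, 1):
            fine[i, :, axis] = np.interp(
                fine_t, coarse_t, tracks.positions[i, :, axis]
            )
    states = np.repeat(tracks.states, factor, axis=1)[:, :n_frames]
    if states.shape[1] < n_frames:
        pad = np.repeat(states[:, -1:], n_frames - states.shape[1], axis=1)
        states = np.concatenate([states, pad], axis=1)
    return TrackSet(fine, states)


def credible_intervals(ensemble: PosteriorEnsemble, level: float = 0.95) -> dict:
    """Per-frame, per-axis empirical quantile intervals of the tracks.

    Uses the samples whose particle count equals the posterior mode; each
    sample's particles are matched to the MAP sample's by minimum mean
    distance (Hungarian assignment) to remove label switching.  ``level = 0``
    collapses both bounds to the median track.

    Returns a dict with ``median``, ``low``, ``high`` arrays of shape
    ``(M, N, 2)`` plus ``level`` and ``n_particles``.
    """
    if not 0.0 <= level < 1.0:
        raise ValueError("level must lie in [0, 1)")
    if not ensemble.samples:
        raise ValueError("ensemble is empty")
    m_mode = ensemble.modal_m
    subset = [s for s in ensemble.samples if s.n_particles == m_mode]
    values = np.array([s.log_posterior for s in subset])
    ref = subset[int(np.argmax(values))].tracks.positions
    if m_mode == 0:
        empty = np.zeros((0, ensemble.samples[0].tracks.n_frames, 2))
        return {
            "median": empty,
            "low": empty,
            "high": empty,
            "level": level,
            "n_particles": 0,
        }
    aligned = np.empty((len(subset),) + ref.shape)
    for idx, s in enumerate(subset):
        pos = s.tracks.positions
        cost = np.linalg.norm(
            pos[:, None, :, :] - ref[None, :, :, :], axis=-1
        ).mean(axis=-1)
        rows, cols = linear_sum_assignment(cost)
        order = np.empty(m_mode, dtype=int)
        order[cols] = rows
        aligned[idx] = pos[order]
    lo_q, hi_q = 0.5 - level / 2.0, 0.5 + level / 2.0
    return {
        "median": np.quantile(aligned, 0.5, axis=0),
        "low": np.quantile(aligned, lo_q, axis=0),
        "high": np.quantile(aligned, hi_q, axis=0),
        "level": level,
        "n_particles": m_mode,
    }
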