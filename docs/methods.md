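# Methods

This note documents the model, the numerical and design choices, and what
the synthetic studies do and do not demonstrate.

## Observation model

Single-photon detector pixels report, per exposure, only whether at least
one photon was registered. Photon arrivals at pixel `p` in frame `n` are
Poisson with mean `u_np`, so the binary datum is
`w_np ~ Bernoulli(1 − exp(−u_np))`. The expected count decomposes as

    u_np = DC_p + h · Σ_m f_nm · ∬_A PSF(q; x_nm) dq

- `DC_p` — expected dark counts per exposure, per pixel. Dark counts are
  thermal false detections; hot pixels are simply pixels with large `DC_p`
  and are *modeled*, not discarded, because an unmodeled hot pixel can
  masquerade as an extra stationary emitter.
- `F_p` — boolean usable flag. Dead or disconnected pixels contribute
  exactly zero terms to the likelihood (not zero-valued observations).
- `h` — brightness: expected photons per exposure delivered by one
  in-focus bright emitter, whose PSF mass integrates to 1 over the plane.
  Brightness calibration is what lets the sampler distinguish "one bright
  emitter" from "two overlapping dim ones". `h` is a user input here; with
  an emission rate `R` (photons/s) and exposure `Δt`, `h = R·Δt`.
- `f_nm` — fixed 0/1 photophysical (bright/dark) state per particle and
  frame, all-bright by default. Blinking inference is out of scope.

Because fluorescence lifetimes (~10 ns) are utterly negligible against the
exposure (≥10 μs), a photon excited in one frame is detected in a later
frame with probability `exp(−(1−ε)Δt/τ)` (ε the excitation phase), about
`exp(−500) ≈ 7×10⁻²¹⁸` at 10 μs — frames are independent, and the
likelihood factorizes over frames and pixels
(`post_frame_emission_probability` computes the bound). This factorization
is also the parallelization contract: `chunked_log_likelihood` evaluates any
partition of the (frame, pixel) index set and recovers the total exactly,
which is the extension point for distributed or GPU execution.

**Binned frames.** A frame formed by summing `k` binary exposures is, under
the same generative model, exactly `Binomial(k, 1 − exp(−u))` with `u` per
constituent exposure; at `k = 1` this reduces to the Bernoulli form. We use
this exact form rather than a Gaussian or Poisson approximation.

**Numerics.** `log(1 − exp(−u))` is evaluated with a `log(−expm1(−u))` /
`log1p(−exp(−u))` branch split at `u = ln 2`, accurate down to the
dark-count regime `u ~ 10⁻³`. An observed detection at `u = 0` returns
`−inf` rather than raising, so samplers reject impossible proposals
uniformly.

## PSF

The pixel-integrated PSF is a symmetric 2D Gaussian with
`σ = 0.21·λ/NA` (the standard Gaussian fit to the Airy profile; e.g.
NA 1.45 at λ 665 nm gives σ ≈ 96 nm, consistent with a ~250 nm PSF
radius). The pixel integral is then a product of two 1D Gaussian CDF
differences over pixel edges — closed-form, vectorizable, and verified in
the tests against adaptive 2D quadrature to 1e-10. `σ` is user-overridable
for calibrated systems; Airy, astigmatic, and z-dependent PSFs are
out of scope. Positions are 2D: all tracked motion here is planar
(membrane-bound or stage-driven), and the observation model has no axial
information to offer without an engineered PSF.

Coordinates: positions in nm, x along columns, y along rows; pixel `(i, j)`
is the half-open square `[j·a, (j+1)·a) × [i·a, (i+1)·a)` for pixel size
`a`. This convention round-trips exactly between simulator and inference.

## Priors

- **Motion**: `x_n ~ Normal(x_{n−1}, MSD·I)` per axis. `MSD` is defined as
  the per-axis displacement variance per frame interval (nm²), so
  `D = MSD/(2Δt)`. This single documented convention resolves the
  ambiguity between writing the increment variance as "MSD" or "2·MSD";
  every conversion in the package uses it.
- **Initial position**: uniform over a configurable field-of-view
  rectangle (default: the pixel grid).
- **Particle count**: Poisson(mean 1) truncated at `m_max` (default 20) —
  weakly informative; the likelihood, via brightness calibration,
  dominates the count inference.
- **MSD**: inverse-gamma(shape 2, scale = prior-mean guess), positive
  support, infinite variance (weakly informative), and conjugate to the
  Gaussian increments, giving an exact Gibbs update.

These priors primarily fix the support of each variable; all are proper.

## Sampler

Metropolis-within-Gibbs over `(M, tracks, MSD)`:

1. **Positions.** Frames of equal parity are conditionally independent
   given the complementary parity (the motion prior couples only adjacent
   frames), so all even frames of one particle are updated in a single
   vectorized Metropolis block, then all odd frames. Two proposal types
   run every sweep: a Gaussian random walk (step adapted toward 0.3
   acceptance during burn-in only, then frozen so the stationary target is
   untouched), and an independence "jump" proposal drawn from that frame's
   own detection image (dark-count-subtracted counts, Gaussian-jittered at
   the PSF scale, mixed with a uniform floor so the proposal density is
   bounded below; the Metropolis–Hastings correction uses the explicit
   mixture density). Jumps let a frame lock directly onto its photons from
   anywhere in the FOV, which random walks cannot do across a flat
   likelihood. Between the single-frame and whole-track scales,
   *block-translation* moves shift contiguous blocks of frames (default
   scales 16 and 64, random phase each call, alternating block parity)
   jointly: only the two boundary edges pay a motion-prior cost, so the
   collective "wiggle" modes that dominate the autocorrelation of smoothed
   tracks mix directly — without them, per-frame credible intervals
   under-disperse badly at feasible chain lengths. A whole-track
   translation move handles global offsets. Block and single-frame steps
   adapt independently during burn-in.
2. **MSD.** Exact conjugate inverse-gamma Gibbs draw given displacements —
   interwoven with a *non-centered* move that proposes `MSD' = MSD·e^ε`
   and rescales every track's increments by `√(MSD'/MSD)` about its first
   frame. In the non-centered parameterization the increment prior cancels
   exactly, leaving only the MSD prior (with log-scale Jacobian) and the
   likelihood ratio. The interweaving is essential: the centered Gibbs
   draw alone mixes pathologically in the position–MSD "funnel" (sampled
   increments always mirror the current MSD, so MSD barely moves).
   Both MSD updates start only after a third of burn-in: from a cold
   (constant-track) initialization the increments carry no information, so
   the Gibbs draw would collapse MSD toward zero while the rescale move
   would random-walk it under its heavy-tailed prior — either way stranding
   the chain before the positions have adapted to the data.
3. **Particle count** (nonparametric mode). Reversible-jump birth/death.
   A birth anchors a new track at a position drawn from the smoothed
   *residual* image (observed detection rate minus the rate expected under
   the current tracks, clipped at zero, Gaussian-smoothed at the PSF
   scale, uniform floor weight 0.1) at a uniformly chosen anchor frame,
   and extends it in both directions with motion-prior increments. The
   proposal density of the whole track is evaluated as a mixture over all
   N possible anchor frames, so the reverse (death) density is exactly
   computable, and the increment factors cancel analytically against the
   motion prior. Death removes a uniformly chosen particle, with the
   residual map recomputed excluding it. The acceptance ratio contains
   **no** 1/(M+1) selection factor: with an exchangeable target the
   reverse death of any insertion position returns the same state, and the
   factor cancels — the flat-likelihood test (below) detects this exactly,
   recovering the truncated-Poisson marginal only with the correct ratio.

Likelihood deltas exploit binary-data structure: per frame the
log-likelihood is `−k·Σ_p u_p + Σ_{w>0} w·(u + log(1−e^{−u}))` plus
binomial constants, so a position change needs only (a) the closed-form
total PSF mass over the unmasked grid and (b) the sparse set of pixels that
actually fired. All deltas are exact; a periodic full recomputation bounds
floating-point drift (observed ≤ 1e-15 relative; asserted ≤ 1e-6).

One seeded generator drives all randomness in a fixed documented order
(position halves, jumps, shift, birth/death, MSD), so identical
configuration and data reproduce ensembles exactly.

**Initialization.** Parametric mode anchors constant tracks at draws from
the empty-state residual map *without* the uniform exploration floor — the
floor is a reversibility device for the birth proposal, and at a cold start
it would strand a fraction of runs far from the data with no way back (or
uses user-supplied warm-start tracks —
recommended, and supported via `upsample_tracks`, when per-frame signal is
far below one photon: track the binned stack first, interpolate, refine).
Nonparametric mode starts empty and lets births discover emitters. A
non-finite initial posterior after retries raises with a diagnostic (it
almost always means a detection on a zero-dark-count pixel, i.e. a missing
calibration).

**Point estimates and uncertainty.** The MAP sample is the retained draw
with the highest joint log-posterior (earliest among ties). Credible
intervals are per-frame, per-axis empirical quantiles over the samples at
the modal particle count, after Hungarian matching of particle labels to
the MAP sample to remove label switching.

## Simulator

The simulator draws trajectories (free diffusion with per-axis increment
variance `2DΔt`; or the piezo-stage protocol of constant dwells separated
by instantaneous 200 nm axis-aligned steps; or immobile emitters), renders
binary frames with *exactly* the likelihood's expected-photon field, and
applies the frame manipulations studied here (k-fold binning, stroboscopic
subsetting). Dark-count maps are constant or log-normal with a configurable
fraction of 100× hot pixels and dead pixels, emulating real SPAD-array
defect statistics.

What it does **not** emulate: intra-exposure motion blur within one binary
frame (positions are sampled once per frame, matching the observation
model; at 10–50 μs the per-frame displacement is small against a pixel for
the D range studied), afterpulsing, pixel crosstalk, read noise (SPADs have
none), and blinking kinetics (states are fixed inputs). Passing tests
therefore validate the inference under the stated model, including
realistic defect maps — not under optical aberrations or photophysics the
model excludes. Note that *k-fold binned* frames do contain genuine motion
blur (the particle moves across the k constituent frames), which is exactly
the effect the exposure-bias study measures.

## Validation studies and problem sizes

Three end-to-end protocols (`spadtrack.experiments`) run both in the test
suite (reduced sizes) and in `scripts/acceptance.py`:

- **Two-emitter counting/tracking**: 1,500 frames (1,000 in tests), 32×32
  ROI, 10 μs, NA 1.45/665 nm optics, h = 2, log-normal dark counts,
  separation 400 nm, nonparametric. Checks modal M = 2 and MAP-track
  deviation below ~50 nm.
- **Exposure bias**: D = 5 μm²/s, 50 μs frames, NA 1.49, 100 nm pixels,
  ~15,000 photons/s; 40 bins of k = 255 (12.75 ms). The ROI (96×96) is
  centred on the trajectory, as an experimenter would choose it; rare
  excursions beyond the ROI trigger a redraw. The emission wavelength is
  taken as 590 nm (Atto565-like). Reports the relative bias of the
  binned-frame D estimate; the test additionally verifies the bias is
  downward relative to a native-frame estimate warm-started from the
  binned track.
- **Piezo protocol**: 40 ms dwells (4,000 frames at 10 μs), 200 nm steps,
  3 steps (2 in tests), h = 5, 24×24 ROI, parametric M = 1. The MAP track
  is segmented into dwells by median-filtered change-point detection and
  the mean inter-dwell displacement is compared to 200 nm.

Sizes were chosen so each study carries enough photons for the quantity it
checks while completing in minutes on one CPU; they are stated here so the
numbers are interpretable as scaled-down replications of the corresponding
full-scale experiments.

## Known limitations

- Single global MSD shared by all particles; no state switching or
  anomalous diffusion.
- 2D only; the Rayleigh jump-distance prediction deliberately raises for
  3D rather than silently using the wrong form.
- Cold-start inference at ≪1 photon/frame/emitter on large fields relies
  on the warm-start workflow; a cold chain can stall in a diffuse mode
  where the track explains scattered dark counts.
- Change-point dwell segmentation assumes dwell durations well above the
  smoothing window and steps well above the tracking noise.
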