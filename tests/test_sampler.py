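"""MCMC kernels: prior recovery, conjugacy, determinism, bookkeeping."""

import numpy as np
import pytest
from scipy import stats

from spadtrack import (
    Calibration,
    FrameStack,
    PixelGrid,
    PosteriorSample,
    PriorConfig,
    SamplerConfig,
    SimConfig,
    TrackSet,
    credible_intervals,
    make_calibration,
    render_frames,
    run,
    simulate_tracks,
)
from spadtrack.sampler import Chain, PosteriorEnsemble, upsample_tracks


def masked_problem(n_frames=50, shape=(8, 8), seed=0, m_particles=1, **prior_kw):
    """A stack whose pixels are all defective: the likelihood is flat."""
    grid = PixelGrid(*shape, 100.0)
    from spadtrack import PsfModel

    cal = Calibration(
        dc=np.zeros(shape),
        mask=np.zeros(shape, dtype=bool),
        h=1.0,
        psf=PsfModel(96.0),
    )
    stack = FrameStack(
        counts=np.zeros((n_frames, *shape), dtype=np.uint8), exposure=1e-5, grid=grid
    )
    prior_defaults = dict(
        fov=((0.0, grid.width), (0.0, grid.height)), msd_mean=100.0
    )
    prior_defaults.update(prior_kw)
    prior = PriorConfig(**prior_defaults)
    init = None
    if m_particles:
        rng = np.random.default_rng(seed)
        init = TrackSet(
            np.tile(rng.uniform(200, 600, (m_particles, 1, 2)), (1, n_frames, 1))
        )
    return stack, cal, prior, init


def small_signal_problem(seed=3, n_frames=250):
    cfg = SimConfig(
        kind="brownian", n_frames=n_frames, msd=50.0, h=3.0,
        n_rows=16, n_cols=16, exposure=1e-5, dc=1e-3,
    )
    rng = np.random.default_rng(seed)
    tracks = simulate_tracks(cfg, rng)
    cal = make_calibration(cfg, rng)
    stack = render_frames(tracks, cal, cfg.grid, cfg.exposure, rng)
    prior = PriorConfig(
        fov=((0.0, cfg.grid.width), (0.0, cfg.grid.height)), msd_mean=100.0
    )
    return stack, cal, prior, tracks


class TestDeterminism:
    def test_identical_seed_identical_ensembles(self):
        stack, cal, prior, truth = small_signal_problem()
        cfg = SamplerConfig(
            mode="parametric", n_particles=1, n_samples=20, burn_in=20, seed=9
        )
        e1 = run(stack, cal, prior, cfg)
        e2 = run(stack, cal, prior, cfg)
        np.testing.assert_array_equal(e1.msd_samples, e2.msd_samples)
        for s1, s2 in zip(e1.samples, e2.samples):
            np.testing.assert_array_equal(s1.tracks.positions, s2.tracks.positions)
            assert s1.log_posterior == s2.log_posterior

    def test_zero_steps_freeze_the_chain(self):
        stack, cal, prior, init = masked_problem()
        cfg = SamplerConfig(
            mode="parametric", n_particles=1, step_nm=0.0, shift_nm=0.0,
            use_frame_jumps=False, update_msd=False, adapt=False,
            n_samples=10, burn_in=5, seed=1,
        )
        ens = run(stack, cal, prior, cfg, init_tracks=init)
        first = ens.samples[0]
        for s in ens.samples[1:]:
            np.testing.assert_array_equal(s.tracks.positions, first.tracks.positions)
            assert s.log_posterior == first.log_posterior

    def test_zero_delta_proposal_always_accepted(self):
        # Metropolis rule min(1, e^0) = 1
        stack, cal, prior, init = masked_problem()
        cfg = SamplerConfig(mode="parametric", n_particles=1, seed=4)
        chain = Chain(stack, cal, prior, cfg, init_tracks=init)
        x_new = chain.positions[0, ::2] + 1.0
        K = x_new.shape[0]
        chain._accept_frames(0, 0, x_new, np.zeros(K), np.zeros(K), "single_frame")
        assert chain.acceptance["single_frame"]["accepted"] == K


class TestPriorRecovery:
    def test_flat_likelihood_recovers_motion_prior_variance(self):
        # with every pixel masked the position sweep targets the motion prior:
        # sampled displacement variance must converge to the configured MSD
        stack, cal, prior, init = masked_problem(n_frames=50)
        cfg = SamplerConfig(
            mode="parametric", n_particles=1, update_msd=False, seed=11,
            n_samples=8000, burn_in=12000, thin=1, msd_init=100.0,
            recompute_every=0, use_frame_jumps=False,
        )
        chain = Chain(stack, cal, prior, cfg, init_tracks=init)
        total = cfg.burn_in + cfg.n_samples
        ss, count = 0.0, 0
        for i in range(total):
            chain.sweep(i)
            if cfg.adapt and i < cfg.burn_in and (i + 1) % cfg.adapt_interval == 0:
                chain._adapt_step()
            if i >= cfg.burn_in:
                inc = np.diff(chain.positions[0], axis=0)
                ss += float(np.sum(inc * inc))
                count += inc.size
        assert ss / count == pytest.approx(100.0, rel=0.05)

    def test_msd_gibbs_matches_conjugate_posterior(self):
        # fixed tracks: the Gibbs conditional is inverse-gamma with
        # shape a0 + n/2 and scale b0 + SS/2
        stack, cal, prior, init = masked_problem(n_frames=40, seed=5)
        rng = np.random.default_rng(6)
        pos = np.cumsum(rng.normal(0, 9.0, (1, 40, 2)), axis=1) + 400.0
        init = TrackSet(pos)
        cfg = SamplerConfig(
            mode="parametric", n_particles=1, update_positions=False, seed=7
        )
        chain = Chain(stack, cal, prior, cfg, init_tracks=init)
        draws = []
        for _ in range(3000):
            chain.update_msd()
            draws.append(chain.msd)
        inc = np.diff(pos, axis=1)
        shape = prior.msd_shape + inc.size / 2
        scale = prior.msd_scale + float(np.sum(inc * inc)) / 2
        ks = stats.kstest(draws, stats.invgamma(shape, scale=scale).cdf)
        assert ks.pvalue > 0.01

    def test_msd_prior_draw_when_no_particles(self):
        stack, cal, prior, _ = masked_problem(m_particles=0)
        cfg = SamplerConfig(mode="nonparametric", seed=8, birth_death_prob=0.0)
        chain = Chain(stack, cal, prior, cfg)
        draws = []
        for _ in range(2000):
            chain.update_msd()
            draws.append(chain.msd)
        ks = stats.kstest(
            draws, stats.invgamma(prior.msd_shape, scale=prior.msd_scale).cdf
        )
        assert ks.pvalue > 0.01

    def test_birth_death_recovers_truncated_poisson(self):
        # flat likelihood: the particle-count marginal is the truncated
        # Poisson prior
        stack, cal, prior, _ = masked_problem(
            n_frames=10, m_particles=0, m_max=5, m_mean=1.0
        )
        cfg = SamplerConfig(
            mode="nonparametric", seed=13, update_msd=False, msd_init=100.0,
            use_frame_jumps=False, adapt=False, recompute_every=0,
        )
        chain = Chain(stack, cal, prior, cfg)
        counts = np.zeros(prior.m_max + 1)
        burn, keep = 2000, 30000
        for i in range(burn + keep):
            chain.update_tracks()
            chain.birth_death_move()
            if i >= burn:
                counts[chain.n_particles] += 1
        probs = np.exp(
            [
                stats.poisson.logpmf(m, 1.0)
                for m in range(prior.m_max + 1)
            ]
        )
        probs /= probs.sum()
        expected = probs * counts.sum()
        keep_bins = expected > 5
        # thin the correlated chain by pooling: chi-square on pooled counts is
        # anti-conservative, so require only gross agreement
        rel = counts[keep_bins] / counts.sum()
        np.testing.assert_allclose(rel, probs[keep_bins], atol=0.04)

    def test_death_at_zero_particles_is_noop(self):
        stack, cal, prior, _ = masked_problem(m_particles=0)
        cfg = SamplerConfig(mode="nonparametric", seed=14)
        chain = Chain(stack, cal, prior, cfg)
        for _ in range(50):
            chain.birth_death_move()
            assert 0 <= chain.n_particles <= prior.m_max


class TestBookkeeping:
    def test_delta_updates_match_full_recompute(self):
        stack, cal, prior, _ = small_signal_problem(seed=21)
        cfg = SamplerConfig(
            mode="parametric", n_particles=1, n_samples=50, burn_in=100,
            seed=22, recompute_every=50,
        )
        ens = run(stack, cal, prior, cfg)
        assert ens.diagnostics["loglik_delta_max_error"] < 1e-6

    def test_map_tie_breaks_to_earliest(self):
        t = TrackSet(np.zeros((1, 3, 2)))
        samples = [
            PosteriorSample(1, t, 10.0, -5.0),
            PosteriorSample(1, t, 20.0, -3.0),
            PosteriorSample(1, t, 30.0, -3.0),
        ]
        ens = PosteriorEnsemble(
            samples=samples, acceptance={}, diagnostics={}, frame_interval=1e-5
        )
        assert ens.map_sample.msd == 20.0

    def test_log_posterior_finite_for_all_samples(self):
        stack, cal, prior, _ = small_signal_problem(seed=23)
        cfg = SamplerConfig(
            mode="parametric", n_particles=1, n_samples=30, burn_in=50, seed=24
        )
        ens = run(stack, cal, prior, cfg)
        assert np.all(np.isfinite([s.log_posterior for s in ens.samples]))

    def test_initialization_error_on_impossible_data(self, psf_typical):
        # a detection on a pixel with zero expected rate and no particles
        grid = PixelGrid(4, 4, 100.0)
        counts = np.zeros((5, 4, 4), dtype=np.uint8)
        counts[0, 2, 2] = 1
        stack = FrameStack(counts=counts, exposure=1e-5, grid=grid)
        cal = Calibration(
            dc=np.zeros((4, 4)), mask=np.ones((4, 4), bool), h=1.0, psf=psf_typical
        )
        cfg = SamplerConfig(mode="nonparametric", seed=1)
        with pytest.raises(RuntimeError, match="non-finite"):
            Chain(stack, cal, None, cfg)

    def test_stationarity_no_drift_from_posterior_sample(self):
        # Geweke-style: log-posterior of first vs last third of a long chain
        # started from an equilibrated state shows no systematic drift
        stack, cal, prior, _ = small_signal_problem(seed=31, n_frames=120)
        cfg = SamplerConfig(
            mode="parametric", n_particles=1, n_samples=900, burn_in=300, seed=32
        )
        ens = run(stack, cal, prior, cfg)
        lp = np.array([s.log_posterior for s in ens.samples])
        a, b = lp[:300], lp[-300:]
        # crude effective-sample correction for autocorrelation
        z = (a.mean() - b.mean()) / np.sqrt((a.var() + b.var()) / 30.0)
        assert abs(z) < 3.0


@pytest.fixture(scope="module")
def interval_ensemble():
    stack, cal, prior, _ = small_signal_problem(seed=41)
    cfg = SamplerConfig(
        mode="parametric", n_particles=1, n_samples=200, burn_in=150, seed=42
    )
    return run(stack, cal, prior, cfg)


class TestIntervalsAndModes:
    @pytest.fixture
    def ensemble(self, interval_ensemble):
        return interval_ensemble

    def test_intervals_widen_with_level(self, ensemble):
        narrow = credible_intervals(ensemble, 0.5)
        wide = credible_intervals(ensemble, 0.95)
        assert np.all(wide["low"] <= narrow["low"] + 1e-12)
        assert np.all(wide["high"] >= narrow["high"] - 1e-12)

    def test_level_zero_collapses_to_median(self, ensemble):
        point = credible_intervals(ensemble, 0.0)
        np.testing.assert_allclose(point["low"], point["median"])
        np.testing.assert_allclose(point["high"], point["median"])

    def test_invalid_level_rejected(self, ensemble):
        with pytest.raises(ValueError):
            credible_intervals(ensemble, 1.0)
        with pytest.raises(ValueError):
            credible_intervals(ensemble, -0.1)

    def test_parametric_mode_never_attempts_birth_death(self, ensemble):
        assert ensemble.acceptance["birth"]["attempted"] == 0
        assert ensemble.acceptance["death"]["attempted"] == 0


class TestUpsampleTracks:
    def test_constant_track_upsamples_to_constant(self):
        coarse = TrackSet(np.full((1, 4, 2), 300.0))
        fine = upsample_tracks(coarse, 10)
        assert fine.n_frames == 40
        np.testing.assert_allclose(fine.positions, 300.0)

    def test_linear_ramp_preserved(self):
        coarse = TrackSet(
            np.stack(
                [np.linspace(0, 300, 4), np.zeros(4)], axis=-1
            )[None]
        )
        fine = upsample_tracks(coarse, 100, 400)
        # fine positions interpolate the coarse ramp monotonically, holding
        # the endpoint values outside the coarse-sample support
        assert np.all(np.diff(fine.positions[0, :, 0]) >= 0)
        assert fine.positions[0, 0, 0] == pytest.approx(0.0)
        assert fine.positions[0, 399, 0] == pytest.approx(300.0)
        assert fine.positions[0, 200, 0] == pytest.approx(150.0, abs=2.0)
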