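"""Observation model: expected photons, Bernoulli/binomial likelihood, chunking."""

import numpy as np
import pytest
from scipy.special import gammaln

from spadtrack import (
    Calibration,
    FrameStack,
    PixelGrid,
    PsfModel,
    TrackSet,
    binned_log_likelihood,
    chunked_log_likelihood,
    estimate_dark_counts,
    expected_photons,
    log_likelihood,
    pixel_integral,
    post_frame_emission_probability,
)
from spadtrack.likelihood import log1mexp


def brute_force_loglik(counts, u, mask, k=1):
    """Oracle: naive triple loop over per-pixel Bernoulli/binomial masses."""
    total = 0.0
    n, rows, cols = counts.shape
    for t in range(n):
        for i in range(rows):
            for j in range(cols):
                if not mask[i, j]:
                    continue
                w = counts[t, i, j]
                p = 1.0 - np.exp(-u[t, i, j])
                comb = gammaln(k + 1) - gammaln(w + 1) - gammaln(k - w + 1)
                with np.errstate(divide="ignore"):
                    total += comb + w * np.log(p) + (k - w) * np.log1p(-p)
    return total


def make_stack(counts, grid, k=1):
    return FrameStack(counts=counts, exposure=1e-5, grid=grid, bin_count=k)


class TestExpectedPhotons:
    def test_no_particles_gives_dark_counts(self, grid8, flat_cal):
        tracks = TrackSet.empty(5)
        u = expected_photons(tracks, flat_cal, grid8)
        np.testing.assert_array_equal(u, np.broadcast_to(flat_cal.dc, (5, 8, 8)))

    def test_dark_state_frame_gives_dark_counts(self, grid8, flat_cal, rng):
        pos = rng.uniform(100, 700, size=(1, 4, 2))
        states = np.array([[1, 0, 1, 0]], dtype=np.uint8)
        u = expected_photons(TrackSet(pos, states), flat_cal, grid8)
        np.testing.assert_array_equal(u[1], flat_cal.dc)
        np.testing.assert_array_equal(u[3], flat_cal.dc)
        assert u[0].sum() > flat_cal.dc.sum()

    def test_single_particle_value_against_psf_oracle(self, grid8, psf_typical):
        # u = DC + h * fraction with h = 2, DC = 0.01
        cal = Calibration(
            dc=np.full((8, 8), 0.01),
            mask=np.ones((8, 8), dtype=bool),
            h=2.0,
            psf=psf_typical,
        )
        pos = np.array([[[330.0, 410.0]]])
        u = expected_photons(TrackSet(pos), cal, grid8)
        frac = pixel_integral((330.0, 410.0), (4, 3), psf_typical, grid8)
        assert u[0, 4, 3] == pytest.approx(0.01 + 2.0 * frac, rel=1e-12)

    def test_adding_particle_never_decreases_u(self, grid8, flat_cal, rng):
        one = TrackSet(rng.uniform(0, 800, size=(1, 6, 2)))
        two = TrackSet(
            np.concatenate([one.positions, rng.uniform(0, 800, size=(1, 6, 2))])
        )
        u1 = expected_photons(one, flat_cal, grid8)
        u2 = expected_photons(two, flat_cal, grid8)
        assert np.all(u2 >= u1 - 1e-15)


class TestLogLikelihood:
    def test_all_zero_data_zero_u_is_certain(self, grid8, psf_typical):
        cal = Calibration(
            dc=np.zeros((8, 8)), mask=np.ones((8, 8), bool), h=1.0, psf=psf_typical
        )
        stack = make_stack(np.zeros((3, 8, 8), dtype=np.uint8), grid8)
        assert log_likelihood(stack, np.zeros((3, 8, 8)), cal) == 0.0

    def test_single_pixel_closed_form(self, psf_typical):
        grid = PixelGrid(1, 1, 100.0)
        cal = Calibration(
            dc=np.zeros((1, 1)), mask=np.ones((1, 1), bool), h=1.0, psf=psf_typical
        )
        stack = make_stack(np.ones((1, 1, 1), dtype=np.uint8), grid)
        u = np.full((1, 1, 1), np.log(2.0))
        assert log_likelihood(stack, u, cal) == pytest.approx(np.log(0.5))

    def test_detection_at_zero_rate_is_minus_inf(self, psf_typical):
        grid = PixelGrid(1, 1, 100.0)
        cal = Calibration(
            dc=np.zeros((1, 1)), mask=np.ones((1, 1), bool), h=1.0, psf=psf_typical
        )
        stack = make_stack(np.ones((1, 1, 1), dtype=np.uint8), grid)
        assert log_likelihood(stack, np.zeros((1, 1, 1)), cal) == -np.inf

    def test_matches_brute_force_loop_oracle(self, grid8, psf_typical, rng):
        counts = (rng.random((10, 8, 8)) < 0.3).astype(np.uint8)
        u = rng.exponential(0.5, size=(10, 8, 8))
        mask = rng.random((8, 8)) > 0.1
        cal = Calibration(
            dc=np.zeros((8, 8)), mask=mask, h=1.0, psf=psf_typical
        )
        stack = make_stack(counts, grid8)
        assert log_likelihood(stack, u, cal) == pytest.approx(
            brute_force_loglik(counts, u, mask), rel=1e-12
        )

    def test_value_never_positive(self, grid8, flat_cal, rng):
        counts = (rng.random((5, 8, 8)) < 0.2).astype(np.uint8)
        u = rng.exponential(0.3, size=(5, 8, 8))
        assert log_likelihood(make_stack(counts, grid8), u, flat_cal) <= 0.0

    def test_masked_pixel_neutrality(self, grid8, psf_typical, rng):
        mask = np.ones((8, 8), bool)
        mask[2, 5] = False
        cal = Calibration(dc=np.full((8, 8), 0.01), mask=mask, h=1.0, psf=psf_typical)
        counts = (rng.random((6, 8, 8)) < 0.2).astype(np.uint8)
        u = rng.exponential(0.3, size=(6, 8, 8))
        base = log_likelihood(make_stack(counts, grid8), u, cal)
        toggled = counts.copy()
        toggled[:, 2, 5] = 1 - toggled[:, 2, 5]
        assert log_likelihood(make_stack(toggled, grid8), u, cal) == base

    def test_monotonicity_in_u(self):
        # w = 1: log-density nondecreasing in u; w = 0: strictly decreasing
        u = np.linspace(0.01, 5.0, 50)
        fired = log1mexp(u)
        assert np.all(np.diff(fired) >= 0)
        assert np.all(np.diff(-u) < 0)

    def test_factorizes_over_frames(self, grid8, flat_cal, rng):
        counts = (rng.random((4, 8, 8)) < 0.2).astype(np.uint8)
        u = rng.exponential(0.3, size=(4, 8, 8))
        whole = log_likelihood(make_stack(counts, grid8), u, flat_cal)
        parts = sum(
            log_likelihood(make_stack(counts[t : t + 1], grid8), u[t : t + 1], flat_cal)
            for t in range(4)
        )
        assert whole == pytest.approx(parts, rel=1e-12)


class TestBinnedLogLikelihood:
    def test_k1_equals_bernoulli(self, grid8, flat_cal, rng):
        counts = (rng.random((5, 8, 8)) < 0.2).astype(np.uint8)
        u = rng.exponential(0.3, size=(5, 8, 8))
        stack = make_stack(counts, grid8, k=1)
        assert binned_log_likelihood(stack, u, flat_cal) == log_likelihood(
            stack, u, flat_cal
        )

    def test_zero_u_zero_counts(self, grid8, psf_typical):
        cal = Calibration(
            dc=np.zeros((8, 8)), mask=np.ones((8, 8), bool), h=1.0, psf=psf_typical
        )
        stack = make_stack(np.zeros((2, 8, 8), dtype=np.uint8), grid8, k=4)
        assert binned_log_likelihood(stack, np.zeros((2, 8, 8)), cal) == 0.0

    def test_binomial_mass_closed_form(self, psf_typical):
        # k=15, u=0.1, w=3: log C(15,3) + 3 log(1-e^-0.1) + 12 (-0.1)
        grid = PixelGrid(1, 1, 100.0)
        cal = Calibration(
            dc=np.zeros((1, 1)), mask=np.ones((1, 1), bool), h=1.0, psf=psf_typical
        )
        stack = make_stack(np.full((1, 1, 1), 3, dtype=np.int64), grid, k=15)
        expected = (
            np.log(455.0) + 3 * np.log(1 - np.exp(-0.1)) + 12 * (-0.1)
        )
        got = binned_log_likelihood(stack, np.full((1, 1, 1), 0.1), cal)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_matches_brute_force_binomial(self, grid8, psf_typical, rng):
        k = 7
        counts = rng.integers(0, k + 1, size=(4, 8, 8))
        u = rng.exponential(0.3, size=(4, 8, 8))
        mask = rng.random((8, 8)) > 0.1
        cal = Calibration(dc=np.zeros((8, 8)), mask=mask, h=1.0, psf=psf_typical)
        stack = make_stack(counts, grid8, k=k)
        assert binned_log_likelihood(stack, u, cal) == pytest.approx(
            brute_force_loglik(counts, u, mask, k=k), rel=1e-12
        )

    def test_counts_above_bin_count_rejected(self, grid8):
        with pytest.raises(ValueError):
            FrameStack(
                counts=np.full((1, 8, 8), 5, dtype=np.int64),
                exposure=1e-5,
                grid=grid8,
                bin_count=4,
            )


class TestChunkedLogLikelihood:
    @pytest.fixture
    def problem(self, rng, psf_typical):
        grid = PixelGrid(12, 12, 100.0)
        cal = Calibration(
            dc=np.full((12, 12), 1e-3),
            mask=rng.random((12, 12)) > 0.05,
            h=2.0,
            psf=psf_typical,
        )
        tracks = TrackSet(rng.uniform(100, 1100, size=(2, 20, 2)))
        u = expected_photons(tracks, cal, grid)
        counts = (rng.random(u.shape) < (1 - np.exp(-u))).astype(np.uint8)
        stack = make_stack(counts, grid)
        return stack, tracks, cal, grid

    def test_single_chunk_equals_plain(self, problem):
        stack, tracks, cal, grid = problem
        u = expected_photons(tracks, cal, grid)
        plain = log_likelihood(stack, u, cal)
        assert chunked_log_likelihood(stack, tracks, cal, grid) == pytest.approx(
            plain, rel=1e-12
        )

    def test_frame_and_pixel_partitions_agree(self, problem):
        stack, tracks, cal, grid = problem
        n, npix = stack.n_frames, grid.n_pixels
        whole = chunked_log_likelihood(stack, tracks, cal, grid)
        by_frames = [
            (np.arange(lo, min(lo + 7, n)), np.arange(npix)) for lo in range(0, n, 7)
        ]
        by_pixels = [
            (np.arange(n), np.arange(lo, min(lo + 50, npix)))
            for lo in range(0, npix, 50)
        ]
        for chunks in (by_frames, by_pixels):
            value = chunked_log_likelihood(stack, tracks, cal, grid, chunks)
            assert value == pytest.approx(whole, rel=1e-9)

    def test_random_partitions_agree(self, problem, rng):
        stack, tracks, cal, grid = problem
        n, npix = stack.n_frames, grid.n_pixels
        whole = chunked_log_likelihood(stack, tracks, cal, grid)
        for _ in range(16):
            frame_cut = int(rng.integers(1, n))
            pix_cut = int(rng.integers(1, npix))
            chunks = [
                (np.arange(frame_cut), np.arange(pix_cut)),
                (np.arange(frame_cut), np.arange(pix_cut, npix)),
                (np.arange(frame_cut, n), np.arange(pix_cut)),
                (np.arange(frame_cut, n), np.arange(pix_cut, npix)),
            ]
            assert chunked_log_likelihood(
                stack, tracks, cal, grid, chunks
            ) == pytest.approx(whole, rel=1e-9)

    def test_incomplete_or_overlapping_partition_rejected(self, problem):
        stack, tracks, cal, grid = problem
        n, npix = stack.n_frames, grid.n_pixels
        with pytest.raises(ValueError):
            chunked_log_likelihood(
                stack, tracks, cal, grid, [(np.arange(n - 1), np.arange(npix))]
            )
        with pytest.raises(ValueError):
            chunked_log_likelihood(
                stack,
                tracks,
                cal,
                grid,
                [(np.arange(n), np.arange(npix)), (np.arange(1), np.arange(1))],
            )


class TestDarkCountEstimation:
    def test_all_zero_stack(self, grid8):
        stack = make_stack(np.zeros((100, 8, 8), dtype=np.uint8), grid8)
        dc, mask = estimate_dark_counts(stack)
        np.testing.assert_array_equal(dc, 0.0)
        assert mask.all()

    def test_rate_inversion_closed_form(self, grid8):
        counts = np.zeros((100, 8, 8), dtype=np.uint8)
        counts[:39, 2, 3] = 1  # fires in 39 of 100 frames
        dc, _ = estimate_dark_counts(make_stack(counts, grid8))
        assert dc[2, 3] == pytest.approx(-np.log(0.61), rel=1e-12)
        assert dc[2, 3] == pytest.approx(0.4943, abs=5e-5)

    def test_rate_inversion_consistent_with_simulation(self, grid8, rng):
        true_dc = 0.4943
        p = 1 - np.exp(-true_dc)
        counts = (rng.random((20000, 8, 8)) < p).astype(np.uint8)
        dc, _ = estimate_dark_counts(make_stack(counts, grid8))
        assert dc.mean() == pytest.approx(true_dc, rel=0.02)

    def test_always_firing_pixel_flagged_not_infinite(self, grid8):
        counts = np.zeros((200, 8, 8), dtype=np.uint8)
        counts[:, 5, 5] = 1
        dc, mask = estimate_dark_counts(make_stack(counts, grid8))
        assert not mask[5, 5]
        assert np.isfinite(dc[5, 5])

    def test_empty_stack_rejected(self, grid8):
        with pytest.raises(ValueError):
            estimate_dark_counts(
                make_stack(np.zeros((0, 8, 8), dtype=np.uint8), grid8)
            )


def test_post_frame_emission_probability_bound():
    # 10 ns lifetime, mid-exposure excitation of a 10 us frame: exp(-500)
    p = post_frame_emission_probability(10e-9, 10e-6)
    assert p == pytest.approx(np.exp(-500.0))
    assert p < 1e-200
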