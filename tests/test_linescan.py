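"""Linescan sampling, shift correlation, threshold, and the randomized null."""

import numpy as np
import pytest
from scipy import stats

from mck.exceptions import BoundsError, ThresholdUndefinedError
from mck.geometry import Polyline, px_to_nm
from mck.linescan import (Linescan, ShiftCurve, colocalization_frequency,
                          colocalization_threshold, randomized_frequency,
                          sample_linescan, sample_profile,
                          shift_correlation_curve)
from mck.simulate import SceneSpec, generate_tubular_scene
from mck.stack import FrameStack


def make_stack(arrays, pixel_size=32.0):
    data = np.stack(arrays)[None]
    return FrameStack(data, [f"ch{i}" for i in range(len(arrays))],
                      pixel_size, 1.0)


def noise_linescans(n_lines, length, rng, step=32.0):
    scans = []
    for i in range(n_lines):
        scans.append(Linescan(np.arange(length) * step,
                              {"a": rng.standard_normal(length),
                               "b": rng.standard_normal(length)},
                              line_id=f"ls{i}"))
    return scans


class TestSampleLinescan:
    def test_constant_field(self):
        stack = make_stack([np.full((64, 64), 7.0)])
        line = Polyline(np.array([[200.0, 500.0], [1500.0, 900.0]]), 32.0)
        scan = sample_linescan(stack, line)
        assert np.allclose(scan.channel_profiles["ch0"], 7.0)

    def test_linear_ramp_gives_arithmetic_progression(self):
        px = 32.0
        img = np.tile(px_to_nm(np.arange(64), px), (64, 1))
        stack = make_stack([img])
        y = px_to_nm(30, px)
        line = Polyline(np.array([[px_to_nm(2, px), y],
                                  [px_to_nm(60, px), y]]), px)
        prof = sample_linescan(stack, line).channel_profiles["ch0"]
        assert np.allclose(np.diff(prof), px)

    def test_out_of_bounds_rejected(self):
        stack = make_stack([np.zeros((64, 64))])
        line = Polyline(np.array([[-100.0, 100.0], [500.0, 100.0]]), 32.0)
        with pytest.raises(BoundsError):
            sample_linescan(stack, line)

    def test_diagonal_profile_peaks_at_tube_axis(self):
        # oracle: 10x-oversampled interpolation locates the true axis
        # crossing of a rendered noiseless tube
        spec = SceneSpec(field_size=(64, 64), psf_sigma=42.0, seed=1)
        y = px_to_nm(32, spec.pixel_size)
        axis_line = Polyline(np.array([[300.0, y], [1700.0, y]]), 32.0)
        stack, _ = generate_tubular_scene(spec, 160.0, axis_line)
        diag = Polyline(np.array([[600.0, 500.0], [1400.0, 1500.0]]), 32.0)
        scan = sample_linescan(stack, diag)
        prof = scan.channel_profiles["mito"]
        coarse_arc = scan.arc_positions[np.argmax(prof)]

        fine = Polyline(diag.vertices, sampling_step=3.2)
        prof_fine = sample_profile(stack.frame(0, "mito"), fine,
                                   spec.pixel_size)
        fine_arc = fine.arc_positions()[np.argmax(prof_fine)]
        assert abs(coarse_arc - fine_arc) <= 0.5 * 32.0


class TestShiftCurve:
    def test_identical_channels_correlate_at_one(self, rng):
        prof = rng.standard_normal(100)
        scan = Linescan(np.arange(100) * 32.0, {"a": prof, "b": prof.copy()})
        curve = shift_correlation_curve([scan], "a", "b", 320.0)
        assert curve.at(0.0)[0] == pytest.approx(1.0)

    def test_constructed_displacement_peaks_at_k_steps(self, rng):
        # channel b equals channel a displaced by exactly 3 samples
        a = rng.standard_normal(200)
        b = np.roll(a, 3)
        scan = Linescan(np.arange(200) * 32.0, {"a": a, "b": b})
        curve = shift_correlation_curve([scan], "a", "b", 320.0)
        m, _ = curve.at(3 * 32.0)
        assert m == pytest.approx(1.0)
        assert np.nanargmax(curve.mean_correlation) == \
            np.argmin(np.abs(curve.shift_distances - 96.0))

    def test_zero_shift_equals_direct_pearson_bitwise(self, rng):
        scans = noise_linescans(15, 120, rng)
        curve = shift_correlation_curve(scans, "a", "b", 320.0)
        direct = np.asarray(
            [np.corrcoef(s.channel_profiles["a"],
                         s.channel_profiles["b"])[0, 1] for s in scans])
        assert curve.at(0.0)[0] == direct.mean()   # bit-for-bit

    def test_white_noise_stays_within_null_band(self, rng):
        # null sd of Pearson r is ~1/sqrt(n-1); with 20 linescans the SEM
        # band should cover the mean at essentially every shift
        scans = noise_linescans(20, 200, rng)
        curve = shift_correlation_curve(scans, "a", "b", 640.0)
        assert np.all(np.abs(curve.mean_correlation) < 3 * curve.dispersion
                      + 1e-12)

    def test_channel_swap_symmetry(self, rng):
        scans = noise_linescans(5, 100, rng)
        ab = shift_correlation_curve(scans, "a", "b", 160.0)
        ba = shift_correlation_curve(scans, "b", "a", 160.0)
        assert np.allclose(ab.mean_correlation,
                           ba.mean_correlation[::-1], equal_nan=True)

    def test_zero_variance_linescan_excluded_and_logged(self, rng):
        flat = Linescan(np.arange(100) * 32.0,
                        {"a": np.ones(100), "b": rng.standard_normal(100)},
                        line_id="flat")
        good = noise_linescans(3, 100, rng)
        curve = shift_correlation_curve(good + [flat], "a", "b", 160.0)
        assert any(lid == "flat" for lid, _ in curve.exclusions)
        assert np.all(curve.n_used == 3)

    def test_too_short_linescan_rejected(self, rng):
        scans = noise_linescans(2, 10, rng)
        with pytest.raises(ValueError):
            shift_correlation_curve(scans, "a", "b", 320.0)


def constructed_curve(drop_after_nm, mean_high=0.9, sem=0.01, step=32.0,
                      max_shift=640.0):
    n = int(max_shift / step)
    d = np.arange(-n, n + 1) * step
    mean = np.where(np.abs(d) <= drop_after_nm, mean_high, 0.0)
    return ShiftCurve(d, mean, np.full_like(mean, sem),
                      np.full(len(d), 10, dtype=int), 10, step)


class TestThreshold:
    def test_constructed_curve_gives_224nm(self):
        # curve positive out to the 7th step (7 * 32 = 224 nm), ~0 beyond
        curve = constructed_curve(224.0)
        assert colocalization_threshold(curve) == 224.0

    def test_zero_shift_ci_spanning_zero_is_undefined(self):
        curve = constructed_curve(224.0, mean_high=0.005, sem=0.5)
        with pytest.raises(ThresholdUndefinedError):
            colocalization_threshold(curve)

    def test_wider_dispersion_never_increases_threshold(self):
        # monotonicity of the CI rule in the dispersion: strong zero-shift
        # peak, weak flanks that a wider SEM pushes below significance
        def curve(sem):
            c = constructed_curve(224.0, mean_high=0.05, sem=sem)
            c.mean_correlation[np.abs(c.shift_distances) == 0] = 0.9
            return c
        t1 = colocalization_threshold(curve(0.01))
        t2 = colocalization_threshold(curve(0.03))
        assert t2 <= t1
        assert (t1, t2) == (224.0, 0.0)

    def test_psf_limited_threshold_on_perfect_pairs(self):
        # offset_sd = 0, noiseless: recovered threshold is at least the
        # PSF-limited correlation length from an exhaustive 1-pixel
        # shift-and-correlate oracle on the same images
        from mck.simulate import generate_spot_pair_scene
        spec = SceneSpec(field_size=(384, 384), seed=3)
        stack, gt = generate_spot_pair_scene(spec, 40, 0.0)
        half, wn = 640.0 + 128, 384 * 32.0
        scans, profs = [], []
        for i in range(40):
            x, y = gt.object_tracks[f"spots_a_{i}"].xy[0]
            if x - half < 32 or x + half > wn - 32:
                continue
            line = Polyline(np.array([[x - half, y], [x + half, y]]), 32.0,
                            line_id=f"l{i}")
            scan = sample_linescan(stack, line)
            scans.append(scan)
            profs.append((scan.channel_profiles["spots_a"],
                          scan.channel_profiles["spots_b"]))
        curve = shift_correlation_curve(scans, "spots_a", "spots_b", 640.0)
        threshold = colocalization_threshold(curve)

        # brute-force oracle: largest 1-pixel shift with mean r - z*sem > 0
        z = stats.norm.ppf(0.975)
        oracle = 0
        for k in range(1, 21):
            rs = []
            for a, b in profs:
                for sign in (1, -1):
                    j = sign * k
                    aa = a[j:] if j > 0 else a[:j]
                    bb = b[:-j] if j > 0 else b[-j:]
                    if np.ptp(aa) and np.ptp(bb):
                        rs.append(np.corrcoef(aa, bb)[0, 1])
            rs = np.asarray(rs)
            if rs.mean() - z * rs.std(ddof=1) / np.sqrt(len(rs)) <= 0:
                break
            oracle = k * 32
        assert threshold >= oracle - 32  # within one shift step of oracle
        assert threshold >= 64           # clearly above zero: PSF-limited


class TestColocFrequency:
    def test_coincident_sets_give_one(self, rng):
        pts = rng.uniform(0, 5000, (30, 2))
        assert colocalization_frequency(pts, pts.copy(), 224.0) == 1.0

    def test_boundary_displacement_is_strictly_excluded(self):
        a = np.stack(np.meshgrid(np.arange(5) * 1000.0,
                                 np.arange(5) * 1000.0), -1).reshape(-1, 2)
        b = a + np.array([224.0, 0.0])
        assert colocalization_frequency(a, b, 224.0) == 0.0

    def test_empty_b_warns_and_returns_zero(self):
        with pytest.warns(UserWarning):
            out = colocalization_frequency(np.array([[0.0, 0.0]]),
                                           np.empty((0, 2)), 100.0)
        assert out == 0.0

    def test_matches_all_pairs_brute_force_and_rayleigh(self, rng):
        # 100 A uniform in 10x10 um, B = A + Gaussian(50 nm): frequency at
        # 224 nm equals the all-pairs computation and ~ the Rayleigh CDF
        a = rng.uniform(0, 10000.0, (100, 2))
        b = a + rng.normal(0, 50.0, (100, 2))
        frac = colocalization_frequency(a, b, 224.0)
        d = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=2)
        brute = np.mean(d.min(axis=1) < 224.0)
        assert frac == brute
        rayleigh = 1 - np.exp(-224.0 ** 2 / (2 * 50.0 ** 2))
        assert frac == pytest.approx(rayleigh, abs=0.05)

    def test_small_sets_match_exhaustive_exactly(self, rng):
        for n in range(1, 10):
            a = rng.uniform(0, 2000, (n, 2))
            b = rng.uniform(0, 2000, (n, 2))
            d = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=2)
            assert colocalization_frequency(a, b, 300.0) == \
                np.mean(d.min(axis=1) < 300.0)


class TestRandomizedNull:
    def test_vanishing_radius_null_is_zero(self, rng):
        a = rng.uniform(500, 5000, (20, 2))
        b = rng.uniform(500, 5000, (20, 2))
        mask = np.ones((200, 200), dtype=bool)
        res = randomized_frequency(a, b, mask, 1e-3, 50, seed=1)
        assert np.all(res.null_fractions == 0)

    def test_poisson_nearest_neighbour_law(self, rng):
        # oracle: 1 - exp(-lambda pi r^2) for uniform B in a large mask
        px, n_grid = 32.0, 300
        area = (n_grid * px) ** 2
        r = 224.0
        lam_pi_r2 = 0.5
        n_b = int(round(lam_pi_r2 / (np.pi * r * r) * area))
        a = rng.uniform(r + 200, n_grid * px - r - 200, (200, 2))
        b = rng.uniform(0, n_grid * px, (n_b, 2))
        mask = np.ones((n_grid, n_grid), dtype=bool)
        res = randomized_frequency(a, b, mask, r, 300, seed=2, pixel_size=px)
        pred = 1 - np.exp(-lam_pi_r2)
        se = res.null_fractions.std(ddof=1) / np.sqrt(300)
        assert abs(res.null_mean - pred) < max(2 * se, 0.01)

    def test_perfect_pairs_versus_sparse_null_significant(self, rng):
        # oracle: recompute the t statistic from the two sample vectors
        images_a = [rng.uniform(1000, 8000, (30, 2)) for _ in range(5)]
        images_b = [a + rng.normal(0, 20.0, a.shape) for a in images_a]
        mask = np.ones((300, 300), dtype=bool)
        res = randomized_frequency(images_a, images_b, mask, 224.0, 100,
                                   seed=3)
        assert res.p_value < 1e-3
        t = stats.ttest_ind(res.observed_per_image, res.null_fractions)
        assert res.p_value == t.pvalue

    def test_zero_permutations_rejected(self, rng):
        a = rng.uniform(0, 1000, (5, 2))
        with pytest.raises(ValueError):
            randomized_frequency(a, a, np.ones((10, 10), bool), 100.0, 0)

    def test_mask_smaller_than_b_count_rejected(self, rng):
        a = rng.uniform(0, 1000, (5, 2))
        mask = np.zeros((10, 10), bool)
        mask[0, :3] = True
        with pytest.raises(ValueError):
            randomized_frequency(a, a, mask, 100.0, 10)
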