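"""Detection, linking, velocities, trajectory correlation, MSD, kymographs."""

import numpy as np
import pytest

from mck.exceptions import (BoundsError, DegenerateProfileError,
                            DegenerateTrackError)
from mck.geometry import Polyline, px_to_nm
from mck.simulate import SceneSpec, generate_mdt_event, generate_track, render
from mck.tracking import (Track, detect_spots, ensemble_msd,
                          fit_anomalous_exponent, kymograph, link_tracks,
                          msd, trajectory_correlation, velocities)


def ballistic_track(v=100.0, n=50, dt=1.0, direction=(1.0, 0.0),
                    origin=(0.0, 0.0)):
    t = np.arange(n)
    u = np.asarray(direction) / np.linalg.norm(direction)
    return Track("b", t, np.asarray(origin) + np.outer(t * dt * v, u), dt)


class TestDetectSpots:
    def test_blank_frame_yields_no_detections(self):
        det = detect_spots(np.zeros((64, 64)), 42.0, 0.3, 32.0)
        assert len(det) == 0

    def test_single_spot_localized_subpixel(self, small_spec):
        true = np.array([[1003.0, 997.0]])
        stack = render(small_spec, positions={"a": [true]})
        det = detect_spots(stack.frame(0, "a"), 42.0, 0.3, 32.0)
        assert len(det) == 1
        err = np.hypot(det.x_nm[0] - 1003.0, det.y_nm[0] - 997.0)
        assert err < 0.25 * 32.0

    def test_two_well_separated_spots_both_found(self, small_spec):
        pts = np.array([[500.0, 500.0], [1500.0, 1500.0]])  # ~24 sigma apart
        stack = render(small_spec, positions={"a": [pts]})
        det = detect_spots(stack.frame(0, "a"), 42.0, 0.3, 32.0)
        assert len(det) == 2


class TestLinkTracks:
    def test_static_detection_gives_one_full_track(self):
        dets = [np.array([[500.0, 500.0]])] * 10
        tracks = link_tracks(dets, 100.0, 1.0)
        assert len(tracks) == 1 and len(tracks[0]) == 10

    def test_two_distant_movers_never_switch(self):
        t = np.arange(20)
        a = np.column_stack([100.0 * t + 500, np.full(20, 500.0)])
        b = np.column_stack([100.0 * t + 500, np.full(20, 9500.0)])
        dets = [np.array([a[i], b[i]]) for i in range(20)]
        tracks = link_tracks(dets, 300.0, 1.0)
        assert len(tracks) == 2
        for trk in tracks:
            assert np.ptp(trk.xy[:, 1]) == 0  # stayed in its own lane

    def test_brownian_links_match_ground_truth(self):
        # >= 95% correct frame-to-frame links at max_disp = 5*sqrt(4 D dt)
        spec = SceneSpec(n_frames=40, frame_interval=1.0, seed=21)
        rng = np.random.default_rng(17)
        D = 2000.0
        truths = [generate_track(spec, "brownian", D=D,
                                 origin=rng.uniform(2000, 14000, 2),
                                 rng=rng, n_frames=40, object_id=f"t{i}")
                  for i in range(12)]
        dets = [np.array([trk.xy[t] for trk in truths]) for t in range(40)]
        tracks = link_tracks(dets, 5 * np.sqrt(4 * D * 1.0), 1.0)
        # correct links keep each truth in a single recovered track
        correct = sum(len(t) for t in tracks if len(t) == 40)
        assert correct / (12 * 40) >= 0.95


class TestVelocities:
    def test_ballistic_speeds_constant(self):
        assert np.allclose(velocities(ballistic_track(100.0)), 100.0)

    def test_stationary_speeds_zero(self):
        trk = Track("s", np.arange(10), np.zeros((10, 2)), 1.0)
        assert np.allclose(velocities(trk), 0.0)

    def test_scripted_piecewise_speeds_recovered(self):
        # oracle: the generator's event log scripts the speeds
        spec = SceneSpec(field_size=(128, 320), n_frames=121,
                         frame_interval=1.0, seed=2)
        _, gt = generate_mdt_event(spec, 50.0, "unsynchronized",
                                   burst=(10, 20), render_images=False)
        v = velocities(gt.object_tracks["nucleoid"])
        assert np.allclose(v[11:20], 1.5 * 50.0)   # burst window
        assert np.allclose(v[1:10], 0.5 * 50.0)    # lag phase


class TestTrajectoryCorrelation:
    def test_identical_tracks_correlate_at_one(self):
        spec = SceneSpec(n_frames=100, seed=3)
        trk = generate_track(spec, "brownian", D=1e3)
        out = trajectory_correlation(trk, trk)
        assert out.speed_correlation == pytest.approx(1.0)
        assert out.position_correlation == pytest.approx(1.0)

    def test_coupled_fixture_speed_correlation_near_one(self):
        spec = SceneSpec(field_size=(128, 320), n_frames=121,
                         frame_interval=1.0, seed=2)
        _, gt = generate_mdt_event(spec, 50.0, "coupled",
                                   speed_modulation=0.3, render_images=False)
        out = trajectory_correlation(gt.object_tracks["tip"],
                                     gt.object_tracks["nucleoid"])
        assert out.speed_correlation > 0.99

    def test_independent_brownian_tracks_weakly_correlated(self):
        spec = SceneSpec(n_frames=200, seed=4)
        rng = np.random.default_rng(99)
        hits = 0
        for _ in range(20):
            a = generate_track(spec, "brownian", D=1e3, rng=rng, n_frames=200)
            b = generate_track(spec, "brownian", D=1e3, rng=rng, n_frames=200)
            if abs(trajectory_correlation(a, b).speed_correlation) < 0.2:
                hits += 1
        assert hits >= 18   # ~95% of independent pairs under the null sd

    def test_constant_speed_pair_is_degenerate(self):
        with pytest.raises(DegenerateTrackError):
            trajectory_correlation(ballistic_track(), ballistic_track())

    def test_symmetry_and_translation_invariance(self):
        spec = SceneSpec(n_frames=80, seed=5)
        rng = np.random.default_rng(7)
        a = generate_track(spec, "brownian", D=500.0, rng=rng, n_frames=80)
        b = generate_track(spec, "brownian", D=500.0, rng=rng, n_frames=80)
        r_ab = trajectory_correlation(a, b).speed_correlation
        r_ba = trajectory_correlation(b, a).speed_correlation
        shifted = Track("b2", b.frames, b.xy + [5000.0, -3000.0],
                        b.frame_interval)
        r_shift = trajectory_correlation(a, shifted).speed_correlation
        assert r_ab == pytest.approx(r_ba)
        assert r_ab == pytest.approx(r_shift)


class TestMsd:
    def test_stationary_track_msd_zero(self):
        trk = Track("s", np.arange(20), np.zeros((20, 2)), 1.0)
        assert np.allclose(msd(trk, 5)["msd_nm2"], 0.0)

    def test_ballistic_closed_form(self):
        trk = ballistic_track(v=100.0, n=40)
        table = msd(trk, 10)
        assert np.allclose(table["msd_nm2"],
                           (100.0 * table["lag_s"]) ** 2)

    def test_brownian_ensemble_near_theory(self):
        spec = SceneSpec(n_frames=200, seed=6)
        rng = np.random.default_rng(23)
        tracks = [generate_track(spec, "brownian", D=1e4, rng=rng,
                                 n_frames=200, object_id=f"t{i}")
                  for i in range(200)]
        table = ensemble_msd(tracks, 10)
        theory = 4e4 * table["lag_s"]
        assert np.allclose(table["msd_nm2"], theory, rtol=0.10)

    def test_invariance_under_rigid_motion(self):
        spec = SceneSpec(n_frames=100, seed=8)
        trk = generate_track(spec, "brownian", D=1e3)
        ang = 0.7
        R = np.array([[np.cos(ang), -np.sin(ang)],
                      [np.sin(ang), np.cos(ang)]])
        moved = Track("m", trk.frames, trk.xy @ R.T + [123.0, -456.0], 1.0)
        assert np.allclose(msd(trk, 10)["msd_nm2"],
                           msd(moved, 10)["msd_nm2"])


class TestAnomalousExponent:
    def test_ballistic_alpha_exactly_two(self):
        fit = fit_anomalous_exponent(msd(ballistic_track(n=60), 20))
        assert fit.alpha == pytest.approx(2.0, abs=1e-9)

    def test_brownian_alpha_near_one(self):
        spec = SceneSpec(n_frames=500, seed=9)
        rng = np.random.default_rng(31)
        alphas = [fit_anomalous_exponent(
            msd(generate_track(spec, "brownian", D=1e4, rng=rng,
                               n_frames=500), 100)).alpha
            for _ in range(40)]
        assert 0.85 <= np.mean(alphas) <= 1.15

    def test_fractional_alpha_recovered(self):
        spec = SceneSpec(n_frames=500, seed=10)
        rng = np.random.default_rng(37)
        alphas = [fit_anomalous_exponent(
            msd(generate_track(spec, "anomalous", D=100.0, alpha_true=1.5,
                               rng=rng, n_frames=500), 100)).alpha
            for _ in range(40)]
        assert 1.4 <= np.mean(alphas) <= 1.6

    def test_zero_msd_in_range_rejected(self):
        trk = Track("s", np.arange(20), np.zeros((20, 2)), 1.0)
        with pytest.raises(DegenerateProfileError):
            fit_anomalous_exponent(msd(trk, 10))


class TestKymograph:
    def test_static_stack_rows_identical(self, small_spec):
        spec = SceneSpec(field_size=(64, 64), n_frames=5, seed=0)
        pts = np.tile(np.array([[1000.0, 1000.0]]), (5, 1, 1))
        stack = render(spec, positions={"a": pts})
        y = px_to_nm(31, 32.0)
        line = Polyline(np.array([[300.0, y], [1700.0, y]]), 32.0)
        k = kymograph(stack, line, "a")
        assert np.allclose(k.values, k.values[0])

    def test_moving_spot_ridge_slope(self):
        # spot at 64 nm/s along the line, 32 nm sampling, 1 s frames:
        # ridge advances 2 columns per row
        spec = SceneSpec(field_size=(32, 256), n_frames=40, seed=0)
        y = px_to_nm(16, 32.0)
        pos = np.array([[[500.0 + 64.0 * t, y]] for t in range(40)])
        stack = render(spec, positions={"spot": pos})
        line = Polyline(np.array([[200.0, y], [7800.0, y]]), 32.0)
        k = kymograph(stack, line, "spot")
        ridge = np.argmax(k.values, axis=1)
        slope = np.polyfit(np.arange(40), ridge, 1)[0]
        assert slope == pytest.approx(2.0, abs=0.05)

    def test_width_averaging_matches_width1_on_wide_tube(self):
        spec = SceneSpec(field_size=(64, 64), psf_sigma=42.0, n_frames=2,
                         seed=1)
        y = px_to_nm(32, 32.0)
        from mck.simulate import generate_tubular_scene
        stack, _ = generate_tubular_scene(
            spec, 350.0, Polyline(np.array([[400.0, y], [1600.0, y]]), 32.0))
        line = Polyline(np.array([[500.0, y], [1500.0, y]]), 32.0)
        k1 = kymograph(stack, line, "mito", width=1)
        k3 = kymograph(stack, line, "mito", width=3)
        assert np.allclose(k1.values, k3.values, rtol=0.05)

    def test_even_width_rejected(self, small_spec):
        stack = render(small_spec, positions={"a": [np.array([[1000.0,
                                                               1000.0]])]})
        line = Polyline(np.array([[300.0, 1000.0], [1700.0, 1000.0]]), 32.0)
        with pytest.raises(ValueError):
            kymograph(stack, line, "a", width=2)

    def test_line_outside_bounds_rejected(self, small_spec):
        stack = render(small_spec, positions={"a": [np.array([[1000.0,
                                                               1000.0]])]})
        line = Polyline(np.array([[300.0, 10.0], [1700.0, 10.0]]), 32.0)
        with pytest.raises(BoundsError):
            kymograph(stack, line, "a", width=3)
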