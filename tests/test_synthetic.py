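"""Trajectory generator, forward ray-cast rendering, and virtual markers."""

import numpy as np
import pytest

from chairsts import (
    CONDITION_PRESETS,
    ChairGeometry,
    PerturbationSpec,
    angles_from_markers,
    forward_distance_thigh,
    forward_distance_trunk,
    generate_trajectory,
    simulate_markers,
    simulate_trial,
    thigh_angle_from_distance,
)
from chairsts.synthetic import SEATED_THIGH_DEG, thigh_offset_for_weight_shift


class TestPresets:
    def test_exactly_seven_conditions(self):
        assert set(CONDITION_PRESETS) == {
            "normal", "tilt_increase", "tilt_decrease", "slow", "fast",
            "weight_shift_right", "weight_shift_left",
        }

    def test_tilt_presets_bracket_normal_amplitude(self):
        p = CONDITION_PRESETS
        assert (p["tilt_decrease"].flexion_amplitude_deg
                < p["normal"].flexion_amplitude_deg
                < p["tilt_increase"].flexion_amplitude_deg)

    def test_speed_presets_bracket_normal_duration(self):
        p = CONDITION_PRESETS
        assert p["fast"].duration_s < p["normal"].duration_s < p["slow"].duration_s

    def test_weight_shift_asymmetry_is_mirrored(self):
        p = CONDITION_PRESETS
        assert p["weight_shift_right"].asymmetry_gain == pytest.approx(
            -p["weight_shift_left"].asymmetry_gain
        )
        assert thigh_offset_for_weight_shift(p["weight_shift_right"]) > 0
        assert thigh_offset_for_weight_shift(p["normal"]) == 0.0


class TestGenerateTrajectory:
    def test_peak_equals_programmed_amplitude_within_jitter(self):
        preset = CONDITION_PRESETS["normal"]
        a = generate_trajectory(preset, seed=3)
        peak = np.max(a.theta_trunk)
        assert abs(peak - preset.flexion_amplitude_deg) <= (
            0.05 * preset.flexion_amplitude_deg + 1e-9
        )
        nominal = generate_trajectory(preset)  # no seed: no jitter
        assert np.max(nominal.theta_trunk) == pytest.approx(
            preset.flexion_amplitude_deg, abs=1e-9
        )

    def test_slow_and_fast_share_the_same_path_shape(self):
        slow = generate_trajectory("slow")
        fast = generate_trajectory("fast")
        ratio = (CONDITION_PRESETS["slow"].duration_s
                 / CONDITION_PRESETS["fast"].duration_s)
        # ... and peak times in the duration ratio
        # same amplitude to within grid resolution of the flat peak ...
        for s in (slow, fast):
            assert np.max(s.theta_trunk) == pytest.approx(50.0, abs=0.1)
        t_peak_slow = slow.t[np.argmax(slow.theta_trunk)] - 0.5
        t_peak_fast = fast.t[np.argmax(fast.theta_trunk)] - 0.5
        assert t_peak_slow / t_peak_fast == pytest.approx(ratio, rel=0.05)

    def test_boundary_velocities_vanish(self):
        # minimum-jerk boundary conditions: velocity -> 0 at segment edges.
        # Discrete one-sided velocity near a boundary scales as dt^2, so at
        # 1 kHz it must already be far below any physiological rate.
        a = generate_trajectory("normal", fs=1000.0)
        v = np.gradient(a.theta_trunk, a.t)
        assert abs(v[0]) < 1e-9     # quiet sitting
        assert abs(v[-1]) < 0.01    # end of settle, deg/s
        i_peak = int(np.argmax(a.theta_trunk))
        assert abs(v[i_peak]) < 0.01

    def test_thigh_rises_from_seated_to_vertical(self):
        a = generate_trajectory("normal")
        assert a.theta_thigh[0] == pytest.approx(SEATED_THIGH_DEG)
        assert a.theta_thigh[-1] == pytest.approx(90.0, abs=0.5)
        assert np.all(np.diff(a.theta_thigh) >= -1e-12)

    def test_low_rate_rejected(self):
        with pytest.raises(ValueError):
            generate_trajectory("normal", fs=20.0)


class TestForwardModels:
    def test_thigh_inverse_of_derived_example(self, geom):
        # the geometry example in reverse: 33.4668 degrees renders to 100 mm
        d = forward_distance_thigh(33.46679807621535, geom)
        assert d == pytest.approx(100.0, abs=1e-6)

    def test_trunk_seated_distance_is_seat_minus_hip(self, geom):
        # trunk vertical over a horizontal thigh: d = l_seat - l_thigh
        assert forward_distance_trunk(0.0, 0.0, geom) == pytest.approx(147.0)

    def test_surface_offset_breaks_the_identity(self, geom):
        p = PerturbationSpec(surface_offset_mm=20.0)
        d = forward_distance_thigh(40.0, geom, p)
        recovered = thigh_angle_from_distance(d, geom)
        assert abs(recovered - 40.0) > 0.5

    def test_noise_respects_the_seeded_stream(self, geom):
        p = PerturbationSpec(distance_noise_sd_mm=2.0, seed=11)
        d1 = forward_distance_thigh(np.full(50, 40.0), geom, p)
        d2 = forward_distance_thigh(np.full(50, 40.0), geom, p)
        assert np.array_equal(d1, d2)
        assert np.std(d1) == pytest.approx(2.0, rel=0.5)

    def test_beam_miss_raises_on_scalar(self, geom):
        with pytest.raises(ValueError):
            forward_distance_thigh(-60.0, geom)  # thigh folded under the seat

    def test_knee_shift_changes_only_the_shifted_samples(self, geom):
        th = np.full(20, 30.0)
        shift = np.concatenate([np.zeros(10), np.full(10, 30.0)])
        d = forward_distance_thigh(th, geom, knee_shift_mm=shift)
        assert np.ptp(d[:10]) == pytest.approx(0.0, abs=1e-12)
        assert abs(d[15] - d[5]) > 1.0


class TestMarkers:
    def test_noiseless_markers_reproduce_truth(self, geom):
        truth = generate_trajectory("normal", fs=100.0)
        m = simulate_markers(truth, geom)
        back = angles_from_markers(m)
        assert back.source == "marker-based"
        assert back.theta_trunk == pytest.approx(truth.theta_trunk, abs=1e-9)
        assert back.theta_thigh == pytest.approx(truth.theta_thigh, abs=1e-9)

    def test_thigh_marker_segment_is_rigid(self, geom):
        truth = generate_trajectory("tilt_increase", fs=100.0)
        m = simulate_markers(truth, geom)
        seg = m.greater_trochanter - m.lateral_femoral_condyle
        lengths = np.hypot(seg[:, 0], seg[:, 1])
        assert np.ptp(lengths) < 1e-9
        assert lengths[0] == pytest.approx(geom.l_thigh)

    def test_c7_above_sacrum_in_quiet_sitting(self, geom):
        truth = generate_trajectory("normal", fs=100.0)
        m = simulate_markers(truth, geom)
        assert m.c7[0, 1] > m.sacrum[0, 1]

    def test_marker_noise_propagates_to_angle_noise(self, geom):
        # sd(theta) ~ sqrt(2) * sigma / L radians for small angles
        rng = np.random.default_rng(5)
        t = np.arange(0, 10.0, 1 / 100)
        truth_trunk = np.zeros_like(t)
        truth_thigh = np.full_like(t, SEATED_THIGH_DEG)
        from chairsts import AngleSeries

        truth = AngleSeries(t, truth_trunk, truth_thigh, fs=100.0)
        p = PerturbationSpec(marker_noise_sd_mm=1.0)
        m = simulate_markers(truth, geom, p, rng=rng)
        back = angles_from_markers(m)
        expected = np.degrees(np.sqrt(2) * 1.0 / 400.0)
        assert np.std(back.theta_trunk) == pytest.approx(expected, rel=0.15)

    def test_coincident_markers_flag_invalid_frames(self):
        from chairsts import MarkerSeries

        t = np.arange(3) / 100
        z = np.zeros((3, 2))
        up = np.tile([[0.0, 400.0]], (3, 1))
        right = np.tile([[400.0, 0.0]], (3, 1))
        m = MarkerSeries(t, up, z, z.copy(), z.copy())  # thigh markers coincide
        back = angles_from_markers(m)
        assert not back.valid.any()

    @pytest.mark.parametrize(
        "dx, dy, expected",
        [(0.0, 400.0, 0.0), (-283.0, 283.0, 45.0)],
    )
    def test_trunk_angle_sign_convention(self, dx, dy, expected):
        # forward lean (C7 anterior of sacrum, i.e. -x) is positive flexion
        from chairsts import MarkerSeries

        t = np.arange(3) / 100
        sacrum = np.zeros((3, 2))
        c7 = np.tile([[dx, dy]], (3, 1))
        condyle = np.zeros((3, 2))
        troch = np.tile([[400.0, 10.0]], (3, 1))
        back = angles_from_markers(MarkerSeries(t, c7, sacrum, troch, condyle))
        assert back.theta_trunk[0] == pytest.approx(expected, abs=0.01)


class TestSimulateTrial:
    def test_same_seed_is_bit_identical(self, geom):
        p = PerturbationSpec(distance_noise_sd_mm=2.0, marker_noise_sd_mm=1.0)
        a = simulate_trial("normal", geom, p, seed=42, trajectory_seed=7)
        b = simulate_trial("normal", geom, p, seed=42, trajectory_seed=7)
        assert np.array_equal(a.distances.d_thigh, b.distances.d_thigh)
        assert np.array_equal(a.markers.c7, b.markers.c7)

    def test_noise_seeds_share_the_noiseless_core(self, geom):
        p = PerturbationSpec(distance_noise_sd_mm=2.0)
        trials = [simulate_trial("normal", geom, p, seed=s) for s in (1, 2, 3)]
        # distinct noise ...
        assert not np.array_equal(trials[0].distances.d_thigh,
                                  trials[1].distances.d_thigh)
        # ... identical underlying truth
        for tr in trials[1:]:
            assert np.array_equal(trials[0].truth.theta_trunk, tr.truth.theta_trunk)

    def test_recorded_events_match_the_truth_series(self, geom):
        trial = simulate_trial("slow", geom)
        ev = trial.events
        peak_from_truth = int(np.argmax(trial.truth.theta_trunk))
        assert abs(peak_from_truth - ev["peak_flexion_idx"]) <= 1
        assert ev["onset_idx"] < ev["peak_flexion_idx"] < ev["max_extension_idx"]

    def test_distances_and_markers_cover_the_same_interval(self, geom):
        trial = simulate_trial("fast", geom)
        assert trial.distances.t[0] == trial.markers.t[0] == 0.0
        assert abs(trial.distances.t[-1] - trial.markers.t[-1]) < 1 / 30 + 1e-9

    def test_noiseless_trial_is_valid_through_max_extension(self, geom):
        trial = simulate_trial("normal", geom)
        assert trial.distances.valid[: trial.events["max_extension_idx"] + 1].all()
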