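"""Two-link inverse geometry: closed-form conversions and round trips."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chairsts import (
    AngleSeries,
    ChairGeometry,
    DistanceSeries,
    Point2D,
    angles_from_distances,
    forward_distance_thigh,
    forward_distance_trunk,
    hip_position,
    thigh_angle_from_distance,
    trunk_angle_from_distance,
)


class TestChairGeometry:
    def test_defaults_are_the_published_chair(self, geom):
        assert geom.phi_s1 == 63.5
        assert geom.l_s1 == 130.0
        assert geom.l_offset == 50.0
        assert geom.phi_s2 == 90.0
        assert geom.l_seat == 550.0
        assert geom.l_s2 == 465.0
        assert geom.l_thigh == 403.0
        assert geom.seat_height == 400.0

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"l_s1": 0.0},
            {"l_thigh": -5.0},
            {"phi_s1": 0.0},
            {"phi_s1": 180.0},
            {"phi_s2": 181.0},
        ],
    )
    def test_invariants_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ChairGeometry(**kwargs)

    def test_with_thigh_length(self, geom):
        g2 = geom.with_thigh_length(446.0)
        assert g2.l_thigh == 446.0
        assert g2.l_s1 == geom.l_s1

    def test_point2d_rejects_non_finite(self):
        with pytest.raises(ValueError):
            Point2D(np.nan, 0.0)


class TestThighAngle:
    def test_zero_distance_is_a_domain_error(self, geom):
        with pytest.raises(ValueError):
            thigh_angle_from_distance(0.0, geom)

    def test_hand_computed_example(self, geom):
        # atan(100 sin 63.5 / (180 - 100 cos 63.5)) evaluated independently
        assert thigh_angle_from_distance(100.0, geom) == pytest.approx(
            33.46679807621535, abs=1e-9
        )

    def test_round_trip_identity(self, geom):
        d = forward_distance_thigh(45.0, geom)
        assert thigh_angle_from_distance(d, geom) == pytest.approx(45.0, abs=1e-9)

    def test_monotonic_in_distance(self, geom):
        # the seat beam sweeps upward with distance, so larger distances mean
        # a more raised thigh everywhere the model is defined
        d = np.linspace(10.0, 380.0, 500)
        theta = thigh_angle_from_distance(d, geom)
        assert np.all(np.isfinite(theta))
        assert np.all(np.diff(theta) > 0)

    def test_array_input_flags_bad_samples_as_nan(self, geom):
        d = np.array([100.0, -5.0, 5000.0 * 0 + 100.0])
        theta = thigh_angle_from_distance(d, geom)
        assert np.isnan(theta[1])
        assert np.isfinite(theta[0]) and np.isfinite(theta[2])


class TestHipPosition:
    def test_horizontal_thigh(self, geom):
        p = hip_position(0.0, geom)
        assert (p.x, p.y) == (403.0, 0.0)

    def test_hand_computed_30_degrees(self, geom):
        p = hip_position(30.0, geom)
        assert p.x == pytest.approx(349.0082377251288, abs=1e-9)
        assert p.y == pytest.approx(201.5, abs=1e-9)

    def test_near_vertical_limit(self, geom):
        p = hip_position(90.0 - 1e-7, geom)
        assert p.x == pytest.approx(0.0, abs=1e-3)
        assert p.y == pytest.approx(geom.l_thigh, abs=1e-6)

    @pytest.mark.parametrize("theta", [-90.0, 90.0, 120.0])
    def test_out_of_range_rejected(self, geom, theta):
        with pytest.raises(ValueError):
            hip_position(theta, geom)


class TestTrunkAngle:
    def test_vertical_trunk_when_numerator_vanishes(self, geom):
        # hip at (403, 0); d = l_seat - x_hip makes the numerator zero
        hip = Point2D(403.0, 0.0)
        assert trunk_angle_from_distance(147.0, hip, geom) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_hand_computed_example(self, geom):
        hip = Point2D(349.0, 201.5)
        # atan((250 - (550-349)) / (465 - 201.5)) evaluated independently
        assert trunk_angle_from_distance(250.0, hip, geom) == pytest.approx(
            10.534296052844557, abs=1e-6
        )

    def test_round_trip_identity(self, geom):
        d = forward_distance_trunk(30.0, 20.0, geom)
        hip = hip_position(20.0, geom)
        assert trunk_angle_from_distance(d, hip, geom) == pytest.approx(
            30.0, abs=1e-9
        )

    def test_zero_distance_rejected(self, geom):
        with pytest.raises(ValueError):
            trunk_angle_from_distance(0.0, Point2D(403.0, 0.0), geom)

    def test_hit_below_hip_height_is_domain_error(self, geom):
        # denominator l_s2 - d cos(phi) - y_hip <= 0: hip above the beam
        hip = Point2D(100.0, 470.0)
        with pytest.raises(ValueError):
            trunk_angle_from_distance(100.0, hip, geom)


class TestAnglesFromDistances:
    @staticmethod
    def _series(d_thigh, d_trunk, fs=30.0):
        n = len(d_thigh)
        t = np.arange(n) / fs
        return DistanceSeries(t, d_thigh, d_trunk, fs=fs)

    def test_empty_series_rejected(self, geom):
        with pytest.raises(ValueError):
            DistanceSeries(np.array([]), np.array([]), np.array([]))

    def test_constant_distances_give_constant_angles(self, geom):
        s = self._series(np.full(30, 100.0), np.full(30, 200.0))
        a = angles_from_distances(s, geom)
        assert a.source == "chair-model"
        assert np.ptp(a.theta_thigh) == pytest.approx(0.0, abs=1e-12)
        assert np.ptp(a.theta_trunk) == pytest.approx(0.0, abs=1e-12)

    def test_out_of_range_sample_flagged_not_raised(self, geom):
        d_thigh = np.full(30, 100.0)
        d_trunk = np.full(30, 200.0)
        d_trunk[10] = 5000.0  # beyond sensor_max_range
        a = angles_from_distances(self._series(d_thigh, d_trunk), geom)
        assert len(a) == 30
        assert not a.valid[10]
        assert np.isnan(a.theta_trunk[10])
        assert a.valid.sum() == 29

    def test_matches_scalar_ops_sample_by_sample(self, geom, rng):
        d_thigh = rng.uniform(50, 300, 20)
        d_trunk = rng.uniform(100, 400, 20)
        a = angles_from_distances(self._series(d_thigh, d_trunk), geom)
        for i in range(20):
            th = thigh_angle_from_distance(float(d_thigh[i]), geom)
            hip = hip_position(th, geom)
            tr = trunk_angle_from_distance(float(d_trunk[i]), hip, geom)
            assert a.theta_thigh[i] == pytest.approx(th, abs=1e-12)
            assert a.theta_trunk[i] == pytest.approx(tr, abs=1e-12)


class TestRoundTripProperty:
    @settings(max_examples=200, derandomize=True)
    @given(
        theta_thigh=st.floats(5.0, 85.0),
        theta_trunk=st.floats(-30.0, 70.0),
    )
    def test_forward_then_invert_recovers_both_angles(self, theta_thigh, theta_trunk):
        geom = ChairGeometry()
        try:
            d1 = forward_distance_thigh(theta_thigh, geom)
            d2 = forward_distance_trunk(theta_trunk, theta_thigh, geom)
        except ValueError:
            return  # beam misses: outside the model's domain, nothing to check
        if not (0 < d1 <= geom.sensor_max_range and 0 < d2 <= geom.sensor_max_range):
            return
        th = thigh_angle_from_distance(d1, geom)
        tr = trunk_angle_from_distance(d2, hip_position(th, geom), geom)
        assert th == pytest.approx(theta_thigh, abs=1e-6)
        assert tr == pytest.approx(theta_trunk, abs=1e-6)

    def test_frame_consistency_rigid_lean(self, geom):
        # the same trunk lean seen through different thigh postures must
        # invert to the same trunk angle
        for theta_thigh in (10.0, 30.0, 60.0):
            d = forward_distance_trunk(25.0, theta_thigh, geom)
            hip = hip_position(theta_thigh, geom)
            assert trunk_angle_from_distance(d, hip, geom) == pytest.approx(
                25.0, abs=1e-9
            )


class TestSeriesContainers:
    def test_distance_series_requires_uniform_time(self):
        t = np.array([0.0, 1 / 30, 3 / 30])
        with pytest.raises(ValueError):
            DistanceSeries(t, np.ones(3), np.ones(3))

    def test_angle_series_infers_validity_from_nan(self):
        t = np.arange(4) / 30
        trunk = np.array([0.0, 1.0, np.nan, 3.0])
        a = AngleSeries(t, trunk, np.full(4, 5.0))
        assert list(a.valid) == [True, True, False, True]

    def test_length_mismatch_rejected(self):
        t = np.arange(3) / 30
        with pytest.raises(ValueError):
            AngleSeries(t, np.zeros(3), np.zeros(4))
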