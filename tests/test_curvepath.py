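"""Geometry kernel: resampling, arc lengths, chords, angles, curvature."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tipsgeo.curvepath import (
    ArcInterval,
    CenterlinePath,
    CurvatureParams,
    angle_deg,
    arc_distance,
    chord_direction,
    max_curvature_station,
    max_section_curvature,
    resample_path,
)
from tipsgeo.errors import (
    DegeneratePathError,
    DegenerateVectorError,
    InsufficientLengthError,
    OutOfRangeError,
)

from conftest import (
    circular_arc_path,
    oracle_max_curvature,
    random_rotation,
    sharp_bend_path,
)


class TestResample:
    def test_straight_segment_spacing_one(self):
        p = resample_path(np.array([[0, 0, 0], [0, 0, 60.0]]), 1.0)
        assert len(p) == 61
        np.testing.assert_allclose(p.cumlen_mm, np.arange(61.0))

    def test_irregular_straight_polyline_preserves_length(self):
        rng = np.random.default_rng(0)
        z = np.sort(np.concatenate([[0.0, 100.0], rng.uniform(0, 100, 30)]))
        pts = np.column_stack([np.zeros_like(z), np.zeros_like(z), z])
        p = resample_path(pts, 2.0)
        assert abs(p.total_length_mm - 100.0) <= 1.0

    def test_quarter_circle_arc_length(self):
        t = np.linspace(0, np.pi / 2, 1600)
        pts = np.column_stack([20 * np.cos(t), 20 * np.sin(t), np.zeros_like(t)])
        p = resample_path(pts, 1.0)
        assert abs(p.total_length_mm - 10 * np.pi) <= 0.1

    def test_endpoints_preserved(self):
        pts = np.array([[1.0, 2.0, 3.0], [4.0, 5.0, 9.0], [0.0, -1.0, 20.0]])
        p = resample_path(pts, 0.7)
        np.testing.assert_array_equal(p.points[0], pts[0])
        np.testing.assert_array_equal(p.points[-1], pts[-1])

    def test_coincident_points_rejected(self):
        with pytest.raises(DegeneratePathError):
            resample_path(np.array([[1.0, 1, 1], [1, 1, 1], [1, 1, 1]]), 1.0)

    def test_uniform_step_invariant(self):
        p = sharp_bend_path(70.0, spacing_mm=0.4)
        steps = np.diff(p.cumlen_mm)
        assert np.all(np.abs(steps - p.spacing_mm) <= 0.5 * p.spacing_mm + 1e-9)


class TestArcDistance:
    def test_straight(self):
        p = resample_path(np.array([[0, 0, 0], [0, 0, 60.0]]), 1.0)
        assert arc_distance(p, 0.0, 60.0) == 60.0

    def test_identity(self):
        p = sharp_bend_path(45.0)
        assert arc_distance(p, 13.7, 13.7) == 0.0

    def test_quarter_circle_endpoints(self):
        p = circular_arc_path(20.0, 90.0)
        assert abs(arc_distance(p, 0.0, p.total_length_mm) - 10 * np.pi) <= 0.05

    def test_out_of_range(self):
        p = resample_path(np.array([[0, 0, 0], [0, 0, 60.0]]), 1.0)
        with pytest.raises(OutOfRangeError):
            arc_distance(p, 0.0, 61.0)


class TestChordDirection:
    def test_straight_along_z(self):
        p = resample_path(np.array([[0, 0, 0], [0, 0, 60.0]]), 1.0)
        for s in (0.0, 17.3, 50.0):
            np.testing.assert_allclose(chord_direction(p, s, 10.0), [0, 0, 1], atol=1e-12)

    def test_reflection_negates_direction(self):
        p = sharp_bend_path(30.0)
        q = CenterlinePath(-p.points, p.spacing_mm)
        d1 = chord_direction(p, 5.0, 10.0)
        d2 = chord_direction(q, 5.0, 10.0)
        np.testing.assert_allclose(d2, -d1, atol=1e-12)

    def test_circle_chord_closed_form(self):
        R, sweep = 20.0, 90.0
        p = circular_arc_path(R, sweep)
        s, chord = 5.0, 10.0
        got = chord_direction(p, s, chord)
        t0, t1 = s / R, (s + chord) / R
        a = np.array([R * np.sin(t0), 0, R * (1 - np.cos(t0))])
        b = np.array([R * np.sin(t1), 0, R * (1 - np.cos(t1))])
        expect = (b - a) / np.linalg.norm(b - a)
        np.testing.assert_allclose(got, expect, atol=5e-4)

    def test_backward_orientation_points_downstream(self):
        p = resample_path(np.array([[0, 0, 0], [0, 0, 60.0]]), 1.0)
        np.testing.assert_allclose(
            chord_direction(p, 30.0, 10.0, "backward"), [0, 0, 1], atol=1e-12
        )

    def test_chord_out_of_range(self):
        p = resample_path(np.array([[0, 0, 0], [0, 0, 20.0]]), 1.0)
        with pytest.raises(OutOfRangeError):
            chord_direction(p, 15.0, 10.0)


@pytest.mark.parametrize(
    "u, v, expected",
    [
        ([0, 0, 1], [0, 0, 1], 0.0),
        ([1, 0, 0], [0, 1, 0], 90.0),
        ([1, 0, 0], [-1, 0, 0], 180.0),
        ([1, 1, 0], [1, 0, 0], 45.0),
    ],
)
def test_angle_deg(u, v, expected):
    assert angle_deg(np.array(u, float), np.array(v, float)) == pytest.approx(expected)


def test_angle_deg_zero_vector():
    with pytest.raises(DegenerateVectorError):
        angle_deg(np.zeros(3), np.array([1.0, 0, 0]))


class TestMaxSectionCurvature:
    def test_straight_is_zero(self):
        p = resample_path(np.array([[0, 0, 0], [0, 0, 60.0]]), 1.0)
        assert max_section_curvature(p, ArcInterval(0, 60)) == 0.0

    def test_sharp_90_bend_gives_90(self):
        p = sharp_bend_path(90.0, arm_mm=20.0)
        got = max_section_curvature(p, ArcInterval(0, p.total_length_mm))
        assert got == pytest.approx(90.0, abs=1e-9)

    def test_sharp_45_bend_matches_oracle(self):
        p = sharp_bend_path(45.0, arm_mm=20.0)
        got = max_section_curvature(p, ArcInterval(0, p.total_length_mm))
        assert got == pytest.approx(45.0, abs=0.5)
        oracle = oracle_max_curvature(p, 0, p.total_length_mm)
        assert got == pytest.approx(oracle, abs=0.5)

    def test_gentle_arc_below_total_bend_and_matches_oracle(self):
        # 60 degrees of bend spread over 80 mm: the windowed measure sees
        # only (chord+gap)/R of it
        R = 80.0 / np.radians(60.0)
        p = circular_arc_path(R, 60.0)
        got = max_section_curvature(p, ArcInterval(0, p.total_length_mm))
        assert got < 60.0
        oracle = oracle_max_curvature(p, 0, p.total_length_mm)
        assert got == pytest.approx(oracle, abs=0.5)
        closed_form = np.degrees(15.0 / R)
        assert got == pytest.approx(closed_form, abs=0.5)

    def test_interval_too_short(self):
        p = resample_path(np.array([[0, 0, 0], [0, 0, 60.0]]), 1.0)
        with pytest.raises(InsufficientLengthError):
            max_section_curvature(p, ArcInterval(0, 20))

    def test_monotone_in_bend_angle(self):
        vals = [
            max_section_curvature(
                sharp_bend_path(t, arm_mm=20.0),
                ArcInterval(0, 40.0),
            )
            for t in (0.01, 15, 30, 45, 60, 90, 120, 150, 179)
        ]
        assert all(b >= a - 1e-9 for a, b in zip(vals, vals[1:]))

    def test_nonnegative_and_station_reported(self):
        p = sharp_bend_path(30.0)
        ang, station = max_curvature_station(p, ArcInterval(0, p.total_length_mm))
        assert ang >= 0.0
        assert 0 <= station <= p.total_length_mm


@settings(max_examples=20, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10**6))
def test_rigid_motion_invariance(seed):
    """Rotating + translating all points changes no angle or arc length."""
    rng = np.random.default_rng(seed)
    p = sharp_bend_path(rng.uniform(10, 170), arm_mm=20.0, plane_deg=rng.uniform(0, 180))
    R = random_rotation(rng)
    t = rng.uniform(-100, 100, 3)
    q = CenterlinePath((R @ p.points.T).T + t, p.spacing_mm)
    iv = ArcInterval(0, min(p.total_length_mm, q.total_length_mm))
    a1 = max_section_curvature(p, iv)
    a2 = max_section_curvature(q, iv)
    assert a2 == pytest.approx(a1, abs=1e-6)
    assert q.total_length_mm == pytest.approx(p.total_length_mm, rel=1e-9)


def test_scale_covariance():
    """Uniform scaling by k scales arc lengths by k and leaves angles alone."""
    k = 2.5
    p = sharp_bend_path(60.0, arm_mm=20.0)
    q = CenterlinePath(k * p.points, k * p.spacing_mm)
    assert q.total_length_mm == pytest.approx(k * p.total_length_mm, rel=1e-9)
    a1 = max_section_curvature(p, ArcInterval(0, p.total_length_mm))
    a2 = max_section_curvature(
        q,
        ArcInterval(0, q.total_length_mm),
        CurvatureParams(gap_mm=5 * k, chord_mm=10 * k, station_step_mm=0.5 * k),
    )
    assert a2 == pytest.approx(a1, rel=1e-6, abs=1e-9)


def test_json_round_trip():
    p = sharp_bend_path(42.0)
    q = CenterlinePath.from_json(p.to_json())
    np.testing.assert_allclose(q.points, p.points)
    assert q.spacing_mm == p.spacing_mm
    params = CurvatureParams(gap_mm=4.0, chord_mm=8.0)
    assert CurvatureParams.from_dict(params.to_dict()) == params
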