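"""Assembly of the seven stent-geometry parameters."""

import numpy as np
import pytest

from tipsgeo.curvepath import CurvatureParams, resample_path
from tipsgeo.errors import InvalidLandmarksError, NoLumenError
from tipsgeo.phantom import PhantomSpec, make_phantom
from tipsgeo.tips_metrics import (
    PathLandmarks,
    alpha_angle,
    compute_all,
    compute_path_metrics,
    covered_ends_angle,
    covered_length,
    cranial_end_to_ivc,
    confluence_to_stent,
    min_stent_diameter,
    snap_landmarks,
)
from tipsgeo.volume_centerline import SectionProfile, extract_centerline

from conftest import densify_polyline, sharp_bend_path


def straight_path(total=100.0, spacing=0.5):
    return resample_path(np.array([[0, 0, 0], [0, 0, total]]), spacing)


def landmarks(u=20.0, c0=35.0, c1=75.0, s1=None, total=100.0):
    s1 = c1 if s1 is None else s1
    return PathLandmarks(0.0, u, c0, c1, s1, total)


class TestLandmarks:
    def test_ordering_enforced(self):
        lm = PathLandmarks(0.0, 30.0, 20.0, 75.0, 75.0, 100.0)
        with pytest.raises(InvalidLandmarksError):
            lm.validate(100.0)

    def test_nonzero_origin_rejected(self):
        lm = PathLandmarks(5.0, 30.0, 40.0, 75.0, 75.0, 100.0)
        with pytest.raises(InvalidLandmarksError):
            lm.validate(100.0)

    def test_terminus_must_match_path(self):
        with pytest.raises(InvalidLandmarksError):
            landmarks(total=90.0).validate(100.0)

    def test_snap_recovers_arc_positions(self):
        p = sharp_bend_path(60.0, arm_mm=30.0, spacing_mm=0.5)
        truth = {"uncovered_distal_begin": 8.3, "covered_distal_begin": 20.1,
                 "covered_cranial_end": 47.9, "stent_cranial_end": 50.2}
        pts = {k: np.column_stack(
            [np.interp([v], p.cumlen_mm, p.points[:, i]) for i in range(3)]
        )[0] for k, v in truth.items()}
        lm = snap_landmarks(p, pts)
        for k, v in truth.items():
            assert getattr(lm, k) == pytest.approx(v, abs=0.05)


class TestDistances:
    def test_stent_ending_at_ivc(self):
        p = straight_path()
        lm = landmarks(s1=100.0, c1=100.0, c0=35.0)
        assert cranial_end_to_ivc(p, lm) == 0.0

    def test_cranial_offset_construction(self):
        # cranial stent end placed 16.49 mm before the path terminus
        p = straight_path()
        lm = landmarks(c1=100.0 - 16.49, s1=100.0 - 16.49)
        assert cranial_end_to_ivc(p, lm) == pytest.approx(16.49)

    def test_covered_lengths(self):
        p = straight_path()
        assert covered_length(p, landmarks(c0=35.0, c1=35.0)) == 0.0
        assert covered_length(p, landmarks(c0=20.0, c1=80.0)) == pytest.approx(60.0)

    def test_confluence_to_stent(self):
        p = straight_path()
        assert confluence_to_stent(p, landmarks(u=0.0, c0=10.0)) == 0.0
        assert confluence_to_stent(p, landmarks(u=20.0)) == pytest.approx(20.0)


class TestAngles:
    def test_straight_stent_angles_zero(self):
        p = straight_path()
        lm = landmarks()
        assert covered_ends_angle(p, lm) == pytest.approx(0.0, abs=1e-9)
        assert alpha_angle(p, lm) == pytest.approx(0.0, abs=1e-9)

    def test_planar_elbow_covered_ends(self):
        # 90-degree elbow in the middle of the covered span
        p = sharp_bend_path(90.0, arm_mm=30.0, spacing_mm=0.25)
        lm = PathLandmarks(0.0, 5.0, 10.0, 50.0, 50.0, p.total_length_mm)
        assert covered_ends_angle(p, lm) == pytest.approx(90.0, abs=1e-6)

    def test_alpha_perpendicular_construction(self):
        # sharp 90-degree turn exactly at the covered beginning
        p = sharp_bend_path(90.0, arm_mm=30.0, spacing_mm=0.25)
        lm = PathLandmarks(0.0, 10.0, 30.0, 55.0, 55.0, p.total_length_mm)
        assert alpha_angle(p, lm) == pytest.approx(90.0, abs=1e-6)

    def test_smooth_arc_tangent_angle(self):
        # gentle planar arc: angle between covered-end tangents equals the
        # arc swept between the chord midpoints
        R = 120.0
        th = np.linspace(0, 0.8, 4000)
        pts = np.column_stack([R * np.sin(th), np.zeros_like(th), R * (1 - np.cos(th))])
        p = resample_path(pts, 0.25)
        lm = PathLandmarks(0.0, 10.0, 20.0, 80.0, 80.0, p.total_length_mm)
        # chord midpoints sit at s=25 and s=75 (forward chord at the distal
        # end, backward chord at the cranial end), 50 mm apart on the arc
        swept = np.degrees(50.0 / R)
        assert covered_ends_angle(p, lm) == pytest.approx(swept, abs=1.0)


class TestDiameter:
    def test_min_over_profiles(self):
        profs = [
            SectionProfile(s, np.zeros(3), np.array([0, 0, 1.0]), d, np.pi * (d / 2) ** 2)
            for s, d in [(0, 8.1), (1, 7.4), (2, 8.0)]
        ]
        assert min_stent_diameter(profs) == pytest.approx(7.4)

    def test_single_profile(self):
        prof = SectionProfile(0.0, np.zeros(3), np.array([0, 0, 1.0]), 8.27, 53.7)
        assert min_stent_diameter([prof]) == pytest.approx(8.27)

    def test_all_empty_raises(self):
        profs = [SectionProfile(0.0, np.zeros(3), np.array([0, 0, 1.0]), 0, 0, empty=True)]
        with pytest.raises(NoLumenError):
            min_stent_diameter(profs)


class TestComputeAll:
    def test_straight_phantom_full_pipeline(self, straight_extraction):
        spec, volume, truth, path = straight_extraction
        lm = snap_landmarks(path, truth.landmark_points)
        geo = compute_all(volume, path, lm)
        assert geo.max_curvature_deg == pytest.approx(0.0, abs=0.5)
        assert geo.covered_ends_angle_deg == pytest.approx(0.0, abs=1.0)
        assert geo.alpha_angle_deg == pytest.approx(0.0, abs=1.0)
        assert geo.covered_length_mm == pytest.approx(spec.covered_length_mm, abs=1.0)
        assert geo.confluence_to_stent_mm == pytest.approx(spec.pv_length_mm, abs=1.0)
        assert geo.cranial_end_to_ivc_mm == pytest.approx(spec.cranial_offset_mm, abs=1.0)
        assert geo.min_stent_diameter_mm == pytest.approx(2 * spec.radius_mm, abs=1.0)

    def test_elbow_phantom_matches_truth(self):
        spec = PhantomSpec(kind="bend", bend_deg=60.0, spacing_mm=1.0, bend_plane_deg=75.0)
        volume, truth = make_phantom(spec)
        path = extract_centerline(volume, truth.seed_set(), spacing_mm=1.0)
        lm = snap_landmarks(path, truth.landmark_points)
        geo = compute_all(volume, path, lm)
        t = truth.geometry
        assert geo.max_curvature_deg == pytest.approx(t.max_curvature_deg, abs=3.0)
        assert geo.covered_length_mm == pytest.approx(t.covered_length_mm, abs=1.0)
        assert geo.min_stent_diameter_mm == pytest.approx(t.min_stent_diameter_mm, abs=1.0)

    def test_invalid_landmarks_propagate(self, straight_extraction):
        _, volume, _, path = straight_extraction
        bad = PathLandmarks(0.0, 40.0, 20.0, 60.0, 60.0, path.total_length_mm)
        with pytest.raises(InvalidLandmarksError):
            compute_all(volume, path, bad)

    def test_sum_rule(self, straight_extraction):
        """confluence-to-stent + stent length + cranial-to-IVC = total length."""
        _, volume, truth, path = straight_extraction
        lm = snap_landmarks(path, truth.landmark_points)
        m = compute_path_metrics(path, lm)
        stent_len = lm.stent_cranial_end - lm.uncovered_distal_begin
        total = m["confluence_to_stent_mm"] + stent_len + m["cranial_end_to_ivc_mm"]
        assert total == pytest.approx(path.total_length_mm, abs=0.5)

    def test_metrics_rigid_motion_invariant_on_exact_path(self):
        from conftest import random_rotation

        p = sharp_bend_path(45.0, arm_mm=30.0, spacing_mm=0.25, plane_deg=20.0)
        lm = PathLandmarks(0.0, 5.0, 12.0, 52.0, 52.0, p.total_length_mm)
        base = compute_path_metrics(p, lm)
        rng = np.random.default_rng(11)
        R = random_rotation(rng)
        t = rng.uniform(-40, 40, 3)
        from tipsgeo.curvepath import CenterlinePath

        q = CenterlinePath((R @ p.points.T).T + t, p.spacing_mm)
        moved = compute_path_metrics(q, lm)
        for k in base:
            tol = 1e-6 if k.endswith("deg") else 1e-6 * max(1.0, abs(base[k]))
            assert moved[k] == pytest.approx(base[k], abs=tol)
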