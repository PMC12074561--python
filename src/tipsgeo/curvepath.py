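"""Geometry kernel for 3D centerline paths.

A :class:`CenterlinePath` is an ordered polyline of 3D points in millimetres
(LPS patient frame), resampled at a nominal uniform arc-length step, with the
cumulative arc length stored per point.  All stent-geometry measurements are
defined on this substrate: arc distances between stations, chord directions
over fixed-length chords, angles between chords, and the maximum sectional
curvature — the largest change of direction between two 1-cm chords separated
by a 5-mm gap, maximised over the stent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .errors import (
    DegeneratePathError,
    DegenerateVectorError,
    InsufficientLengthError,
    OutOfRangeError,
)

__all__ = [
    "CurvatureParams",
    "ArcInterval",
    "CenterlinePath",
    "resample_path",
    "arc_distance",
    "point_at",
    "chord_direction",
    "angle_deg",
    "section_curvature_profile",
    "max_section_curvature",
    "max_curvature_station",
]

_EPS = 1e-9


@dataclass(frozen=True)
class CurvatureParams:
    """Layout of the sectional-curvature measurement.

    gap_mm
        Separation between the two measured sections (default 5 mm).
    chord_mm
        Length of each straight section (default 10 mm, i.e. 1 cm).
    station_step_mm
        Step of the sliding station used to maximise the angle over the
        stent; 0.5 mm keeps the maximum within ~0.5 degrees of the
        continuous optimum on smooth paths.
    """

    gap_mm: float = 5.0
    chord_mm: float = 10.0
    station_step_mm: float = 0.5

    def __post_init__(self) -> None:
        if self.gap_mm <= 0 or self.chord_mm <= 0 or self.station_step_mm <= 0:
            raise ValueError("gap_mm, chord_mm and station_step_mm must be > 0")

    @property
    def window_mm(self) -> float:
        """Total arc length spanned by one chord pair."""
        return 2.0 * self.chord_mm + self.gap_mm

    def to_dict(self) -> dict:
        return {
            "gap_mm": self.gap_mm,
            "chord_mm": self.chord_mm,
            "station_step_mm": self.station_step_mm,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CurvatureParams":
        return cls(**d)


@dataclass(frozen=True)
class ArcInterval:
    """A closed interval of arc-length positions on a path (mm)."""

    s_start_mm: float
    s_end_mm: float

    def __post_init__(self) -> None:
        if not (0 <= self.s_start_mm <= self.s_end_mm):
            raise ValueError(
                f"need 0 <= s_start <= s_end, got [{self.s_start_mm}, {self.s_end_mm}]"
            )

    @property
    def length_mm(self) -> float:
        return self.s_end_mm - self.s_start_mm


class CenterlinePath:
    """An ordered 3D polyline with uniform nominal spacing and arc lengths.

    Parameters
    ----------
    points
        (N, 3) array of millimetre coordinates, N >= 2, no two consecutive
        points identical.
    spacing_mm
        Nominal resampling step.  Interior steps must be uniform within
        half the nominal spacing.
    """

    def __init__(self, points: np.ndarray, spacing_mm: float):
        points = np.asarray(points, dtype=float)
        if points.ndim != 2 or points.shape[1] != 3 or points.shape[0] < 2:
            raise DegeneratePathError("need an (N, 3) array with N >= 2")
        if not np.all(np.isfinite(points)):
            raise DegeneratePathError("non-finite coordinates")
        seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
        if np.any(seg <= 0):
            raise DegeneratePathError("consecutive duplicate points")
        cumlen = np.concatenate([[0.0], np.cumsum(seg)])
        if points.shape[0] > 2:
            dev = np.abs(seg[:-1] - spacing_mm)  # last step may be short
            if np.any(dev > 0.5 * spacing_mm + _EPS):
                raise DegeneratePathError(
                    "arc-length steps deviate more than 0.5*spacing from nominal"
                )
        self.points = points
        self.spacing_mm = float(spacing_mm)
        self.cumlen_mm = cumlen

    @property
    def total_length_mm(self) -> float:
        return float(self.cumlen_mm[-1])

    def __len__(self) -> int:
        return self.points.shape[0]

    # -- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "points_mm": self.points.tolist(),
            "spacing_mm": self.spacing_mm,
            "cumlen_mm": self.cumlen_mm.tolist(),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_dict(cls, d: dict) -> "CenterlinePath":
        return cls(np.asarray(d["points_mm"], dtype=float), float(d["spacing_mm"]))

    @classmethod
    def from_json(cls, s: str) -> "CenterlinePath":
        return cls.from_dict(json.loads(s))


def resample_path(raw_points: np.ndarray, spacing_mm: float) -> CenterlinePath:
    """Resample a raw polyline at uniform arc-length steps.

    The first and last input points are preserved exactly; interior points
    are linearly interpolated along the input polyline.  Consecutive
    duplicate input points are dropped before interpolation.
    """
    if spacing_mm <= 0:
        raise ValueError("spacing_mm must be > 0")
    pts = np.asarray(raw_points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 2:
        raise DegeneratePathError("need at least two 3D points")
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    keep = np.concatenate([[True], seg > _EPS])
    pts = pts[keep]
    if pts.shape[0] < 2:
        raise DegeneratePathError("all input points coincide")
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    n = max(2, int(round(total / spacing_mm)) + 1)
    s = np.linspace(0.0, total, n)
    out = np.column_stack([np.interp(s, cum, pts[:, k]) for k in range(3)])
    out[0] = pts[0]
    out[-1] = pts[-1]
    return CenterlinePath(out, spacing_mm=total / (n - 1))


def _check_range(path: CenterlinePath, s: float) -> None:
    if s < -_EPS or s > path.total_length_mm + _EPS:
        raise OutOfRangeError(
            f"arc position {s} outside [0, {path.total_length_mm}]"
        )


def points_at(path: CenterlinePath, s: np.ndarray) -> np.ndarray:
    """Interpolate path points at the given arc-length positions (vectorised)."""
    s = np.asarray(s, dtype=float)
    return np.column_stack(
        [np.interp(s, path.cumlen_mm, path.points[:, k]) for k in range(3)]
    )


def point_at(path: CenterlinePath, s_mm: float) -> np.ndarray:
    """Interpolate the path point at arc-length position ``s_mm``."""
    _check_range(path, s_mm)
    return points_at(path, np.array([s_mm]))[0]


def arc_distance(path: CenterlinePath, s_a_mm: float, s_b_mm: float) -> float:
    """Distance between two stations measured along the path (mm)."""
    _check_range(path, s_a_mm)
    _check_range(path, s_b_mm)
    return abs(float(s_b_mm) - float(s_a_mm))


def chord_direction(
    path: CenterlinePath, s_mm: float, chord_mm: float, orientation: str = "forward"
) -> np.ndarray:
    """Unit direction of a fixed-length chord anchored at station ``s_mm``.

    ``forward`` takes the chord [s, s+chord]; ``backward`` takes
    [s-chord, s].  Both point "downstream" (from chord start to chord end),
    so on a straight path the two orientations give the same vector.
    """
    if orientation == "forward":
        a, b = s_mm, s_mm + chord_mm
    elif orientation == "backward":
        a, b = s_mm - chord_mm, s_mm
    else:
        raise ValueError(f"orientation must be forward|backward, got {orientation!r}")
    if a < -_EPS or b > path.total_length_mm + _EPS:
        raise OutOfRangeError(
            f"chord [{a}, {b}] exceeds path extent [0, {path.total_length_mm}]"
        )
    p = points_at(path, np.array([a, b]))
    v = p[1] - p[0]
    n = np.linalg.norm(v)
    if n <= _EPS:
        raise DegeneratePathError("zero-length chord")
    return v / n


def angle_deg(u: np.ndarray, v: np.ndarray) -> float:
    """Angle between two 3-vectors in degrees, in [0, 180]."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu <= _EPS or nv <= _EPS:
        raise DegenerateVectorError("zero vector has no direction")
    c = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def section_curvature_profile(
    path: CenterlinePath,
    stent: ArcInterval,
    params: CurvatureParams = CurvatureParams(),
) -> tuple[np.ndarray, np.ndarray]:
    """Chord-pair angles at every admissible sliding station.

    At station ``s`` the first chord spans [s, s+chord] and the second
    spans [s+chord+gap, s+2*chord+gap]; the returned angle is the change
    of direction between the two chords.  Stations run from the start of
    the stent interval to the last position where the full chord-pair
    window still fits inside it.

    Returns
    -------
    (stations, angles)
        Arrays of station arc positions (mm) and angles (degrees).
    """
    w = params.window_mm
    if stent.length_mm < w - _EPS:
        raise InsufficientLengthError(
            f"stent interval {stent.length_mm:.2f} mm shorter than "
            f"chord-pair window {w:.2f} mm"
        )
    if stent.s_end_mm > path.total_length_mm + _EPS:
        raise OutOfRangeError("stent interval exceeds path extent")
    s0 = stent.s_start_mm
    s_last = stent.s_end_mm - w
    stations = s0 + np.arange(0.0, s_last - s0 + _EPS, params.station_step_mm)
    if stations[-1] < s_last - _EPS:
        stations = np.append(stations, s_last)
    c, g = params.chord_mm, params.gap_mm
    p0 = points_at(path, stations)
    p1 = points_at(path, stations + c)
    p2 = points_at(path, stations + c + g)
    p3 = points_at(path, stations + w)
    d1 = p1 - p0
    d2 = p3 - p2
    n1 = np.linalg.norm(d1, axis=1)
    n2 = np.linalg.norm(d2, axis=1)
    if np.any(n1 <= _EPS) or np.any(n2 <= _EPS):
        raise DegeneratePathError("zero-length chord in curvature profile")
    cosang = np.clip(np.sum(d1 * d2, axis=1) / (n1 * n2), -1.0, 1.0)
    return stations, np.degrees(np.arccos(cosang))


def max_section_curvature(
    path: CenterlinePath,
    stent: ArcInterval,
    params: CurvatureParams = CurvatureParams(),
) -> float:
    """Maximum change of direction between gapped chord pairs (degrees).

    Zero for a straight path; equals the full bend angle when a localized
    planar bend falls between one chord pair.
    """
    _, angles = section_curvature_profile(path, stent, params)
    return float(np.max(angles))


def max_curvature_station(
    path: CenterlinePath,
    stent: ArcInterval,
    params: CurvatureParams = CurvatureParams(),
) -> tuple[float, float]:
    """Return (angle_deg, station_mm) of the maximum; first station on ties."""
    stations, angles = section_curvature_profile(path, stent, params)
    i = int(np.argmax(angles))
    return float(angles[i]), float(stations[i])
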