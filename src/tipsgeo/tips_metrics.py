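"""The seven 3D TIPS stent-geometry parameters.

Measured on a venous centerline path running from the portal venous
confluence, through the stent tract, to the IVC, delimited by six landmark
arc positions:

* distance from the cranial stent end to the IVC (mm)
* minimal stent diameter (mm)
* length of the covered stent portion (mm)
* maximum sectional stent curvature (degrees)
* angle between the covered stent ends (degrees)
* alpha angle between the portal-vein course and the covered stent's
  caudal beginning (degrees)
* length from the portal confluence to the (uncovered) stent beginning (mm)

All distances are arc lengths along the path; angles are measured between
1-cm chord directions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from .curvepath import (
    ArcInterval,
    CenterlinePath,
    CurvatureParams,
    angle_deg,
    arc_distance,
    chord_direction,
    max_section_curvature,
)
from .errors import InvalidLandmarksError, NoLumenError
from .volume_centerline import (
    COVERED_STENT,
    LabelVolume,
    SectionProfile,
    UNCOVERED_STENT,
    profile_stent,
)

__all__ = [
    "PathLandmarks",
    "TipsGeometry",
    "snap_landmarks",
    "cranial_end_to_ivc",
    "covered_length",
    "confluence_to_stent",
    "covered_ends_angle",
    "alpha_angle",
    "min_stent_diameter",
    "compute_path_metrics",
    "compute_all",
    "CSV_COLUMNS",
]

_LM_ORDER = (
    "confluence_start",
    "uncovered_distal_begin",
    "covered_distal_begin",
    "covered_cranial_end",
    "stent_cranial_end",
    "ivc_junction",
)


@dataclass(frozen=True)
class PathLandmarks:
    """Arc-length positions (mm) of the six anatomical/stent landmarks."""

    confluence_start: float
    uncovered_distal_begin: float
    covered_distal_begin: float
    covered_cranial_end: float
    stent_cranial_end: float
    ivc_junction: float

    def validate(self, total_length_mm: float | None = None, tol: float = 1e-6) -> None:
        vals = [getattr(self, k) for k in _LM_ORDER]
        if abs(vals[0]) > tol:
            raise InvalidLandmarksError("confluence_start must be 0 (path origin)")
        if any(b < a - tol for a, b in zip(vals[:-1], vals[1:])):
            raise InvalidLandmarksError(f"landmarks not non-decreasing: {vals}")
        if total_length_mm is not None and abs(self.ivc_junction - total_length_mm) > max(tol, 0.5):
            raise InvalidLandmarksError(
                f"ivc_junction {self.ivc_junction} != path length {total_length_mm}"
            )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PathLandmarks":
        return cls(**{k: float(d[k]) for k in _LM_ORDER})


@dataclass(frozen=True)
class TipsGeometry:
    """The seven measured parameters, lengths in mm and angles in degrees."""

    cranial_end_to_ivc_mm: float
    min_stent_diameter_mm: float
    covered_length_mm: float
    max_curvature_deg: float
    covered_ends_angle_deg: float
    alpha_angle_deg: float
    confluence_to_stent_mm: float

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict())


# column names mirroring the cohort-table row block (snake_case)
CSV_COLUMNS = {
    "cranial_end_to_ivc_mm": "cranial_tips_stent_end_mm",
    "min_stent_diameter_mm": "minimal_stent_diameter_mm",
    "covered_length_mm": "length_of_covered_stent_portion_mm",
    "max_curvature_deg": "stent_curvature_deg",
    "covered_ends_angle_deg": "angle_between_covered_stent_ends_deg",
    "alpha_angle_deg": "alpha_angle_deg",
    "confluence_to_stent_mm": "confluence_to_tips_stent_mm",
}


def snap_landmarks(path: CenterlinePath, points: dict) -> PathLandmarks:
    """Snap 3D landmark points to the nearest path stations.

    ``points`` maps the four interior landmark names to [x, y, z] mm;
    ``confluence_start`` and ``ivc_junction`` are pinned to the path ends
    (they define the path) and may be omitted.
    """
    out = {"confluence_start": 0.0, "ivc_junction": path.total_length_mm}
    a = path.points[:-1]
    seg = path.points[1:] - a
    seg_len2 = np.sum(seg**2, axis=1)
    for name in _LM_ORDER[1:-1]:
        p = np.asarray(points[name], dtype=float)
        # project onto every segment for a sub-station arc position
        t = np.clip(np.sum((p - a) * seg, axis=1) / seg_len2, 0.0, 1.0)
        foot = a + t[:, np.newaxis] * seg
        i = int(np.argmin(np.linalg.norm(foot - p, axis=1)))
        out[name] = float(
            path.cumlen_mm[i] + t[i] * (path.cumlen_mm[i + 1] - path.cumlen_mm[i])
        )
    lm = PathLandmarks(**out)
    lm.validate(path.total_length_mm)
    return lm


def _checked(path: CenterlinePath, lm: PathLandmarks) -> None:
    lm.validate(path.total_length_mm)


def cranial_end_to_ivc(path: CenterlinePath, lm: PathLandmarks) -> float:
    """Arc length from the cranial stent end to the IVC junction (mm)."""
    _checked(path, lm)
    return arc_distance(path, lm.stent_cranial_end, lm.ivc_junction)


def covered_length(path: CenterlinePath, lm: PathLandmarks) -> float:
    """Arc length of the covered (graft-lined) stent portion (mm)."""
    _checked(path, lm)
    return arc_distance(path, lm.covered_distal_begin, lm.covered_cranial_end)


def confluence_to_stent(path: CenterlinePath, lm: PathLandmarks) -> float:
    """Arc length from the path origin to the uncovered stent beginning (mm)."""
    _checked(path, lm)
    return arc_distance(path, lm.confluence_start, lm.uncovered_distal_begin)


def covered_ends_angle(
    path: CenterlinePath, lm: PathLandmarks, chord_mm: float = 10.0
) -> float:
    """Angle between the axes of the two covered stent ends (degrees).

    Each end axis is the local 1-cm chord tangent pointing downstream:
    the forward chord at the distal covered end and the backward chord at
    the cranial covered end, so a straight stent yields 0.
    """
    _checked(path, lm)
    u = chord_direction(path, lm.covered_distal_begin, chord_mm, "forward")
    v = chord_direction(path, lm.covered_cranial_end, chord_mm, "backward")
    return angle_deg(u, v)


def alpha_angle(
    path: CenterlinePath, lm: PathLandmarks, chord_mm: float = 10.0
) -> float:
    """Angle between the portal-vein course and the covered stent's start.

    The PV course is the backward 1-cm chord just upstream of the covered
    stent's caudal beginning; the stent start is the forward chord from the
    same station.  Collinear course and stent give 0 degrees.
    """
    _checked(path, lm)
    u = chord_direction(path, lm.covered_distal_begin, chord_mm, "backward")
    v = chord_direction(path, lm.covered_distal_begin, chord_mm, "forward")
    return angle_deg(u, v)


def min_stent_diameter(profiles: list[SectionProfile]) -> float:
    """Smallest equivalent-circle diameter over the stent sections (mm)."""
    ok = [p.equiv_diameter_mm for p in profiles if not p.empty]
    if not ok:
        raise NoLumenError("all cross-section profiles are empty")
    return float(min(ok))


def compute_path_metrics(
    path: CenterlinePath,
    lm: PathLandmarks,
    params: CurvatureParams = CurvatureParams(),
    chord_mm: float = 10.0,
) -> dict:
    """The six path-derived metrics (everything except the diameter).

    Curvature is maximised over the whole stent, uncovered portion
    included: the interval [uncovered_distal_begin, stent_cranial_end].
    """
    _checked(path, lm)
    stent = ArcInterval(lm.uncovered_distal_begin, lm.stent_cranial_end)
    return {
        "cranial_end_to_ivc_mm": cranial_end_to_ivc(path, lm),
        "covered_length_mm": covered_length(path, lm),
        "confluence_to_stent_mm": confluence_to_stent(path, lm),
        "max_curvature_deg": max_section_curvature(path, stent, params),
        "covered_ends_angle_deg": covered_ends_angle(path, lm, chord_mm),
        "alpha_angle_deg": alpha_angle(path, lm, chord_mm),
    }


def compute_all(
    volume: LabelVolume,
    path: CenterlinePath,
    lm: PathLandmarks,
    params: CurvatureParams = CurvatureParams(),
    chord_mm: float = 10.0,
    profile_step_mm: float = 1.0,
    stent_labels: tuple = (UNCOVERED_STENT, COVERED_STENT),
) -> TipsGeometry:
    """Assemble all seven geometry parameters from volume + path + landmarks."""
    m = compute_path_metrics(path, lm, params, chord_mm)
    stent = ArcInterval(lm.uncovered_distal_begin, lm.stent_cranial_end)
    profiles = profile_stent(volume, path, stent, profile_step_mm, stent_labels)
    m["min_stent_diameter_mm"] = min_stent_diameter(profiles)
    return TipsGeometry(**m)
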