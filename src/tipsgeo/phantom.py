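"""Synthetic stent/vessel phantoms with analytic ground truth.

The patient CTs behind the method are not public, so every measurement
operation is validated against parametric tube phantoms rendered into label
volumes.  A phantom's centerline is built as an arc-length-parameterised
planar curve: straight runs with optional localized turns (sharp bends are
rounded by a small fillet arc so they are renderable) or a circular arc
swept across the stent.  Because the curve is parameterised by arc length,
every landmark position and every along-path distance of the ground truth is
exact by construction; ground-truth angles and curvature are the package's
chord estimators evaluated on the exact analytic curve (for a localized bend
with long straight arms this equals the nominal bend angle exactly, since
the fillet fits inside the 5-mm measurement gap).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import NamedTuple

import numpy as np
from scipy.spatial import cKDTree

from .curvepath import (
    ArcInterval,
    CenterlinePath,
    CurvatureParams,
    max_section_curvature,
    points_at,
    resample_path,
)
from .errors import ParameterError
from .tips_metrics import PathLandmarks, TipsGeometry, compute_path_metrics
from .volume_centerline import (
    COVERED_STENT,
    LUMEN,
    LabelVolume,
    SeedSet,
    UNCOVERED_STENT,
)

__all__ = ["PhantomSpec", "PhantomTruth", "PhantomCase", "make_phantom", "phantom_suite"]

_DENSE_DS = 0.05   # integration step for the analytic curve (mm)
_TREE_DS = 0.2     # centerline sampling used for voxel labeling (mm)


@dataclass(frozen=True)
class PhantomSpec:
    """Parametric description of one phantom.

    kind
        "straight", "bend" (single planar turn of ``bend_deg`` at
        ``vertex_s_mm``), "arc" (circular arc of ``arc_sweep_deg`` swept
        uniformly across the stent interval), or "composite" (a PV->stent
        turn of ``alpha_deg`` at the covered beginning plus a stent->HV
        turn of ``hv_bend_deg`` at the cranial stent end).
    Segment lengths (mm): pv_length -> uncovered -> covered -> cranial
    offset to the IVC; the stent's cranial end coincides with the covered
    cranial end (graft-lined up to the tip, uncovered only distally).
    """

    kind: str = "straight"
    pv_length_mm: float = 20.0
    uncovered_length_mm: float = 15.0
    covered_length_mm: float = 40.0
    cranial_offset_mm: float = 6.0
    radius_mm: float = 4.0
    bend_deg: float = 0.0
    vertex_s_mm: float | None = None
    fillet_radius_mm: float = 2.0
    arc_sweep_deg: float = 0.0
    alpha_deg: float = 0.0
    hv_bend_deg: float = 0.0
    bend_plane_deg: float = 0.0
    waist_diameter_mm: float | None = None
    waist_s_mm: float | None = None
    waist_halfwidth_mm: float = 6.0
    spacing_mm: float = 1.0
    dropout: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("straight", "bend", "arc", "composite"):
            raise ParameterError(f"unknown phantom kind {self.kind!r}")
        for ang in (self.bend_deg, self.alpha_deg, self.hv_bend_deg):
            if not (0.0 <= ang <= 180.0):
                raise ParameterError("bend angles must lie in [0, 180] degrees")
        if not (0.0 <= self.dropout < 1.0):
            raise ParameterError("dropout must lie in [0, 1)")

    # landmark arc positions, exact by construction
    @property
    def s_uncovered_begin(self) -> float:
        return self.pv_length_mm

    @property
    def s_covered_begin(self) -> float:
        return self.pv_length_mm + self.uncovered_length_mm

    @property
    def s_covered_end(self) -> float:
        return self.s_covered_begin + self.covered_length_mm

    @property
    def total_length_mm(self) -> float:
        return self.s_covered_end + self.cranial_offset_mm

    def min_radius_mm(self) -> float:
        r = self.radius_mm
        if self.waist_diameter_mm is not None:
            r = min(r, self.waist_diameter_mm / 2.0)
        return r

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "PhantomSpec":
        return cls(**json.loads(s))


@dataclass
class PhantomTruth:
    """Exact centerline, landmarks and geometry implied by a spec."""

    path: CenterlinePath
    landmarks: PathLandmarks
    geometry: TipsGeometry
    landmark_points: dict = field(default_factory=dict)

    def seed_set(self) -> SeedSet:
        return SeedSet(self.path.points[0], self.path.points[-1])

    def to_json(self) -> str:
        return json.dumps(
            {
                "path": self.path.to_dict(),
                "landmarks": self.landmarks.to_dict(),
                "geometry": self.geometry.to_dict(),
                "landmark_points": {k: list(v) for k, v in self.landmark_points.items()},
            }
        )


class PhantomCase(NamedTuple):
    spec: PhantomSpec
    volume: LabelVolume
    truth: PhantomTruth


# ---------------------------------------------------------------------------
# analytic centerline
# ---------------------------------------------------------------------------

def _turn_events(spec: PhantomSpec) -> list[tuple[float, float, float]]:
    """(center_s, turn_deg, ramp_length) of each localized direction change."""
    events = []
    if spec.kind == "bend" and spec.bend_deg > 0:
        v = spec.vertex_s_mm
        if v is None:
            v = spec.s_covered_begin + spec.covered_length_mm / 2.0
        events.append((v, spec.bend_deg, spec.fillet_radius_mm))
    elif spec.kind == "composite":
        if spec.alpha_deg > 0:
            events.append((spec.s_covered_begin, spec.alpha_deg, spec.fillet_radius_mm))
        if spec.hv_bend_deg > 0:
            events.append((spec.s_covered_end, spec.hv_bend_deg, spec.fillet_radius_mm))
    return events


def _direction_angle(spec: PhantomSpec, s: np.ndarray) -> np.ndarray:
    """In-plane direction angle phi(s) in radians."""
    phi = np.zeros_like(s)
    if spec.kind == "arc" and spec.arc_sweep_deg > 0:
        a, b = spec.s_uncovered_begin, spec.s_covered_end
        sweep = np.radians(spec.arc_sweep_deg)
        phi += sweep * np.clip((s - a) / (b - a), 0.0, 1.0)
    for center, turn_deg, fillet in _turn_events(spec):
        turn = np.radians(turn_deg)
        half = 0.5 * fillet * turn  # fillet arc length / 2
        phi += turn * np.clip((s - (center - half)) / (2.0 * half), 0.0, 1.0)
    return phi


def _dense_centerline(spec: PhantomSpec, ds: float = _DENSE_DS) -> tuple[np.ndarray, np.ndarray]:
    """(s, points) of the analytic curve sampled at step ``ds``."""
    total = spec.total_length_mm
    n = int(np.ceil(total / ds)) + 1
    s = np.linspace(0.0, total, n)
    phi = _direction_angle(spec, s)
    b = np.radians(spec.bend_plane_deg)
    e1 = np.array([0.0, 0.0, 1.0])
    e2 = np.array([np.cos(b), np.sin(b), 0.0])
    d = np.cos(phi)[:, None] * e1 + np.sin(phi)[:, None] * e2
    # trapezoidal integration of the unit tangent
    step = np.diff(s)[:, None] * 0.5 * (d[1:] + d[:-1])
    pts = np.vstack([np.zeros(3), np.cumsum(step, axis=0)])
    return s, pts


def _radius_profile(spec: PhantomSpec, s: np.ndarray) -> np.ndarray:
    r = np.full_like(s, spec.radius_mm)
    if spec.waist_diameter_mm is not None:
        sw = spec.waist_s_mm
        if sw is None:
            sw = spec.s_covered_begin + spec.covered_length_mm / 2.0
        h = spec.waist_halfwidth_mm
        inside = np.abs(s - sw) < h
        dip = spec.radius_mm - spec.waist_diameter_mm / 2.0
        r[inside] -= dip * np.cos(np.pi * (s[inside] - sw) / (2.0 * h)) ** 2
    return r


def _truth_from_path(spec: PhantomSpec, path: CenterlinePath) -> PhantomTruth:
    lm = PathLandmarks(
        confluence_start=0.0,
        uncovered_distal_begin=spec.s_uncovered_begin,
        covered_distal_begin=spec.s_covered_begin,
        covered_cranial_end=spec.s_covered_end,
        stent_cranial_end=spec.s_covered_end,
        ivc_junction=path.total_length_mm,
    )
    params = CurvatureParams(station_step_mm=0.1)
    m = compute_path_metrics(path, lm, params)
    m["min_stent_diameter_mm"] = 2.0 * spec.min_radius_mm()
    lm_points = {
        name: points_at(path, np.array([getattr(lm, name)]))[0]
        for name in (
            "uncovered_distal_begin",
            "covered_distal_begin",
            "covered_cranial_end",
            "stent_cranial_end",
        )
    }
    return PhantomTruth(path, lm, TipsGeometry(**m), lm_points)


def analytic_arc_curvature(spec: PhantomSpec, params: CurvatureParams = CurvatureParams()) -> float:
    """Closed-form chord-pair curvature of an "arc" phantom (degrees).

    On a circular arc a chord's direction is the tangent at its midpoint,
    so the chord-pair angle is the arc swept between the two chord
    midpoints: (chord + gap) / R radians.
    """
    if spec.kind != "arc":
        raise ParameterError("closed form applies to arc phantoms only")
    stent_len = spec.uncovered_length_mm + spec.covered_length_mm
    radius = stent_len / np.radians(spec.arc_sweep_deg)
    return float(np.degrees((params.chord_mm + params.gap_mm) / radius))


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def make_phantom(spec: PhantomSpec) -> tuple[LabelVolume, PhantomTruth]:
    """Render a spec into a label volume and return it with its ground truth.

    Every voxel whose center lies within the (possibly waisted) radius
    profile of the analytic centerline receives the label of its arc
    interval: lumen outside the stent, uncovered / covered stent inside.
    Label dropout (strut artefacts) is applied reproducibly from the spec
    seed.
    """
    if spec.min_radius_mm() < 2.0 * spec.spacing_mm:
        raise ParameterError(
            f"tube radius {spec.min_radius_mm()} mm under 2 voxels "
            f"({spec.spacing_mm} mm spacing): unmeasurable"
        )
    s_dense, pts_dense = _dense_centerline(spec)
    truth_path = resample_path(pts_dense, 0.25)
    truth = _truth_from_path(spec, truth_path)

    stride = max(1, int(round(_TREE_DS / _DENSE_DS)))
    s_tree = s_dense[::stride]
    tree_pts = pts_dense[::stride]

    margin = spec.radius_mm + 3.0
    lo = pts_dense.min(axis=0) - margin
    hi = pts_dense.max(axis=0) + margin
    sp = spec.spacing_mm
    shape = np.ceil((hi - lo) / sp).astype(int) + 1
    tree = cKDTree(tree_pts)

    voxels = np.zeros(shape, dtype=np.uint8)
    # process in z-slabs to bound the coordinate array size
    ii = np.arange(shape[0]) * sp + lo[0]
    jj = np.arange(shape[1]) * sp + lo[1]
    slab = max(1, int(2e6 // (shape[0] * shape[1])))
    for k0 in range(0, shape[2], slab):
        kk = np.arange(k0, min(k0 + slab, shape[2]))
        X, Y, Z = np.meshgrid(ii, jj, kk * sp + lo[2], indexing="ij")
        centers = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
        dist, idx = tree.query(centers, workers=-1)
        s_near = s_tree[idx]
        inside = dist <= _radius_profile(spec, s_near)
        lab = np.zeros(centers.shape[0], dtype=np.uint8)
        sn = s_near[inside]
        code = np.full(sn.shape, LUMEN, dtype=np.uint8)
        code[(sn >= spec.s_uncovered_begin) & (sn < spec.s_covered_begin)] = UNCOVERED_STENT
        code[(sn >= spec.s_covered_begin) & (sn < spec.s_covered_end)] = COVERED_STENT
        lab[inside] = code
        voxels[:, :, kk] = lab.reshape(X.shape)

    if spec.dropout > 0:
        rng = np.random.default_rng(spec.seed)
        labeled = voxels > 0
        drop = rng.random(voxels.shape) < spec.dropout
        voxels[labeled & drop] = 0

    volume = LabelVolume(voxels, spacing_mm=np.full(3, sp), origin=lo)
    return volume, truth


# ---------------------------------------------------------------------------
# deterministic test battery
# ---------------------------------------------------------------------------

def phantom_suite(seed: int = 0) -> list[PhantomCase]:
    """Deterministic battery of >= 40 phantoms spanning the study conditions.

    Straight tubes at four cranial offsets (0, 6, 16.5, 26.5 mm — spanning
    the cohort's group medians), localized bends of 15–120 degrees, waist
    diameters 6/7/8 mm, gentle arcs, and composite PV->stent->HV tracts,
    each at 0.5 and 1.0 mm voxel spacing.
    """
    specs: list[PhantomSpec] = []
    spacings = (0.5, 1.0)
    for sp in spacings:
        for off in (0.0, 6.0, 16.5, 26.5):
            specs.append(PhantomSpec(kind="straight", cranial_offset_mm=off, spacing_mm=sp))
    i = 0
    for sp in spacings:
        for off in (6.0, 16.5):
            for theta in (15.0, 30.0, 45.0, 60.0, 90.0, 120.0):
                specs.append(
                    PhantomSpec(
                        kind="bend",
                        bend_deg=theta,
                        cranial_offset_mm=off,
                        bend_plane_deg=(i * 40.0) % 180.0,
                        spacing_mm=sp,
                    )
                )
                i += 1
    for sp in spacings:
        for wd in (6.0, 7.0, 8.0):
            specs.append(
                PhantomSpec(
                    kind="straight", radius_mm=5.0, waist_diameter_mm=wd, spacing_mm=sp
                )
            )
    for sp in spacings:
        for sweep in (30.0, 60.0):
            specs.append(
                PhantomSpec(
                    kind="arc",
                    arc_sweep_deg=sweep,
                    pv_length_mm=15.0,
                    covered_length_mm=60.0,
                    bend_plane_deg=(90.0 if sweep == 60.0 else 30.0),
                    spacing_mm=sp,
                )
            )
    for k, alpha in enumerate((30.0, 60.0, 90.0)):
        specs.append(
            PhantomSpec(
                kind="composite",
                alpha_deg=alpha,
                hv_bend_deg=30.0,
                uncovered_length_mm=25.0,
                cranial_offset_mm=16.5,
                bend_plane_deg=20.0 + 50.0 * k,
                spacing_mm=1.0,
            )
        )
    cases = []
    for j, spec in enumerate(specs):
        spec = PhantomSpec(**{**asdict(spec), "seed": (seed + j) % (2**31)})
        volume, truth = make_phantom(spec)
        cases.append(PhantomCase(spec, volume, truth))
    return cases
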