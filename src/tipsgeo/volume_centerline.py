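"""Semiautomated centerline extraction through labeled vascular volumes.

The post-TIPS CT is represented as a :class:`LabelVolume` — an integer voxel
grid (background 0, vessel lumen 1, uncovered stent 2, covered stent 3) with
millimetre spacing, origin and an orthonormal direction matrix in the LPS
patient frame.  Given user-supplied seed points at the portal venous
confluence and in the IVC, :func:`extract_centerline` finds a minimum-cost
26-connected voxel path whose edge costs are inversely weighted by the
distance to background (medialness), re-centers each station on the centroid
of its orthogonal cross-section, and resamples to a uniform-step
:class:`~tipsgeo.curvepath.CenterlinePath`.

Cross-sections orthogonal to the path (multiplanar reconstructions) are
resampled on a fine in-plane grid by :func:`section_profile`, which reports
the area and equivalent-circle diameter of the connected component of
selected labels containing the path point.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

from .curvepath import CenterlinePath, ArcInterval, point_at, points_at, resample_path
from .errors import BadSeedError, NoPathError, OutOfRangeError

__all__ = [
    "BACKGROUND",
    "LUMEN",
    "UNCOVERED_STENT",
    "COVERED_STENT",
    "LabelVolume",
    "SeedSet",
    "SectionProfile",
    "extract_centerline",
    "section_profile",
    "profile_stent",
]

BACKGROUND = 0
LUMEN = 1
UNCOVERED_STENT = 2
COVERED_STENT = 3

_VALID_LABELS = frozenset({BACKGROUND, LUMEN, UNCOVERED_STENT, COVERED_STENT})

# LPS <-> RAS: negate the first two world axes (DICOM vs NIfTI convention)
_RAS2LPS = np.diag([-1.0, -1.0, 1.0, 1.0])


@dataclass
class LabelVolume:
    """Integer label grid with LPS millimetre geometry.

    voxels[i, j, k] maps to world point origin + direction @ (spacing * (i,j,k)).
    """

    voxels: np.ndarray
    spacing_mm: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    direction: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be a 3D array")
        self.spacing_mm = np.asarray(self.spacing_mm, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)
        if np.any(self.spacing_mm <= 0):
            raise ValueError("spacing must be > 0 per axis")
        if not np.allclose(self.direction @ self.direction.T, np.eye(3), atol=1e-6):
            raise ValueError("direction matrix must be orthonormal")
        labels = np.unique(self.voxels)
        if not set(int(v) for v in labels) <= _VALID_LABELS:
            raise ValueError(f"labels must be within {sorted(_VALID_LABELS)}")

    # -- geometry ------------------------------------------------------

    @property
    def affine(self) -> np.ndarray:
        """4x4 index -> LPS world map."""
        a = np.eye(4)
        a[:3, :3] = self.direction * self.spacing_mm[np.newaxis, :]
        a[:3, 3] = self.origin
        return a

    def index_to_world(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.asarray(ijk, dtype=float)
        return (self.direction @ (self.spacing_mm * ijk).T).T + self.origin

    def world_to_index(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.asarray(xyz, dtype=float)
        return (self.direction.T @ (xyz - self.origin).T).T / self.spacing_mm

    # -- NIfTI I/O (RAS on disk, LPS in memory) ------------------------

    @classmethod
    def from_nifti(cls, path: str) -> "LabelVolume":
        import nibabel as nib

        img = nib.load(path)
        affine = _RAS2LPS @ img.affine
        m = affine[:3, :3]
        spacing = np.linalg.norm(m, axis=0)
        direction = m / spacing[np.newaxis, :]
        data = np.asarray(img.dataobj).astype(np.int16)
        return cls(data, spacing_mm=spacing, origin=affine[:3, 3], direction=direction)

    def to_nifti(self, path: str) -> None:
        import nibabel as nib

        ras = _RAS2LPS @ self.affine
        nib.save(nib.Nifti1Image(self.voxels.astype(np.uint8), ras), path)


@dataclass
class SeedSet:
    """User-supplied seeds in LPS millimetres: the semiautomated input."""

    confluence: np.ndarray
    ivc: np.ndarray
    waypoints: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.confluence = np.asarray(self.confluence, dtype=float)
        self.ivc = np.asarray(self.ivc, dtype=float)
        self.waypoints = [np.asarray(w, dtype=float) for w in self.waypoints]

    def to_json(self) -> str:
        return json.dumps(
            {
                "confluence": self.confluence.tolist(),
                "ivc": self.ivc.tolist(),
                "waypoints": [w.tolist() for w in self.waypoints],
            }
        )

    @classmethod
    def from_json(cls, s: str) -> "SeedSet":
        d = json.loads(s)
        return cls(d["confluence"], d["ivc"], d.get("waypoints", []))


@dataclass
class SectionProfile:
    """One orthogonal cross-section: area and equivalent-circle diameter."""

    s_mm: float
    center: np.ndarray
    normal: np.ndarray
    equiv_diameter_mm: float
    area_mm2: float
    empty: bool = False


# ---------------------------------------------------------------------------
# path search
# ---------------------------------------------------------------------------

def _neighbor_offsets() -> np.ndarray:
    offs = [
        (i, j, k)
        for i in (-1, 0, 1)
        for j in (-1, 0, 1)
        for k in (-1, 0, 1)
        if (i, j, k) != (0, 0, 0)
    ]
    # keep one of each +/- pair; both directions added explicitly
    return np.array([o for o in offs if o > (0, 0, 0)])


def _seed_to_node(volume: LabelVolume, mask: np.ndarray, node_id: np.ndarray,
                  seed: np.ndarray, name: str) -> int:
    ijk = np.rint(volume.world_to_index(seed)).astype(int)
    if np.any(ijk < 0) or np.any(ijk >= mask.shape) or not mask[tuple(ijk)]:
        raise BadSeedError(f"{name} seed {seed.tolist()} lies in background")
    return int(node_id[tuple(ijk)])


def extract_centerline(
    volume: LabelVolume,
    seeds: SeedSet,
    spacing_mm: float = 1.0,
    medialness_eps_mm: float = 0.1,
    smooth_window_mm: float = 2.0,
    recenter_passes: int = 2,
    refine_bends: bool = True,
) -> CenterlinePath:
    """Minimum-cost medial path from the confluence seed to the IVC seed.

    The voxel graph is 26-connected over non-background voxels; each edge
    costs (Euclidean step length) / (eps + distance-to-background at the
    target voxel), which pulls the geodesic onto the medial axis.  The voxel
    polyline is lightly smoothed to stabilise tangents, resampled at
    ``spacing_mm``, and each interior station is then re-centered on the
    centroid of the connected in-plane component of its orthogonal
    cross-section (``recenter_passes`` iterations); re-centering, rather
    than heavier smoothing, is what removes voxel jitter, so localized
    bends are not flattened.
    """
    mask = volume.voxels != BACKGROUND
    if not mask.any():
        raise NoPathError("volume contains no non-background voxels")
    dt = ndimage.distance_transform_edt(mask, sampling=volume.spacing_mm)

    node_id = np.full(mask.shape, -1, dtype=np.int64)
    n = int(mask.sum())
    node_id[mask] = np.arange(n)

    rows, cols, data = [], [], []
    for off in _neighbor_offsets():
        sa = tuple(slice(max(0, -o), mask.shape[d] - max(0, o))
                   for d, o in enumerate(off))
        sb = tuple(slice(max(0, o), mask.shape[d] + min(0, o))
                   for d, o in enumerate(off))
        both = mask[sa] & mask[sb]
        if not both.any():
            continue
        a = node_id[sa][both]
        b = node_id[sb][both]
        step = float(np.linalg.norm(off * volume.spacing_mm))
        da = dt[sa][both]
        db = dt[sb][both]
        rows.append(a)
        cols.append(b)
        data.append(step / (medialness_eps_mm + db))
        rows.append(b)
        cols.append(a)
        data.append(step / (medialness_eps_mm + da))
    graph = csr_matrix(
        (np.concatenate(data), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    )

    stops = [seeds.confluence, *seeds.waypoints, seeds.ivc]
    names = ["confluence"] + [f"waypoint {i}" for i in range(len(seeds.waypoints))] + ["ivc"]
    nodes = [_seed_to_node(volume, mask, node_id, s, nm) for s, nm in zip(stops, names)]

    ijk_of_node = np.argwhere(mask)
    voxel_path: list[np.ndarray] = []
    for src, dst in zip(nodes[:-1], nodes[1:]):
        dist, pred = dijkstra(
            graph, directed=True, indices=src, return_predecessors=True
        )
        if not np.isfinite(dist[dst]):
            raise NoPathError("seeds are not connected through labeled voxels")
        chain = [dst]
        while chain[-1] != src:
            chain.append(int(pred[chain[-1]]))
        chain.reverse()
        if voxel_path:
            chain = chain[1:]
        voxel_path.extend(ijk_of_node[chain])
    pts = volume.index_to_world(np.asarray(voxel_path, dtype=float))

    pts = _moving_average(pts, smooth_window_mm, float(np.min(volume.spacing_mm)))
    path = resample_path(pts, spacing_mm)
    for _ in range(recenter_passes):
        if len(path) <= 4:
            break
        pts = _recenter_stations(volume, path, dt)
        path = resample_path(pts, spacing_mm)
    if len(path) > 4:
        # light smoothing removes residual centroid jitter; sharp bends that
        # it would round off are rebuilt analytically right after
        pts = _moving_average(path.points, smooth_window_mm, spacing_mm)
        path = resample_path(pts, spacing_mm)
    if refine_bends and len(path) > 4:
        path = _refine_corners(volume, path, spacing_mm, dt)
    return path


def _moving_average(pts: np.ndarray, window_mm: float, step_mm: float) -> np.ndarray:
    """Boxcar-smooth interior points; endpoints are kept fixed."""
    half = max(1, int(round(0.5 * window_mm / max(step_mm, 1e-6))))
    if pts.shape[0] <= 2 * half + 1:
        return pts
    kernel = np.ones(2 * half + 1) / (2 * half + 1)
    sm = np.column_stack(
        [np.convolve(np.pad(pts[:, k], half, mode="edge"), kernel, mode="valid")
         for k in range(3)]
    )
    sm[0] = pts[0]
    sm[-1] = pts[-1]
    return sm


def _tangent_at(path: CenterlinePath, s: float, chord_mm: float = 4.0) -> np.ndarray:
    """Central-difference chord tangent, clipped at the path ends."""
    a = max(0.0, s - 0.5 * chord_mm)
    b = min(path.total_length_mm, s + 0.5 * chord_mm)
    p = points_at(path, np.array([a, b]))
    v = p[1] - p[0]
    return v / np.linalg.norm(v)


def _plane_basis(normal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.zeros(3)
    a[int(np.argmin(np.abs(normal)))] = 1.0
    u = np.cross(normal, a)
    u /= np.linalg.norm(u)
    v = np.cross(normal, u)
    return u, v


def _plane_labels(
    volume: LabelVolume,
    center: np.ndarray,
    normal: np.ndarray,
    half_extent_mm: float,
    grid_mm: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Nearest-neighbour label samples on a plane orthogonal to ``normal``.

    The in-plane grid is symmetric about the center and offset by half a
    cell, so sample points never fall exactly on voxel boundaries (which
    would make nearest-neighbour rounding systematically one-sided and
    bias component centroids).

    Returns (labels2d, world points grid, u, v)."""
    u, v = _plane_basis(normal)
    n = int(np.ceil(half_extent_mm / grid_mm))
    r = (np.arange(-n, n) + 0.5) * grid_mm
    X, Y = np.meshgrid(r, r, indexing="ij")
    world = (
        center[np.newaxis, np.newaxis, :]
        + X[..., np.newaxis] * u[np.newaxis, np.newaxis, :]
        + Y[..., np.newaxis] * v[np.newaxis, np.newaxis, :]
    )
    idx = volume.world_to_index(world.reshape(-1, 3)).T
    lab = ndimage.map_coordinates(
        volume.voxels, idx, order=0, mode="constant", cval=BACKGROUND
    ).reshape(X.shape)
    return lab, world, u, v


_STRUCT8 = np.ones((3, 3), dtype=bool)


def _component_mask(mask2d: np.ndarray, grid_mm: float) -> np.ndarray | None:
    """8-connected component containing (or nearest within 2 mm of) the center."""
    if not mask2d.any():
        return None
    lab, _ = ndimage.label(mask2d, structure=_STRUCT8)
    ci = tuple(np.array(mask2d.shape) // 2)
    if mask2d[ci]:
        return lab == lab[ci]
    inside = np.argwhere(mask2d)
    d2 = np.sum((inside - np.array(ci)) ** 2, axis=1)
    j = int(np.argmin(d2))
    if d2[j] * grid_mm**2 > 2.0**2:
        return None
    return lab == lab[tuple(inside[j])]


def _recenter_stations(
    volume: LabelVolume,
    path: CenterlinePath,
    dt: np.ndarray,
    clip_extra_mm: float | None = None,
    damp: float = 1.0,
) -> np.ndarray:
    """Move each interior station toward the centroid of its cross-section.

    ``clip_extra_mm`` restricts the centroid to component pixels within
    (local inscribed radius + clip_extra_mm) of the station; ``damp``
    scales each correction step (useful because at sharp bends the oblique
    slice centroid overshoots the local axis).
    """
    pts = path.points.copy()
    grid = 0.25
    for i in range(1, len(path) - 1):
        s = path.cumlen_mm[i]
        normal = _tangent_at(path, s)
        ijk = np.clip(
            np.rint(volume.world_to_index(pts[i])).astype(int),
            0,
            np.array(dt.shape) - 1,
        )
        r_local = float(dt[tuple(ijk)])
        half = r_local * 1.5 + 1.0
        lab2d, world, _, _ = _plane_labels(volume, pts[i], normal, half, grid)
        comp = _component_mask(lab2d != BACKGROUND, grid)
        if comp is None:
            continue
        sel = world[comp]
        if clip_extra_mm is not None:
            rad = np.linalg.norm(sel - pts[i], axis=1)
            sel = sel[rad <= r_local + clip_extra_mm]
            if sel.shape[0] == 0:
                continue
        pts[i] = pts[i] + damp * (sel.mean(axis=0) - pts[i])
    return pts


# ---------------------------------------------------------------------------
# localized-bend reconstruction
# ---------------------------------------------------------------------------
#
# Around a sharp bend the cross-sections of the tube overlap and both the
# medialness geodesic and centroid re-centering cut or round the corner: the
# generative axis there is not recoverable from inscribed-sphere information
# alone.  The convex outer wall, however, still follows the swept surface of
# the bend (outer radius = axis fillet radius + tube radius), so the corner
# can be rebuilt from it: fit the two straight arms, intersect them, probe
# the outer wall along the exterior bisector to recover the axis apex, and
# replace the corner with the circular fillet tangent to both arms through
# that apex.


def _fit_line(pts: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Total-least-squares 3D line fit: (point, unit direction, rms residual)."""
    c = pts.mean(axis=0)
    u, s, vt = np.linalg.svd(pts - c, full_matrices=False)
    d = vt[0]
    resid = np.linalg.norm((pts - c) - np.outer((pts - c) @ d, d), axis=1)
    return c, d, float(np.sqrt(np.mean(resid**2)))


def _last_inside(volume: LabelVolume, start: np.ndarray, direction: np.ndarray,
                 t_max: float, step: float = 0.1) -> float:
    """Largest t <= t_max still inside the labeled solid along a ray.

    Uses linearly interpolated occupancy (>= 0.5) for a sub-voxel wall
    position estimate."""
    t = np.arange(0.0, t_max + step, step)
    pts = start[np.newaxis, :] + t[:, np.newaxis] * direction[np.newaxis, :]
    idx = volume.world_to_index(pts).T
    occ = ndimage.map_coordinates(
        (volume.voxels != BACKGROUND).astype(np.float32),
        idx, order=1, mode="constant", cval=0.0,
    )
    inside = np.nonzero(occ >= 0.5)[0]
    if inside.size == 0:
        return 0.0
    return float(t[inside[-1]])


def _corner_zones(path: CenterlinePath, thresh_deg: float, chord: float = 6.0) -> list[float]:
    """Centers of localized high-curvature zones.

    A corner that has been chamfered by the path search shows up as two
    curvature peaks (entering and leaving the chamfer), so each
    above-threshold run is summarised by its curvature-weighted center
    rather than its argmax, and nearby runs are merged.
    """
    s = path.cumlen_mm
    ok = (s >= chord) & (s <= s[-1] - chord)
    if not ok.any():
        return []
    st = s[ok]
    a = points_at(path, st - chord)
    m = points_at(path, st)
    b = points_at(path, st + chord)
    d1 = m - a
    d2 = b - m
    cosang = np.sum(d1 * d2, axis=1) / (
        np.linalg.norm(d1, axis=1) * np.linalg.norm(d2, axis=1)
    )
    kappa = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    above = kappa > thresh_deg
    runs: list[tuple[float, float]] = []  # (weighted center, total weight)
    i = 0
    while i < len(st):
        if above[i]:
            j = i
            while j + 1 < len(st) and above[j + 1]:
                j += 1
            w = kappa[i:j + 1]
            runs.append((float(np.average(st[i:j + 1], weights=w)), float(w.sum())))
            i = j + 1
        else:
            i += 1
    merged: list[tuple[float, float]] = []
    for z, w in runs:
        if merged and z - merged[-1][0] < 10.0:
            z0, w0 = merged[-1]
            merged[-1] = ((z0 * w0 + z * w) / (w0 + w), w0 + w)
        else:
            merged.append((z, w))
    return [z for z, _ in merged]


def _refine_corners(
    volume: LabelVolume,
    path: CenterlinePath,
    spacing_mm: float,
    dt: np.ndarray,
    thresh_deg: float = 20.0,
    arm_near_mm: float = 4.0,
    arm_far_mm: float = 16.0,
) -> CenterlinePath:
    """Rebuild sharp localized bends as outer-wall-derived fillet arcs."""
    zones = _corner_zones(path, thresh_deg)
    if not zones:
        return path
    pts = path.points
    shift = 0.0  # replacements change arc length upstream of later zones
    for s_star in zones:
        s_star += shift
        s = path.cumlen_mm
        # fit the arms as far from the disturbed corner zone as the path
        # allows: prefer the widest clearance, falling back toward the
        # corner only when the path (or a neighbouring bend) is too close
        fit = None
        for near in (arm_near_mm + 4.0, arm_near_mm + 2.0, arm_near_mm):
            far = near + (arm_far_mm - arm_near_mm)
            if s_star - far < 0 or s_star + far > s[-1]:
                continue
            w1 = (s >= s_star - far) & (s <= s_star - near)
            w2 = (s >= s_star + near) & (s <= s_star + far)
            if w1.sum() < 4 or w2.sum() < 4:
                continue
            c1, u, r1 = _fit_line(pts[w1])
            c2, v, r2 = _fit_line(pts[w2])
            if r1 <= 0.2 and r2 <= 0.2:
                fit = (w1, w2, c1, u, c2, v, near)
                break
        if fit is None:
            continue  # arms never straighten: a gentle curve, leave it alone
        w1, w2, c1, u, c2, v, near_used = fit
        if u @ (pts[w1][-1] - pts[w1][0]) < 0:
            u = -u
        if v @ (pts[w2][-1] - pts[w2][0]) < 0:
            v = -v
        cosu = float(np.clip(u @ v, -1.0, 1.0))
        theta = np.arccos(cosu)
        if theta < np.radians(5.0):
            continue
        # closest approach of the two arm lines -> corner vertex X
        w0 = c2 - c1
        a, b, c = u @ u, u @ v, v @ v
        d, e = u @ w0, v @ w0
        den = a * c - b * b
        if abs(den) < 1e-12:
            continue
        t1 = (d * c - b * e) / den
        t2 = (b * d - a * e) / den
        x_vertex = 0.5 * ((c1 + t1 * u) + (c2 + t2 * v))
        bis_out = u - v
        nb = np.linalg.norm(bis_out)
        if nb < 1e-9:
            continue
        bis_out /= nb
        # local tube radius: cross-section equivalent radius on the arms
        # (sub-voxel accurate), falling back to the inscribed distance
        radii = []
        for s_arm in (float(s[w1].mean()), float(s[w2].mean())):
            prof = section_profile(volume, path, s_arm)
            if not prof.empty:
                radii.append(prof.equiv_diameter_mm / 2.0)
        mask_r = float(np.mean(radii)) if radii else _local_radius(volume, dt, pts[w1], pts[w2])
        sin_psi = float(np.cos(0.5 * theta))  # half interior angle
        if 1.0 - sin_psi < 1e-6:
            continue
        rho = _fillet_radius_from_wall(
            volume, x_vertex, bis_out, u, v, theta, mask_r
        )
        if rho is None:
            # fallback: single-ray apex depth (outer wall along the bisector
            # sits at t = rho + r - rho/sin(psi) from the arm intersection)
            t_out = _last_inside(volume, x_vertex, bis_out, mask_r + 15.0)
            rho = max(mask_r - t_out, 0.0) * sin_psi / (1.0 - sin_psi)
        # keep the rebuilt turn strictly local (within the measurement gap)
        rho = float(np.clip(rho, 0.25, 4.5 / theta))
        tang = rho * np.tan(0.5 * theta)
        T1 = x_vertex - tang * u
        T2 = x_vertex + tang * v
        center = x_vertex + (rho / sin_psi) * (-bis_out)
        # sweep the fillet arc from T1 to T2 around the corner axis
        r1v = T1 - center
        r2v = T2 - center
        axis = np.cross(r1v, r2v)
        na = np.linalg.norm(axis)
        if na < 1e-9:
            continue
        axis /= na
        narc = max(2, int(np.ceil(rho * theta / max(spacing_mm * 0.5, 0.1))))
        angs = np.linspace(0.0, theta, narc + 1)
        arc = center + np.array(
            [_rotate(r1v, axis, a_) for a_ in angs]
        )
        # replace the whole disturbed zone [s*-near, s*+near]: projected
        # point on arm 1 -> straight -> fillet arc -> straight -> projected
        # point on arm 2 (the leftovers of the chamfer outside the fillet
        # would otherwise still contaminate chord directions)
        inner1 = np.nonzero(s >= s_star - near_used)[0]
        inner2 = np.nonzero(s <= s_star + near_used)[0]
        if inner1.size == 0 or inner2.size == 0:
            continue
        j1, j2 = int(inner1[0]), int(inner2[-1])
        if j2 <= j1 or j1 < 1 or j2 > len(pts) - 2:
            continue
        p1p = c1 + ((pts[j1] - c1) @ u) * u
        p2p = c2 + ((pts[j2] - c2) @ v) * v
        old_len = path.total_length_mm
        pts = np.vstack([pts[:j1], [p1p], arc, [p2p], pts[j2 + 1:]])
        path = resample_path(pts, spacing_mm)
        pts = path.points
        shift += path.total_length_mm - old_len
    return path


def _fillet_radius_from_wall(
    volume: LabelVolume,
    x_vertex: np.ndarray,
    bis_out: np.ndarray,
    u: np.ndarray,
    v: np.ndarray,
    theta: float,
    tube_r: float,
) -> float | None:
    """Axis fillet radius estimated from the convex outer wall.

    The outer wall of the bend is a torus of radius (fillet + tube radius)
    around the fillet center, which lies at distance fillet/sin(psi) from
    the arm intersection along the interior bisector.  A wall hit at
    distance t along a ray at angle g from the exterior bisector therefore
    satisfies a quadratic in the fillet radius rho:

        rho^2 (1/sin^2(psi) - 1) + 2 rho (t cos(g)/sin(psi) - r) = r^2 - t^2

    Each ray of a small fan yields a closed-form estimate; the median is
    returned (a free circle fit would be ill-conditioned here because the
    probed wall spans only a short arc).  Returns None without enough
    wall hits.
    """
    e_t = u + v
    e_t = e_t - (e_t @ bis_out) * bis_out
    n = np.linalg.norm(e_t)
    if n < 1e-9:
        return None
    e_t /= n
    sin_psi = float(np.cos(0.5 * theta))
    a_coef = 1.0 / sin_psi**2 - 1.0
    if a_coef < 1e-9:
        return None
    gmax = min(np.radians(25.0), 0.4 * theta)
    estimates = []
    for g in np.linspace(-gmax, gmax, 9):
        d = np.cos(g) * bis_out + np.sin(g) * e_t
        t = _last_inside(volume, x_vertex, d, tube_r + 15.0)
        if t <= 0.5:
            continue
        b_coef = 2.0 * (t * np.cos(g) / sin_psi - tube_r)
        c_coef = t * t - tube_r * tube_r
        disc = b_coef * b_coef - 4.0 * a_coef * c_coef
        if disc < 0:
            continue
        rho = (-b_coef + np.sqrt(disc)) / (2.0 * a_coef)
        if rho > 0:
            estimates.append(rho)
    if len(estimates) < 5:
        return None
    return float(np.median(estimates))


def _local_radius(
    volume: LabelVolume, dt: np.ndarray, arm1: np.ndarray, arm2: np.ndarray
) -> float:
    """Median distance-to-background over on-axis arm points (tube radius)."""
    pts = np.vstack([arm1, arm2])
    ijk = np.clip(
        np.rint(volume.world_to_index(pts)).astype(int),
        0,
        np.array(dt.shape) - 1,
    )
    return float(np.median(dt[tuple(ijk.T)]))


def _rotate(vec: np.ndarray, axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation of ``vec`` about unit ``axis``."""
    return (
        vec * np.cos(angle)
        + np.cross(axis, vec) * np.sin(angle)
        + axis * (axis @ vec) * (1.0 - np.cos(angle))
    )


# ---------------------------------------------------------------------------
# cross-section profiling
# ---------------------------------------------------------------------------

def section_profile(
    volume: LabelVolume,
    path: CenterlinePath,
    s_mm: float,
    labels_of_interest: tuple = (LUMEN, UNCOVERED_STENT, COVERED_STENT),
    grid_mm: float = 0.25,
    extent_mm: float = 40.0,
    tangent_chord_mm: float = 4.0,
) -> SectionProfile:
    """Area and equivalent diameter of the cross-section at station ``s_mm``.

    The selected labels are resampled on a ``grid_mm`` grid over an
    ``extent_mm`` square orthogonal to the local tangent; only the
    8-connected component containing the path point is kept.  An empty
    plane yields a flagged zero-area profile, not an error.
    """
    if s_mm < -1e-9 or s_mm > path.total_length_mm + 1e-9:
        raise OutOfRangeError(f"station {s_mm} outside path")
    center = point_at(path, min(max(s_mm, 0.0), path.total_length_mm))
    normal = _tangent_at(path, s_mm, tangent_chord_mm)
    lab2d, _, _, _ = _plane_labels(volume, center, normal, extent_mm / 2.0, grid_mm)
    mask2d = np.isin(lab2d, labels_of_interest)
    comp = _component_mask(mask2d, grid_mm)
    if comp is None:
        return SectionProfile(float(s_mm), center, normal, 0.0, 0.0, empty=True)
    area = float(comp.sum()) * grid_mm * grid_mm
    return SectionProfile(
        float(s_mm), center, normal, 2.0 * np.sqrt(area / np.pi), area
    )


def profile_stent(
    volume: LabelVolume,
    path: CenterlinePath,
    stent: ArcInterval,
    step_mm: float = 1.0,
    labels_of_interest: tuple = (UNCOVERED_STENT, COVERED_STENT),
    end_inset_mm: float | None = None,
    **kwargs,
) -> list[SectionProfile]:
    """Section profiles at uniform stations across the stent interval.

    Planes placed exactly on the boundary between label regions cut a
    partial shell of the selected labels and report a spuriously small
    section, so stations are inset from the interval ends by
    ``end_inset_mm`` (default: one voxel spacing) unless the interval is
    too short to allow it.
    """
    if stent.s_end_mm > path.total_length_mm + 1e-9:
        raise OutOfRangeError("stent interval exceeds path extent")
    if end_inset_mm is None:
        end_inset_mm = 2.0 * float(np.max(volume.spacing_mm))
    a, b = stent.s_start_mm, stent.s_end_mm
    if b - a > 2.0 * end_inset_mm + step_mm:
        a, b = a + end_inset_mm, b - end_inset_mm
    stations = a + np.arange(0.0, b - a + 1e-9, step_mm)
    if stations[-1] < b - 1e-9:
        stations = np.append(stations, b)
    return [
        section_profile(volume, path, float(s), labels_of_interest, **kwargs)
        for s in stations
    ]
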