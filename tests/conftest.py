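"""Shared fixtures and independent oracles for the test suite."""

import numpy as np
import pytest

from tipsgeo.curvepath import CenterlinePath, resample_path


def densify_polyline(vertices: np.ndarray, ds: float = 0.1) -> np.ndarray:
    """Sample a polyline densely so sharp corners survive resampling."""
    vertices = np.asarray(vertices, dtype=float)
    out = []
    for a, b in zip(vertices[:-1], vertices[1:]):
        n = max(1, int(np.ceil(np.linalg.norm(b - a) / ds)))
        out.append(a + (b - a) * np.linspace(0, 1, n, endpoint=False)[:, None])
    out.append(vertices[-1:])
    return np.vstack(out)


def sharp_bend_path(
    theta_deg: float,
    arm_mm: float = 20.0,
    spacing_mm: float = 0.25,
    plane_deg: float = 0.0,
) -> CenterlinePath:
    """Two straight arms meeting at a sharp planar vertex of ``theta_deg``."""
    t = np.radians(theta_deg)
    b = np.radians(plane_deg)
    e1 = np.array([0.0, 0.0, 1.0])
    e2 = np.array([np.cos(b), np.sin(b), 0.0])
    v0 = np.zeros(3)
    v1 = arm_mm * e1
    v2 = v1 + arm_mm * (np.cos(t) * e1 + np.sin(t) * e2)
    return resample_path(densify_polyline(np.array([v0, v1, v2])), spacing_mm)


def circular_arc_path(
    radius_mm: float, sweep_deg: float, spacing_mm: float = 0.25
) -> CenterlinePath:
    th = np.linspace(0.0, np.radians(sweep_deg), 4000)
    pts = np.column_stack(
        [radius_mm * np.sin(th), np.zeros_like(th), radius_mm * (1 - np.cos(th))]
    )
    return resample_path(pts, spacing_mm)


def oracle_max_curvature(
    path: CenterlinePath,
    s_start: float,
    s_end: float,
    gap: float = 5.0,
    chord: float = 10.0,
    step: float = 0.1,
) -> float:
    """Exhaustive chord-pair search on a fine station grid.

    Written independently of the library implementation: plain numpy
    interpolation of the path and a dense loop-free grid evaluation.
    """
    cum = path.cumlen_mm
    pts = path.points

    def interp(s):
        return np.column_stack([np.interp(s, cum, pts[:, k]) for k in range(3)])

    window = 2 * chord + gap
    stations = np.arange(s_start, s_end - window + 1e-9, step)
    if stations.size == 0:
        raise ValueError("interval too short")
    a = interp(stations)
    b = interp(stations + chord)
    c = interp(stations + chord + gap)
    d = interp(stations + window)
    u = b - a
    v = d - c
    cosang = np.sum(u * v, axis=1) / (
        np.linalg.norm(u, axis=1) * np.linalg.norm(v, axis=1)
    )
    return float(np.max(np.degrees(np.arccos(np.clip(cosang, -1, 1)))))


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def random_smooth_path(
    rng: np.random.Generator, length_mm: float = 80.0, ds: float = 0.25
) -> CenterlinePath:
    """A random gently-curving 3D path built from low-frequency direction angles."""
    n = int(length_mm / ds) + 1
    s = np.linspace(0.0, 1.0, n)
    def angle_series(scale):
        out = np.zeros(n)
        for k in range(1, 4):
            out += (
                rng.normal(scale=scale / k)
                * np.sin(np.pi * k * s + rng.uniform(0, 2 * np.pi))
            )
        return out
    theta = angle_series(0.5)   # polar wobble (radians)
    phi = angle_series(1.0)     # azimuthal wobble
    d = np.column_stack(
        [np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi), np.cos(theta)]
    )
    pts = np.vstack([np.zeros(3), np.cumsum(ds * 0.5 * (d[1:] + d[:-1]), axis=0)])
    return resample_path(pts, ds)


@pytest.fixture(scope="session")
def straight_phantom():
    from tipsgeo.phantom import PhantomSpec, make_phantom

    spec = PhantomSpec(kind="straight", spacing_mm=1.0)
    volume, truth = make_phantom(spec)
    return spec, volume, truth


@pytest.fixture(scope="session")
def straight_extraction(straight_phantom):
    from tipsgeo.volume_centerline import extract_centerline

    spec, volume, truth = straight_phantom
    path = extract_centerline(volume, truth.seed_set(), spacing_mm=1.0)
    return spec, volume, truth, path
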