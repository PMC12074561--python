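"""Worked examples of the maximum sectional curvature metric.

The metric segments the stent centerline into 1-cm straight chords
separated by 5-mm gaps and reports the largest change of direction between
a chord pair, maximised over the stent.  A straight stent scores 0; a
sharp localized 90-degree bend scores 90; a gentle arc scores only the
bend accumulated across one chord-pair window.
"""

import numpy as np

from tipsgeo import ArcInterval, max_section_curvature, resample_path


def densify(vertices, ds=0.1):
    out = []
    for a, b in zip(vertices[:-1], vertices[1:]):
        n = max(1, int(np.ceil(np.linalg.norm(b - a) / ds)))
        out.append(a + (b - a) * np.linspace(0, 1, n, endpoint=False)[:, None])
    out.append(vertices[-1:])
    return np.vstack(out)


# 1. straight 60 mm stent
straight = resample_path(np.array([[0.0, 0, 0], [0, 0, 60.0]]), 1.0)
v = max_section_curvature(straight, ArcInterval(0, 60))
print(f"straight 60 mm stent:            {v:6.2f} deg   (a straight stent scores 0)")

# 2. sharp planar 90-degree bend, 20 mm arms
verts = np.array([[0.0, 0, 0], [0, 0, 20.0], [20.0, 0, 20.0]])
bend = resample_path(densify(verts), 0.25)
v = max_section_curvature(bend, ArcInterval(0, bend.total_length_mm))
print(f"sharp 90-degree localized bend:  {v:6.2f} deg   (the full bend fits in one gap)")

# 3. gentle arc: 60 degrees of total bend spread over 80 mm
R = 80.0 / np.radians(60.0)
th = np.linspace(0, np.radians(60.0), 4000)
arc = resample_path(
    np.column_stack([R * np.sin(th), np.zeros_like(th), R * (1 - np.cos(th))]), 0.25
)
v = max_section_curvature(arc, ArcInterval(0, arc.total_length_mm))
print(f"60-degree bend spread over 80mm: {v:6.2f} deg   "
      f"(only (chord+gap)/R = {np.degrees(15 / R):.2f} deg per window)")
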