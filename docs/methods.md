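# Methods

## Coordinate conventions and data model

All in-memory geometry lives in LPS millimetres (the DICOM patient
frame). NIfTI volumes, which are RAS on disk, are converted on load by
negating the first two world axes and converted back on save. A
`LabelVolume` carries an integer voxel grid (0 background, 1 vessel
lumen, 2 uncovered stent, 3 covered stent), per-axis spacing, origin and
an orthonormal direction matrix; the labels are assumed to partition the
vessel, i.e. the stent labels cover the whole lumen over the stented
interval.

A `CenterlinePath` is an ordered polyline resampled at a uniform nominal
arc-length step (default 1 mm, linear interpolation, no implicit
smoothing), with cumulative arc length stored per point. All "length
from A to B" parameters are arc lengths along this path, not straight
Euclidean distances: the anatomy the path follows is curved, and the
drawn-segment reading of each parameter refers to the vessel course. The
alternative (straight chords between landmark points) is not exposed.

## The sectional curvature metric

The stent curvature parameter is defined combinatorially rather than
differentially: two straight 1-cm chords separated by a 5-mm gap slide
along the stented interval, and the reported value is the maximum angle
between the two chord directions over all admissible stations. Reported
units are degrees — the angle itself, matching the worked reference
cases (0 for a straight stent, 90 for a 90° bend contained within one
gap window).

Choices a reader should know:

- **Sliding, phase-free maximisation.** A fixed 5-mm partition of the
  stent would make the value depend on an arbitrary phase; sliding the
  station (default step 0.5 mm, ≤ 10% of the gap) always finds the
  configuration that brackets a localized bend, and on smooth paths
  stays within ~0.5° of the continuous optimum. A sliding maximum can
  only be larger than any fixed-phase partition value.
- **"Gap" means chord-end to chord-start.** The second chord begins
  5 mm after the first one ends, so one chord pair spans 25 mm of arc;
  the stent interval must be at least that long.
- **The interval includes the uncovered distal portion** — the metric is
  maximised over the entire stent, from the uncovered beginning to the
  cranial end.
- The first station achieving the maximum is available for diagnostics
  (`max_curvature_station`); ties are broken toward the caudal end.

For a circular arc of radius R the metric has the closed form
(chord + gap)/R radians (each chord's direction is the tangent at its
midpoint), which the tests use as an independent oracle alongside an
exhaustive 0.1-mm grid search.

## Centerline extraction

Extraction is semiautomated: the user supplies one seed at the portal
venous confluence, one in the IVC, and optionally ordered waypoints.
The algorithm:

1. **Medialness geodesic.** A 26-connected graph over non-background
   voxels, edge weight = Euclidean step length / (0.1 mm + distance to
   background at the target voxel); Dijkstra from seed to seed. The
   distance-transform weighting pulls the geodesic toward the medial
   axis instead of hugging the wall.
2. **Light smoothing and resampling** (2 mm boxcar, endpoints fixed) to
   stabilise tangent estimates, then uniform resampling.
3. **Cross-section re-centering** (2 passes): each interior station
   moves to the centroid of the 8-connected in-plane component of its
   orthogonal cross-section, sampled at 0.25 mm. The in-plane grid is
   symmetric about the station and offset by half a cell so sample
   points never fall exactly on voxel boundaries — on-boundary points
   round systematically to one side and would bias the centroid by a
   visible fraction of a voxel. On a straight digitized tube this step
   recovers the axis essentially exactly.
4. **Light smoothing again**, removing residual centroid jitter; any
   sharp bend this would round off is rebuilt in the next step.
5. **Localized-bend reconstruction.** Around a kink whose radius is
   smaller than the tube radius, the generative axis is not recoverable
   from inscribed-sphere information: the medialness geodesic chamfers
   the corner and section centroids overshoot outward, because the
   cross-sections there overlap. The convex outer wall, however, still
   follows the swept surface of the bend (outer radius = axis fillet
   radius + tube radius). High-curvature zones are detected on the path
   (direction change over ±6 mm above 20°, curvature-weighted run
   centers, runs merged within 10 mm), the two straight arms are fitted
   by total least squares on windows clear of the disturbance (widest
   clearance first, residual ≤ 0.2 mm), and the corner is replaced by
   the circular fillet tangent to both arm lines whose radius is
   estimated from a fan of 9 rays probing the outer wall about the
   exterior bisector — each wall hit yields a closed-form quadratic for
   the fillet radius (a free circle fit over so short a wall arc would
   be ill-conditioned), and the median is used, clamped so the rebuilt
   turn stays within the curvature measurement gap. Gentle curves never
   trigger the detector and are left untouched.

Swapping the seeds reverses the path with sub-percent length change.
The phantom round-trip accuracy this pipeline achieves (axis within a
fraction of a voxel, angles within ~1–2°, lengths within ~0.5 mm) is
what the acceptance-scale tests assert.

## Cross-section profiles and the minimal diameter

Sections orthogonal to the path are resampled on a 0.25-mm in-plane grid
over a 40-mm square, keeping the 8-connected component that contains the
path point (or the nearest in-plane labeled pixel within 2 mm). The
reported diameter is the equivalent-circle diameter, 2·sqrt(area/π) —
robust to ragged strut-level label noise, unlike min/max Feret widths.
The minimal stent diameter is the minimum over stations at 1-mm steps
across the stent interval, with stations inset two voxels from the
interval ends: a plane placed exactly on the boundary between label
regions cuts a partial shell and reports a spuriously small section.
An empty plane yields a flagged zero-area profile, never an error, and
flagged profiles are excluded from the minimum (all-flagged is an
error).

## Phantom generator

Phantoms emulate a labeled post-TIPS CT, not the CT itself: clean
integer labels on a millimetre grid, no Hounsfield values, beam
hardening, motion, or segmentation error (an optional label-dropout
fraction emulates strut artefacts; it defaults to 0). Passing the
phantom suite therefore demonstrates geometric fidelity of the
measurement chain, not robustness to segmentation quality.

The centerline is built as an arc-length-parameterised planar curve —
direction angle φ(s) integrated at 0.05 mm — so every landmark position
and every along-path distance of the ground truth is exact by
construction. Sharp bend vertices are rounded with a 2-mm fillet for
renderability; the fillet arc (≤ 4.2 mm up to 120°) fits inside the
5-mm measurement gap, so the chord-pair curvature of a localized bend
still attains the full nominal angle. Ground-truth angles and curvature
are the package's own chord estimators evaluated on the exact analytic
curve (for bends with long straight arms these equal the nominal angles
exactly; for arcs they match the closed form above). The ground-truth
minimal diameter is 2× the minimum of the analytic radius profile.

Voxelisation labels every voxel whose center lies within the radius
profile of the nearest centerline point (0.2-mm dense sampling), by arc
interval: lumen before the stent and after it, uncovered then covered
stent inside. Default dimensions — 4-mm tube radius (5 mm for waisted
phantoms, nominal 10-mm stent), 20-mm portal segment, 15-mm uncovered
and 40-mm covered portions — are scaled to keep volumes compact while
leaving every chord measurement room; the deterministic suite spans
bends of 15–120°, cranial offsets 0/6/16.5/26.5 mm, waist diameters
6/7/8 mm, arc sweeps 30/60°, composite tracts with alpha angles
30/60/90°, at 0.5 and 1.0 mm isotropic spacing (45 phantoms). Identical
seeds give bit-identical volumes.

## Cohort statistics

Group comparisons use the Pearson chi-square test (no continuity
correction, matching common clinical-statistics practice) for
categorical variables and the two-sided Mann–Whitney U test for
continuous ones, with per-variable pairwise deletion of missing values;
constant variables are reported with p = 1 and flagged rather than
dropped silently.

Cox proportional-hazards models are fitted with lifelines (Efron tie
handling; Wald 95% CIs on the log-hazard scale; per-analysis
complete-case). Forward stepwise selection adds, at each step, the
candidate with the smallest entry-test p-value below 0.1, then removes
any included variable whose Wald p exceeds 0.1, until stable. The
endpoints are time-to-event throughout, so the selection is stepwise
*Cox* selection even though such procedures are sometimes described in
clinical reports with logistic-regression vocabulary. The entry test is
a likelihood-ratio test between the nested partial likelihoods (exact
from two fits; a score test at the constrained optimum would need
bespoke derivative code for no practical inferential difference at
cohort sizes); `StatsConfig.entry_test="wald"` switches to the
candidate's Wald p in the augmented model. Stepwise uses complete cases
over all candidates so every candidate model sees the same subjects.
The time-to-CT sensitivity analysis reruns the same selection over the
retained predictors plus the procedure-to-CT delay.

### Cohort simulator

The simulator draws geometry covariates to match the emulated cohort's
published medians and IQRs: curvature lognormal (median 42.12°, σ from
the IQR 36.47–50.37), cranial-end distance exponential with median
9.99 mm (its IQR 2.00–17.93 is more skewed than any two-parameter
family fits exactly; the exponential reproduces the median and the
right tail), the remaining continuous covariates normal from
median/IQR, clipped to physical ranges (angles to [0°, 180°], lengths
to ≥ 0), plus categorical procedure covariates (stent type 57/43,
nominal sizes). Event times are exponential with hazard
`baseline · exp(Σ β(x − median))` — covariates centered at their
medians so the baseline rate refers to a median subject — with default
log-hazard effects ln(1.020) per curvature degree and ln(1.061) per mm
of cranial-end distance, and independent exponential censoring. The
default rates (baseline 0.002/day, censoring 0.001/day) produce roughly
30% censoring under the default effects, the regime the calibration
tests exercise. What the simulator does **not** model: correlated
geometry covariates, non-proportional hazards, informative censoring,
measurement error in the geometry — parameter-recovery results bound
estimation behaviour under a correctly specified model only.

## Numerical choices and degenerate inputs

- Station step 0.5 mm for curvature maximisation; tests compare against
  a 0.1-mm exhaustive grid within 0.5°.
- Chord length 10 mm everywhere a local direction is needed (end-plane
  axes, alpha angle), matching the curvature section scale; the section
  plane tangent uses a 4-mm central-difference chord to smooth voxel
  jitter.
- Landmarks given as 3D points are snapped by orthogonal projection
  onto the path's segments (sub-station resolution), not to the nearest
  station.
- Degenerate inputs fail loudly with typed errors: all-coincident input
  points, chords beyond the path, stent intervals shorter than one
  chord-pair window, seeds in background, disconnected seeds, landmark
  order violations, all-empty profiles, cohorts with fewer than two
  events, zero-variance covariates.
- Zero-length profile intervals yield a single section; identical
  arc-length arguments give distance 0.

## Known limitations

- At kinks sharper than the tube radius the measured path is a model
  reconstruction (arms + fillet from the outer wall), accurate for
  tube-like geometry with locally straight arms; two bends closer than
  ~16 mm, or a bend within ~8 mm of a path end, fall back to the
  unrefined path.
- The minimal-diameter end inset (2 voxels) means a stenosis in the
  outermost 1–2 mm of the stent would be attributed to the nearest
  interior section.
- Curvature values depend on the gap/chord layout by definition; values
  measured with other layouts are not comparable.
- The statistics stage assumes right-censored single-event data; no
  competing risks.
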