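# Methods

This note documents the models behind `autotan`: the synthetic anatomy,
the beam and dose model, the target-volume construction, the segment
generator and weight optimizer, the evaluation conventions, and the
design choices made where the clinical workflow leaves the details open.
It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Coordinates and lattice

All volumes live on one regular lattice in a patient-LPS-like frame
(x toward the patient's left, y posterior, z superior), millimetres.  A
voxel (i, j, k) is the half-open box `[origin + i·s, origin + (i+1)·s)`;
volumes are voxel counts times the voxel volume, with no sub-voxel
interpolation.  The default lattice is 2.5 mm isotropic over
300 × 300 × 150 mm (120 × 120 × 60 voxels): fine enough to resolve a
1 cm MLC leaf and the 2–3 cm lung bite, small enough that a full
planning run takes seconds to tens of seconds on one CPU.  A guard
rejects configurations above 10^8 voxels.

## Synthetic phantom

The phantom emulates a CT-simulated whole-breast patient:

* **Thorax**: elliptical cylinder, semi-axes 130 × 85 mm, water density
  (1.0 g/cm³), spanning the grid in z.
* **Lungs**: ellipsoids (45 × 62 × 65 mm semi-axes) centred ±55 mm off
  the midline inside the thorax, density 0.26 g/cm³ (a standard adult
  lung surrogate).  Density is piecewise constant — there is no imaging
  noise, so the mean density over a lung mask is exactly the configured
  value.
* **Heart**: a 40 mm-radius water sphere left of midline, offset
  (35, −10, −25) mm from the thorax centre — an antero-medial
  (mediastinal) position whose anterior edge clips the posterior corner
  of left-sided tangent fields, the situation that produces the small
  but nonzero mean heart doses seen clinically.  Lungs are carved around
  it.
* **Breast**: a half-ellipsoid (default base radius 60 mm, anterior
  height 55 mm, circular base) seated on the chest wall at 40° from the
  anterior midline on the configured side, its axis along the local
  outward surface normal.  The shallow gap that chest-wall curvature
  leaves under the tangent base plane is filled down to the thorax
  surface so the breast sits flush.  Optional surface noise perturbs the
  boundary with a smooth random field (~15 mm correlation length) of
  given RMS amplitude; the default phantom uses 0 mm (exactly the
  analytic shape), the suite 1 mm.

`default_phantom_suite(n, seed)` spans base radii 50–72 mm monotonically
(height 0.9 × radius), alternates left/right laterality, and derives
each phantom's noise seed from the suite seed, so a suite is fully
reproducible from `(n, seed)`.  The size range covers open-field
hotspots from ~107% to ~113% of prescription — the regime in which the
segment budget formula allows zero to three segments.

## Beams and the beam's-eye view

Gantry 0° means the beam enters from the anterior; angles increase
toward the patient's left, rotating about the superior axis.  Each
beam's BEV frame is oriented so +u (the leaf-travel axis) points toward
the anterior field border and +v toward superior; apertures are cm at
the isocenter plane (SAD 100 cm).  Leaf rows are 1 cm wide and tile the
y-jaw span; one leaf bank therefore forms the posterior lung block and
the other blocks anterior hotspots.

`default_tangent_setup` places the pair along the chest-wall tangent at
the breast base (medial and lateral entries, exactly opposed), fits the
jaws to the breast projection with 2 cm anterior flash and 7 mm
superior/inferior margins, and sets the posterior border so the field
bites 2.5 cm into the lung: the jaw sits 2.5 cm behind the *median*
per-row anterior lung surface, and the CP1 MLC contours rows where the
lung bulges further anteriorly.  The prerequisite checker accepts bites
in [1, 4] cm (±1 cm tolerance around the prescribed 2–3 cm placement),
classifies beams within ±10° of 0°/180° as supraclavicular/posterior-
axillary types rather than tangents, uses half-open quadrants
([0°, 90°), …), and demands opposite quadrants with circular separation
in [160°, 180°].  Mixed-energy plans pair beams only within one energy.

BEV projection is divergent through the source; a BEV pixel is set iff
it falls inside the bounding box of the eight projected corners of any
mask voxel (a ≤ half-pixel over-cover that errs on the safe side for
blocking).

## Dose engine

Per control point, dose at voxel v is

    D(v) = MU · w · C · F(u(v), v(v)) · PDD(z(v)) · (SAD / d(v))²

with `F` the aperture fluence — an area-weighted (anti-aliased) raster
of jaws ∩ leaf openings convolved with an isotropic Gaussian penumbra
(σ = 3 mm at isocenter) — `z` the radiological depth (trilinear midpoint
sampling of density along the ray from the grid entry point; ≤ 1.5 mm
steps in the bulk engine, 0.5 mm in the per-point API, validated against
0.1 mm fixed-step integration to within 1%), `d` the Euclidean source
distance, and the percent-depth-dose

    PDD(z) = N · (1 − e^(−β z)) · e^(−μ z),   max_z PDD = 1.

Defaults: β = 2.5 cm²/g (buildup peak at 1.79 g/cm²), μ = 0.029 cm²/g,
calibration C = 1 cGy/MU at the PDD peak of a 10 × 10 cm field.  μ is
derived, not fitted: because the engine applies the inverse-square
factor separately, the attenuation coefficient must carry only the
non-geometric part of the depth falloff, and μ = 0.029 makes
`e^(−μ·8.4) · (101.6/110)²` ≈ 0.68, reproducing the canonical 6 MV
PDD(10 cm) ≈ 67% at 100 cm SSD.  (Using a published narrow-beam μ here
would double-count distance falloff and roughly double the anterior
hotspot.)

The model is primary-only: no scatter kernels, no electron
contamination, no heterogeneity corrections beyond radiological depth.
Consequences worth knowing: out-of-field dose is penumbral only (organs
fully outside the field receive ~0 Gy, so the heart metric is meaningful
only when the heart clips the field, as on the left-sided phantoms); and
thin-tissue regions lack the scatter-loss cooling a convolution engine
would show.  Geometry (depth, projection, inverse square) depends only
on the beam, so it is cached per beam; each control point costs one 2D
fluence interpolation, and plan dose is linear in control-point weights.

Plans are normalized so the calculation point — by default the breast
apex-axis midpoint pulled 1 cm posterior — receives the prescription's
normalization percentage of the per-fraction dose; beam MUs are
back-computed from the normalization scale.  Dose grids hold total dose
(Gy over all fractions).  The default prescription is 40.05 Gy in 15
fractions at 100% normalization.

## PTV, tip and base

The PTV is the 95% isodose of the open tangents, read as 95% of the
*prescription* dose (the clinical norm; a `relative_to="max"` flag
supports the max-relative reading), intersected with the body, minus
both lungs, minus a 4 mm skin rind (voxel-centre distance to the body
surface, including the half-voxel offset of the distance transform),
keeping the largest 26-connected component (ties broken toward the
lowest voxel index).

The tip/base split contracts the posterior jaw of a working copy of the
pair by 3 cm (clipping leaf edges to the new jaw; an error is raised if
the contraction reaches the field extent), recomputes dose with the same
normalization point, and takes tip = PTV ∩ {≥ 95% isodose of the
contracted fields}, base = the rest.  The input plan is never mutated.

## Segment loop and weight optimization

The segment budget N = int((Dmax − 105)/2.5) (truncation toward zero) is
fixed once from the open-field maximum over the PTV; the hotspot
schedule h_k then falls linearly from 2.5% to 1% across those N
iterations, which makes "linearly reduced to 1% at the last segment"
well-defined.  Each iteration: recompute dose; stop if Dmax ≤ 105% of
prescription or the hotspot volume is below 0.1 cm³ (sub-voxel hotspots
do not deserve a segment); threshold at (1 − h_k/100) of the *current*
PTV maximum; split the hotspot by tip/base membership; extend the tip
part to the anterior and the base part to the posterior field border in
the BEV (this is what guarantees each leaf row keeps a single open
interval and the MLC can form the shape); advance leaves from their CP1
positions so the segment aperture is row-wise contained in CP1 — the
dosimetrist's lung block survives in every segment; give the segment
w_k = 2 · h_k/100 of its beam's MU, taken from the open control point.
Beams alternate, medial tangent first.  A hotspot that would close every
row (degenerate aperture) skips the iteration and advances the beam
cycle.  Dmax and hotspots are always measured over the PTV, not the
whole body.

Weight optimization minimizes, over the PTV and the segment weights,

    50 · mean(((D − Rx)/Rx)²) + 50 · mean((max(0, D − 1.05·Rx)/Rx)²)

with each beam's open weight the complement of its segment weights
(weights within a beam always sum to 1) and renormalization to the
calculation point applied inside the objective (dose is a ratio of
linear functions of the weights, so the problem stays smooth).  The
solver is deterministic SLSQP with box bounds; segments that end below
the 4 MU minimum are either pushed to the bound (if they are worth at
least half the minimum) or dropped to exactly zero and pruned, with one
re-solve per adjustment round; the returned objective never exceeds the
incoming one.  Rerunning the whole pipeline on the same inputs is
bit-identical — there is no hidden randomness.

A structural property of the budget formula: any plan whose open-field
maximum lies in (105%, 107.5%] receives a budget of zero, so its hotspot
survives untouched even though it exceeds the preferred 105% level (and,
in the worst corner of that band, the 107% limit).  The smallest-breast
phantom of the default suite lands in this band; the behavior is
faithful to the truncated cap and is left as-is rather than special-
cased.

## Evaluation and statistics

The eight metrics: ipsilateral lung V16Gy (reported regardless of
fractionation), mean heart dose, PTV V90/V95/V105 (V107 also computed)
as percent of total prescription with inclusive thresholds, number of
MU-carrying control points (open fields counted by default — a cohort
mean of ~7 manual segments with two open fields implies the inclusive
convention; a flag selects segments-only), MU-weighted segment area
(the MU-fraction-weighted mean of aperture areas, leaf openings clipped
to the jaws), and total MU.

The Wilcoxon signed-rank test discards zero differences, midranks ties,
and computes the exact two-sided p-value from the full signed-rank
distribution via dynamic programming over doubled ranks — identical to
enumerating all 2^n sign assignments — for up to 25 nonzero differences,
switching to a tie-corrected normal approximation beyond.  All-zero
differences return W = 0, p = 1 by convention.  Cohort comparison tables
report mean ± SD per set and the p-value per metric at α = 0.05.

## Problem sizes

Unit and property tests run on 5 mm phantoms (60 × 60 × 30) where a full
planning run takes ~2 s; the acceptance tests and `scripts/acceptance.py`
use the default 2.5 mm resolution, one default phantom plus the
10-phantom suite, ~12 s per phantom.  These sizes were chosen so the
whole suite exercises the complete algorithm at the resolution the MLC
geometry needs while staying desk-scale.

## Known limitations

* Primary-only dose: no scatter, so absolute out-of-field doses are
  underestimated and no commercial-TPS numbers are reproduced; the
  engine is meant to reproduce the *structure* (anterior hotspot,
  depth/obliquity trends) the planning algorithm consumes.
* The phantom is convex and static: no breathing motion, no wires, no
  surgical deformation; passing tests show the algorithm's behavior on
  clean geometry, not robustness to real anatomy.
* The forward loop never revisits earlier segments (by design, as in
  manual forward planning); only their weights are re-optimized.
* Couch rotations, asymmetric-jaw feathering, supraclavicular field
  placement and DICOM-RT interchange are out of scope.
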