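# Methods

## Coordinate convention and geometry model

All volumes live on a regular axis-aligned lattice in LPS patient
coordinates (x → patient left, y → posterior, z → superior); an axial
slice is a fixed-z plane and every "anterior–posterior" measurement is a
ray along y. The voxel center of index (i, j, k) is
`origin + (i·sx, j·sy, k·sz)`. Structure surfaces are located at
occupied-voxel faces (center ± half a voxel) with no sub-voxel
interpolation, and probe rays snap to the nearest voxel column. These
choices make every geometric quantity deterministic and testable against
exhaustive per-voxel oracles, at the price of a discretization error
bounded by half a voxel per surface — about 0.5 mm at the default 1 mm
spacing, comparable to contouring slice resolution.

"Midline" is the x of the CTV center of mass (prostate midline), not
couch midline, and "midgland" its z. This is robust to patient offset on
the scanner and is configurable only in the sense that the anatomic
frame is an explicit object the caller may construct differently.
Centers of mass are unweighted means of occupied voxel centers: contours
carry no intensity.

## Perirectal space map

Each map cell is the gap `y_rectum_anterior − y_CTV_posterior` along the
A-P ray at one vertex of the 5 × 5 coronal grid (offsets −20…+20 mm from
midline and midgland in 10 mm steps). Cells whose ray misses either
contour are *missing* and stay missing; negative gaps (crossing
contours, a contouring artifact) clamp to zero with a logged warning,
including at the central ray when the anatomic frame is built.
Aggregates are complete-case per cell with sample (n−1) standard
deviations. Two distinct "overall" means exist and are both exposed: the
equal-weight mean over a single map's non-missing cells, and a cohort
pooling of per-patient values; on published cohort data they differ
(≈11.0 vs 10.1 mm) because row coverage varies, so the package never
conflates them. Difference maps are post − pre (space *created* is
positive); a cell missing in either operand is missing in the delta.

## Placement metrics

θ has its vertex at the gel center of mass, endpoints at the
posterior-CTV and anterior-rectum points on the central ray, and is
computed from the arccosine of the normalized inner product. It is
undefined (not an error) when no gel is present, so gel-absent patients
remain in cohort analyses with a normalized score of 0. The normalized
score is (θ/180°)·(V/V_ref); V_ref defaults to the cohort's largest
contoured gel and can be frozen by configuration for cross-cohort
comparison.

The symmetry rubric examines three axial slices (midgland, ±10 mm). A
slice counts as gel-present when its cross-section holds at least
0.05 cc (configurable) — a guard against single stray contour voxels —
and the lateral deviation is the |x| distance of the in-slice gel
centroid from midline. Centroid rather than maximum extent was chosen
for robustness to ragged contours. Categories: SYM1 (all three present,
deviation < 10 mm), SYM2 (exactly one slice in [10, 20) mm), SYM3plus
(any ≥ 20 mm or two or more ≥ 10 mm), and distinct missing-slice
categories (inferior absence reported separately because it is the
clinically consequential one; two or more absent slices collapse to
MULTI_MISSING).

## Rectum DVH

The cumulative DVH is built from the multiset of voxel doses inside the
rectum mask, one voxel volume each, without partial-volume weighting.
`rDmax N cc` inverts the DVH by linear interpolation between bracketing
sorted voxel doses (the k-th hottest voxel covers cumulative volume
(k−1, k] voxel volumes); the difference from a pure step lookup is
bounded by one voxel's dose spread, verified against sorted-voxel brute
force in the tests. `rV x%` is reported both in cc and as % of rectum
volume because protocol constraint tables use cc while regression
results are invariant to the choice. Constraint comparisons are
inclusive (observing exactly the limit passes); only the single
published rectal limit (3 cc ≤ 3440 cGy) ships as a default — any fuller
protocol table must be supplied by the user.

## Cohort statistics

Simple regressions report R² = squared Pearson r (identity enforced to
1e−10 in tests); the two-sample test is pooled-variance Student t by
default with Welch behind a flag; Shapiro–Wilk screening delegates to
scipy. In standardized regressions both predictors *and* response are
z-scored, so β is in SD units. No multiple-testing correction is applied
by default, matching common practice for exploratory dosimetric grids; a
Benjamini–Hochberg option exists. Missing values are complete-case per
analysis, so effective n varies between analyses exactly as in clinical
cohorts with heterogeneous imaging. The battery's three-variable
regression (θ, V, θ·V → rDmax 1 cc) reports conventional
(df_model, df_resid) degrees of freedom. Degenerate analyses (zero
variance, too few patients) surface as NaN cells or notes, never
exceptions.

## Synthetic phantoms

The generator builds, on a 128 × 128 × 96 lattice at 1 mm (defaults):

* **CTV**: an ellipsoid of the requested volume (default 40.1 cc) with
  fixed semi-axis proportions 1.05 : 0.80 : 1.15 (wider than deep,
  longest craniocaudally — a generic prostate shape).
* **Rectum**: an elliptical tube posterior to the CTV (half-width 26 mm,
  half-depth 9 mm) whose anterior wall sits a native 2 mm behind the
  posterior CTV face at the central ray — emulating the 1–2 mm native
  inferomedial perirectal space.
* **Gel**: a dome draped on the posterior CTV surface with thickness
  profile t(r) = t_max·√(1 − (r/R)²) and fixed aspect t_max = 0.55 R, so
  volume alone determines the shape (10.3 cc ⇒ R ≈ 20.7 mm,
  t_max ≈ 11.4 mm, which opens ≈ 10 mm of central space — the clinically
  typical gain). The dome center is displaceable in x/z (placement
  quality) and can float off the CTV surface in y. Where the gel
  interposes, the rectum cross-section is displaced posteriorly by the
  local gel thickness — the space-creation mechanism as pure geometry,
  no biomechanics.
* **Dose**: prescription (3625 cGy) inside the PTV — the CTV plus a
  5 mm margin reduced to 3 mm posteriorly — decaying as
  exp(−0.08 · distance-to-PTV-surface) outside. The 8 %/mm falloff is a
  configurable geometric surrogate for a steep posterior SBRT gradient,
  monotone by construction, sufficient to exercise DVH code; it is not a
  beam or Monte Carlo calculation. Per-patient dose-scale noise
  (SD 2 %) emulates plan-to-plan variability.

Each phantom carries ground truth: the planted gel COM and volume from
the analytic dome integral, the central displacement, the analytic gap
profile at the 25 map offsets, and θ computed from the planted COM with
P/R taken at the realized central voxel faces (the analytic target
surfaces differ by at most half a voxel; recording the realized faces
makes the truth describe the phantom actually built while the gel COM
remains analytic, keeping recovery tests non-circular).

**Cohort sampling.** Volumes are truncated normals matching the
clinical cohort conditions (CTV 40.1 ± 22.5 cc on [13, 108]; gel
10.3 ± 4.5 cc on [3, 22]). Placement offsets follow a two-component
mixture emulating the operator learning curve: with probability 0.4 a
near-ideal placement (component SD 2 mm) and otherwise a dispersed one
(SD 12 mm), bounded at ±25 mm. A single-SD normal cannot reproduce the
clinically observed θ spread of roughly 70 ± 49° (it yields SDs of
27–40°); the mixture lands at ≈ 70 ± 50° and also produces the observed
mix of symmetric, asymmetric and missing-slice patients. Acute toxicity
grades (0–2) are assigned probabilistically with probability rising
logistically in the cohort-standardized rDmax 1 cc, calibrated so about
a third of a typical cohort is symptomatic — a qualitative pattern
plant, not a quantitative toxicity model. All randomness flows through
one seeded generator; identical seeds give bit-identical cohorts.

**What the phantoms do not emulate.** Real CT/MR intensities, contouring
variability, oblique anatomy, rectal filling changes, gel resorption,
and true treatment-planning dose (no beam model, no heterogeneity).
Passing recovery tests therefore demonstrates the *pipeline's*
correctness on known geometry, not clinical accuracy of any particular
measurement protocol; the statistical battery's R² values on synthetic
cohorts reflect the generator's planted placement–dose link, and only
their structural ordering (the interaction score outranking its
factors) — not their magnitudes — should be read as a model property.

## Numerical and degenerate-input choices

* Surfaces at voxel faces; no trilinear resampling anywhere.
* Negative perirectal gaps clamp to 0 (a crossing contour pair means
  "no space", not "negative space" and not "missing").
* θ raises a degenerate-angle error only when the gel COM lies within
  1e−6 mm of an endpoint.
* Map aggregation requires at least one non-missing cell; rows/columns
  with fewer than two cells report an undefined SD.
* DVH inverse lookups clamp at the hottest voxel dose for hot volumes
  smaller than one voxel.
* Out-of-lattice probe points raise a distinct out-of-bounds error at
  the primitive level; at map level they become missing cells, matching
  the "absence of contour" semantics of clinical maps.
* Infeasible phantoms (anatomy running off the lattice) raise rather
  than silently truncating; cohort sampling redraws up to 20 times.

## Problem sizes

Default analyses use 20-patient cohorts on 128 × 128 × 96 mm-resolution
lattices (≈ 1.6 M voxels per volume); the test suite exercises oracle
comparisons on ≤ 32³ grids where exhaustive enumeration is cheap, and
parameter-recovery sweeps on full-resolution phantoms.

## Known limitations

* θ recovery on phantoms is typically within 1–2° of the planted value,
  but degrades for near-degenerate configurations where the gel COM lies
  within a couple of millimetres of the P–R segment yet far from its
  midpoint: the angle's sensitivity to the COM scales with the inverse
  distance to the endpoints, so voxelization-scale COM shifts can cost
  several degrees there.
* The perirectal map measures along A-P rays only; it is not a shortest
  3D surface-distance field.
* SYM3–SYM5 subcategories of the finer published symmetry rubric are
  collapsed into a single SYM3plus bucket.
* DICOM RTSTRUCT/RTDOSE ingestion is out of scope (NIfTI and a plain
  JSON format are supported); masks are assumed co-registered.
* No biological dose modeling (EQD2/NTCP) and no plan optimization.
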