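# Methods

`osteomap` implements a virtual-morphometry workflow for tubular bones
(designed around the second metatarsal): biomechanical orientation,
cross-sectional geometry (CSG), equiangular-semilandmark geometric
morphometrics, and relative-cortical-thickness mapping, all computed on
segmented voxel volumes.  Because real microCT material is rarely shareable,
the package ships a synthetic phantom generator whose every geometric
property is known in closed form; the entire pipeline is validated against
those ground truths.

## Coordinate system and biomechanical length

A bone is oriented by an anatomical frame built from user-supplied (or
generator-supplied) reference points: the origin is the central point of the
distal articular surface; the z-axis runs through the central point of the
proximal articulation and the most distal point of the distal articulation,
pointing proximally; the x-axis is the direction in the best-fit plane of a
dorsal-surface patch orthogonal to z (+x lateral by convention); y = z × x
points plantarly.  "Central point" of an articular surface is operationalized
as the centroid of a user-delimited patch; the points are supplied, not
auto-detected — digitizing them is out of scope.

Biomechanical length is the distance between the extreme intersections of
the bone surface with the z-axis line, measured by marching along the axis
at half-voxel steps through the trilinearly interpolated bone mask.
Positions along the shaft are fractions of this length (0 distal, 1
proximal).  Section planes at fraction f pass through
`distal_extreme + f · L · z` with normal z, so plane placement is affine in f.

For a bone missing its distal end, length is estimated by proportional
scaling from a complete reference specimen using a homologous dimension
(the midshaft mediolateral external diameter): `L = L_ref · d/d_ref`.  This
assumes isometry between the two specimens; the package exposes it as a
pure ratio plus a diameter-measurement helper.

## Cross sections and outlines

A section resamples the label field on an in-plane grid at the native voxel
spacing (grid extent from the bone bounding box projected onto the section
axes).  The external outline is the 0.5-level marching-squares contour of
the bone indicator; the internal (endosteal) outline is the contour of the
cavity indicator; a cavity-free section is reported distinctly
(`internal_outline = None`), never as an empty polygon.

The raw contour of a binary mask wiggles by up to half a voxel, which
biases extreme-fiber distances (max |y|, max radius) upward and therefore
section moduli downward.  Outlines are smoothed with a wrapped
Savitzky–Golay filter (quadratic, window ≈ 2.5 voxels of arc length):
locally parabolic curves are reproduced exactly, so circles keep their
radius — unlike Gaussian level-set smoothing, which shrinks curved
boundaries.  With this choice all closed-form annulus oracles (areas,
second moments, moduli) agree within 1% at 0.1 mm spacing.

The section's centre of gravity is the area centroid of the cortical
annulus (external minus internal polygon), computed with shapely.  This is
also the origin for the equiangular rays: k (default 21) rays at angles
2πi/k, index 0 pointing laterally (+x) and proceeding toward plantar (+y).
Semilandmark i on each outline is the farthest ray–outline intersection;
multiple intersections (possible under extreme callus lobes) keep the
farthest point and log a warning.  The farthest-intersection rule preserves
the external/internal pairing needed by the thickness map.

## Cross-sectional geometry

Areas and second moments of the annulus are exact polygon integrals
(Green's theorem) about the centroidal mediolateral (x) and dorsoplantar
(y) axes: CA, TA, CA% = 100·CA/TA, Ix = ∫y²dA, Iy = ∫x²dA, J = Ix + Iy.
Section moduli use the external-outline extreme fibers — Zx = Ix/max|y|,
Zy = Iy/max|x|, Zp = J/max r — because bending and torsional strength are
governed by the outermost fiber; Zp is defined as J over the maximal radial
distance from the centroid, the convention of the CSG literature (the exact
convention is not otherwise pinned down).  Moduli are standardized by
(ML diameter × DP diameter × biomechanical length), which removes isotropic
size exactly (both numerator and denominator scale as s³).

The default series cuts 61 sections at 1% increments from 20% to 80% of
biomechanical length.

### Reliable-region screening

A localized periosteal reaction (bone callus) corrupts CSG in part of the
shaft.  `select_reliable_region` turns the usual visual judgement into a
statistic: at each fraction the target's Zx/Zy and CA% are compared with
the reference sample's distribution via a robust z-score
(median / 1.4826·MAD), and the longest contiguous run of unremarkable
fractions is returned.

Two numerical choices matter.  First, the per-fraction MAD of a small
reference sample (≈10 specimens with axially smooth profiles) has very few
effective degrees of freedom, so the scale is median-filtered along the
fraction axis and floored at 1.5× the global median scale — a pooled
estimate that still widens where the reference is genuinely more variable.
Second, the screen evaluates 2 metrics × 61 strongly correlated fractions;
a 2σ cut is therefore expected to flag some healthy fractions on nearly
every bone, while a genuine callus produces z ≈ 10–16.  The module default
stays at `threshold_z = 2` (configurable); the validation study uses 3,
which across many simulated samples detects the callus support to within
the taper shoulder (the cosine taper drops below the population noise floor
around 0.4 mm of apposition) while never chopping the healthy 50–70% band.

## Geometric morphometrics

Three landmark datasets describe one bone:

1. **diaphysis** — 21 sections between 50% and 70%, each with 21 external
   plus 21 internal equiangular semilandmarks: 882 points, ordered
   section-major (ascending fraction), external ring before internal ring,
   each ring in angular order from lateral;
2. **proximal** — the 3 vertices of the proximal articular facet (order is
   semantic: dorsal, plantar-medial, plantar-lateral; violations are
   rejected) plus 21 external semilandmarks at 80%: 24 points;
3. **distal** — 6 named type-II landmarks (medial/lateral epicondyles,
   medial/lateral plantar condyles, dorsal-most point, most distally
   projecting point) plus 15 evenly spaced articular-surface semilandmarks:
   21 points.  Mirrored (left-side) specimens swap medial/lateral roles via
   a bookkeeping helper.

GPA centres each configuration, scales it to unit centroid size and
iteratively rotates it to the evolving mean (SVD rotations with det +1 — no
reflections) until the mean changes by < 1e-10.  Semilandmarks are **not**
slid: equiangular semilandmarks are geometrically, not surface-, defined,
so sliding would destroy their correspondence rule.  After convergence the
whole solution is rotated onto the principal axes of the mean shape with
deterministic axis signs, making the result independent of input order.

Shape variation is summarized by PCA on the covariance of the flattened
aligned coordinates (shape variables share one scale, so a correlation PCA
would be wrong).  Component signs are fixed so the largest-magnitude
loading is positive.  Outlier removal is an explicit user-supplied id list;
no automatic rule is invented.  PC-extreme configurations are
`mean + score · loading`, reshaped to the landmark template — landmark
reconstructions only, no surface warping.

Allometry is tested by regressing a chosen PC score on log centroid size;
significance comes from a permutation test on R² (default 10,000
permutations, seeded, add-one p estimator), which makes no normality
assumptions at the small sample sizes typical of such studies.

## Relative cortical thickness

For each paired ray i, `Rct_i = Ct_i / r_i`, with Ct the along-ray distance
between external and internal semilandmarks and r the centroid-to-external
distance.  The ratio is dimensionless and scale-free.  The diaphysis
between 53% and 65% is unrolled into a 13 × 21 matrix (rows distal →
proximal, columns lateral → plantar → medial → dorsal), flattened row-major
for PCA so loadings map back to (fraction, angle) unambiguously.
Reconstructed PC-extreme maps are never clamped; entries outside (0, 1) are
counted and reported with a warning.

## The phantom generator

A phantom is built from an analytic field, then rasterized (labels:
background / cortical / cavity; isotropic spacing):

- **centerline** — a planar circular arc in the dorsoplantar plane with a
  stated maximal deflection at midshaft (default 2 mm), the simplest
  curvature model that makes orientation non-trivial;
- **cross-section** — annulus with outer radius R(s, θ) and cortical
  thickness t(s, θ); profiles are scalars or vectorized callables, so
  elliptical sections, angular thickness gradients or eccentric cavities
  are one lambda away;
- **epiphyses** — the outer radius is expanded by a cosine-blended factor
  (default 1.4×) over the terminal 15% at each end, and the medullary
  cavity closes smoothly over the terminal 8% (exactly solid in the last
  2%), giving the orientation stage articular "ends" without claiming
  anatomical realism;
- **callus** — a cosine-tapered periosteal increment of the outer radius
  over a stated axial window; the cavity is untouched (periosteal, not
  endosteal, reaction).  The callused bone is re-rasterized from its
  generating spec, so the perturbation is exact, and voxel coordinates are
  computed as integer offsets × spacing so voxels shared between
  differently sized grids classify identically.

Default spec: length 65 mm, outer radius 5 mm, cortex 2 mm, curvature 2 mm
— the proportions of a generic adult second metatarsal.  Validation rejects
specs whose cavity vanishes, whose cortex spans < 2 voxels, or whose
length/spacing ratio is < 100 (1% sectioning would be meaningless).

Populations draw per-specimen profiles as group mean + independent smooth
noise: a low-order Fourier series in angle (harmonics 0–2) modulated by a
quadratic in axial fraction, rescaled to a stated RMS amplitude (mm).  Both
the thickness and the outer-radius profile receive independent noise
fields: a population varying only in cortex would make the external shape
index Zx/Zy nearly degenerate across specimens, which no real comparative
sample is.  Group effects shift profile means (e.g. +0.6 mm cortical
thickness).  Everything is reproducible from a single seed via spawned
generators, and each phantom carries a ground-truth record (frame, length,
sampled thickness field, generating spec) serialized as a JSON sidecar.

What the phantoms do **not** emulate: trabecular bone, cortical porosity,
scanner noise and partial-volume artifacts, segmentation errors, and real
anatomical shape (epiphyses are radial bulges, not condyles).  Passing
tests therefore demonstrate the correctness of the measurement chain on
clean segmented geometry, not robustness to acquisition artifacts.

## Validation studies and problem sizes

The test suite and `scripts/acceptance.py` regenerate everything from code;
sizes were chosen to exercise each claim at the resolution it needs:

- closed-form CSG and Rct oracles on a 70 mm straight tube at 0.1 mm
  spacing (the finest grid used; ~8.5 M voxels);
- an eccentric-cavity tube checked per-ray against a dense nearest-voxel
  ray-casting oracle that shares no code with the shapely measurement path;
- the two-group recovery study: 10 + 10 specimens, 0.6 mm cortical
  thickness contrast, 0.1 mm RMS profile noise, 0.3 mm spacing — both the
  diaphyseal-shape PC1 and the thickness-map PC1 must classify groups by
  score sign at ≥ 90% accuracy;
- the callus screen: 10 healthy reference draws plus an 11th draw given a
  3 mm callus over fractions 0.20–0.45;
- the allometry test size: 500 null simulations at n = 35 with 1,000
  permutations, checked against the binomial 95% CI around α = 0.05.

## Known limitations

- Sub-voxel accuracy of outlines is ~0.1–0.5 voxel; quantities dominated by
  a single extreme point (Zp via max radius) carry the largest relative
  bias (≈0.5–1% at 0.1 mm spacing on a 5 mm radius).
- The farthest-intersection rule makes non-star-shaped outlines merely
  tolerated, not faithfully represented.
- The reliable-region screen assumes the reference sample is healthy and
  homogeneous; screening a specimen against a mixed-group reference can
  legitimately find no normal fraction (the pipeline records the absence
  rather than failing).
- `estimate_length_from_reference` is a stated isometry assumption, not a
  validated regression.
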