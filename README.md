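# osteomap

Virtual morphometry of tubular bones from segmented voxel volumes:
biomechanical orientation, cross-sectional geometry (CSG), equiangular
semilandmark geometric morphometrics, and relative-cortical-thickness maps
— with a synthetic phantom generator that provides closed-form ground truth
for every stage.

## Who this is for

Biological anthropologists and bone-biomechanics researchers who quantify
long-bone diaphyseal structure from microCT/CT segmentations — and who want
each step of that chain (orientation, sectioning, landmarking, CSG,
Procrustes/PCA, thickness maps) as tested, composable library functions
rather than a one-off script.

## The measurements

A bone is placed in an anatomical frame (origin at the distal articular
centre, z through the articular extremes pointing proximally, +x lateral,
+y plantar); **biomechanical length** is measured between the extreme bone
points on the z-axis, and everything downstream is expressed as a fraction
of it (0% distal, 100% proximal).

- **CSG** — 61 cross sections (20–80%, 1% steps); per section the cortical
  annulus gives CA, TA, CA%, second moments Ix, Iy, J = Ix + Iy by exact
  polygon integration, and extreme-fiber moduli Zx = Ix/max|y|,
  Zy = Iy/max|x|, Zp = J/max r, standardized by
  (ML diameter × DP diameter × length).  A robust screen compares a
  specimen's Zx/Zy and CA% profiles against a reference sample to find the
  longest shaft interval unaffected by local pathology (e.g. a stress
  callus).
- **Shape** — three landmark datasets (diaphysis 50–70%: 21 sections × 21
  paired equiangular semilandmarks on the external and internal outlines =
  882 points; proximal: 3 facet vertices + 21 semilandmarks at 80%;
  distal: 6 type-II landmarks + 15 surface semilandmarks), generalized
  Procrustes analysis (translate/rotate/scale, no reflection, no sliding),
  covariance PCA, PC-extreme shape reconstruction, and a permutation test
  for allometry (PC score vs. log centroid size).
- **Thickness maps** — per ray, relative cortical thickness
  `Rct_i = Ct_i / r_i` (cortical thickness over centroid-to-surface
  distance); 13 sections (53–65%) × 21 angular stations unrolled into a
  13 × 21 matrix (lateral → plantar → medial → dorsal), compared across
  specimens by PCA with colormap-style reconstructions at PC extremes.

## Worked example

```python
import numpy as np
from osteomap import (
    BonePhantomSpec, generate_bone, orient_bone, extract_section,
    equiangular_semilandmarks, relative_thickness, section_properties,
)
from osteomap.phantom import anatomical_points

# a straight tube: outer radius 5 mm, cortex 2 mm, length 70 mm
spec = BonePhantomSpec(
    length_mm=70.0, shaft_curvature_mm=0.0, outer_radius_profile=5.0,
    cortical_thickness_profile=2.0, epiphysis_scale=1.0, voxel_spacing_mm=0.1,
)
volume, truth = generate_bone(spec)
frame = orient_bone(volume, anatomical_points(spec))
print(f"biomechanical length: {frame.biomechanical_length_mm:.1f} mm")

section = extract_section(volume, frame, 0.5)          # midshaft
rec = section_properties(section, frame.biomechanical_length_mm)
print(f"CA  = {rec.CA:.2f} mm^2   (16*pi  = {16*np.pi:.2f})")
print(f"Ix  = {rec.Ix:.1f} mm^4  (136*pi = {136*np.pi:.1f})")
print(f"Zp  = {rec.Zp:.1f} mm^3  (54.4*pi = {54.4*np.pi:.1f})")

slm = equiangular_semilandmarks(section, k=21)
rct = relative_thickness(section, slm)
print(f"Rct = {rct.mean():.3f} +/- {rct.std():.3f}  (exact: 0.400)")
```

prints

```
biomechanical length: 70.0 mm
CA  = 50.24 mm^2   (16*pi  = 50.27)
Ix  = 425.9 mm^4  (136*pi = 427.3)
Zp  = 170.1 mm^3  (54.4*pi = 170.9)
Rct = 0.401 +/- 0.001  (exact: 0.400)
```

For an annulus with outer radius 5 mm and inner radius 3 mm the closed
forms are CA = 16π mm², Ix = 136π mm⁴, Zp = 54.4π mm³ and Rct = 0.4 on
every ray; the measured values recover them to well under 1% at 0.1 mm
voxel spacing.

## Command line

```bash
# simulate a two-group population (thickness contrast 0.6 mm)
osteomap simulate --n 10 --groups "A:0.0,B:0.6" --noise-sd 0.1 --seed 1 --out pop/

# run every stage from a YAML config (or from the manifest written above)
osteomap run-all --config config.yaml --out results/
```

`run-all` executes orient → CSG → reliable-region screen → GPA/PCA →
thickness-map PCA and writes tidy CSVs plus a JSON report (with its
markdown twin) carrying the seed and config hash; reruns with the same
seed are bit-identical.

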