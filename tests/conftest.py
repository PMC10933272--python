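"""Shared fixtures: phantoms and independent measurement oracles.

Expensive phantoms are session-scoped so the whole suite (including the
acceptance tests) rasterizes each geometry once.
"""

from __future__ import annotations

import numpy as np
import pytest

from osteomap.orientation import orient_bone
from osteomap.phantom import BonePhantomSpec, anatomical_points, generate_bone, generate_population
from osteomap.volume import CORTICAL, LabeledVolume

# ---------------------------------------------------------------------------
# oracles (deliberately independent of the shapely/contour measurement path)
# ---------------------------------------------------------------------------


def raycast_section(
    volume: LabeledVolume, z_mm: float, angles: np.ndarray, origin_xy=None, step_frac=0.2
):
    """Dense ray-casting on the voxel mask at a transverse plane.

    Marches each ray outward from ``origin_xy`` (default: cortical-pixel
    centroid) sampling the nearest-voxel label, and returns per-angle
    (r_inner, r_outer, cortical_thickness) where thickness is the summed
    cortical path length along the ray.
    """
    sp = volume.spacing_mm
    k = int(round((z_mm - volume.origin_mm[2]) / sp))
    plane = volume.labels[:, :, k]
    xs = volume.origin_mm[0] + sp * np.arange(plane.shape[0])
    ys = volume.origin_mm[1] + sp * np.arange(plane.shape[1])
    if origin_xy is None:
        ci, cj = np.nonzero(plane == CORTICAL)
        origin_xy = np.array([xs[ci].mean(), ys[cj].mean()])
    step = sp * step_frac
    rmax = max(xs[-1] - xs[0], ys[-1] - ys[0])
    rs = np.arange(step, rmax, step)
    out = np.empty((len(angles), 3))
    for a, ang in enumerate(np.asarray(angles, float)):
        px = origin_xy[0] + rs * np.cos(ang)
        py = origin_xy[1] + rs * np.sin(ang)
        ii = np.clip(np.round((px - xs[0]) / sp).astype(int), 0, plane.shape[0] - 1)
        jj = np.clip(np.round((py - ys[0]) / sp).astype(int), 0, plane.shape[1] - 1)
        lab = plane[ii, jj]
        cort = np.flatnonzero(lab == CORTICAL)
        if len(cort) == 0:
            raise ValueError(f"oracle ray at {ang} hits no cortex")
        out[a] = rs[cort[0]], rs[cort[-1]], len(cort) * step
    return origin_xy, out


def pixel_moments(volume: LabeledVolume, z_mm: float):
    """Pixel-counting CSG oracle: (CA, Ix, Iy) from cortical pixels at a plane."""
    sp = volume.spacing_mm
    k = int(round((z_mm - volume.origin_mm[2]) / sp))
    plane = volume.labels[:, :, k] == CORTICAL
    ii, jj = np.nonzero(plane)
    x = volume.origin_mm[0] + sp * ii
    y = volume.origin_mm[1] + sp * jj
    x = x - x.mean()
    y = y - y.mean()
    area = len(ii) * sp**2
    ix = np.sum(y**2) * sp**2
    iy = np.sum(x**2) * sp**2
    return area, ix, iy


# ---------------------------------------------------------------------------
# session phantoms
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def fine_cylinder():
    """Straight tube, R=5 / t=2 / L=70 mm at 0.1 mm spacing (closed-form oracle)."""
    spec = BonePhantomSpec(
        length_mm=70.0, shaft_curvature_mm=0.0, outer_radius_profile=5.0,
        cortical_thickness_profile=2.0, epiphysis_scale=1.0, voxel_spacing_mm=0.1,
    )
    volume, truth = generate_bone(spec)
    frame = orient_bone(volume, anatomical_points(spec))
    return spec, volume, truth, frame


@pytest.fixture(scope="session")
def eccentric_cylinder():
    """Short tube with the medullary cavity offset 1 mm laterally.

    Outer circle R=5 about the centerline; cavity = circle of radius 3
    centred 1 mm toward +x, encoded as an angle-dependent thickness profile.
    """
    d, r_cav, R = 1.0, 3.0, 5.0

    def thickness(s, theta):
        theta = np.asarray(theta, float)
        rho_in = d * np.cos(theta) + np.sqrt(r_cav**2 - (d * np.sin(theta)) ** 2)
        return np.broadcast_to(R - rho_in, np.broadcast_shapes(np.shape(s), theta.shape)).copy()

    spec = BonePhantomSpec(
        length_mm=20.0, shaft_curvature_mm=0.0, outer_radius_profile=R,
        cortical_thickness_profile=thickness, epiphysis_scale=1.0, voxel_spacing_mm=0.1,
    )
    volume, truth = generate_bone(spec)
    frame = orient_bone(volume, anatomical_points(spec))
    return spec, volume, truth, frame


@pytest.fixture(scope="session")
def curved_phantom():
    """Curved bone with flared ends at working resolution."""
    spec = BonePhantomSpec(
        length_mm=60.0, shaft_curvature_mm=3.0, outer_radius_profile=5.0,
        cortical_thickness_profile=2.0, epiphysis_scale=1.4, voxel_spacing_mm=0.25,
    )
    volume, truth = generate_bone(spec)
    frame = orient_bone(volume, anatomical_points(spec))
    return spec, volume, truth, frame


POPULATION_SEED = 20240915


@pytest.fixture(scope="session")
def two_group_population():
    """Two groups differing by 0.6 mm mean cortical thickness, n=10 each,
    smooth specimen noise of 0.1 mm RMS."""
    return generate_population(
        n=10,
        group_effects={"thin": {"thickness_delta_mm": 0.0}, "thick": {"thickness_delta_mm": 0.6}},
        noise_sd=0.1,
        seed=POPULATION_SEED,
    )


@pytest.fixture(scope="session")
def population_analysis(two_group_population):
    """Frames, diaphyseal shape configurations and thickness matrices for the
    two-group population (shared by recovery and acceptance tests)."""
    from osteomap.morphometrics import build_diaphysis_dataset
    from osteomap.thickness import build_matrix

    frames, configs, matrices, groups = [], [], [], []
    for i, (vol, truth) in enumerate(two_group_population):
        sid = f"{truth.group_label}{i:02d}"
        frame = orient_bone(vol, anatomical_points(truth.spec))
        frames.append(frame)
        configs.append(build_diaphysis_dataset(vol, frame, specimen_id=sid))
        matrices.append(build_matrix(vol, frame, specimen_id=sid))
        groups.append(truth.group_label)
    return {"frames": frames, "configs": configs, "matrices": matrices, "groups": groups}
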