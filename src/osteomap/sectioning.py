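"""Cross-section extraction and equiangular semilandmark placement.

Sections are cut perpendicular to the biomechanical z-axis at stated
fractions of biomechanical length.  In-plane coordinates are (+x lateral,
+y plantar), mm.  The cortical annulus is traced at sub-voxel precision with
marching squares on the resampled label field; semilandmarks are the
farthest intersections of equiangular rays from the section's centre of
gravity (the area centroid of the cortical annulus) with each outline,
ordered lateral → plantar → medial → dorsal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal
from shapely.geometry import LinearRing, LineString, Point, Polygon
from skimage import measure

from .orientation import BiomechanicalFrame, axial_plane
from .volume import CAVITY, LabeledVolume

logger = logging.getLogger(__name__)


class SectioningError(ValueError):
    """Section cannot be extracted or landmarked at the requested fraction."""


@dataclass
class CrossSection:
    """One planar cut: external/internal cortical outlines + centroid, mm.

    ``internal_outline`` is None for solid (cavity-free) sections.  Outlines
    are closed, simple, counterclockwise polygons; ``centroid`` is the area
    centroid of the cortical annulus.
    """

    fraction: float
    external_outline: np.ndarray  # (m, 2)
    internal_outline: np.ndarray | None
    centroid: np.ndarray  # (2,)

    @property
    def has_cavity(self) -> bool:
        return self.internal_outline is not None


@dataclass
class SectionSemilandmarks:
    """Paired equiangular semilandmarks of one section."""

    angles: np.ndarray  # (k,) radians from lateral (+x)
    external_points: np.ndarray  # (k, 2) mm
    internal_points: np.ndarray | None  # (k, 2) mm or None


def _shoelace_area(poly: np.ndarray) -> float:
    x, y = poly[:, 0], poly[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def _as_ccw(poly: np.ndarray) -> np.ndarray:
    return poly if _shoelace_area(poly) > 0 else poly[::-1]


def _smooth_closed(poly: np.ndarray) -> np.ndarray:
    """Suppress voxel-scale contour wiggle without shrinking curved outlines.

    Savitzky-Golay (quadratic, wrapped) along the contour reproduces local
    parabolas exactly, so circles keep their radius while the half-voxel
    stair-step noise of the marching-squares polygon is averaged out.  The
    window scales with the vertex count (~2.5 voxels of arc length).
    """
    n = len(poly)
    window = min(41, max(7, (n // 13) | 1))
    if n <= window:
        return poly
    return signal.savgol_filter(poly, window, 2, axis=0, mode="wrap")


def _largest_closed_contour(field: np.ndarray) -> np.ndarray | None:
    """Largest closed 0.5-level contour of a sampled indicator field."""
    best, best_area = None, 0.0
    for c in measure.find_contours(field, 0.5):
        if len(c) < 4 or not np.allclose(c[0], c[-1]):
            continue
        area = abs(_shoelace_area(c[:-1]))
        if area > best_area:
            best, best_area = c[:-1], area
    return best


def extract_section(
    volume: LabeledVolume, frame: BiomechanicalFrame, fraction: float
) -> CrossSection:
    """Cut the volume at a fraction of biomechanical length.

    The label field is resampled on an in-plane grid at the native voxel
    spacing; external outline = 0.5-level contour of the bone indicator,
    internal outline = 0.5-level contour of the cavity indicator.
    """
    p0, _ = axial_plane(frame, fraction)
    sp = volume.spacing_mm

    bone = volume.bone_mask()
    if not bone.any():
        raise SectioningError("volume contains no bone")
    lo_i, hi_i = np.empty(3, int), np.empty(3, int)
    for ax in range(3):
        proj = np.any(bone, axis=tuple(a for a in range(3) if a != ax))
        nz = np.flatnonzero(proj)
        lo_i[ax], hi_i[ax] = nz[0], nz[-1]
    half_diag = 0.5 * np.linalg.norm((hi_i - lo_i + 2) * sp)
    # plane must pass near the bone at all
    center_w = volume.origin_mm + sp * (lo_i + hi_i) / 2.0
    if abs(np.dot(p0 - center_w, frame.z_axis)) > half_diag:
        raise SectioningError(f"section plane at fraction {fraction} misses the bone")

    # in-plane extent: projection of the bone bounding box onto the section axes
    lo_w = volume.origin_mm + sp * (lo_i - 1)
    hi_w = volume.origin_mm + sp * (hi_i + 1)
    box = np.array(
        [[a, b, c] for a in (lo_w[0], hi_w[0]) for b in (lo_w[1], hi_w[1]) for c in (lo_w[2], hi_w[2])]
    ) - p0
    nu = int(np.ceil(np.abs(box @ frame.x_axis).max() / sp)) + 2
    nv = int(np.ceil(np.abs(box @ frame.y_axis).max() / sp)) + 2
    cu = np.arange(-nu, nu + 1) * sp
    cv = np.arange(-nv, nv + 1) * sp
    U, V = np.meshgrid(cu, cv, indexing="ij")
    P = p0 + U[..., None] * frame.x_axis + V[..., None] * frame.y_axis
    ijk = volume.world_to_index(P).transpose(2, 0, 1)

    bone_f = ndimage.map_coordinates(bone.astype(np.float32), ijk, order=1)
    if bone_f.max() < 0.5:
        raise SectioningError(f"no cortical bone in the plane at fraction {fraction}")
    cav_f = ndimage.map_coordinates(
        (volume.labels == CAVITY).astype(np.float32), ijk, order=1
    )

    ext_c = _largest_closed_contour(bone_f)
    if ext_c is None:
        raise SectioningError(f"no closed external outline at fraction {fraction}")
    def contour_to_mm(c: np.ndarray) -> np.ndarray:
        return np.column_stack([-nu * sp + c[:, 0] * sp, -nv * sp + c[:, 1] * sp])

    external = _as_ccw(_smooth_closed(contour_to_mm(ext_c)))
    internal = None
    if cav_f.max() >= 0.5:
        int_c = _largest_closed_contour(cav_f)
        if int_c is not None:
            internal = _as_ccw(_smooth_closed(contour_to_mm(int_c)))

    ext_poly = Polygon(external)
    if not ext_poly.is_valid:
        ext_poly = ext_poly.buffer(0)
    if internal is not None:
        int_poly = Polygon(internal)
        if not ext_poly.contains(int_poly.representative_point()):
            raise SectioningError(
                f"internal outline not inside external outline at fraction {fraction}"
            )
        centroid = Polygon(external, holes=[internal[::-1]]).centroid
    else:
        centroid = ext_poly.centroid
    return CrossSection(
        fraction=float(fraction),
        external_outline=external,
        internal_outline=internal,
        centroid=np.array([centroid.x, centroid.y]),
    )


def section_series(
    volume: LabeledVolume,
    frame: BiomechanicalFrame,
    from_fraction: float,
    to_fraction: float,
    step: float,
) -> list[CrossSection]:
    """Inclusive series of sections; count = round((to-from)/step) + 1."""
    if step <= 0:
        raise ValueError("step must be positive")
    if from_fraction > to_fraction:
        raise ValueError("from_fraction must not exceed to_fraction")
    count = int(round((to_fraction - from_fraction) / step)) + 1
    fractions = from_fraction + step * np.arange(count)
    out = []
    for f in fractions:
        try:
            out.append(extract_section(volume, frame, float(f)))
        except SectioningError as exc:
            raise SectioningError(f"section at fraction {f:.3f} failed: {exc}") from exc
    return out


def _ray_farthest(ring: LinearRing, origin: np.ndarray, angle: float, reach: float):
    """Farthest intersection of the ray from origin at angle with a ring."""
    direction = np.array([np.cos(angle), np.sin(angle)])
    ray = LineString([origin, origin + reach * direction])
    inter = ray.intersection(ring)
    if inter.is_empty:
        return None, 0
    pts: list[Point] = []
    geoms = getattr(inter, "geoms", [inter])
    for g in geoms:
        if isinstance(g, Point):
            pts.append(g)
        else:  # grazing segment: use its endpoints
            pts.extend(Point(c) for c in g.coords)
    dists = [np.hypot(p.x - origin[0], p.y - origin[1]) for p in pts]
    best = pts[int(np.argmax(dists))]
    return np.array([best.x, best.y]), len(pts)


def equiangular_semilandmarks(
    section: CrossSection, k: int = 21, start_angle: float = 0.0
) -> SectionSemilandmarks:
    """Place k paired equiangular semilandmarks on the section outlines.

    Ray i leaves the section centroid at ``start_angle + 2*pi*i/k`` (index 0
    = lateral by default, proceeding toward plantar).  When a ray crosses an
    outline more than once (possible with strong callus lobes), the farthest
    intersection is taken for both outlines and a warning is logged.
    """
    if k < 3:
        raise ValueError("need at least 3 rays")
    angles = start_angle + 2 * np.pi * np.arange(k) / k
    ext_ring = LinearRing(section.external_outline)
    int_ring = LinearRing(section.internal_outline) if section.has_cavity else None
    reach = 4.0 * max(
        np.linalg.norm(section.external_outline - section.centroid, axis=1).max(), 1e-6
    )
    ext_pts = np.empty((k, 2))
    int_pts = np.empty((k, 2)) if int_ring is not None else None
    for i, a in enumerate(angles):
        p, nhits = _ray_farthest(ext_ring, section.centroid, a, reach)
        if p is None:
            raise SectioningError(
                f"ray at angle {a:.4f} rad does not intersect the external outline"
            )
        if nhits > 1:
            logger.warning(
                "fraction %.3f: ray %.4f rad crosses the external outline %d times; "
                "keeping the farthest intersection", section.fraction, a, nhits,
            )
        ext_pts[i] = p
        if int_ring is not None:
            q, nh2 = _ray_farthest(int_ring, section.centroid, a, reach)
            if q is None:
                raise SectioningError(
                    f"ray at angle {a:.4f} rad does not intersect the internal outline"
                )
            if nh2 > 1:
                logger.warning(
                    "fraction %.3f: ray %.4f rad crosses the internal outline %d times",
                    section.fraction, a, nh2,
                )
            int_pts[i] = q
    return SectionSemilandmarks(angles=angles, external_points=ext_pts, internal_points=int_pts)


def outline_contour_at_80(
    volume: LabeledVolume, frame: BiomechanicalFrame, k: int = 21
) -> tuple[CrossSection, SectionSemilandmarks]:
    """External outline at 80% of biomechanical length with k semilandmarks."""
    section = extract_section(volume, frame, 0.80)
    slm = equiangular_semilandmarks(section, k=k)
    return section, SectionSemilandmarks(
        angles=slm.angles, external_points=slm.external_points, internal_points=None
    )


def midshaft_ml_diameter(
    volume: LabeledVolume, frame: BiomechanicalFrame, fraction: float = 0.5
) -> float:
    """Mediolateral external diameter at a shaft fraction (default midshaft)."""
    ext = extract_section(volume, frame, fraction).external_outline
    return float(ext[:, 0].max() - ext[:, 0].min())
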