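"""Biomechanical orientation of a tubular bone.

The anatomical coordinate system follows the convention used in
cross-sectional geometry studies of metatarsals: the origin sits at the
central point of the distal articular surface, the z-axis runs through the
central point of the proximal articulation and the most distal point of the
distal articulation (pointing proximally), the x-axis is parallel to the
dorsal surface of the distal epiphysis (+x lateral), and the y-axis
completes the right-handed frame pointing plantarly.  Biomechanical length
is the distance between the most extreme bone-surface points lying on the
z-axis; positions along the shaft are expressed as fractions of it
(0 = distal, 1 = proximal).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .volume import LabeledVolume


class OrientationError(ValueError):
    """Degenerate anatomical geometry (collinear patch, axis miss, …)."""


@dataclass
class AnatomicalPoints:
    """Manually (or synthetically) placed anatomical reference points, mm."""

    distal_articular_center: np.ndarray
    proximal_articular_center: np.ndarray
    most_distal_articular_point: np.ndarray
    dorsal_surface_patch: np.ndarray  # (>=3, 3) points on the dorsal surface

    def __post_init__(self) -> None:
        self.distal_articular_center = np.asarray(self.distal_articular_center, float).reshape(3)
        self.proximal_articular_center = np.asarray(self.proximal_articular_center, float).reshape(3)
        self.most_distal_articular_point = np.asarray(
            self.most_distal_articular_point, float
        ).reshape(3)
        self.dorsal_surface_patch = np.asarray(self.dorsal_surface_patch, float).reshape(-1, 3)
        if np.allclose(self.distal_articular_center, self.proximal_articular_center):
            raise OrientationError("distal and proximal articular centers coincide")
        if len(self.dorsal_surface_patch) < 3:
            raise OrientationError("dorsal surface patch needs at least 3 points")

    def transformed(self, rotation: np.ndarray, translation: np.ndarray = None) -> "AnatomicalPoints":
        """Apply a rigid motion p -> R p + t to every point."""
        t = np.zeros(3) if translation is None else np.asarray(translation, float)
        R = np.asarray(rotation, float)
        return AnatomicalPoints(
            R @ self.distal_articular_center + t,
            R @ self.proximal_articular_center + t,
            R @ self.most_distal_articular_point + t,
            self.dorsal_surface_patch @ R.T + t,
        )


@dataclass
class BiomechanicalFrame:
    """Origin + orthonormal right-handed axes + biomechanical length."""

    origin: np.ndarray
    x_axis: np.ndarray
    y_axis: np.ndarray
    z_axis: np.ndarray
    biomechanical_length_mm: float
    distal_extreme_mm: np.ndarray = None  # most distal bone point on the z-axis

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, float).reshape(3)
        for name in ("x_axis", "y_axis", "z_axis"):
            v = np.asarray(getattr(self, name), float).reshape(3)
            setattr(self, name, v / np.linalg.norm(v))
        R = self.rotation
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
            raise OrientationError("axes are not orthonormal")
        if np.linalg.det(R) < 0:
            raise OrientationError("axes are not right-handed")
        if self.biomechanical_length_mm <= 0:
            raise OrientationError("biomechanical length must be positive")
        if self.distal_extreme_mm is None:
            self.distal_extreme_mm = self.origin.copy()
        else:
            self.distal_extreme_mm = np.asarray(self.distal_extreme_mm, float).reshape(3)

    @property
    def rotation(self) -> np.ndarray:
        """World-from-frame rotation matrix, columns = x, y, z axes."""
        return np.column_stack([self.x_axis, self.y_axis, self.z_axis])

    def world_to_frame(self, points_mm: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points_mm, float)) - self.origin
        out = p @ self.rotation
        return out[0] if np.ndim(points_mm) == 1 else out

    def to_json(self) -> str:
        return json.dumps(
            {
                "origin_mm": self.origin.tolist(),
                "x_axis": self.x_axis.tolist(),
                "y_axis": self.y_axis.tolist(),
                "z_axis": self.z_axis.tolist(),
                "biomechanical_length_mm": self.biomechanical_length_mm,
                "distal_extreme_mm": self.distal_extreme_mm.tolist(),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "BiomechanicalFrame":
        d = json.loads(text)
        return cls(
            d["origin_mm"], d["x_axis"], d["y_axis"], d["z_axis"],
            d["biomechanical_length_mm"], d.get("distal_extreme_mm"),
        )


def _best_fit_plane_normal(points: np.ndarray) -> np.ndarray:
    """Unit normal of the total-least-squares plane through a point patch."""
    centered = points - points.mean(axis=0)
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[1] < 1e-9 * max(s[0], 1e-30):
        raise OrientationError("dorsal surface patch is collinear")
    return vt[-1]


def compute_frame(points: AnatomicalPoints) -> BiomechanicalFrame:
    """Anatomical frame from supplied reference points.

    z runs from the most distal point of the distal articulation to the
    central point of the proximal articulation; x lies in the best-fit plane
    of the dorsal patch, orthogonal to z; y = z × x, sign-fixed to point
    plantarly (away from the dorsal patch, toward the bone interior).
    """
    z = points.proximal_articular_center - points.most_distal_articular_point
    z = z / np.linalg.norm(z)
    n = _best_fit_plane_normal(points.dorsal_surface_patch)
    x = np.cross(n, z)
    nx = np.linalg.norm(x)
    if nx < 1e-8:
        raise OrientationError("z-axis is parallel to the dorsal plane normal")
    x = x / nx
    y = np.cross(z, x)
    # plantar direction: from the dorsal patch toward the distal articular center
    plantar_hint = points.distal_articular_center - points.dorsal_surface_patch.mean(axis=0)
    if np.dot(y, plantar_hint) < 0:
        x, y = -x, -y
    chord = np.linalg.norm(
        points.proximal_articular_center - points.most_distal_articular_point
    )
    return BiomechanicalFrame(
        origin=points.distal_articular_center,
        x_axis=x, y_axis=y, z_axis=z,
        biomechanical_length_mm=chord,
        distal_extreme_mm=points.most_distal_articular_point,
    )


def biomechanical_length(
    points: AnatomicalPoints, volume: LabeledVolume, frame: BiomechanicalFrame
) -> float:
    """Length between the extreme bone-surface intersections with the z-axis.

    Also updates ``frame.biomechanical_length_mm`` and
    ``frame.distal_extreme_mm`` in place so downstream sectioning uses the
    measured, not the chord, length.
    """
    anchor = points.most_distal_articular_point
    lo, hi = volume.world_bounds()
    # parameter range of the z-line that can intersect the volume box
    corners = np.array([[a, b, c] for a in (lo[0], hi[0]) for b in (lo[1], hi[1]) for c in (lo[2], hi[2])])
    t_proj = (corners - anchor) @ frame.z_axis
    step = volume.spacing_mm / 2.0
    ts = np.arange(t_proj.min() - step, t_proj.max() + step, step)
    pts = anchor + ts[:, None] * frame.z_axis
    vals = ndimage.map_coordinates(
        volume.bone_mask().astype(np.float32), volume.world_to_index(pts).T, order=1
    )
    inside = vals >= 0.5
    if not inside.any():
        raise OrientationError("z-axis does not intersect the bone")
    t_min, t_max = ts[inside][0], ts[inside][-1]
    length = float(t_max - t_min)
    frame.biomechanical_length_mm = length
    frame.distal_extreme_mm = anchor + t_min * frame.z_axis
    return length


def orient_bone(volume: LabeledVolume, points: AnatomicalPoints) -> BiomechanicalFrame:
    """Convenience: frame from points with the length measured on the volume."""
    frame = compute_frame(points)
    biomechanical_length(points, volume, frame)
    return frame


def axial_plane(frame: BiomechanicalFrame, fraction: float) -> tuple[np.ndarray, np.ndarray]:
    """Section plane (point, normal) at a fraction of biomechanical length."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"fraction {fraction} outside [0, 1]")
    point = frame.distal_extreme_mm + fraction * frame.biomechanical_length_mm * frame.z_axis
    return point, frame.z_axis.copy()


def estimate_length_from_reference(
    incomplete_dimension_mm: float,
    reference_dimension_mm: float,
    reference_length_mm: float,
) -> float:
    """Estimate biomechanical length of an incomplete bone by proportion.

    Uses a homologous dimension measurable on both bones (by convention the
    midshaft mediolateral diameter): length = reference length scaled by the
    dimension ratio.  Assumes isometry between the two specimens.
    """
    if reference_dimension_mm <= 0:
        raise ValueError("reference dimension must be positive")
    if incomplete_dimension_mm <= 0:
        raise ValueError("incomplete specimen dimension must be positive")
    if reference_length_mm <= 0:
        raise ValueError("reference length must be positive")
    return reference_length_mm * incomplete_dimension_mm / reference_dimension_mm


# -- CSV interchange -------------------------------------------------------

_POINT_ROWS = (
    "distal_articular_center",
    "proximal_articular_center",
    "most_distal_articular_point",
)


def points_to_csv(points: AnatomicalPoints, specimen_id: str, path: str) -> None:
    rows = []
    for name in _POINT_ROWS:
        x, y, z = getattr(points, name)
        rows.append((specimen_id, name, x, y, z))
    for i, (x, y, z) in enumerate(points.dorsal_surface_patch):
        rows.append((specimen_id, f"dorsal_patch_{i}", x, y, z))
    pd.DataFrame(rows, columns=["specimen_id", "point", "x_mm", "y_mm", "z_mm"]).to_csv(
        path, index=False
    )


def points_from_csv(path: str, specimen_id: str | None = None) -> AnatomicalPoints:
    df = pd.read_csv(path)
    if specimen_id is not None:
        df = df[df["specimen_id"] == specimen_id]
    if df.empty:
        raise ValueError(f"no anatomical points for specimen {specimen_id!r} in {path}")
    by_name = {r.point: np.array([r.x_mm, r.y_mm, r.z_mm]) for r in df.itertuples()}
    patch = [v for k, v in sorted(by_name.items()) if k.startswith("dorsal_patch_")]
    missing = [n for n in _POINT_ROWS if n not in by_name]
    if missing:
        raise ValueError(f"missing anatomical points: {missing}")
    return AnatomicalPoints(
        by_name["distal_articular_center"],
        by_name["proximal_articular_center"],
        by_name["most_distal_articular_point"],
        np.array(patch),
    )
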