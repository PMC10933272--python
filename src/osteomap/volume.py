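"""Labeled voxel volumes for segmented bone scans.

A :class:`LabeledVolume` is a three-label voxel grid (background, cortical
bone, medullary cavity) on an isotropic physical grid.  Array axes map to
world axes as ``(i, j, k) -> (x, y, z)``; the world position of voxel
``(i, j, k)`` is ``origin + spacing * (i, j, k)`` (voxel centres).  In the
canonical anatomical pose +x is lateral, +y plantar and +z proximal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import tifffile

BACKGROUND = 0
CORTICAL = 1
CAVITY = 2

_VALID_LABELS = frozenset({BACKGROUND, CORTICAL, CAVITY})


@dataclass
class LabeledVolume:
    """Voxel grid with background / cortical / cavity labels and mm spacing."""

    labels: np.ndarray  # uint8, shape (nx, ny, nz)
    spacing_mm: float
    origin_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.labels = np.ascontiguousarray(self.labels, dtype=np.uint8)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3-D array")
        if self.spacing_mm <= 0:
            raise ValueError("spacing must be positive")
        extra = set(np.unique(self.labels)) - _VALID_LABELS
        if extra:
            raise ValueError(f"unexpected label values {sorted(extra)}")
        self.origin_mm = np.asarray(self.origin_mm, dtype=float).reshape(3)

    # -- geometry helpers -------------------------------------------------

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def world_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """(min, max) world coordinates of the voxel-centre grid, mm."""
        lo = self.origin_mm
        hi = self.origin_mm + self.spacing_mm * (np.array(self.shape) - 1)
        return lo, hi

    def world_to_index(self, points_mm: np.ndarray) -> np.ndarray:
        """Map world coordinates (…, 3) to fractional voxel indices."""
        return (np.asarray(points_mm, dtype=float) - self.origin_mm) / self.spacing_mm

    def bone_mask(self) -> np.ndarray:
        return self.labels != BACKGROUND

    def cortical_volume_mm3(self) -> float:
        return float(np.count_nonzero(self.labels == CORTICAL)) * self.spacing_mm**3


def mirror_volume(volume: LabeledVolume) -> LabeledVolume:
    """Reflect a volume across the plane normal to the mediolateral (x) axis.

    Used to bring left-side bones into right-side convention.  The reflection
    plane passes through the centre of the grid, so mirroring twice restores
    the original volume voxel-for-voxel.
    """
    if volume.labels.size == 0 or not volume.bone_mask().any():
        raise ValueError("cannot mirror an empty volume")
    return LabeledVolume(
        labels=np.flip(volume.labels, axis=0).copy(),
        spacing_mm=volume.spacing_mm,
        origin_mm=volume.origin_mm.copy(),
    )


# -- file IO ---------------------------------------------------------------


def save_nifti(volume: LabeledVolume, path: str) -> None:
    affine = np.diag([volume.spacing_mm] * 3 + [1.0])
    affine[:3, 3] = volume.origin_mm
    nib.save(nib.Nifti1Image(volume.labels, affine), path)


def load_nifti(path: str) -> LabeledVolume:
    img = nib.load(path)
    spacing = float(img.affine[0, 0])
    scales = np.diag(img.affine)[:3]
    if not np.allclose(scales, spacing, rtol=1e-4):
        raise ValueError("anisotropic or rotated volumes are not supported")
    data = np.asarray(img.dataobj).astype(np.uint8)
    return LabeledVolume(data, spacing_mm=spacing, origin_mm=img.affine[:3, 3])


def save_tiff_stack(volume: LabeledVolume, path: str) -> None:
    """TIFF stack, one page per z slice; spacing stored in the description."""
    pages = np.moveaxis(volume.labels, 2, 0)  # (nz, nx, ny)
    meta = {"spacing_mm": volume.spacing_mm, "origin_mm": volume.origin_mm.tolist()}
    tifffile.imwrite(path, pages, description=repr(meta))
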