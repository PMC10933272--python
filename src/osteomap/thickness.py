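"""Relative-cortical-thickness maps of the diaphysis.

For each paired semilandmark ray i of a cross section, the relative
cortical thickness is

    Rct_i = Ct_i / r_i

with Ct_i the cortical thickness along the ray (distance between the paired
external and internal semilandmarks) and r_i the distance from the section
centroid to the external semilandmark.  Being a ratio, Rct is dimensionless
and invariant to isotropic scaling of the bone.

The diaphysis between 53% and 65% of biomechanical length is unrolled into
a 13 × 21 matrix: rows are sections ordered distal → proximal, columns are
the angular stations ordered lateral → plantar → medial → dorsal (wrapping
back to lateral).  Populations of matrices are compared by covariance PCA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .morphometrics import PCAResult, covariance_pca
from .orientation import BiomechanicalFrame
from .sectioning import CrossSection, SectionSemilandmarks, equiangular_semilandmarks, section_series
from .volume import LabeledVolume


@dataclass
class ThicknessMatrix:
    """Unrolled relative-cortical-thickness map of one diaphysis."""

    specimen_id: str
    fractions: np.ndarray  # (n_rows,), ascending (distal -> proximal)
    angles: np.ndarray  # (n_cols,), radians from lateral
    values: np.ndarray  # (n_rows, n_cols), Rct
    out_of_range: int = 0  # entries outside (0, 1); nonzero only for PC reconstructions

    def __post_init__(self) -> None:
        self.fractions = np.asarray(self.fractions, float)
        self.angles = np.asarray(self.angles, float)
        self.values = np.asarray(self.values, float)
        if self.values.shape != (len(self.fractions), len(self.angles)):
            raise ValueError("values shape must be (n_fractions, n_angles)")
        if np.any(np.diff(self.fractions) <= 0):
            raise ValueError("rows must be ordered distal -> proximal (ascending fraction)")

    @property
    def column_labels(self) -> list[str]:
        """Angular station labels L0, L1, … from the lateral margin."""
        return [f"L{i}" for i in range(len(self.angles))]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=np.round(self.fractions, 4), columns=self.column_labels)


def relative_thickness(section: CrossSection, slm: SectionSemilandmarks) -> np.ndarray:
    """Per-ray Rct = Ct / r for one section's paired semilandmarks."""
    if slm.internal_points is None:
        raise ValueError("paired internal semilandmarks are required")
    ct = np.linalg.norm(slm.external_points - slm.internal_points, axis=1)
    r = np.linalg.norm(slm.external_points - section.centroid, axis=1)
    if np.any(r <= 0):
        raise ValueError("zero centroid-to-surface distance on some ray")
    return ct / r


def build_matrix(
    volume: LabeledVolume,
    frame: BiomechanicalFrame,
    from_fraction: float = 0.53,
    to_fraction: float = 0.65,
    step: float = 0.01,
    k: int = 21,
    specimen_id: str = "specimen",
) -> ThicknessMatrix:
    """Unrolled Rct matrix (13 rows × 21 columns at the defaults)."""
    sections = section_series(volume, frame, from_fraction, to_fraction, step)
    rows = []
    for sec in sections:
        slm = equiangular_semilandmarks(sec, k=k)
        rows.append(relative_thickness(sec, slm))
    values = np.vstack(rows)
    if np.any(values <= 0) or np.any(values >= 1):
        raise ValueError("measured Rct values must lie strictly inside (0, 1)")
    angles = 2 * np.pi * np.arange(k) / k
    fractions = from_fraction + step * np.arange(len(sections))
    return ThicknessMatrix(specimen_id, fractions, angles, values)


def pca_matrices(
    matrices: Sequence[ThicknessMatrix], exclude: Iterable[str] = ()
) -> PCAResult:
    """Covariance PCA over specimens' row-major-flattened Rct matrices."""
    if len(matrices) < 3:
        raise ValueError("need at least 3 matrices")
    shape = matrices[0].values.shape
    for m in matrices:
        if m.values.shape != shape:
            raise ValueError("all matrices must have the same shape")
    data = np.stack([m.values.reshape(-1) for m in matrices])  # row-major
    return covariance_pca(data, [m.specimen_id for m in matrices], exclude)


def colormap_at_pc_extreme(
    result: PCAResult,
    component: int,
    score: float,
    template: ThicknessMatrix,
) -> ThicknessMatrix:
    """Rct map reconstructed at a PC score (mean + score × loading).

    Values are NOT clamped; entries falling outside (0, 1) are counted in
    ``out_of_range`` and reported with a warning.
    """
    if not 0 <= component < len(result.loadings):
        raise IndexError(f"component {component} out of range")
    vec = result.mean_vector + score * result.loadings[component]
    values = vec.reshape(template.values.shape)
    n_bad = int(np.sum((values <= 0) | (values >= 1)))
    if n_bad:
        warnings.warn(
            f"{n_bad} reconstructed Rct values fall outside (0, 1)", stacklevel=2
        )
    return ThicknessMatrix(
        specimen_id=f"PC{component + 1}@{score:+.4g}",
        fractions=template.fractions,
        angles=template.angles,
        values=values,
        out_of_range=n_bad,
    )


def matrix_to_csv(matrix: ThicknessMatrix, path: str) -> None:
    matrix.to_dataframe().to_csv(path, index_label="fraction")


def matrices_to_long_csv(matrices: Sequence[ThicknessMatrix], path: str) -> None:
    """Stacked long-format export (specimen, fraction, station, angle, Rct)."""
    rows = []
    for m in matrices:
        for i, f in enumerate(m.fractions):
            for j, a in enumerate(m.angles):
                rows.append((m.specimen_id, round(float(f), 4), m.column_labels[j], a, m.values[i, j]))
    pd.DataFrame(
        rows, columns=["specimen_id", "fraction", "station", "angle_rad", "rct"]
    ).to_csv(path, index=False)
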