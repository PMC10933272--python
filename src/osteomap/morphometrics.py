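"""Landmark datasets, generalized Procrustes analysis and shape PCA.

Three datasets describe a metatarsal: (1) the diaphysis as 21 cross sections
between 50% and 70% of biomechanical length with 21 paired equiangular
semilandmarks on the external and internal cortical outlines (882 points);
(2) the proximal epiphysis as 3 articular-facet vertices plus 21 external
semilandmarks at 80% (24 points); (3) the distal epiphysis as 6 named
type-II landmarks plus 15 articular-surface semilandmarks (21 points).

GPA removes position, orientation and size (unit centroid size); the
equiangular semilandmarks are geometrically, not surface-, defined and are
therefore not slid.  Shape variation is summarized by covariance PCA of the
aligned coordinates, with landmark-space reconstructions at chosen PC
scores and a permutation test for allometry (shape score vs. log centroid
size).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .orientation import BiomechanicalFrame
from .sectioning import equiangular_semilandmarks, outline_contour_at_80, section_series
from .volume import LabeledVolume

DATASET_SIZES = {"diaphysis": 882, "proximal": 24, "distal": 21}

DISTAL_LANDMARK_NAMES = (
    "medial_epicondyle",
    "medial_plantar_condyle",
    "dorsal_surface_point",
    "distal_head_point",
    "lateral_epicondyle",
    "lateral_plantar_condyle",
)

_MIRROR_SWAP = {
    "medial_epicondyle": "lateral_epicondyle",
    "medial_plantar_condyle": "lateral_plantar_condyle",
    "lateral_epicondyle": "medial_epicondyle",
    "lateral_plantar_condyle": "medial_plantar_condyle",
}


@dataclass
class LandmarkConfiguration:
    specimen_id: str
    dataset: str  # 'diaphysis' | 'proximal' | 'distal'
    points: np.ndarray  # (n, 3) mm, fixed per-dataset ordering
    point_roles: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, float).reshape(-1, 3)
        if self.dataset not in DATASET_SIZES:
            raise ValueError(f"unknown dataset {self.dataset!r}")
        n = len(self.points)
        # standard templates are 882 / 24 / 21 points; non-default section
        # ranges or ray counts still have to respect the dataset structure
        if self.dataset == "diaphysis" and (n == 0 or n % 2 != 0):
            raise ValueError(f"diaphysis dataset needs paired outline points, got {n}")
        if self.dataset == "distal" and n != DATASET_SIZES["distal"]:
            raise ValueError(f"distal dataset needs 21 points, got {n}")
        if self.dataset == "proximal" and n < 6:
            raise ValueError(f"proximal dataset needs 3 vertices + semilandmarks, got {n}")
        if not self.point_roles:
            self.point_roles = ["semilandmark"] * len(self.points)
        if len(self.point_roles) != len(self.points):
            raise ValueError("point_roles length mismatch")

    @property
    def centroid_size(self) -> float:
        c = self.points - self.points.mean(axis=0)
        return float(np.sqrt(np.sum(c**2)))


@dataclass
class ProcrustesResult:
    aligned: np.ndarray  # (n_specimens, n_points, 3), unit centroid size
    mean_shape: np.ndarray  # (n_points, 3)
    centroid_sizes: np.ndarray  # (n_specimens,)
    specimen_ids: list[str]
    dataset: str
    iterations: int


@dataclass
class PCAResult:
    scores: np.ndarray  # (n, n_components)
    loadings: np.ndarray  # (n_components, n_features), orthonormal rows
    eigenvalues: np.ndarray
    percent_variance: np.ndarray
    mean_vector: np.ndarray
    specimen_ids: list[str]


# -- dataset builders ------------------------------------------------------


def build_diaphysis_dataset(
    volume: LabeledVolume,
    frame: BiomechanicalFrame,
    from_fraction: float = 0.50,
    to_fraction: float = 0.70,
    step: float = 0.01,
    k: int = 21,
    specimen_id: str = "specimen",
) -> LandmarkConfiguration:
    """Diaphyseal dataset: sections × k external + k internal semilandmarks.

    Ordering is section-major (ascending fraction); within a section the k
    external points come first, then the k internal points, each in angular
    order from lateral.  Points are in biomechanical-frame coordinates
    (x, y, fraction × length).
    """
    sections = section_series(volume, frame, from_fraction, to_fraction, step)
    pts = []
    L = frame.biomechanical_length_mm
    for sec in sections:
        slm = equiangular_semilandmarks(sec, k=k)
        if slm.internal_points is None:
            raise ValueError(f"no internal outline at fraction {sec.fraction:.3f}")
        z = sec.fraction * L
        pts.append(np.column_stack([slm.external_points, np.full(k, z)]))
        pts.append(np.column_stack([slm.internal_points, np.full(k, z)]))
    points = np.vstack(pts)
    return LandmarkConfiguration(specimen_id, "diaphysis", points)


def build_proximal_dataset(
    volume: LabeledVolume,
    frame: BiomechanicalFrame,
    articular_vertices: np.ndarray,
    k: int = 21,
    specimen_id: str = "specimen",
) -> LandmarkConfiguration:
    """Proximal dataset: 3 facet vertices + k external semilandmarks at 80%.

    The vertex order is semantic — (dorsal, plantar-medial, plantar-lateral)
    — and is verified in frame coordinates (dorsal = smallest y; medial =
    smallest x; lateral = largest x).
    """
    v = np.asarray(articular_vertices, float).reshape(3, 3)
    vf = frame.world_to_frame(v)
    if not (np.argmin(vf[:, 1]) == 0 and np.argmin(vf[:, 0]) == 1 and np.argmax(vf[:, 0]) == 2):
        raise ValueError(
            "articular vertices out of order: expected (dorsal, plantar-medial, "
            "plantar-lateral)"
        )
    _, slm = outline_contour_at_80(volume, frame, k=k)
    z80 = 0.80 * frame.biomechanical_length_mm
    ring = np.column_stack([slm.external_points, np.full(k, z80)])
    points = np.vstack([vf, ring])
    roles = ["landmark"] * 3 + ["semilandmark"] * k
    return LandmarkConfiguration(specimen_id, "proximal", points, roles)


def build_distal_dataset(
    landmarks: Mapping[str, np.ndarray],
    surface_semilandmarks: np.ndarray,
    specimen_id: str = "specimen",
) -> LandmarkConfiguration:
    """Distal dataset: 6 named type-II landmarks + 15 surface semilandmarks."""
    missing = [n for n in DISTAL_LANDMARK_NAMES if n not in landmarks]
    if missing:
        raise ValueError(f"missing distal landmarks: {missing}")
    slm = np.asarray(surface_semilandmarks, float).reshape(-1, 3)
    if len(slm) != 15:
        raise ValueError(f"need 15 surface semilandmarks, got {len(slm)}")
    named = np.array([np.asarray(landmarks[n], float) for n in DISTAL_LANDMARK_NAMES])
    points = np.vstack([named, slm])
    uniq = np.unique(np.round(points, 9), axis=0)
    if len(uniq) < len(points):
        raise ValueError("duplicate points in distal configuration")
    roles = ["landmark"] * 6 + ["semilandmark"] * 15
    return LandmarkConfiguration(specimen_id, "distal", points, roles)


def mirror_distal_landmarks(
    landmarks: Mapping[str, np.ndarray],
) -> dict[str, np.ndarray]:
    """Mirror a distal landmark set across the mediolateral plane (x -> -x),
    swapping medial/lateral roles so names stay anatomically correct."""
    out = {}
    for name, p in landmarks.items():
        q = np.asarray(p, float).copy()
        q[0] = -q[0]
        out[_MIRROR_SWAP.get(name, name)] = q
    return out


# -- generalized Procrustes analysis ---------------------------------------


def _canonical_axes(shape: np.ndarray) -> np.ndarray:
    """Rotation (det +1) taking a configuration onto its principal axes,
    with each axis sign-fixed by its largest-magnitude coordinate."""
    _, _, vt = np.linalg.svd(shape - shape.mean(axis=0), full_matrices=False)
    V = vt.T
    for j in range(V.shape[1]):
        if V[np.argmax(np.abs(V[:, j])), j] < 0:
            V[:, j] = -V[:, j]
    if np.linalg.det(V) < 0:
        V[:, -1] = -V[:, -1]
    return V


def _optimal_rotation(source: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Rotation R (det +1, no reflection) minimizing ||source @ R - target||."""
    u, _, vt = np.linalg.svd(source.T @ target)
    d = np.sign(np.linalg.det(u @ vt))
    return u @ np.diag([1.0, 1.0, d]) @ vt


def procrustes_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Frobenius distance between two aligned unit-size configurations."""
    return float(np.linalg.norm(a - b))


def gpa(
    configs: Sequence[LandmarkConfiguration],
    tol: float = 1e-10,
    max_iter: int = 200,
) -> ProcrustesResult:
    """Generalized Procrustes superimposition (translate, rotate, scale).

    Configurations are centred, scaled to unit centroid size and iteratively
    rotated to the evolving mean shape until the mean changes by less than
    ``tol``.  Reflections are not allowed and semilandmarks are not slid.
    """
    if len(configs) < 2:
        raise ValueError("need at least 2 configurations")
    dataset = configs[0].dataset
    n_points = len(configs[0].points)
    if any(c.dataset != dataset or len(c.points) != n_points for c in configs):
        raise ValueError("all configurations must come from the same dataset template")

    X = np.stack([c.points for c in configs]).astype(float)
    X -= X.mean(axis=1, keepdims=True)
    sizes = np.sqrt((X**2).sum(axis=(1, 2)))
    if np.any(sizes <= 0):
        raise ValueError("degenerate configuration with zero centroid size")
    X /= sizes[:, None, None]

    mean = X[0].copy()
    iterations = 0
    for iterations in range(1, max_iter + 1):
        for i in range(len(X)):
            X[i] = X[i] @ _optimal_rotation(X[i], mean)
        new_mean = X.mean(axis=0)
        new_mean -= new_mean.mean(axis=0)
        new_mean /= np.linalg.norm(new_mean)
        if np.linalg.norm(new_mean - mean) < tol:
            mean = new_mean
            break
        mean = new_mean

    # canonical orientation: principal axes of the mean shape, deterministic
    # signs — makes the result independent of the input ordering
    Rc = _canonical_axes(mean)
    mean = mean @ Rc
    X = X @ Rc
    return ProcrustesResult(
        aligned=X,
        mean_shape=mean,
        centroid_sizes=sizes,
        specimen_ids=[c.specimen_id for c in configs],
        dataset=dataset,
        iterations=iterations,
    )


# -- covariance PCA --------------------------------------------------------


def covariance_pca(
    data: np.ndarray, specimen_ids: Sequence[str], exclude: Iterable[str] = ()
) -> PCAResult:
    """Covariance PCA of row-wise observations with deterministic signs.

    Each component's sign is fixed so that its largest-magnitude loading is
    positive.  ``percent_variance`` sums to 100 over nonzero components.
    """
    exclude = set(exclude)
    unknown = exclude - set(specimen_ids)
    if unknown:
        raise ValueError(f"cannot exclude unknown specimens: {sorted(unknown)}")
    keep = [i for i, sid in enumerate(specimen_ids) if sid not in exclude]
    if len(keep) < 3:
        raise ValueError("need at least 3 retained specimens for PCA")
    ids = [specimen_ids[i] for i in keep]
    data = np.asarray(data, float)[keep]

    mean_vector = data.mean(axis=0)
    centered = data - mean_vector
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    n = len(keep)
    eigenvalues = s**2 / (n - 1)
    nonzero = eigenvalues > max(eigenvalues.max(), 1e-300) * 1e-12
    rank = int(nonzero.sum())
    loadings = vt[:rank]
    scores = u[:, :rank] * s[:rank]
    for j in range(rank):  # deterministic sign
        pivot = np.argmax(np.abs(loadings[j]))
        if loadings[j, pivot] < 0:
            loadings[j] = -loadings[j]
            scores[:, j] = -scores[:, j]
    eigenvalues = eigenvalues[:rank]
    percent = 100.0 * eigenvalues / eigenvalues.sum() if rank else eigenvalues
    return PCAResult(
        scores=scores,
        loadings=loadings,
        eigenvalues=eigenvalues,
        percent_variance=percent,
        mean_vector=mean_vector,
        specimen_ids=ids,
    )


def pca(aligned: ProcrustesResult, exclude: Iterable[str] = ()) -> PCAResult:
    """Shape PCA on flattened Procrustes-aligned coordinates."""
    n = aligned.aligned.shape[0]
    return covariance_pca(aligned.aligned.reshape(n, -1), aligned.specimen_ids, exclude)


def shape_at_pc_extreme(result: PCAResult, component: int, score: float) -> np.ndarray:
    """Landmark configuration reconstructed at a given PC score, (n, 3)."""
    if not 0 <= component < len(result.loadings):
        raise IndexError(f"component {component} out of range")
    vec = result.mean_vector + score * result.loadings[component]
    return vec.reshape(-1, 3)


# -- allometry -------------------------------------------------------------


def allometry_test(
    result: PCAResult,
    centroid_sizes: np.ndarray,
    component: int = 0,
    n_permutations: int = 10_000,
    seed: int = 0,
) -> tuple[float, float, float]:
    """Permutation test of allometry: PC score regressed on log centroid size.

    Returns (slope, R², p) where p is the proportion of permutations of the
    scores whose R² reaches the observed one (add-one estimator).
    """
    sizes = np.asarray(centroid_sizes, float)
    if np.any(sizes <= 0):
        raise ValueError("centroid sizes must be positive")
    if np.ptp(sizes) == 0:
        raise ValueError("centroid sizes are constant; allometry is undefined")
    scores = result.scores[:, component]
    if len(scores) != len(sizes):
        raise ValueError("one centroid size per retained specimen is required")
    x = np.log(sizes)
    fit = stats.linregress(x, scores)
    r2_obs = fit.rvalue**2

    rng = np.random.default_rng(seed)
    xc = x - x.mean()
    perm = rng.permuted(np.tile(scores, (n_permutations, 1)), axis=1)
    pc = perm - perm.mean(axis=1, keepdims=True)
    num = pc @ xc
    r2_perm = num**2 / (np.sum(xc**2) * np.sum(pc**2, axis=1))
    p = (1 + int(np.sum(r2_perm >= r2_obs - 1e-15))) / (n_permutations + 1)
    return float(fit.slope), float(r2_obs), float(p)
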