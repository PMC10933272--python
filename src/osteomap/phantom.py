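"""Synthetic metatarsal-like bone phantoms with known ground truth.

A phantom is a curved tube: a planar circular-arc centerline (deflection in
the dorsoplantar plane), an annular cortical cross-section whose outer
radius and cortical thickness vary with axial fraction ``s`` and polar angle
``theta`` (theta = 0 lateral, pi/2 plantar), radially expanded "epiphyses"
blended over the terminal 15% of the length, and solid (cavity-free) ends.
Optionally a localized periosteal thickening ("callus") can be added in the
shaft.  Every phantom carries a :class:`GroundTruth` record (generating
frame, length, sampled thickness field) so downstream measurements can be
checked against what was asked for.

Profiles are either scalars (mm) or callables ``f(s, theta) -> mm`` that
broadcast over numpy arrays.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np

from .orientation import AnatomicalPoints, BiomechanicalFrame
from .volume import CAVITY, CORTICAL, LabeledVolume

Profile = float | Callable[[np.ndarray, np.ndarray], np.ndarray]

EPIPHYSIS_BLEND_FRACTION = 0.15  # terminal fraction over which the ends flare
SOLID_END_FRACTION = 0.08  # terminal fraction over which the cavity closes

_TRUTH_FRACTIONS = np.round(np.arange(0.20, 0.8001, 0.01), 4)
_TRUTH_ANGLES = 2 * np.pi * np.arange(84) / 84


class PhantomError(ValueError):
    """Invalid phantom specification."""


def as_profile(p: Profile) -> Callable[[np.ndarray, np.ndarray], np.ndarray]:
    if callable(p):
        return p
    v = float(p)

    def constant(s, theta):
        return np.full(np.broadcast_shapes(np.shape(s), np.shape(theta)), v)

    return constant


@dataclass
class BonePhantomSpec:
    """Parameters of one synthetic bone.

    Defaults describe a generic adult second metatarsal: ~65 mm long, ~5 mm
    outer midshaft radius with a ~2 mm cortex, a 2 mm dorsoplantar shaft
    deflection, and moderately flared articular ends.
    """

    length_mm: float = 65.0
    shaft_curvature_mm: float = 2.0  # max dorsoplantar centerline deflection
    outer_radius_profile: Profile = 5.0
    cortical_thickness_profile: Profile = 2.0
    epiphysis_scale: float = 1.4
    voxel_spacing_mm: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        if self.length_mm <= 0 or self.voxel_spacing_mm <= 0:
            raise PhantomError("length and spacing must be positive")
        if self.length_mm / self.voxel_spacing_mm < 100:
            raise PhantomError(
                f"spacing {self.voxel_spacing_mm} mm too coarse for length "
                f"{self.length_mm} mm: need length/spacing >= 100 for 1% sectioning"
            )
        if self.epiphysis_scale <= 0:
            raise PhantomError("epiphysis_scale must be positive")
        if self.shaft_curvature_mm < 0:
            raise PhantomError("shaft_curvature_mm must be non-negative")
        s = np.linspace(0.05, 0.95, 37)[:, None]
        th = np.linspace(0, 2 * np.pi, 73)[None, :]
        R = np.asarray(as_profile(self.outer_radius_profile)(s, th), float)
        t = np.asarray(as_profile(self.cortical_thickness_profile)(s, th), float)
        if np.any(R <= 0):
            raise PhantomError("outer radius profile must be positive everywhere")
        if np.any(t >= R):
            raise PhantomError(
                "cortical thickness must be smaller than the outer radius "
                "everywhere (the medullary cavity must exist)"
            )
        if np.any(t < 2 * self.voxel_spacing_mm):
            raise PhantomError(
                f"spacing {self.voxel_spacing_mm} mm too coarse: the cortex must "
                "span at least 2 voxels everywhere"
            )


@dataclass
class CallusParams:
    center_fraction: float
    axial_extent: float
    magnitude_mm: float

    def delta(self, s: np.ndarray) -> np.ndarray:
        """Cosine-tapered outer-radius increment, mm; 0 outside the window."""
        u = np.abs(np.asarray(s, float) - self.center_fraction)
        half = self.axial_extent / 2.0
        out = np.where(
            u <= half, self.magnitude_mm * 0.5 * (1 + np.cos(np.pi * u / half)), 0.0
        )
        return out


@dataclass
class GroundTruth:
    """What the generator actually built, for oracle tests downstream."""

    frame: BiomechanicalFrame
    biomechanical_length_mm: float
    thickness_fractions: np.ndarray  # (61,), 0.20 … 0.80
    thickness_angles: np.ndarray  # (84,), radians from lateral
    thickness_field_mm: np.ndarray  # (61, 84) cortical thickness
    group_label: str = "default"
    spec: BonePhantomSpec | None = None
    callus: CallusParams | None = None

    def to_json(self) -> str:
        d = {
            "frame": json.loads(self.frame.to_json()),
            "biomechanical_length_mm": self.biomechanical_length_mm,
            "thickness_fractions": self.thickness_fractions.tolist(),
            "thickness_angles": self.thickness_angles.tolist(),
            "thickness_field_mm": self.thickness_field_mm.tolist(),
            "group_label": self.group_label,
        }
        if self.callus is not None:
            d["callus"] = vars(self.callus)
        if self.spec is not None:
            d["spec"] = {
                k: v
                for k, v in vars(self.spec).items()
                if not callable(v)
            }
        return json.dumps(d)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        callus = CallusParams(**d["callus"]) if "callus" in d else None
        return cls(
            frame=BiomechanicalFrame.from_json(json.dumps(d["frame"])),
            biomechanical_length_mm=d["biomechanical_length_mm"],
            thickness_fractions=np.array(d["thickness_fractions"]),
            thickness_angles=np.array(d["thickness_angles"]),
            thickness_field_mm=np.array(d["thickness_field_mm"]),
            group_label=d.get("group_label", "default"),
            callus=callus,
        )


# -- geometry fields -------------------------------------------------------


def centerline_offset_mm(spec: BonePhantomSpec, s: np.ndarray) -> np.ndarray:
    """Dorsoplantar (+y) centerline deflection at axial fraction s.

    Planar circular arc through both ends with maximal deflection
    ``shaft_curvature_mm`` at midshaft.
    """
    s = np.asarray(s, float)
    d = spec.shaft_curvature_mm
    if d == 0:
        return np.zeros_like(s)
    L = spec.length_mm
    Rc = ((L / 2) ** 2 + d**2) / (2 * d)
    z = s * L
    return np.sqrt(Rc**2 - (z - L / 2) ** 2) - (Rc - d)


def _end_blend(s: np.ndarray, width: float = EPIPHYSIS_BLEND_FRACTION) -> np.ndarray:
    """Cosine weight: 1 at either bone end, 0 within the shaft."""
    s = np.asarray(s, float)
    w = np.zeros_like(s)
    m = s < width
    w[m] = 0.5 * (1 + np.cos(np.pi * s[m] / width))
    m = s > 1 - width
    w[m] = 0.5 * (1 + np.cos(np.pi * (1 - s[m]) / width))
    return w


def epiphysis_factor(spec: BonePhantomSpec, s: np.ndarray) -> np.ndarray:
    return 1.0 + (spec.epiphysis_scale - 1.0) * _end_blend(s)


def _cavity_factor(s: np.ndarray, width: float = SOLID_END_FRACTION) -> np.ndarray:
    """Smoothstep closing the medullary cavity at the terminal ends.

    Exactly zero over the terminal quarter of the closure window so the end
    sections are genuinely solid (no residual one-voxel cavity core).
    """
    s = np.asarray(s, float)
    u = np.clip((np.minimum(s, 1 - s) / width - 0.25) / 0.75, 0.0, 1.0)
    return u * u * (3 - 2 * u)


def _rasterize(spec: BonePhantomSpec, callus: CallusParams | None) -> LabeledVolume:
    sp = spec.voxel_spacing_mm
    L = spec.length_mm
    Rprof = as_profile(spec.outer_radius_profile)
    tprof = as_profile(spec.cortical_thickness_profile)

    # transverse extent from a dense profile sample (plus callus and margin)
    s_smp = np.linspace(0, 1, 101)[:, None]
    th_smp = np.linspace(0, 2 * np.pi, 73)[None, :]
    Rmax = float(np.max(np.asarray(Rprof(s_smp, th_smp)) * epiphysis_factor(spec, s_smp)))
    if callus is not None:
        Rmax += callus.magnitude_mm
    ext_x = Rmax + 2 * sp
    ext_y = Rmax + spec.shaft_curvature_mm + 2 * sp

    nhx = int(np.ceil(ext_x / sp))
    nhy = int(np.ceil(ext_y / sp))
    nx, ny = 2 * nhx + 1, 2 * nhy + 1  # odd counts keep the grid mirror-symmetric
    nz = int(round(L / sp)) + 1
    origin = np.array([-nhx * sp, -nhy * sp, 0.0])

    # integer-offset coordinates: voxels shared between differently sized
    # grids get bitwise-identical positions (stable boundary classification)
    xs = ((np.arange(nx) - nhx) * sp)[:, None, None]
    ys = ((np.arange(ny) - nhy) * sp)[None, :, None]
    labels = np.zeros((nx, ny, nz), dtype=np.uint8)

    block = max(1, int(4e6 // (nx * ny)))  # chunk z to bound temporaries
    for k0 in range(0, nz, block):
        k1 = min(nz, k0 + block)
        zs = (np.arange(k0, k1) * sp)[None, None, :]
        s = zs / L
        yc = centerline_offset_mm(spec, s)
        dy = ys - yc
        rho = np.sqrt(xs**2 + dy**2)
        theta = np.arctan2(dy, np.broadcast_to(xs, rho.shape))
        E = epiphysis_factor(spec, s)
        Rout = np.asarray(Rprof(s, theta), float) * E
        t = np.asarray(tprof(s, theta), float)
        Rin = np.maximum(Rout - t, 0.0) * _cavity_factor(s)
        if callus is not None:
            Rout = Rout + callus.delta(s)
        blk = np.zeros(rho.shape, dtype=np.uint8)
        blk[rho <= Rout] = CORTICAL
        blk[(Rin > 0) & (rho <= Rin)] = CAVITY
        labels[:, :, k0:k1] = blk

    return LabeledVolume(labels, spacing_mm=sp, origin_mm=origin)


def _ground_truth(
    spec: BonePhantomSpec, callus: CallusParams | None, group_label: str
) -> GroundTruth:
    frame = BiomechanicalFrame(
        origin=np.zeros(3),
        x_axis=[1, 0, 0], y_axis=[0, 1, 0], z_axis=[0, 0, 1],
        biomechanical_length_mm=spec.length_mm,
        distal_extreme_mm=np.zeros(3),
    )
    s = _TRUTH_FRACTIONS[:, None]
    th = _TRUTH_ANGLES[None, :]
    t = np.broadcast_to(
        np.asarray(as_profile(spec.cortical_thickness_profile)(s, th), float),
        (len(_TRUTH_FRACTIONS), len(_TRUTH_ANGLES)),
    ).copy()
    if callus is not None:
        t = t + callus.delta(s)  # periosteal apposition thickens the cortex
    return GroundTruth(
        frame=frame,
        biomechanical_length_mm=spec.length_mm,
        thickness_fractions=_TRUTH_FRACTIONS.copy(),
        thickness_angles=_TRUTH_ANGLES.copy(),
        thickness_field_mm=t,
        group_label=group_label,
        spec=spec,
        callus=callus,
    )


def generate_bone(
    spec: BonePhantomSpec, group_label: str = "default"
) -> tuple[LabeledVolume, GroundTruth]:
    """Rasterize one phantom and record its ground truth.

    The volume has exactly the three labels background/cortical/cavity and an
    annular cortex throughout the shaft; the canonical pose puts the distal
    end at z = 0 and the shaft axis along +z, so the generating frame is the
    identity.
    """
    spec.validate()
    return _rasterize(spec, None), _ground_truth(spec, None, group_label)


def add_callus(
    volume: LabeledVolume,
    truth: GroundTruth,
    center_fraction: float,
    axial_extent: float,
    magnitude_mm: float,
) -> tuple[LabeledVolume, GroundTruth]:
    """Add a smooth periosteal thickening (healing-callus model) to a phantom.

    The outer radius is raised by up to ``magnitude_mm`` with a cosine taper
    over the axial window ``center_fraction ± axial_extent/2``; the medullary
    cavity is untouched (periosteal, not endosteal, reaction).  The phantom
    is re-rasterized from its generating spec so the perturbation is exact.
    """
    if truth.spec is None:
        raise PhantomError("ground truth does not carry its generating spec")
    if magnitude_mm < 0:
        raise PhantomError("callus magnitude must be non-negative")
    lo = center_fraction - axial_extent / 2
    hi = center_fraction + axial_extent / 2
    if not (0.0 < lo and hi < 1.0):
        raise PhantomError("callus window must lie strictly inside (0, 1)")
    if lo < EPIPHYSIS_BLEND_FRACTION or hi > 1 - EPIPHYSIS_BLEND_FRACTION:
        raise PhantomError(
            f"callus window [{lo:.3f}, {hi:.3f}] overlaps an epiphysis "
            f"(terminal {EPIPHYSIS_BLEND_FRACTION:.0%} at each end)"
        )
    if magnitude_mm == 0:
        return volume, truth
    callus = CallusParams(center_fraction, axial_extent, magnitude_mm)
    return _rasterize(truth.spec, callus), _ground_truth(truth.spec, callus, truth.group_label)


# -- anatomical reference points ------------------------------------------


def anatomical_points(spec: BonePhantomSpec) -> AnatomicalPoints:
    """Reference points of a phantom in its canonical pose.

    The dorsal patch is an exactly planar quad on the dorsal tangent plane of
    the distal epiphysis (normal −y in canonical pose), which makes the
    recovered frame the identity for an unrotated phantom.
    """
    L = spec.length_mm
    ss = np.linspace(0, 0.1, 21)
    r_d = np.asarray(as_profile(spec.outer_radius_profile)(ss, np.full_like(ss, -np.pi / 2)))
    y0 = float(np.min(centerline_offset_mm(spec, ss) - r_d * epiphysis_factor(spec, ss)))
    a = 0.4 * float(np.median(r_d))
    patch = np.array(
        [[-a, y0, 0.02 * L], [a, y0, 0.02 * L], [-a, y0, 0.08 * L], [a, y0, 0.08 * L]]
    )
    return AnatomicalPoints(
        distal_articular_center=[0.0, 0.0, 0.0],
        proximal_articular_center=[0.0, 0.0, L],
        most_distal_articular_point=[0.0, 0.0, 0.0],
        dorsal_surface_patch=patch,
    )


def _surface_point(spec: BonePhantomSpec, s: float, theta: float) -> np.ndarray:
    r = float(as_profile(spec.outer_radius_profile)(np.asarray(s), np.asarray(theta)))
    r *= float(epiphysis_factor(spec, np.asarray(s)))
    yc = float(centerline_offset_mm(spec, np.asarray(s)))
    return np.array([r * np.cos(theta), yc + r * np.sin(theta), s * spec.length_mm])


def proximal_facet_vertices(spec: BonePhantomSpec) -> np.ndarray:
    """Three ordered vertices of a synthetic proximal articular facet.

    Order is semantic: (dorsal, plantar-medial, plantar-lateral).
    """
    s = 0.97
    return np.array(
        [
            _surface_point(spec, s, -np.pi / 2),  # dorsal
            _surface_point(spec, s, 3 * np.pi / 4),  # plantar-medial
            _surface_point(spec, s, np.pi / 4),  # plantar-lateral
        ]
    )


def distal_landmarks(spec: BonePhantomSpec) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Synthetic distal-epiphysis template: 6 named landmarks + 15 ring
    semilandmarks evenly spaced on the articular surface."""
    s_lm = 0.05
    named = {
        "medial_epicondyle": _surface_point(spec, s_lm, np.pi),
        "medial_plantar_condyle": _surface_point(spec, s_lm, np.pi / 2 + 0.35),
        "dorsal_surface_point": _surface_point(spec, s_lm, -np.pi / 2),
        "distal_head_point": np.array([0.0, float(centerline_offset_mm(spec, np.asarray(0.0))), 0.0]),
        "lateral_epicondyle": _surface_point(spec, s_lm, 0.0),
        "lateral_plantar_condyle": _surface_point(spec, s_lm, np.pi / 2 - 0.35),
    }
    ring = np.array(
        [_surface_point(spec, 0.03, 2 * np.pi * i / 15) for i in range(15)]
    )
    return named, ring


# -- populations -----------------------------------------------------------


class _FourierNoiseProfile:
    """Base profile + smooth random field: low-order Fourier series in angle
    times a quadratic polynomial in axial fraction, scaled to a target RMS."""

    def __init__(self, base: Profile, offset: float, coeffs: np.ndarray, rms: float):
        self._base = as_profile(base)
        self._offset = float(offset)
        self._coeffs = np.asarray(coeffs, float)  # (n_harm, 2, 3)
        if rms > 0 and self._coeffs.size:
            raw = self._field(
                np.linspace(0.2, 0.8, 31)[:, None], np.linspace(0, 2 * np.pi, 63)[None, :]
            )
            scale = np.sqrt(np.mean(raw**2))
            self._coeffs = self._coeffs * (rms / scale if scale > 0 else 0.0)

    def _field(self, s, theta):
        s = np.asarray(s, float)
        theta = np.asarray(theta, float)
        out = np.zeros(np.broadcast_shapes(s.shape, theta.shape))
        axial = np.stack([np.ones_like(s), s - 0.5, (s - 0.5) ** 2])
        for m in range(self._coeffs.shape[0]):
            trig = np.stack([np.cos(m * theta), np.sin(m * theta)])
            for p in range(2):
                for j in range(3):
                    out = out + self._coeffs[m, p, j] * trig[p] * axial[j]
        return out

    def __call__(self, s, theta):
        return np.asarray(self._base(s, theta), float) + self._offset + self._field(s, theta)


def generate_population(
    n: int,
    group_effects: Mapping[str, Mapping[str, float]],
    noise_sd: float,
    seed: int,
    base_spec: BonePhantomSpec | None = None,
) -> list[tuple[LabeledVolume, GroundTruth]]:
    """Simulate ``n`` specimens per group.

    ``group_effects`` maps a group label to a perturbation of the base spec:
    keys ``thickness_delta_mm`` and/or ``radius_delta_mm`` shift the group
    mean cortical-thickness / outer-radius profiles.  Each specimen adds an
    independent smooth noise field of RMS amplitude ``noise_sd`` (mm) to its
    thickness profile.  Fully reproducible for a fixed seed.
    """
    if n < 2:
        raise PhantomError("need at least 2 specimens per group")
    if not group_effects:
        raise PhantomError("need at least one group")
    if noise_sd < 0:
        raise PhantomError("noise_sd must be non-negative")
    base = base_spec or BonePhantomSpec(
        length_mm=60.0, shaft_curvature_mm=2.0, outer_radius_profile=5.0,
        cortical_thickness_profile=2.0, epiphysis_scale=1.4, voxel_spacing_mm=0.3,
    )
    out: list[tuple[LabeledVolume, GroundTruth]] = []
    for gi, (group, effect) in enumerate(sorted(group_effects.items())):
        dt = float(effect.get("thickness_delta_mm", 0.0))
        dr = float(effect.get("radius_delta_mm", 0.0))
        for i in range(n):
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=int(seed) % 2**31, spawn_key=(gi, i))
            )
            if noise_sd > 0:
                coeffs_t = rng.standard_normal((3, 2, 3))
                coeffs_r = rng.standard_normal((3, 2, 3))
            else:
                coeffs_t = coeffs_r = np.zeros((3, 2, 3))
            # both profiles receive independent smooth noise: real specimens
            # vary in external shape as much as in cortical thickness
            spec_i = replace(
                base,
                cortical_thickness_profile=_FourierNoiseProfile(
                    base.cortical_thickness_profile, dt, coeffs_t, noise_sd
                ),
                outer_radius_profile=_FourierNoiseProfile(
                    base.outer_radius_profile, dr, coeffs_r, noise_sd
                ),
                seed=int(rng.integers(2**31)),
            )
            vol, truth = generate_bone(spec_i, group_label=group)
            out.append((vol, truth))
    return out
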