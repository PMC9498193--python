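"""Synthetic knee-like MRI phantoms with exact ground-truth labels.

The phantom emulates the characteristics of sagittal knee MRI stacks used
for bone-template extraction: anisotropic grids (1 mm slice distance, 0.4 mm
in-plane), a bright cortical rim around a darker marrow interior, diffuse
boundaries (Gaussian blur in mm), additive noise, and per-scanner intensity
gain.  Bones are built from superellipsoids and cylinders so that solid
volumes have closed forms, giving analytic oracles for meshing and metric
tests.  Cartilage labels are thin shells included only so downstream
"discard cartilage" handling is exercised; no attempt is made at anatomical
fidelity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import gamma

import numpy as np
from scipy import ndimage

from .io import DEFAULT_LABEL_CODES, ImageVolume, LabelVolume, ProbabilityVolume

__all__ = [
    "Superellipsoid",
    "Cylinder",
    "PhantomSpec",
    "NOISE_SD_HARD",
    "default_bones",
    "generate_phantom",
    "generate_cohort",
    "make_biased_probability",
]

#: Noise level (scanner units) of the phantom's "hard" condition: the
#: background/marrow intensity gap is then only 2.5 standard deviations,
#: emulating low-quality acquisitions with poor bone/soft-tissue contrast.
NOISE_SD_HARD = 16.0


@dataclass
class Superellipsoid:
    """Solid ``|x/a|^p + |y/b|^p + |z/c|^p <= 1`` in world (mm) coordinates.

    ``p = 2`` is an ellipsoid; larger ``p`` gives boxier shapes resembling
    condyles and plateaus.  The solid volume has the closed form
    ``8 a b c Γ(1+1/p)^3 / Γ(1+3/p)``.
    """

    center_mm: tuple
    half_axes_mm: tuple
    exponent: float = 2.0

    def contains(self, coords: np.ndarray) -> np.ndarray:
        c = np.asarray(self.center_mm, dtype=float)
        a = np.asarray(self.half_axes_mm, dtype=float)
        if np.any(a <= 0):
            raise ValueError("half axes must be positive")
        u = np.abs((coords - c) / a) ** self.exponent
        return u.sum(axis=-1) <= 1.0

    def volume_mm3(self) -> float:
        a, b, c = self.half_axes_mm
        p = self.exponent
        return 8.0 * a * b * c * gamma(1 + 1 / p) ** 3 / gamma(1 + 3 / p)


@dataclass
class Cylinder:
    """Solid circular cylinder with axis along one grid axis, in mm."""

    center_mm: tuple
    radius_mm: float
    half_length_mm: float
    axis: int = 1  # default: along the row (superior-inferior) axis

    def contains(self, coords: np.ndarray) -> np.ndarray:
        c = np.asarray(self.center_mm, dtype=float)
        d = coords - c
        along = np.abs(d[..., self.axis]) <= self.half_length_mm
        perp_axes = [i for i in range(3) if i != self.axis]
        r2 = d[..., perp_axes[0]] ** 2 + d[..., perp_axes[1]] ** 2
        return along & (r2 <= self.radius_mm**2)

    def volume_mm3(self) -> float:
        return float(np.pi * self.radius_mm**2 * 2 * self.half_length_mm)


def default_bones(extent_mm: np.ndarray) -> dict:
    """Default bone/cartilage layout scaled to the grid's physical extent.

    Axis 0 is the slice (medio-lateral) axis; axis 1 runs superior to
    inferior (femur above, tibia below); axis 2 is anterior-posterior with
    the patella anterior to the femoral condyle.
    """
    E = np.asarray(extent_mm, dtype=float)
    return {
        "femur": [
            Superellipsoid(
                center_mm=(0.50 * E[0], 0.28 * E[1], 0.55 * E[2]),
                half_axes_mm=(0.30 * E[0], 0.17 * E[1], 0.24 * E[2]),
                exponent=2.5,
            ),
            Cylinder(
                center_mm=(0.50 * E[0], 0.10 * E[1], 0.58 * E[2]),
                radius_mm=0.12 * E[2],
                half_length_mm=0.12 * E[1],
                axis=1,
            ),
        ],
        "femoral_cartilage": [
            Superellipsoid(
                center_mm=(0.50 * E[0], 0.472 * E[1], 0.55 * E[2]),
                half_axes_mm=(0.24 * E[0], 0.011 * E[1], 0.19 * E[2]),
                exponent=2.5,
            )
        ],
        "tibial_cartilage": [
            Superellipsoid(
                center_mm=(0.50 * E[0], 0.502 * E[1], 0.55 * E[2]),
                half_axes_mm=(0.24 * E[0], 0.011 * E[1], 0.19 * E[2]),
                exponent=2.5,
            )
        ],
        "tibia": [
            Superellipsoid(
                center_mm=(0.50 * E[0], 0.61 * E[1], 0.55 * E[2]),
                half_axes_mm=(0.27 * E[0], 0.075 * E[1], 0.22 * E[2]),
                exponent=3.0,
            ),
            Cylinder(
                center_mm=(0.50 * E[0], 0.80 * E[1], 0.55 * E[2]),
                radius_mm=0.10 * E[2],
                half_length_mm=0.20 * E[1],
                axis=1,
            ),
        ],
        "patella": [
            Superellipsoid(
                center_mm=(0.50 * E[0], 0.26 * E[1], 0.14 * E[2]),
                half_axes_mm=(0.12 * E[0], 0.09 * E[1], 0.07 * E[2]),
                exponent=2.0,
            )
        ],
    }


@dataclass
class PhantomSpec:
    """Parameters for one synthetic knee volume.

    ``bones`` maps structure names (must exist in ``label_codes``) to lists
    of solids whose union forms that structure; structures must be pairwise
    disjoint on the voxel grid.  Intensities are piecewise constant
    (background / cortical rim / marrow interior / cartilage) before a
    spacing-aware Gaussian blur of ``boundary_blur_sigma_mm`` and additive
    Gaussian noise of ``noise_sd`` are applied.
    """

    grid_shape: tuple = (64, 128, 128)
    spacing_mm: tuple = (1.0, 0.4, 0.4)
    origin_mm: tuple = (0.0, 0.0, 0.0)
    bones: dict | None = None  # None -> default_bones(extent)
    rim_thickness_mm: float = 1.2
    intensity_background: float = 40.0
    intensity_rim: float = 220.0
    intensity_interior: float = 80.0
    intensity_cartilage: float = 150.0
    gain: float = 1.0
    boundary_blur_sigma_mm: float = 0.8
    noise_sd: float = 8.0
    seed: int = 0
    label_codes: dict = field(default_factory=lambda: dict(DEFAULT_LABEL_CODES))

    def __post_init__(self):
        if len(self.grid_shape) != 3 or any(int(s) < 1 for s in self.grid_shape):
            raise ValueError("grid_shape must be 3 positive integers")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing must be strictly positive")
        if self.boundary_blur_sigma_mm < 0 or self.noise_sd < 0:
            raise ValueError("blur and noise must be non-negative")
        if self.gain <= 0:
            raise ValueError("gain must be positive")

    @property
    def extent_mm(self) -> np.ndarray:
        return (np.array(self.grid_shape) - 1) * np.array(self.spacing_mm)

    def resolved_bones(self) -> dict:
        bones = self.bones if self.bones is not None else default_bones(self.extent_mm)
        unknown = set(bones) - set(self.label_codes)
        if unknown:
            raise ValueError(f"bone names {sorted(unknown)} missing from label_codes")
        return bones


def _world_coords(spec: PhantomSpec) -> np.ndarray:
    axes = [
        spec.origin_mm[a] + np.arange(spec.grid_shape[a]) * spec.spacing_mm[a]
        for a in range(3)
    ]
    grid = np.meshgrid(*axes, indexing="ij")
    return np.stack(grid, axis=-1)


_CARTILAGE = {"femoral_cartilage", "tibial_cartilage"}


def generate_phantom(spec: PhantomSpec) -> tuple[ImageVolume, LabelVolume]:
    """Render one phantom: exact labels plus the blurred, noisy image.

    Deterministic under ``spec.seed``.  Raises if two structures overlap on
    the voxel grid.
    """
    coords = _world_coords(spec)
    labels = np.zeros(spec.grid_shape, dtype=np.int32)
    spacing = np.array(spec.spacing_mm, dtype=float)

    for name, solids in spec.resolved_bones().items():
        code = int(spec.label_codes[name])
        mask = np.zeros(spec.grid_shape, dtype=bool)
        for solid in solids:
            mask |= solid.contains(coords)
        clash = mask & (labels != 0)
        if clash.any():
            raise ValueError(
                f"structure {name!r} overlaps a previously placed structure "
                f"({int(clash.sum())} voxels)"
            )
        labels[mask] = code

    image = np.full(spec.grid_shape, spec.intensity_background, dtype=float)
    bone_names = [n for n in spec.resolved_bones() if n not in _CARTILAGE]
    for name in bone_names:
        mask = labels == int(spec.label_codes[name])
        if not mask.any():
            continue
        # spacing-aware rim: interior is deeper than rim_thickness_mm from the edge
        depth_mm = ndimage.distance_transform_edt(mask, sampling=spacing)
        image[mask] = spec.intensity_rim
        image[depth_mm > spec.rim_thickness_mm] = spec.intensity_interior
    for name in _CARTILAGE & set(spec.resolved_bones()):
        image[labels == int(spec.label_codes[name])] = spec.intensity_cartilage

    image *= spec.gain
    if spec.boundary_blur_sigma_mm > 0:
        image = ndimage.gaussian_filter(image, sigma=spec.boundary_blur_sigma_mm / spacing)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        image = image + rng.normal(0.0, spec.noise_sd, size=image.shape)

    img_vol = ImageVolume(voxels=image, spacing_mm=spacing, origin_mm=np.array(spec.origin_mm))
    lab_vol = LabelVolume(
        labels=labels,
        spacing_mm=spacing,
        origin_mm=np.array(spec.origin_mm),
        label_codes=dict(spec.label_codes),
    )
    return img_vol, lab_vol


def generate_cohort(
    n_cases: int, base_spec: PhantomSpec | None = None, seed: int = 0
) -> list[tuple[str, ImageVolume, LabelVolume]]:
    """Generate ``n_cases`` phantoms with per-case anatomical and scanner jitter.

    Each case perturbs bone sizes/positions by a few percent and draws a
    per-scanner intensity gain in [0.85, 1.15], mimicking the variety of a
    multi-centre cohort.  Returns ``(case_id, image, labels)`` triples;
    deterministic under ``seed``.
    """
    if n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    base = base_spec if base_spec is not None else PhantomSpec()
    children = np.random.SeedSequence(seed).spawn(n_cases)
    out = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        case_seed = int(rng.integers(0, 2**31 - 1))
        extent = base.extent_mm
        bones = base.resolved_bones()
        jittered: dict = {}
        scale = rng.uniform(0.93, 1.05)
        shift = rng.uniform(-0.015, 0.015, size=3) * extent
        for name, solids in bones.items():
            new_solids = []
            for s in solids:
                if isinstance(s, Superellipsoid):
                    new_solids.append(
                        Superellipsoid(
                            center_mm=tuple(np.asarray(s.center_mm) + shift),
                            half_axes_mm=tuple(np.asarray(s.half_axes_mm) * scale),
                            exponent=s.exponent,
                        )
                    )
                else:
                    new_solids.append(
                        Cylinder(
                            center_mm=tuple(np.asarray(s.center_mm) + shift),
                            radius_mm=s.radius_mm * scale,
                            half_length_mm=s.half_length_mm,
                            axis=s.axis,
                        )
                    )
            jittered[name] = new_solids
        spec_i = PhantomSpec(
            grid_shape=base.grid_shape,
            spacing_mm=base.spacing_mm,
            origin_mm=base.origin_mm,
            bones=jittered,
            rim_thickness_mm=base.rim_thickness_mm,
            intensity_background=base.intensity_background,
            intensity_rim=base.intensity_rim,
            intensity_interior=base.intensity_interior,
            intensity_cartilage=base.intensity_cartilage,
            gain=float(rng.uniform(0.85, 1.15)),
            boundary_blur_sigma_mm=base.boundary_blur_sigma_mm,
            noise_sd=base.noise_sd,
            seed=case_seed,
            label_codes=base.label_codes,
        )
        img, lab = generate_phantom(spec_i)
        out.append((f"case{i:03d}", img, lab))
    return out


def make_biased_probability(
    label: LabelVolume, blur_sigma_mm: float, bias: float
) -> ProbabilityVolume:
    """Construct a probability field whose geometrically optimal threshold is known.

    The foreground indicator (``labels > 0``) is blurred with a spacing-aware
    Gaussian of ``blur_sigma_mm`` and shifted by ``bias``, then clipped to
    [0, 1].  Along the boundary normal the blurred indicator crosses 0.5
    exactly at the true surface, so the iso-level recovering the true
    boundary is ``0.5 + bias``: a network that systematically under- or
    over-calls the foreground is emulated by a negative or positive bias,
    and the geometrically optimal threshold is known analytically.
    """
    if blur_sigma_mm <= 0:
        raise ValueError("blur_sigma_mm must be > 0")
    if abs(bias) >= 0.5:
        raise ValueError("|bias| must be < 0.5 so the optimal threshold stays in (0,1)")
    indicator = (label.labels > 0).astype(float)
    sigma_vox = blur_sigma_mm / np.asarray(label.spacing_mm, dtype=float)
    probs = ndimage.gaussian_filter(indicator, sigma=sigma_vox) + bias
    return ProbabilityVolume(
        probs=np.clip(probs, 0.0, 1.0),
        spacing_mm=label.spacing_mm,
        origin_mm=label.origin_mm,
    )
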