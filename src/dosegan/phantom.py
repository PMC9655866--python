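"""Synthetic pelvic phantoms with analytic reference dose fields.

Each phantom is a body ellipsoid of soft-tissue HU inside an air
background, containing two bone-density femoral-head spheres, a central
PTV, a bladder anterior and a rectum posterior to it.  The reference dose
delivers the prescription inside the PTV and falls off exponentially with
Euclidean distance from the PTV surface, which yields realistic DVH
shoulders, nontrivial isodose surfaces and the OAR dose ordering (bladder/
rectum hotter than femoral heads) that the evaluation suite assumes.

Geometry is specified in millimetres relative to the grid centre; the
default geometry is defined on a 224 mm cube (64^3 voxels at 3.5 mm) and
scales with the requested extent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grid import DoseDistribution, StructureSet, VolumeGrid

HU_AIR = -600.0
REFERENCE_EXTENT_MM = 224.0  # extent the default geometry was designed on


@dataclass
class Ellipsoid:
    center: tuple[float, float, float]  # mm offsets from grid centre (z, y, x)
    semi_axes: tuple[float, float, float]  # mm

    def __post_init__(self):
        if any(a <= 0 for a in self.semi_axes):
            raise ValueError(f"semi-axes must be positive, got {self.semi_axes}")


def _default_geometry(scale: float) -> dict[str, Ellipsoid]:
    """Pelvic layout: +y is posterior, +x is patient-left."""
    s = scale
    return {
        "body": Ellipsoid((0, 0, 0), (100 * s, 85 * s, 105 * s)),
        "ptv": Ellipsoid((0, 5 * s, 0), (30 * s, 25 * s, 25 * s)),
        "bladder": Ellipsoid((0, -40 * s, 0), (22 * s, 18 * s, 22 * s)),
        "rectum": Ellipsoid((0, 45 * s, 0), (26 * s, 12 * s, 12 * s)),
        "femur_head_l": Ellipsoid((0, 10 * s, 72 * s), (20 * s, 20 * s, 20 * s)),
        "femur_head_r": Ellipsoid((0, 10 * s, -72 * s), (20 * s, 20 * s, 20 * s)),
    }


@dataclass
class PhantomSpec:
    """Geometry, intensity and noise parameters of one synthetic case."""

    shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (3.5, 3.5, 3.5)
    structures: dict[str, Ellipsoid] = field(default_factory=dict)
    hu_soft_tissue: float = 30.0
    hu_bone: float = 700.0
    hu_air: float = HU_AIR
    prescription: float = 5400.0  # cGy (54 Gy)
    falloff_mm: float = 25.0
    noise_hu: float = 20.0
    noise_dose_frac: float = 0.005  # sd as fraction of prescription
    seed: int = 0
    # per-case anatomical variability (fractional jitter of sizes/offsets)
    jitter: float = 0.0

    def __post_init__(self):
        if not self.structures:
            extent = min(n * s for n, s in zip(self.shape, self.spacing))
            self.structures = _default_geometry(extent / REFERENCE_EXTENT_MM)
        if self.falloff_mm <= 0:
            raise ValueError("falloff scale must be positive")


def _coords_mm(shape, spacing):
    axes = [
        (np.arange(n) - (n - 1) / 2.0) * sp for n, sp in zip(shape, spacing)
    ]
    return np.meshgrid(*axes, indexing="ij")


def _ellipsoid_mask(ell: Ellipsoid, coords) -> np.ndarray:
    z, y, x = coords
    cz, cy, cx = ell.center
    az, ay, ax = ell.semi_axes
    return (
        ((z - cz) / az) ** 2 + ((y - cy) / ay) ** 2 + ((x - cx) / ax) ** 2
    ) <= 1.0


def generate_phantom(spec: PhantomSpec) -> tuple[VolumeGrid, StructureSet]:
    """Deterministically build (CT, structure set) for one phantom."""
    rng = np.random.default_rng(spec.seed)
    coords = _coords_mm(spec.shape, spec.spacing)
    geo = dict(spec.structures)
    if spec.jitter > 0:
        for name, ell in geo.items():
            if name == "body":
                continue
            jc = rng.uniform(-spec.jitter, spec.jitter, 3)
            js = rng.uniform(-spec.jitter, spec.jitter, 3)
            geo[name] = Ellipsoid(
                tuple(c + j * a for c, j, a in zip(ell.center, jc, ell.semi_axes)),
                tuple(a * (1.0 + j) for a, j in zip(ell.semi_axes, js)),
            )
    masks = {name: _ellipsoid_mask(ell, coords) for name, ell in geo.items()}
    body = masks["body"]
    for name, m in masks.items():
        if name != "body" and np.any(m & ~body):
            raise ValueError(f"structure {name!r} extends outside the body")

    ct = np.full(spec.shape, spec.hu_air, dtype=np.float32)
    ct[body] = spec.hu_soft_tissue
    # subtle soft-tissue contrast so organs are visible to the network
    ct[masks["bladder"]] = 0.0
    ct[masks["rectum"]] = spec.hu_soft_tissue + 20.0
    ct[masks["ptv"]] = spec.hu_soft_tissue + 10.0
    ct[masks["femur_head_l"]] = spec.hu_bone
    ct[masks["femur_head_r"]] = spec.hu_bone
    if spec.noise_hu > 0:
        noise = rng.normal(0.0, spec.noise_hu, spec.shape).astype(np.float32)
        ct[body] += noise[body]

    grid = VolumeGrid(ct, spec.spacing)
    structures = StructureSet(
        {n: m.astype(np.uint8) for n, m in masks.items()}, spec.spacing
    )
    return grid, structures


def generate_reference_dose(
    structures: StructureSet,
    prescription: float = 5400.0,
    falloff_mm: float = 25.0,
    seed: int = 0,
    noise_frac: float = 0.005,
) -> DoseDistribution:
    """Analytic reference dose: Rx inside the PTV, exp(-d/falloff) outside.

    ``d`` is the Euclidean distance (mm) to the nearest PTV voxel; seeded
    Gaussian noise of sd ``noise_frac * prescription`` is added and the
    result clipped at zero.
    """
    if "ptv" not in structures or not np.any(structures["ptv"]):
        raise ValueError("structure set has no non-empty PTV")
    if falloff_mm <= 0:
        raise ValueError("falloff scale must be positive")
    ptv = structures["ptv"].astype(bool)
    dist = ndimage.distance_transform_edt(~ptv, sampling=structures.spacing)
    dose = prescription * np.exp(-dist / falloff_mm)
    if noise_frac > 0:
        rng = np.random.default_rng(seed)
        dose = dose + rng.normal(0.0, noise_frac * prescription, dose.shape)
    dose = np.clip(dose, 0.0, None).astype(np.float32)
    return DoseDistribution(
        VolumeGrid(dose, structures.spacing, structures.origin), prescription
    )


def generate_case(spec: PhantomSpec):
    """Convenience: (ct, structures, dose) for one spec."""
    ct, structures = generate_phantom(spec)
    dose = generate_reference_dose(
        structures, spec.prescription, spec.falloff_mm,
        seed=spec.seed + 1_000_003, noise_frac=spec.noise_dose_frac,
    )
    return ct, structures, dose


def generate_cohort(n: int, shape=(64, 64, 64), seed: int = 0, jitter: float = 0.08,
                    **overrides):
    """Generate ``n`` phantoms with per-case anatomical jitter."""
    cases = []
    for i in range(n):
        spec = PhantomSpec(shape=shape, seed=seed + i, jitter=jitter, **overrides)
        cases.append(generate_case(spec))
    return cases
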