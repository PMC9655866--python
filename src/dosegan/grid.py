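"""Core volumetric containers: scalar grids, structure sets, dose maps.

Axis convention throughout the package: arrays are indexed
``(transverse slice, row, column)`` — i.e. (superior-inferior, anterior-
posterior, left-right).  Spacing is millimetres per axis in the same order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

# roles a structure set is expected to provide
STRUCTURE_ROLES = ("body", "ptv", "bladder", "rectum", "femur_head_l", "femur_head_r")


@dataclass
class VolumeGrid:
    """A 3D scalar field with voxel spacing (mm) and origin offset (mm)."""

    values: np.ndarray
    spacing: tuple[float, float, float] = (3.5, 3.5, 3.5)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"VolumeGrid needs a 3D array, got ndim={self.values.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")

    @property
    def shape(self):
        return self.values.shape

    def with_values(self, values) -> "VolumeGrid":
        return replace(self, values=np.asarray(values))

    def same_geometry(self, other: "VolumeGrid", atol=1e-6) -> bool:
        return self.shape == other.shape and np.allclose(
            self.spacing, other.spacing, atol=atol
        )


@dataclass
class StructureSet:
    """Named binary masks sharing one grid geometry."""

    masks: dict[str, np.ndarray]
    spacing: tuple[float, float, float] = (3.5, 3.5, 3.5)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        shapes = {m.shape for m in self.masks.values()}
        if len(shapes) > 1:
            raise ValueError(f"masks have inconsistent shapes: {shapes}")
        for name, m in self.masks.items():
            vals = np.unique(m)
            if not np.all(np.isin(vals, (0, 1))):
                raise ValueError(f"mask {name!r} is not binary")
            self.masks[name] = m.astype(np.uint8)
        if "ptv" in self.masks and "body" in self.masks:
            if np.any(self.masks["ptv"] & ~self.masks["body"]):
                raise ValueError("PTV mask extends outside the body mask")

    def __getitem__(self, name: str) -> np.ndarray:
        return self.masks[name]

    def __contains__(self, name: str) -> bool:
        return name in self.masks

    @property
    def names(self):
        return list(self.masks)

    @property
    def shape(self):
        return next(iter(self.masks.values())).shape


@dataclass
class DoseDistribution:
    """A dose grid in cGy plus its prescription dose."""

    grid: VolumeGrid
    prescription: float  # cGy

    def __post_init__(self):
        if self.prescription <= 0:
            raise ValueError(f"prescription must be positive, got {self.prescription}")
        if np.any(self.grid.values < 0):
            raise ValueError("dose values must be non-negative")

    @property
    def values(self) -> np.ndarray:
        return self.grid.values
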