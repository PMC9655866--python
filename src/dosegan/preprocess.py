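"""Intensity, label and geometry normalisation of CT / mask / dose volumes.

The pipeline maps every channel onto a common intensity scale before it
enters the network: CT is truncated to the pelvic window [-600, 1000] HU,
structure masks are painted with fixed label values on the same HU scale,
dose is expressed on [0, 1.2 x prescription], and all channels are mapped
affinely onto [-1, 1] to match the generator's tanh output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .grid import DoseDistribution, StructureSet, VolumeGrid

HU_RANGE = (-600.0, 1000.0)
HU_BACKGROUND = -600.0
DOSE_HEADROOM = 1.2  # dose channel is normalised on [0, 1.2 * prescription]

#: label value painted into each structure channel (background -600)
STRUCTURE_LABELS = {
    "body": -400.0,
    "femur_head_r": -200.0,
    "femur_head_l": 200.0,
    "rectum": 600.0,
    "bladder": 800.0,
    "ptv": 1000.0,
}

#: channel order (after dose and CT) for each dataset scheme
SCHEME_STRUCTURES = {
    "A": ("ptv", "body", "femur_head_r", "femur_head_l", "rectum", "bladder"),
    "B": ("ptv",),
    "C": (),
}


def truncate_hu(ct: VolumeGrid, lo: float = HU_RANGE[0], hi: float = HU_RANGE[1]) -> VolumeGrid:
    """Clamp CT values to the pelvic HU window [-600, 1000]."""
    vals = ct.values
    if not np.all(np.isfinite(vals)):
        idx = tuple(int(i) for i in np.argwhere(~np.isfinite(vals))[0])
        raise ValueError(f"non-finite CT voxel at index {idx}")
    return ct.with_values(np.clip(vals, lo, hi))


def encode_structure_channels(
    structures: StructureSet, names=None
) -> dict[str, np.ndarray]:
    """Paint each binary mask with its label value, background -600.

    Returns float arrays on the HU scale, one per requested structure.
    """
    names = list(STRUCTURE_LABELS) if names is None else list(names)
    out = {}
    for name in names:
        if name not in structures:
            raise KeyError(f"structure set is missing required mask {name!r}")
        mask = structures[name].astype(bool)
        chan = np.full(mask.shape, HU_BACKGROUND, dtype=np.float32)
        chan[mask] = STRUCTURE_LABELS[name]
        out[name] = chan
    return out


def resample_isotropic(
    grid: VolumeGrid, target_spacing_mm: float = 3.5, mode: str = "linear"
) -> VolumeGrid:
    """Resample onto isotropic voxels of ``target_spacing_mm``.

    ``mode`` is "linear" for CT/dose and "nearest" for masks.  Sampling is
    index-space scaling (voxel i sits at i * spacing mm from the origin), so
    the physical extent is preserved to within one voxel.
    """
    if target_spacing_mm <= 0:
        raise ValueError(f"target spacing must be positive, got {target_spacing_mm}")
    order = {"linear": 1, "nearest": 0}[mode]
    factors = [s / target_spacing_mm for s in grid.spacing]
    new_shape = tuple(max(1, int(round(n * f))) for n, f in zip(grid.shape, factors))
    if new_shape == grid.shape and np.allclose(grid.spacing, target_spacing_mm):
        return VolumeGrid(grid.values.copy(), (target_spacing_mm,) * 3, grid.origin)
    coords = np.meshgrid(
        *[np.arange(n) * target_spacing_mm / s for n, s in zip(new_shape, grid.spacing)],
        indexing="ij",
    )
    vals = ndimage.map_coordinates(
        grid.values.astype(np.float64), np.array(coords), order=order, mode="nearest"
    )
    if order == 0:
        vals = vals.astype(grid.values.dtype)
    return VolumeGrid(vals, (target_spacing_mm,) * 3, grid.origin)


def crop_or_pad_center(
    grid: VolumeGrid,
    size: int | tuple[int, int, int] = 128,
    center: tuple[int, int, int] | None = None,
    pad_value: float = 0.0,
) -> VolumeGrid:
    """Extract a window of ``size`` voxels centred on ``center`` (indices).

    Out-of-bounds regions are filled with ``pad_value`` (-600 for CT and
    label channels, 0 for dose).  Windows are half-open and 0-based; the
    window start on each axis is ``center - size // 2``.
    """
    if grid.values.size == 0:
        raise ValueError("cannot crop an empty grid")
    size = (size,) * 3 if np.isscalar(size) else tuple(size)
    if any(s <= 0 for s in size):
        raise ValueError(f"crop size must be positive, got {size}")
    if center is None:
        center = tuple(n // 2 for n in grid.shape)
    out = np.full(size, pad_value, dtype=grid.values.dtype)
    src, dst = [], []
    for n, s, c in zip(grid.shape, size, center):
        start = int(c) - s // 2
        lo, hi = max(start, 0), min(start + s, n)
        if lo >= hi:
            raise ValueError("crop window does not intersect the grid")
        src.append(slice(lo, hi))
        dst.append(slice(lo - start, hi - start))
    out[tuple(dst)] = grid.values[tuple(src)]
    origin = tuple(
        o + (int(c) - s // 2) * sp
        for o, c, s, sp in zip(grid.origin, center, size, grid.spacing)
    )
    return VolumeGrid(out, grid.spacing, origin)


def mask_centroid(mask: np.ndarray) -> tuple[int, int, int]:
    """Integer centroid of a binary mask (crop centring rule)."""
    if not np.any(mask):
        raise ValueError("mask is empty")
    return tuple(int(round(c)) for c in ndimage.center_of_mass(mask))


def normalize_affine(values: np.ndarray, value_range: tuple[float, float]) -> np.ndarray:
    """Affine map of ``value_range`` onto [-1, 1]."""
    lo, hi = value_range
    if not hi > lo:
        raise ValueError(f"degenerate range {value_range}")
    return (2.0 * (np.asarray(values, dtype=np.float64) - lo) / (hi - lo) - 1.0)


def denormalize_affine(values: np.ndarray, value_range: tuple[float, float]) -> np.ndarray:
    """Inverse of :func:`normalize_affine`."""
    lo, hi = value_range
    if not hi > lo:
        raise ValueError(f"degenerate range {value_range}")
    return (np.asarray(values, dtype=np.float64) + 1.0) * (hi - lo) / 2.0 + lo


def dose_range(prescription: float) -> tuple[float, float]:
    return (0.0, DOSE_HEADROOM * prescription)


@dataclass
class ChannelStack:
    """The multichannel model input X for one case.

    ``channels`` is (C, D, H, W), normalised to [-1, 1].  Channel 0 is the
    dose when ``has_dose`` (training); at inference the dose channel is
    omitted.
    """

    scheme: str
    channels: np.ndarray
    names: tuple[str, ...]
    prescription: float
    spacing: tuple[float, float, float] = (3.5, 3.5, 3.5)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    has_dose: bool = True

    def __post_init__(self):
        expected = {"A": 8, "B": 3, "C": 2}[self.scheme]
        if not self.has_dose:
            expected -= 1
        if self.channels.shape[0] != expected:
            raise ValueError(
                f"scheme {self.scheme} expects {expected} channels, "
                f"got {self.channels.shape[0]}"
            )

    @property
    def n_channels(self) -> int:
        return self.channels.shape[0]

    def without_dose(self) -> "ChannelStack":
        if not self.has_dose:
            return self
        return ChannelStack(
            self.scheme, self.channels[1:], self.names[1:], self.prescription,
            self.spacing, self.origin, has_dose=False,
        )

    @property
    def gt_dose_channel(self) -> np.ndarray:
        if not self.has_dose:
            raise ValueError("stack has no dose channel")
        return self.channels[0]


def assemble_channel_stack(
    ct: VolumeGrid,
    structures: StructureSet | None,
    dose: DoseDistribution | None,
    scheme: str = "A",
    prescription: float | None = None,
) -> ChannelStack:
    """Build the normalised input stack for one dataset scheme.

    Channel order: (dose,) CT, then scheme structures — for scheme A:
    PTV, body, femur-R, femur-L, rectum, bladder.  ``dose=None`` produces
    an inference stack without the dose channel.
    """
    if scheme not in SCHEME_STRUCTURES:
        raise ValueError(f"unknown scheme {scheme!r}")
    chans, names = [], []
    rx = prescription if prescription is not None else (
        dose.prescription if dose is not None else None
    )
    if rx is None:
        raise ValueError("prescription required when no dose is supplied")
    if dose is not None:
        if not dose.grid.same_geometry(ct):
            raise ValueError("dose and CT geometries differ")
        chans.append(normalize_affine(dose.values, dose_range(rx)))
        names.append("dose")
    chans.append(normalize_affine(truncate_hu(ct).values, HU_RANGE))
    names.append("ct")
    wanted = SCHEME_STRUCTURES[scheme]
    if wanted:
        if structures is None:
            raise ValueError(f"scheme {scheme} requires structures {wanted}")
        if structures.shape != ct.shape:
            raise ValueError("structure and CT geometries differ")
        encoded = encode_structure_channels(structures, wanted)
        for name in wanted:
            chans.append(normalize_affine(encoded[name], HU_RANGE))
            names.append(name)
    stack = np.stack(chans).astype(np.float32)
    return ChannelStack(
        scheme, stack, tuple(names), float(rx), ct.spacing, ct.origin,
        has_dose=dose is not None,
    )
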