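"""File interchange: NIfTI volumes, DICOM RTDOSE ingestion, case manifests.

A *case directory* holds NIfTI volumes plus a ``manifest.json`` mapping
roles to files and recording the prescription in cGy::

    {"prescription_cgy": 5400.0,
     "ct": "ct.nii.gz", "dose": "dose.nii.gz",
     "structures": {"body": "body.nii.gz", "ptv": "ptv.nii.gz", ...}}
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .grid import DoseDistribution, StructureSet, VolumeGrid

MANIFEST_NAME = "manifest.json"


def write_nifti(path, grid: VolumeGrid) -> None:
    affine = np.diag(list(grid.spacing) + [1.0])
    affine[:3, 3] = grid.origin
    img = nib.Nifti1Image(np.asarray(grid.values), affine)
    img.header.set_zooms(grid.spacing)
    nib.save(img, str(path))


def read_nifti(path) -> VolumeGrid:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(o) for o in img.affine[:3, 3])
    return VolumeGrid(np.asarray(img.dataobj), spacing, origin)


def load_rtdose_scaled(dose_file) -> DoseDistribution:
    """Read a DICOM RTDOSE file, applying its dose-grid scale factor.

    The stored integer grid is multiplied by ``DoseGridScaling`` and
    converted to cGy (RTDOSE dose units are usually GY).  The prescription
    is not part of RTDOSE and must be attached by the caller; a nominal
    value equal to the maximum dose is used as a placeholder when absent.
    """
    import pydicom

    ds = pydicom.dcmread(str(dose_file))
    if "DoseGridScaling" not in ds:
        raise ValueError("RTDOSE file has no DoseGridScaling element")
    scale = float(ds.DoseGridScaling)
    dose = ds.pixel_array.astype(np.float64) * scale
    units = str(getattr(ds, "DoseUnits", "GY")).upper()
    if units == "GY":
        dose *= 100.0  # -> cGy
    elif units != "CGY":
        raise ValueError(f"unsupported DoseUnits {units!r}")
    spacing_rc = getattr(ds, "PixelSpacing", [1.0, 1.0])
    offsets = getattr(ds, "GridFrameOffsetVector", None)
    dz = float(offsets[1] - offsets[0]) if offsets is not None and len(offsets) > 1 else 1.0
    grid = VolumeGrid(dose, (abs(dz), float(spacing_rc[0]), float(spacing_rc[1])))
    rx = float(dose.max()) if dose.max() > 0 else 1.0
    return DoseDistribution(grid, rx)


def write_case(
    directory,
    ct: VolumeGrid,
    structures: StructureSet,
    dose: DoseDistribution | None = None,
    prescription: float | None = None,
) -> Path:
    """Write a case directory (NIfTI volumes + manifest)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {"structures": {}}
    write_nifti(directory / "ct.nii.gz", ct)
    manifest["ct"] = "ct.nii.gz"
    for name, mask in structures.masks.items():
        fname = f"{name}.nii.gz"
        write_nifti(
            directory / fname,
            VolumeGrid(mask.astype(np.uint8), structures.spacing, structures.origin),
        )
        manifest["structures"][name] = fname
    if dose is not None:
        write_nifti(directory / "dose.nii.gz", dose.grid)
        manifest["dose"] = "dose.nii.gz"
        manifest["prescription_cgy"] = float(dose.prescription)
    if prescription is not None:
        manifest["prescription_cgy"] = float(prescription)
    (directory / MANIFEST_NAME).write_text(json.dumps(manifest, indent=1))
    return directory / MANIFEST_NAME


def read_case(directory):
    """Read a case directory -> (ct, structures, dose-or-None, prescription)."""
    directory = Path(directory)
    manifest = json.loads((directory / MANIFEST_NAME).read_text())
    ct = read_nifti(directory / manifest["ct"])
    masks = {
        name: np.asarray(read_nifti(directory / f).values)
        for name, f in manifest["structures"].items()
    }
    structures = StructureSet(masks, ct.spacing, ct.origin)
    rx = float(manifest.get("prescription_cgy", 0.0))
    dose = None
    if "dose" in manifest:
        dose = DoseDistribution(read_nifti(directory / manifest["dose"]), rx)
    return ct, structures, dose, rx
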