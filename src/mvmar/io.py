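"""Slice / sinogram readers and writers, provenance sidecars, PNG egress.

NPZ is the canonical lossless interchange format (float64 values plus
metadata).  DICOM and NIfTI are supported for ingress; DICOM stored values
are rescaled to HU via RescaleSlope/RescaleIntercept.  PNG output is 8-bit
after window/level for visual inspection only.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from pathlib import Path

import numpy as np

from .errors import ValidationError
from .geometry import ScanGeometry, SliceImage, Sinogram

log = logging.getLogger(__name__)

#: (window level, window width) presets, HU.
WINDOW_PRESETS = {"bone": (450.0, 1600.0), "soft": (40.0, 400.0), "lung": (-400.0, 1500.0)}


def _detect_format(path: Path) -> str:
    name = path.name.lower()
    if name.endswith(".npz"):
        return "npz"
    if name.endswith((".nii", ".nii.gz")):
        return "nifti"
    if name.endswith((".dcm", ".ima")):
        return "dicom"
    raise ValidationError(f"cannot infer format of {path}; pass format explicitly")


def read_slice(path: str | Path, fmt: str | None = None,
               slice_index: int | None = None) -> SliceImage:
    """Read one 2-D slice in HU from NPZ, NIfTI or DICOM."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    fmt = fmt or _detect_format(path)
    if fmt == "npz":
        with np.load(path) as data:
            return SliceImage(data["values"], float(data["pixel_spacing"]),
                              str(data["modality"]) if "modality" in data else "unknown")
    if fmt == "nifti":
        import nibabel as nib
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
        if data.ndim == 3:
            if data.shape[2] == 1:
                data = data[:, :, 0]
            elif slice_index is None:
                raise ValidationError(
                    "3-D NIfTI input: select a slice with --slice-index")
            else:
                data = data[:, :, slice_index]
        spacing = float(img.header.get_zooms()[0])
        return SliceImage(data.astype(np.float64), spacing, "unknown")
    if fmt == "dicom":
        import pydicom
        ds = pydicom.dcmread(str(path))
        values = ds.pixel_array.astype(np.float64)
        modality = "kV"
        if hasattr(ds, "RescaleSlope") and hasattr(ds, "RescaleIntercept"):
            values = values * float(ds.RescaleSlope) + float(ds.RescaleIntercept)
        else:
            warnings.warn("DICOM without rescale tags: returning raw stored values")
            modality = "unknown"
        spacing = float(ds.PixelSpacing[0]) if hasattr(ds, "PixelSpacing") else 1.0
        return SliceImage(values, spacing, modality)
    raise ValidationError(f"unknown format {fmt!r}")


def write_slice(path: str | Path, img: SliceImage) -> None:
    """Write a slice as NPZ (canonical) or NIfTI."""
    path = Path(path)
    fmt = _detect_format(path)
    if fmt == "npz":
        np.savez(path, values=img.values, pixel_spacing=img.pixel_spacing,
                 modality=img.modality)
    elif fmt == "nifti":
        import nibabel as nib
        affine = np.diag([img.pixel_spacing, img.pixel_spacing, 1.0, 1.0])
        nib.save(nib.Nifti1Image(img.values.astype(np.float64), affine), str(path))
    else:
        raise ValidationError(f"cannot write slices as {fmt!r}")


def write_png(path: str | Path, img: SliceImage, window: str | tuple[float, float] = "soft"):
    """8-bit window/level rendering for visual inspection."""
    import imageio.v3 as iio
    level, width = WINDOW_PRESETS[window] if isinstance(window, str) else window
    lo, hi = level - width / 2.0, level + width / 2.0
    scaled = np.clip((img.values - lo) / (hi - lo), 0.0, 1.0)
    iio.imwrite(Path(path), (scaled * 255).astype(np.uint8))


def write_sinogram(path: str | Path, sino: Sinogram) -> None:
    np.savez(Path(path), values=sino.values, angles=sino.geometry.angles,
             bin_spacing=sino.geometry.bin_spacing)


def read_sinogram(path: str | Path, geometry: ScanGeometry) -> Sinogram:
    with np.load(Path(path)) as data:
        return Sinogram(data["values"], geometry)


def write_provenance(artifact_path: str | Path, config: dict, seed: int | None = None,
                     extra: dict | None = None) -> Path:
    """JSON sidecar recording everything needed to regenerate the artifact."""
    import mvmar
    payload = {
        "artifact": Path(artifact_path).name,
        "config": config,
        "seed": seed,
        "config_hash": hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:16],
        "versions": {"mvmar": mvmar.__version__, "numpy": np.__version__},
    }
    if extra:
        payload.update(extra)
    sidecar = Path(str(artifact_path) + ".json")
    sidecar.write_text(json.dumps(payload, indent=2, default=str))
    return sidecar
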