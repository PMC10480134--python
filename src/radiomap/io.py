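"""Reading and writing volumes as NIfTI or NRRD.

SimpleITK backs both formats.  SimpleITK arrays are (z, y, x) ordered;
this module transposes to the package's (x, y, z) convention on the way in
and back on the way out, and carries spacing/origin through the headers.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import SimpleITK as sitk

from .geometry import ImageVolume, SphereVOI, VolumeGeometry

__all__ = ["read_volume", "write_volume", "read_vois", "write_vois"]

_SUFFIXES = (".nii", ".nii.gz", ".nrrd")


def _check_suffix(path: Path) -> None:
    name = path.name.lower()
    if not any(name.endswith(s) for s in _SUFFIXES):
        raise ValueError(f"unsupported volume format {path.name!r}; use .nii, .nii.gz or .nrrd")


def read_volume(path: str | Path) -> ImageVolume:
    """Read a 3-D scalar NIfTI or NRRD volume.

    Raises
    ------
    ValueError
        If the payload is not 3-D scalar.
    """
    path = Path(path)
    _check_suffix(path)
    img = sitk.ReadImage(str(path))
    if img.GetDimension() != 3:
        raise ValueError(f"expected a 3-D volume, got {img.GetDimension()}-D in {path.name}")
    if img.GetNumberOfComponentsPerPixel() != 1:
        raise ValueError(
            f"expected a scalar volume, got {img.GetNumberOfComponentsPerPixel()} components"
        )
    arr = sitk.GetArrayFromImage(img)  # (z, y, x)
    values = np.ascontiguousarray(arr.transpose(2, 1, 0))
    spacing = tuple(img.GetSpacing())
    # SimpleITK's origin is the centre of voxel (0,0,0); ours the corner.
    origin = tuple(o - 0.5 * s for o, s in zip(img.GetOrigin(), spacing))
    geom = VolumeGeometry(spacing=spacing, origin=origin, shape=values.shape)
    return ImageVolume(values, geom)


def write_volume(vol: ImageVolume, path: str | Path) -> Path:
    """Write a volume as NIfTI (.nii/.nii.gz) or NRRD (.nrrd)."""
    path = Path(path)
    _check_suffix(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arr = np.ascontiguousarray(np.asarray(vol.values).transpose(2, 1, 0))
    img = sitk.GetImageFromArray(arr)
    img.SetSpacing(tuple(vol.geometry.spacing))
    img.SetOrigin(tuple(o + 0.5 * s for o, s in zip(vol.geometry.origin, vol.geometry.spacing)))
    sitk.WriteImage(img, str(path))
    return path


def write_vois(vois: list[SphereVOI], path: str | Path) -> Path:
    """Write sphere VOIs as a JSON sidecar (centre mm, diameter mm)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = [{"center_mm": list(v.center), "diameter_mm": v.diameter} for v in vois]
    path.write_text(json.dumps(payload, indent=2) + "\n")
    return path


def read_vois(path: str | Path) -> list[SphereVOI]:
    payload = json.loads(Path(path).read_text())
    return [SphereVOI(tuple(d["center_mm"]), d["diameter_mm"]) for d in payload]
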