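"""Reading and writing image volumes (NRRD / NIfTI-1) via SimpleITK.

Arrays are indexed ``[i, j, k]`` with axis 3 (``k``) the slice axis, matching
the (x, y, z) order of the stored ``spacing`` vector.  SimpleITK's array view
is (z, y, x), so volumes are transposed on the way in and out.
"""

from __future__ import annotations

import os

import numpy as np
import SimpleITK as sitk

from radrep.errors import FormatError

_EXTENSIONS = (".nrrd", ".nii", ".nii.gz")


def write_image(array: np.ndarray, spacing, path: str | os.PathLike) -> None:
    """Write a 3D array with (x, y, z) spacing in mm to NRRD or NIfTI-1.

    Masks should be passed as uint8 {0, 1}; intensity volumes as float.
    """
    arr = np.asarray(array)
    if arr.ndim != 3:
        raise FormatError(f"expected a 3D array, got shape {arr.shape}")
    img = sitk.GetImageFromArray(np.ascontiguousarray(arr.transpose(2, 1, 0)))
    img.SetSpacing(tuple(float(s) for s in spacing))
    sitk.WriteImage(img, os.fspath(path))


def read_image(path: str | os.PathLike) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Read a 3D image; return (array indexed [i, j, k], spacing (x, y, z) mm)."""
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FormatError(f"no such file: {path}")
    try:
        img = sitk.ReadImage(path)
    except Exception as exc:  # SimpleITK raises RuntimeError on parse failure
        raise FormatError(f"could not read {path}: {exc}") from exc
    if img.GetDimension() != 3:
        raise FormatError(f"{path}: expected a 3D image, got {img.GetDimension()}D")
    arr = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    return np.asarray(arr), tuple(float(s) for s in img.GetSpacing())
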