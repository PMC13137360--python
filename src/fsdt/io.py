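"""Readers and writers: PNG/TIFF slices, NIfTI volumes, JSON reports."""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from fsdt.preprocess import ImageSlice, to_grayscale

__all__ = ["read_image", "write_image", "write_report", "read_report", "REPORT_SCHEMA_VERSION"]

REPORT_SCHEMA_VERSION = 1


class FormatError(ValueError):
    """Unrecognized or corrupt image input."""


def _bit_depth_of(arr: np.ndarray) -> int:
    return 16 if arr.dtype.itemsize > 1 else 8


def read_image(path: str | Path, slice_index: int | None = None,
               spacing: float = 1.0) -> ImageSlice:
    """Read a grayscale or RGB PNG/TIFF, or one axial slice of a NIfTI volume.

    RGB input is collapsed with the standard luma weights; integer bit depth
    is preserved (8- or 16-bit). For NIfTI, ``slice_index`` selects the axial
    (last-axis) slice and intensities are min-max rescaled to 16-bit, since
    NIfTI voxels carry arbitrary scanner units.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image: {path}")
    suffixes = "".join(path.suffixes).lower()
    if suffixes.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        vol = np.asanyarray(nib.load(path).dataobj)
        if vol.ndim == 4:
            vol = vol[..., 0]
        if vol.ndim != 3:
            raise FormatError(f"expected a 3-D NIfTI volume, got ndim={vol.ndim}")
        k = slice_index if slice_index is not None else vol.shape[2] // 2
        if not (0 <= k < vol.shape[2]):
            raise IndexError(f"slice {k} out of range [0, {vol.shape[2]})")
        sl = np.asarray(vol[:, :, k], dtype=np.float64)
        lo, hi = sl.min(), sl.max()
        scaled = (sl - lo) / (hi - lo) * 65535.0 if hi > lo else np.zeros_like(sl)
        return ImageSlice(np.rint(scaled), bit_depth=16, spacing=spacing)
    if path.suffix.lower() not in (".png", ".tif", ".tiff"):
        raise FormatError(f"unsupported image format: {path.suffix}")
    try:
        arr = iio.imread(path)
    except Exception as exc:  # corrupt file
        raise FormatError(f"cannot decode {path}: {exc}") from exc
    if arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[..., :3]
    bit_depth = _bit_depth_of(arr)
    return to_grayscale(arr, bit_depth=bit_depth, spacing=spacing)


def write_image(image: ImageSlice, path: str | Path) -> Path:
    """Write a slice as 8- or 16-bit grayscale PNG (per its bit depth)."""
    path = Path(path)
    iio.imwrite(path, image.quantized())
    return path


def write_report(report: dict, path: str | Path) -> Path:
    """Write a JSON report with an embedded schema version."""
    path = Path(path)
    payload = {"schema_version": REPORT_SCHEMA_VERSION, **report}
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return path


def read_report(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
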