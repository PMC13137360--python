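"""Slice-level pre-processing: grayscale conversion, denoising, contrast maps,
edge map and gradient magnitude.

All maps are shape-preserving, computed in float64 with replicate ("nearest")
border handling so that image borders do not produce spurious responses that
would inflate per-section maxima. Intensities are only re-quantized on export.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import ndimage

__all__ = [
    "ImageSlice", "FeatureMaps", "to_grayscale", "denoise",
    "contrast_maps", "edge_map", "gradient_magnitude", "compute_feature_maps",
]

#: unnormalized 3x3 Sobel kernels; column-gradient kernel (responds to
#: horizontal intensity changes) and its transpose.
_SOBEL_COL = np.array([[-1.0, 0.0, 1.0],
                       [-2.0, 0.0, 2.0],
                       [-1.0, 0.0, 1.0]])
_SOBEL_ROW = _SOBEL_COL.T


@dataclass(frozen=True)
class ImageSlice:
    """A 2-D grayscale intensity raster.

    Parameters
    ----------
    pixels
        2-D float array; values must lie in ``[0, 2**bit_depth - 1]``.
    bit_depth
        8 or 16; fixes the intensity scale used for normalization.
    spacing
        Physical units per pixel (isotropic), default 1.0.
    """

    pixels: np.ndarray
    bit_depth: int = 8
    spacing: float = 1.0

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        object.__setattr__(self, "pixels", px)
        if px.ndim != 2:
            raise ValueError(f"ImageSlice requires a 2-D raster, got ndim={px.ndim}")
        if px.shape[0] < 8 or px.shape[1] < 8:
            raise ValueError(f"ImageSlice requires height, width >= 8, got {px.shape}")
        if self.bit_depth not in (8, 16):
            raise ValueError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        lo, hi = float(px.min()), float(px.max())
        if lo < 0 or hi > self.intensity_max:
            raise ValueError(
                f"intensities [{lo}, {hi}] outside [0, {self.intensity_max}] "
                f"for bit depth {self.bit_depth}")

    @property
    def intensity_max(self) -> float:
        return float(2 ** self.bit_depth - 1)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def quantized(self) -> np.ndarray:
        """Round back to the integer dtype implied by the bit depth."""
        dtype = np.uint8 if self.bit_depth == 8 else np.uint16
        return np.clip(np.rint(self.pixels), 0, self.intensity_max).astype(dtype)


@dataclass(frozen=True)
class FeatureMaps:
    """Per-pixel maps derived from one denoised slice: Sobel edge magnitude,
    horizontal/vertical contrast, central-difference gradient magnitude."""

    edge: np.ndarray
    contrast_h: np.ndarray
    contrast_v: np.ndarray
    grad_mag: np.ndarray
    denoised: ImageSlice

    def __post_init__(self) -> None:
        shape = self.denoised.shape
        for name in ("edge", "contrast_h", "contrast_v", "grad_mag"):
            m = getattr(self, name)
            if m.shape != shape:
                raise ValueError(f"{name} shape {m.shape} != image shape {shape}")


def to_grayscale(raster: np.ndarray, bit_depth: int = 8, spacing: float = 1.0) -> ImageSlice:
    """Convert a 1- or 3-channel raster to a single-channel :class:`ImageSlice`.

    Three-channel input is collapsed with the Rec. 601 luma weights
    0.299 R + 0.587 G + 0.114 B and rounded to the nearest integer level;
    single-channel input passes through unchanged.
    """
    arr = np.asarray(raster, dtype=np.float64)
    if arr.ndim == 2:
        return ImageSlice(arr, bit_depth=bit_depth, spacing=spacing)
    if arr.ndim == 3 and arr.shape[2] == 3:
        luma = arr[..., 0] * 0.299 + arr[..., 1] * 0.587 + arr[..., 2] * 0.114
        return ImageSlice(np.rint(luma), bit_depth=bit_depth, spacing=spacing)
    raise ValueError(
        f"unsupported channel layout {arr.shape}; expected HxW or HxWx3")


def denoise(image: ImageSlice, method: Literal["median", "gaussian"] = "median",
            radius: int = 1) -> ImageSlice:
    """Remove pixel noise with a median (default) or Gaussian filter.

    ``radius`` is the half-width of the median window (window side
    ``2*radius + 1``) or the Gaussian sigma in pixels.
    """
    if radius < 1:
        raise ValueError(f"radius must be >= 1, got {radius}")
    h, w = image.shape
    if radius >= min(h, w) / 2:
        raise ValueError(f"radius {radius} too large for shape {image.shape}")
    if method == "median":
        out = ndimage.median_filter(image.pixels, size=2 * radius + 1, mode="nearest")
    elif method == "gaussian":
        out = ndimage.gaussian_filter(image.pixels, sigma=float(radius), mode="nearest")
        out = np.clip(out, 0.0, image.intensity_max)
    else:
        raise ValueError(f"unknown denoise method {method!r}")
    return ImageSlice(out, bit_depth=image.bit_depth, spacing=image.spacing)


def contrast_maps(image: ImageSlice) -> tuple[np.ndarray, np.ndarray]:
    """Absolute forward-difference contrast along columns (C_H) and rows (C_V).

    The last column (resp. row) is replicated so both maps keep the input
    shape; their trailing column/row is therefore zero.
    """
    px = image.pixels
    c_h = np.zeros_like(px)
    c_h[:, :-1] = np.abs(px[:, 1:] - px[:, :-1])
    c_v = np.zeros_like(px)
    c_v[:-1, :] = np.abs(px[1:, :] - px[:-1, :])
    return c_h, c_v


def edge_map(image: ImageSlice) -> np.ndarray:
    """Sobel gradient magnitude sqrt(Gx^2 + Gy^2) with replicate padding.

    Uses the unnormalized 3x3 kernels, so an isolated interior intensity step
    of height ``h`` produces a response of ``4 h`` along the step.
    """
    px = image.pixels
    gx = ndimage.correlate(px, _SOBEL_COL, mode="nearest")
    gy = ndimage.correlate(px, _SOBEL_ROW, mode="nearest")
    return np.hypot(gx, gy)


def gradient_magnitude(image: ImageSlice) -> np.ndarray:
    """Central-difference gradient magnitude with replicate padding.

    Kept distinct from :func:`edge_map` (Sobel) because the pipeline computes
    both: the smoothed Sobel magnitude feeds edge statistics while this plain
    central difference is the per-pixel gradient the detection stage consumes.
    A linear ramp of unit slope yields magnitude 1 at interior pixels.
    """
    px = image.pixels
    padded = np.pad(px, 1, mode="edge")
    gx = (padded[1:-1, 2:] - padded[1:-1, :-2]) / 2.0
    gy = (padded[2:, 1:-1] - padded[:-2, 1:-1]) / 2.0
    return np.hypot(gx, gy)


def compute_feature_maps(image: ImageSlice, method: Literal["median", "gaussian"] = "median",
                         radius: int = 1) -> FeatureMaps:
    """Denoise once and derive every per-pixel map from the denoised slice."""
    den = denoise(image, method=method, radius=radius)
    c_h, c_v = contrast_maps(den)
    return FeatureMaps(
        edge=edge_map(den),
        contrast_h=c_h,
        contrast_v=c_v,
        grad_mag=gradient_magnitude(den),
        denoised=den,
    )
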