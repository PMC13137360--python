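"""Synthetic brain-like MRI phantom generator with exact ground-truth masks.

A phantom is an elliptical "head" of textured tissue on a zero background,
optionally carrying one or more bright elliptical tumors placed fully inside
the head. Tissue texture is the sum of a smooth low-frequency field and
per-pixel Gaussian noise, both scaled by ``tissue_noise_sd``; tumors add a
contrast bump whose hard elliptical support is the ground-truth mask and
whose intensity profile has a 1-px Gaussian-softened boundary. Every phantom
is reproducible in isolation: the pseudo-random stream is keyed by
``(seed, index)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy import ndimage

from fsdt.preprocess import ImageSlice

__all__ = ["PhantomConfig", "GroundTruth", "generate_phantom", "generate_dataset"]

logger = logging.getLogger(__name__)

_PLACEMENT_RETRIES = 50


@dataclass(frozen=True)
class PhantomConfig:
    """Generation parameters; all ranges are inclusive ``(low, high)`` pairs."""

    image_height: int = 128
    image_width: int = 128
    bit_depth: int = 8
    head_axis_fractions: tuple[float, float] = (0.84, 0.88)
    tissue_mean: float = 110.0
    tissue_noise_sd: float = 6.0
    tumor_count_range: tuple[int, int] = (1, 2)
    tumor_radius_range: tuple[float, float] = (4.0, 12.0)
    tumor_contrast_range: tuple[float, float] = (60.0, 120.0)
    tumor_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("tumor_count_range", "tumor_radius_range", "tumor_contrast_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} must satisfy low <= high, got ({lo}, {hi})")
        if self.tumor_count_range[0] < 0:
            raise ValueError("tumor counts must be >= 0")
        if self.tumor_radius_range[0] < 1:
            raise ValueError("tumor radii must be >= 1 pixel")
        if self.tumor_contrast_range[0] <= 0:
            raise ValueError("tumor contrast must be > 0")
        if not all(0 < f < 1 for f in self.head_axis_fractions):
            raise ValueError("head_axis_fractions must lie in (0, 1)")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")
        if not (0.0 <= self.tumor_fraction <= 1.0):
            raise ValueError("tumor_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class GroundTruth:
    """Exact binary tumor mask plus per-tumor pixel areas."""

    mask: np.ndarray
    tumor_areas: tuple[int, ...]

    def __post_init__(self) -> None:
        if int(self.mask.sum()) != sum(self.tumor_areas):
            raise ValueError("mask pixel count must equal sum of tumor areas")

    @property
    def tumor_label(self) -> int:
        """1 iff the mask has at least one positive pixel."""
        return int(self.mask.any())

    @property
    def total_tumor_px(self) -> int:
        return int(self.mask.sum())


def _head_ellipse(h: int, w: int, fractions: tuple[float, float]) -> np.ndarray:
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    ay, ax = fractions[0] * h / 2.0, fractions[1] * w / 2.0
    yy, xx = np.mgrid[0:h, 0:w]
    return ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0


def _tumor_support(h: int, w: int, cy: float, cx: float, r_major: float,
                   ratio: float, theta: float) -> np.ndarray:
    """Rasterize a rotated filled ellipse: pixel centers inside the boundary."""
    yy, xx = np.mgrid[0:h, 0:w]
    dy, dx = yy - cy, xx - cx
    u = np.cos(theta) * dx + np.sin(theta) * dy
    v = -np.sin(theta) * dx + np.cos(theta) * dy
    return (u / r_major) ** 2 + (v / (r_major * ratio)) ** 2 <= 1.0


def generate_phantom(config: PhantomConfig, index: int = 0) -> tuple[ImageSlice, GroundTruth]:
    """Generate one phantom slice and its ground truth.

    Deterministic for a fixed ``(config.seed, index)``. Tumors that cannot be
    placed fully inside the head without overlapping an earlier tumor after a
    bounded number of retries are skipped with a log message.
    """
    h, w = config.image_height, config.image_width
    rng = np.random.default_rng([config.seed & 0x7FFFFFFF, index])
    head = _head_ellipse(h, w, config.head_axis_fractions)

    texture = ndimage.gaussian_filter(rng.standard_normal((h, w)), sigma=6.0)
    sd = texture.std()
    if sd > 0:
        texture *= config.tissue_noise_sd / sd
    noise = rng.normal(0.0, config.tissue_noise_sd, size=(h, w))
    image = np.where(head, config.tissue_mean + texture + noise, 0.0)

    lo, hi = config.tumor_count_range
    n_tumors = int(rng.integers(lo, hi + 1))
    mask = np.zeros((h, w), dtype=bool)
    areas: list[int] = []
    for t in range(n_tumors):
        placed = False
        for _ in range(_PLACEMENT_RETRIES):
            r = float(rng.uniform(*config.tumor_radius_range))
            ratio = float(rng.uniform(0.6, 1.0))
            theta = float(rng.uniform(0.0, np.pi))
            cy = float(rng.uniform(r, h - 1 - r))
            cx = float(rng.uniform(r, w - 1 - r))
            support = _tumor_support(h, w, cy, cx, r, ratio, theta)
            if not support.any():
                continue
            if not head[support].all():        # must sit fully inside the head
                continue
            if (mask & support).any():         # tumors never overlap
                continue
            contrast = float(rng.uniform(*config.tumor_contrast_range))
            profile = ndimage.gaussian_filter(support.astype(np.float64), sigma=1.0)
            peak = profile.max()
            if peak > 0:
                profile /= peak
            image += contrast * profile
            mask |= support
            areas.append(int(support.sum()))
            placed = True
            break
        if not placed:
            logger.warning("phantom (seed=%d, index=%d): skipped unplaceable tumor %d",
                           config.seed, index, t)

    max_val = float(2 ** config.bit_depth - 1)
    quantized = np.clip(np.rint(image), 0.0, max_val)
    quantized[~head] = 0.0
    slice_ = ImageSlice(quantized, bit_depth=config.bit_depth)
    return slice_, GroundTruth(mask=mask, tumor_areas=tuple(areas))


def generate_dataset(n: int, config: PhantomConfig, out_dir: str | Path) -> pd.DataFrame:
    """Write ``n`` phantoms (image + mask PNGs) and return their manifest.

    Exactly ``round(n * config.tumor_fraction)`` images carry at least one
    tumor; which indices those are is decided by a seeded shuffle so the
    manifest is identical across reruns. The manifest CSV has columns
    path, mask_path, label, n_tumors, total_tumor_px, seed, index.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    n_pos = round(n * config.tumor_fraction)
    order = np.random.default_rng([config.seed & 0x7FFFFFFF, 0xBA1A]).permutation(n)
    positive = np.zeros(n, dtype=bool)
    positive[order[:n_pos]] = True

    lo, hi = config.tumor_count_range
    pos_range = (max(lo, 1), max(hi, 1))
    records = []
    for i in range(n):
        cfg_i = replace(config, tumor_count_range=pos_range if positive[i] else (0, 0))
        img, gt = generate_phantom(cfg_i, index=i)
        img_path = out_dir / f"phantom_{i:04d}.png"
        mask_path = out_dir / f"phantom_{i:04d}_mask.png"
        iio.imwrite(img_path, img.quantized())
        iio.imwrite(mask_path, (gt.mask.astype(np.uint8) * 255))
        records.append({
            "path": str(img_path), "mask_path": str(mask_path),
            "label": gt.tumor_label, "n_tumors": len(gt.tumor_areas),
            "total_tumor_px": gt.total_tumor_px,
            "seed": config.seed, "index": i,
        })
    manifest = pd.DataFrame.from_records(records)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
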