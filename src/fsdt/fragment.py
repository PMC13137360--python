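"""Cross-sectional fragmentation and per-section pixel-distribution analysis.

A slice is tiled into a regular grid of disjoint rectangular sections
(default 2 rows x 5 cols = 10 sections). Each section yields its intensity
extrema PD_min / PD_max, a 64-bin histogram, binary maps of the pixels
attaining the maximum / minimum representation criteria, and an uncertainty
score un_c — the intensity range normalized by the bit-depth scale. From
these, two replicated views of every section are built: the
minimum-referenced view P, (I - PD_min) / range, and the maximum-referenced
view Q, (PD_max - I) / range. A section whose Q view is identically zero and
whose uncertainty is zero carries no usable signal and is discarded
(the Q = 0 rule).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from fsdt.preprocess import ImageSlice

__all__ = [
    "SegmentGrid", "PixelDistribution", "UncertaintyScore",
    "ReplicatedSegments", "PriorDiagnosis",
    "cross_section_segment", "pixel_distribution", "uncertainty",
    "replicate_segments", "monitor_min_representation",
    "HIST_BINS", "DEFAULT_TAIL_FRACTION",
]

logger = logging.getLogger(__name__)

HIST_BINS = 64
DEFAULT_TAIL_FRACTION = 0.05
MIN_SECTION_SIDE = 4

#: a rectangle (row_start, row_end, col_start, col_end), half-open, 0-based
Rect = tuple[int, int, int, int]


@dataclass(frozen=True)
class SegmentGrid:
    """Disjoint rectangular tiling of a slice; sections are row-major."""

    section_bounds: tuple[Rect, ...]
    rows: int
    cols: int
    source_shape: tuple[int, int]

    @property
    def n_sections(self) -> int:
        return self.rows * self.cols

    def coverage_raster(self) -> np.ndarray:
        """Count, per pixel, how many sections claim it (1 everywhere iff valid)."""
        cov = np.zeros(self.source_shape, dtype=np.int64)
        for r0, r1, c0, c1 in self.section_bounds:
            cov[r0:r1, c0:c1] += 1
        return cov


@dataclass(frozen=True)
class PixelDistribution:
    """Per-section intensity statistics.

    ``x_map`` marks pixels attaining the maximum-representation criterion
    (within ``tail_fraction * range`` of PD_max); ``y_map`` the
    minimum-representation criterion. For a constant section both maps are
    defined empty.
    """

    pd_min: float
    pd_max: float
    histogram: np.ndarray
    x_map: np.ndarray
    y_map: np.ndarray
    section_id: int

    def __post_init__(self) -> None:
        if self.pd_min > self.pd_max:
            raise ValueError(f"pd_min {self.pd_min} > pd_max {self.pd_max}")
        if np.logical_and(self.x_map, self.y_map).any():
            raise ValueError("a pixel cannot be both max- and min-classified")

    @property
    def value_range(self) -> float:
        return self.pd_max - self.pd_min


@dataclass(frozen=True)
class UncertaintyScore:
    """Normalized intensity range of one section, in [0, 1]."""

    un_c: float
    section_id: int


@dataclass(frozen=True)
class ReplicatedSegments:
    """The P (min-referenced) and Q (max-referenced) views of every retained
    section, plus the ids removed by the Q = 0 rule."""

    p_set: tuple[np.ndarray, ...]
    q_set: tuple[np.ndarray, ...]
    section_ids: tuple[int, ...]
    discarded_ids: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.p_set) != len(self.q_set) or len(self.p_set) != len(self.section_ids):
            raise ValueError("p_set, q_set and section_ids must align")


@dataclass
class PriorDiagnosis:
    """Ordered earlier detection results for the same subject (may be empty)."""

    previous_results: list = field(default_factory=list)

    @property
    def sequence_length(self) -> int:
        return len(self.previous_results)


def cross_section_segment(image: ImageSlice, rows: int = 2, cols: int = 5) -> SegmentGrid:
    """Tile the slice into ``rows x cols`` disjoint rectangles.

    Division remainders are absorbed by the last row / column of sections, so
    the union covers every pixel exactly once. Each section must be at least
    4 x 4 pixels.
    """
    h, w = image.shape
    if rows < 1 or cols < 1:
        raise ValueError("rows and cols must be >= 1")
    if h // rows < MIN_SECTION_SIDE or w // cols < MIN_SECTION_SIDE:
        raise ValueError(
            f"grid {rows}x{cols} on shape {image.shape} yields sections "
            f"smaller than {MIN_SECTION_SIDE}x{MIN_SECTION_SIDE}")
    rh, cw = h // rows, w // cols
    bounds: list[Rect] = []
    for i in range(rows):
        r0 = i * rh
        r1 = (i + 1) * rh if i < rows - 1 else h
        for j in range(cols):
            c0 = j * cw
            c1 = (j + 1) * cw if j < cols - 1 else w
            bounds.append((r0, r1, c0, c1))
    return SegmentGrid(tuple(bounds), rows=rows, cols=cols, source_shape=(h, w))


def pixel_distribution(image: ImageSlice, section: Rect, section_id: int = 0,
                       tail_fraction: float = DEFAULT_TAIL_FRACTION) -> PixelDistribution:
    """Exact extrema, 64-bin histogram and min/max representation maps of a section.

    The histogram bins span the full bit-depth range ``[0, 2**bit_depth - 1]``
    so bins are comparable across sections and images.
    """
    r0, r1, c0, c1 = section
    if r1 <= r0 or c1 <= c0:
        raise ValueError(f"empty section {section}")
    h, w = image.shape
    if r0 < 0 or c0 < 0 or r1 > h or c1 > w:
        raise ValueError(f"section {section} outside image of shape {image.shape}")
    block = image.pixels[r0:r1, c0:c1]
    pd_min = float(block.min())
    pd_max = float(block.max())
    hist, _ = np.histogram(block, bins=HIST_BINS, range=(0.0, image.intensity_max + 1.0))
    rng = pd_max - pd_min
    if rng == 0.0:
        x_map = np.zeros(block.shape, dtype=bool)
        y_map = np.zeros(block.shape, dtype=bool)
    else:
        x_map = block >= pd_max - tail_fraction * rng
        y_map = block <= pd_min + tail_fraction * rng
        overlap = x_map & y_map  # can only happen for pathological tail fractions
        x_map = x_map & ~overlap
        y_map = y_map & ~overlap
    return PixelDistribution(pd_min=pd_min, pd_max=pd_max, histogram=hist,
                             x_map=x_map, y_map=y_map, section_id=section_id)


def uncertainty(pd: PixelDistribution, bit_depth: int = 8) -> UncertaintyScore:
    """un_c = (PD_max - PD_min) / (2**bit_depth - 1), clamped to [0, 1].

    Zero iff the section is constant; monotone in the intensity range.
    """
    if bit_depth not in (8, 16):
        raise ValueError(f"bit_depth must be 8 or 16, got {bit_depth}")
    scale = float(2 ** bit_depth - 1)
    un_c = min(max(pd.value_range / scale, 0.0), 1.0)
    return UncertaintyScore(un_c=un_c, section_id=pd.section_id)


def replicate_segments(grid: SegmentGrid, image: ImageSlice,
                       pds: list[PixelDistribution]) -> ReplicatedSegments:
    """Build the P (min-referenced) and Q (max-referenced) views per section.

    P = (I - PD_min) / range and Q = (PD_max - I) / range, both in [0, 1];
    a zero-range section yields all-zero views. Sections whose Q view is
    identically zero *and* whose uncertainty is zero are moved to
    ``discarded_ids`` — the Q = 0 rule: such sections are constant and carry
    no distributional signal.
    """
    if len(pds) != grid.n_sections:
        raise ValueError(f"expected {grid.n_sections} distributions, got {len(pds)}")
    p_set: list[np.ndarray] = []
    q_set: list[np.ndarray] = []
    kept: list[int] = []
    discarded: list[int] = []
    for sec_id, (bounds, pd) in enumerate(zip(grid.section_bounds, pds)):
        r0, r1, c0, c1 = bounds
        block = image.pixels[r0:r1, c0:c1]
        rng = pd.value_range
        if rng == 0.0:
            discarded.append(sec_id)
            continue
        p_set.append((block - pd.pd_min) / rng)
        q_set.append((pd.pd_max - block) / rng)
        kept.append(sec_id)
    return ReplicatedSegments(p_set=tuple(p_set), q_set=tuple(q_set),
                              section_ids=tuple(kept), discarded_ids=tuple(discarded))


def monitor_min_representation(reps: ReplicatedSegments,
                               floor_per_pixel: float = 1e-6) -> list[int]:
    """Flag retained sections whose Q-view mass is dangerously low.

    A retained section is at risk of degenerating to Q = 0 when the sum of
    its max-referenced view falls below ``floor_per_pixel`` times its pixel
    count (i.e. the section is almost entirely at its own maximum). Flagged
    sections are kept but logged so a caller can audit near-degenerate data.
    """
    flagged: list[int] = []
    for sec_id, q in zip(reps.section_ids, reps.q_set):
        if float(q.sum()) < floor_per_pixel * q.size:
            flagged.append(sec_id)
            logger.warning("section %d near Q=0: max-view mass %.3g", sec_id, q.sum())
    return flagged
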