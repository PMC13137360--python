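"""The 17-element per-section feature vector.

The vector is the package's canonical training-regime description of a
section; its order is frozen (see :data:`FEATURE_NAMES`) so exported
matrices are reproducible. It combines the pixel-distribution statistics
that drive the uncertainty gating (entries 1-8) with summaries of every
pre-processing map (entries 9-14) and a brightness/location triple computed
against a global intensity threshold (entries 15-17).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from fsdt.fragment import PixelDistribution, Rect, SegmentGrid, ReplicatedSegments
from fsdt.preprocess import FeatureMaps

__all__ = ["SegmentFeatures", "FEATURE_NAMES", "extract_features", "feature_matrix"]

FEATURE_NAMES: tuple[str, ...] = (
    "pd_min", "pd_max", "range", "mean", "std", "median",
    "entropy", "skewness",
    "mean_edge", "mean_contrast_h", "std_contrast_h",
    "mean_contrast_v", "std_contrast_v", "mean_grad_mag",
    "bright_fraction", "bright_centroid_row", "bright_centroid_col",
)


@dataclass(frozen=True)
class SegmentFeatures:
    """Ordered 17-vector for one section; ``vector[2] == vector[1] - vector[0]``."""

    vector: np.ndarray
    section_id: int

    def __post_init__(self) -> None:
        v = np.asarray(self.vector, dtype=np.float64)
        object.__setattr__(self, "vector", v)
        if v.shape != (17,):
            raise ValueError(f"feature vector must have length 17, got {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ValueError("feature vector contains non-finite entries")


def _entropy_bits(hist: np.ndarray) -> float:
    """Shannon entropy (base 2) of a count histogram; 0 for a single bin."""
    total = hist.sum()
    if total == 0:
        return 0.0
    p = hist[hist > 0] / total
    return float(-(p * np.log2(p)).sum())


def _skewness(values: np.ndarray) -> float:
    """Population skewness; 0 for a zero-variance section."""
    mu = values.mean()
    sd = values.std()
    if sd == 0.0:
        return 0.0
    return float(((values - mu) ** 3).mean() / sd ** 3)


def extract_features(section: Rect, maps: FeatureMaps, pd: PixelDistribution,
                     global_threshold: float) -> SegmentFeatures:
    """Compute the 17-feature vector of one section.

    ``global_threshold`` is the per-image bright threshold (see
    :func:`fsdt.detect.global_bright_threshold`); bright-pixel fraction and
    centroid are measured against it. Degenerate (constant) sections get
    entropy 0, skewness 0 and a centered centroid.
    """
    r0, r1, c0, c1 = section
    h, w = maps.denoised.shape
    if r0 < 0 or c0 < 0 or r1 > h or c1 > w or r1 <= r0 or c1 <= c0:
        raise ValueError(f"section {section} outside image of shape {(h, w)}")
    block = maps.denoised.pixels[r0:r1, c0:c1]

    bright = block > global_threshold
    n_bright = int(bright.sum())
    if n_bright == 0:
        centroid_r, centroid_c = 0.5, 0.5
    else:
        rr, cc = np.nonzero(bright)
        side_r = max(block.shape[0] - 1, 1)
        side_c = max(block.shape[1] - 1, 1)
        centroid_r = float(rr.mean() / side_r)
        centroid_c = float(cc.mean() / side_c)

    vector = np.array([
        pd.pd_min,
        pd.pd_max,
        pd.pd_max - pd.pd_min,
        block.mean(),
        block.std(),                      # population std: sections are full populations
        float(np.median(block)),
        _entropy_bits(pd.histogram),
        _skewness(block),
        maps.edge[r0:r1, c0:c1].mean(),
        maps.contrast_h[r0:r1, c0:c1].mean(),
        maps.contrast_h[r0:r1, c0:c1].std(),
        maps.contrast_v[r0:r1, c0:c1].mean(),
        maps.contrast_v[r0:r1, c0:c1].std(),
        maps.grad_mag[r0:r1, c0:c1].mean(),
        n_bright / block.size,
        centroid_r,
        centroid_c,
    ])
    return SegmentFeatures(vector=vector, section_id=pd.section_id)


def feature_matrix(grid: SegmentGrid, maps: FeatureMaps,
                   pds: list[PixelDistribution], global_threshold: float,
                   reps: ReplicatedSegments | None = None,
                   ) -> tuple[np.ndarray, list[int]]:
    """Stack per-section features into an S x 17 matrix.

    When ``reps`` is given, rows cover only the retained sections (the Q = 0
    discards are excluded); otherwise all sections appear. Returns the matrix
    and the section ids of its rows, in order.
    """
    if len(pds) != grid.n_sections:
        raise ValueError(f"expected {grid.n_sections} distributions, got {len(pds)}")
    keep = set(reps.section_ids) if reps is not None else None
    rows: list[np.ndarray] = []
    ids: list[int] = []
    for sec_id, (bounds, pd) in enumerate(zip(grid.section_bounds, pds)):
        if keep is not None and sec_id not in keep:
            continue
        feats = extract_features(bounds, maps, pd, global_threshold)
        rows.append(feats.vector)
        ids.append(sec_id)
    matrix = np.vstack(rows) if rows else np.empty((0, 17))
    return matrix, ids
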