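"""End-to-end orchestration: build section-level training data from labelled
slices, train the classifier, and evaluate detection over an image set.

Section training labels come from the ground-truth masks: a retained section
is a positive example when at least ``min_overlap_px`` of its pixels are
tumor. Image-level evaluation compares the pipeline's presence verdict
(delta) with the manifest label and, on true positives, the estimated size
omega with the mask area.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from fsdt.cnn import ModelConfig, SegmentCNN, TrainingRecord, build_model, train
from fsdt.config import PipelineConfig
from fsdt.detect import DetectionResult, detect_image
from fsdt.fragment import cross_section_segment, pixel_distribution, replicate_segments
from fsdt.metrics import MetricReport, analysis_ratio, compute_metrics, confusion
from fsdt.phantom import PhantomConfig, generate_phantom
from fsdt.preprocess import ImageSlice, compute_feature_maps

__all__ = [
    "section_training_data", "train_sections", "evaluate_images",
    "phantom_suite", "EvaluationSummary",
]


@dataclass
class EvaluationSummary:
    """Image-level evaluation over a set of slices."""

    results: list[DetectionResult]
    report: MetricReport
    size_errors: list[float]          # |omega - truth| / truth on true positives
    median_size_error: float | None
    rho_e_mean: float


def section_training_data(images: list[ImageSlice], masks: list[np.ndarray],
                          config: PipelineConfig):
    """Extract (P, Q, label) triples for every retained section of every image.

    Returns ``(p_set, q_set, labels)`` with labels 1 where the section
    overlaps its mask by at least ``config.min_overlap_px`` pixels.
    """
    p_set, q_set, labels = [], [], []
    for image, mask in zip(images, masks):
        maps = compute_feature_maps(image, method=config.denoise_method,
                                    radius=config.denoise_radius)
        work = maps.denoised
        grid = cross_section_segment(work, rows=config.grid_rows, cols=config.grid_cols)
        pds = [pixel_distribution(work, b, section_id=i,
                                  tail_fraction=config.tail_fraction)
               for i, b in enumerate(grid.section_bounds)]
        reps = replicate_segments(grid, work, pds)
        for p, q, sec_id in zip(reps.p_set, reps.q_set, reps.section_ids):
            r0, r1, c0, c1 = grid.section_bounds[sec_id]
            overlap = int(mask[r0:r1, c0:c1].sum())
            p_set.append(p)
            q_set.append(q)
            labels.append(int(overlap >= config.min_overlap_px))
    return p_set, q_set, np.asarray(labels, dtype=int)


def train_sections(p_set, q_set, labels,
                   model_config: ModelConfig) -> tuple[SegmentCNN, TrainingRecord]:
    """Build a seeded model and train it on the section views."""
    model = build_model(model_config)
    record = train(model, p_set, q_set, labels, model_config)
    return model, record


def evaluate_images(images: list[ImageSlice], truth_labels, truth_areas,
                    model: SegmentCNN, config: PipelineConfig) -> EvaluationSummary:
    """Detect on every image and score against image-level truth.

    ``truth_areas`` are mask pixel counts (0 for tumor-free images); relative
    size errors are collected on true-positive detections only, where both
    omega and the truth are meaningful.
    """
    results: list[DetectionResult] = []
    preds: list[int] = []
    size_errors: list[float] = []
    for i, image in enumerate(images):
        result, _ = detect_image(
            image, model, rows=config.grid_rows, cols=config.grid_cols,
            tau_seg=config.tau_seg, u_floor=config.u_floor,
            theta_img=config.theta_img, denoise_method=config.denoise_method,
            denoise_radius=config.denoise_radius, image_id=str(i))
        results.append(result)
        preds.append(result.delta)
        if result.delta == 1 and truth_labels[i] == 1 and truth_areas[i] > 0:
            size_errors.append(abs(result.omega_px - truth_areas[i]) / truth_areas[i])
    counts = confusion(preds, list(truth_labels), level="image")
    report = compute_metrics(counts)
    report.analysis_ratio = analysis_ratio(results, margin=config.margin)
    report.n_units = len(images)
    median_err = float(np.median(size_errors)) if size_errors else None
    rho_e_mean = float(np.mean([r.rho_e for r in results])) if results else 0.0
    return EvaluationSummary(results=results, report=report,
                             size_errors=size_errors,
                             median_size_error=median_err, rho_e_mean=rho_e_mean)


def phantom_suite(n: int, config: PipelineConfig, seed: int | None = None,
                  index_offset: int = 0):
    """Generate ``n`` balanced phantoms in memory (no files).

    Returns ``(images, masks, labels, areas)``. The tumor-bearing subset is
    exactly ``round(n * tumor_fraction)``, chosen by a seeded shuffle, so the
    class balance is under direct control.
    """
    phantom_cfg: PhantomConfig = config.phantom
    if seed is not None:
        phantom_cfg = replace(phantom_cfg, seed=seed)
    n_pos = round(n * phantom_cfg.tumor_fraction)
    order = np.random.default_rng([phantom_cfg.seed & 0x7FFFFFFF, 0xBA1A]).permutation(n)
    positive = np.zeros(n, dtype=bool)
    positive[order[:n_pos]] = True
    lo, hi = phantom_cfg.tumor_count_range
    pos_range = (max(lo, 1), max(hi, 1))

    images, masks, labels, areas = [], [], [], []
    for i in range(n):
        cfg_i = replace(phantom_cfg,
                        tumor_count_range=pos_range if positive[i] else (0, 0))
        img, gt = generate_phantom(cfg_i, index=index_offset + i)
        images.append(img)
        masks.append(gt.mask)
        labels.append(gt.tumor_label)
        areas.append(gt.total_tumor_px)
    return images, masks, np.asarray(labels), np.asarray(areas)
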