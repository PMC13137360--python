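"""Image-level decision stage: section flagging, presence/reform state,
tumor-size estimation and view-disagreement error probability.

A section is flagged tumor-bearing when its classifier probability reaches
the section threshold AND its uncertainty (normalized intensity range)
reaches a small floor — near-constant sections can never be flagged. The
fraction of retained sections flagged is rho_fd; the image-level state delta
is 1 when rho_fd reaches the image threshold. Tumor size omega counts bright
pixels (above the image's bright threshold) inside flagged sections, with
connected components merged across adjacent flagged sections so a lesion
split by a grid line is counted once. rho_e measures decision instability:
the disagreement rate between a P-view-only and a Q-view-only prediction
pass, obtained by masking the other channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from fsdt.cnn import SegmentCNN, predict_batch
from fsdt.fragment import (
    PriorDiagnosis, cross_section_segment, pixel_distribution,
    replicate_segments, uncertainty,
)
from fsdt.preprocess import ImageSlice, compute_feature_maps

__all__ = [
    "DetectionResult", "SectionDecision", "global_bright_threshold",
    "feature_distribution_probability", "segment_decision", "tumor_size",
    "error_probability", "pixel_arrangement_change", "detect_image",
    "DEFAULT_TAU_SEG", "DEFAULT_U_FLOOR", "DEFAULT_THETA_IMG",
]

DEFAULT_TAU_SEG = 0.5
DEFAULT_U_FLOOR = 0.02
DEFAULT_THETA_IMG = 0.1


@dataclass(frozen=True)
class SectionDecision:
    section_id: int
    probability: float
    decision: int
    un_c: float


@dataclass(frozen=True)
class DetectionResult:
    """Outcome of one slice: flagged fraction, presence state, size, instability."""

    rho_fd: float
    delta: int
    omega_px: int
    omega_physical: float
    rho_e: float
    per_section: tuple[SectionDecision, ...]
    discarded_ids: tuple[int, ...]
    threshold_used: float
    image_id: str = ""

    def to_dict(self) -> dict:
        d = asdict(self)
        d["per_section"] = [asdict(s) for s in self.per_section]
        d["discarded_ids"] = list(self.discarded_ids)
        return d


def global_bright_threshold(image: ImageSlice) -> float:
    """Two-stage Otsu bright threshold for one slice.

    On a brain slice a single Otsu pass separates the dark air background
    from the head, not lesion from tissue; a second pass restricted to the
    supra-threshold (head) pixels places the cut between ordinary tissue and
    the bright end of the distribution. Falls back gracefully for
    low-diversity images (constant image -> threshold at its single value,
    so nothing is strictly brighter).
    """
    px = image.pixels
    if np.unique(px).size < 2:
        return float(px.flat[0])
    t0 = float(threshold_otsu(px))
    head = px[px > t0]
    if head.size < 2 or np.unique(head).size < 2:
        return t0
    return float(threshold_otsu(head))


def segment_decision(prob: float, un_c: float, tau_seg: float = DEFAULT_TAU_SEG,
                     u_floor: float = DEFAULT_U_FLOOR) -> int:
    """1 iff ``prob >= tau_seg`` and ``un_c >= u_floor``; ties flag (>=)."""
    for name, v in (("prob", prob), ("un_c", un_c)):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name}={v} outside [0, 1]")
    return int(prob >= tau_seg and un_c >= u_floor)


def feature_distribution_probability(per_section_probs, un_c,
                                     tau_seg: float = DEFAULT_TAU_SEG,
                                     u_floor: float = DEFAULT_U_FLOOR) -> float:
    """Fraction of retained sections flagged: rho_fd = flagged / retained."""
    probs = list(per_section_probs)
    uncs = list(un_c)
    if len(probs) != len(uncs):
        raise ValueError("probability and uncertainty lists must align")
    if not probs:
        raise ValueError("no retained sections")
    flagged = sum(segment_decision(p, u, tau_seg, u_floor) for p, u in zip(probs, uncs))
    return flagged / len(probs)


def tumor_size(flagged_sections, grid, image: ImageSlice,
               bright_threshold: float | None = None,
               spacing: float | None = None) -> tuple[int, float]:
    """Bright-pixel area (px) within flagged sections, components merged.

    Bright pixels are those above the image's bright threshold. Counting is
    restricted to flagged sections, but a connected bright component is
    counted in full once it touches any flagged section, so a lesion split
    across a grid line is not halved or double-counted. Returns
    ``(area_px, area_physical)`` where the physical area uses ``spacing**2``
    (defaults to the slice's spacing).
    """
    if not flagged_sections:
        return 0, 0.0
    if bright_threshold is None:
        bright_threshold = global_bright_threshold(image)
    bright = image.pixels > bright_threshold
    labels, n_comp = ndimage.label(bright)
    if n_comp == 0:
        return 0, 0.0
    flag_mask = np.zeros(image.shape, dtype=bool)
    for sec_id in flagged_sections:
        r0, r1, c0, c1 = grid.section_bounds[sec_id]
        flag_mask[r0:r1, c0:c1] = True
    touched = np.unique(labels[flag_mask & bright])
    touched = touched[touched > 0]
    area = int(np.isin(labels, touched).sum())
    sp = image.spacing if spacing is None else spacing
    return area, area * sp * sp


def error_probability(p_decisions, q_decisions) -> float:
    """Disagreement rate between P-only and Q-only section decisions."""
    p = list(p_decisions)
    q = list(q_decisions)
    if len(p) != len(q):
        raise ValueError("P-view and Q-view decision lists must align")
    if not p:
        return 0.0
    return float(np.mean([int(a != b) for a, b in zip(p, q)]))


def pixel_arrangement_change(current: DetectionResult,
                             prior: PriorDiagnosis) -> dict:
    """Compare the current section decisions with the latest prior visit.

    Labels every section {stable, new, resolved}; the image-level reform flag
    is raised when any section turned from clear to flagged. With no prior
    visit, flagged sections are labelled "new" and the report carries a
    ``baseline: "none"`` note.
    """
    cur = {s.section_id: s.decision for s in current.per_section}
    if prior.sequence_length == 0:
        transitions = {sid: ("new" if d == 1 else "stable") for sid, d in cur.items()}
        return {"baseline": "none",
                "transitions": transitions,
                "reform": any(d == 1 for d in cur.values())}
    last = prior.previous_results[-1]
    prev = {s.section_id: s.decision for s in last.per_section}
    if set(prev) != set(cur):
        raise ValueError("section geometry differs between visits")
    transitions = {}
    for sid, d in cur.items():
        if d == prev[sid]:
            transitions[sid] = "stable"
        elif d == 1:
            transitions[sid] = "new"
        else:
            transitions[sid] = "resolved"
    return {"baseline": "prior",
            "transitions": transitions,
            "reform": any(v == "new" for v in transitions.values())}


def detect_image(image: ImageSlice, model: SegmentCNN, rows: int = 2, cols: int = 5,
                 tau_seg: float = DEFAULT_TAU_SEG, u_floor: float = DEFAULT_U_FLOOR,
                 theta_img: float = DEFAULT_THETA_IMG,
                 denoise_method: str = "median", denoise_radius: int = 1,
                 prior: PriorDiagnosis | None = None, image_id: str = "",
                 ) -> tuple[DetectionResult, dict | None]:
    """Run the full per-image pipeline and return (result, change_report).

    Stages: pre-processing -> fragmentation -> pixel-distribution statistics
    and uncertainty -> P/Q replication with the Q=0 discard -> classifier
    prediction -> section decisions -> rho_fd / delta / omega / rho_e ->
    optional change report against prior visits. Deterministic for a fixed
    (image, model).
    """
    maps = compute_feature_maps(image, method=denoise_method, radius=denoise_radius)
    work = maps.denoised
    grid = cross_section_segment(work, rows=rows, cols=cols)
    pds = [pixel_distribution(work, b, section_id=i)
           for i, b in enumerate(grid.section_bounds)]
    uncs = {pd.section_id: uncertainty(pd, work.bit_depth).un_c for pd in pds}
    reps = replicate_segments(grid, work, pds)

    if reps.section_ids:
        probs = predict_batch(model, reps.p_set, reps.q_set)
        zero = [np.zeros_like(p) for p in reps.p_set]
        probs_p_only = predict_batch(model, reps.p_set, zero)
        probs_q_only = predict_batch(model, zero, reps.q_set)
    else:
        probs = probs_p_only = probs_q_only = np.empty(0)

    decisions = []
    for sec_id, prob in zip(reps.section_ids, probs):
        decisions.append(SectionDecision(
            section_id=sec_id, probability=float(prob),
            decision=segment_decision(float(prob), uncs[sec_id], tau_seg, u_floor),
            un_c=uncs[sec_id]))

    retained = len(decisions)
    flagged_ids = [d.section_id for d in decisions if d.decision == 1]
    rho_fd = len(flagged_ids) / retained if retained else 0.0
    delta = int(retained > 0 and rho_fd >= theta_img)
    if delta:
        bright_t = global_bright_threshold(work)
        omega_px, omega_phys = tumor_size(flagged_ids, grid, work,
                                          bright_threshold=bright_t)
    else:
        omega_px, omega_phys = 0, 0.0

    p_dec = [segment_decision(float(p), uncs[s], tau_seg, u_floor)
             for s, p in zip(reps.section_ids, probs_p_only)]
    q_dec = [segment_decision(float(p), uncs[s], tau_seg, u_floor)
             for s, p in zip(reps.section_ids, probs_q_only)]
    rho_e = error_probability(p_dec, q_dec)

    result = DetectionResult(
        rho_fd=rho_fd, delta=delta, omega_px=omega_px, omega_physical=omega_phys,
        rho_e=rho_e, per_section=tuple(decisions),
        discarded_ids=reps.discarded_ids, threshold_used=tau_seg, image_id=image_id)
    change = pixel_arrangement_change(result, prior) if prior is not None else None
    return result, change
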