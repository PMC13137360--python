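"""Decision stage: flagging rules, size estimation, change tracking,
and the end-to-end seeded detection run on phantoms."""

import dataclasses

import numpy as np
import pytest

from fsdt.detect import (
    DetectionResult, SectionDecision, detect_image, error_probability,
    feature_distribution_probability, global_bright_threshold,
    pixel_arrangement_change, segment_decision, tumor_size,
)
from fsdt.fragment import PriorDiagnosis, cross_section_segment
from fsdt.phantom import PhantomConfig, generate_phantom
from fsdt.preprocess import ImageSlice


def _slice(arr, **kw):
    return ImageSlice(np.asarray(arr, dtype=float), **kw)


class TestSegmentDecision:
    @pytest.mark.parametrize("prob,un_c,expected", [
        (0.9, 0.5, 1),
        (0.9, 0.0, 0),     # degenerate section suppressed by the floor
        (0.5, 0.5, 1),     # tie at the threshold flags
        (0.49, 0.5, 0),
        (0.9, 0.02, 1),    # tie at the uncertainty floor flags
    ])
    def test_rule(self, prob, un_c, expected):
        assert segment_decision(prob, un_c) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            segment_decision(1.2, 0.5)


class TestFeatureDistributionProbability:
    def test_none_flagged(self):
        assert feature_distribution_probability([0.1] * 10, [0.5] * 10) == 0.0

    def test_all_flagged(self):
        assert feature_distribution_probability([0.9] * 10, [0.5] * 10) == 1.0

    def test_counting(self):
        probs = [0.9, 0.8, 0.7] + [0.1] * 7
        assert feature_distribution_probability(probs, [0.5] * 10) == pytest.approx(0.3)

    def test_matches_naive_counter(self):
        rng = np.random.default_rng(0)
        probs = rng.uniform(0, 1, 25)
        uncs = rng.uniform(0, 1, 25)
        flagged = 0
        for p, u in zip(probs, uncs):
            if p >= 0.5 and u >= 0.02:
                flagged += 1
        assert feature_distribution_probability(probs, uncs) == flagged / 25

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(1)
        probs = rng.uniform(0, 1, 40)
        uncs = rng.uniform(0.1, 1, 40)
        values = [feature_distribution_probability(probs, uncs, tau_seg=t)
                  for t in (0.2, 0.4, 0.6, 0.8)]
        assert values == sorted(values, reverse=True)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            feature_distribution_probability([], [])


class TestTumorSize:
    def _image_with_disc(self, center, r=8):
        px = np.full((60, 100), 50.0)
        yy, xx = np.mgrid[0:60, 0:100]
        disc = (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= r ** 2
        px[disc] = 220.0
        return _slice(px), disc

    def test_no_flagged_sections_zero(self):
        img, _ = self._image_with_disc((30, 25))
        grid = cross_section_segment(img, 2, 5)
        assert tumor_size([], grid, img) == (0, 0.0)

    def test_disc_in_one_section_counted_exactly(self):
        img, disc = self._image_with_disc((15, 10), r=6)
        grid = cross_section_segment(img, 2, 5)     # sections 30x20
        omega, _ = tumor_size([0], grid, img, bright_threshold=127.0)
        assert omega == int(disc.sum())

    def test_split_disc_merged_not_double_counted(self):
        # disc centered on the boundary between sections 0 and 1 (col 20)
        img, disc = self._image_with_disc((15, 20), r=6)
        grid = cross_section_segment(img, 2, 5)
        both, _ = tumor_size([0, 1], grid, img, bright_threshold=127.0)
        assert both == int(disc.sum())
        # a single flagged section still pulls in the whole merged component
        one, _ = tumor_size([0], grid, img, bright_threshold=127.0)
        assert one == int(disc.sum())

    def test_physical_units_use_spacing(self):
        img, disc = self._image_with_disc((15, 10), r=5)
        img = _slice(img.pixels)
        grid = cross_section_segment(img, 2, 5)
        _, phys = tumor_size([0], grid, img, bright_threshold=127.0, spacing=0.5)
        assert phys == pytest.approx(int(disc.sum()) * 0.25)


class TestErrorProbability:
    def test_identical_zero(self):
        assert error_probability([1, 0, 1], [1, 0, 1]) == 0.0

    def test_partial_disagreement(self):
        assert error_probability([1, 1, 0, 0, 1, 0, 0, 0, 0, 0],
                                 [1, 0, 1, 0, 1, 0, 0, 0, 0, 0]) == pytest.approx(0.2)

    def test_complete_disagreement(self):
        assert error_probability([1, 1, 1], [0, 0, 0]) == 1.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            error_probability([1], [1, 0])


def _result_with(decisions):
    sections = tuple(SectionDecision(i, 0.9 if d else 0.1, d, 0.5)
                     for i, d in enumerate(decisions))
    rho = sum(decisions) / len(decisions)
    return DetectionResult(rho_fd=rho, delta=int(rho > 0), omega_px=0,
                           omega_physical=0.0, rho_e=0.0, per_section=sections,
                           discarded_ids=(), threshold_used=0.5)


class TestPixelArrangementChange:
    def test_identical_visits_all_stable(self):
        r = _result_with([0, 1, 0, 1])
        report = pixel_arrangement_change(r, PriorDiagnosis([r]))
        assert set(report["transitions"].values()) == {"stable"}
        assert report["reform"] is False

    def test_new_sections_raise_reform(self):
        prior = _result_with([0, 0, 0, 0])
        current = _result_with([0, 1, 1, 0])
        report = pixel_arrangement_change(current, PriorDiagnosis([prior]))
        assert list(report["transitions"].values()).count("new") == 2
        assert report["reform"] is True

    def test_resolved_sections_mean_cured(self):
        prior = _result_with([0, 1, 1, 0])
        current = _result_with([0, 0, 0, 0])
        report = pixel_arrangement_change(current, PriorDiagnosis([prior]))
        assert list(report["transitions"].values()).count("resolved") == 2
        assert report["reform"] is False
        assert current.delta == 0

    def test_empty_prior_notes_no_baseline(self):
        report = pixel_arrangement_change(_result_with([1, 0]), PriorDiagnosis())
        assert report["baseline"] == "none"
        assert report["transitions"][0] == "new"

    def test_geometry_mismatch_rejected(self):
        with pytest.raises(ValueError):
            pixel_arrangement_change(_result_with([1, 0]),
                                     PriorDiagnosis([_result_with([1, 0, 0])]))


class TestGlobalBrightThreshold:
    def test_constant_image(self):
        t = global_bright_threshold(_slice(np.full((16, 16), 80.0)))
        assert t == 80.0

    def test_separates_tumor_from_tissue_on_phantom(self):
        cfg = PhantomConfig(seed=6, tumor_count_range=(1, 1))
        img, gt = generate_phantom(cfg, 0)
        t = global_bright_threshold(img)
        assert t > cfg.tissue_mean              # above typical tissue
        assert img.pixels[gt.mask].mean() > t   # tumors are mostly brighter


class TestDetectImage:
    def test_tumor_free_phantom_clear(self, pipeline_config, trained_model):
        model, _ = trained_model
        cfg = PhantomConfig(seed=21, tumor_count_range=(0, 0))
        img, _ = generate_phantom(cfg, 0)
        result, _ = detect_image(img, model)
        assert result.delta == 0 and result.omega_px == 0

    def test_tumor_phantom_detected_and_sized(self, trained_model):
        model, _ = trained_model
        cfg = PhantomConfig(seed=22, tumor_count_range=(1, 1),
                            tumor_radius_range=(8.0, 8.0))
        img, gt = generate_phantom(cfg, 1)
        result, _ = detect_image(img, model)
        assert result.delta == 1
        assert result.omega_px == pytest.approx(gt.total_tumor_px, rel=0.2)

    def test_rerun_bit_identical(self, trained_model):
        model, _ = trained_model
        img, _ = generate_phantom(PhantomConfig(seed=23), 2)
        r1, _ = detect_image(img, model)
        r2, _ = detect_image(img, model)
        assert r1 == r2

    def test_invariant_ranges(self, trained_model):
        model, _ = trained_model
        for index in range(4):
            img, _ = generate_phantom(PhantomConfig(seed=24), index)
            r, _ = detect_image(img, model)
            assert 0.0 <= r.rho_fd <= 1.0 and 0.0 <= r.rho_e <= 1.0
            assert r.omega_px >= 0
            if r.delta == 0:
                assert r.omega_px == 0
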