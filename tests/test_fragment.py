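"""Grid tiling, pixel-distribution statistics, uncertainty and P/Q views."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fsdt.fragment import (
    cross_section_segment, monitor_min_representation, pixel_distribution,
    replicate_segments, uncertainty,
)
from fsdt.preprocess import ImageSlice


def _slice(arr, **kw):
    return ImageSlice(np.asarray(arr, dtype=float), **kw)


def _rand_image(rng, h, w):
    return _slice(rng.integers(0, 256, size=(h, w)).astype(float))


class TestCrossSectionSegment:
    def test_even_division(self):
        grid = cross_section_segment(_slice(np.zeros((100, 100))), 2, 5)
        assert grid.n_sections == 10
        for r0, r1, c0, c1 in grid.section_bounds:
            assert (r1 - r0, c1 - c0) == (50, 20)

    def test_remainder_absorbed_by_last_row_col(self):
        grid = cross_section_segment(_slice(np.zeros((101, 103))), 2, 5)
        heights = {b[1] - b[0] for b in grid.section_bounds}
        widths = {b[3] - b[2] for b in grid.section_bounds}
        assert heights == {50, 51} and widths == {20, 23}
        assert (grid.coverage_raster() == 1).all()

    def test_identity_tiling(self):
        grid = cross_section_segment(_slice(np.zeros((30, 40))), 1, 1)
        assert grid.section_bounds == ((0, 30, 0, 40),)

    def test_too_small_sections_rejected(self):
        with pytest.raises(ValueError):
            cross_section_segment(_slice(np.zeros((10, 10))), 3, 3)

    @settings(max_examples=20, deadline=None)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_tiling_conservation(self, seed):
        """Every pixel belongs to exactly one section for random shapes/grids."""
        rng = np.random.default_rng(seed)
        h, w = int(rng.integers(16, 200)), int(rng.integers(16, 200))
        rows = int(rng.integers(1, max(2, h // 4)))
        cols = int(rng.integers(1, max(2, w // 4)))
        if h // rows < 4 or w // cols < 4:
            rows, cols = 2, 2
        grid = cross_section_segment(_slice(np.zeros((h, w))), rows, cols)
        assert (grid.coverage_raster() == 1).all()


class TestPixelDistribution:
    def test_constant_section_degenerate_maps(self):
        pd = pixel_distribution(_slice(np.full((8, 8), 10.0)), (0, 8, 0, 8))
        assert pd.pd_min == pd.pd_max == 10.0
        assert not pd.x_map.any() and not pd.y_map.any()

    def test_exact_extrema(self):
        px = np.zeros((8, 8))
        px[0, 0], px[0, 1], px[1, 0], px[1, 1] = 0, 255, 128, 64
        pd = pixel_distribution(_slice(px), (0, 2, 0, 2))
        assert (pd.pd_min, pd.pd_max) == (0.0, 255.0)

    def test_histogram_counts_conserve(self):
        rng = np.random.default_rng(4)
        img = _rand_image(rng, 20, 30)
        pd = pixel_distribution(img, (3, 17, 5, 25))
        assert pd.histogram.sum() == 14 * 20

    def test_xy_maps_disjoint_and_extremes_marked(self):
        rng = np.random.default_rng(5)
        img = _rand_image(rng, 16, 16)
        pd = pixel_distribution(img, (0, 16, 0, 16))
        block = img.pixels
        assert pd.x_map[block == pd.pd_max].all()
        assert pd.y_map[block == pd.pd_min].all()
        assert not (pd.x_map & pd.y_map).any()

    def test_empty_or_outside_section_rejected(self):
        img = _slice(np.zeros((10, 10)))
        with pytest.raises(ValueError):
            pixel_distribution(img, (5, 5, 0, 10))
        with pytest.raises(ValueError):
            pixel_distribution(img, (0, 12, 0, 10))

    @pytest.mark.parametrize("seed", range(5))
    def test_extrema_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        img = _rand_image(rng, 32, 32)
        grid = cross_section_segment(img, 4, 4)
        for i, (r0, r1, c0, c1) in enumerate(grid.section_bounds):
            pd = pixel_distribution(img, (r0, r1, c0, c1), section_id=i)
            lo, hi = np.inf, -np.inf
            for r in range(r0, r1):
                for c in range(c0, c1):
                    lo = min(lo, img.pixels[r, c])
                    hi = max(hi, img.pixels[r, c])
            assert (pd.pd_min, pd.pd_max) == (lo, hi)


class TestUncertainty:
    def test_constant_zero(self):
        pd = pixel_distribution(_slice(np.full((8, 8), 3.0)), (0, 8, 0, 8))
        assert uncertainty(pd, 8).un_c == 0.0

    def test_full_range_is_one(self):
        px = np.zeros((8, 8))
        px[0, 0] = 255.0
        pd = pixel_distribution(_slice(px), (0, 8, 0, 8))
        assert uncertainty(pd, 8).un_c == 1.0

    def test_formula_value(self):
        px = np.full((8, 8), 50.0)
        px[3, 3] = 150.0
        pd = pixel_distribution(_slice(px), (0, 8, 0, 8))
        assert uncertainty(pd, 8).un_c == pytest.approx(100 / 255)

    def test_monotone_in_range(self):
        scores = []
        for hi in (60.0, 120.0, 240.0):
            px = np.full((8, 8), 50.0)
            px[0, 0] = hi
            pd = pixel_distribution(_slice(px), (0, 8, 0, 8))
            scores.append(uncertainty(pd, 8).un_c)
        assert scores == sorted(scores)

    def test_bit_depth_16_scale(self):
        px = np.full((8, 8), 0.0)
        px[0, 0] = 65535.0
        pd = pixel_distribution(_slice(px, bit_depth=16), (0, 8, 0, 8))
        assert uncertainty(pd, 16).un_c == 1.0


class TestReplicateSegments:
    def _grid_pds(self, img, rows=2, cols=2):
        grid = cross_section_segment(img, rows, cols)
        pds = [pixel_distribution(img, b, section_id=i)
               for i, b in enumerate(grid.section_bounds)]
        return grid, pds

    def test_constant_section_discarded(self):
        px = np.zeros((16, 16))
        px[8:, :] = np.random.default_rng(0).integers(1, 255, (8, 16))
        img = _slice(px)
        grid, pds = self._grid_pds(img, 2, 2)
        reps = replicate_segments(grid, img, pds)
        assert 0 in reps.discarded_ids and 1 in reps.discarded_ids
        assert len(reps.p_set) + len(reps.discarded_ids) == grid.n_sections

    def test_views_normalized_to_unit_interval(self):
        rng = np.random.default_rng(6)
        img = _rand_image(rng, 16, 16)
        grid, pds = self._grid_pds(img)
        reps = replicate_segments(grid, img, pds)
        for p, q in zip(reps.p_set, reps.q_set):
            assert p.min() == 0.0 and p.max() == 1.0
            assert np.allclose(p + q, 1.0)

    def test_mismatched_lengths_rejected(self):
        rng = np.random.default_rng(7)
        img = _rand_image(rng, 16, 16)
        grid, pds = self._grid_pds(img)
        with pytest.raises(ValueError):
            replicate_segments(grid, img, pds[:-1])


class TestMonitorMinRepresentation:
    def test_textured_phantom_unflagged(self):
        from fsdt.phantom import PhantomConfig, generate_phantom

        img, _ = generate_phantom(PhantomConfig(seed=8), 0)
        grid = cross_section_segment(img, 2, 5)
        pds = [pixel_distribution(img, b, section_id=i)
               for i, b in enumerate(grid.section_bounds)]
        reps = replicate_segments(grid, img, pds)
        assert monitor_min_representation(reps) == []

    def test_near_maximal_section_flagged(self):
        # a section almost entirely at its own maximum has near-zero Q mass
        px = np.full((8, 16), 200.0)
        px[0, 0] = 199.9999
        img = _slice(px)
        grid = cross_section_segment(img, 1, 2)
        pds = [pixel_distribution(img, b, section_id=i)
               for i, b in enumerate(grid.section_bounds)]
        reps = replicate_segments(grid, img, pds)
        flagged = monitor_min_representation(reps, floor_per_pixel=0.05)
        assert 0 in flagged
        assert set(flagged) <= set(reps.section_ids)
        assert not set(flagged) & set(reps.discarded_ids)
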