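"""Watershed partitioning and full-lambda-schedule merging."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from geobia.raster import Raster
from geobia.segmentation import (
    AdjacencyEdge,
    SegmentMap,
    boundary_lengths,
    build_hierarchy,
    full_lambda_merge,
    lambda_cost,
    region_stats,
    validate_partition,
    watershed_segment,
)

from helpers import greedy_merge_oracle, random_voronoi_partition, smooth_random_raster


def two_pit_surface(size=64):
    rows, cols = np.mgrid[0:size, 0:size].astype(float)
    pit1 = -2.0 * np.exp(-(((rows - 32) ** 2 + (cols - 16) ** 2)) / 40.0)
    pit2 = -2.0 * np.exp(-(((rows - 32) ** 2 + (cols - 48) ** 2)) / 40.0)
    return Raster(pit1 + pit2)


class TestWatershed:
    def test_constant_image_yields_single_segment(self):
        seg = watershed_segment(Raster(np.full((32, 32), 1.5)), scale=50.0)
        assert seg.n_segments == 1
        validate_partition(seg)

    def test_two_pits_give_two_basins_split_on_the_ridge(self):
        surface = two_pit_surface()
        seg = watershed_segment(surface, scale=0.0)
        assert seg.n_segments == 2
        validate_partition(seg)
        # the boundary column between the pits must sit on the ridge crest
        labels = seg.labels
        row = labels[32, :]
        change = np.where(row[:-1] != row[1:])[0]
        assert len(change) == 1
        boundary_col = int(change[0])
        profile = surface.values[32, :]
        # ridge crest = maximum of the inter-pit profile
        crest = 16 + int(np.argmax(profile[16:49]))
        assert abs(boundary_col - crest) <= 1

    def test_segment_count_monotone_in_scale(self, rng):
        img = smooth_random_raster(rng, 48)
        counts = [
            watershed_segment(img, s).n_segments for s in (0, 20, 40, 60, 80, 100)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))
        assert counts[0] > counts[-1]

    def test_scale_outside_range_rejected(self):
        with pytest.raises(ValueError):
            watershed_segment(Raster(np.zeros((32, 32))), scale=101.0)


class TestLambdaCost:
    def test_identical_means_cost_zero(self):
        e = AdjacencyEdge(1, 2, 5, np.array([3.0, 1.0]), np.array([3.0, 1.0]))
        assert lambda_cost(e, (10, 99)) == 0.0

    def test_worked_four_pixel_example(self):
        # |Oi|=|Oj|=2, means 10 and 12, shared boundary 2 -> (1*4)/2 = 2.0
        e = AdjacencyEdge(1, 2, 2, np.array([10.0]), np.array([12.0]))
        assert lambda_cost(e, (2, 2)) == pytest.approx(2.0)

    def test_algebraic_scaling_in_boundary_and_area(self):
        e1 = AdjacencyEdge(1, 2, 2, np.array([10.0]), np.array([12.0]))
        e2 = AdjacencyEdge(1, 2, 4, np.array([10.0]), np.array([12.0]))
        assert lambda_cost(e2, (2, 2)) == pytest.approx(
            lambda_cost(e1, (2, 2)) / 2
        )
        assert lambda_cost(e1, (4, 4)) == pytest.approx(
            2 * lambda_cost(e1, (2, 2))
        )

    @settings(max_examples=100, derandomize=True)
    @given(
        ai=st.integers(1, 10_000),
        aj=st.integers(1, 10_000),
        length=st.integers(1, 500),
        ui=st.floats(-100, 100),
        uj=st.floats(-100, 100),
    )
    def test_cost_nonnegative_and_symmetric(self, ai, aj, length, ui, uj):
        e = AdjacencyEdge(1, 2, length, np.array([ui]), np.array([uj]))
        e_swapped = AdjacencyEdge(2, 1, length, np.array([uj]), np.array([ui]))
        t = lambda_cost(e, (ai, aj))
        assert t >= 0.0
        assert t == pytest.approx(lambda_cost(e_swapped, (aj, ai)))

    def test_zero_boundary_rejected(self):
        e = AdjacencyEdge(1, 2, 0, np.array([1.0]), np.array([2.0]))
        with pytest.raises(ValueError):
            lambda_cost(e, (1, 1))


def checkerboard_partition():
    labels = np.array(
        [
            [1, 1, 2, 2],
            [1, 1, 2, 2],
            [3, 3, 4, 4],
            [3, 3, 4, 4],
        ],
        dtype=np.int32,
    )
    return SegmentMap(labels)


class TestFullLambdaMerge:
    def test_identical_means_merge_at_any_positive_level(self):
        seg = checkerboard_partition()
        layer = Raster(np.ones((4, 4)))
        merged = full_lambda_merge(seg, [layer], merge_level=50.0)
        assert merged.n_segments == 1

    def test_level_zero_changes_nothing(self, rng):
        seg = checkerboard_partition()
        layer = Raster(rng.uniform(0, 1, (4, 4)))
        merged = full_lambda_merge(seg, [layer], merge_level=0.0)
        assert np.array_equal(merged.labels, seg.labels)

    def test_level_out_of_range_rejected(self):
        seg = checkerboard_partition()
        with pytest.raises(ValueError):
            full_lambda_merge(seg, [Raster(np.ones((4, 4)))], merge_level=101.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_merge_sequence_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        seg = random_voronoi_partition(rng, 24, 10)
        layers = [Raster(rng.uniform(0, 1, (24, 24))) for _ in range(2)]
        _, seq = full_lambda_merge(seg, layers, 70.0, return_sequence=True)
        oracle_seq = greedy_merge_oracle(seg, layers, 70.0)
        assert seq == oracle_seq

    def test_partition_valid_and_mass_conserved_after_merging(self, rng):
        seg = random_voronoi_partition(rng, 32, 12)
        layer = Raster(rng.uniform(0, 1, (32, 32)))
        merged = full_lambda_merge(seg, [layer], 80.0)
        validate_partition(merged)
        # total pixel count and value sums invariant
        areas, sums = region_stats(merged.labels, [layer.values])
        assert areas[1:].sum() == 32 * 32
        assert sums[1:, 0].sum() == pytest.approx(layer.values.sum())

    def test_segment_count_monotone_in_merge_level(self, rng):
        seg = random_voronoi_partition(rng, 32, 12)
        layer = Raster(rng.uniform(0, 1, (32, 32)))
        counts = [
            full_lambda_merge(seg, [layer], lvl).n_segments
            for lvl in (0, 25, 50, 75, 100)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestHierarchy:
    def test_equal_merge_levels_give_identical_maps(self, rng):
        img = smooth_random_raster(rng, 48)
        sub, sup = build_hierarchy(img, [img], scale=30.0, merge_sub=60.0, merge_super=60.0)
        assert np.array_equal(sub.labels, sup.labels)

    def test_super_has_no_more_segments_than_sub(self, rng):
        img = smooth_random_raster(rng, 48)
        sub, sup = build_hierarchy(img, [img], scale=30.0, merge_sub=50.0, merge_super=90.0)
        assert sup.n_segments <= sub.n_segments
        validate_partition(sub)
        validate_partition(sup)

    def test_reversed_merge_levels_rejected(self, rng):
        img = smooth_random_raster(rng, 48)
        with pytest.raises(ValueError):
            build_hierarchy(img, [img], scale=30.0, merge_sub=90.0, merge_super=50.0)

    def test_published_parameterizations_are_accepted(self, rng):
        # the two parameter sets used in the original study must run as-is
        img = smooth_random_raster(rng, 48)
        for scale, m_sub, m_super in ((30.0, 95.0, 95.7), (10.0, 95.6, 98.5)):
            sub, sup = build_hierarchy(
                img, [img], scale=scale, merge_sub=m_sub, merge_super=m_super
            )
            assert sup.n_segments <= sub.n_segments


def test_boundary_lengths_symmetric_counts():
    labels = np.array([[1, 1, 2], [1, 2, 2], [3, 3, 3]], dtype=np.int32)
    lengths = boundary_lengths(labels)
    assert lengths[(1, 2)] == 3
    assert lengths[(1, 3)] == 1
    assert lengths[(2, 3)] == 2
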