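"""Fuzzy partition, entropy objective, DE optimizer and segmentation."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import thermofoot as tf
from thermofoot.fuzzy import (
    FuzzyPartition,
    exhaustive_best_partition,
    membership_matrix,
    segment_thermogram,
)
from thermofoot.thermogram import ValidationError


def make_partition(breakpoints, levels=256, n=None):
    n = n or len(breakpoints) // 2 + 1
    return FuzzyPartition(n_segments=n, breakpoints=np.asarray(breakpoints, float),
                          levels=levels)


class TestHistogram:
    def test_direct_count(self):
        img = tf.GrayImage(np.array([[0, 0], [1, 1]]), levels=2)
        h = tf.compute_histogram(img)
        np.testing.assert_allclose(h.probs, [0.5, 0.5])

    def test_single_value_is_one_hot(self):
        img = tf.GrayImage(np.full((3, 3), 5), levels=8)
        h = tf.compute_histogram(img)
        assert h.probs[5] == 1.0 and h.probs.sum() == 1.0

    def test_mask_restriction_counts_only_masked_pixels(self):
        img = tf.GrayImage(np.array([[0, 3], [3, 3]]), levels=4)
        mask = np.array([[True, False], [False, False]])
        h = tf.compute_histogram(img, restrict_to=mask)
        assert h.probs[0] == 1.0

    def test_empty_mask_rejected(self):
        img = tf.GrayImage(np.zeros((2, 2), dtype=int), levels=2)
        with pytest.raises(ValidationError):
            tf.compute_histogram(img, restrict_to=np.zeros((2, 2), dtype=bool))


class TestMembership:
    def test_overlap_midpoint_is_half_half(self):
        p = make_partition([100, 200])
        np.testing.assert_allclose(tf.membership(p, 150), [0.5, 0.5])

    def test_saturated_below_first_breakpoint(self):
        p = make_partition([100, 200])
        np.testing.assert_allclose(tf.membership(p, 50), [1.0, 0.0])

    @given(st.lists(st.integers(0, 255), min_size=2, max_size=8)
           .filter(lambda v: len(v) % 2 == 0))
    def test_partition_of_unity_everywhere(self, raw):
        p = make_partition(sorted(raw))
        mu = membership_matrix(p)
        assert mu.min() >= -1e-12
        np.testing.assert_allclose(mu.sum(axis=0), 1.0, atol=1e-9)

    def test_unsorted_breakpoints_rejected(self):
        with pytest.raises(ValidationError):
            make_partition([200, 100])


class TestEntropy:
    def test_one_hot_histogram_has_zero_entropy(self):
        h = tf.Histogram(probs=np.eye(16)[3], levels=16)
        p = make_partition([4, 10], levels=16)
        assert tf.total_fuzzy_entropy(h, p) == pytest.approx(0.0, abs=1e-12)

    def test_uniform_histogram_crisp_midpoint_matches_hand_sum(self):
        # independent hand evaluation on 4 bins: each segment holds two
        # bins with conditional mass 1/2 -> H_i = ln 2; normalized by
        # n ln L = 2 ln 4 gives exactly 0.5
        h = tf.Histogram(probs=np.full(4, 0.25), levels=4)
        p = make_partition([1, 1], levels=4)   # crisp step between bins 1 and 2
        expected = 2 * np.log(2) / (2 * np.log(4))
        assert tf.total_fuzzy_entropy(h, p) == pytest.approx(expected, abs=1e-12)
        assert tf.total_fuzzy_entropy(h, p, normalize=False) == pytest.approx(
            2 * np.log(2), abs=1e-12)

    def test_invariant_to_permuting_zero_probability_bins(self):
        probs = np.zeros(32)
        probs[[2, 20]] = 0.5
        h1 = tf.Histogram(probs=probs, levels=32)
        probs2 = probs.copy()  # zero bins rearranged: identical histogram mass
        h2 = tf.Histogram(probs=probs2, levels=32)
        p = make_partition([8, 24], levels=32)
        assert tf.total_fuzzy_entropy(h1, p) == tf.total_fuzzy_entropy(h2, p)


class TestOptimizer:
    def test_same_seed_gives_identical_partition(self, rng):
        h = tf.Histogram(probs=rng.dirichlet(np.ones(32)), levels=32)
        a = tf.optimize_partition(h, 2, tf.DEConfig(seed=5))
        b = tf.optimize_partition(h, 2, tf.DEConfig(seed=5))
        np.testing.assert_array_equal(a.breakpoints, b.breakpoints)

    def test_bimodal_threshold_lies_between_modes_and_matches_exhaustive(self):
        rng = np.random.default_rng(3)
        samples = np.concatenate([rng.normal(8, 2, 400), rng.normal(24, 2, 400)])
        pix = np.clip(np.round(samples), 0, 31).astype(int)
        h = tf.Histogram(probs=np.bincount(pix, minlength=32) / len(pix), levels=32)
        p = tf.optimize_partition(h, 2, tf.DEConfig(seed=3))
        _, best = exhaustive_best_partition(h, 2)
        assert tf.total_fuzzy_entropy(h, p) == pytest.approx(best, abs=1e-9)
        thr = tf.extract_thresholds(p).thresholds[0]
        assert 8 < thr < 24

    def test_de_beats_random_partitions(self, rng):
        h = tf.Histogram(probs=rng.dirichlet(np.ones(32) * 0.3), levels=32)
        p = tf.optimize_partition(h, 3, tf.DEConfig(seed=1))
        best_de = tf.total_fuzzy_entropy(h, p)
        for _ in range(1000):
            bp = np.sort(rng.uniform(0, 31, size=4).round())
            rand_h = tf.total_fuzzy_entropy(h, make_partition(bp, levels=32))
            assert best_de >= rand_h - 1e-12

    def test_infeasible_segment_count_rejected(self, rng):
        h = tf.Histogram(probs=rng.dirichlet(np.ones(4)), levels=4)
        with pytest.raises(ValidationError):
            tf.optimize_partition(h, 4, tf.DEConfig(seed=0))


class TestThresholds:
    def test_midpoint_of_overlap(self):
        assert tf.extract_thresholds(make_partition([100, 200])).thresholds[0] == 150

    def test_four_segments_give_three_sorted_thresholds(self):
        t = tf.extract_thresholds(make_partition([10, 20, 80, 120, 200, 240]))
        assert len(t) == 3
        assert np.all(np.diff(t.thresholds) > 0)

    def test_duplicate_midpoints_repaired_upward(self):
        t = tf.extract_thresholds(make_partition([10, 10, 10, 10]))
        assert np.all(np.diff(t.thresholds) > 0)


class TestSegment:
    def test_label_is_count_of_thresholds_strictly_below(self):
        img = tf.GrayImage(np.array([[0, 0], [1, 2]]), levels=4)
        res = tf.segment(img, tf.ThresholdSet(np.array([1])))
        np.testing.assert_array_equal(res.labels, [[0, 0], [0, 1]])

    def test_empty_threshold_set_gives_single_segment(self):
        img = tf.GrayImage(np.arange(9).reshape(3, 3), levels=16)
        res = tf.segment(img, tf.ThresholdSet(np.array([], dtype=int)))
        assert np.all(res.labels == 0)

    def test_top_segment_count_matches_histogram_mass(self, rng):
        img = tf.GrayImage(rng.integers(0, 32, size=(10, 10)), levels=32)
        res = tf.segment(img, tf.ThresholdSet(np.array([10, 20])))
        h = tf.compute_histogram(img)
        mass_above = h.probs[21:].sum()
        assert res.roi_mask.sum() == pytest.approx(mass_above * 100, abs=1e-9)

    @given(st.integers(0, 30), st.integers(0, 31))
    def test_monotone_labeling(self, g_low, delta):
        img = tf.GrayImage(np.array([[g_low, min(g_low + delta, 31)]]), levels=32)
        res = tf.segment(img, tf.ThresholdSet(np.array([7, 15, 23])))
        assert res.labels[0, 0] <= res.labels[0, 1]


class TestLevelSelection:
    def test_reports_entropy_for_every_candidate(self, butterfly):
        t, _, _ = butterfly
        img = tf.to_gray(t, 64)
        res = tf.select_segmentation_level(img, [2, 3], tf.DEConfig(seed=0, generations=40),
                                           mask=t.mask)
        assert set(res.entropy_table) == {2, 3}
        assert all(np.isfinite(v) for v in res.entropy_table.values())

    def test_single_candidate_is_selected(self, butterfly):
        t, _, _ = butterfly
        img = tf.to_gray(t, 64)
        res = tf.select_segmentation_level(img, [3], tf.DEConfig(seed=0, generations=40),
                                           mask=t.mask)
        assert len(res.thresholds) == 2


def test_pipeline_partition_of_unity_at_optimum(butterfly):
    t, _, _ = butterfly
    res = segment_thermogram(t, 3, tf.DEConfig(seed=2, generations=60))
    mu = membership_matrix(res.partition)
    np.testing.assert_allclose(mu.sum(axis=0), 1.0, atol=1e-9)
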