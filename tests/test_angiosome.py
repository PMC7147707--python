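"""Angiosome partition geometry, TCI arithmetic and level grading."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import thermofoot as tf
from thermofoot.angiosome import LCA, LPA, MCA, MPA, AngiosomeTemps
from thermofoot.thermogram import ValidationError


@pytest.fixture(scope="module")
def rect():
    mask = np.ones((100, 40), dtype=bool)
    return mask, tf.partition_angiosomes(mask, side="left")


class TestPartition:
    def test_four_regions_non_empty_and_cover_mask(self, rect):
        mask, amap = rect
        sizes = {r: (amap.labels == r).sum() for r in (MPA, LPA, MCA, LCA)}
        assert all(s > 0 for s in sizes.values())
        assert sum(sizes.values()) == mask.sum()
        assert np.all((amap.labels > 0) == mask)

    def test_regions_are_disjoint(self, rect):
        _, amap = rect
        # one label per pixel by construction of a label image
        assert set(np.unique(amap.labels)) <= {0, MPA, LPA, MCA, LCA}

    def test_heel_band_occupies_proximal_27_percent(self, rect):
        _, amap = rect
        heel = (amap.labels == MCA) | (amap.labels == LCA)
        rows = np.flatnonzero(heel.any(axis=1))
        assert rows.min() == 73 and rows.max() == 99

    def test_mirrored_mask_with_flipped_side_mirrors_labels(self):
        mask = np.zeros((60, 30), dtype=bool)
        mask[5:55, 4:20] = True
        left = tf.partition_angiosomes(mask, side="left")
        right = tf.partition_angiosomes(mask[:, ::-1], side="right")
        np.testing.assert_array_equal(left.labels, right.labels[:, ::-1])

    def test_disconnected_mask_rejected(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[2:5, 2:5] = True
        mask[12:15, 12:15] = True
        with pytest.raises(ValidationError):
            tf.partition_angiosomes(mask)


class TestMeans:
    def test_constant_field_gives_constant_means(self, rect):
        mask, amap = rect
        t = tf.Thermogram(temps=np.full(mask.shape, 30.0), mask=mask)
        m = tf.angiosome_means(t, amap)
        assert m.mpa == m.lpa == m.mca == m.lca == 30.0

    def test_region_specific_temperature_is_isolated(self, rect):
        mask, amap = rect
        temps = np.full(mask.shape, 30.0)
        temps[amap.labels == MPA] = 32.0
        m = tf.angiosome_means(tf.Thermogram(temps=temps, mask=mask), amap)
        assert m.mpa == 32.0 and m.lpa == m.mca == m.lca == 30.0

    def test_background_temperature_does_not_affect_means(self):
        mask = np.zeros((40, 20), dtype=bool)
        mask[5:35, 4:16] = True
        amap = tf.partition_angiosomes(mask)
        temps = np.full(mask.shape, 30.0)
        cold = temps.copy()
        cold[~mask] = -10.0
        a = tf.angiosome_means(tf.Thermogram(temps=temps, mask=mask), amap)
        b = tf.angiosome_means(tf.Thermogram(temps=cold, mask=mask), amap)
        assert a == b


class TestTCI:
    def test_uniform_offset(self):
        ref = AngiosomeTemps(30, 30, 30, 30)
        sub = AngiosomeTemps(28, 28, 28, 28)
        assert tf.compute_tci(sub, ref) == pytest.approx(2.0)

    def test_identity_gives_zero(self):
        ref = AngiosomeTemps(30, 31, 29, 30)
        assert tf.compute_tci(ref, ref) == 0.0

    def test_signed_mean_cancels_opposite_changes(self):
        ref = AngiosomeTemps(30, 30, 30, 30)
        sub = AngiosomeTemps(31, 29, 30, 30)
        assert tf.compute_tci(sub, ref) == pytest.approx(0.0)
        assert tf.compute_tci(sub, ref, absolute=True) == pytest.approx(0.5)

    @given(st.floats(-3, 3),
           st.tuples(*[st.floats(25, 35)] * 4),
           st.tuples(*[st.floats(25, 35)] * 4))
    def test_uniform_shift_linearity(self, delta, r, s):
        ref, sub = AngiosomeTemps(*r), AngiosomeTemps(*s)
        shifted = AngiosomeTemps(*(x + delta for x in s))
        assert tf.compute_tci(shifted, ref) == pytest.approx(
            tf.compute_tci(sub, ref) - delta, abs=1e-9)


class TestLevels:
    @pytest.mark.parametrize("tci,level", [
        (0.5, 1), (-0.5, 1), (1.5, 2), (2.5, 3), (3.5, 4), (4.5, 5), (100.0, 5),
    ])
    def test_default_boundaries(self, tci, level):
        assert tf.assign_level(tci) == level

    def test_interval_membership_with_custom_boundaries(self):
        assert tf.assign_level(2.5, boundaries=(1, 2, 3, 4)) == 3

    def test_level_non_decreasing_in_magnitude(self):
        values = np.linspace(0, 6, 61)
        levels = [tf.assign_level(v) for v in values]
        assert np.all(np.diff(levels) >= 0)

    def test_non_monotone_boundaries_rejected(self):
        with pytest.raises(ValidationError):
            tf.assign_level(1.0, boundaries=(1, 3, 2, 4))


def test_grade_thermogram_end_to_end():
    spec = tf.SyntheticSpec(pattern="hot_region", target_class=4, noise_sd=0.0, seed=11)
    t = tf.generate_synthetic(spec)
    result = tf.grade_thermogram(t, tf.synthetic_reference(spec))
    assert result.level == 4
    assert result.tci < 0  # hot subject: control minus subject is negative
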