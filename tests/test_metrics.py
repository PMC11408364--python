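import math

import numpy as np
import pytest

from zcoloc import (
    ROIBox,
    ThresholdRange,
    ValidationError,
    analyze,
    intersection_2ch,
    intersection_3ch,
    is_defined,
    pearson,
    weight_mask,
)
from zcoloc.thresholding import WeightMask

from conftest import make_stack, random_stack
from oracles import intersection_oracle, mask_set, pcc_oracle


def mask_from_support(support, n=8):
    """WeightMask with 1s at the given flat indices of an n-voxel grid."""
    w = np.zeros(n, dtype=np.uint8)
    w[list(support)] = 1
    return WeightMask(weights=w.reshape(1, 1, n), source_channel=0,
                      threshold=ThresholdRange(0, 1))


class TestPearson:
    def test_identical_channels_give_plus_one(self, rng):
        v = rng.integers(0, 255, (3, 4, 4)).astype(np.uint8)
        t = ThresholdRange(0, 255)
        assert pearson(v, v.copy(), t, t) == pytest.approx(1.0)

    def test_complemented_channel_gives_minus_one(self, rng):
        v = rng.integers(0, 255, (3, 4, 4)).astype(np.uint8)
        t = ThresholdRange(0, 255)
        assert pearson(v, 255 - v, t, t) == pytest.approx(-1.0)

    def test_small_integer_example_matches_literal_oracle(self):
        a = np.array([1, 3, 4, 6, 2, 5, 3, 4], dtype=np.float64).reshape(2, 2, 2)
        b = np.array([2, 2, 5, 7, 1, 4, 6, 3], dtype=np.float64).reshape(2, 2, 2)
        t = ThresholdRange(2, 5)
        expected = pcc_oracle(a, b, (2, 5), (2, 5))
        assert pearson(a, b, t, t) == pytest.approx(expected, rel=1e-14)

    def test_zero_variance_is_undefined_not_zero(self):
        flat = np.full((2, 2, 2), 7.0)
        varying = np.arange(8, dtype=np.float64).reshape(2, 2, 2)
        t = ThresholdRange(0, 100)
        r = pearson(flat, varying, t, t)
        assert not is_defined(r)
        assert math.isnan(r)

    def test_thresholds_can_zero_out_a_channel(self):
        """Preprocessing may remove all variance; result is undefined."""
        a = np.array([9.0, 9.0, 9.0, 9.0]).reshape(1, 2, 2)
        b = np.arange(4, dtype=np.float64).reshape(1, 2, 2)
        r = pearson(a, b, ThresholdRange(0, 5), ThresholdRange(0, 5))
        assert not is_defined(r)

    def test_symmetry(self, rng):
        a = rng.integers(0, 100, (2, 3, 3)).astype(np.float64)
        b = rng.integers(0, 100, (2, 3, 3)).astype(np.float64)
        ta, tb = ThresholdRange(10, 80), ThresholdRange(5, 90)
        assert pearson(a, b, ta, tb) == pytest.approx(
            pearson(b, a, tb, ta), rel=1e-14)

    def test_shape_mismatch_rejected(self):
        t = ThresholdRange(0, 10)
        with pytest.raises(ValidationError):
            pearson(np.zeros((1, 2, 2)), np.zeros((1, 2, 3)), t, t)


class TestIntersection2ch:
    def test_identical_masks(self):
        m = mask_from_support({0, 2, 5})
        assert intersection_2ch(m, m) == (1.0, 1.0, 1.0)

    def test_disjoint_masks(self):
        a, b = mask_from_support({0, 1}), mask_from_support({5, 6})
        assert intersection_2ch(a, b) == (0.0, 0.0, 0.0)

    def test_counted_example(self):
        """|A| = 4, |B| = 3, |A∩B| = 2 on an 8-voxel grid."""
        a = mask_from_support({0, 1, 2, 3})
        b = mask_from_support({2, 3, 4})
        I, i1, i2 = intersection_2ch(a, b)
        assert I == pytest.approx(0.4)
        assert i1 == pytest.approx(0.5)
        assert i2 == pytest.approx(2 / 3)

    def test_empty_union_all_undefined(self):
        e = mask_from_support(set())
        assert all(not is_defined(x) for x in intersection_2ch(e, e))

    def test_one_empty_mask(self):
        e = mask_from_support(set())
        b = mask_from_support({1, 2})
        I, i1, i2 = intersection_2ch(e, b)
        assert I == 0.0 and i2 == 0.0
        assert not is_defined(i1)


class TestIntersection3ch:
    def test_identical_masks(self):
        m = mask_from_support({1, 4})
        assert intersection_3ch(m, m, m) == (1.0, 1.0, 1.0, 1.0)

    def test_sliding_support_example(self):
        """Supports {1,2,3}, {2,3,4}, {3,4,5}: union 5, triple 1."""
        a = mask_from_support({1, 2, 3}, n=6)
        b = mask_from_support({2, 3, 4}, n=6)
        c = mask_from_support({3, 4, 5}, n=6)
        I, i1, i2, i3 = intersection_3ch(a, b, c)
        assert I == pytest.approx(0.2)
        assert i1 == i2 == i3 == pytest.approx(1 / 3)

    def test_denominator_is_union_volume(self, rng):
        for _ in range(20):
            sup = [set(rng.choice(12, size=rng.integers(0, 10),
                                  replace=False).tolist()) for _ in range(3)]
            masks = [mask_from_support(s, n=12) for s in sup]
            I, *_ = intersection_3ch(*masks)
            union = len(sup[0] | sup[1] | sup[2])
            triple = len(sup[0] & sup[1] & sup[2])
            if union:
                assert I == pytest.approx(triple / union)
            else:
                assert not is_defined(I)

    def test_duplicated_mask_reduces_to_two_channel(self, rng):
        for _ in range(20):
            sup = [set(rng.choice(10, size=rng.integers(1, 8),
                                  replace=False).tolist()) for _ in range(2)]
            a, b = (mask_from_support(s, n=10) for s in sup)
            I2, i1_2, i2_2 = intersection_2ch(a, b)
            I3, i1_3, i2_3, i3_3 = intersection_3ch(a, b, b)
            assert I3 == pytest.approx(I2)
            assert i1_3 == pytest.approx(i1_2)
            assert i2_3 == pytest.approx(i2_2) and i3_3 == pytest.approx(i2_2)


class TestAnalyze:
    def make_inputs(self, rng, n_channels=2):
        stack = random_stack(rng, n_channels=n_channels, dims=(4, 6, 6))
        thresholds = {i + 1: ThresholdRange(50, 220)
                      for i in range(n_channels)}
        return stack, thresholds

    def test_selecting_four_channels_rejected(self, rng):
        stack = random_stack(rng, n_channels=4)
        t = {i: ThresholdRange(0, 255) for i in range(1, 5)}
        with pytest.raises(ValidationError, match="2 or 3"):
            analyze(stack, [1, 2, 3, 4], t)

    def test_one_channel_rejected(self, rng):
        stack, t = self.make_inputs(rng)
        with pytest.raises(ValidationError):
            analyze(stack, [1], t)

    def test_invalid_and_duplicate_indices_rejected(self, rng):
        stack, t = self.make_inputs(rng)
        with pytest.raises(ValidationError):
            analyze(stack, [1, 9], t)
        with pytest.raises(ValidationError):
            analyze(stack, [1, 1], t)

    def test_omitted_roi_equals_full_extent_box(self, rng):
        stack, t = self.make_inputs(rng)
        r1 = analyze(stack, [1, 2], t)
        r2 = analyze(stack, [1, 2], t, box=ROIBox((0, 0, 0), stack.dims))
        assert r1.global_intersection == r2.global_intersection
        assert r1.pcc == r2.pcc
        assert r1.venn_fractions == r2.venn_fractions
        assert r1.n_voxels == r2.n_voxels == 4 * 6 * 6

    def test_engineered_overlap_fraction(self):
        """Masks designed so the intersection is 0.4 of the union."""
        a = np.zeros((1, 2, 5), np.uint8)
        b = np.zeros((1, 2, 5), np.uint8)
        a[0, :, :2] = 100  # |A| = 4
        b[0, 0, 1:4] = 100  # |B| = 3, overlap = 1... adjust to 2/5 of union
        a[0, 1, 2] = 0
        # supports: A = {(0,0),(0,1),(1,0),(1,1)}, B = {(0,1),(0,2),(0,3)}
        stack = make_stack([a, b])
        t = {1: ThresholdRange(50, 255), 2: ThresholdRange(50, 255)}
        res = analyze(stack, [1, 2], t)
        # |A|=4, |B|=3, |A∩B|=1 → I = 1/6
        assert res.global_intersection == pytest.approx(1 / 6)

    def test_metrics_commute_with_cropping(self, rng):
        stack, t = self.make_inputs(rng, n_channels=3)
        box = ROIBox((1, 1, 0), (4, 5, 6))
        from zcoloc import crop
        direct = analyze(stack, [1, 2, 3], t, box=box)
        pre_cropped = analyze(crop(stack, box), [1, 2, 3], t)
        assert direct.n_voxels == pre_cropped.n_voxels
        assert direct.global_intersection == pre_cropped.global_intersection
        for k in direct.pcc:
            assert direct.pcc[k] == pytest.approx(pre_cropped.pcc[k],
                                                  rel=1e-12, nan_ok=True)

    def test_pcc_pairs_cover_all_combinations_ascending(self, rng):
        stack, t = self.make_inputs(rng, n_channels=3)
        res = analyze(stack, [3, 1, 2], t)
        assert sorted(res.pcc) == [(1, 2), (1, 3), (2, 3)]
        assert res.selected_channels == [1, 2, 3]

    def test_intersection_depends_only_on_masks(self, rng):
        """Any intensity change preserving masks preserves I and i_k."""
        stack, t = self.make_inputs(rng)
        res1 = analyze(stack, [1, 2], t)
        # remap in-range values to another in-range value, out-of-range too
        for ch in stack.channels:
            v = ch.voxels
            inside = (v > 50) & (v <= 220)
            v[inside] = 100
            v[~inside] = 0
        res2 = analyze(stack, [1, 2], t)
        assert res1.global_intersection == res2.global_intersection
        assert res1.per_channel_intersection == res2.per_channel_intersection

    def test_venn_all_channel_region_equals_global_I(self, rng):
        stack, t = self.make_inputs(rng, n_channels=3)
        res = analyze(stack, [1, 2, 3], t)
        if is_defined(res.global_intersection):
            assert res.venn_fractions[frozenset({1, 2, 3})] == pytest.approx(
                res.global_intersection)
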