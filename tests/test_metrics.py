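import math

import numpy as np
import pytest

from maskfuse import (
    BinaryMask,
    MaskSeries,
    ShapeError,
    boundary_pixels,
    confusion_counts,
    directed_hausdorff,
    evaluate_series,
    hausdorff,
    hd_is_defined,
    iou,
)

from conftest import mask_from_rows, random_mask


# ---------------------------------------------------------------- oracles
def brute_iou(pred, gt):
    p = {tuple(x) for x in np.argwhere(pred.bool())}
    g = {tuple(x) for x in np.argwhere(gt.bool())}
    if not p and not g:
        return 1.0
    return len(p & g) / len(p | g)


def brute_boundary(mask):
    fg = {tuple(x) for x in np.argwhere(mask.bool())}
    h, w = mask.shape
    out = set()
    for (r, c) in fg:
        for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            nr, nc = r + dr, c + dc
            if not (0 <= nr < h and 0 <= nc < w) or (nr, nc) not in fg:
                out.add((r, c))
                break
    return out

def brute_directed_hd(A, B):
    return max(
        min(math.sqrt((a[0] - b[0]) ** 2 + (a[1] - b[1]) ** 2) for b in B)
        for a in A
    )


def brute_hd(pred, gt):
    a = brute_boundary(pred)
    b = brute_boundary(gt)
    if not a and not b:
        return 0.0
    if not a or not b:
        return None
    return max(brute_directed_hd(a, b), brute_directed_hd(b, a))


# ---------------------------------------------------------------- confusion
class TestConfusionCounts:
    def test_identical_masks_have_no_errors(self, rng):
        m = random_mask(rng, 6, 6)
        cc = confusion_counts(m, m)
        assert cc.fp == cc.fn == 0
        assert cc.tp == m.foreground_count()

    def test_all_background_prediction_counts_all_misses(self):
        gt = mask_from_rows("1110", "1110", "1000", "0000")  # 7 fg pixels
        pred = BinaryMask(np.zeros((4, 4), dtype=np.uint8))
        cc = confusion_counts(pred, gt)
        assert (cc.tp, cc.fp, cc.fn) == (0, 0, 7)

    def test_hand_enumerated_two_by_two(self):
        pred = mask_from_rows("11", "00")
        gt = mask_from_rows("01", "01")
        cc = confusion_counts(pred, gt)
        assert (cc.tp, cc.fp, cc.fn, cc.tn) == (1, 1, 1, 1)

    def test_counts_conserve_pixel_total(self, rng):
        for _ in range(20):
            a = random_mask(rng, 7, 5)
            b = random_mask(rng, 7, 5)
            assert confusion_counts(a, b).total == 35

    def test_dimension_mismatch_rejected(self, rng):
        with pytest.raises(ShapeError):
            confusion_counts(random_mask(rng, 3, 3), random_mask(rng, 4, 4))


# ---------------------------------------------------------------- iou
class TestIoU:
    def test_identical_nonempty_is_one(self, rng):
        m = random_mask(rng, 8, 8, p=0.6)
        assert iou(m, m) == 1.0

    def test_disjoint_nonempty_is_zero(self):
        a = mask_from_rows("10", "00")
        b = mask_from_rows("00", "01")
        assert iou(a, b) == 0.0

    def test_one_overlap_three_union(self):
        pred = mask_from_rows("11", "00")
        gt = mask_from_rows("01", "01")
        assert iou(pred, gt) == pytest.approx(1 / 3)

    def test_both_empty_scores_perfect(self):
        e = BinaryMask(np.zeros((4, 4), dtype=np.uint8))
        assert iou(e, e) == 1.0

    def test_symmetric_and_in_unit_interval(self, rng):
        for _ in range(50):
            a = random_mask(rng, 9, 6)
            b = random_mask(rng, 9, 6)
            v = iou(a, b)
            assert v == iou(b, a)
            assert 0.0 <= v <= 1.0

    def test_matches_set_oracle(self, rng):
        for _ in range(100):
            a = random_mask(rng, 8, 8, p=rng.uniform(0.1, 0.9))
            b = random_mask(rng, 8, 8, p=rng.uniform(0.1, 0.9))
            assert iou(a, b) == pytest.approx(brute_iou(a, b), abs=0)


# ---------------------------------------------------------------- boundary
class TestBoundaryPixels:
    def test_empty_mask_has_empty_boundary(self):
        assert len(boundary_pixels(BinaryMask(np.zeros((3, 3), dtype=np.uint8)))) == 0

    def test_single_pixel_is_its_own_boundary(self):
        m = mask_from_rows("000", "010", "000")
        np.testing.assert_array_equal(boundary_pixels(m), [[1, 1]])

    def test_full_3x3_boundary_excludes_center(self):
        m = BinaryMask(np.ones((3, 3), dtype=np.uint8))
        pts = {tuple(p) for p in boundary_pixels(m)}
        assert pts == {(r, c) for r in range(3) for c in range(3)} - {(1, 1)}

    def test_matches_four_neighbor_oracle(self, rng):
        for _ in range(50):
            m = random_mask(rng, 10, 7, p=rng.uniform(0.2, 0.8))
            got = {tuple(p) for p in boundary_pixels(m)}
            assert got == brute_boundary(m)


# ---------------------------------------------------------------- hausdorff
class TestDirectedHausdorff:
    def test_identical_sets_distance_zero(self):
        A = np.array([[0, 0], [2, 3]])
        assert directed_hausdorff(A, A) == 0.0

    def test_three_four_five_triangle(self):
        assert directed_hausdorff([[0, 0]], [[3, 4]]) == pytest.approx(5.0, abs=1e-12)

    def test_max_over_first_set(self):
        assert directed_hausdorff([[0, 0], [10, 0]], [[0, 0]]) == 10.0

    def test_empty_set_is_undefined(self):
        assert not hd_is_defined(directed_hausdorff(np.empty((0, 2)), [[0, 0]]))


class TestHausdorff:
    def test_identical_nonempty_is_zero(self, rng):
        m = random_mask(rng, 8, 8, p=0.5)
        if m.is_empty():
            pytest.skip("degenerate draw")
        assert hausdorff(m, m) == 0.0

    def test_single_pixel_masks_euclidean(self):
        a = np.zeros((5, 5), dtype=np.uint8)
        b = np.zeros((5, 5), dtype=np.uint8)
        a[0, 0] = 1
        b[3, 4] = 1
        assert hausdorff(BinaryMask(a), BinaryMask(b)) == pytest.approx(5.0, abs=1e-12)

    def test_both_empty_is_zero(self):
        e = BinaryMask(np.zeros((4, 4), dtype=np.uint8))
        assert hausdorff(e, e) == 0.0

    def test_one_empty_is_undefined(self):
        e = BinaryMask(np.zeros((3, 3), dtype=np.uint8))
        m = mask_from_rows("100", "000", "000")
        assert not hd_is_defined(hausdorff(e, m))
        assert not hd_is_defined(hausdorff(m, e))

    def test_symmetry_and_identity_of_indiscernible_boundaries(self, rng):
        for _ in range(40):
            a = random_mask(rng, 8, 8, p=0.5)
            b = random_mask(rng, 8, 8, p=0.5)
            if a.is_empty() or b.is_empty():
                continue
            hd = hausdorff(a, b)
            assert hd == hausdorff(b, a)
            same_boundary = {tuple(p) for p in boundary_pixels(a)} == {
                tuple(p) for p in boundary_pixels(b)
            }
            assert (hd == 0.0) == same_boundary

    def test_triangle_inequality(self, rng):
        n = 0
        while n < 60:
            a, b, c = (random_mask(rng, 8, 8, p=0.4) for _ in range(3))
            if any(m.is_empty() for m in (a, b, c)):
                continue
            n += 1
            assert hausdorff(a, c) <= hausdorff(a, b) + hausdorff(b, c) + 1e-9

    def test_matches_brute_force_oracle_exactly(self, rng):
        for _ in range(150):
            h, w = rng.integers(1, 17, size=2)
            a = random_mask(rng, h, w, p=rng.uniform(0.1, 0.9))
            b = random_mask(rng, h, w, p=rng.uniform(0.1, 0.9))
            expected = brute_hd(a, b)
            got = hausdorff(a, b)
            if expected is None:
                assert not hd_is_defined(got)
            else:
                assert got == pytest.approx(expected, abs=1e-12)


# ---------------------------------------------------------------- series
class TestEvaluateSeries:
    def test_perfect_prediction(self, tiny_series):
        res = evaluate_series(tiny_series, tiny_series)
        assert res.mean_iou == 1.0
        assert res.pooled_iou == 1.0
        assert res.mean_hd == 0.0
        assert res.n_undefined_hd == 0

    def test_mean_iou_averages_slices(self):
        gt1 = mask_from_rows("1100", "0000")
        gt2 = mask_from_rows("0011", "0000")
        pred2 = mask_from_rows("0000", "1100")  # disjoint, same size
        preds = MaskSeries([gt1, pred2], "p")
        gts = MaskSeries([gt1, gt2], "g")
        res = evaluate_series(preds, gts)
        assert [s.iou for s in res.per_slice] == [1.0, 0.0]
        assert res.mean_iou == pytest.approx(0.5)

    def test_undefined_hd_counted_not_averaged(self):
        empty = BinaryMask(np.zeros((4, 4), dtype=np.uint8))
        blob = mask_from_rows("0000", "0110", "0110", "0000")
        preds = MaskSeries([blob, blob], "p")
        gts = MaskSeries([blob, empty], "g")
        res = evaluate_series(preds, gts)
        assert res.n_undefined_hd == 1
        assert res.mean_hd == 0.0  # only the defined slice contributes

    def test_pooled_weighs_large_slices_more(self):
        big = BinaryMask(np.ones((4, 4), dtype=np.uint8))
        small_gt = mask_from_rows("1000", "0000", "0000", "0000")
        small_pred = mask_from_rows("0100", "0000", "0000", "0000")
        preds = MaskSeries([big, small_pred], "p")
        gts = MaskSeries([big, small_gt], "g")
        res = evaluate_series(preds, gts)
        # mean: (1 + 0)/2; pooled: 16/(16+1+1)
        assert res.mean_iou == pytest.approx(0.5)
        assert res.pooled_iou == pytest.approx(16 / 18)

    def test_length_mismatch_rejected(self, tiny_series):
        short = MaskSeries(list(tiny_series)[:1], "s")
        with pytest.raises(ShapeError):
            evaluate_series(tiny_series, short)
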