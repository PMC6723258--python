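"""Metric tests: IoU, matching, precision/recall, PR curves, AP.

The AP and PR implementations are checked against an independent
brute-force oracle that recomputes IoUs pixel-by-pixel from coordinate
sets and traces the score sweep with naive loops.
"""

import itertools

import numpy as np
import pytest

from phasetime import (
    InstanceMaskSet,
    average_precision,
    box_iou,
    evaluate_suite,
    mask_iou,
    match_instances,
    mean_mask_iou,
    pr_curve,
    precision_recall,
)

from conftest import perturbed_predictions, random_maskset
from oracles import oracle_ap, oracle_match, oracle_pair_iou, oracle_pr_points


# ----------------------------------------------------------------- mask IoU

def square_mask(shape, r0, c0, h, w):
    m = np.zeros(shape, dtype=bool)
    m[r0 : r0 + h, c0 : c0 + w] = True
    return m


class TestMaskIoU:
    def test_identity_disjoint_shift(self):
        a = square_mask((8, 8), 2, 2, 2, 2)
        assert mask_iou(a, a) == 1.0
        assert mask_iou(a, square_mask((8, 8), 5, 5, 2, 2)) == 0.0
        # 2x2 square vs same square shifted one column: inter 2, union 6
        assert mask_iou(a, square_mask((8, 8), 2, 3, 2, 2)) == pytest.approx(1 / 3)

    def test_empty_conventions(self):
        empty = np.zeros((4, 4), dtype=bool)
        assert mask_iou(empty, empty) == 1.0
        assert mask_iou(empty, square_mask((4, 4), 0, 0, 2, 2)) == 0.0

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            mask_iou(np.zeros((3, 3), bool), np.zeros((4, 4), bool))

    def test_symmetry_and_bounds(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            a = rng.random((10, 10)) > 0.6
            b = rng.random((10, 10)) > 0.6
            v = mask_iou(a, b)
            assert v == mask_iou(b, a)
            assert 0.0 <= v <= 1.0


class TestBoxIoU:
    def test_examples(self):
        assert box_iou((0, 0, 2, 2), (0, 0, 2, 2)) == 1.0
        assert box_iou((0, 0, 2, 2), (0, 1, 2, 3)) == pytest.approx(1 / 3)
        assert box_iou((0, 0, 2, 2), (5, 5, 7, 7)) == 0.0

    def test_zero_area_raises(self):
        with pytest.raises(ValueError):
            box_iou((0, 0, 0, 2), (0, 0, 2, 2))


# ----------------------------------------------------------------- matching

class TestMatching:
    def test_identical_sets_all_tp(self):
        rng = np.random.default_rng(0)
        s = random_maskset(rng, n_max=5)
        m = match_instances(s, s, 0.5)
        assert m.tp == len(s) and m.fp == 0 and m.fn == 0

    def test_empty_predictions_all_fn(self):
        rng = np.random.default_rng(1)
        s = random_maskset(rng, n_max=5)
        m = match_instances(s, InstanceMaskSet.empty(s.shape), 0.5)
        assert m.tp == 0 and m.fn == len(s)

    def test_double_prediction_one_tp_one_fp(self):
        shape = (16, 16)
        label = InstanceMaskSet(shape, [square_mask(shape, 4, 4, 6, 6)])
        preds = InstanceMaskSet(
            shape,
            [square_mask(shape, 4, 4, 6, 6), square_mask(shape, 5, 4, 6, 6)],
            [0.9, 0.8],
        )
        m = match_instances(label, preds, 0.5)
        assert m.tp == 1 and m.fp == 1 and m.fn == 0
        # the higher-scored, higher-IoU prediction claims the label, and the
        # resulting pairing maximises total matched IoU among assignments
        assert m.pairs[0][1] == 0
        best = max(
            sum(oracle_pair_iou(label.masks[i], preds.masks[j])
                for i, j in zip(range(1), perm))
            for perm in itertools.permutations(range(2), 1)
        )
        assert m.pairs[0][2] == pytest.approx(best)

    def test_conservation_invariant(self):
        rng = np.random.default_rng(2)
        for _ in range(30):
            s_l = random_maskset(rng, n_max=6)
            s_p = random_maskset(rng, n_max=6, scored=True)
            for t in (0.3, 0.5, 0.7):
                m = match_instances(s_l, s_p, t)
                assert m.tp + m.fn == len(s_l)
                assert m.tp + m.fp == len(s_p)
                assert all(iou > t for _, _, iou in m.pairs)

    def test_invalid_threshold_raises(self):
        s = InstanceMaskSet.empty((4, 4))
        with pytest.raises(ValueError):
            match_instances(s, s, 1.5)


class TestPrecisionRecall:
    def test_direct_substitution(self):
        rng = np.random.default_rng(3)
        s_l = random_maskset(rng, n_max=5)
        s_p = perturbed_predictions(rng, s_l, jitter=0, extra_fp=0)
        m = match_instances(s_l, s_p, 0.5)
        p, r = precision_recall(m)
        assert p == pytest.approx(m.tp / max(m.tp + m.fp, 1))
        assert r == pytest.approx(m.tp / max(m.tp + m.fn, 1))

    def test_degenerate_conventions(self):
        empty = InstanceMaskSet.empty((4, 4))
        assert precision_recall(match_instances(empty, empty, 0.5)) == (1.0, 1.0)

    def test_all_false_positive(self):
        shape = (8, 8)
        empty = InstanceMaskSet.empty(shape)
        preds = InstanceMaskSet(shape, [square_mask(shape, 0, 0, 3, 3)], [0.9])
        p, _ = precision_recall(match_instances(empty, preds, 0.5))
        assert p == 0.0


# ----------------------------------------------------------------- PR / AP

class TestPRCurve:
    def test_perfect_predictions_flat_curve(self):
        rng = np.random.default_rng(4)
        s_l = random_maskset(rng, n_max=4)
        s_p = InstanceMaskSet(s_l.shape, list(s_l.masks), [0.99] * len(s_l))
        curve = pr_curve(s_l, s_p, 0.5, thresholds=[0.1, 0.5, 0.9])
        assert all(p == 1.0 and r == 1.0 for _, p, r in curve.points)

    def test_recall_monotone_in_threshold(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            s_l = random_maskset(rng, n_max=5)
            s_p = perturbed_predictions(rng, s_l)
            if len(s_p) == 0 or len(s_l) == 0:
                continue
            curve = pr_curve(s_l, s_p, 0.5)
            recalls = [r for _, _, r in curve.points]
            assert all(a >= b for a, b in zip(recalls, recalls[1:]))

    def test_matches_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            s_l = random_maskset(rng, n_max=5)
            s_p = perturbed_predictions(rng, s_l)
            if len(s_p) == 0:
                continue
            curve = pr_curve(s_l, s_p, 0.4)
            expected = oracle_pr_points(s_l, s_p, 0.4)
            assert len(curve.points) == len(expected)
            for got, exp in zip(curve.points, expected):
                assert got == pytest.approx(exp, abs=1e-12)


class TestAveragePrecision:
    def test_perfect_and_hopeless(self):
        rng = np.random.default_rng(7)
        s_l = random_maskset(rng, n_max=4)
        perfect = InstanceMaskSet(s_l.shape, list(s_l.masks), [0.9] * len(s_l))
        assert average_precision([(s_l, perfect)], 0.5).mean_ap == 1.0
        shape = (16, 16)
        labels = InstanceMaskSet(shape, [square_mask(shape, 0, 0, 4, 4)])
        far = InstanceMaskSet(shape, [square_mask(shape, 10, 10, 4, 4)], [0.8])
        assert average_precision([(labels, far)], 0.5).mean_ap == 0.0

    def test_empty_empty_convention(self):
        empty = InstanceMaskSet.empty((8, 8))
        assert average_precision([(empty, empty)], 0.5).mean_ap == 1.0

    def test_matches_oracle_on_random_scenes(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            s_l = random_maskset(rng, n_max=5)
            s_p = perturbed_predictions(rng, s_l)
            got = average_precision([(s_l, s_p)], 0.45).mean_ap
            assert got == pytest.approx(oracle_ap(s_l, s_p, 0.45), abs=1e-12)

    def test_ap_non_increasing_in_t_iou(self):
        rng = np.random.default_rng(9)
        images = []
        for _ in range(8):
            s_l = random_maskset(rng, n_max=5)
            images.append((s_l, perturbed_predictions(rng, s_l)))
        aps = [average_precision(images, t).mean_ap
               for t in (0.3, 0.4, 0.5, 0.6, 0.7)]
        assert all(a >= b - 1e-12 for a, b in zip(aps, aps[1:]))


class TestSuiteAndMeanIoU:
    def test_suite_shape_and_perfect_predictions(self):
        rng = np.random.default_rng(10)
        images = []
        for _ in range(4):
            s_l = random_maskset(rng, n_max=4)
            images.append(
                (s_l, InstanceMaskSet(s_l.shape, list(s_l.masks),
                                      [0.95] * len(s_l))))
        df = evaluate_suite(images)
        assert set(df["mode"]) == {"box", "mask"}
        assert len(df) == 2 * 9  # both modes over the 0.3..0.7 grid
        assert (df["mean_ap"] == 1.0).all()

    def test_mean_mask_iou_examples(self):
        shape = (16, 16)
        a = InstanceMaskSet(shape, [square_mask(shape, 2, 2, 4, 4),
                                    square_mask(shape, 9, 9, 4, 4)])
        assert mean_mask_iou([a], [a]) == (1.0, 0.0)
        # pooled mean/sd over matched pairs equals manual computation
        rng = np.random.default_rng(11)
        golden, pred, manual = [], [], []
        for _ in range(10):
            s_l = random_maskset(rng, n_max=4)
            s_p = perturbed_predictions(rng, s_l, jitter=1, extra_fp=0)
            golden.append(s_l)
            pred.append(s_p)
            manual.extend(iou for _, _, iou in oracle_match(s_l, s_p, 0.5))
        mean, sd = mean_mask_iou(golden, pred)
        assert mean == pytest.approx(np.mean(manual), abs=1e-12)
        assert sd == pytest.approx(np.std(manual), abs=1e-12)

    def test_mean_mask_iou_errors(self):
        empty = InstanceMaskSet.empty((8, 8))
        with pytest.raises(ValueError):
            mean_mask_iou([empty], [empty])
        with pytest.raises(ValueError):
            mean_mask_iou([empty], [empty, empty])
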