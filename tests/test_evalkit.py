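"""Metrics, matching, line profiles and class-distribution summaries."""

from itertools import permutations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import mandifrac as mf
from mandifrac import evalkit
from mandifrac.detect import Detection, box_iou
from mandifrac.evalkit import (EvalCounts, MatchCriteria, UndefinedMetricError,
                               class_distribution, f1, line_profile,
                               precision, recall)


class TestMetrics:
    def test_precision_examples(self):
        assert precision(EvalCounts(97, 0, 0)) == 1.0
        assert precision(EvalCounts(3, 1, 0)) == 0.75
        assert precision(EvalCounts(0, 5, 0)) == 0.0

    def test_recall_examples(self):
        assert recall(EvalCounts(5, 0, 0)) == 1.0
        assert recall(EvalCounts(4, 0, 1)) == 0.8
        assert recall(EvalCounts(0, 0, 3)) == 0.0

    def test_f1_fixed_point(self):
        assert f1(1.0, 1.0) == 1.0

    def test_undefined_cases_signal_distinctly(self):
        with pytest.raises(UndefinedMetricError):
            precision(EvalCounts(0, 0, 5))
        with pytest.raises(UndefinedMetricError):
            recall(EvalCounts(0, 3, 0))
        with pytest.raises(UndefinedMetricError):
            f1(0.0, 0.0)

    @given(st.floats(0.001, 1.0), st.floats(0.001, 1.0))
    @settings(max_examples=100, deadline=None)
    def test_f1_between_min_and_max_and_below_geometric(self, p, r):
        v = f1(p, r)
        assert min(p, r) - 1e-12 <= v <= max(p, r) + 1e-12
        assert v <= np.sqrt(p * r) + 1e-12


def _fake_result(boxes, line_mask=None, shape=(64, 64)):
    from mandifrac.postproc import fuse_detections
    m = np.zeros(shape, np.uint8) if line_mask is None else line_mask
    return fuse_detections(boxes, m)


def _fake_gt(boxes, shape=(64, 64)):
    """GroundTruth with box-only fractures (polyline = box diagonal)."""
    specs = []
    for klass, (x0, y0, x1, y1) in boxes:
        poly = np.array([[x0 + 1, y0 + 1], [x1 - 2, y1 - 2]], dtype=float)
        specs.append(mf.FractureSpec(klass=klass, shape="oblique_gap",
                                     polyline=poly, gap_px=2.0,
                                     box=(x0, y0, x1, y1)))
    return mf.GroundTruth(specs=specs, line_mask=np.zeros(shape, np.uint8),
                          tooth_mask=np.zeros(shape, np.uint8),
                          boxes=list(boxes))


def _oracle_max_tp(pred_boxes, gt_boxes, iou_min=0.5):
    """Exhaustive maximum one-to-one matching over all assignment orders."""
    n, m = len(pred_boxes), len(gt_boxes)
    best = 0
    gt_idx = range(m)
    for k in range(min(n, m), -1, -1):
        if k <= best:
            break
        for pred_subset in permutations(range(n), k):
            for gt_subset in permutations(gt_idx, k):
                ok = all(
                    box_iou(pred_boxes[i].box, gt_boxes[j][1]) >= iou_min
                    for i, j in zip(pred_subset, gt_subset))
                if ok:
                    best = max(best, k)
                    break
            if best == k:
                break
    return best


def _random_instance(rng, shape=(64, 64)):
    n_gt = int(rng.integers(0, 7))
    n_pred = int(rng.integers(0, 7))
    classes = list(mf.CLASS_NAMES)
    gt_boxes = []
    for _ in range(n_gt):
        x0, y0 = rng.integers(0, 40, 2)
        w, h = rng.integers(6, 20, 2)
        gt_boxes.append((classes[int(rng.integers(6))],
                         (int(x0), int(y0), int(min(x0 + w, 63)),
                          int(min(y0 + h, 63)))))
    preds = []
    for _ in range(n_pred):
        if gt_boxes and rng.random() < 0.6:
            klass, (x0, y0, x1, y1) = gt_boxes[int(rng.integers(len(gt_boxes)))]
            dx, dy = rng.integers(-4, 5, 2)
            box = (max(int(x0 + dx), 0), max(int(y0 + dy), 0),
                   min(int(x1 + dx), 64), min(int(y1 + dy), 64))
            if box[2] <= box[0] or box[3] <= box[1]:
                continue
            preds.append(Detection(klass, box, float(rng.random())))
        else:
            x0, y0 = rng.integers(0, 40, 2)
            w, h = rng.integers(6, 20, 2)
            preds.append(Detection(classes[int(rng.integers(6))],
                                   (int(x0), int(y0), int(min(x0 + w, 63)),
                                    int(min(y0 + h, 63))),
                                   float(rng.random())))
    return preds, gt_boxes


class TestMatching:
    def test_perfect_detector(self):
        gt_boxes = [("body", (5, 5, 20, 20)), ("angle", (30, 30, 50, 50))]
        gt = _fake_gt(gt_boxes)
        pred = _fake_result([Detection(k, b, 0.9) for k, b in gt_boxes])
        c = evalkit.match_detections(pred, gt)
        assert (c.tp, c.fp, c.fn) == (2, 0, 0)

    def test_no_predictions(self):
        gt = _fake_gt([("body", (5, 5, 20, 20))])
        c = evalkit.match_detections(_fake_result([]), gt)
        assert (c.tp, c.fp, c.fn) == (0, 0, 1)

    def test_dual_modality_match_consumes_both(self):
        """One fracture hit by a correct box AND an overlapping line
        component: one TP, zero FP."""
        gt_box = ("body", (10, 20, 50, 40))
        gt = _fake_gt([gt_box])
        line = np.zeros((64, 64), np.uint8)
        # component along the GT polyline (the box diagonal)
        from mandifrac.phantom import rasterize_polyline
        raster = rasterize_polyline(gt.specs[0].polyline, (64, 64))
        line[raster] = 1
        pred = _fake_result([Detection("body", gt_box[1], 0.9)], line)
        assert len(pred.line_components) == 1
        c = evalkit.match_detections(pred, gt)
        assert (c.tp, c.fp, c.fn) == (1, 0, 0)

    def test_line_component_alone_is_tp(self):
        gt = _fake_gt([("body", (10, 20, 50, 40))])
        from mandifrac.phantom import rasterize_polyline
        line = np.zeros((64, 64), np.uint8)
        line[rasterize_polyline(gt.specs[0].polyline, (64, 64))] = 1
        c = evalkit.match_detections(_fake_result([], line), gt)
        assert (c.tp, c.fp, c.fn) == (1, 0, 0)

    def test_far_line_component_is_fp(self):
        gt = _fake_gt([("body", (40, 40, 60, 60))])
        line = np.zeros((64, 64), np.uint8)
        line[2:4, 2:20] = 1
        c = evalkit.match_detections(_fake_result([], line), gt)
        assert (c.tp, c.fp, c.fn) == (0, 1, 1)

    def test_agrees_with_exhaustive_max_tp_oracle(self):
        """Optimal one-to-one box matching equals brute-force enumeration on
        200 random instances with <= 6 GT and <= 6 predictions."""
        rng = np.random.default_rng(7)
        for _ in range(200):
            preds, gt_boxes = _random_instance(rng)
            gt = _fake_gt(gt_boxes)
            c = evalkit.match_detections(_fake_result(preds), gt)
            assert c.tp == _oracle_max_tp(preds, gt_boxes)

    def test_count_conservation_fuzz(self):
        """tp + fn = |GT| and tp + fp = |preds| for box-only predictions."""
        rng = np.random.default_rng(11)
        for _ in range(100):
            preds, gt_boxes = _random_instance(rng)
            gt = _fake_gt(gt_boxes)
            c = evalkit.match_detections(_fake_result(preds), gt)
            assert c.tp + c.fn == len(gt_boxes)
            assert c.tp + c.fp == len(preds)


class TestLineProfile:
    def test_flat_field(self):
        img = np.full((32, 32), 100, np.uint8)
        s = line_profile(img, (2, 5), (28, 5))
        assert (s.maximum, s.minimum, s.mean, s.std) == (100, 100, 100, 0)

    def test_two_pixel_closed_form(self):
        img = np.zeros((4, 4), np.uint8)
        img[1, 2] = 255
        s = line_profile(img, (1, 1), (2, 1))
        assert s.mean == 127.5 and s.std == 127.5
        assert s.minimum == 0 and s.maximum == 255

    def test_transpose_symmetry(self, rng):
        img = rng.integers(0, 255, (40, 40)).astype(np.uint8)
        s1 = line_profile(img, (3, 10), (35, 10))
        s2 = line_profile(img.T, (10, 3), (10, 35))
        assert s1 == s2

    def test_degenerate_segment_rejected(self):
        with pytest.raises(ValueError):
            line_profile(np.zeros((8, 8), np.uint8), (2, 2), (2, 2))


class TestClassDistribution:
    def test_clinical_training_table(self):
        d = class_distribution((153, 145, 183, 91, 39, 13))
        assert d.total == 624
        assert d.percentages[:5] == (24.519, 23.237, 29.327, 14.583, 6.25)
        assert d.middle_share == 91.667

    def test_clinical_test_table(self):
        d = class_distribution((25, 20, 29, 8, 13, 2))
        assert d.percentages[:4] == (25.773, 20.619, 29.897, 8.247)
        assert d.middle_share == 84.536

    def test_degenerate(self):
        d = class_distribution((1, 0, 0, 0, 0, 0))
        assert d.percentages == (100.0, 0.0, 0.0, 0.0, 0.0, 0.0)
        assert d.side_share == 0.0

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            class_distribution((0,) * 6)

    def test_percentages_sum_to_100_within_rounding(self, rng):
        for _ in range(20):
            counts = rng.integers(0, 50, 6)
            if counts.sum() == 0:
                continue
            d = class_distribution(counts)
            assert sum(d.percentages) == pytest.approx(100.0, abs=0.01)
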