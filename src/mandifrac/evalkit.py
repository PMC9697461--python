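"""Evaluation protocol: detection matching, precision/recall/F1, profiles.

Detection quality is scored per fracture with TP/FP/FN counts only — the
test population contains no fracture-free radiograph, so a true-negative
count is undefined and specificity-style metrics are deliberately absent.
Precision = TP/(TP+FP) measures misdetection, recall = TP/(TP+FN) measures
undetection, F1 is their harmonic mean.

Matching mixed box + line predictions against ground truth is done one-to-one
and optimally (maximum TP via assignment), boxes first: a ground-truth
fracture counts as detected if a predicted box overlaps its box at IoU >=
``box_iou_min`` or a predicted line component lies along its fracture line.
A fracture matched by both modalities is one TP and consumes both
predictions, so agreement between modalities is never penalised as a false
positive.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
from scipy.ndimage import binary_dilation
from scipy.optimize import linear_sum_assignment

from .detect import box_iou
from .phantom import CLASS_NAMES, rasterize_polyline

MIDDLE_CLASSES = CLASS_NAMES[:4]     # symphysis, body, angle, ramus
SIDE_CLASSES = CLASS_NAMES[4:]       # condyle, coronoid


class UndefinedMetricError(ZeroDivisionError):
    """The metric's denominator is zero; the value is undefined, not 0."""


@dataclass(frozen=True)
class EvalCounts:
    tp: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("counts must be nonnegative")

    def __add__(self, other: "EvalCounts") -> "EvalCounts":
        return EvalCounts(self.tp + other.tp, self.fp + other.fp,
                          self.fn + other.fn)


@dataclass(frozen=True)
class MatchCriteria:
    box_iou_min: float = 0.5
    line_dilate_px: int = 5
    line_overlap_min: float = 0.5

    def __post_init__(self):
        if not 0 < self.box_iou_min <= 1 or not 0 < self.line_overlap_min <= 1:
            raise ValueError("thresholds must be in (0, 1]")
        if self.line_dilate_px < 1:
            raise ValueError("line_dilate_px must be >= 1")


@dataclass(frozen=True)
class ProfileStats:
    maximum: float
    minimum: float
    mean: float
    std: float


@dataclass(frozen=True)
class ClassDistribution:
    counts: tuple
    total: int
    percentages: tuple
    middle_share: float
    side_share: float


# ---------------------------------------------------------------------------
# matching

def _optimal_match(compat: np.ndarray) -> list:
    """Max-cardinality one-to-one matching on a boolean pred x gt matrix.

    Solved as an assignment problem; among maximum matchings the one with the
    largest summed compatibility score is returned (scores in (0, 1] act as
    tie-breaks and never outweigh an extra match).
    """
    if compat.size == 0:
        return []
    score = np.where(compat > 0, 1.0 + compat, 0.0)
    rows, cols = linear_sum_assignment(score, maximize=True)
    return [(r, c) for r, c in zip(rows, cols) if compat[r, c] > 0]


def _line_match_score(comp_mask: np.ndarray, gt_line_dilated: np.ndarray,
                      min_overlap: float) -> float:
    """Fraction of the predicted component lying on the tolerance-dilated
    ground-truth line; 0 when below the acceptance fraction."""
    npix = int(comp_mask.sum())
    if npix == 0:
        return 0.0
    frac = int((comp_mask & gt_line_dilated).sum()) / npix
    return frac if frac >= min_overlap else 0.0


def match_detections(pred, gt, criteria: MatchCriteria = MatchCriteria()) -> EvalCounts:
    """Score a DetectionResult against phantom GroundTruth.

    One-to-one, maximum-TP matching in two stages (boxes, then line
    components).  Line components can only match fractures that have a
    labelled line (displaced fractures have none).  A ground truth matched in
    both stages consumes both predictions but counts a single TP.
    """
    gt_specs = gt.specs
    n_gt = len(gt_specs)
    boxes = pred.boxes
    shape = gt.line_mask.shape

    # stage 1: boxes vs GT boxes
    compat = np.zeros((len(boxes), n_gt))
    for i, d in enumerate(boxes):
        for j, s in enumerate(gt_specs):
            iou = box_iou(d.box, s.box)
            if iou >= criteria.box_iou_min:
                compat[i, j] = iou
    box_pairs = _optimal_match(compat)
    matched_gt = {j for _, j in box_pairs}
    matched_box_pred = {i for i, _ in box_pairs}

    # stage 2: line components vs GT fracture lines (non-displaced only)
    comps = pred.line_components
    gt_dilated = {}
    struct = _disk(criteria.line_dilate_px)
    for j, s in enumerate(gt_specs):
        if s.shape != "displaced":
            raster = rasterize_polyline(s.polyline, shape)
            gt_dilated[j] = binary_dilation(raster, structure=struct)
    comp_masks = []
    for c in comps:
        m = np.zeros(shape, dtype=bool)
        x0, y0, x1, y1 = c["bbox"]
        m[y0:y1, x0:x1] = pred.line_mask[y0:y1, x0:x1] > 0
        comp_masks.append(m)

    lcompat = np.zeros((len(comps), n_gt))
    for i, cm in enumerate(comp_masks):
        for j in gt_dilated:
            lcompat[i, j] = _line_match_score(cm, gt_dilated[j],
                                              criteria.line_overlap_min)
    # prefer unmatched GT (new TPs) over consuming doubles: restrict a first
    # assignment to unmatched GT, then let leftovers consume matched GT
    unmatched_cols = [j for j in range(n_gt) if j not in matched_gt]
    sub = lcompat[:, unmatched_cols] if unmatched_cols else np.zeros((len(comps), 0))
    line_pairs = _optimal_match(sub)
    new_tp_gt = {unmatched_cols[c] for _, c in line_pairs}
    used_comps = {r for r, _ in line_pairs}

    consumed = 0
    for i in range(len(comps)):
        if i in used_comps:
            continue
        j_best = int(np.argmax(lcompat[i])) if n_gt else -1
        if j_best >= 0 and lcompat[i, j_best] > 0 and (
                j_best in matched_gt or j_best in new_tp_gt):
            consumed += 1
            used_comps.add(i)

    tp = len(matched_gt) + len(new_tp_gt)
    fp = (len(boxes) - len(matched_box_pred)) + (len(comps) - len(used_comps))
    fn = n_gt - tp
    return EvalCounts(tp=tp, fp=fp, fn=fn)


def _disk(radius: int) -> np.ndarray:
    yy, xx = np.mgrid[-radius:radius + 1, -radius:radius + 1]
    return xx * xx + yy * yy <= radius * radius


# ---------------------------------------------------------------------------
# metrics

def precision(c: EvalCounts) -> float:
    if c.tp + c.fp == 0:
        raise UndefinedMetricError("precision undefined: no predictions")
    return c.tp / (c.tp + c.fp)


def recall(c: EvalCounts) -> float:
    if c.tp + c.fn == 0:
        raise UndefinedMetricError("recall undefined: no ground truth")
    return c.tp / (c.tp + c.fn)


def f1(p: float, r: float) -> float:
    """Harmonic mean 2pr/(p+r) of precision and recall."""
    if p + r == 0:
        raise UndefinedMetricError("f1 undefined: precision = recall = 0")
    return 2.0 * p * r / (p + r)


# ---------------------------------------------------------------------------
# line profiles

def line_profile(image: np.ndarray, p0: tuple, p1: tuple) -> ProfileStats:
    """Max/min/mean/population-std of pixels along the Bresenham segment
    from ``p0`` to ``p1`` (points given as (x, y))."""
    if tuple(p0) == tuple(p1):
        raise ValueError("profile endpoints must differ")
    h, w = image.shape
    for (x, y) in (p0, p1):
        if not (0 <= x < w and 0 <= y < h):
            raise ValueError(f"endpoint {(x, y)} outside image {w}x{h}")
    from skimage.draw import line as draw_line
    rr, cc = draw_line(int(p0[1]), int(p0[0]), int(p1[1]), int(p1[0]))
    vals = image[rr, cc].astype(float)
    return ProfileStats(maximum=float(vals.max()), minimum=float(vals.min()),
                        mean=float(vals.mean()), std=float(vals.std()))


# ---------------------------------------------------------------------------
# class distributions

def _round3(x: float) -> float:
    return float(Decimal(repr(float(x))).quantize(Decimal("0.001"), ROUND_HALF_UP))


def class_distribution(counts) -> ClassDistribution:
    """Percentages (round-half-up, 3 decimals) plus middle/side shares.

    Middle = symphysis/body/angle/ramus; side = condyle/coronoid, matching
    the anatomical grouping used for panoramic radiographs (the side regions
    are laterally compressed in the projection).
    """
    c = np.asarray(counts, dtype=int)
    if c.shape != (6,):
        raise ValueError("counts must be a 6-vector")
    if np.any(c < 0) or c.sum() == 0:
        raise ValueError("counts must be nonnegative and not all zero")
    total = int(c.sum())
    pct = tuple(_round3(100.0 * k / total) for k in c)
    middle = _round3(100.0 * c[:4].sum() / total)
    side = _round3(100.0 * c[4:].sum() / total)
    return ClassDistribution(counts=tuple(int(k) for k in c), total=total,
                             percentages=pct, middle_share=middle,
                             side_share=side)


def evaluation_report(per_image_counts: list) -> dict:
    """Aggregate counts into the JSON report structure used by the CLI."""
    agg = EvalCounts(0, 0, 0)
    for c in per_image_counts:
        agg = agg + c
    rep = {
        "per_image": [{"tp": c.tp, "fp": c.fp, "fn": c.fn}
                      for c in per_image_counts],
        "total": {"tp": agg.tp, "fp": agg.fp, "fn": agg.fn},
    }
    try:
        p = precision(agg)
        r = recall(agg)
        rep["precision"] = _round3(p)
        rep["recall"] = _round3(r)
        rep["f1"] = _round3(f1(p, r))
    except UndefinedMetricError:
        rep["precision"] = rep["recall"] = rep["f1"] = None
    return rep
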