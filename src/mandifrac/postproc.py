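"""Tooth-region suppression, component filtering, NMS and box-line fusion.

This is the pipeline's bespoke stage.  The tooth-row mask predicted by the
second U-Net is dilated and hole-filled, inverted into a binary weight map,
and multiplied into the fracture-line mask: any fracture line predicted
inside the tooth band (almost always the radiolucent gap between two teeth)
is erased.  The surviving mask is despeckled, detector boxes are de-duplicated
with class-wise NMS, and boxes plus line components are reported together —
union semantics, no cross-modality suppression.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import binary_dilation, binary_fill_holes
from skimage.draw import rectangle_perimeter
from skimage.measure import label, regionprops

from .detect import Detection, box_iou


class PostprocError(ValueError):
    pass


@dataclass
class DetectionResult:
    boxes: list                      # [Detection], post duplicate removal
    line_components: list            # [dict(pixels=int, bbox=(x0,y0,x1,y1))]
    line_mask: np.ndarray            # suppressed + filtered binary mask
    overlay: np.ndarray | None = None


def _as_binary(mask: np.ndarray) -> np.ndarray:
    m = np.asarray(mask)
    if not np.isin(np.unique(m), (0, 1)).all():
        raise PostprocError("mask must be binary {0,1}")
    return m.astype(np.uint8)


def _disk(radius: int) -> np.ndarray:
    yy, xx = np.mgrid[-radius:radius + 1, -radius:radius + 1]
    return xx * xx + yy * yy <= radius * radius


def fill_tooth_region(mask: np.ndarray, se_radius: int = 3,
                      iterations: int = 2) -> np.ndarray:
    """Dilate the tooth mask and close its interior holes.

    Dilation is extensive (output contains input); flood-fill closes any
    remaining enclosed hole, so a second application changes nothing once the
    band is solid.
    """
    if se_radius < 1:
        raise PostprocError("se_radius must be >= 1")
    m = _as_binary(mask).astype(bool)
    out = binary_dilation(m, structure=_disk(se_radius), iterations=iterations)
    out = binary_fill_holes(out)
    return out.astype(np.uint8)


def invert_mask(mask: np.ndarray) -> np.ndarray:
    """Pixelwise 1 - v: the weight map used for suppression."""
    return (1 - _as_binary(mask)).astype(np.uint8)


def suppress_fracture_in_tooth(frac_mask: np.ndarray,
                               tooth_filled: np.ndarray) -> np.ndarray:
    """Multiply the fracture mask by the inverted tooth map.

    Equivalent to ``frac AND NOT tooth_filled``: fracture-line pixels inside
    the (filled) tooth region are erased, everything else passes through.
    """
    f = _as_binary(frac_mask)
    t = _as_binary(tooth_filled)
    if f.shape != t.shape:
        raise PostprocError(f"shape mismatch {f.shape} vs {t.shape}")
    return (f * invert_mask(t)).astype(np.uint8)


def filter_components(mask: np.ndarray, min_component_size: int = 20) -> np.ndarray:
    """Drop 8-connected components smaller than ``min_component_size`` px."""
    m = _as_binary(mask)
    if min_component_size <= 0:
        return m
    lab = label(m, connectivity=2)
    out = np.zeros_like(m)
    for r in regionprops(lab):
        if r.area >= min_component_size:
            out[lab == r.label] = 1
    return out


def remove_duplicate_boxes(dets: list, iou_threshold: float = 0.5) -> list:
    """Class-wise greedy NMS, confidence-descending.

    Ties in confidence are broken by larger area, then by left edge; a box is
    dropped when its IoU with an already-kept box of the same class reaches
    the threshold.  Idempotent and never increases the box count.
    """
    if not 0 < iou_threshold <= 1:
        raise PostprocError("iou_threshold must be in (0, 1]")
    order = sorted(dets, key=lambda d: (-d.confidence, -d.area, d.box[0]))
    kept = []
    for d in order:
        if any(k.klass == d.klass and box_iou(k.box, d.box) >= iou_threshold
               for k in kept):
            continue
        kept.append(d)
    return kept


def line_components(mask: np.ndarray) -> list:
    """Connected components of a line mask as (pixel count, bbox) records."""
    lab = label(_as_binary(mask), connectivity=2)
    comps = []
    for r in regionprops(lab):
        y0, x0, y1, x1 = r.bbox
        comps.append({"pixels": int(r.area), "bbox": (int(x0), int(y0),
                                                      int(x1), int(y1)),
                      "label": int(r.label)})
    return comps


def fuse_detections(boxes: list, line_mask: np.ndarray,
                    image: np.ndarray | None = None) -> DetectionResult:
    """Union of surviving boxes and line components, plus an overlay.

    ``line_mask`` must already be suppressed and filtered.  A line inside a
    box is kept — the two modalities are complementary, not competing.
    """
    m = _as_binary(line_mask)
    if image is not None and image.shape != m.shape:
        raise PostprocError("image and line_mask shapes differ")
    comps = line_components(m)
    overlay = None
    if image is not None:
        overlay = draw_overlay(image, boxes, m)
    return DetectionResult(boxes=list(boxes), line_components=comps,
                           line_mask=m, overlay=overlay)


def draw_overlay(image: np.ndarray, boxes: list, line_mask: np.ndarray) -> np.ndarray:
    """RGB overlay: detections as red rectangles, line pixels in red."""
    h, w = image.shape
    rgb = np.stack([image] * 3, axis=-1).astype(np.uint8)
    rgb[line_mask > 0] = (255, 40, 40)
    for d in boxes:
        x0, y0, x1, y1 = d.box
        rr, cc = rectangle_perimeter((y0, x0), end=(min(y1, h) - 1, min(x1, w) - 1),
                                     shape=(h, w))
        rgb[rr, cc] = (255, 40, 40)
    return rgb
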