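"""Box-detection stage: YOLO-format I/O and a pluggable box source.

The box source is either (a) a detections file — so any external detector's
output can drive the fusion stage — or (b) a compact reference detector: a
single-scale convolutional grid that predicts per-cell objectness, class
scores and box offsets, trainable on phantoms in minutes.  A full YOLOv4
backbone is deliberately out of scope; the pipeline's contribution is in the
suppression/fusion stages downstream of whatever produces the boxes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage.transform import resize

from . import _nn
from ._nn import Adam, Conv1x1, Conv3x3, MaxPool2, Sequential, conv_block, sigmoid
from .phantom import CLASS_NAMES


class DetectError(ValueError):
    pass


@dataclass(frozen=True)
class Detection:
    klass: str
    box: tuple              # (x0, y0, x1, y1), half-open pixel rect
    confidence: float = 1.0

    def __post_init__(self):
        if self.klass not in CLASS_NAMES:
            raise DetectError(f"unknown class {self.klass!r}")
        if not 0.0 <= self.confidence <= 1.0:
            raise DetectError("confidence must be in [0, 1]")
        x0, y0, x1, y1 = self.box
        if x1 <= x0 or y1 <= y0:
            raise DetectError("box must have positive extent")

    @property
    def area(self) -> float:
        x0, y0, x1, y1 = self.box
        return (x1 - x0) * (y1 - y0)


def box_iou(a: tuple, b: tuple) -> float:
    ax0, ay0, ax1, ay1 = a
    bx0, by0, bx1, by1 = b
    iw = min(ax1, bx1) - max(ax0, bx0)
    ih = min(ay1, by1) - max(ay0, by0)
    if iw <= 0 or ih <= 0:
        return 0.0
    inter = iw * ih
    union = (ax1 - ax0) * (ay1 - ay0) + (bx1 - bx0) * (by1 - by0) - inter
    return inter / union


# ---------------------------------------------------------------------------
# YOLO text I/O

def _yolo_to_pixels(cx, cy, w, h, width, height) -> tuple:
    pw, ph = round(w * width), round(h * height)
    x0 = round(cx * width - w * width / 2)
    y0 = round(cy * height - h * height / 2)
    return (int(x0), int(y0), int(x0 + pw), int(y0 + ph))


def read_annotations(path, image_size: tuple) -> list:
    """Parse a YOLO text file into pixel-space detections.

    ``image_size`` is (width, height).  Lines are ``class_id cx cy w h`` with
    an optional sixth confidence column; ground-truth files get confidence 1.
    """
    width, height = image_size
    path = Path(path)
    dets = []
    for ln, raw in enumerate(path.read_text().splitlines(), start=1):
        raw = raw.strip()
        if not raw:
            continue
        fields = raw.split()
        if len(fields) not in (5, 6):
            raise DetectError(f"{path}:{ln}: expected 5 or 6 fields, got {len(fields)}")
        try:
            cid = int(fields[0])
            cx, cy, w, h = map(float, fields[1:5])
            conf = float(fields[5]) if len(fields) == 6 else 1.0
        except ValueError as e:
            raise DetectError(f"{path}:{ln}: malformed number ({e})") from e
        if not 0 <= cid <= 5:
            raise DetectError(f"{path}:{ln}: class_id {cid} outside 0..5")
        if not (0 <= cx <= 1 and 0 <= cy <= 1 and 0 < w <= 1 and 0 < h <= 1):
            raise DetectError(f"{path}:{ln}: coordinates outside [0, 1]")
        box = _yolo_to_pixels(cx, cy, w, h, width, height)
        box = (max(box[0], 0), max(box[1], 0),
               min(box[2], width), min(box[3], height))
        dets.append(Detection(CLASS_NAMES[cid], box, conf))
    return dets


def write_detections(dets: list, path, image_size: tuple) -> None:
    """Write detections in YOLO text format with a confidence sixth column."""
    width, height = image_size
    lines = []
    for d in dets:
        x0, y0, x1, y1 = d.box
        cx, cy = (x0 + x1) / 2 / width, (y0 + y1) / 2 / height
        w, h = (x1 - x0) / width, (y1 - y0) / height
        cid = CLASS_NAMES.index(d.klass)
        lines.append(f"{cid} {cx:.6f} {cy:.6f} {w:.6f} {h:.6f} {d.confidence:.4f}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def detections_to_json(dets: list, path) -> None:
    Path(path).write_text(json.dumps(
        [{"class": d.klass, "box": list(d.box), "confidence": d.confidence}
         for d in dets], indent=1))


def detections_from_json(path) -> list:
    return [Detection(r["class"], tuple(r["box"]), r["confidence"])
            for r in json.loads(Path(path).read_text())]


# ---------------------------------------------------------------------------
# compact reference grid detector

@dataclass(frozen=True)
class GridDetectorSpec:
    input_size: int = 128
    grid: int = 8                # cells per side; input_size/grid = cell px
    base_channels: int = 8

    def __post_init__(self):
        if self.input_size % self.grid != 0:
            raise DetectError("input_size must be divisible by grid")


class GridDetector:
    """Single-scale grid detector: per cell 1 objectness + 4 box + 6 classes."""

    N_OUT = 1 + 4 + len(CLASS_NAMES)

    def __init__(self, spec: GridDetectorSpec, rng: np.random.Generator | None = None):
        self.spec = spec
        rng = rng or np.random.default_rng(0)
        n_pools = int(np.log2(spec.input_size // spec.grid))
        layers = []
        c_in, c = 1, spec.base_channels
        for _ in range(n_pools):
            layers.append(conv_block(c_in, c, "elu", 1.0, rng))
            layers.append(MaxPool2())
            c_in, c = c, min(c * 2, 64)
        layers.append(Conv3x3(c_in, c_in, rng, bias=True))
        layers.append(_nn.Activation("elu"))
        self.backbone = Sequential(layers)
        self.head = Conv1x1(c_in, self.N_OUT, rng)
        self._layers = [self.backbone, self.head]

    def forward(self, x, train=False):
        return self.head.forward(self.backbone.forward(x, train), train)

    def backward(self, dy):
        self.backbone.backward(self.head.backward(dy))

    def save(self, path):
        np.savez_compressed(path, __spec__=json.dumps(self.spec.__dict__),
                            **_nn.collect_state(self._layers))

    @classmethod
    def from_file(cls, path):
        data = np.load(path)
        spec = GridDetectorSpec(**json.loads(str(data["__spec__"])))
        model = cls(spec)
        _nn.load_state(model._layers,
                       {k: data[k] for k in data.files if k != "__spec__"})
        return model


def _encode_targets(boxes: list, spec: GridDetectorSpec, img_w: int, img_h: int):
    """Target tensors on the grid; one positive cell per GT box center."""
    g = spec.grid
    obj = np.zeros((1, g, g), dtype=_nn.F32)
    tbox = np.zeros((4, g, g), dtype=_nn.F32)
    tcls = np.zeros((len(CLASS_NAMES), g, g), dtype=_nn.F32)
    for klass, (x0, y0, x1, y1) in boxes:
        cx, cy = (x0 + x1) / 2 / img_w, (y0 + y1) / 2 / img_h
        gx, gy = min(int(cx * g), g - 1), min(int(cy * g), g - 1)
        obj[0, gy, gx] = 1.0
        tbox[0, gy, gx] = cx * g - gx          # in-cell offsets, [0,1)
        tbox[1, gy, gx] = cy * g - gy
        tbox[2, gy, gx] = np.sqrt((x1 - x0) / img_w)
        tbox[3, gy, gx] = np.sqrt((y1 - y0) / img_h)
        tcls[CLASS_NAMES.index(klass), gy, gx] = 1.0
    return obj, tbox, tcls


def train_detector(samples: list, spec: GridDetectorSpec | None = None,
                   epochs: int = 60, lr: float = 2e-3, batch_size: int = 8,
                   seed: int = 0) -> tuple:
    """Train the reference detector on (image, [(klass, box), ...]) samples."""
    if not samples:
        raise DetectError("training set must be nonempty")
    spec = spec or GridDetectorSpec()
    size = spec.input_size
    xs, objs, tboxes, tclss = [], [], [], []
    for img, boxes in samples:
        h, w = img.shape
        x = resize(img.astype(float), (size, size), order=1,
                   preserve_range=True, anti_aliasing=False) / 255.0
        xs.append(x)
        o, b, c = _encode_targets(boxes, spec, w, h)
        objs.append(o); tboxes.append(b); tclss.append(c)
    xs = np.stack(xs)[:, None].astype(_nn.F32)
    objs, tboxes, tclss = map(np.stack, (objs, tboxes, tclss))

    rng = np.random.default_rng(seed)
    model = GridDetector(spec, rng)
    opt = Adam(model._layers, lr=lr)
    n = len(samples)
    history = []
    for _ in range(epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            out = model.forward(xs[idx], train=True)
            loss, dout = _detector_loss(out, objs[idx], tboxes[idx], tclss[idx])
            model.backward(dout)
            opt.step()
            losses.append(loss)
        history.append(float(np.mean(losses)))
    return model, history


def _detector_loss(out, obj, tbox, tcls):
    """BCE objectness everywhere; box MSE + class BCE on positive cells."""
    n = out.shape[0]
    dout = np.zeros_like(out)
    zo = out[:, 0:1]
    po = sigmoid(zo)
    eps = 1e-7
    l_obj = -(obj * np.log(po + eps) + (1 - obj) * np.log(1 - po + eps)).mean()
    dout[:, 0:1] = (po - obj) / zo.size

    pos = obj > 0.5                            # (n,1,g,g)
    npos = max(int(pos.sum()), 1)
    pb = sigmoid(out[:, 1:5])
    diff = (pb - tbox) * pos
    l_box = float((diff ** 2).sum()) / npos
    dout[:, 1:5] = 2.0 * diff * pb * (1 - pb) / npos

    zc = out[:, 5:]
    pc = sigmoid(zc)
    l_cls = float(-(tcls * np.log(pc + eps)
                    + (1 - tcls) * np.log(1 - pc + eps))[np.broadcast_to(pos, zc.shape)].sum()) / npos
    dout[:, 5:] = (pc - tcls) * pos / npos

    return l_obj + 2.0 * l_box + 0.5 * l_cls, dout.astype(_nn.F32)


def _decode(out, spec: GridDetectorSpec, img_w: int, img_h: int,
            conf_threshold: float) -> list:
    g = spec.grid
    po = sigmoid(out[0, 0])
    pb = sigmoid(out[0, 1:5])
    pc = sigmoid(out[0, 5:])
    dets = []
    for gy in range(g):
        for gx in range(g):
            conf = float(po[gy, gx])
            if conf <= conf_threshold:
                continue
            cx = (gx + pb[0, gy, gx]) / g * img_w
            cy = (gy + pb[1, gy, gx]) / g * img_h
            bw = float(pb[2, gy, gx]) ** 2 * img_w
            bh = float(pb[3, gy, gx]) ** 2 * img_h
            x0, y0 = cx - bw / 2, cy - bh / 2
            box = (int(max(round(x0), 0)), int(max(round(y0), 0)),
                   int(min(round(x0 + bw), img_w)), int(min(round(y0 + bh), img_h)))
            if box[2] <= box[0] or box[3] <= box[1]:
                continue
            cid = int(pc[:, gy, gx].argmax())
            dets.append(Detection(CLASS_NAMES[cid], box, conf))
    return dets


def detect_boxes(source, image: np.ndarray, conf_threshold: float = 0.25) -> list:
    """Run the box source on an image.

    ``source`` is a path (YOLO ``.txt`` or detections ``.json`` — the
    stand-in for an external detector) or a trained :class:`GridDetector`.
    """
    h, w = image.shape
    if isinstance(source, (str, Path)):
        p = Path(source)
        if not p.exists():
            raise DetectError(f"detections file not found: {p}")
        if p.suffix == ".json":
            return detections_from_json(p)
        return read_annotations(p, (w, h))
    if isinstance(source, GridDetector):
        size = source.spec.input_size
        x = resize(image.astype(float), (size, size), order=1,
                   preserve_range=True, anti_aliasing=False) / 255.0
        out = source.forward(x[None, None].astype(_nn.F32), train=False)
        return _decode(out, source.spec, w, h, conf_threshold)
    raise DetectError(f"unsupported box source: {type(source).__name__}")
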