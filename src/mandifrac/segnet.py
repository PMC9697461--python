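"""U-Net construction, training and mask inference.

The same network is trained twice in the pipeline: once on fracture-line
masks and once on tooth-row-region masks.  The architecture is the standard
encoder/decoder with skip connections — per resolution level two 3x3
conv + batch-norm + activation blocks, 2x2 max pooling on the way down
(channels double), nearest upsampling plus skip concatenation on the way up —
with the activation selectable between ReLU, LeakyReLU and ELU.  ELU is the
default: its exponential negative branch keeps gradients alive for negative
inputs, which lowers the false-detection rate on thin fracture lines.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from skimage.transform import resize

from . import _nn
from ._nn import (Adam, Conv1x1, MaxPool2, bce_dice_loss, conv_block, sigmoid)

elu = _nn.elu  # scalar/array ELU, re-exported as part of this module's surface


class SegnetError(ValueError):
    pass


@dataclass(frozen=True)
class UNetSpec:
    input_size: int = 512
    depth: int = 5
    base_channels: int = 16
    activation: str = "elu"
    elu_alpha: float = 1.0

    def __post_init__(self):
        if self.depth < 2:
            raise SegnetError("depth must be >= 2")
        if self.input_size % (2 ** (self.depth - 1)) != 0:
            raise SegnetError(
                f"input_size {self.input_size} not divisible by 2^{self.depth - 1}")
        if self.activation not in ("relu", "leaky_relu", "elu"):
            raise SegnetError(f"unknown activation {self.activation!r}")
        if self.elu_alpha <= 0:
            raise SegnetError("elu_alpha must be > 0")


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 6
    learning_rate: float = 1e-4
    epochs: int = 300
    seed: int = 0
    loss: str = "bce_dice"      # "bce" or "bce_dice"
    dice_weight: float = 1.0

    def __post_init__(self):
        if self.batch_size < 1:
            raise SegnetError("batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise SegnetError("learning_rate must be > 0")
        if self.loss not in ("bce", "bce_dice"):
            raise SegnetError(f"unknown loss {self.loss!r}")


#: desk-scale training recipe: small net, few epochs, minutes on one CPU
SMOKE_UNET = UNetSpec(input_size=128, depth=3, base_channels=8, activation="elu")
SMOKE_TRAIN = TrainConfig(batch_size=4, learning_rate=2e-3, epochs=30, seed=0)


class UNet:
    """Encoder-decoder segmentation network with skip connections."""

    def __init__(self, spec: UNetSpec, rng: np.random.Generator | None = None):
        self.spec = spec
        rng = rng or np.random.default_rng(0)
        act, al = spec.activation, spec.elu_alpha
        ch = [spec.base_channels * 2 ** i for i in range(spec.depth)]
        self.enc = [conv_block(1 if i == 0 else ch[i - 1], ch[i], act, al, rng)
                    for i in range(spec.depth - 1)]
        self.bottleneck = conv_block(ch[spec.depth - 2], ch[spec.depth - 1],
                                     act, al, rng)
        self.dec = [conv_block(ch[i] + ch[i + 1], ch[i], act, al, rng)
                    for i in range(spec.depth - 1)]
        self.head = Conv1x1(ch[0], 1, rng)
        self._layers = self.enc + [self.bottleneck] + self.dec + [self.head]
        self._pools = []

    # -- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        skips = []
        self._pools = []
        h = x
        for blk in self.enc:
            h = blk.forward(h, train)
            skips.append(h)
            p = MaxPool2()
            h = p.forward(h, train)
            self._pools.append(p)
        h = self.bottleneck.forward(h, train)
        self._skip_channels = [s.shape[1] for s in skips]
        # decoder, bottom (coarse) to top (full resolution)
        for i in reversed(range(len(self.dec))):
            h = _up(h)
            h = np.concatenate([skips[i], h], axis=1)
            h = self.dec[i].forward(h, train)
        return self.head.forward(h, train)

    def backward(self, dlogits: np.ndarray) -> None:
        dy = self.head.backward(dlogits)
        dskips = [None] * len(self.dec)
        # reverse through the decoder: top block first
        for i in range(len(self.dec)):
            dy = self.dec[i].backward(dy)
            cs = self._skip_channels[i]
            dskips[i] = dy[:, :cs]
            dy = _up_backward(dy[:, cs:])
        dy = self.bottleneck.backward(dy)
        for i in reversed(range(len(self.enc))):
            dy = self._pools[i].backward(dy)
            dy = dy + dskips[i]
            dy = self.enc[i].backward(dy)

    # -- persistence --------------------------------------------------------
    def state(self) -> dict:
        return _nn.collect_state(self._layers)

    def load(self, state: dict) -> None:
        _nn.load_state(self._layers, state)

    def save(self, path) -> None:
        path = Path(path)
        np.savez_compressed(path, __spec__=json.dumps(asdict(self.spec)),
                            **self.state())

    @classmethod
    def from_file(cls, path) -> "UNet":
        data = np.load(path)
        spec = UNetSpec(**json.loads(str(data["__spec__"])))
        model = cls(spec)
        model.load({k: data[k] for k in data.files if k != "__spec__"})
        return model


def _up(h):
    return h.repeat(2, axis=2).repeat(2, axis=3)


def _up_backward(dy):
    n, c, h, w = dy.shape
    return dy.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5)).astype(_nn.F32)


def build_unet(spec: UNetSpec, seed: int = 0) -> UNet:
    """Construct a U-Net with He-initialised weights (deterministic in seed)."""
    return UNet(spec, np.random.default_rng(seed))


# ---------------------------------------------------------------------------
# training

def _to_net_size(image: np.ndarray, size: int, is_mask: bool) -> np.ndarray:
    if image.shape == (size, size):
        return image.astype(float)
    order = 0 if is_mask else 1
    out = resize(image.astype(float), (size, size), order=order,
                 preserve_range=True, anti_aliasing=False)
    return out


def train_segmenter(pairs: list, cfg: TrainConfig, spec: UNetSpec,
                    log_fn=None) -> tuple:
    """Train a U-Net on (image, binary mask) pairs; returns (model, history).

    Images are scaled to [0, 1] at the network input; per-epoch mean loss is
    recorded.  Fixed ``cfg.seed`` gives an identical loss trajectory.
    """
    if not pairs:
        raise SegnetError("training set must be nonempty")
    size = spec.input_size
    xs = np.stack([_to_net_size(im, size, False) / 255.0 for im, _ in pairs])
    ys = np.stack([(_to_net_size(m, size, True) > 0.5).astype(float)
                   for _, m in pairs])
    xs = xs[:, None].astype(_nn.F32)
    ys = ys[:, None].astype(_nn.F32)

    rng = np.random.default_rng(cfg.seed)
    model = UNet(spec, rng)
    opt = Adam(model._layers, lr=cfg.learning_rate)
    dice_w = cfg.dice_weight if cfg.loss == "bce_dice" else 0.0

    history = []
    n = len(pairs)
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            logits = model.forward(xs[idx], train=True)
            loss, dlogits = bce_dice_loss(logits, ys[idx], dice_w)
            model.backward(dlogits)
            opt.step()
            losses.append(loss)
        history.append(float(np.mean(losses)))
        if log_fn is not None:
            log_fn(epoch, history[-1])
    return model, history


def predict_mask(model: UNet, image: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Binary mask at the input image's own resolution.

    The image is resized to the network input size, segmented, thresholded
    (strictly greater, so threshold 1.0 is empty and 0.0 is all ones), and
    the mask is mapped back by nearest-neighbour resize.
    """
    h, w = image.shape
    size = model.spec.input_size
    x = (_to_net_size(image, size, False) / 255.0)[None, None].astype(_nn.F32)
    logits = model.forward(x, train=False)
    prob = sigmoid(logits)[0, 0]
    mask = (prob > threshold).astype(np.uint8)
    if mask.shape != (h, w):
        mask = resize(mask, (h, w), order=0, preserve_range=True,
                      anti_aliasing=False).astype(np.uint8)
    return mask


def dice_coefficient(a: np.ndarray, b: np.ndarray) -> float:
    """2|A∩B| / (|A|+|B|); defined as 1.0 when both masks are empty."""
    a = np.asarray(a) > 0
    b = np.asarray(b) > 0
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / denom


def save_manifest(path, cfg: TrainConfig, spec: UNetSpec, history: list) -> None:
    Path(path).write_text(json.dumps({
        "train_config": asdict(cfg), "unet_spec": asdict(spec),
        "loss_history": history,
    }, indent=1))
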