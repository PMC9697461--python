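"""Minimal NumPy convolutional-network engine.

Implements exactly the pieces the segmentation U-Net and the compact grid
detector need: 3x3 (same-padding) and 1x1 convolutions via im2col, batch
normalization, ReLU / LeakyReLU / ELU activations, 2x2 max pooling, nearest
2x upsampling, channel concatenation, and an Adam optimizer.  Every layer has
an explicit ``forward``/``backward`` pair; tensors are ``float32`` arrays in
NCHW layout.  Everything is deterministic given the initialisation RNG.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

F32 = np.float32


def elu(x, alpha: float = 1.0):
    """ELU: x for x >= 0, alpha*(exp(x)-1) otherwise; C1 at 0 for alpha=1.

    The negative branch keeps a nonzero derivative alpha*exp(x) everywhere,
    which is the point of using it over ReLU (no dying units).
    """
    x = np.asarray(x, dtype=float)
    out = np.where(x >= 0, x, alpha * np.expm1(np.minimum(x, 0.0)))
    return out if out.ndim else float(out)


class Layer:
    params: dict
    grads: dict

    def __init__(self):
        self.params, self.grads = {}, {}

    def forward(self, x, train: bool):
        raise NotImplementedError

    def backward(self, dy):
        raise NotImplementedError


class Conv3x3(Layer):
    """3x3 convolution, stride 1, zero same-padding, no bias (BN follows)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 bias: bool = False):
        super().__init__()
        fan_in = c_in * 9
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, fan_in))
        self.params["w"] = w.astype(F32)
        self.c_in, self.c_out = c_in, c_out
        self.use_bias = bias
        if bias:
            self.params["b"] = np.zeros(c_out, dtype=F32)

    def forward(self, x, train: bool):
        n, c, h, w = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        win = sliding_window_view(xp, (3, 3), axis=(2, 3))  # n,c,h,w,3,3
        cols = win.transpose(0, 1, 4, 5, 2, 3).reshape(n, c * 9, h * w)
        self._cols, self._shape = cols, (n, c, h, w)
        out = np.matmul(self.params["w"], cols).reshape(n, self.c_out, h, w)
        if self.use_bias:
            out += self.params["b"][None, :, None, None]
        return np.ascontiguousarray(out, dtype=F32)

    def backward(self, dy):
        n, c, h, w = self._shape
        dyf = dy.reshape(n, self.c_out, h * w)
        self.grads["w"] = np.einsum("nfp,ncp->fc", dyf, self._cols,
                                    optimize=True).astype(F32)
        if self.use_bias:
            self.grads["b"] = dy.sum(axis=(0, 2, 3)).astype(F32)
        dcols = np.matmul(self.params["w"].T, dyf)       # n, c*9, h*w
        dcols = dcols.reshape(n, c, 3, 3, h, w)
        dxp = np.zeros((n, c, h + 2, w + 2), dtype=F32)
        for ky in range(3):
            for kx in range(3):
                dxp[:, :, ky:ky + h, kx:kx + w] += dcols[:, :, ky, kx]
        self._cols = None
        return dxp[:, :, 1:h + 1, 1:w + 1]


class Conv1x1(Layer):
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        super().__init__()
        w = rng.normal(0.0, np.sqrt(2.0 / c_in), size=(c_out, c_in))
        self.params["w"] = w.astype(F32)
        self.params["b"] = np.zeros(c_out, dtype=F32)

    def forward(self, x, train: bool):
        self._x = x
        out = np.einsum("fc,nchw->nfhw", self.params["w"], x, optimize=True)
        return (out + self.params["b"][None, :, None, None]).astype(F32)

    def backward(self, dy):
        self.grads["w"] = np.einsum("nfhw,nchw->fc", dy, self._x,
                                    optimize=True).astype(F32)
        self.grads["b"] = dy.sum(axis=(0, 2, 3)).astype(F32)
        dx = np.einsum("fc,nfhw->nchw", self.params["w"], dy, optimize=True)
        self._x = None
        return dx.astype(F32)


class BatchNorm(Layer):
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.params["gamma"] = np.ones(c, dtype=F32)
        self.params["beta"] = np.zeros(c, dtype=F32)
        self.running_mean = np.zeros(c, dtype=F32)
        self.running_var = np.ones(c, dtype=F32)
        self.momentum, self.eps = momentum, eps

    def forward(self, x, train: bool):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean).astype(F32)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var).astype(F32)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        self._xhat, self._inv, self._train = xhat.astype(F32), inv, train
        g, b = self.params["gamma"], self.params["beta"]
        return (xhat * g[None, :, None, None] + b[None, :, None, None]).astype(F32)

    def backward(self, dy):
        xhat, inv = self._xhat, self._inv
        g = self.params["gamma"]
        self.grads["gamma"] = (dy * xhat).sum(axis=(0, 2, 3)).astype(F32)
        self.grads["beta"] = dy.sum(axis=(0, 2, 3)).astype(F32)
        if not self._train:
            return (dy * (g * inv)[None, :, None, None]).astype(F32)
        m = dy.shape[0] * dy.shape[2] * dy.shape[3]
        dxhat = dy * g[None, :, None, None]
        t1 = dxhat.sum(axis=(0, 2, 3), keepdims=True)
        t2 = (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
        dx = (inv[None, :, None, None] / m) * (m * dxhat - t1 - xhat * t2)
        self._xhat = None
        return dx.astype(F32)


class Activation(Layer):
    def __init__(self, kind: str, alpha: float = 1.0):
        super().__init__()
        if kind not in ("relu", "leaky_relu", "elu"):
            raise ValueError(f"unknown activation {kind!r}")
        self.kind, self.alpha = kind, alpha

    def forward(self, x, train: bool):
        if self.kind == "relu":
            out = np.maximum(x, 0)
            self._grad = (x > 0).astype(F32)
        elif self.kind == "leaky_relu":
            out = np.where(x > 0, x, 0.01 * x)
            self._grad = np.where(x > 0, F32(1.0), F32(0.01))
        else:
            neg = self.alpha * np.expm1(np.minimum(x, 0.0))
            out = np.where(x >= 0, x, neg)
            self._grad = np.where(x >= 0, F32(1.0), (neg + self.alpha)).astype(F32)
        return out.astype(F32)

    def backward(self, dy):
        g, self._grad = self._grad, None
        return (dy * g).astype(F32)


class MaxPool2(Layer):
    def forward(self, x, train: bool):
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        xr = xr.reshape(n, c, h // 2, w // 2, 4)
        self._idx = xr.argmax(axis=-1)
        self._shape = (n, c, h, w)
        return np.take_along_axis(xr, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, dy):
        n, c, h, w = self._shape
        flat = np.zeros((n, c, h // 2, w // 2, 4), dtype=F32)
        np.put_along_axis(flat, self._idx[..., None], dy[..., None], axis=-1)
        flat = flat.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        self._idx = None
        return flat.reshape(n, c, h, w)


class Upsample2(Layer):
    def forward(self, x, train: bool):
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dy):
        n, c, h, w = dy.shape
        return dy.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5)).astype(F32)


class Sequential(Layer):
    def __init__(self, layers: list):
        super().__init__()
        self.layers = layers

    def forward(self, x, train: bool):
        for l in self.layers:
            x = l.forward(x, train)
        return x

    def backward(self, dy):
        for l in reversed(self.layers):
            dy = l.backward(dy)
        return dy


def conv_block(c_in, c_out, activation, elu_alpha, rng) -> Sequential:
    """conv3x3 -> batch norm -> activation, twice."""
    return Sequential([
        Conv3x3(c_in, c_out, rng), BatchNorm(c_out),
        Activation(activation, elu_alpha),
        Conv3x3(c_out, c_out, rng), BatchNorm(c_out),
        Activation(activation, elu_alpha),
    ])


def iter_layers(layer):
    if isinstance(layer, Sequential):
        for l in layer.layers:
            yield from iter_layers(l)
    else:
        yield layer


class Adam:
    def __init__(self, layers: list, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.entries = []
        for top in layers:
            for l in iter_layers(top):
                for k in l.params:
                    self.entries.append((l, k))
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(l.params[k]) for l, k in self.entries]
        self.v = [np.zeros_like(l.params[k]) for l, k in self.entries]
        self.t = 0

    def step(self):
        self.t += 1
        b1t, b2t = 1 - self.b1 ** self.t, 1 - self.b2 ** self.t
        for i, (l, k) in enumerate(self.entries):
            g = l.grads.get(k)
            if g is None:
                continue
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            l.params[k] -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(F32)


# ---------------------------------------------------------------------------
# losses

def sigmoid(z):
    out = np.empty_like(z, dtype=F32)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_dice_loss(logits, targets, dice_weight: float = 1.0):
    """Mean binary cross-entropy plus a soft-Dice term; returns (loss, dlogits).

    The Dice term counteracts the extreme foreground/background imbalance of
    thin fracture-line masks, which plain BCE handles poorly.
    """
    p = sigmoid(logits)
    t = targets
    n = logits.size
    eps = 1e-7
    bce = -(t * np.log(p + eps) + (1 - t) * np.log(1 - p + eps)).mean()
    dbce = (p - t) / n

    smooth = 1.0
    inter = float((p * t).sum())
    sums = float(p.sum() + t.sum())
    dice = (2 * inter + smooth) / (sums + smooth)
    # d(1-dice)/dp = -(2*t*(sums+s) - (2*inter+s)) / (sums+s)^2
    ddice_dp = -(2 * t * (sums + smooth) - (2 * inter + smooth)) / (sums + smooth) ** 2
    dlogits = dbce + dice_weight * ddice_dp * p * (1 - p)
    loss = bce + dice_weight * (1.0 - dice)
    return float(loss), dlogits.astype(F32)


# ---------------------------------------------------------------------------
# parameter (de)serialisation

def collect_state(layers: list) -> dict:
    state = {}
    for ti, top in enumerate(layers):
        for li, l in enumerate(iter_layers(top)):
            for k, v in l.params.items():
                state[f"{ti}.{li}.{k}"] = v
            if isinstance(l, BatchNorm):
                state[f"{ti}.{li}.running_mean"] = l.running_mean
                state[f"{ti}.{li}.running_var"] = l.running_var
    return state


def load_state(layers: list, state: dict) -> None:
    for ti, top in enumerate(layers):
        for li, l in enumerate(iter_layers(top)):
            for k in l.params:
                l.params[k] = np.array(state[f"{ti}.{li}.{k}"], dtype=F32)
            if isinstance(l, BatchNorm):
                l.running_mean = np.array(state[f"{ti}.{li}.running_mean"], dtype=F32)
                l.running_var = np.array(state[f"{ti}.{li}.running_var"], dtype=F32)
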