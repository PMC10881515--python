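"""Minimal NumPy neural-network backend.

Two backbones live here behind one interface:

* :class:`ToyCNN` — a small 4-block convolutional classifier with full
  backpropagation and plain SGD, sized so that desk-scale training runs on a
  single CPU in minutes. Its declared feature layer is the penultimate
  globally-average-pooled activation.
* :class:`EfficientNetB0` — a forward-only implementation of the standard
  EfficientNet-B0 architecture (MBConv blocks with squeeze-and-excitation)
  up to and including the 672-channel ``block6a_expand_activation`` layer
  used for feature extraction. Weights are He-initialized deterministically
  from a seed; batch-norm layers run with identity statistics. All
  architecture contracts (layer names, channel counts) follow the standard
  B0 definition.

Convolutions are computed as a sum of kernel-shift matrix products, which
keeps peak memory low and is fast enough at desk scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["ToyCNN", "EfficientNetB0", "SGD", "softmax"]


# ---------------------------------------------------------------------------
# functional primitives
# ---------------------------------------------------------------------------

def _same_pad(size: int, k: int, s: int) -> tuple[int, int]:
    """TF-style 'same' padding amounts (before, after) for one dimension."""
    out = math.ceil(size / s)
    total = max((out - 1) * s + k - size, 0)
    return total // 2, total - total // 2


def _pad_same(x: np.ndarray, kh: int, kw: int, s: int) -> np.ndarray:
    ph = _same_pad(x.shape[1], kh, s)
    pw = _same_pad(x.shape[2], kw, s)
    if ph == (0, 0) and pw == (0, 0):
        return x
    return np.pad(x, ((0, 0), ph, pw, (0, 0)))


def conv2d(x: np.ndarray, w: np.ndarray, b: np.ndarray | None = None, stride: int = 1,
           padding: str = "same") -> np.ndarray:
    """Standard convolution; x: (N,H,W,Cin), w: (kh,kw,Cin,Cout)."""
    kh, kw = w.shape[:2]
    xp = _pad_same(x, kh, kw, stride) if padding == "same" else x
    ho = (xp.shape[1] - kh) // stride + 1
    wo = (xp.shape[2] - kw) // stride + 1
    out = np.zeros((x.shape[0], ho, wo, w.shape[3]), dtype=np.float32)
    for i in range(kh):
        for j in range(kw):
            sl = xp[:, i : i + ho * stride : stride, j : j + wo * stride : stride, :]
            out += sl @ w[i, j]
    if b is not None:
        out += b
    return out


def depthwise_conv2d(x: np.ndarray, w: np.ndarray, stride: int = 1) -> np.ndarray:
    """Depthwise convolution; x: (N,H,W,C), w: (kh,kw,C)."""
    kh, kw = w.shape[:2]
    xp = _pad_same(x, kh, kw, stride)
    ho = (xp.shape[1] - kh) // stride + 1
    wo = (xp.shape[2] - kw) // stride + 1
    out = np.zeros((x.shape[0], ho, wo, x.shape[3]), dtype=np.float32)
    for i in range(kh):
        for j in range(kw):
            sl = xp[:, i : i + ho * stride : stride, j : j + wo * stride : stride, :]
            out += sl * w[i, j]
    return out


def swish(x: np.ndarray) -> np.ndarray:
    return x * (1.0 / (1.0 + np.exp(-x)))


def sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _he_conv(rng: np.random.Generator, kh: int, kw: int, cin: int, cout: int) -> np.ndarray:
    std = math.sqrt(2.0 / (kh * kw * cin))
    return rng.normal(0.0, std, size=(kh, kw, cin, cout)).astype(np.float32)


def _he_dense(rng: np.random.Generator, n_in: int, n_out: int) -> np.ndarray:
    std = math.sqrt(2.0 / n_in)
    return rng.normal(0.0, std, size=(n_in, n_out)).astype(np.float32)


# ---------------------------------------------------------------------------
# trainable layers for the toy CNN
# ---------------------------------------------------------------------------

class Conv2D:
    """3x3 'same' stride-1 convolution with backprop."""

    def __init__(self, rng: np.random.Generator, cin: int, cout: int, k: int = 3):
        self.w = _he_conv(rng, k, k, cin, cout)
        self.b = np.zeros(cout, dtype=np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self.k = k

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._xp = _pad_same(x, self.k, self.k, 1)
        self._in_shape = x.shape
        return conv2d(x, self.w, self.b, stride=1, padding="same")

    def backward(self, grad: np.ndarray) -> np.ndarray:
        k = self.k
        n, ho, wo, _ = grad.shape
        self.dw.fill(0.0)
        dxp = np.zeros_like(self._xp)
        for i in range(k):
            for j in range(k):
                sl = self._xp[:, i : i + ho, j : j + wo, :]
                self.dw[i, j] = np.tensordot(sl, grad, axes=([0, 1, 2], [0, 1, 2]))
                dxp[:, i : i + ho, j : j + wo, :] += grad @ self.w[i, j].T
        self.db = grad.sum(axis=(0, 1, 2))
        ph = _same_pad(self._in_shape[1], k, 1)
        pw = _same_pad(self._in_shape[2], k, 1)
        return dxp[:, ph[0] : dxp.shape[1] - ph[1], pw[0] : dxp.shape[2] - pw[1], :]

    @property
    def params(self):
        return [(self.w, self.dw), (self.b, self.db)]


class ReLU:
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask

    params: list = []


class MaxPool2:
    """2x2 max pooling, stride 2 (input H, W assumed even)."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        r = x.reshape(n, h // 2, 2, w // 2, 2, c).transpose(0, 1, 3, 5, 2, 4)
        r = r.reshape(n, h // 2, w // 2, c, 4)
        self._argmax = r.argmax(axis=-1)
        self._in_shape = x.shape
        return np.take_along_axis(r, self._argmax[..., None], axis=-1)[..., 0]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, ho, wo, c = grad.shape
        slots = np.zeros((n, ho, wo, c, 4), dtype=grad.dtype)
        np.put_along_axis(slots, self._argmax[..., None], grad[..., None], axis=-1)
        out = slots.reshape(n, ho, wo, c, 2, 2).transpose(0, 1, 4, 2, 5, 3)
        return out.reshape(self._in_shape)

    params: list = []


class GlobalAvgPool:
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._in_shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, h, w, c = self._in_shape
        return np.broadcast_to(grad[:, None, None, :] / (h * w), self._in_shape).copy()

    params: list = []


class Dense:
    def __init__(self, rng: np.random.Generator, n_in: int, n_out: int):
        self.w = _he_dense(rng, n_in, n_out)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.w + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.dw = self._x.T @ grad
        self.db = grad.sum(axis=0)
        return grad @ self.w.T

    @property
    def params(self):
        return [(self.w, self.dw), (self.b, self.db)]


class SGD:
    """Plain stochastic gradient descent (momentum 0, constant LR)."""

    def __init__(self, params, lr: float = 0.005):
        self.params = params
        self.lr = lr

    def step(self) -> None:
        for w, dw in self.params:
            w -= self.lr * dw


class ToyCNN:
    """Small 4-block CNN classifier for desk-scale training.

    Feature layer: ``pooled_features`` — the globally averaged activation of
    the last convolutional block (dimension = ``widths[-1]``).
    """

    FEATURE_LAYER = "pooled_features"

    def __init__(
        self,
        n_channels: int = 5,
        n_classes: int = 2,
        widths: tuple[int, ...] = (16, 32, 64, 64),
        seed: int = 0,
    ):
        rng = np.random.default_rng(seed)
        self.widths = widths
        self.layers = []
        cin = n_channels
        for w in widths:
            self.layers += [Conv2D(rng, cin, w), ReLU(), MaxPool2()]
            cin = w
        self.pool = GlobalAvgPool()
        self.head = Dense(rng, cin, n_classes)
        self.n_classes = n_classes
        self.n_channels = n_channels
        self.feature_dim = cin

    @property
    def available_layers(self) -> list[str]:
        return [self.FEATURE_LAYER]

    def features(self, x: np.ndarray, layer: str | None = None) -> np.ndarray:
        layer = layer or self.FEATURE_LAYER
        if layer != self.FEATURE_LAYER:
            raise KeyError(
                f"layer {layer!r} not found; available layers: {self.available_layers}"
            )
        h = np.asarray(x, dtype=np.float32)
        for lyr in self.layers:
            h = lyr.forward(h)
        return self.pool.forward(h)

    def forward(self, x: np.ndarray) -> np.ndarray:
        return self.head.forward(self.features(x))

    def backward_from_logits(self, dlogits: np.ndarray) -> None:
        grad = self.head.backward(dlogits)
        grad = self.pool.backward(grad)
        for lyr in reversed(self.layers):
            grad = lyr.backward(grad)

    def parameters(self):
        out = []
        for lyr in self.layers:
            out.extend(lyr.params)
        out.extend(self.head.params)
        return out

    def predict_proba(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        probs = []
        for i in range(0, len(x), batch_size):
            probs.append(softmax(self.forward(x[i : i + batch_size])))
        return np.concatenate(probs) if probs else np.zeros((0, self.n_classes))


def cross_entropy(logits: np.ndarray, targets: np.ndarray) -> tuple[float, np.ndarray]:
    """Categorical cross-entropy against target distributions.

    Returns (mean loss, gradient w.r.t. logits). ``targets`` rows are
    probability vectors (hard one-hot or smoothed/soft labels).
    """
    p = softmax(logits)
    eps = 1e-12
    loss = float(-(targets * np.log(p + eps)).sum(axis=1).mean())
    dlogits = (p - targets) / logits.shape[0]
    return loss, dlogits


# ---------------------------------------------------------------------------
# EfficientNet-B0 (forward only)
# ---------------------------------------------------------------------------

# (kernel, stride, expand_ratio, in_filters, out_filters, n_repeats)
_B0_BLOCKS = [
    (3, 1, 1, 32, 16, 1),   # block1
    (3, 2, 6, 16, 24, 2),   # block2
    (5, 2, 6, 24, 40, 2),   # block3
    (3, 2, 6, 40, 80, 3),   # block4
    (5, 1, 6, 80, 112, 3),  # block5
    (5, 2, 6, 112, 192, 4), # block6
    (3, 1, 6, 192, 320, 1), # block7
]
_SE_RATIO = 0.25


class EfficientNetB0:
    """Forward-only EfficientNet-B0 feature extractor.

    Layer names follow the standard naming (``stem_activation``,
    ``block<i><a-z>_expand_activation``, ...). The default feature layer is
    ``block6a_expand_activation`` whose channel count is 672 (the block-6
    input width 112 times the expansion ratio 6) — an architecture property
    independent of input spatial size. Activations are globally average
    pooled by the callers in :mod:`morphoprof.features`.

    ``n_input_channels`` other than 3 inflates the stem by channel-mean
    replication (each new input channel uses the mean of the 3-channel stem
    kernel, rescaled by 3/n to preserve activation magnitude).
    """

    FEATURE_LAYER = "block6a_expand_activation"

    def __init__(self, n_input_channels: int = 3, seed: int = 0):
        rng = np.random.default_rng(seed)
        stem3 = _he_conv(rng, 3, 3, 3, 32)
        if n_input_channels == 3:
            self.stem_w = stem3
        else:
            mean = stem3.mean(axis=2, keepdims=True)
            self.stem_w = np.repeat(mean, n_input_channels, axis=2) * (3.0 / n_input_channels)
        self.n_input_channels = n_input_channels

        self.blocks = []
        self._layer_dims: dict[str, int] = {"stem_activation": 32}
        for bi, (k, s, e, cin, cout, reps) in enumerate(_B0_BLOCKS, start=1):
            for r in range(reps):
                name = f"block{bi}{chr(ord('a') + r)}"
                b_in = cin if r == 0 else cout
                b_stride = s if r == 0 else 1
                mid = b_in * e
                se = max(1, int(b_in * _SE_RATIO))
                params = {
                    "name": name,
                    "kernel": k,
                    "stride": b_stride,
                    "expand": e,
                    "cin": b_in,
                    "cmid": mid,
                    "cout": cout,
                    "w_expand": _he_conv(rng, 1, 1, b_in, mid) if e != 1 else None,
                    "w_dw": rng.normal(0, math.sqrt(2.0 / (k * k)), size=(k, k, mid)).astype(np.float32),
                    "w_se_reduce": _he_dense(rng, mid, se),
                    "b_se_reduce": np.zeros(se, dtype=np.float32),
                    "w_se_expand": _he_dense(rng, se, mid),
                    "b_se_expand": np.zeros(mid, dtype=np.float32),
                    "w_project": _he_conv(rng, 1, 1, mid, cout),
                }
                self.blocks.append(params)
                if e != 1:
                    self._layer_dims[f"{name}_expand_activation"] = mid
                self._layer_dims[f"{name}_project_bn"] = cout

    @property
    def available_layers(self) -> list[str]:
        return sorted(self._layer_dims)

    def feature_dim(self, layer: str | None = None) -> int:
        layer = layer or self.FEATURE_LAYER
        if layer not in self._layer_dims:
            raise KeyError(
                f"layer {layer!r} not found; available layers: {self.available_layers}"
            )
        return self._layer_dims[layer]

    def forward_features(self, x: np.ndarray, layer: str | None = None) -> np.ndarray:
        """Run the network up to ``layer`` and return its activation map."""
        layer = layer or self.FEATURE_LAYER
        if layer not in self._layer_dims:
            raise KeyError(
                f"layer {layer!r} not found; available layers: {self.available_layers}"
            )
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 3:
            x = x[None]
        if x.shape[-1] != self.n_input_channels:
            raise ValueError(
                f"expected {self.n_input_channels} input channels, got {x.shape[-1]}"
            )
        h = swish(conv2d(x, self.stem_w, stride=2, padding="same"))
        if layer == "stem_activation":
            return h
        for blk in self.blocks:
            h, hit = self._run_block(h, blk, layer)
            if hit is not None:
                return hit
        raise AssertionError("unreachable: layer registry out of sync")

    def _run_block(self, x: np.ndarray, blk: dict, want: str):
        name = blk["name"]
        h = x
        if blk["w_expand"] is not None:
            h = swish(conv2d(h, blk["w_expand"], stride=1, padding="same"))
            if want == f"{name}_expand_activation":
                return x, h
        h = swish(depthwise_conv2d(h, blk["w_dw"], stride=blk["stride"]))
        # squeeze and excitation
        z = h.mean(axis=(1, 2))
        z = swish(z @ blk["w_se_reduce"] + blk["b_se_reduce"])
        z = sigmoid(z @ blk["w_se_expand"] + blk["b_se_expand"])
        h = h * z[:, None, None, :]
        h = conv2d(h, blk["w_project"], stride=1, padding="same")
        if blk["stride"] == 1 and blk["cin"] == blk["cout"] and x.shape == h.shape:
            h = h + x
        if want == f"{name}_project_bn":
            return h, h
        return h, None
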