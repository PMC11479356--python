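"""Minimal NumPy neural-network engine for the small residual CNN.

Implements exactly the pieces the classifier needs — 3x3/1x1 convolutions
via im2col, batch normalization, ReLU, residual blocks, global average
pooling, a dense head, softmax cross-entropy and Adam — with explicit
backward passes. Arrays are float32 NCHW; all initialization is seeded.
"""

from __future__ import annotations

import numpy as np


def _im2col(x: np.ndarray, k: int, stride: int, pad: int):
    b, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]
    ho, wo = win.shape[2], win.shape[3]
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(b * ho * wo, c * k * k)
    return cols, (b, c, h, w, ho, wo)


def _col2im(dcols: np.ndarray, shape, k: int, stride: int, pad: int) -> np.ndarray:
    b, c, h, w, ho, wo = shape
    dxp = np.zeros((b, c, h + 2 * pad, w + 2 * pad), dtype=dcols.dtype)
    d6 = dcols.reshape(b, ho, wo, c, k, k).transpose(0, 3, 1, 2, 4, 5)
    for ki in range(k):
        for kj in range(k):
            dxp[:, :, ki : ki + stride * ho : stride, kj : kj + stride * wo : stride] += d6[..., ki, kj]
    return dxp[:, :, pad : pad + h, pad : pad + w]


class Conv2d:
    """Bias-free convolution (a following batch norm supplies the shift)."""

    def __init__(self, cin: int, cout: int, k: int, stride: int, rng: np.random.Generator):
        std = np.sqrt(2.0 / (cin * k * k))  # He init for ReLU nets
        self.weight = rng.normal(0.0, std, size=(cout, cin * k * k)).astype(np.float32)
        self.k, self.stride, self.pad = k, stride, k // 2
        self.dweight = np.zeros_like(self.weight)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        cols, shape = _im2col(x, self.k, self.stride, self.pad)
        y = cols @ self.weight.T
        b, _, _, _, ho, wo = shape
        if train:
            self._cache = (cols, shape)
        return y.reshape(b, ho, wo, -1).transpose(0, 3, 1, 2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cols, shape = self._cache
        dyf = dy.transpose(0, 2, 3, 1).reshape(-1, dy.shape[1])
        self.dweight = (dyf.T @ cols).astype(np.float32)
        dcols = dyf @ self.weight
        return _col2im(dcols, shape, self.k, self.stride, self.pad)

    def params(self):
        return [("weight", self)]


class BatchNorm2d:
    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(c, dtype=np.float32)
        self.beta = np.zeros(c, dtype=np.float32)
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.momentum, self.eps = momentum, eps
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        if train:
            self._cache = (xhat, inv, x.shape)
        return self.gamma[None, :, None, None] * xhat + self.beta[None, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv, shape = self._cache
        m = shape[0] * shape[2] * shape[3]
        self.dgamma = (dy * xhat).sum(axis=(0, 2, 3)).astype(np.float32)
        self.dbeta = dy.sum(axis=(0, 2, 3)).astype(np.float32)
        g = self.gamma[None, :, None, None]
        dxhat = dy * g
        dx = (
            dxhat
            - dxhat.mean(axis=(0, 2, 3), keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=(0, 2, 3), keepdims=True)
        ) * inv[None, :, None, None]
        return dx

    def params(self):
        return [("gamma", self), ("beta", self)]


class _ConvBN:
    """Convolution + batch norm pair (kept together so folding is trivial)."""

    def __init__(self, cin, cout, k, stride, rng):
        self.conv = Conv2d(cin, cout, k, stride, rng)
        self.bn = BatchNorm2d(cout)

    def forward(self, x, train=False):
        return self.bn.forward(self.conv.forward(x, train), train)

    def backward(self, dy):
        return self.conv.backward(self.bn.backward(dy))

    def folded_weight(self):
        """Return (weight, bias) with the batch norm folded in (eval mode)."""
        g = self.bn.gamma / np.sqrt(self.bn.running_var + self.bn.eps)
        w = self.conv.weight * g[:, None]
        b = self.bn.beta - g * self.bn.running_mean
        return w, b

    def layers(self):
        return [self.conv, self.bn]


def _relu(x):
    return np.maximum(x, 0.0)


class ResBlock:
    """Two 3x3 conv+BN with a skip; stride-2 entry uses a 1x1 projection."""

    def __init__(self, cin: int, cout: int, stride: int, rng: np.random.Generator):
        self.main1 = _ConvBN(cin, cout, 3, stride, rng)
        self.main2 = _ConvBN(cout, cout, 3, 1, rng)
        self.proj = _ConvBN(cin, cout, 1, stride, rng) if (stride != 1 or cin != cout) else None

    def forward(self, x, train=False):
        h1 = _relu(self.main1.forward(x, train))
        h2 = self.main2.forward(h1, train)
        short = self.proj.forward(x, train) if self.proj is not None else x
        out = _relu(h2 + short)
        if train:
            self._cache = (h1 > 0, out > 0)
        return out

    def backward(self, dy):
        mask1, mask_out = self._cache
        d = dy * mask_out
        dshort = self.proj.backward(d) if self.proj is not None else d
        dh1 = self.main2.backward(d) * mask1
        dx = self.main1.backward(dh1)
        return dx + dshort

    def layers(self):
        out = self.main1.layers() + self.main2.layers()
        if self.proj is not None:
            out += self.proj.layers()
        return out


class Dense:
    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        std = np.sqrt(2.0 / cin)
        self.weight = rng.normal(0.0, std, size=(cin, cout)).astype(np.float32)
        self.bias = np.zeros(cout, dtype=np.float32)
        self.dweight = np.zeros_like(self.weight)
        self.dbias = np.zeros_like(self.bias)

    def forward(self, x, train=False):
        if train:
            self._cache = x
        return x @ self.weight + self.bias

    def backward(self, dy):
        x = self._cache
        self.dweight = (x.T @ dy).astype(np.float32)
        self.dbias = dy.sum(axis=0).astype(np.float32)
        return dy @ self.weight.T

    def params(self):
        return [("weight", self), ("bias", self)]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(probs: np.ndarray, y: np.ndarray) -> float:
    return float(-np.mean(np.log(np.clip(probs[np.arange(len(y)), y], 1e-12, None))))


class ResidualCNN:
    """Stem conv -> three residual stages -> global average pool -> dense."""

    def __init__(self, n_classes: int, widths=(8, 16, 32), stem_channels: int = 8, seed: int = 0):
        if len(widths) == 0 or any(w < 1 for w in widths):
            raise ValueError(f"invalid stage widths {widths}")
        rng = np.random.default_rng(seed)
        self.stem = _ConvBN(1, stem_channels, 3, 1, rng)
        self.blocks = []
        cin = stem_channels
        for w in widths:
            self.blocks.append(ResBlock(cin, w, stride=2, rng=rng))
            cin = w
        self.head = Dense(cin, n_classes, rng)
        self.n_classes = n_classes

    # -- forward / backward ------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """x: (B, 48, 32) or (B, 1, 48, 32) -> logits (B, n_classes)."""
        if x.ndim == 3:
            x = x[:, None, :, :]
        h = _relu(self.stem.forward(x.astype(np.float32), train))
        if train:
            self._stem_mask = h > 0
        for blk in self.blocks:
            h = blk.forward(h, train)
        self._pool_shape = h.shape
        pooled = h.mean(axis=(2, 3))
        return self.head.forward(pooled, train)

    def backward(self, dlogits: np.ndarray) -> None:
        dpool = self.head.backward(dlogits)
        b, c, hh, ww = self._pool_shape
        dh = np.broadcast_to(dpool[:, :, None, None] / (hh * ww), self._pool_shape).astype(np.float32)
        for blk in reversed(self.blocks):
            dh = blk.backward(dh)
        self.stem.backward(dh * self._stem_mask)

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        out = [softmax(self.forward(x[i : i + batch_size])) for i in range(0, len(x), batch_size)]
        return np.concatenate(out, axis=0)

    # -- parameter plumbing ------------------------------------------------
    def layers(self):
        out = self.stem.layers()
        for blk in self.blocks:
            out += blk.layers()
        out.append(self.head)
        return out

    def parameters(self):
        return [(name, layer) for layer in self.layers() for name, layer in layer.params()]

    def param_count(self) -> int:
        return sum(getattr(layer, name).size for name, layer in self.parameters())

    def get_weights(self) -> list[np.ndarray]:
        state = [getattr(layer, name).copy() for name, layer in self.parameters()]
        for layer in self.layers():
            if isinstance(layer, BatchNorm2d):
                state += [layer.running_mean.copy(), layer.running_var.copy()]
        return state

    def set_weights(self, state: list[np.ndarray]) -> None:
        it = iter(state)
        for name, layer in self.parameters():
            setattr(layer, name, next(it).copy())
        for layer in self.layers():
            if isinstance(layer, BatchNorm2d):
                layer.running_mean = next(it).copy()
                layer.running_var = next(it).copy()


class Adam:
    def __init__(self, model: ResidualCNN, lr: float = 1e-3, b1=0.9, b2=0.999, eps=1e-8):
        self.model, self.lr, self.b1, self.b2, self.eps = model, lr, b1, b2, eps
        self.m = [np.zeros_like(getattr(l, n)) for n, l in model.parameters()]
        self.v = [np.zeros_like(getattr(l, n)) for n, l in model.parameters()]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for i, (name, layer) in enumerate(self.model.parameters()):
            g = getattr(layer, "d" + name)
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p = getattr(layer, name)
            setattr(layer, name, p - self.lr * mhat / (np.sqrt(vhat) + self.eps))
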