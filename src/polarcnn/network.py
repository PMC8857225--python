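"""Minimal numpy implementation of the layers the classifier needs.

Semantics follow the Keras/TensorFlow-1.x conventions the architecture was
designed under: 'same' convolution padding (extra pad on bottom/right for
odd totals), Glorot-uniform weight initialization, SGD with momentum and
the hyperbolic decay schedule lr_t = lr / (1 + decay * iterations), and
class-weighted binary cross-entropy averaged over the batch size. The
output layer is linear here; the sigmoid is fused into the loss for
numerical stability and applied explicitly at prediction time.

All arrays are float32, NHWC. Gradient correctness is covered by
finite-difference tests.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

F32 = np.float32


def glorot_uniform(rng, shape, fan_in, fan_out):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(F32)


def same_pad(size: int, kernel: int, stride: int) -> tuple[int, int]:
    """TF 'SAME' padding: (before, after) with the extra pixel after."""
    out = -(-size // stride)  # ceil
    total = max((out - 1) * stride + kernel - size, 0)
    return total // 2, total - total // 2


class Layer:
    params: tuple = ()

    def forward(self, x, training=False):
        raise NotImplementedError

    def backward(self, grad):
        raise NotImplementedError

    @property
    def n_params(self) -> int:
        return sum(int(np.prod(p.shape)) for p in self.params)


class Conv2D(Layer):
    """3x3 convolution, stride 2, 'same' padding, optional ReLU."""

    def __init__(self, in_ch, filters, kernel=3, stride=2, relu=True, rng=None):
        self.kernel, self.stride, self.relu = kernel, stride, relu
        fan_in = kernel * kernel * in_ch
        fan_out = kernel * kernel * filters
        self.W = glorot_uniform(rng, (kernel, kernel, in_ch, filters), fan_in, fan_out)
        self.b = np.zeros(filters, dtype=F32)
        self.name = f"conv_{filters}"

    @property
    def params(self):
        return (self.W, self.b)

    def grads(self):
        return (self.dW, self.db)

    def out_shape(self, shape):
        h, w, _ = shape
        return (-(-h // self.stride), -(-w // self.stride), self.W.shape[3])

    def _cols(self, x):
        k, s = self.kernel, self.stride
        pt, pb = same_pad(x.shape[1], k, s)
        pl, pr = same_pad(x.shape[2], k, s)
        xp = np.pad(x, ((0, 0), (pt, pb), (pl, pr), (0, 0)))
        win = sliding_window_view(xp, (k, k), axis=(1, 2))[:, ::s, ::s]
        # (n, ho, wo, c, k, k) -> (n*ho*wo, k*k*c) matching W.reshape(k*k*c, f)
        n, ho, wo = win.shape[:3]
        cols = np.ascontiguousarray(win.transpose(0, 1, 2, 4, 5, 3)).reshape(
            n * ho * wo, -1
        )
        return cols, (n, ho, wo), (pt, pb, pl, pr), xp.shape

    def forward(self, x, training=False):
        cols, (n, ho, wo), pads, xp_shape = self._cols(x)
        f = self.W.shape[3]
        z = cols @ self.W.reshape(-1, f) + self.b
        z = z.reshape(n, ho, wo, f)
        if self.relu:
            z = np.maximum(z, 0)
        if training:
            self._cache = (cols, x.shape, pads, xp_shape, z if self.relu else None)
        return z

    def backward(self, grad):
        cols, x_shape, (pt, pb, pl, pr), xp_shape, act = self._cache
        k, s, f = self.kernel, self.stride, self.W.shape[3]
        if self.relu:
            grad = grad * (act > 0)
        n, ho, wo = grad.shape[:3]
        gf = grad.reshape(-1, f)
        self.dW = (cols.T @ gf).reshape(self.W.shape)
        self.db = gf.sum(axis=0)
        dcols = (gf @ self.W.reshape(-1, f).T).reshape(n, ho, wo, k, k, -1)
        dxp = np.zeros(xp_shape, dtype=F32)
        for i in range(k):
            for j in range(k):
                dxp[:, i : i + s * ho : s, j : j + s * wo : s, :] += dcols[
                    :, :, :, i, j, :
                ]
        h, w = x_shape[1], x_shape[2]
        return dxp[:, pt : pt + h, pl : pl + w, :]


class MaxPool2D(Layer):
    """2x2 max pooling, stride 2 (inputs have even spatial size here)."""

    def __init__(self, window=2):
        self.window = window
        self.name = "maxpool"

    def out_shape(self, shape):
        h, w, c = shape
        return (h // self.window, w // self.window, c)

    def forward(self, x, training=False):
        p = self.window
        n, h, w, c = x.shape
        tiles = x.reshape(n, h // p, p, w // p, p, c)
        out = tiles.max(axis=(2, 4))
        if training:
            self._cache = (x.shape, tiles, out)
        return out

    def backward(self, grad):
        x_shape, tiles, out = self._cache
        p = self.window
        mask = tiles == out[:, :, None, :, None, :]
        # spread ties evenly so the gradient check balances exactly
        counts = mask.sum(axis=(2, 4), keepdims=True)
        dtiles = mask / counts * grad[:, :, None, :, None, :]
        return dtiles.reshape(x_shape).astype(F32)


class Flatten(Layer):
    def __init__(self):
        self.name = "flatten"

    def out_shape(self, shape):
        return (int(np.prod(shape)),)

    def forward(self, x, training=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Dense(Layer):
    """Fully connected layer with optional ReLU and L2 kernel penalty."""

    def __init__(self, in_dim, units, relu=True, l2=0.0, rng=None):
        self.W = glorot_uniform(rng, (in_dim, units), in_dim, units)
        self.b = np.zeros(units, dtype=F32)
        self.relu, self.l2 = relu, l2
        self.name = f"dense_{units}"

    @property
    def params(self):
        return (self.W, self.b)

    def grads(self):
        return (self.dW, self.db)

    def out_shape(self, shape):
        return (self.W.shape[1],)

    def penalty(self) -> float:
        return float(self.l2 * np.sum(self.W.astype(np.float64) ** 2))

    def forward(self, x, training=False):
        z = x @ self.W + self.b
        if self.relu:
            z = np.maximum(z, 0)
        if training:
            self._cache = (x, z if self.relu else None)
        return z

    def backward(self, grad):
        x, act = self._cache
        if self.relu:
            grad = grad * (act > 0)
        self.dW = x.T @ grad
        if self.l2:
            self.dW = self.dW + 2.0 * self.l2 * self.W
        self.db = grad.sum(axis=0)
        return grad @ self.W.T


def sigmoid(z):
    out = np.empty_like(z, dtype=F32)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def weighted_bce_with_logits(logits, y, sample_weight=None):
    """(loss, dlogits): BCE through a fused sigmoid, mean over batch size.

    ``sample_weight`` multiplies each term (class weighting); the sum is
    divided by the batch size, matching the class_weight convention of the
    training framework the architecture was tuned in.
    """
    z = logits.astype(np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    n = z.size
    w = np.ones(n) if sample_weight is None else np.asarray(sample_weight, float)
    # log(1+e^z) computed stably
    softplus = np.maximum(z, 0) + np.log1p(np.exp(-np.abs(z)))
    loss = float(np.sum(w * (softplus - y * z)) / n)
    p = 1.0 / (1.0 + np.exp(-np.abs(z)))
    p = np.where(z >= 0, p, 1.0 - p)  # sigmoid(z)
    dz = (w * (p - y) / n).astype(F32).reshape(logits.shape)
    return loss, dz


class SGD:
    """Momentum SGD with hyperbolic learning-rate decay."""

    def __init__(self, layers, lr=0.005, momentum=0.9, decay=1e-8):
        self.layers = [l for l in layers if l.params]
        self.lr, self.momentum, self.decay = lr, momentum, decay
        self.iterations = 0
        self.velocity = [
            [np.zeros_like(p) for p in l.params] for l in self.layers
        ]

    def step(self):
        lr_t = self.lr / (1.0 + self.decay * self.iterations)
        for layer, vels in zip(self.layers, self.velocity):
            for p, g, v in zip(layer.params, layer.grads(), vels):
                v *= self.momentum
                v -= lr_t * g
                p += v
        self.iterations += 1
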