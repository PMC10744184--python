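"""Minimal convolutional neural-network layers on numpy, NCHW layout.

Implements exactly what the residual-denoising GAN needs: strided convolution,
transposed convolution, batch normalization, (leaky) ReLU, global average
pooling, a dense head, Adam, and numerically stable binary cross-entropy /
MSE losses.  Every layer carries an analytic backward pass; the test suite
verifies each against central finite differences.

All randomness is injected through ``numpy.random.Generator`` objects, so a
fixed seed reproduces training bit for bit on a given platform.
"""

from __future__ import annotations

import numpy as np


# ---------------------------------------------------------------------------
# im2col / col2im


def _out_size(n: int, k: int, stride: int, pad: int) -> int:
    return (n + 2 * pad - k) // stride + 1


def im2col(x: np.ndarray, k: int, stride: int, pad: int) -> np.ndarray:
    """(N, C, H, W) -> (N, C*k*k, Ho*Wo) patch matrix."""
    n, c, h, w = x.shape
    ho, wo = _out_size(h, k, stride, pad), _out_size(w, k, stride, pad)
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else x
    cols = np.empty((n, c, k, k, ho, wo), dtype=x.dtype)
    for i in range(k):
        for j in range(k):
            cols[:, :, i, j] = xp[:, :, i:i + stride * ho:stride,
                                  j:j + stride * wo:stride]
    return cols.reshape(n, c * k * k, ho * wo)


def col2im(cols: np.ndarray, x_shape: tuple, k: int, stride: int, pad: int
           ) -> np.ndarray:
    """Adjoint of :func:`im2col`: scatter-add patches back onto the image."""
    n, c, h, w = x_shape
    ho, wo = _out_size(h, k, stride, pad), _out_size(w, k, stride, pad)
    xp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=cols.dtype)
    cols6 = cols.reshape(n, c, k, k, ho, wo)
    for i in range(k):
        for j in range(k):
            xp[:, :, i:i + stride * ho:stride, j:j + stride * wo:stride] += \
                cols6[:, :, i, j]
    if pad:
        return xp[:, :, pad:-pad, pad:-pad]
    return xp


# ---------------------------------------------------------------------------
# layers


class Layer:
    """Base class: parameters and their gradients live in dicts by name."""

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, gout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def zero_grads(self) -> None:
        for k in self.grads:
            self.grads[k][...] = 0.0


class Conv2d(Layer):
    def __init__(self, c_in: int, c_out: int, k: int = 3, stride: int = 1,
                 pad: int = 1, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / (c_in * k * k))    # He initialization
        self.k, self.stride, self.pad = k, stride, pad
        self.c_in, self.c_out = c_in, c_out
        self.params["W"] = rng.standard_normal((c_out, c_in, k, k)) * scale
        self.params["b"] = np.zeros(c_out)
        self.grads["W"] = np.zeros_like(self.params["W"])
        self.grads["b"] = np.zeros_like(self.params["b"])

    def forward(self, x, train=True):
        self._x_shape = x.shape
        self._cols = im2col(x, self.k, self.stride, self.pad)
        w2 = self.params["W"].reshape(self.c_out, -1)
        out = np.einsum("of,nfl->nol", w2, self._cols, optimize=True)
        out += self.params["b"][None, :, None]
        n = x.shape[0]
        ho = _out_size(x.shape[2], self.k, self.stride, self.pad)
        wo = _out_size(x.shape[3], self.k, self.stride, self.pad)
        return out.reshape(n, self.c_out, ho, wo)

    def backward(self, gout):
        n = gout.shape[0]
        g2 = gout.reshape(n, self.c_out, -1)
        self.grads["W"] += np.einsum("nol,nfl->of", g2, self._cols,
                                     optimize=True).reshape(self.params["W"].shape)
        self.grads["b"] += g2.sum(axis=(0, 2))
        w2 = self.params["W"].reshape(self.c_out, -1)
        gcols = np.einsum("of,nol->nfl", w2, g2, optimize=True)
        return col2im(gcols, self._x_shape, self.k, self.stride, self.pad)


class ConvTranspose2d(Layer):
    """Transposed convolution; with k=4, stride=2, pad=1 it doubles H and W."""

    def __init__(self, c_in: int, c_out: int, k: int = 4, stride: int = 2,
                 pad: int = 1, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / (c_in * k * k))
        self.k, self.stride, self.pad = k, stride, pad
        self.c_in, self.c_out = c_in, c_out
        self.params["W"] = rng.standard_normal((c_in, c_out, k, k)) * scale
        self.params["b"] = np.zeros(c_out)
        self.grads["W"] = np.zeros_like(self.params["W"])
        self.grads["b"] = np.zeros_like(self.params["b"])

    def _out_hw(self, h: int, w: int) -> tuple[int, int]:
        return ((h - 1) * self.stride - 2 * self.pad + self.k,
                (w - 1) * self.stride - 2 * self.pad + self.k)

    def forward(self, x, train=True):
        n, _, h, w = x.shape
        self._x = x
        ho, wo = self._out_hw(h, w)
        w2 = self.params["W"].reshape(self.c_in, -1)     # (Ci, Co*k*k)
        cols = np.einsum("if,nil->nfl", w2, x.reshape(n, self.c_in, h * w),
                         optimize=True)
        out = col2im(cols, (n, self.c_out, ho, wo), self.k, self.stride, self.pad)
        return out + self.params["b"][None, :, None, None]

    def backward(self, gout):
        n, _, h, w = self._x.shape
        gcols = im2col(gout, self.k, self.stride, self.pad)  # (N, Co*k*k, h*w)
        w2 = self.params["W"].reshape(self.c_in, -1)
        gx = np.einsum("if,nfl->nil", w2, gcols, optimize=True)
        self.grads["W"] += np.einsum(
            "nil,nfl->if", self._x.reshape(n, self.c_in, h * w), gcols,
            optimize=True).reshape(self.params["W"].shape)
        self.grads["b"] += gout.sum(axis=(0, 2, 3))
        return gx.reshape(self._x.shape)


class BatchNorm2d(Layer):
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.params["gamma"] = np.ones(c)
        self.params["beta"] = np.zeros(c)
        self.grads["gamma"] = np.zeros(c)
        self.grads["beta"] = np.zeros(c)
        self.running_mean = np.zeros(c)
        self.running_var = np.ones(c)

    def forward(self, x, train=True):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var)
        else:
            mean, var = self.running_mean, self.running_var
        self._invstd = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mean[None, :, None, None]) * self._invstd[None, :, None, None]
        self._train = train
        return (self.params["gamma"][None, :, None, None] * self._xhat
                + self.params["beta"][None, :, None, None])

    def backward(self, gout):
        self.grads["gamma"] += (gout * self._xhat).sum(axis=(0, 2, 3))
        self.grads["beta"] += gout.sum(axis=(0, 2, 3))
        g = gout * self.params["gamma"][None, :, None, None]
        if not self._train:
            return g * self._invstd[None, :, None, None]
        m = gout.shape[0] * gout.shape[2] * gout.shape[3]
        sum_g = g.sum(axis=(0, 2, 3), keepdims=True)
        sum_gx = (g * self._xhat).sum(axis=(0, 2, 3), keepdims=True)
        return (self._invstd[None, :, None, None] / m
                * (m * g - sum_g - self._xhat * sum_gx))


class ReLU(Layer):
    def forward(self, x, train=True):
        self._mask = x > 0
        return x * self._mask

    def backward(self, gout):
        return gout * self._mask


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.2):
        super().__init__()
        self.slope = slope

    def forward(self, x, train=True):
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, gout):
        return np.where(self._mask, gout, self.slope * gout)


class GlobalAvgPool(Layer):
    """(N, C, H, W) -> (N, C)."""

    def forward(self, x, train=True):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, gout):
        n, c, h, w = self._shape
        return np.broadcast_to(gout[:, :, None, None], self._shape) / (h * w)


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.params["W"] = rng.standard_normal((d_in, d_out)) * np.sqrt(2.0 / d_in)
        self.params["b"] = np.zeros(d_out)
        self.grads["W"] = np.zeros_like(self.params["W"])
        self.grads["b"] = np.zeros_like(self.params["b"])

    def forward(self, x, train=True):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, gout):
        self.grads["W"] += self._x.T @ gout
        self.grads["b"] += gout.sum(axis=0)
        return gout @ self.params["W"].T


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, gout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            gout = layer.backward(gout)
        return gout

    def zero_grads(self) -> None:
        for layer in self.layers:
            layer.zero_grads()

    def state_arrays(self) -> dict[str, np.ndarray]:
        """Flat name -> array mapping of parameters and BN running stats."""
        out = {}
        for i, layer in enumerate(self.layers):
            for name, arr in layer.params.items():
                out[f"layer{i}.{name}"] = arr
            if isinstance(layer, BatchNorm2d):
                out[f"layer{i}.running_mean"] = layer.running_mean
                out[f"layer{i}.running_var"] = layer.running_var
        return out

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.layers):
            for name in layer.params:
                layer.params[name][...] = state[f"layer{i}.{name}"]
            if isinstance(layer, BatchNorm2d):
                layer.running_mean[...] = state[f"layer{i}.running_mean"]
                layer.running_var[...] = state[f"layer{i}.running_var"]


class Adam:
    """Adaptive moment estimation over the parameters of several layers."""

    def __init__(self, model: Sequential, lr: float = 5e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.model, self.lr, self.beta1, self.beta2, self.eps = (
            model, lr, beta1, beta2, eps)
        self.t = 0
        self.m = [{k: np.zeros_like(v) for k, v in layer.params.items()}
                  for layer in model.layers]
        self.v = [{k: np.zeros_like(v) for k, v in layer.params.items()}
                  for layer in model.layers]

    def step(self) -> None:
        self.t += 1
        b1c = 1.0 - self.beta1 ** self.t
        b2c = 1.0 - self.beta2 ** self.t
        for i, layer in enumerate(self.model.layers):
            for k, p in layer.params.items():
                g = layer.grads[k]
                self.m[i][k] = self.beta1 * self.m[i][k] + (1 - self.beta1) * g
                self.v[i][k] = self.beta2 * self.v[i][k] + (1 - self.beta2) * g * g
                p -= self.lr * (self.m[i][k] / b1c) / (
                    np.sqrt(self.v[i][k] / b2c) + self.eps)


# ---------------------------------------------------------------------------
# losses


def mse_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean squared error and its gradient w.r.t. ``pred``."""
    diff = pred - target
    return float(np.mean(diff * diff)), 2.0 * diff / diff.size


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(logits: np.ndarray, targets: np.ndarray
                    ) -> tuple[float, np.ndarray]:
    """Stable binary cross-entropy on logits; returns (loss, dloss/dlogits)."""
    loss = np.mean(np.maximum(logits, 0) - logits * targets
                   + np.log1p(np.exp(-np.abs(logits))))
    grad = (sigmoid(logits) - targets) / logits.size
    return float(loss), grad
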