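"""Minimal self-contained neural-network core (numpy).

Implements exactly what the frame classifiers need: dense and 3x3
convolutional layers, batch normalization, ReLU, 2x2 max pooling, global
average pooling, the Adam optimizer, and a per-label weighted logistic
(sigmoid cross-entropy) loss.  Forward/backward passes are hand-derived;
everything is float64 and seeded, so training is bit-reproducible.

Shapes follow the NCHW convention for convolutional layers: inputs are
(batch, channels, height, width).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Dense",
    "Conv2D",
    "BatchNorm",
    "ReLU",
    "MaxPool2x2",
    "GlobalAvgPool",
    "Flatten",
    "Sequential",
    "Adam",
    "sigmoid",
    "weighted_bce_with_logits",
    "weighted_mse",
]


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class Layer:
    """Base layer: parameters in ``params``, matching gradients in ``grads``."""

    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        # He initialization (ReLU-friendly)
        w = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        b = np.zeros(n_out)
        self.params = [w, b]
        self.grads = [np.zeros_like(w), np.zeros_like(b)]

    def forward(self, x, train):
        self._x = x
        return x @ self.params[0] + self.params[1]

    def backward(self, grad):
        self.grads[0][...] = self._x.T @ grad
        self.grads[1][...] = grad.sum(axis=0)
        return grad @ self.params[0].T


class Conv2D(Layer):
    """3x3 (or kxk) same-padding convolution via im2col."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        rng: np.random.Generator,
        kernel: int = 3,
    ) -> None:
        super().__init__()
        self.k = kernel
        fan_in = in_channels * kernel * kernel
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_channels, fan_in))
        b = np.zeros(out_channels)
        self.params = [w, b]
        self.grads = [np.zeros_like(w), np.zeros_like(b)]
        self.in_channels = in_channels
        self.out_channels = out_channels

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        # x padded: (B, C, H+k-1, W+k-1) -> (B, H, W, C*k*k)
        k = self.k
        B, C, H, W = self._shape
        cols = np.empty((B, H, W, C * k * k), dtype=x.dtype)
        n = 0
        for c in range(C):
            for di in range(k):
                for dj in range(k):
                    cols[..., n] = x[:, c, di : di + H, dj : dj + W]
                    n += 1
        return cols

    def forward(self, x, train):
        k = self.k
        p = k // 2
        self._shape = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        cols = self._im2col(xp)  # (B, H, W, C*k*k)
        self._cols = cols
        B, C, H, W = x.shape
        out = cols @ self.params[0].T + self.params[1]  # (B, H, W, O)
        return out.transpose(0, 3, 1, 2)

    def backward(self, grad):
        k = self.k
        p = k // 2
        B, C, H, W = self._shape
        g = grad.transpose(0, 2, 3, 1)  # (B, H, W, O)
        self.grads[0][...] = np.einsum("bhwo,bhwn->on", g, self._cols)
        self.grads[1][...] = g.sum(axis=(0, 1, 2))
        # input gradient: scatter col gradients back
        gcols = g @ self.params[0]  # (B, H, W, C*k*k)
        gx = np.zeros((B, C, H + 2 * p, W + 2 * p))
        n = 0
        for c in range(C):
            for di in range(k):
                for dj in range(k):
                    gx[:, c, di : di + H, dj : dj + W] += gcols[..., n]
                    n += 1
        return gx[:, :, p : p + H, p : p + W]


class BatchNorm(Layer):
    """Batch normalization over the batch (and spatial dims for 4-D input)."""

    def __init__(self, n_features: int, momentum: float = 0.9, eps: float = 1e-5):
        super().__init__()
        self.params = [np.ones(n_features), np.zeros(n_features)]
        self.grads = [np.zeros(n_features), np.zeros(n_features)]
        self.running_mean = np.zeros(n_features)
        self.running_var = np.ones(n_features)
        self.momentum = momentum
        self.eps = eps

    def _axes(self, x):
        return (0,) if x.ndim == 2 else (0, 2, 3)

    def _reshape(self, v, x):
        return v if x.ndim == 2 else v[None, :, None, None]

    def forward(self, x, train):
        axes = self._axes(x)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - self._reshape(mean, x)) / self._reshape(self._std, x)
        return self._reshape(self.params[0], x) * self._xhat + self._reshape(
            self.params[1], x
        )

    def backward(self, grad):
        axes = self._axes(grad)
        m = np.prod([grad.shape[a] for a in axes])
        self.grads[0][...] = (grad * self._xhat).sum(axis=axes)
        self.grads[1][...] = grad.sum(axis=axes)
        gamma = self._reshape(self.params[0], grad)
        gxhat = grad * gamma
        # standard batch-norm backward
        return (
            gxhat
            - self._reshape(gxhat.sum(axis=axes) / m, grad)
            - self._xhat * self._reshape((gxhat * self._xhat).sum(axis=axes) / m, grad)
        ) / self._reshape(self._std, grad)


class ReLU(Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class MaxPool2x2(Layer):
    def forward(self, x, train):
        B, C, H, W = x.shape
        H2, W2 = H // 2, W // 2
        x = x[:, :, : H2 * 2, : W2 * 2]
        self._in_shape = (B, C, H, W)
        blocks = x.reshape(B, C, H2, 2, W2, 2)
        out = blocks.max(axis=(3, 5))
        self._mask = blocks == out[:, :, :, None, :, None]
        return out

    def backward(self, grad):
        B, C, H, W = self._in_shape
        H2, W2 = H // 2, W // 2
        g = self._mask * grad[:, :, :, None, :, None]
        # split ties evenly so gradient mass is conserved
        g = g / self._mask.sum(axis=(3, 5), keepdims=True)
        gx = np.zeros((B, C, H, W))
        gx[:, :, : H2 * 2, : W2 * 2] = g.reshape(B, C, H2 * 2, W2 * 2)
        return gx


class GlobalAvgPool(Layer):
    def forward(self, x, train):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, grad):
        B, C, H, W = self._shape
        return np.broadcast_to(grad[:, :, None, None] / (H * W), self._shape).copy()


class Flatten(Layer):
    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    @property
    def params(self):
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self):
        return [g for layer in self.layers for g in layer.grads]


class Adam:
    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g**2
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def weighted_bce_with_logits(
    logits: np.ndarray, targets: np.ndarray, weights: np.ndarray
) -> tuple[float, np.ndarray]:
    """Per-element sigmoid cross-entropy with per-element weights.

    Returns (mean weighted loss, gradient w.r.t. logits).  The gradient is
    normalized by the batch size, matching the loss normalization.
    """
    z, y, w = logits, targets, weights
    # log(1 + exp(-|z|)) formulation for stability
    loss_elem = np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))
    n = z.shape[0]
    loss = float((w * loss_elem).sum() / n)
    grad = w * (sigmoid(z) - y) / n
    return loss, grad


def weighted_mse(
    preds: np.ndarray, targets: np.ndarray, weights: np.ndarray
) -> tuple[float, np.ndarray]:
    """Weighted squared error; returns (mean loss, gradient w.r.t. preds)."""
    diff = preds - targets
    n = preds.shape[0]
    loss = float((weights * diff**2).sum() / n)
    return loss, 2.0 * weights * diff / n
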