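"""Minimal numpy neural-network core.

Implements exactly the pieces the pipeline needs — dense and 3x3
convolutional layers with manual backprop, softmax heads with
cross-entropy and soft-F1 losses, plain SGD, and a one-cycle learning
rate schedule.  Everything is deterministic given a
``numpy.random.Generator``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Linear",
    "ReLU",
    "Conv3x3",
    "AvgPool",
    "GlobalAvgPool",
    "Flatten",
    "Sequential",
    "softmax",
    "one_cycle_lr",
    "softf1_grad_wrt_probs",
    "cross_entropy_grad_wrt_probs",
    "softmax_backprop",
]


def softmax(z: np.ndarray) -> np.ndarray:
    """Row-wise softmax, numerically stabilised."""
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def one_cycle_lr(
    step: int,
    total_steps: int,
    max_lr: float,
    warmup_frac: float = 0.25,
    div_start: float = 25.0,
    div_end: float = 100.0,
) -> float:
    """Learning rate at ``step`` of a one-cycle schedule.

    Linear warm-up from ``max_lr/div_start`` to ``max_lr`` over the first
    ``warmup_frac`` of the iterations, then cosine decay down to
    ``max_lr/div_end``.
    """
    if total_steps <= 1:
        return max_lr
    warm = max(1, int(round(warmup_frac * total_steps)))
    if step < warm:
        lo = max_lr / div_start
        return lo + (max_lr - lo) * step / warm
    t = (step - warm) / max(1, total_steps - warm)
    lo = max_lr / div_end
    return lo + 0.5 * (max_lr - lo) * (1.0 + np.cos(np.pi * min(t, 1.0)))


class Layer:
    """Base layer: forward caches what backward needs."""

    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Linear(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        # He initialisation — hidden layers use rectifier activations
        scale = np.sqrt(2.0 / n_in)
        self.W = rng.normal(0.0, scale, size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads[0][...] = self._x.T @ dout
        self.grads[1][...] = dout.sum(axis=0)
        return dout @ self.W.T


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


def _im2col(x: np.ndarray) -> np.ndarray:
    """(N, H, W, C) -> (N, H, W, 9C) patches for a 3x3 kernel, zero pad 1."""
    n, h, w, c = x.shape
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
    cols = np.empty((n, h, w, 9 * c), dtype=x.dtype)
    k = 0
    for di in range(3):
        for dj in range(3):
            cols[..., k * c : (k + 1) * c] = xp[:, di : di + h, dj : dj + w, :]
            k += 1
    return cols


def _col2im(cols: np.ndarray, c: int) -> np.ndarray:
    """Adjoint of :func:`_im2col`."""
    n, h, w, _ = cols.shape
    xp = np.zeros((n, h + 2, w + 2, c), dtype=cols.dtype)
    k = 0
    for di in range(3):
        for dj in range(3):
            xp[:, di : di + h, dj : dj + w, :] += cols[..., k * c : (k + 1) * c]
            k += 1
    return xp[:, 1:-1, 1:-1, :]


class Conv3x3(Layer):
    """3x3 convolution, stride 1, zero padding 1, NHWC layout."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        scale = np.sqrt(2.0 / (9 * c_in))
        self.W = rng.normal(0.0, scale, size=(9 * c_in, c_out))
        self.b = np.zeros(c_out)
        self.c_in = c_in
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._cols = _im2col(x)
        return self._cols @ self.W + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, h, w, c_out = dout.shape
        cols2 = self._cols.reshape(-1, self._cols.shape[-1])
        dflat = dout.reshape(-1, c_out)
        self.grads[0][...] = cols2.T @ dflat
        self.grads[1][...] = dflat.sum(axis=0)
        dcols = dout @ self.W.T
        return _col2im(dcols, self.c_in)


class AvgPool(Layer):
    """Non-overlapping average pooling by integer factor (NHWC)."""

    def __init__(self, factor: int) -> None:
        super().__init__()
        self.f = factor

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        f = self.f
        hh, ww = h // f, w // f
        x = x[:, : hh * f, : ww * f, :]
        self._shape = x.shape
        return x.reshape(n, hh, f, ww, f, c).mean(axis=(2, 4))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, h, w, c = self._shape
        f = self.f
        d = np.repeat(np.repeat(dout, f, axis=1), f, axis=2) / (f * f)
        return d


class GlobalAvgPool(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._hw = x.shape[1] * x.shape[2]
        self._shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, h, w, c = self._shape
        return np.broadcast_to(dout[:, None, None, :], self._shape) / self._hw


class Flatten(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)


class Sequential:
    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dout: np.ndarray) -> None:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)

    def sgd_step(self, lr: float, weight_decay: float = 0.0) -> None:
        for layer in self.layers:
            for p, g in zip(layer.params, layer.grads):
                if weight_decay and p.ndim > 1:  # decay weights, not biases
                    p -= lr * (g + weight_decay * p)
                else:
                    p -= lr * g

    def parameters(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]


def softf1_grad_wrt_probs(theta: np.ndarray, y: np.ndarray, eps: float) -> np.ndarray:
    """Gradient of the per-example soft-F1 loss with respect to theta.

    Each class term is 1 - 2*theta_k*y_k / (theta_k + y_k + eps); the
    derivative is -2*y_k*(y_k + eps) / (theta_k + y_k + eps)^2, averaged
    over K.  Rows are examples.
    """
    k = theta.shape[-1]
    d = theta + y + eps
    return -2.0 * y * (y + eps) / (d * d) / k


def cross_entropy_grad_wrt_probs(theta: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Gradient of -log(theta_true) w.r.t. theta (one-hot y)."""
    t = np.clip(theta, 1e-12, None)
    return -y / t


def softmax_backprop(theta: np.ndarray, dtheta: np.ndarray) -> np.ndarray:
    """Push a gradient w.r.t. softmax outputs back to the logits."""
    dot = (dtheta * theta).sum(axis=-1, keepdims=True)
    return theta * (dtheta - dot)
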