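"""Minimal feed-forward / convolutional network core on numpy.

Channels-last layout throughout: conv inputs are (N, H, W, C) float arrays.
Convolutions are "valid" (no padding) with stride 1; pooling is 2×2 max
with stride 2, truncating odd trailing rows/columns.  Every layer exposes
``forward(x, train)`` and ``backward(grad)`` and keeps its parameter and
gradient arrays in ``params`` / ``grads`` so an optimizer can walk them.

All randomness (weight init, batch shuffling) is injected through
``numpy.random.Generator`` instances, which keeps whole training runs
reproducible from a single seed.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2D(Layer):
    """Valid convolution, stride 1, He-initialised."""

    def __init__(self, in_channels: int, filters: int, kernel: int,
                 rng: np.random.Generator) -> None:
        super().__init__()
        fan_in = in_channels * kernel * kernel
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, filters))
        b = np.zeros(filters)
        self.kernel = kernel
        self.in_channels = in_channels
        self.params = [w, b]
        self.grads = [np.zeros_like(w), np.zeros_like(b)]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        k = self.kernel
        # (N, OH, OW, C, k, k) view -> columns
        patches = sliding_window_view(x, (k, k), axis=(1, 2))
        n, oh, ow = patches.shape[:3]
        self._cols = patches.reshape(n, oh, ow, -1)
        self._in_shape = x.shape
        w, b = self.params
        return self._cols @ w + b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        w, _ = self.params
        n, oh, ow, f = grad.shape
        cols = self._cols.reshape(-1, w.shape[0])
        g = grad.reshape(-1, f)
        self.grads[0][...] = cols.T @ g
        self.grads[1][...] = g.sum(axis=0)
        dcols = (g @ w.T).reshape(n, oh, ow, self.in_channels, self.kernel, self.kernel)
        dx = np.zeros(self._in_shape)
        for i in range(self.kernel):
            for j in range(self.kernel):
                dx[:, i : i + oh, j : j + ow, :] += dcols[:, :, :, :, i, j]
        return dx


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class MaxPool2x2(Layer):
    """2×2 max pooling, stride 2; ties route gradient to the first maximum."""

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, h, w, c = x.shape
        oh, ow = h // 2, w // 2
        self._in_shape = x.shape
        x = x[:, : 2 * oh, : 2 * ow, :]
        windows = x.reshape(n, oh, 2, ow, 2, c).transpose(0, 1, 3, 5, 2, 4).reshape(
            n, oh, ow, c, 4
        )
        self._argmax = windows.argmax(axis=-1)
        return np.take_along_axis(windows, self._argmax[..., None], axis=-1)[..., 0]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, oh, ow, c = grad.shape
        dwin = np.zeros((n, oh, ow, c, 4))
        np.put_along_axis(dwin, self._argmax[..., None], grad[..., None], axis=-1)
        dx = np.zeros(self._in_shape)
        dx_view = dx[:, : 2 * oh, : 2 * ow, :].reshape(n, oh, 2, ow, 2, c)
        dx_view[...] = dwin.reshape(n, oh, ow, c, 2, 2).transpose(0, 1, 4, 2, 5, 3)
        return dx


class BatchNorm(Layer):
    """Per-channel batch normalisation (over batch and spatial axes)."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5) -> None:
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        gamma = np.ones(channels)
        beta = np.zeros(channels)
        self.params = [gamma, beta]
        self.grads = [np.zeros_like(gamma), np.zeros_like(beta)]
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self._seen_batch = False

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        axes = tuple(range(x.ndim - 1))
        gamma, beta = self.params
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            if not self._seen_batch:
                # warm start so short runs have usable inference statistics
                self.running_mean[...] = mean
                self.running_var[...] = var
                self._seen_batch = True
            else:
                self.running_mean += self.momentum * (mean - self.running_mean)
                self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean) / self._std
        self._m = int(np.prod([x.shape[a] for a in axes]))
        return gamma * self._xhat + beta

    def backward(self, grad: np.ndarray) -> np.ndarray:
        axes = tuple(range(grad.ndim - 1))
        gamma, _ = self.params
        self.grads[0][...] = (grad * self._xhat).sum(axis=axes)
        self.grads[1][...] = grad.sum(axis=axes)
        m = self._m
        dxhat = grad * gamma
        return (
            dxhat - dxhat.mean(axis=axes) - self._xhat * (dxhat * self._xhat).mean(axis=axes)
        ) / self._std


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._in_shape)


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator) -> None:
        super().__init__()
        w = rng.normal(0.0, np.sqrt(2.0 / in_features), size=(in_features, out_features))
        b = np.zeros(out_features)
        self.params = [w, b]
        self.grads = [np.zeros_like(w), np.zeros_like(b)]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x
        w, b = self.params
        return x @ w + b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        w, _ = self.params
        self.grads[0][...] = self._x.T @ grad
        self.grads[1][...] = grad.sum(axis=0)
        return grad @ w.T


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy of integer labels; returns (loss, dlogits)."""
    probs = softmax(logits)
    n = logits.shape[0]
    loss = float(-np.log(probs[np.arange(n), labels] + 1e-12).mean())
    dlogits = probs.copy()
    dlogits[np.arange(n), labels] -= 1.0
    return loss, dlogits / n


class Network:
    """A plain layer stack with weight snapshot/restore for early stopping."""

    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, grad: np.ndarray) -> None:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)

    def parameters(self) -> list[tuple[np.ndarray, np.ndarray]]:
        return [(p, g) for l in self.layers for p, g in zip(l.params, l.grads)]

    def get_state(self) -> list[np.ndarray]:
        state = [p.copy() for l in self.layers for p in l.params]
        for l in self.layers:
            if isinstance(l, BatchNorm):
                state.extend([l.running_mean.copy(), l.running_var.copy()])
        return state

    def set_state(self, state: list[np.ndarray]) -> None:
        it = iter(state[: sum(len(l.params) for l in self.layers)])
        for l in self.layers:
            for p in l.params:
                p[...] = next(it)
        rest = iter(state[sum(len(l.params) for l in self.layers) :])
        for l in self.layers:
            if isinstance(l, BatchNorm):
                l.running_mean[...] = next(rest)
                l.running_var[...] = next(rest)


class RMSProp:
    """Momentum-free adaptive optimizer (squared-gradient moving average)."""

    def __init__(self, network: Network, lr: float = 1e-3, rho: float = 0.9,
                 eps: float = 1e-8) -> None:
        self.pairs = network.parameters()
        self.lr, self.rho, self.eps = lr, rho, eps
        self.cache = [np.zeros_like(p) for p, _ in self.pairs]

    def step(self) -> None:
        for (p, g), c in zip(self.pairs, self.cache):
            c *= self.rho
            c += (1 - self.rho) * g * g
            p -= self.lr * g / (np.sqrt(c) + self.eps)
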