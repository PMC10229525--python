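"""Minimal deterministic feed-forward/convolutional network engine.

Small seeded numpy implementation of exactly what the classifiers need:
dense layers, ReLU, 3x3 'same' convolution (im2col), 2x2 max pooling,
softmax cross-entropy and single-logit heads, and Adam. Sized for the
compact architectures used here (tens of thousands of parameters), with
bit-reproducible behaviour given a seed.
"""

from __future__ import annotations

import numpy as np


class Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        limit = np.sqrt(6.0 / (n_in + n_out))  # Glorot uniform
        self.w = rng.uniform(-limit, limit, size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.w + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        # in place: the optimizer holds references to dw/db
        self.dw[...] = self._x.T @ grad
        self.db[...] = grad.sum(axis=0)
        return grad @ self.w.T

    @property
    def params(self):
        return [(self.w, self.dw), (self.b, self.db)]


class ReLU:
    params: list = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class Flatten:
    params: list = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)


class Conv3x3:
    """Single-input-channel 3x3 convolution, stride 1, 'same' zero padding."""

    def __init__(self, n_filters: int, rng: np.random.Generator, kernel: int = 3):
        self.k = kernel
        fan_in = kernel * kernel
        limit = np.sqrt(6.0 / (fan_in + n_filters))
        self.w = rng.uniform(-limit, limit, size=(fan_in, n_filters))
        self.b = np.zeros(n_filters)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        n, h, w = x.shape
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (p, p), (p, p)))
        cols = np.empty((n, h * w, self.k * self.k))
        idx = 0
        for di in range(self.k):
            for dj in range(self.k):
                cols[:, :, idx] = xp[:, di:di + h, dj:dj + w].reshape(n, -1)
                idx += 1
        return cols

    def forward(self, x: np.ndarray) -> np.ndarray:
        # x: (n, H, W) -> (n, H, W, F)
        self._hw = x.shape[1:]
        self._cols = self._im2col(x)
        out = self._cols @ self.w + self.b
        n = x.shape[0]
        return out.reshape(n, *self._hw, -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, h, w, f = grad.shape
        g = grad.reshape(n, h * w, f)
        self.dw[...] = np.einsum("npk,npf->kf", self._cols, g)
        self.db[...] = g.sum(axis=(0, 1))
        gcols = g @ self.w.T  # (n, h*w, k*k)
        p = self.k // 2
        dxp = np.zeros((n, h + 2 * p, w + 2 * p))
        idx = 0
        for di in range(self.k):
            for dj in range(self.k):
                dxp[:, di:di + h, dj:dj + w] += gcols[:, :, idx].reshape(n, h, w)
                idx += 1
        return dxp[:, p:p + h, p:p + w]

    @property
    def params(self):
        return [(self.w, self.dw), (self.b, self.db)]


class MaxPool2:
    """2x2 max pooling with stride 2; trailing odd rows/cols are dropped."""

    params: list = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, f = x.shape
        ho, wo = h // 2, w // 2
        xt = x[:, :ho * 2, :wo * 2, :].reshape(n, ho, 2, wo, 2, f)
        self._x_shape = x.shape
        windows = xt.transpose(0, 1, 3, 5, 2, 4).reshape(n, ho, wo, f, 4)
        self._argmax = windows.argmax(axis=-1)
        return windows.max(axis=-1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, ho, wo, f = grad.shape
        dwin = np.zeros((n, ho, wo, f, 4))
        np.put_along_axis(dwin, self._argmax[..., None], grad[..., None], axis=-1)
        dx = np.zeros(self._x_shape)
        dxt = dwin.reshape(n, ho, wo, f, 2, 2).transpose(0, 1, 4, 2, 5, 3)
        dx[:, :ho * 2, :wo * 2, :] = dxt.reshape(n, ho * 2, wo * 2, f)
        return dx


class Sequential:
    def __init__(self, layers: list):
        self.layers = layers

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    @property
    def params(self):
        return [p for layer in self.layers for p in layer.params]

    def n_parameters(self) -> int:
        return sum(p.size for p, _ in self.params)


class Adam:
    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for i, (p, g) in enumerate(self.params):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy_grad(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean softmax cross-entropy and its gradient wrt the logits.

    ``y`` holds integer class indices.
    """
    n = len(y)
    p = softmax(logits)
    loss = float(-np.mean(np.log(p[np.arange(n), y] + 1e-12)))
    grad = p
    grad[np.arange(n), y] -= 1.0
    return loss, grad / n


def make_mlp(n_in: int, hidden: tuple[int, ...], n_out: int,
             rng: np.random.Generator) -> Sequential:
    layers: list = []
    prev = n_in
    for h in hidden:
        layers += [Dense(prev, h, rng), ReLU()]
        prev = h
    layers.append(Dense(prev, n_out, rng))
    return Sequential(layers)


def make_cnn(input_hw: tuple[int, int], n_filters: int, kernel: int,
             hidden: int, n_out: int, rng: np.random.Generator) -> Sequential:
    h, w = input_hw
    flat = (h // 2) * (w // 2) * n_filters
    return Sequential(
        [
            Conv3x3(n_filters, rng, kernel=kernel),
            ReLU(),
            MaxPool2(),
            Flatten(),
            Dense(flat, hidden, rng),
            ReLU(),
            Dense(hidden, n_out, rng),
        ]
    )
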