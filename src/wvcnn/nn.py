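"""Minimal sequential neural-network engine for small 1-D CNN classifiers.

Implements exactly what the ensemble members need — 1-D convolution
(stride 1, no padding, single input channel), flatten, dense, dropout,
ReLU/softmax/sigmoid activations, categorical cross-entropy and the Adam
optimizer — as plain NumPy forward/backward passes.  Everything is driven
by one ``numpy.random.Generator``, so training is bit-reproducible.

The output layer's ``backward`` expects the gradient with respect to its
*logits*: for softmax with cross-entropy (and equally for sigmoid with
per-class binary cross-entropy) that gradient is ``(probs - targets) / B``,
which :meth:`SequentialNet.train_batch` supplies directly.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def _glorot(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class Layer:
    """Base layer: parameter-less identity."""

    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray, training: bool, rng: np.random.Generator) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv1D(Layer):
    """Valid-mode 1-D convolution over a single-channel sequence, ReLU."""

    def __init__(self, filters: int, kernel: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.kernel = kernel
        self.filters = filters
        W = _glorot(rng, (kernel, filters), kernel, kernel * filters)
        b = np.zeros(filters)
        self.params = [W, b]
        self.grads = [np.zeros_like(W), np.zeros_like(b)]

    def forward(self, x: np.ndarray, training: bool, rng: np.random.Generator) -> np.ndarray:
        W, b = self.params
        self._windows = sliding_window_view(x, self.kernel, axis=1)  # (B, L', K)
        z = self._windows @ W + b  # (B, L', F)
        self._mask = z > 0
        return np.where(self._mask, z, 0.0)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        W, _ = self.params
        dz = grad * self._mask
        self.grads[0][...] = np.einsum("blk,blf->kf", self._windows, dz)
        self.grads[1][...] = dz.sum(axis=(0, 1))
        B, Lp, _ = dz.shape
        dx = np.zeros((B, Lp + self.kernel - 1))
        for t in range(self.kernel):
            dx[:, t : t + Lp] += dz @ W[t]
        return dx


class Flatten(Layer):
    def forward(self, x: np.ndarray, training: bool, rng: np.random.Generator) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)


class Dense(Layer):
    """Fully connected layer with relu, softmax, sigmoid or linear output."""

    def __init__(self, in_dim: int, units: int, activation: str, rng: np.random.Generator) -> None:
        super().__init__()
        if activation not in ("relu", "softmax", "sigmoid", "none"):
            raise ValueError(f"unknown activation {activation!r}")
        self.activation = activation
        W = _glorot(rng, (in_dim, units), in_dim, units)
        b = np.zeros(units)
        self.params = [W, b]
        self.grads = [np.zeros_like(W), np.zeros_like(b)]

    def forward(self, x: np.ndarray, training: bool, rng: np.random.Generator) -> np.ndarray:
        self._x = x
        z = x @ self.params[0] + self.params[1]
        if self.activation == "relu":
            self._mask = z > 0
            return np.where(self._mask, z, 0.0)
        if self.activation == "softmax":
            return softmax(z)
        if self.activation == "sigmoid":
            return 1.0 / (1.0 + np.exp(-z))
        return z

    def backward(self, grad: np.ndarray) -> np.ndarray:
        # softmax/sigmoid output layers receive the logit-space gradient
        dz = grad * self._mask if self.activation == "relu" else grad
        self.grads[0][...] = self._x.T @ dz
        self.grads[1][...] = dz.sum(axis=0)
        return dz @ self.params[0].T


class Dropout(Layer):
    """Inverted dropout: active only while training."""

    def __init__(self, rate: float) -> None:
        super().__init__()
        if not 0.0 < rate < 1.0:
            raise ValueError("dropout rate must be in (0, 1)")
        self.rate = rate

    def forward(self, x: np.ndarray, training: bool, rng: np.random.Generator) -> np.ndarray:
        if not training:
            self._mask = None
            return x
        self._mask = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad if self._mask is None else grad * self._mask


class Adam:
    """Adam with the standard bias correction; no weight decay."""

    def __init__(
        self,
        params: list[np.ndarray],
        learning_rate: float = 0.001,
        beta1: float = 0.9,
        beta2: float = 0.999,
        epsilon: float = 1e-7,
    ) -> None:
        self.params = params
        self.lr = learning_rate
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = epsilon
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


class SequentialNet:
    """A stack of layers trained with cross-entropy and Adam."""

    def __init__(self, layers: list[Layer], rng: np.random.Generator) -> None:
        self.layers = layers
        self.rng = rng

    @property
    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training, self.rng)
        return x

    def backward(self, grad: np.ndarray) -> None:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        probs = self.forward(x, training=False)
        # sigmoid outputs are renormalized into a distribution
        return probs / probs.sum(axis=1, keepdims=True)

    def train_batch(self, x: np.ndarray, targets: np.ndarray, optimizer: Adam) -> float:
        probs = self.forward(x, training=True)
        eps = 1e-12
        loss = -np.mean(np.sum(targets * np.log(probs + eps), axis=1))
        self.backward((probs - targets) / len(x))
        optimizer.step(self.grads)
        return float(loss)

    def fit(
        self,
        x: np.ndarray,
        targets: np.ndarray,
        epochs: int,
        batch_size: int,
        optimizer: Adam,
    ) -> list[float]:
        """Mini-batch training; returns the mean loss per epoch."""
        n = len(x)
        history = []
        for _ in range(epochs):
            order = self.rng.permutation(n)
            losses = []
            for start in range(0, n, batch_size):
                idx = order[start : start + batch_size]
                losses.append(self.train_batch(x[idx], targets[idx], optimizer))
            history.append(float(np.mean(losses)))
        return history
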