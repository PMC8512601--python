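"""Minimal deterministic neural-network layer library (numpy, CPU).

Implements exactly what the reference sequence classifiers need: 1-D valid
convolution, a tanh recurrent layer, dense output, ReLU, global average
pooling over time, softmax cross-entropy, and Adam. Forward and backward
passes are hand-derived and covered by finite-difference gradient checks in
the test suite. All randomness flows through a caller-supplied
``numpy.random.Generator``, so training is bit-reproducible within one
runtime environment.

Array convention: batches are ``(B, T, C)`` — batch, time steps, channels —
until pooling or the recurrent layer collapses time, after which they are
``(B, F)``.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "softmax",
    "log_softmax",
    "Dense",
    "Conv1d",
    "ReLU",
    "GlobalAvgPool",
    "RNN",
    "Sequential",
    "Adam",
    "cross_entropy_grad",
]


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    """Numerically stable softmax."""
    z = np.asarray(z, dtype=float)
    m = z.max(axis=axis, keepdims=True)
    e = np.exp(z - m)
    return e / e.sum(axis=axis, keepdims=True)


def log_softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = np.asarray(z, dtype=float)
    m = z.max(axis=axis, keepdims=True)
    s = z - m
    return s - np.log(np.exp(s).sum(axis=axis, keepdims=True))


def cross_entropy_grad(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean multiclass cross-entropy from logits and its gradient."""
    b = logits.shape[0]
    logp = log_softmax(logits)
    loss = -float(logp[np.arange(b), y].mean())
    dlogits = softmax(logits)
    dlogits[np.arange(b), y] -= 1.0
    return loss, dlogits / b


def _glorot(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Layer:
    """Base class; parameterised layers fill ``params`` and ``grads``."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Dense(Layer):
    """Affine map on ``(B, F_in) -> (B, F_out)``."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.params["W"] = _glorot(rng, (n_in, n_out), n_in, n_out)
        self.params["b"] = np.zeros(n_out)

    def forward(self, x):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout):
        self.grads["W"] = self._x.T @ dout
        self.grads["b"] = dout.sum(axis=0)
        return dout @ self.params["W"].T


class Conv1d(Layer):
    """Valid 1-D convolution over time: ``(B, T, C) -> (B, L, F)``.

    ``L = (T - k) // stride + 1``. Implemented as im2col + matmul; the
    weight matrix has one row per (tap, input channel) pair.
    """

    def __init__(
        self,
        n_in: int,
        n_out: int,
        kernel: int,
        rng: np.random.Generator,
        stride: int = 1,
    ) -> None:
        super().__init__()
        if kernel < 1 or stride < 1:
            raise ValueError("kernel and stride must be >= 1")
        self.kernel = kernel
        self.stride = stride
        self.n_in = n_in
        fan_in = kernel * n_in
        self.params["W"] = _glorot(rng, (fan_in, n_out), fan_in, n_out)
        self.params["b"] = np.zeros(n_out)

    def forward(self, x):
        b, t, c = x.shape
        k, s = self.kernel, self.stride
        if t < k:
            raise ValueError(f"input of {t} steps shorter than kernel {k}")
        starts = np.arange(0, t - k + 1, s)
        view = sliding_window_view(x, k, axis=1)  # (B, T-k+1, C, k)
        cols = view[:, starts].transpose(0, 1, 3, 2)  # (B, L, k, C)
        self._cols = cols.reshape(b, len(starts), k * c)
        self._in_shape = x.shape
        self._starts = starts
        return self._cols @ self.params["W"] + self.params["b"]

    def backward(self, dout):
        b, t, c = self._in_shape
        k = self.kernel
        self.grads["W"] = np.einsum("blf,blo->fo", self._cols, dout)
        self.grads["b"] = dout.sum(axis=(0, 1))
        dcols = (dout @ self.params["W"].T).reshape(b, -1, k, c)
        dx = np.zeros(self._in_shape)
        for i, start in enumerate(self._starts):
            dx[:, start : start + k, :] += dcols[:, i]
        return dx


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class GlobalAvgPool(Layer):
    """Mean over the time axis: ``(B, T, F) -> (B, F)``."""

    def forward(self, x):
        self._t = x.shape[1]
        return x.mean(axis=1)

    def backward(self, dout):
        return np.repeat(dout[:, None, :], self._t, axis=1) / self._t


class RNN(Layer):
    """Tanh recurrent layer, ``h_t = tanh(x_t Wx + h_{t-1} Wh + b)``.

    Returns the full hidden sequence ``(B, T, H)`` when
    ``return_sequences`` is true (for stacking), else the final hidden
    state ``(B, H)``. Backpropagation through time is exact over the whole
    window.
    """

    def __init__(
        self,
        n_in: int,
        n_hidden: int,
        rng: np.random.Generator,
        return_sequences: bool = False,
    ) -> None:
        super().__init__()
        self.n_hidden = n_hidden
        self.return_sequences = return_sequences
        self.params["Wx"] = _glorot(rng, (n_in, n_hidden), n_in, n_hidden)
        # orthogonal-ish recurrent init keeps gradients stable over T ~ 100
        a = rng.normal(size=(n_hidden, n_hidden))
        q, _ = np.linalg.qr(a)
        self.params["Wh"] = q
        self.params["b"] = np.zeros(n_hidden)

    def forward(self, x):
        b, t, _ = x.shape
        wx, wh, bias = self.params["Wx"], self.params["Wh"], self.params["b"]
        hs = np.empty((b, t, self.n_hidden))
        h = np.zeros((b, self.n_hidden))
        xw = x @ wx + bias
        for step in range(t):
            h = np.tanh(xw[:, step] + h @ wh)
            hs[:, step] = h
        self._x, self._hs = x, hs
        return hs if self.return_sequences else hs[:, -1]

    def backward(self, dout):
        x, hs = self._x, self._hs
        b, t, _ = x.shape
        wx, wh = self.params["Wx"], self.params["Wh"]
        d_wx = np.zeros_like(wx)
        d_wh = np.zeros_like(wh)
        d_b = np.zeros_like(self.params["b"])
        dx = np.zeros_like(x)
        dh = np.zeros((b, self.n_hidden))
        for step in range(t - 1, -1, -1):
            if self.return_sequences:
                dh = dh + dout[:, step]
            elif step == t - 1:
                dh = dh + dout
            da = dh * (1.0 - hs[:, step] ** 2)
            d_wx += x[:, step].T @ da
            h_prev = hs[:, step - 1] if step > 0 else np.zeros((b, self.n_hidden))
            d_wh += h_prev.T @ da
            d_b += da.sum(axis=0)
            dx[:, step] = da @ wx.T
            dh = da @ wh.T
        self.grads["Wx"], self.grads["Wh"], self.grads["b"] = d_wx, d_wh, d_b
        return dx


class Sequential:
    """A feed-forward stack of layers with a shared backward pass."""

    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def parameters(self):
        """Yield ``(key, layer, name)`` triples for every trainable array."""
        for i, layer in enumerate(self.layers):
            for name in layer.params:
                yield (i, name), layer, name

    def state_arrays(self) -> dict[str, np.ndarray]:
        """Flat name -> array mapping for persistence."""
        return {
            f"layer{i}_{name}": layer.params[name]
            for (i, name), layer, name in self.parameters()
        }

    def load_state(self, arrays: dict[str, np.ndarray]) -> None:
        for (i, name), layer, _ in self.parameters():
            layer.params[name] = np.asarray(arrays[f"layer{i}_{name}"], dtype=float)


class Adam:
    """Adam optimizer over a :class:`Sequential`'s parameters."""

    def __init__(
        self,
        net: Sequential,
        lr: float = 1e-2,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ) -> None:
        self.net = net
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self._m: dict = {}
        self._v: dict = {}

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for key, layer, name in self.net.parameters():
            g = layer.grads.get(name)
            if g is None:
                continue
            m = self._m.setdefault(key, np.zeros_like(g))
            v = self._v.setdefault(key, np.zeros_like(g))
            m[:] = b1 * m + (1 - b1) * g
            v[:] = b2 * v + (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            layer.params[name] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
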