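"""Minimal numpy neural-network layers for desk-scale audits.

Dense and N-dimensional convolution (stride 1, valid padding, implemented
as matrix multiplication over sliding windows), 2x max pooling, ReLU, and
an Adam optimizer with softmax cross-entropy.  Deliberately small: the
audit framework is model-agnostic, these layers exist so the end-to-end
pipeline trains in seconds on one CPU with fully deterministic, seedable
initialisation.
"""

from __future__ import annotations

import copy
from typing import Optional, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Layer:
    """Base layer: forward caches what backward needs; params/grads by name."""

    def __init__(self):
        self.params: dict = {}
        self.grads: dict = {}

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        scale = np.sqrt(2.0 / n_in)
        self.params = {"W": rng.normal(0.0, scale, (n_in, n_out)),
                       "b": np.zeros(n_out)}

    def forward(self, x):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout):
        self.grads = {"W": self._x.T @ dout, "b": dout.sum(axis=0)}
        return dout @ self.params["W"].T


class Conv(Layer):
    """N-dimensional convolution, stride 1, no padding.

    Input ``(B, C_in, *S)``; kernel ``k`` along every structured axis.
    """

    def __init__(self, n_in: int, n_out: int, k: int, ndim: int,
                 rng: np.random.Generator):
        super().__init__()
        self.k, self.ndim = k, ndim
        kshape = (k,) * ndim
        fan_in = n_in * k ** ndim
        self.params = {"W": rng.normal(0.0, np.sqrt(2.0 / fan_in),
                                       (n_out, n_in) + kshape),
                       "b": np.zeros(n_out)}

    def _cols(self, x):
        # (B, C, *Sout, *K) -> (B, *Sout, C, *K) -> (B*P, C*k^d)
        win = sliding_window_view(
            x, (self.k,) * self.ndim, axis=tuple(range(2, 2 + self.ndim)))
        win = np.moveaxis(win, 1, 1 + self.ndim)
        sout = win.shape[1:1 + self.ndim]
        cols = win.reshape(x.shape[0] * int(np.prod(sout)), -1)
        return cols, sout

    def forward(self, x):
        W, b = self.params["W"], self.params["b"]
        cols, sout = self._cols(x)
        self._cols_cache, self._x_shape, self._sout = cols, x.shape, sout
        out = cols @ W.reshape(W.shape[0], -1).T + b
        out = out.reshape((x.shape[0],) + sout + (W.shape[0],))
        return np.moveaxis(out, -1, 1)

    def backward(self, dout):
        W = self.params["W"]
        n_out = W.shape[0]
        dmat = np.moveaxis(dout, 1, -1).reshape(-1, n_out)
        self.grads = {"W": (dmat.T @ self._cols_cache).reshape(W.shape),
                      "b": dmat.sum(axis=0)}
        # dx = full-correlation of dout with the flipped kernel, again as
        # a matmul over sliding windows of the zero-padded upstream grad.
        pad = [(0, 0), (0, 0)] + [(self.k - 1, self.k - 1)] * self.ndim
        dpad = np.pad(dout, pad)
        win = sliding_window_view(
            dpad, (self.k,) * self.ndim, axis=tuple(range(2, 2 + self.ndim)))
        win = np.moveaxis(win, 1, 1 + self.ndim)  # (B, *Sin, F, *K)
        cols = win.reshape(self._x_shape[0] * int(np.prod(self._x_shape[2:])), -1)
        wflip = W
        for ax in range(2, 2 + self.ndim):
            wflip = np.flip(wflip, axis=ax)
        wmat = np.moveaxis(wflip, 1, -1).reshape(-1, W.shape[1])  # (F*k^d, C_in)
        dx = cols @ wmat
        dx = dx.reshape((self._x_shape[0],) + self._x_shape[2:] + (W.shape[1],))
        return np.moveaxis(dx, -1, 1)


class MaxPool(Layer):
    """2x downsampling along every structured axis (odd trailing elements
    are cropped)."""

    def forward(self, x):
        ndim = x.ndim - 2
        crop = tuple([slice(None), slice(None)] +
                     [slice(0, (s // 2) * 2) for s in x.shape[2:]])
        xc = x[crop]
        self._x_shape = x.shape
        self._crop_shape = xc.shape
        shape = list(xc.shape[:2])
        for s in xc.shape[2:]:
            shape += [s // 2, 2]
        xr = xc.reshape(shape)
        pool_axes = tuple(3 + 2 * i for i in range(ndim))
        m = xr.max(axis=pool_axes, keepdims=True)
        mask = (xr == m)
        self._mask = mask / mask.sum(axis=pool_axes, keepdims=True)
        self._pool_axes = pool_axes
        return np.squeeze(m, axis=pool_axes)

    def backward(self, dout):
        d = np.expand_dims(dout, axis=self._pool_axes)
        dxr = (self._mask * d).reshape(self._crop_shape)
        dx = np.zeros(self._x_shape, dtype=dout.dtype)
        dx[tuple([slice(None), slice(None)] +
                 [slice(0, s) for s in self._crop_shape[2:]])] = dxr
        return dx


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class Flatten(Layer):
    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class GlobalMaxPool(Layer):
    """Max over all structured axes -> (B, C); used by the text model so
    input length need not be fixed at build time."""

    def forward(self, x):
        axes = tuple(range(2, x.ndim))
        m = x.max(axis=axes, keepdims=True)
        mask = (x == m)
        self._mask = mask / mask.sum(axis=axes, keepdims=True)
        self._axes = axes
        return np.squeeze(m, axis=axes)

    def backward(self, dout):
        return self._mask * np.expand_dims(dout, axis=self._axes)


class Adam:
    """Adam with per-parameter first/second moment state."""

    def __init__(self, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.lr, self.betas, self.eps = lr, betas, eps
        self.t = 0
        self._m: dict = {}
        self._v: dict = {}

    def step(self, layers: Sequence[Layer]) -> None:
        self.t += 1
        b1, b2 = self.betas
        for i, layer in enumerate(layers):
            for name, p in layer.params.items():
                g = layer.grads[name]
                key = (i, name)
                m = self._m.setdefault(key, np.zeros_like(p))
                v = self._v.setdefault(key, np.zeros_like(p))
                m[...] = b1 * m + (1 - b1) * g
                v[...] = b2 * v + (1 - b2) * g * g
                mhat = m / (1 - b1 ** self.t)
                vhat = v / (1 - b2 ** self.t)
                p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class SequentialClassifier:
    """Feed-forward classifier with the fit-step/score contract the
    training harness consumes."""

    def __init__(self, layers: Sequence[Layer], n_classes: int):
        self.layers = list(layers)
        self.n_classes = n_classes

    # -- contract -----------------------------------------------------
    def train_step(self, x: np.ndarray, y: np.ndarray, optimizer: Adam) -> float:
        """One forward/backward/update pass; returns the batch loss."""
        logits = self.forward(x)
        probs = softmax(logits)
        n = x.shape[0]
        eps = 1e-12
        loss = -np.log(probs[np.arange(n), y] + eps).mean()
        dlogits = probs.copy()
        dlogits[np.arange(n), y] -= 1.0
        dlogits /= n
        dout = dlogits
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        optimizer.step(self.layers)
        return float(loss)

    def scores(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Class probabilities, evaluated in chunks to bound memory."""
        outs = [softmax(self.forward(x[i:i + batch_size]))
                for i in range(0, x.shape[0], batch_size)]
        return np.concatenate(outs, axis=0)

    # -- plumbing -----------------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def get_weights(self) -> list:
        return [copy.deepcopy(layer.params) for layer in self.layers]

    def set_weights(self, weights: list) -> None:
        for layer, params in zip(self.layers, weights):
            for name in layer.params:
                layer.params[name][...] = params[name]

    @property
    def n_parameters(self) -> int:
        return int(sum(p.size for layer in self.layers
                       for p in layer.params.values()))
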