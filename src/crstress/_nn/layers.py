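"""Layers with explicit forward/backward passes.

Each layer caches what its backward pass needs during forward; calling
``backward`` before ``forward`` is a usage error. Parameters and their
gradients are exposed through ``params()`` as (name, value, grad) triples
so the optimizer can update them in place.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Layer:
    """Base class: stateless layers only need forward/backward."""

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self):
        return []

    def state_dict(self):
        return {k: v.copy() for k, v in self._state().items()}

    def load_state_dict(self, state):
        for k, v in self._state().items():
            v[...] = state[k]

    def _state(self):
        return {}


def conv_out_size(n: int, kernel: int, stride: int, padding: int) -> int:
    """Closed-form spatial extent after a convolution."""
    return (n + 2 * padding - kernel) // stride + 1


class Conv2d(Layer):
    """2-D convolution (cross-correlation) via im2col.

    Weight layout (C_out, C_in, k, k); He-uniform initialization.
    """

    def __init__(self, in_channels, out_channels, kernel=6, stride=2,
                 padding=2, rng=None, dtype=np.float32):
        rng = rng or np.random.default_rng()
        fan_in = in_channels * kernel * kernel
        bound = np.sqrt(6.0 / fan_in)
        self.W = rng.uniform(-bound, bound,
                             (out_channels, in_channels, kernel, kernel)).astype(dtype)
        self.b = np.zeros(out_channels, dtype=dtype)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.kernel, self.stride, self.padding = kernel, stride, padding

    def forward(self, x, train=True):
        k, s, p = self.kernel, self.stride, self.padding
        n, c, h, w = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        ho, wo = win.shape[2], win.shape[3]
        # (N, Ho, Wo, C*k*k) rows against (C*k*k, C_out) columns
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
            n * ho * wo, c * k * k)
        out = cols @ self.W.reshape(self.W.shape[0], -1).T + self.b
        self._cache = (cols, x.shape, ho, wo)
        return out.reshape(n, ho, wo, -1).transpose(0, 3, 1, 2)

    def backward(self, dout):
        k, s, p = self.kernel, self.stride, self.padding
        cols, xshape, ho, wo = self._cache
        n, c, h, w = xshape
        co = self.W.shape[0]
        dcols_rows = dout.transpose(0, 2, 3, 1).reshape(n * ho * wo, co)
        self.dW[...] = (dcols_rows.T @ cols).reshape(self.W.shape)
        self.db[...] = dcols_rows.sum(axis=0)
        dcols = (dcols_rows @ self.W.reshape(co, -1)).reshape(n, ho, wo, c, k, k)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=dout.dtype)
        # scatter-add per kernel offset: 36 strided adds instead of np.add.at
        dcols = dcols.transpose(0, 3, 1, 2, 4, 5)  # N, C, Ho, Wo, k, k
        for i in range(k):
            for j in range(k):
                dxp[:, :, i:i + s * ho:s, j:j + s * wo:s] += dcols[..., i, j]
        return dxp[:, :, p:p + h, p:p + w]

    def params(self):
        return [("W", self.W, self.dW), ("b", self.b, self.db)]

    def _state(self):
        return {"W": self.W, "b": self.b}


class MaxPool2d(Layer):
    """Non-overlapping max pooling (kernel = stride); trailing rows/columns
    that do not fill a window are dropped, matching torch's floor mode."""

    def __init__(self, kernel=2):
        self.kernel = kernel

    def forward(self, x, train=True):
        k = self.kernel
        n, c, h, w = x.shape
        ho, wo = h // k, w // k
        xv = x[:, :, :ho * k, :wo * k].reshape(n, c, ho, k, wo, k)
        win = xv.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, ho, wo, k * k)
        idx = win.argmax(axis=-1)
        out = np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]
        self._cache = (idx, x.shape)
        return out

    def backward(self, dout):
        k = self.kernel
        idx, xshape = self._cache
        n, c, h, w = xshape
        ho, wo = h // k, w // k
        dwin = np.zeros((n, c, ho, wo, k * k), dtype=dout.dtype)
        np.put_along_axis(dwin, idx[..., None], dout[..., None], axis=-1)
        dx = np.zeros(xshape, dtype=dout.dtype)
        dx[:, :, :ho * k, :wo * k] = dwin.reshape(n, c, ho, wo, k, k).transpose(
            0, 1, 2, 4, 3, 5).reshape(n, c, ho * k, wo * k)
        return dx


class ReLU(Layer):
    def forward(self, x, train=True):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class Flatten(Layer):
    def forward(self, x, train=True):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Linear(Layer):
    def __init__(self, in_features, out_features, rng=None, dtype=np.float32):
        rng = rng or np.random.default_rng()
        bound = np.sqrt(6.0 / in_features)
        self.W = rng.uniform(-bound, bound, (out_features, in_features)).astype(dtype)
        self.b = np.zeros(out_features, dtype=dtype)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x, train=True):
        self._x = x
        return x @ self.W.T + self.b

    def backward(self, dout):
        self.dW[...] = dout.T @ self._x
        self.db[...] = dout.sum(axis=0)
        return dout @ self.W

    def params(self):
        return [("W", self.W, self.dW), ("b", self.b, self.db)]

    def _state(self):
        return {"W": self.W, "b": self.b}


class _BatchNorm(Layer):
    """Shared batch-norm arithmetic; subclasses define the reduction axes."""

    def __init__(self, num_features, momentum=0.1, eps=1e-5, dtype=np.float32):
        self.gamma = np.ones(num_features, dtype=dtype)
        self.beta = np.zeros(num_features, dtype=dtype)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(num_features, dtype=dtype)
        self.running_var = np.ones(num_features, dtype=dtype)
        self.momentum, self.eps = momentum, eps

    axes: tuple = ()

    def _reshape(self, v):
        raise NotImplementedError

    def forward(self, x, train=True):
        if train:
            mean = x.mean(axis=self.axes)
            var = x.var(axis=self.axes)
            m = self.momentum
            self.running_mean[...] = (1 - m) * self.running_mean + m * mean
            self.running_var[...] = (1 - m) * self.running_var + m * var
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - self._reshape(mean)) * self._reshape(inv_std)
        self._cache = (xhat, inv_std, train)
        return self._reshape(self.gamma) * xhat + self._reshape(self.beta)

    def backward(self, dout):
        xhat, inv_std, trained = self._cache
        self.dgamma[...] = (dout * xhat).sum(axis=self.axes)
        self.dbeta[...] = dout.sum(axis=self.axes)
        dxhat = dout * self._reshape(self.gamma)
        if not trained:
            # eval mode: running stats are constants, no batch coupling
            return dxhat * self._reshape(inv_std)
        dx = (dxhat - self._reshape(dxhat.mean(axis=self.axes))
              - xhat * self._reshape((dxhat * xhat).mean(axis=self.axes)))
        return dx * self._reshape(inv_std)

    def params(self):
        return [("gamma", self.gamma, self.dgamma), ("beta", self.beta, self.dbeta)]

    def _state(self):
        return {"gamma": self.gamma, "beta": self.beta,
                "running_mean": self.running_mean, "running_var": self.running_var}


class BatchNorm2d(_BatchNorm):
    axes = (0, 2, 3)

    def _reshape(self, v):
        return v.reshape(1, -1, 1, 1)


class BatchNorm1d(_BatchNorm):
    axes = (0,)

    def _reshape(self, v):
        return v.reshape(1, -1)


class Sequential(Layer):
    def __init__(self, *layers):
        self.layers = list(layers)

    def forward(self, x, train=True, capture: int | None = None):
        """Run the stack; if ``capture`` is given, keep a reference to the
        output of that layer index (used by Grad-CAM)."""
        self.captured = None
        for i, layer in enumerate(self.layers):
            x = layer.forward(x, train=train)
            if capture is not None and i == capture:
                self.captured = x
        return x

    def backward(self, dout, stop_at: int | None = None):
        """Backpropagate; if ``stop_at`` is given, return the gradient
        flowing INTO the output of layer ``stop_at`` instead of the input
        gradient (i.e. stop after processing layer ``stop_at + 1``)."""
        for i in range(len(self.layers) - 1, -1, -1):
            if stop_at is not None and i == stop_at:
                return dout
            dout = self.layers[i].backward(dout)
        return dout

    def params(self):
        out = []
        for i, layer in enumerate(self.layers):
            out.extend((f"{i}.{n}", v, g) for n, v, g in layer.params())
        return out

    def state_dict(self):
        return {f"{i}.{k}": v.copy()
                for i, layer in enumerate(self.layers)
                for k, v in layer._state().items()}

    def load_state_dict(self, state):
        for i, layer in enumerate(self.layers):
            for k, v in layer._state().items():
                v[...] = state[f"{i}.{k}"]
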