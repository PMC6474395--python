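"""Minimal feed-forward neural-network substrate in numpy.

Implements exactly what the reconstruction model needs: dense,
convolution and up-convolution (transposed convolution) layers with
hand-derived backward passes, common activations, He ("MSRA")
initialization and the Adam optimizer.  Arrays are NCHW; the default
parameter dtype is float32 (float64 is used by the gradient-check
tests).

Convolutions are expressed through three linear primitives —
``conv_fwd``, ``conv_bwd_input`` and ``conv_bwd_weight`` — built on
``sliding_window_view`` plus BLAS matmuls.  The transposed convolution
is the exact adjoint: its forward pass is ``conv_bwd_input`` and its
input gradient is ``conv_fwd``, which keeps the two layer types
consistent by construction.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param", "Layer", "Dense", "Conv2d", "ConvTranspose2d",
    "ReLU", "LeakyReLU", "Tanh", "Sigmoid", "Reshape", "Flatten",
    "GlobalAvgPool", "Sequential", "Adam", "softmax",
    "conv_fwd", "conv_bwd_input", "conv_bwd_weight",
]


# ---------------------------------------------------------------------------
# convolution primitives

def _pad(x, p):
    if p == 0:
        return x
    return np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))


def _windows(xp, k, stride):
    # xp: (N, C, Hp, Wp) -> (N, C, Ho, Wo, k, k) strided view
    v = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    return v[:, :, ::stride, ::stride]


def conv_out_size(h: int, k: int, stride: int, pad: int) -> int:
    return (h + 2 * pad - k) // stride + 1


def convt_out_size(h: int, k: int, stride: int, pad: int) -> int:
    return (h - 1) * stride - 2 * pad + k


def conv_fwd(x, w, stride=1, pad=0):
    """Correlate ``x`` (N,Ci,H,W) with ``w`` (Co,Ci,k,k) -> (N,Co,Ho,Wo)."""
    n = x.shape[0]
    co, ci, k, _ = w.shape
    v = _windows(_pad(x, pad), k, stride)
    ho, wo = v.shape[2], v.shape[3]
    cols = v.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, ci * k * k)
    y = cols @ w.reshape(co, -1).T
    return y.reshape(n, ho, wo, co).transpose(0, 3, 1, 2)


def conv_bwd_weight(x, gy, stride=1, pad=0, k=None):
    """Gradient of conv_fwd w.r.t. ``w``; gy is (N,Co,Ho,Wo)."""
    n, co, ho, wo = gy.shape
    ci = x.shape[1]
    v = _windows(_pad(x, pad), k, stride)
    cols = v.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, ci * k * k)
    g = gy.transpose(0, 2, 3, 1).reshape(n * ho * wo, co)
    return (g.T @ cols).reshape(co, ci, k, k)


def conv_bwd_input(gy, w, stride=1, pad=0, in_hw=None):
    """Gradient of conv_fwd w.r.t. ``x`` (also the up-convolution forward)."""
    n, co, ho, wo = gy.shape
    _, ci, k, _ = w.shape
    h_in, w_in = in_hw
    g = gy.transpose(0, 2, 3, 1).reshape(n * ho * wo, co)
    cols = (g @ w.reshape(co, -1)).reshape(n, ho, wo, ci, k, k)
    gxp = np.zeros((n, ci, h_in + 2 * pad, w_in + 2 * pad), dtype=gy.dtype)
    for kh in range(k):
        for kw in range(k):
            gxp[:, :, kh:kh + ho * stride:stride, kw:kw + wo * stride:stride] \
                += cols[:, :, :, :, kh, kw].transpose(0, 3, 1, 2)
    if pad:
        gxp = gxp[:, :, pad:-pad, pad:-pad]
    return gxp


def softmax(z):
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


# ---------------------------------------------------------------------------
# layers

class Param:
    __slots__ = ("data", "grad")

    def __init__(self, data):
        self.data = data
        self.grad = np.zeros_like(data)


class Layer:
    """Base layer; subclasses cache whatever the backward pass needs."""

    def params(self):
        return []

    def forward(self, x):  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, gy):  # pragma: no cover - abstract
        raise NotImplementedError


def _msra(rng, shape, fan_in, dtype):
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(dtype)


class Dense(Layer):
    def __init__(self, d_in, d_out, rng, dtype=np.float32):
        self.w = Param(_msra(rng, (d_in, d_out), d_in, dtype))
        self.b = Param(np.zeros(d_out, dtype=dtype))

    def params(self):
        return [self.w, self.b]

    def forward(self, x):
        self._x = x
        return x @ self.w.data + self.b.data

    def backward(self, gy):
        self.w.grad += self._x.T @ gy
        self.b.grad += gy.sum(axis=0)
        return gy @ self.w.data.T


class Conv2d(Layer):
    def __init__(self, c_in, c_out, k, stride, pad, rng, dtype=np.float32):
        self.k, self.stride, self.pad = k, stride, pad
        self.w = Param(_msra(rng, (c_out, c_in, k, k), c_in * k * k, dtype))
        self.b = Param(np.zeros(c_out, dtype=dtype))

    def params(self):
        return [self.w, self.b]

    def forward(self, x):
        self._x = x
        y = conv_fwd(x, self.w.data, self.stride, self.pad)
        return y + self.b.data[None, :, None, None]

    def backward(self, gy):
        self.w.grad += conv_bwd_weight(self._x, gy, self.stride, self.pad, self.k)
        self.b.grad += gy.sum(axis=(0, 2, 3))
        return conv_bwd_input(gy, self.w.data, self.stride, self.pad,
                              self._x.shape[2:])


class ConvTranspose2d(Layer):
    """Up-convolution: the exact adjoint of Conv2d with the same geometry."""

    def __init__(self, c_in, c_out, k, stride, pad, rng, dtype=np.float32):
        self.k, self.stride, self.pad = k, stride, pad
        # stored in conv orientation (c_in plays the conv output role)
        self.w = Param(_msra(rng, (c_in, c_out, k, k), c_in * k * k, dtype))
        self.b = Param(np.zeros(c_out, dtype=dtype))

    def params(self):
        return [self.w, self.b]

    def out_size(self, h):
        return convt_out_size(h, self.k, self.stride, self.pad)

    def forward(self, x):
        self._x = x
        hw = (self.out_size(x.shape[2]), self.out_size(x.shape[3]))
        y = conv_bwd_input(x, self.w.data, self.stride, self.pad, hw)
        return y + self.b.data[None, :, None, None]

    def backward(self, gy):
        self.w.grad += conv_bwd_weight(gy, self._x, self.stride, self.pad, self.k)
        self.b.grad += gy.sum(axis=(0, 2, 3))
        return conv_fwd(gy, self.w.data, self.stride, self.pad)


class ReLU(Layer):
    def forward(self, x):
        self._m = x > 0
        return x * self._m

    def backward(self, gy):
        return gy * self._m


class LeakyReLU(Layer):
    def __init__(self, slope=0.2):
        self.slope = slope

    def forward(self, x):
        self._m = x > 0
        return np.where(self._m, x, self.slope * x)

    def backward(self, gy):
        return np.where(self._m, gy, self.slope * gy)


class Tanh(Layer):
    def forward(self, x):
        self._y = np.tanh(x)
        return self._y

    def backward(self, gy):
        return gy * (1.0 - self._y ** 2)


class Sigmoid(Layer):
    def forward(self, x):
        self._y = 1.0 / (1.0 + np.exp(-x))
        return self._y

    def backward(self, gy):
        return gy * self._y * (1.0 - self._y)


class Reshape(Layer):
    def __init__(self, shape):
        self.shape = shape  # per-sample shape

    def forward(self, x):
        self._in = x.shape
        return x.reshape((x.shape[0],) + tuple(self.shape))

    def backward(self, gy):
        return gy.reshape(self._in)


class Flatten(Reshape):
    def __init__(self):
        pass

    def forward(self, x):
        self._in = x.shape
        return x.reshape(x.shape[0], -1)


class GlobalAvgPool(Layer):
    def forward(self, x):
        self._in = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, gy):
        n, c, h, w = self._in
        return np.broadcast_to(gy[:, :, None, None], self._in) / (h * w)


class Sequential:
    def __init__(self, layers):
        self.layers = list(layers)

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def forward(self, x):
        for l in self.layers:
            x = l.forward(x)
        return x

    __call__ = forward

    def forward_to(self, x, stop):
        """Forward through ``layers[:stop]`` (used for comparator taps)."""
        for l in self.layers[:stop]:
            x = l.forward(x)
        return x

    def backward(self, gy, start=None):
        layers = self.layers if start is None else self.layers[:start]
        for l in reversed(layers):
            gy = l.backward(gy)
        return gy

    def zero_grad(self):
        for p in self.params():
            p.grad[...] = 0.0

    # -- (de)serialization ---------------------------------------------------
    def state_arrays(self):
        return [p.data for p in self.params()]

    def load_state_arrays(self, arrays):
        params = self.params()
        if len(arrays) != len(params):
            raise ValueError("parameter count mismatch in checkpoint")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError("parameter shape mismatch in checkpoint")
            p.data = a.astype(p.data.dtype, copy=True)
            p.grad = np.zeros_like(p.data)


class Adam:
    """Adam with bias correction (Kingma & Ba)."""

    def __init__(self, params, lr=2e-4, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        c1 = 1.0 - b1 ** self.t
        c2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.data -= self.lr * (m / c1) / (np.sqrt(v / c2) + self.eps)

    def state_arrays(self):
        return list(self.m) + list(self.v) + [np.array([self.t])]

    def load_state_arrays(self, arrays):
        n = len(self.params)
        if len(arrays) != 2 * n + 1:
            raise ValueError("optimizer state length mismatch")
        self.m = [a.astype(p.data.dtype, copy=True)
                  for a, p in zip(arrays[:n], self.params)]
        self.v = [a.astype(p.data.dtype, copy=True)
                  for a, p in zip(arrays[n:2 * n], self.params)]
        self.t = int(arrays[2 * n][0])
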