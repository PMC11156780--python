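"""Minimal NumPy neural-network layers with hand-written backpropagation.

Only what the 3D u-net needs: 3D convolution (odd kernel, stride 1, 'same'
padding), 1x1x1 convolution, instance normalization, leaky ReLU, channel
dropout, 2x2x2 average pooling, 2x2x2 stride-2 transpose convolution, sigmoid,
and an Adam optimizer.  Tensors are single volumes shaped (C, X, Y, Z); there
is no batch axis — gradient accumulation over a mini-batch is handled by the
training loop.

Every layer implements ``forward(x, train)`` and ``backward(gy)``; ``backward``
accumulates parameter gradients into ``grads`` and returns the gradient with
respect to the layer input.  Gradients of all layers were validated against
central finite differences (see the test suite).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Layer", "Conv3d", "InstanceNorm3d", "LeakyReLU", "ChannelDropout",
    "AvgPool3d", "ConvTranspose3d", "Sigmoid", "Adam",
]

_EINSUM_KW = dict(optimize=True)

# computation dtype; float64 available for gradient checking
DTYPE = np.float32


class Layer:
    """Base class: parameter/gradient dictionaries keyed by name."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def zero_grad(self) -> None:
        for k in self.grads:
            self.grads[k][...] = 0.0

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, gy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv3d(Layer):
    """3D convolution, odd kernel, stride 1, zero 'same' padding.

    He-normal initialization scaled for the leaky-ReLU nonlinearity.
    """

    def __init__(self, cin: int, cout: int, ksize: int, rng: np.random.Generator,
                 bias: bool = True) -> None:
        super().__init__()
        if ksize % 2 != 1:
            raise ValueError("kernel size must be odd")
        self.cin, self.cout, self.k = cin, cout, ksize
        fan_in = cin * ksize ** 3
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(cout, cin, ksize, ksize, ksize))
        self.params["W"] = w.astype(DTYPE)
        self.grads["W"] = np.zeros_like(self.params["W"])
        if bias:
            self.params["b"] = np.zeros(cout, dtype=DTYPE)
            self.grads["b"] = np.zeros_like(self.params["b"])
        self._win: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if x.shape[0] != self.cin:
            raise ValueError(f"expected {self.cin} input channels, got {x.shape[0]}")
        k, p = self.k, self.k // 2
        if k == 1:
            self._win = x
            y = np.einsum("ixyz,oi->oxyz", x, self.params["W"][:, :, 0, 0, 0], **_EINSUM_KW)
        else:
            xp = np.pad(x, ((0, 0), (p, p), (p, p), (p, p)))
            win = sliding_window_view(xp, (k, k, k), axis=(1, 2, 3))
            self._win = win
            y = np.einsum("ixyzpqr,oipqr->oxyz", win, self.params["W"], **_EINSUM_KW)
        if "b" in self.params:
            y = y + self.params["b"][:, None, None, None]
        return np.ascontiguousarray(y, dtype=DTYPE)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        k, p = self.k, self.k // 2
        if "b" in self.grads:
            self.grads["b"] += gy.sum(axis=(1, 2, 3))
        if k == 1:
            self.grads["W"] += np.einsum("ixyz,oxyz->oi", self._win, gy,
                                         **_EINSUM_KW)[..., None, None, None]
            gx = np.einsum("oxyz,oi->ixyz", gy, self.params["W"][:, :, 0, 0, 0], **_EINSUM_KW)
        else:
            self.grads["W"] += np.einsum("ixyzpqr,oxyz->oipqr", self._win, gy, **_EINSUM_KW)
            gyp = np.pad(gy, ((0, 0), (p, p), (p, p), (p, p)))
            gwin = sliding_window_view(gyp, (k, k, k), axis=(1, 2, 3))
            w_flip = self.params["W"][:, :, ::-1, ::-1, ::-1]
            gx = np.einsum("oxyzpqr,oipqr->ixyz", gwin, w_flip, **_EINSUM_KW)
        self._win = None
        return np.ascontiguousarray(gx, dtype=DTYPE)


class InstanceNorm3d(Layer):
    """Per-channel normalization over the spatial axes with affine scale/shift."""

    def __init__(self, channels: int, eps: float = 1e-5) -> None:
        super().__init__()
        self.eps = eps
        self.params["gamma"] = np.ones(channels, dtype=DTYPE)
        self.params["beta"] = np.zeros(channels, dtype=DTYPE)
        self.grads["gamma"] = np.zeros(channels, dtype=DTYPE)
        self.grads["beta"] = np.zeros(channels, dtype=DTYPE)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        ax = (1, 2, 3)
        mu = x.mean(axis=ax, keepdims=True)
        var = x.var(axis=ax, keepdims=True)
        self._ivar = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mu) * self._ivar
        g = self.params["gamma"][:, None, None, None]
        b = self.params["beta"][:, None, None, None]
        return (g * self._xhat + b).astype(DTYPE)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        ax = (1, 2, 3)
        n = gy[0].size
        xhat, ivar = self._xhat, self._ivar
        self.grads["gamma"] += (gy * xhat).sum(axis=ax)
        self.grads["beta"] += gy.sum(axis=ax)
        g = self.params["gamma"][:, None, None, None]
        gxhat = gy * g
        gx = (gxhat - gxhat.mean(axis=ax, keepdims=True)
              - xhat * (gxhat * xhat).mean(axis=ax, keepdims=True)) * ivar
        self._xhat = self._ivar = None
        return gx.astype(DTYPE)


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.2) -> None:
        super().__init__()
        self.slope = slope

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._pos = x > 0
        return np.where(self._pos, x, self.slope * x).astype(DTYPE)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        gx = np.where(self._pos, gy, self.slope * gy).astype(DTYPE)
        self._pos = None
        return gx


class ChannelDropout(Layer):
    """Channel-wise (volumetric) dropout; identity at evaluation time."""

    def __init__(self, p: float, rng: np.random.Generator) -> None:
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p
        self.rng = rng
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if not train or self.p == 0.0:
            self._mask = None
            return x
        keep = (self.rng.random(x.shape[0]) >= self.p).astype(DTYPE) / (1.0 - self.p)
        self._mask = keep[:, None, None, None]
        return (x * self._mask).astype(DTYPE)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return gy
        gx = (gy * self._mask).astype(DTYPE)
        self._mask = None
        return gx


class AvgPool3d(Layer):
    """2x2x2 average pooling, stride 2."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        c, X, Y, Z = x.shape
        if X % 2 or Y % 2 or Z % 2:
            raise ValueError(f"spatial dimensions must be even for pooling, got {x.shape}")
        self._shape = x.shape
        return x.reshape(c, X // 2, 2, Y // 2, 2, Z // 2, 2).mean(axis=(2, 4, 6))

    def backward(self, gy: np.ndarray) -> np.ndarray:
        c, X, Y, Z = self._shape
        gx = np.broadcast_to(gy[:, :, None, :, None, :, None] / 8.0,
                             (c, X // 2, 2, Y // 2, 2, Z // 2, 2))
        return np.ascontiguousarray(gx).reshape(self._shape).astype(DTYPE)


class ConvTranspose3d(Layer):
    """Kernel-2, stride-2 transpose convolution (doubles every spatial axis)."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator,
                 bias: bool = False) -> None:
        super().__init__()
        self.cin, self.cout = cin, cout
        fan_in = cin * 8
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(cin, cout, 2, 2, 2))
        self.params["W"] = w.astype(DTYPE)
        self.grads["W"] = np.zeros_like(self.params["W"])
        if bias:
            self.params["b"] = np.zeros(cout, dtype=DTYPE)
            self.grads["b"] = np.zeros_like(self.params["b"])

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x
        c, X, Y, Z = x.shape
        t = np.einsum("ixyz,ioabc->oxaybzc", x, self.params["W"], **_EINSUM_KW)
        y = t.reshape(self.cout, 2 * X, 2 * Y, 2 * Z)
        if "b" in self.params:
            y = y + self.params["b"][:, None, None, None]
        return np.ascontiguousarray(y, dtype=DTYPE)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        c, X2, Y2, Z2 = gy.shape
        g = gy.reshape(self.cout, X2 // 2, 2, Y2 // 2, 2, Z2 // 2, 2)
        if "b" in self.grads:
            self.grads["b"] += gy.sum(axis=(1, 2, 3))
        self.grads["W"] += np.einsum("ixyz,oxaybzc->ioabc", self._x, g, **_EINSUM_KW)
        gx = np.einsum("oxaybzc,ioabc->ixyz", g, self.params["W"], **_EINSUM_KW)
        self._x = None
        return np.ascontiguousarray(gx, dtype=DTYPE)


class Sigmoid(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        # numerically stable logistic
        self._y = np.where(x >= 0, 1.0 / (1.0 + np.exp(-x)),
                           np.exp(x) / (1.0 + np.exp(x))).astype(DTYPE)
        return self._y

    def backward(self, gy: np.ndarray) -> np.ndarray:
        gx = (gy * self._y * (1.0 - self._y)).astype(DTYPE)
        self._y = None
        return gx


class Adam:
    """Adam with per-parameter first/second moment state (library-default
    beta1=0.9, beta2=0.999, eps=1e-8)."""

    def __init__(self, layers: list[Layer], lr: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.layers = [l for l in layers if l.params]
        self.lr = lr
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.t = 0
        self._m = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers]
        self._v = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers]

    def zero_grad(self) -> None:
        for layer in self.layers:
            layer.zero_grad()

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for layer, m, v in zip(self.layers, self._m, self._v):
            for k, p in layer.params.items():
                g = layer.grads[k]
                m[k] = self.b1 * m[k] + (1.0 - self.b1) * g
                v[k] = self.b2 * v[k] + (1.0 - self.b2) * g * g
                p -= self.lr * (m[k] / bc1) / (np.sqrt(v[k] / bc2) + self.eps)
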