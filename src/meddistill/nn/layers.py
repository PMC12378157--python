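"""Minimal NumPy layer library with hand-written forward/backward passes.

Conventions: images are ``(batch, channels, height, width)`` float32; every
layer caches what its backward pass needs during ``forward(train=True)`` and
releases it on the next call. Convolution is im2col + BLAS matmul, which is
the fastest portable route for the small spatial sizes this package targets.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import as_strided
from scipy.special import erf


class Param:
    """A trainable tensor with an accumulated gradient."""

    __slots__ = ("value", "grad", "trainable")

    def __init__(self, value: np.ndarray, trainable: bool = True):
        self.value = np.asarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)
        self.trainable = trainable

    @property
    def size(self) -> int:
        return int(self.value.size)


class Layer:
    """Base class. Subclasses define forward/backward and expose params."""

    def params(self) -> dict[str, Param]:
        return {k: v for k, v in vars(self).items() if isinstance(v, Param)}

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def __call__(self, x, train=True):
        return self.forward(x, train=train)


def he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class Linear(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.W = Param(he_init(rng, (d_in, d_out), d_in))
        self.b = Param(np.zeros(d_out, dtype=np.float32))
        self._x = None

    def forward(self, x, train=True):
        if train:
            self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dy):
        self.W.grad += self._x.T @ dy
        self.b.grad += dy.sum(axis=0)
        return dy @ self.W.value.T


class ReLU(Layer):
    def __init__(self):
        self._mask = None

    def forward(self, x, train=True):
        if train:
            self._mask = x > 0
        return np.maximum(x, 0)

    def backward(self, dy):
        return dy * self._mask


class GELU(Layer):
    """Exact Gaussian-error-linear unit (forward only; transformer use)."""

    def forward(self, x, train=True):
        return 0.5 * x * (1.0 + erf(x / np.sqrt(2.0))).astype(x.dtype)

    def backward(self, dy):  # pragma: no cover - teacher never backprops
        raise NotImplementedError("GELU backward not needed: ViT teachers are frozen")


def _windows(x: np.ndarray, k: int, stride: int) -> np.ndarray:
    """Sliding k×k windows of a padded NCHW tensor, shape (b,c,oh,ow,k,k)."""
    b, c, h, w = x.shape
    oh = (h - k) // stride + 1
    ow = (w - k) // stride + 1
    sb, sc, sh, sw = x.strides
    return as_strided(
        x,
        shape=(b, c, oh, ow, k, k),
        strides=(sb, sc, sh * stride, sw * stride, sh, sw),
        writeable=False,
    )


class Conv2d(Layer):
    """im2col convolution; NCHW interface, channels-last internally.

    The channels-last window copy has unit-stride inner runs, which makes
    im2col (the dominant non-GEMM cost at these sizes) several times
    faster than gathering from NCHW.
    """

    def __init__(self, c_in, c_out, k, stride=1, pad=0, bias=True,
                 rng: np.random.Generator | None = None, grad_input=True):
        rng = rng or np.random.default_rng(0)
        self.k, self.stride, self.pad = k, stride, pad
        self.grad_input = grad_input  # False for a network's first layer
        self.W = Param(he_init(rng, (c_out, c_in, k, k), c_in * k * k))
        self.b = Param(np.zeros(c_out, dtype=np.float32)) if bias else None
        self._cols = None
        self._xshape = None

    def params(self):
        p = {"W": self.W}
        if self.b is not None:
            p["b"] = self.b
        return p

    def _w_matrix(self):
        # (k*k*c_in, c_out), matching the (…, k, k, c) column order
        return np.ascontiguousarray(
            self.W.value.transpose(2, 3, 1, 0).reshape(-1, self.W.value.shape[0]))

    def _cols_of(self, x):
        """Channels-last columns (b, oh, ow, k*k*c) of the padded input."""
        xt = np.ascontiguousarray(x.transpose(0, 2, 3, 1), dtype=np.float32)
        if self.pad:
            xt = np.pad(xt, ((0, 0), (self.pad, self.pad),
                             (self.pad, self.pad), (0, 0)))
        b, hp, wp, c = xt.shape
        k, s = self.k, self.stride
        oh = (hp - k) // s + 1
        ow = (wp - k) // s + 1
        sb, sh, sw, sc = xt.strides
        win = as_strided(xt, (b, oh, ow, k, k, c),
                         (sb, sh * s, sw * s, sh, sw, sc), writeable=False)
        return win.reshape(b, oh, ow, k * k * c), (b, hp, wp, c)

    def forward(self, x, train=True):
        cols, padded_shape = self._cols_of(x)
        y = cols @ self._w_matrix()
        if self.b is not None:
            y += self.b.value
        if train:
            self._cols, self._xshape, self._padded = cols, x.shape, padded_shape
        return y.transpose(0, 3, 1, 2)

    def backward(self, dy):
        b, c_out, oh, ow = dy.shape
        k, s = self.k, self.stride
        c_in = self.W.value.shape[1]
        dyt = np.ascontiguousarray(dy.transpose(0, 2, 3, 1))  # b,oh,ow,cout
        dWm = self._cols.reshape(-1, k * k * c_in).T @ dyt.reshape(-1, c_out)
        self.W.grad += dWm.reshape(k, k, c_in, c_out).transpose(3, 2, 0, 1)
        if self.b is not None:
            self.b.grad += dyt.sum(axis=(0, 1, 2))
        if not self.grad_input:
            return None
        dcols = (dyt @ self._w_matrix().T).reshape(b, oh, ow, k, k, c_in)
        dxp = np.zeros(self._padded, dtype=np.float32)  # channels-last
        for i in range(k):
            for j in range(k):
                dxp[:, i:i + s * oh:s, j:j + s * ow:s, :] += dcols[:, :, :, i, j, :]
        if self.pad:
            dxp = dxp[:, self.pad:-self.pad, self.pad:-self.pad, :]
        return np.ascontiguousarray(dxp.transpose(0, 3, 1, 2))


class MaxPool2d(Layer):
    def __init__(self, k, stride=None, pad=0):
        self.k, self.stride, self.pad = k, stride or k, pad
        self._argmax = None
        self._padded = None

    def _flat_windows(self, x):
        """(b, c, oh, ow, k*k) window view/copy of the padded input."""
        if self.k == self.stride and not self.pad and x.shape[2] % self.k == 0 \
                and x.shape[3] % self.k == 0:
            b, c, h, w = x.shape
            k = self.k
            y = x.reshape(b, c, h // k, k, w // k, k).transpose(0, 1, 2, 4, 3, 5)
            return y.reshape(b, c, h // k, w // k, k * k), x.shape
        if self.pad:
            x = np.pad(x, ((0, 0), (0, 0), (self.pad, self.pad),
                           (self.pad, self.pad)), constant_values=-np.inf)
        win = _windows(np.ascontiguousarray(x), self.k, self.stride)
        b, c, oh, ow, k, _ = win.shape
        return win.reshape(b, c, oh, ow, k * k), x.shape

    def forward(self, x, train=True):
        flat, padded_shape = self._flat_windows(x)
        if not train:
            return flat.max(axis=-1)
        amax = flat.argmax(axis=-1)  # first max wins ties
        self._argmax = amax
        self._padded = padded_shape
        return np.take_along_axis(flat, amax[..., None], axis=-1)[..., 0]

    def backward(self, dy):
        b, c, oh, ow = dy.shape
        k, s = self.k, self.stride
        flat = np.zeros((b, c, oh, ow, k * k), dtype=np.float32)
        np.put_along_axis(flat, self._argmax[..., None], dy[..., None], axis=-1)
        if k == s and not self.pad and self._padded == (b, c, oh * k, ow * k):
            win = flat.reshape(b, c, oh, ow, k, k).transpose(0, 1, 2, 4, 3, 5)
            return np.ascontiguousarray(win).reshape(b, c, oh * k, ow * k)
        dxp = np.zeros(self._padded, dtype=np.float32)
        win = flat.reshape(b, c, oh, ow, k, k)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i:i + s * oh:s, j:j + s * ow:s] += win[:, :, :, :, i, j]
        if self.pad:
            dxp = dxp[:, :, self.pad:-self.pad, self.pad:-self.pad]
        return dxp


class GlobalAvgPool(Layer):
    """Spatial mean, (b,c,h,w) → (b,c)."""

    def __init__(self):
        self._hw = None

    def forward(self, x, train=True):
        if train:
            self._hw = x.shape[2:]
        return x.mean(axis=(2, 3))

    def backward(self, dy):
        h, w = self._hw
        return np.broadcast_to(dy[:, :, None, None] / (h * w),
                               dy.shape + (h, w)).astype(np.float32)


class BatchNorm2d(Layer):
    """Per-channel batch normalization with running statistics."""

    def __init__(self, c, momentum=0.1, eps=1e-5):
        self.gamma = Param(np.ones(c, dtype=np.float32))
        self.beta = Param(np.zeros(c, dtype=np.float32))
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.momentum, self.eps = momentum, eps
        self._cache = None

    def forward(self, x, train=True):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        if train:
            self._cache = (xhat, inv, x.shape)
        return self.gamma.value[None, :, None, None] * xhat + self.beta.value[None, :, None, None]

    def backward(self, dy):
        xhat, inv, shape = self._cache
        n = shape[0] * shape[2] * shape[3]
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dy.sum(axis=(0, 2, 3))
        g = self.gamma.value[None, :, None, None]
        dxhat = dy * g
        term1 = dxhat
        term2 = dxhat.mean(axis=(0, 2, 3), keepdims=True)
        term3 = xhat * (dxhat * xhat).mean(axis=(0, 2, 3), keepdims=True)
        return inv[None, :, None, None] * (term1 - term2 - term3)


class LayerNorm(Layer):
    """Last-axis layer normalization (forward only; transformer use)."""

    def __init__(self, d, eps=1e-6):
        self.gamma = Param(np.ones(d, dtype=np.float32))
        self.beta = Param(np.zeros(d, dtype=np.float32))
        self.eps = eps

    def forward(self, x, train=True):
        mean = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        return self.gamma.value * (x - mean) / np.sqrt(var + self.eps) + self.beta.value

    def backward(self, dy):  # pragma: no cover - teacher never backprops
        raise NotImplementedError("LayerNorm backward not needed: ViT teachers are frozen")


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self):
        out = {}
        for i, layer in enumerate(self.layers):
            for name, p in layer.params().items():
                out[f"{i}.{name}"] = p
        return out

    def forward(self, x, train=True):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


def named_params(module, prefix="") -> dict[str, Param]:
    """Walk a Layer (or object with ``.params()``) and name every Param."""
    out = {}
    if isinstance(module, Sequential):
        for i, sub in enumerate(module.layers):
            out.update(named_params(sub, f"{prefix}{i}."))
        return out
    if isinstance(module, Layer):
        direct = {k: v for k, v in vars(module).items() if isinstance(v, Param)}
        for k, v in direct.items():
            out[f"{prefix}{k}"] = v
        for k, v in vars(module).items():
            if isinstance(v, Layer):
                out.update(named_params(v, f"{prefix}{k}."))
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Layer):
                        out.update(named_params(item, f"{prefix}{k}.{i}."))
    return out
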