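"""Minimal NumPy layer library with explicit backpropagation.

Supports exactly what the painting networks need: im2col convolutions,
batch normalization, rectifiers, average/max pooling, global average
pooling, fully connected layers, residual blocks and a Sequential
container.  Tensors are NCHW float32.  Residual blocks follow the
pre-activation arrangement (y = x + F(x), no post-sum nonlinearity), so a
block whose residual branch is zeroed is the identity map exactly.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Layer",
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "AvgPool2d",
    "MaxPool2d",
    "GlobalAvgPool",
    "Flatten",
    "Linear",
    "ResidualBlock",
    "Sequential",
]


class Param:
    """A trainable tensor and its accumulated gradient."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = np.ascontiguousarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)
        self.name = name


class Layer:
    def params(self) -> list[Param]:
        return []

    def modules(self):
        """Depth-first iterator over this layer and any sublayers."""
        yield self

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


def _im2col(xp: np.ndarray, kh: int, kw: int, stride: int):
    """(N,C,Hp,Wp) -> (N*oh*ow, C*kh*kw) patch matrix."""
    n, c, hp, wp = xp.shape
    oh = (hp - kh) // stride + 1
    ow = (wp - kw) // stride + 1
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]                      # (N,C,oh,ow,kh,kw)
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * oh * ow, c * kh * kw)
    return np.ascontiguousarray(cols), oh, ow


def _col2im(dcols: np.ndarray, x_shape, kh: int, kw: int, stride: int, pad: int):
    """Scatter-add patch gradients back to the (padded) input."""
    n, c, h, w = x_shape
    hp, wp = h + 2 * pad, w + 2 * pad
    oh = (hp - kh) // stride + 1
    ow = (wp - kw) // stride + 1
    d = dcols.reshape(n, oh, ow, c, kh, kw).transpose(0, 3, 4, 5, 1, 2)
    dxp = np.zeros((n, c, hp, wp), dtype=dcols.dtype)
    for i in range(kh):
        for j in range(kw):
            dxp[:, :, i:i + stride * oh:stride, j:j + stride * ow:stride] += d[:, :, i, j]
    if pad:
        return dxp[:, :, pad:-pad, pad:-pad]
    return dxp


class Conv2d(Layer):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int = 1,
                 padding: int = 0, rng: np.random.Generator | None = None):
        self.in_ch, self.out_ch = in_ch, out_ch
        self.k, self.stride, self.pad = kernel, stride, padding
        rng = rng or np.random.default_rng(0)
        fan_in = in_ch * kernel * kernel
        self.W = Param(_he_init(rng, (out_ch, fan_in), fan_in), "conv.W")
        self.b = Param(np.zeros(out_ch), "conv.b")
        self._cache = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train=False):
        x = x.astype(np.float32, copy=False)
        xp = np.pad(x, ((0, 0), (0, 0), (self.pad,) * 2, (self.pad,) * 2)) if self.pad else x
        cols, oh, ow = _im2col(xp, self.k, self.k, self.stride)
        out = cols @ self.W.value.T + self.b.value
        n = x.shape[0]
        self._cache = (cols, x.shape, oh, ow) if train else None
        return out.reshape(n, oh, ow, self.out_ch).transpose(0, 3, 1, 2)

    def backward(self, grad):
        cols, x_shape, oh, ow = self._cache
        n = x_shape[0]
        g = grad.transpose(0, 2, 3, 1).reshape(n * oh * ow, self.out_ch)
        self.W.grad += g.T @ cols
        self.b.grad += g.sum(axis=0)
        dcols = g @ self.W.value
        return _col2im(dcols, x_shape, self.k, self.k, self.stride, self.pad)


class BatchNorm2d(Layer):
    """Channel-wise batch normalization (NCHW); running stats for eval."""

    def __init__(self, ch: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(ch), "bn.gamma")
        self.beta = Param(np.zeros(ch), "bn.beta")
        self.running_mean = np.zeros(ch, dtype=np.float32)
        self.running_var = np.ones(ch, dtype=np.float32)
        self.momentum, self.eps = momentum, eps
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train=False):
        x = x.astype(np.float32, copy=False)
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * invstd[None, :, None, None]
        if train:
            self._cache = (xhat, invstd)
        return self.gamma.value[None, :, None, None] * xhat + self.beta.value[None, :, None, None]

    def backward(self, grad):
        xhat, invstd = self._cache
        m = grad.shape[0] * grad.shape[2] * grad.shape[3]
        self.gamma.grad += (grad * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += grad.sum(axis=(0, 2, 3))
        g = grad * self.gamma.value[None, :, None, None]
        gsum = g.sum(axis=(0, 2, 3), keepdims=True)
        gx = (g * xhat).sum(axis=(0, 2, 3), keepdims=True)
        dx = (g - gsum / m - xhat * gx / m) * invstd[None, :, None, None]
        return dx.astype(np.float32, copy=False)


class ReLU(Layer):
    def forward(self, x, train=False):
        out = np.maximum(x, 0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, grad):
        return grad * self._mask


class AvgPool2d(Layer):
    """Average pooling; zero padding counts toward the mean (count-include-pad)."""

    def __init__(self, kernel: int, stride: int, padding: int = 0):
        self.k, self.stride, self.pad = kernel, stride, padding

    def forward(self, x, train=False):
        x = x.astype(np.float32, copy=False)
        xp = np.pad(x, ((0, 0), (0, 0), (self.pad,) * 2, (self.pad,) * 2)) if self.pad else x
        win = np.lib.stride_tricks.sliding_window_view(xp, (self.k, self.k), axis=(2, 3))
        win = win[:, :, ::self.stride, ::self.stride]
        if train:
            self._x_shape = x.shape
        return win.mean(axis=(4, 5))

    def backward(self, grad):
        n, c, oh, ow = grad.shape
        share = (grad / (self.k * self.k)).reshape(n, c, 1, 1, oh, ow)
        dcols = np.broadcast_to(share, (n, c, self.k, self.k, oh, ow))
        dcols = dcols.transpose(0, 4, 5, 1, 2, 3).reshape(n * oh * ow, -1)
        return _col2im(dcols, self._x_shape, self.k, self.k, self.stride, self.pad)


class MaxPool2d(Layer):
    def __init__(self, kernel: int, stride: int, padding: int = 0):
        self.k, self.stride, self.pad = kernel, stride, padding

    def forward(self, x, train=False):
        x = x.astype(np.float32, copy=False)
        if self.pad:
            xp = np.pad(x, ((0, 0), (0, 0), (self.pad,) * 2, (self.pad,) * 2),
                        constant_values=-np.inf)
        else:
            xp = x
        win = np.lib.stride_tricks.sliding_window_view(xp, (self.k, self.k), axis=(2, 3))
        win = win[:, :, ::self.stride, ::self.stride]
        n, c, oh, ow = win.shape[:4]
        flat = win.reshape(n, c, oh, ow, -1)
        arg = flat.argmax(axis=-1)
        out = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]
        if train:
            self._cache = (arg, x.shape)
        return out

    def backward(self, grad):
        arg, x_shape = self._cache
        n, c, oh, ow = grad.shape
        kk = self.k * self.k
        dcols = np.zeros((n, c, oh, ow, kk), dtype=grad.dtype)
        np.put_along_axis(dcols, arg[..., None], grad[..., None], axis=-1)
        dcols = dcols.reshape(n, c, oh, ow, self.k, self.k)
        dcols = dcols.transpose(0, 2, 3, 1, 4, 5).reshape(n * oh * ow, -1)
        return _col2im(dcols, x_shape, self.k, self.k, self.stride, self.pad)


class GlobalAvgPool(Layer):
    """(N,C,H,W) -> (N,C) spatial mean."""

    def forward(self, x, train=False):
        if train:
            self._x_shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, grad):
        n, c, h, w = self._x_shape
        return np.broadcast_to(grad[:, :, None, None] / (h * w), self._x_shape).astype(grad.dtype)


class Flatten(Layer):
    def forward(self, x, train=False):
        if train:
            self._x_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._x_shape)


class Linear(Layer):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.W = Param(_he_init(rng, (out_features, in_features), in_features), "fc.W")
        self.b = Param(np.zeros(out_features), "fc.b")

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train=False):
        x = x.astype(np.float32, copy=False)
        if train:
            self._x = x
        return x @ self.W.value.T + self.b.value

    def backward(self, grad):
        self.W.grad += grad.T @ self._x
        self.b.grad += grad.sum(axis=0)
        return grad @ self.W.value


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def modules(self):
        yield self
        for layer in self.layers:
            yield from layer.modules()

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad


class ResidualBlock(Layer):
    """Pre-activation basic block: y = shortcut(x) + F(x).

    F = BN - ReLU - conv3x3(stride) - BN - ReLU - conv3x3.  The shortcut is
    the identity when shape is preserved, else a strided 1x1 projection.
    With the residual branch zeroed, an identity-shortcut block returns its
    input unchanged.
    """

    def __init__(self, in_ch: int, out_ch: int, stride: int = 1,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.branch = Sequential(
            BatchNorm2d(in_ch), ReLU(),
            Conv2d(in_ch, out_ch, 3, stride=stride, padding=1, rng=rng),
            BatchNorm2d(out_ch), ReLU(),
            Conv2d(out_ch, out_ch, 3, stride=1, padding=1, rng=rng),
        )
        if stride != 1 or in_ch != out_ch:
            self.shortcut = Conv2d(in_ch, out_ch, 1, stride=stride, padding=0, rng=rng)
        else:
            self.shortcut = None

    def params(self):
        ps = self.branch.params()
        if self.shortcut is not None:
            ps += self.shortcut.params()
        return ps

    def modules(self):
        yield self
        yield from self.branch.modules()
        if self.shortcut is not None:
            yield from self.shortcut.modules()

    def zero_residual_branch(self) -> None:
        """Null the residual function F; used to verify the skip identity."""
        for p in self.branch.params():
            p.value[...] = 0.0

    def forward(self, x, train=False):
        fx = self.branch.forward(x, train=train)
        sx = x if self.shortcut is None else self.shortcut.forward(x, train=train)
        return sx + fx

    def backward(self, grad):
        g_branch = self.branch.backward(grad)
        g_short = grad if self.shortcut is None else self.shortcut.backward(grad)
        return g_branch + g_short
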