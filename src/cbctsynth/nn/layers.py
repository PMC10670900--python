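"""Minimal NumPy layers with explicit forward/backward passes.

All tensors are NCHW float32.  Convolutions are evaluated as im2col matrix
products; the input gradient of a 3x3/stride-1/pad-1 convolution is itself
such a convolution with the spatially flipped, channel-transposed kernel, so
forward and backward share one code path.  Every layer caches what its
backward pass needs and exposes ``params()`` as (name, value, grad) triples.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Layer",
    "Conv3x3",
    "Conv1x1",
    "ConvTranspose2x2",
    "BatchNorm2d",
    "ReLU",
    "MaxPool2x2",
]


class Param:
    """A trainable array plus its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.ascontiguousarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Layer:
    def params(self):
        """Yield (name, Param) pairs; default none."""
        return ()

    def state(self):
        """Non-trainable state arrays (e.g. batch-norm running stats)."""
        return ()

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _im2col3(x: np.ndarray) -> np.ndarray:
    """(N,C,H,W) -> (N*H*W, C*9) patches for a 3x3/s1/p1 convolution."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    v = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(2, 3))
    # (N,C,H,W,3,3) -> (N,H,W,C,3,3) -> (N*H*W, C*9)
    return np.ascontiguousarray(v.transpose(0, 2, 3, 1, 4, 5)).reshape(n * h * w, c * 9)


def _conv3_matmul(x: np.ndarray, w_mat: np.ndarray, bias: np.ndarray | None):
    n, c, h, wd = x.shape
    col = _im2col3(x)
    out = col @ w_mat.T
    if bias is not None:
        out += bias
    cout = w_mat.shape[0]
    return out.reshape(n, h, wd, cout).transpose(0, 3, 1, 2), col


class Conv3x3(Layer):
    """3x3 convolution, stride 1, zero padding 1 (shape preserving)."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator, bias: bool = True,
                 w_scale: float = 1.0):
        bound = w_scale / np.sqrt(cin * 9)
        self.w = Param(rng.uniform(-bound, bound, size=(cout, cin, 3, 3)))
        self.b = Param(np.zeros(cout)) if bias else None
        self.cin, self.cout = cin, cout
        self._cache = None

    def params(self):
        yield "w", self.w
        if self.b is not None:
            yield "b", self.b

    def forward(self, x, training):
        w_mat = self.w.value.reshape(self.cout, self.cin * 9)
        out, col = _conv3_matmul(x, w_mat, self.b.value if self.b else None)
        self._cache = (col, x.shape)
        return out

    def backward(self, dy):
        col, xshape = self._cache
        n, c, h, w = xshape
        dy_mat = dy.transpose(0, 2, 3, 1).reshape(n * h * w, self.cout)
        self.w.grad += (dy_mat.T @ col).reshape(self.w.value.shape)
        if self.b is not None:
            self.b.grad += dy_mat.sum(axis=0)
        # dx = conv3x3(dy, W transposed over channels and rotated 180deg)
        w_flip = self.w.value.transpose(1, 0, 2, 3)[:, :, ::-1, ::-1]
        w_mat = np.ascontiguousarray(w_flip).reshape(self.cin, self.cout * 9)
        dx, _ = _conv3_matmul(dy, w_mat, None)
        self._cache = None
        return dx


class Conv1x1(Layer):
    """Pointwise convolution (channel mixing)."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator, bias: bool = True,
                 w_scale: float = 1.0):
        bound = w_scale / np.sqrt(cin)
        self.w = Param(rng.uniform(-bound, bound, size=(cout, cin)))
        self.b = Param(np.zeros(cout)) if bias else None
        self._x = None

    def params(self):
        yield "w", self.w
        if self.b is not None:
            yield "b", self.b

    def forward(self, x, training):
        self._x = x
        out = np.tensordot(self.w.value, x, axes=([1], [1])).transpose(1, 0, 2, 3)
        if self.b is not None:
            out += self.b.value[None, :, None, None]
        return np.ascontiguousarray(out)

    def backward(self, dy):
        x = self._x
        self.w.grad += np.tensordot(dy, x, axes=([0, 2, 3], [0, 2, 3]))
        if self.b is not None:
            self.b.grad += dy.sum(axis=(0, 2, 3))
        dx = np.tensordot(self.w.value.T, dy, axes=([1], [1])).transpose(1, 0, 2, 3)
        self._x = None
        return np.ascontiguousarray(dx)


class ConvTranspose2x2(Layer):
    """Transposed convolution, kernel 2x2, stride 2 (doubles H and W).

    Output windows do not overlap, so each of the four kernel taps fills one
    interleaved quadrant of the output.
    """

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        bound = 1.0 / np.sqrt(cin * 4)
        self.w = Param(rng.uniform(-bound, bound, size=(cin, cout, 2, 2)))
        self.b = Param(np.zeros(cout))
        self._x = None

    def params(self):
        yield "w", self.w
        yield "b", self.b

    def forward(self, x, training):
        self._x = x
        n, c, h, w = x.shape
        cout = self.w.value.shape[1]
        out = np.empty((n, cout, 2 * h, 2 * w), dtype=np.float32)
        for i in range(2):
            for j in range(2):
                o = np.tensordot(x, self.w.value[:, :, i, j], axes=([1], [0]))
                out[:, :, i::2, j::2] = o.transpose(0, 3, 1, 2)
        out += self.b.value[None, :, None, None]
        return out

    def backward(self, dy):
        x = self._x
        dx = np.zeros_like(x)
        for i in range(2):
            for j in range(2):
                dq = dy[:, :, i::2, j::2]
                self.w.grad[:, :, i, j] += np.tensordot(
                    x, dq, axes=([0, 2, 3], [0, 2, 3])
                )
                dx += np.tensordot(
                    dq, self.w.value[:, :, i, j], axes=([1], [1])
                ).transpose(0, 3, 1, 2)
        self.b.grad += dy.sum(axis=(0, 2, 3))
        self._x = None
        return dx


class BatchNorm2d(Layer):
    """Per-channel batch normalisation with running statistics."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    def params(self):
        yield "gamma", self.gamma
        yield "beta", self.beta

    def state(self):
        yield "running_mean", self.running_mean
        yield "running_var", self.running_var

    def forward(self, x, training):
        if training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv_std[None, :, None, None]
        self._cache = (xhat, inv_std, x.shape, training)
        out = xhat * self.gamma.value[None, :, None, None]
        out += self.beta.value[None, :, None, None]
        return out.astype(np.float32, copy=False)

    def backward(self, dy):
        xhat, inv_std, shape, trained = self._cache
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dy.sum(axis=(0, 2, 3))
        g = self.gamma.value[None, :, None, None] * inv_std[None, :, None, None]
        if trained:
            # batch statistics depend on x -> full coupled gradient
            n_eff = shape[0] * shape[2] * shape[3]
            s1 = dy.sum(axis=(0, 2, 3))[None, :, None, None]
            s2 = (dy * xhat).sum(axis=(0, 2, 3))[None, :, None, None]
            dx = g * (dy - s1 / n_eff - xhat * s2 / n_eff)
        else:
            # running statistics are constants -> plain affine gradient
            dx = g * dy
        self._cache = None
        return dx.astype(np.float32, copy=False)


class ReLU(Layer):
    def __init__(self):
        self._mask = None

    def forward(self, x, training):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(np.float32, copy=False)

    def backward(self, dy):
        dx = np.where(self._mask, dy, 0.0).astype(np.float32, copy=False)
        self._mask = None
        return dx


class MaxPool2x2(Layer):
    """2x2 max pooling, stride 2; requires even spatial sides."""

    def __init__(self):
        self._cache = None

    def forward(self, x, training):
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"max-pool needs even spatial sides, got {h}x{w}")
        v = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        v = np.ascontiguousarray(v).reshape(n, c, h // 2, w // 2, 4)
        idx = v.argmax(axis=-1)
        out = np.take_along_axis(v, idx[..., None], axis=-1)[..., 0]
        self._cache = (idx, x.shape)
        return out

    def backward(self, dy):
        idx, (n, c, h, w) = self._cache
        dv = np.zeros((n, c, h // 2, w // 2, 4), dtype=dy.dtype)
        np.put_along_axis(dv, idx[..., None], dy[..., None], axis=-1)
        dx = dv.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        self._cache = None
        return np.ascontiguousarray(dx).reshape(n, c, h, w)
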