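"""Minimal NumPy neural-network layers with manual backpropagation.

Only what the SoS regression encoder-decoder needs: 2-D convolution with
anisotropic kernels/strides ('same'-style padding), batch normalization,
LeakyReLU, 2x2 max pooling, nearest-neighbour x2 upsampling, fixed bilinear
resizing and channel concatenation.  Layers cache what backward needs; all
arithmetic is float32, layout (B, C, H, W).
"""

from __future__ import annotations

from typing import Dict, List, Optional, Tuple

import numpy as np

F32 = np.float32


class Layer:
    """Base: parameterized layers expose params/grads dicts keyed by name."""

    def __init__(self) -> None:
        self.params: Dict[str, np.ndarray] = {}
        self.grads: Dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def xavier_uniform(rng: np.random.Generator, shape: Tuple[int, ...],
                   fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(F32)


def _same_pad(n: int, k: int, s: int) -> Tuple[int, int]:
    out = -(-n // s)  # ceil
    total = max((out - 1) * s + k - n, 0)
    return total // 2, total - total // 2


class Conv2d(Layer):
    """Strided 2-D convolution as a sum over kernel offsets of strided-slice
    tensor contractions (no column buffer; bandwidth-friendly for the small
    channel counts used here)."""

    def __init__(self, cin: int, cout: int, kernel: Tuple[int, int],
                 stride: Tuple[int, int] = (1, 1),
                 rng: Optional[np.random.Generator] = None,
                 zero_init: bool = False):
        super().__init__()
        kh, kw = kernel
        self.cin, self.cout, self.kh, self.kw = cin, cout, kh, kw
        self.stride = stride
        fan_in, fan_out = cin * kh * kw, cout * kh * kw
        if zero_init:
            W = np.zeros((cout, cin, kh, kw), F32)
        else:
            W = xavier_uniform(rng or np.random.default_rng(), (cout, cin, kh, kw),
                               fan_in, fan_out)
        self.params = {"W": W, "b": np.zeros(cout, F32)}
        self.grads = {"W": np.zeros_like(W), "b": np.zeros_like(self.params["b"])}

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        B, C, H, Wd = x.shape
        sh, sw = self.stride
        ph = _same_pad(H, self.kh, sh)
        pw = _same_pad(Wd, self.kw, sw)
        xp = np.pad(x, ((0, 0), (0, 0), ph, pw)).astype(F32)
        Ho = -(-H // sh)
        Wo = -(-Wd // sw)
        W = self.params["W"]
        acc = np.zeros((self.cout, B, Ho, Wo), F32)
        for i in range(self.kh):
            for j in range(self.kw):
                xs = xp[:, :, i:i + (Ho - 1) * sh + 1:sh, j:j + (Wo - 1) * sw + 1:sw]
                # (cout, cin) x (B, cin, Ho, Wo) -> (cout, B, Ho, Wo)
                acc += np.tensordot(W[:, :, i, j], xs, axes=([1], [1]))
        y = np.ascontiguousarray(acc.transpose(1, 0, 2, 3))
        y += self.params["b"][None, :, None, None]
        if train:
            self._cache = (xp, (ph, pw), (Ho, Wo), x.shape)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xp, (ph, pw), (Ho, Wo), xshape = self._cache
        sh, sw = self.stride
        W = self.params["W"]
        dW = self.grads["W"]
        dW[...] = 0.0
        self.grads["b"][...] = dy.sum(axis=(0, 2, 3))
        dxp = np.zeros_like(xp)
        for i in range(self.kh):
            for j in range(self.kw):
                xs = xp[:, :, i:i + (Ho - 1) * sh + 1:sh, j:j + (Wo - 1) * sw + 1:sw]
                dW[:, :, i, j] = np.tensordot(dy, xs, axes=([0, 2, 3], [0, 2, 3]))
                dxs = np.tensordot(W[:, :, i, j], dy, axes=([0], [1])).transpose(1, 0, 2, 3)
                dxp[:, :, i:i + (Ho - 1) * sh + 1:sh, j:j + (Wo - 1) * sw + 1:sw] += dxs
        B, C, H, Wd = xshape
        return dxp[:, :, ph[0]:ph[0] + H, pw[0]:pw[0] + Wd]


class BatchNorm2d(Layer):
    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5):
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.params = {"gamma": np.ones(c, F32), "beta": np.zeros(c, F32)}
        self.grads = {"gamma": np.zeros(c, F32), "beta": np.zeros(c, F32)}
        self.running_mean = np.zeros(c, F32)
        self.running_var = np.ones(c, F32)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            mu = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (self.momentum * self.running_mean
                                 + (1 - self.momentum) * mu).astype(F32)
            self.running_var = (self.momentum * self.running_var
                                + (1 - self.momentum) * var).astype(F32)
        else:
            mu, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu[None, :, None, None]) * inv[None, :, None, None]
        y = self.params["gamma"][None, :, None, None] * xhat + self.params["beta"][None, :, None, None]
        if train:
            self._cache = (xhat.astype(F32), inv.astype(F32))
        return y.astype(F32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        n = dy.shape[0] * dy.shape[2] * dy.shape[3]
        self.grads["gamma"][...] = (dy * xhat).sum(axis=(0, 2, 3))
        self.grads["beta"][...] = dy.sum(axis=(0, 2, 3))
        g = self.params["gamma"][None, :, None, None]
        dxhat = dy * g
        term = (dxhat - dxhat.mean(axis=(0, 2, 3), keepdims=True)
                - xhat * (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True) / n)
        return (term * inv[None, :, None, None]).astype(F32)


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.1):
        super().__init__()
        self.slope = slope

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        y = np.where(x >= 0, x, self.slope * x).astype(F32)
        if train:
            self._mask = x >= 0
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, self.slope * dy).astype(F32)


class MaxPool2x2(Layer):
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        B, C, H, W = x.shape
        xr = x.reshape(B, C, H // 2, 2, W // 2, 2)
        flat = xr.transpose(0, 1, 2, 4, 3, 5).reshape(B, C, H // 2, W // 2, 4)
        idx = flat.argmax(axis=-1)
        y = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
        if train:
            self._idx, self._shape = idx, x.shape
        return y.astype(F32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        B, C, H, W = self._shape
        dflat = np.zeros((B, C, H // 2, W // 2, 4), F32)
        np.put_along_axis(dflat, self._idx[..., None], dy[..., None], axis=-1)
        dx = dflat.reshape(B, C, H // 2, W // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return dx.reshape(B, C, H, W)


class Upsample2x(Layer):
    """Nearest-neighbour x2 (the 'strided' expansion of the decoder)."""

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        B, C, H, W = dy.shape
        return dy.reshape(B, C, H // 2, 2, W // 2, 2).sum(axis=(3, 5)).astype(F32)


def _resize_matrix(n_in: int, n_out: int) -> np.ndarray:
    """Bilinear interpolation matrix between pixel-center grids."""
    R = np.zeros((n_out, n_in), F32)
    pos = (np.arange(n_out) + 0.5) * n_in / n_out - 0.5
    i0 = np.clip(np.floor(pos).astype(int), 0, n_in - 1)
    i1 = np.clip(i0 + 1, 0, n_in - 1)
    frac = np.clip(pos - i0, 0.0, 1.0)
    for o in range(n_out):
        R[o, i0[o]] += 1 - frac[o]
        R[o, i1[o]] += frac[o]
    return R


class Resize(Layer):
    """Fixed bilinear resize to (h_out, w_out) via separable matrices."""

    def __init__(self, h_out: int, w_out: int):
        super().__init__()
        self.h_out, self.w_out = h_out, w_out
        self._Rz: Optional[np.ndarray] = None
        self._Rx: Optional[np.ndarray] = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        B, C, H, W = x.shape
        if self._Rz is None or self._Rz.shape[1] != H:
            self._Rz = _resize_matrix(H, self.h_out)
        if self._Rx is None or self._Rx.shape[1] != W:
            self._Rx = _resize_matrix(W, self.w_out)
        y = np.tensordot(x, self._Rx, axes=([3], [1]))  # (B,C,H,w_out)
        y = np.tensordot(y, self._Rz, axes=([2], [1])).transpose(0, 1, 3, 2)
        return np.ascontiguousarray(y, F32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = np.tensordot(dy, self._Rx, axes=([3], [0]))  # (B,C,h_out,W)
        dx = np.tensordot(dx, self._Rz, axes=([2], [0])).transpose(0, 1, 3, 2)
        return np.ascontiguousarray(dx, F32)


class SGD:
    """Plain stochastic gradient descent with optional classical momentum."""

    def __init__(self, param_groups: List[Tuple[Layer, str]], lr: float,
                 momentum: float = 0.0):
        self.groups = param_groups
        self.lr = lr
        self.momentum = momentum
        self._vel = [np.zeros_like(layer.params[name]) for layer, name in param_groups]

    def step(self) -> None:
        for v, (layer, name) in zip(self._vel, self.groups):
            g = layer.grads[name]
            if self.momentum:
                v *= self.momentum
                v += g
                g = v
            layer.params[name] -= (self.lr * g).astype(layer.params[name].dtype)
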