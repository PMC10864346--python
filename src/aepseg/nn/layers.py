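"""Layers with explicit forward/backward passes.

Conventions: activations are (B, C, H, W) arrays; each module caches what its
backward pass needs during forward and is used once per step.  ``training``
toggles batch-norm statistics and dropout.  Convolutions use "same" zero
padding for 3x3 kernels; downsampling is a stride-2 convolution and
upsampling a 2x2/stride-2 transposed convolution (exact doubling, no
overlap).
"""

from __future__ import annotations

from typing import Iterator

import numpy as np


class Parameter:
    __slots__ = ("data", "grad", "name")

    def __init__(self, data: np.ndarray, name: str = ""):
        self.data = data
        self.grad = np.zeros_like(data)
        self.name = name


class Module:
    def parameters(self) -> Iterator[Parameter]:
        for v in vars(self).values():
            if isinstance(v, Parameter):
                yield v
            elif isinstance(v, Module):
                yield from v.parameters()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item.parameters()

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, gout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def state_arrays(self) -> dict[str, np.ndarray]:
        """Flat name -> array map of parameters and buffers, for checkpoints."""
        out: dict[str, np.ndarray] = {}

        def visit(obj: "Module", prefix: str) -> None:
            for k, v in vars(obj).items():
                key = f"{prefix}{k}"
                if isinstance(v, Parameter):
                    out[key] = v.data
                elif isinstance(v, np.ndarray) and k.startswith("running_"):
                    out[key] = v
                elif isinstance(v, Module):
                    visit(v, key + ".")
                elif isinstance(v, (list, tuple)):
                    for i, item in enumerate(v):
                        if isinstance(item, Module):
                            visit(item, f"{key}.{i}.")

        visit(self, "")
        return out

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        own = self.state_arrays()
        missing = set(own) ^ set(state)
        if missing:
            raise KeyError(f"checkpoint keys do not match model: {sorted(missing)}")
        for k, arr in own.items():
            arr[...] = state[k]


def he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, dtype) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(dtype)


def _im2col(xpad: np.ndarray, k: int, stride: int, ho: int, wo: int) -> np.ndarray:
    """(B, Cin, Hp, Wp) -> (B, Cin*k*k, ho*wo) patch matrix."""
    b, cin = xpad.shape[:2]
    cols = np.empty((b, cin, k, k, ho, wo), dtype=xpad.dtype)
    for i in range(k):
        for j in range(k):
            cols[:, :, i, j] = xpad[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride]
    return cols.reshape(b, cin * k * k, ho * wo)


def _col2im(
    dcols: np.ndarray, xpad_shape: tuple[int, ...], k: int, stride: int, ho: int, wo: int
) -> np.ndarray:
    b, cin = xpad_shape[:2]
    dxpad = np.zeros(xpad_shape, dtype=dcols.dtype)
    d6 = dcols.reshape(b, cin, k, k, ho, wo)
    for i in range(k):
        for j in range(k):
            dxpad[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += d6[:, :, i, j]
    return dxpad


class Conv2d(Module):
    """kxk convolution, zero padding (k-1)//2, optional stride 2."""

    def __init__(
        self,
        in_ch: int,
        out_ch: int,
        kernel_size: int = 3,
        stride: int = 1,
        rng: np.random.Generator | None = None,
        dtype=np.float32,
    ):
        rng = rng or np.random.default_rng(0)
        k = kernel_size
        self.k, self.stride, self.pad = k, stride, (k - 1) // 2
        self.in_ch, self.out_ch = in_ch, out_ch
        self.weight = Parameter(he_init(rng, (out_ch, in_ch, k, k), in_ch * k * k, dtype))
        self.bias = Parameter(np.zeros(out_ch, dtype=dtype))
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        b, cin, h, w = x.shape
        if cin != self.in_ch:
            raise ValueError(f"expected {self.in_ch} input channels, got {cin}")
        p, s, k = self.pad, self.stride, self.k
        ho = (h + 2 * p - k) // s + 1
        wo = (w + 2 * p - k) // s + 1
        xpad = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        cols = _im2col(xpad, k, s, ho, wo)
        w2 = self.weight.data.reshape(self.out_ch, -1)
        out = np.matmul(w2, cols) + self.bias.data[:, None]
        self._cache = (cols, xpad.shape, ho, wo)
        return out.reshape(b, self.out_ch, ho, wo)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        cols, xpad_shape, ho, wo = self._cache  # type: ignore[misc]
        b = gout.shape[0]
        g2 = gout.reshape(b, self.out_ch, ho * wo)
        self.weight.grad += (
            np.matmul(g2, cols.transpose(0, 2, 1)).sum(axis=0).reshape(self.weight.data.shape)
        )
        self.bias.grad += gout.sum(axis=(0, 2, 3))
        w2 = self.weight.data.reshape(self.out_ch, -1)
        dcols = np.matmul(w2.T, g2)
        dxpad = _col2im(dcols, xpad_shape, self.k, self.stride, ho, wo)
        p = self.pad
        self._cache = None
        return dxpad[:, :, p:-p, p:-p] if p else dxpad


class ConvTranspose2d(Module):
    """2x2 transposed convolution with stride 2: exact spatial doubling."""

    def __init__(
        self, in_ch: int, out_ch: int, rng: np.random.Generator | None = None, dtype=np.float32
    ):
        rng = rng or np.random.default_rng(0)
        self.in_ch, self.out_ch = in_ch, out_ch
        self.weight = Parameter(he_init(rng, (in_ch, out_ch, 2, 2), in_ch, dtype))
        self.bias = Parameter(np.zeros(out_ch, dtype=dtype))
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        b, cin, h, w = x.shape
        if cin != self.in_ch:
            raise ValueError(f"expected {self.in_ch} input channels, got {cin}")
        self._x = x
        x2 = x.reshape(b, cin, h * w)
        w2 = self.weight.data.reshape(cin, self.out_ch * 4)
        out = np.matmul(w2.T[None], x2)  # (b, out*4, h*w)
        out = out.reshape(b, self.out_ch, 2, 2, h, w).transpose(0, 1, 4, 2, 5, 3)
        out = out.reshape(b, self.out_ch, 2 * h, 2 * w)
        return out + self.bias.data[None, :, None, None]

    def backward(self, gout: np.ndarray) -> np.ndarray:
        x = self._x
        b, cin, h, w = x.shape  # type: ignore[union-attr]
        g6 = gout.reshape(b, self.out_ch, h, 2, w, 2).transpose(0, 1, 3, 5, 2, 4)
        g2 = g6.reshape(b, self.out_ch * 4, h * w)
        x2 = x.reshape(b, cin, h * w)  # type: ignore[union-attr]
        self.weight.grad += (
            np.matmul(x2, g2.transpose(0, 2, 1)).sum(axis=0).reshape(self.weight.data.shape)
        )
        self.bias.grad += gout.sum(axis=(0, 2, 3))
        w2 = self.weight.data.reshape(cin, self.out_ch * 4)
        dx = np.matmul(w2[None], g2).reshape(x.shape)  # type: ignore[union-attr]
        self._x = None
        return dx


class BatchNorm2d(Module):
    def __init__(self, ch: int, momentum: float = 0.1, eps: float = 1e-5, dtype=np.float32):
        self.gamma = Parameter(np.ones(ch, dtype=dtype))
        self.beta = Parameter(np.zeros(ch, dtype=dtype))
        self.running_mean = np.zeros(ch, dtype=dtype)
        self.running_var = np.ones(ch, dtype=dtype)
        self.momentum, self.eps = momentum, eps
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * invstd[None, :, None, None]
        if training:
            self._cache = (xhat, invstd, x.shape)
        return self.gamma.data[None, :, None, None] * xhat + self.beta.data[None, :, None, None]

    def backward(self, gout: np.ndarray) -> np.ndarray:
        xhat, invstd, shape = self._cache  # type: ignore[misc]
        n = shape[0] * shape[2] * shape[3]
        self.gamma.grad += (gout * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += gout.sum(axis=(0, 2, 3))
        g = gout * self.gamma.data[None, :, None, None]
        # standard batchnorm backward: dx = invstd/n * (n*g - sum g - xhat * sum(g*xhat))
        sum_g = g.sum(axis=(0, 2, 3))[None, :, None, None]
        sum_gx = (g * xhat).sum(axis=(0, 2, 3))[None, :, None, None]
        dx = (invstd[None, :, None, None] / n) * (n * g - sum_g - xhat * sum_gx)
        self._cache = None
        return dx


class ReLU(Module):
    def __init__(self):
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        g = np.where(self._mask, gout, 0.0)
        self._mask = None
        return g


class Dropout(Module):
    """Inverted dropout; draws masks from a caller-owned generator."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate, self.rng = rate, rng
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, gout: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return gout
        g = gout * self._mask
        self._mask = None
        return g


class Sequential(Module):
    def __init__(self, *modules: Module):
        self.modules = list(modules)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        for m in self.modules:
            x = m.forward(x, training)
        return x

    def backward(self, gout: np.ndarray) -> np.ndarray:
        for m in reversed(self.modules):
            gout = m.backward(gout)
        return gout
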