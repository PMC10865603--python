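"""1-D convolutional layers with explicit forward/backward passes.

Design notes
------------
* A layer caches during ``forward(..., training=True)`` exactly what its
  ``backward`` needs; eval-mode forwards cache nothing, so full-width
  inference stays memory-light.
* Convolutions use an im2col strided view for short kernels and an
  FFT cross-correlation path for long kernels (the 7168-sample attention
  kernel), chunked over output channels to bound memory.
* Gradients accumulate into ``Parameter.grad``; the optimizer zeroes them.
"""

from __future__ import annotations

import math

import numpy as np
from numpy.lib.stride_tricks import as_strided
from scipy import fft as sfft

_FFT_KERNEL_MIN = 128
_FFT_CHUNK = 32


class Parameter:
    """A trainable array plus its accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value)
        self.grad = np.zeros_like(self.value)

    @property
    def size(self) -> int:
        return self.value.size

    def zero_grad(self) -> None:
        self.grad[...] = 0


class Module:
    """Base class; parameter discovery walks attributes recursively."""

    def named_parameters(self, prefix: str = ""):
        for name in sorted(vars(self)):
            obj = vars(self)[name]
            path = f"{prefix}{name}"
            if isinstance(obj, Parameter):
                yield path, obj
            elif isinstance(obj, Module):
                yield from obj.named_parameters(prefix=path + ".")
            elif isinstance(obj, (list, tuple)):
                for i, item in enumerate(obj):
                    if isinstance(item, Module):
                        yield from item.named_parameters(prefix=f"{path}.{i}.")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def forward(self, x, training: bool = False):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad):  # pragma: no cover - interface
        raise NotImplementedError

    def __call__(self, x, training: bool = False):
        return self.forward(x, training=training)


def _uniform_init(rng: np.random.Generator, shape, fan_in: int, dtype):
    bound = 1.0 / math.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape).astype(dtype)


class Conv1d(Module):
    """Cross-correlation along time with stride, dilation and explicit padding.

    Input ``(C_in, L)`` -> output ``(C_out, L_out)`` with
    ``L_out = (L + pad_left + pad_right - dilation*(k-1) - 1)//stride + 1``.
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        stride: int = 1,
        dilation: int = 1,
        pad_left: int = 0,
        pad_right: int = 0,
        bias: bool = True,
        rng: np.random.Generator | None = None,
        dtype=np.float32,
    ):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.stride = stride
        self.dilation = dilation
        self.pad_left = pad_left
        self.pad_right = pad_right
        fan_in = in_channels * kernel_size
        self.weight = Parameter(
            _uniform_init(rng, (out_channels, in_channels, kernel_size), fan_in, dtype)
        )
        self.bias = Parameter(_uniform_init(rng, (out_channels,), fan_in, dtype)) if bias else None
        self._xp = None

    # -- helpers ------------------------------------------------------------
    def _use_fft(self) -> bool:
        return (
            self.stride == 1
            and self.dilation == 1
            and self.kernel_size >= _FFT_KERNEL_MIN
        )

    def _out_len(self, L: int) -> int:
        span = self.dilation * (self.kernel_size - 1) + 1
        return (L + self.pad_left + self.pad_right - span) // self.stride + 1

    def _cols(self, xp: np.ndarray, L_out: int) -> np.ndarray:
        s0, s1 = xp.strides
        return as_strided(
            xp,
            shape=(xp.shape[0], self.kernel_size, L_out),
            strides=(s0, s1 * self.dilation, s1 * self.stride),
            writeable=False,
        )

    # -- FFT path (stride 1, dilation 1) ------------------------------------
    @staticmethod
    def _rfft(a, nfft):
        return sfft.rfft(a, nfft, axis=-1)

    def _fft_forward(self, xp: np.ndarray, L_out: int) -> np.ndarray:
        nfft = sfft.next_fast_len(xp.shape[1])
        Xf = self._rfft(xp, nfft)  # (C, F)
        w = self.weight.value
        y = np.empty((self.out_channels, L_out), dtype=xp.dtype)
        for lo in range(0, self.out_channels, _FFT_CHUNK):
            hi = min(lo + _FFT_CHUNK, self.out_channels)
            Wf = self._rfft(w[lo:hi], nfft)  # (o, C, F)
            Yf = np.einsum("cf,ocf->of", Xf, np.conj(Wf))
            y[lo:hi] = sfft.irfft(Yf, nfft, axis=-1)[:, :L_out].real.astype(xp.dtype)
        return y

    def _fft_backward(self, dy: np.ndarray, xp: np.ndarray):
        nfft = sfft.next_fast_len(xp.shape[1])
        Xf = self._rfft(xp, nfft)
        DYf = self._rfft(dy, nfft)
        w = self.weight.value
        K = self.kernel_size
        dxp = np.zeros_like(xp)
        for lo in range(0, self.out_channels, _FFT_CHUNK):
            hi = min(lo + _FFT_CHUNK, self.out_channels)
            # dW[o,c,k] = sum_t xp[c,t+k] dy[o,t]
            Gf = np.einsum("cf,of->ocf", Xf, np.conj(DYf[lo:hi]))
            dw = sfft.irfft(Gf, nfft, axis=-1)[:, :, :K].real
            self.weight.grad[lo:hi] += dw.astype(self.weight.grad.dtype)
            # dxp[c,u] = sum_{o,k} dy[o,u-k] w[o,c,k]
            Wf = self._rfft(w[lo:hi], nfft)
            Df = np.einsum("of,ocf->cf", DYf[lo:hi], Wf)
            dxp += sfft.irfft(Df, nfft, axis=-1)[:, : xp.shape[1]].real.astype(xp.dtype)
        return dxp

    # -- API -----------------------------------------------------------------
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if x.ndim != 2 or x.shape[0] != self.in_channels:
            raise ValueError(
                f"expected input ({self.in_channels}, L), got {x.shape}"
            )
        xp = np.pad(x, ((0, 0), (self.pad_left, self.pad_right)))
        L_out = self._out_len(x.shape[1])
        if L_out < 1:
            raise ValueError("input shorter than kernel span")
        if self._use_fft():
            y = self._fft_forward(xp, L_out)
        else:
            cols = self._cols(xp, L_out)
            y = np.tensordot(self.weight.value, cols, axes=([1, 2], [0, 1]))
        if self.bias is not None:
            y = y + self.bias.value[:, None]
        if training:
            self._xp = xp
            self._L_in = x.shape[1]
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xp = self._xp
        if xp is None:
            raise RuntimeError("backward called without a training-mode forward")
        if self.bias is not None:
            self.bias.grad += dy.sum(axis=1).astype(self.bias.grad.dtype)
        if self._use_fft():
            dxp = self._fft_backward(dy, xp)
        else:
            L_out = dy.shape[1]
            cols = self._cols(xp, L_out)
            self.weight.grad += np.einsum("ot,ckt->ock", dy, cols).astype(
                self.weight.grad.dtype
            )
            dxp = np.zeros_like(xp)
            w = self.weight.value
            for k in range(self.kernel_size):
                start = k * self.dilation
                stop = start + self.stride * (L_out - 1) + 1
                dxp[:, start:stop : self.stride] += w[:, :, k].T @ dy
        end = xp.shape[1] - self.pad_right
        self._xp = None
        return dxp[:, self.pad_left : end]


class CausalConv1d(Conv1d):
    """Left-padded convolution: output at t sees only inputs <= t."""

    def __init__(self, in_channels, out_channels, kernel_size, dilation=1, **kw):
        super().__init__(
            in_channels,
            out_channels,
            kernel_size,
            stride=1,
            dilation=dilation,
            pad_left=dilation * (kernel_size - 1),
            pad_right=0,
            **kw,
        )


class ReLU(Module):
    def forward(self, x, training=False):
        y = np.maximum(x, 0)
        if training:
            self._mask = x > 0
        return y

    def backward(self, dy):
        return dy * self._mask


class Sigmoid(Module):
    def forward(self, x, training=False):
        y = 1.0 / (1.0 + np.exp(-x))
        if training:
            self._y = y
        return y

    def backward(self, dy):
        return dy * self._y * (1.0 - self._y)


class Dropout(Module):
    """Inverted dropout; draws masks from a shared rng box for determinism."""

    def __init__(self, p: float, rng_box: dict):
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p
        self._rng_box = rng_box

    def forward(self, x, training=False):
        if not training or self.p == 0.0:
            self._mask = None
            return x
        rng: np.random.Generator = self._rng_box["rng"]
        keep = 1.0 - self.p
        self._mask = (rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, dy):
        if self._mask is None:
            return dy
        return dy * self._mask


class MaxPool1dSame(Module):
    """Stride-1 max pooling with same-length output (pad with -inf)."""

    def __init__(self, kernel_size: int = 3):
        self.kernel_size = kernel_size
        self.pad_left = (kernel_size - 1) // 2
        self.pad_right = kernel_size - 1 - self.pad_left

    def forward(self, x, training=False):
        xp = np.pad(
            x,
            ((0, 0), (self.pad_left, self.pad_right)),
            constant_values=-np.inf,
        )
        s0, s1 = xp.strides
        view = as_strided(
            xp,
            shape=(x.shape[0], self.kernel_size, x.shape[1]),
            strides=(s0, s1, s1),
            writeable=False,
        )
        if training:
            idx = view.argmax(axis=1)  # (C, L) offset within window
            self._idx = idx
            self._shape = x.shape
            return np.take_along_axis(view, idx[:, None, :], axis=1)[:, 0, :]
        return view.max(axis=1)

    def backward(self, dy):
        C, L = self._shape
        dxp = np.zeros((C, L + self.pad_left + self.pad_right), dtype=dy.dtype)
        rows = np.repeat(np.arange(C), L)
        pos = (self._idx + np.arange(L)[None, :]).ravel()
        np.add.at(dxp, (rows, pos), dy.ravel())
        return dxp[:, self.pad_left : self.pad_left + L]


class AdaptiveAvgPool1d(Module):
    """Average pooling onto a fixed output grid (PyTorch bin convention)."""

    def __init__(self, output_size: int):
        self.output_size = output_size

    def _bins(self, L):
        i = np.arange(self.output_size)
        starts = (i * L) // self.output_size
        ends = -((-(i + 1) * L) // self.output_size)
        return starts, ends

    def forward(self, x, training=False):
        C, L = x.shape
        starts, ends = self._bins(L)
        cs = np.concatenate([np.zeros((C, 1), dtype=np.float64), np.cumsum(x, axis=1, dtype=np.float64)], axis=1)
        y = (cs[:, ends] - cs[:, starts]) / (ends - starts)
        if training:
            self._L = L
        return y.astype(x.dtype)

    def backward(self, dy):
        C = dy.shape[0]
        starts, ends = self._bins(self._L)
        dx = np.zeros((C, self._L), dtype=dy.dtype)
        for i in range(self.output_size):
            dx[:, starts[i] : ends[i]] += (dy[:, i] / (ends[i] - starts[i]))[:, None]
        return dx


class Sequential(Module):
    def __init__(self, *modules: Module):
        self.steps = list(modules)

    def forward(self, x, training=False):
        for m in self.steps:
            x = m.forward(x, training=training)
        return x

    def backward(self, dy):
        for m in reversed(self.steps):
            dy = m.backward(dy)
        return dy
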