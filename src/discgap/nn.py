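"""Minimal NumPy layers for 1D sequence labeling networks.

Implements exactly what the narrowing detector needs: length-preserving
1D convolution (cross-correlation) with an FFT fast path, batch
normalization over (batch, position), ReLU, and an Adam optimizer.
Shapes follow the (batch, channels, length) convention.

The FFT path evaluates the same linear operator as the direct path up to
floating-point rounding; the direct path additionally guarantees exact
zeros outside a kernel's footprint, which matters when probing receptive
fields.
"""

from __future__ import annotations

from typing import Literal

import numpy as np
from scipy import fft as sfft

ConvMethod = Literal["fft", "direct"]


class Conv1d:
    """Length-preserving 1D cross-correlation layer.

    ``y[b, o, t] = sum_{i,k} w[o, i, k] * x_pad[b, i, t + k] + bias[o]``
    with symmetric zero padding of ``(kernel - 1) // 2`` per side.
    Kernel size must be odd so output length equals input length.
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        rng: np.random.Generator,
        method: ConvMethod = "fft",
        dtype: np.dtype = np.float64,
    ) -> None:
        if kernel_size % 2 == 0:
            raise ValueError("kernel_size must be odd to preserve length")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.pad = (kernel_size - 1) // 2
        self.method = method
        self.dtype = np.dtype(dtype)
        scale = np.sqrt(2.0 / (in_channels * kernel_size))  # He init
        self.w = rng.normal(0.0, scale, size=(out_channels, in_channels, kernel_size)).astype(self.dtype)
        self.b = np.zeros(out_channels, dtype=self.dtype)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)
        self._cache: tuple | None = None

    @property
    def params(self) -> list[np.ndarray]:
        return [self.w, self.b]

    @property
    def grads(self) -> list[np.ndarray]:
        return [self.gw, self.gb]

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.ascontiguousarray(x, dtype=self.dtype)
        if self.method == "fft":
            return self._forward_fft(x)
        return self._forward_direct(x)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self.method == "fft":
            return self._backward_fft(dy)
        return self._backward_direct(dy)

    # -- FFT path ----------------------------------------------------------
    # Frequency-domain channel contractions are done as per-frequency
    # batched matmuls (zgemm) — orders of magnitude faster than einsum
    # over complex arrays.
    def _forward_fft(self, x: np.ndarray) -> np.ndarray:
        B, C, L = x.shape
        n = sfft.next_fast_len(L + self.kernel_size)
        xe = np.zeros((B, C, L + 2 * self.pad), dtype=self.dtype)
        xe[:, :, self.pad : self.pad + L] = x
        xef = sfft.rfft(xe, n=n, axis=-1)
        wf = sfft.rfft(self.w, n=n, axis=-1)
        # yf[b,o,f] = sum_i conj(wf[o,i,f]) * xef[b,i,f]
        yf = np.conj(wf).transpose(2, 0, 1) @ xef.transpose(2, 1, 0)  # (F,O,B)
        y = sfft.irfft(yf.transpose(2, 1, 0), n=n, axis=-1)[:, :, :L]
        self._cache = (xef, wf, L, n)
        return y + self.b[None, :, None]

    def _backward_fft(self, dy: np.ndarray) -> np.ndarray:
        xef, wf, L, n = self._cache
        dy = np.ascontiguousarray(dy, dtype=self.dtype)
        dyf = sfft.rfft(dy, n=n, axis=-1)
        # dwf[o,i,f] = sum_b conj(dyf[b,o,f]) * xef[b,i,f]
        dwf = np.conj(dyf).transpose(2, 1, 0) @ xef.transpose(2, 0, 1)  # (F,O,I)
        dw = sfft.irfft(dwf.transpose(1, 2, 0), n=n, axis=-1)[:, :, : self.kernel_size]
        # dxef[b,i,f] = sum_o dyf[b,o,f] * wf[o,i,f]
        dxef = dyf.transpose(2, 0, 1) @ wf.transpose(2, 0, 1)  # (F,B,I)
        dxe = sfft.irfft(dxef.transpose(1, 2, 0), n=n, axis=-1)[
            :, :, : L + 2 * self.pad
        ]
        self.gw[...] = dw
        self.gb[...] = dy.sum(axis=(0, 2))
        return dxe[:, :, self.pad : self.pad + L]

    # -- direct path (exact locality) --------------------------------------
    def _windows(self, x: np.ndarray) -> np.ndarray:
        B, C, L = x.shape
        xe = np.zeros((B, C, L + 2 * self.pad), dtype=self.dtype)
        xe[:, :, self.pad : self.pad + L] = x
        return np.lib.stride_tricks.sliding_window_view(
            xe, self.kernel_size, axis=-1
        )  # (B, C, L, K)

    def _forward_direct(self, x: np.ndarray) -> np.ndarray:
        win = self._windows(x)
        y = np.einsum("biLk,oik->boL", win, self.w)
        self._cache = (win, x.shape)
        return y + self.b[None, :, None]

    def _backward_direct(self, dy: np.ndarray) -> np.ndarray:
        win, (B, C, L) = self._cache
        self.gw[...] = np.einsum("boL,biLk->oik", dy, win)
        self.gb[...] = dy.sum(axis=(0, 2))
        # dx[b,i,s] = sum_{o,k} dy[b,o,s - k + pad] * w[o,i,k]
        dye = np.zeros((B, self.out_channels, L + 2 * self.pad), dtype=self.dtype)
        dye[:, :, self.pad : self.pad + L] = np.asarray(dy, dtype=self.dtype)
        dwin = np.lib.stride_tricks.sliding_window_view(
            dye, self.kernel_size, axis=-1
        )  # (B, O, L, K)
        wflip = self.w[:, :, ::-1]
        return np.einsum("boLk,oik->biL", dwin, wflip)


class BatchNorm1d:
    """Per-channel batch normalization over the (batch, position) axes."""

    def __init__(
        self,
        channels: int,
        eps: float = 1e-5,
        momentum: float = 0.1,
        dtype: np.dtype = np.float64,
    ) -> None:
        self.dtype = np.dtype(dtype)
        self.gamma = np.ones(channels, dtype=self.dtype)
        self.beta = np.zeros(channels, dtype=self.dtype)
        self.eps = eps
        self.momentum = momentum
        self.running_mean = np.zeros(channels, dtype=self.dtype)
        self.running_var = np.ones(channels, dtype=self.dtype)
        self.ggamma = np.zeros_like(self.gamma)
        self.gbeta = np.zeros_like(self.beta)
        self._cache: tuple | None = None

    @property
    def params(self) -> list[np.ndarray]:
        return [self.gamma, self.beta]

    @property
    def grads(self) -> list[np.ndarray]:
        return [self.ggamma, self.gbeta]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean = self.running_mean
            var = self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None]) * inv[None, :, None]
        self._cache = (xhat, inv, training, x.shape)
        return self.gamma[None, :, None] * xhat + self.beta[None, :, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv, training, shape = self._cache
        self.ggamma[...] = (dy * xhat).sum(axis=(0, 2))
        self.gbeta[...] = dy.sum(axis=(0, 2))
        g = self.gamma[None, :, None]
        if not training:
            return dy * g * inv[None, :, None]
        dxhat = dy * g
        term = (
            dxhat
            - dxhat.mean(axis=(0, 2))[None, :, None]
            - xhat * (dxhat * xhat).mean(axis=(0, 2))[None, :, None]
        )
        return term * inv[None, :, None]


class ReLU:
    def __init__(self) -> None:
        self._mask: np.ndarray | None = None

    params: list[np.ndarray] = []
    grads: list[np.ndarray] = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, 0.0)


def softmax(logits: np.ndarray, axis: int = 1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


class Adam:
    """Adam with bias correction, one slot pair per parameter array."""

    def __init__(
        self,
        params: list[np.ndarray],
        grads: list[np.ndarray],
        lr: float,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ) -> None:
        self.params = params
        self.grads = grads
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, self.grads, self.m, self.v):
            m += (1 - b1) * (g - m)
            v += (1 - b2) * (g * g - v)
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
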