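"""Minimal NumPy neural-network layers with explicit backward passes.

Convolutions with kernel > 1 run in the frequency domain (single-block
linear convolution via rFFT), which on a single core is an order of
magnitude cheaper than im2col + gemm for the long kernels used here;
kernel-1 convolutions use a direct batched matmul. Every layer caches what
its backward pass needs and frees the cache afterwards. Arrays flow as
``(batch, channels, length)``.
"""
from __future__ import annotations

import numpy as np
from scipy import fft as sfft


class Param:
    """A trainable array with its gradient accumulator."""

    __slots__ = ("name", "value", "grad", "decay")

    def __init__(self, name: str, value: np.ndarray, decay: bool):
        self.name = name
        self.value = value
        self.grad = np.zeros_like(value)
        self.decay = decay  # whether AdamW weight decay applies


class Conv1d:
    """Strided 1D cross-correlation, bias-free (always followed by BN here).

    Frequency-domain evaluation: with ``N >= L + K - 1`` the circular
    correlation ``c = irfft(rfft(x) * conj(rfft(w)))`` is alias-free on the
    index range the output taps, so ``y[i] = c[(i*stride - pad) mod N]``.
    The backward pass reuses the cached input spectrum.
    """

    def __init__(self, name, cin, cout, kernel, stride, pad, rng, dtype):
        self.cin, self.cout = cin, cout
        self.kernel, self.stride, self.pad = kernel, stride, pad
        scale = np.sqrt(2.0 / (cin * kernel))  # He init
        self.W = Param(
            f"{name}.W",
            rng.normal(0.0, scale, (cout, cin, kernel)).astype(dtype),
            decay=True,
        )
        self._cache = None

    def out_len(self, L: int) -> int:
        return (L + 2 * self.pad - self.kernel) // self.stride + 1

    # -- kernel-1 fast path --------------------------------------------------
    def _forward_k1(self, x, keep_cache):
        xs = x[:, :, :: self.stride] if self.stride > 1 else x
        xs = np.ascontiguousarray(xs)
        if keep_cache:
            self._cache = ("k1", xs, x.shape)
        return np.matmul(self.W.value[:, :, 0], xs)

    def _backward_k1(self, dy):
        _, xs, xshape = self._cache
        self._cache = None
        W = self.W.value[:, :, 0]
        self.W.grad[:, :, 0] += np.matmul(dy, xs.transpose(0, 2, 1)).sum(axis=0)
        dxs = np.matmul(W.T, dy)
        if self.stride == 1:
            return dxs
        dx = np.zeros(xshape, dtype=dy.dtype)
        dx[:, :, :: self.stride] = dxs
        return dx

    # -- FFT path ------------------------------------------------------------
    def _spectra(self, L: int):
        N = sfft.next_fast_len(L + self.kernel - 1, real=True)
        idx = (np.arange(self.out_len(L)) * self.stride - self.pad) % N
        return N, idx

    def forward(self, x: np.ndarray, keep_cache: bool = True) -> np.ndarray:
        B, Cin, L = x.shape
        if Cin != self.cin:
            raise ValueError(f"expected {self.cin} input channels, got {Cin}")
        if self.kernel == 1:
            return self._forward_k1(x, keep_cache)
        N, idx = self._spectra(L)
        Xf = sfft.rfft(x, n=N, axis=-1)  # (B, Cin, F)
        Wf = sfft.rfft(self.W.value, n=N, axis=-1)  # (Cout, Cin, F)
        # correlation: Yf[b,o,f] = sum_c conj(Wf[o,c,f]) Xf[b,c,f]
        Yf = np.matmul(
            Wf.conj().transpose(2, 0, 1), Xf.transpose(2, 1, 0)
        )  # (F, Cout, B)
        c = sfft.irfft(Yf.transpose(2, 1, 0), n=N, axis=-1)  # (B, Cout, N)
        y = np.ascontiguousarray(c[:, :, idx], dtype=x.dtype)
        if keep_cache:
            self._cache = ("fft", Xf, Wf, N, idx, L)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._cache[0] == "k1":
            return self._backward_k1(dy)
        _, Xf, Wf, N, idx, L = self._cache
        self._cache = None
        B = dy.shape[0]
        u = np.zeros((B, self.cout, N), dtype=dy.dtype)
        u[:, :, idx] = dy  # zero-stuffed upsample of dy onto input positions
        Uf = sfft.rfft(u, axis=-1)  # (B, Cout, F)
        # dW[o,c,j] = sum_b,m conj(Uf) Xf -> correlation of u with x
        dWf = np.matmul(
            Uf.conj().transpose(2, 1, 0), Xf.transpose(2, 0, 1)
        )  # (F, Cout, Cin)
        dW = sfft.irfft(dWf.transpose(1, 2, 0), n=N, axis=-1)[..., : self.kernel]
        self.W.grad += dW.astype(self.W.grad.dtype)
        # dx[n] = sum_o (u_o conv w_o,c)[n]
        dXf = np.matmul(
            Wf.transpose(2, 1, 0), Uf.transpose(2, 1, 0)
        )  # (F, Cin, B)
        dx = sfft.irfft(dXf.transpose(2, 1, 0), n=N, axis=-1)[:, :, :L]
        return np.ascontiguousarray(dx, dtype=dy.dtype)

    def params(self):
        return [self.W]


class BatchNorm1d:
    def __init__(self, name, c, dtype, momentum=0.1, eps=1e-5):
        self.gamma = Param(f"{name}.gamma", np.ones((1, c, 1), dtype=dtype), decay=False)
        self.beta = Param(f"{name}.beta", np.zeros((1, c, 1), dtype=dtype), decay=False)
        self.running_mean = np.zeros((1, c, 1), dtype=dtype)
        self.running_var = np.ones((1, c, 1), dtype=dtype)
        self.momentum, self.eps = momentum, eps
        self._cache = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            mean = x.mean(axis=(0, 2), keepdims=True)
            var = x.var(axis=(0, 2), keepdims=True)
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * mean
            )
            self.running_var = (
                (1 - self.momentum) * self.running_var + self.momentum * var
            )
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv_std
        if training:
            self._cache = (xhat, inv_std)
        return self.gamma.value * xhat + self.beta.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._cache
        self._cache = None
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2), keepdims=True)
        self.beta.grad += dy.sum(axis=(0, 2), keepdims=True)
        dxhat = dy * self.gamma.value
        m = dxhat.mean(axis=(0, 2), keepdims=True)
        mx = (dxhat * xhat).mean(axis=(0, 2), keepdims=True)
        return inv_std * (dxhat - m - xhat * mx)

    def params(self):
        return [self.gamma, self.beta]


class ReLU:
    def __init__(self):
        self._mask = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        out = dy * self._mask
        self._mask = None
        return out


class Dropout:
    """Inverted dropout; identity in eval mode."""

    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self._mask = None

    def forward(self, x: np.ndarray, training: bool, rng=None) -> np.ndarray:
        if not training or self.rate == 0.0:
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dy
        out = dy * self._mask
        self._mask = None
        return out


class Linear:
    def __init__(self, name, n_in, n_out, rng, dtype):
        scale = np.sqrt(1.0 / n_in)
        self.W = Param(
            f"{name}.W", rng.normal(0.0, scale, (n_out, n_in)).astype(dtype), decay=True
        )
        self.b = Param(f"{name}.b", np.zeros(n_out, dtype=dtype), decay=False)
        self._cache = None

    def forward(self, x: np.ndarray, keep_cache: bool = True) -> np.ndarray:
        if keep_cache:
            self._cache = x
        return x @ self.W.value.T + self.b.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._cache
        self._cache = None
        self.W.grad += dy.T @ x
        self.b.grad += dy.sum(axis=0)
        return dy @ self.W.value

    def params(self):
        return [self.W, self.b]
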