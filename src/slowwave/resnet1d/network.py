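"""Residual 1D CNN architecture.

Five stride-2 residual blocks (main path: kernel-121 conv + batch norm;
skip: kernel-1 stride-2 conv + batch norm; sum -> ReLU -> dropout) followed
by a kernel-1 conv to a single channel + batch norm, flatten, one fully
connected unit and a sigmoid. A 12,000-sample input flattens to 375
features: each block halves the length (ceil), 12000 -> 6000 -> 3000 ->
1500 -> 750 -> 375.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .layers import BatchNorm1d, Conv1d, Dropout, Linear, ReLU


@dataclass
class CnnConfig:
    in_channels: int = 3
    block_channels: tuple = (6, 12, 24, 48, 96)
    block_kernel: int = 121
    block_stride: int = 2
    head_kernel: int = 1
    head_channels: int = 1
    dropout_rate: float = 0.2
    seed: int = 0
    dtype: str = "float32"

    def __post_init__(self) -> None:
        if len(self.block_channels) != 5:
            raise ValueError("exactly 5 residual blocks are required")
        if self.block_stride != 2:
            raise ValueError("blocks must downsample by 2")
        if self.block_kernel % 2 == 0:
            raise ValueError("block_kernel must be odd for symmetric padding")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")

    def feature_len(self, input_len: int) -> int:
        return math.ceil(input_len / self.block_stride ** len(self.block_channels))


class ResidualBlock:
    def __init__(self, name, cin, cout, kernel, stride, dropout_rate, rng, dtype):
        pad = (kernel - 1) // 2  # symmetric padding -> output length = ceil(L/2)
        self.conv_main = Conv1d(f"{name}.main", cin, cout, kernel, stride, pad, rng, dtype)
        self.bn_main = BatchNorm1d(f"{name}.main_bn", cout, dtype)
        self.conv_skip = Conv1d(f"{name}.skip", cin, cout, 1, stride, 0, rng, dtype)
        self.bn_skip = BatchNorm1d(f"{name}.skip_bn", cout, dtype)
        self.relu = ReLU()
        self.dropout = Dropout(dropout_rate)

    def forward(self, x, training, rng=None, keep_cache=None):
        keep = training if keep_cache is None else keep_cache
        a = self.bn_main.forward(self.conv_main.forward(x, keep_cache=keep), training)
        b = self.bn_skip.forward(self.conv_skip.forward(x, keep_cache=keep), training)
        z = self.relu.forward(a + b, training)
        return self.dropout.forward(z, training, rng)

    def backward(self, d):
        d = self.dropout.backward(d)
        d = self.relu.backward(d)
        dx = self.conv_main.backward(self.bn_main.backward(d))
        dx += self.conv_skip.backward(self.bn_skip.backward(d))
        return dx

    def params(self):
        return (
            self.conv_main.params()
            + self.bn_main.params()
            + self.conv_skip.params()
            + self.bn_skip.params()
        )


class ResNet1d:
    """Stateful model: forward/backward plus eval-mode scoring helpers."""

    def __init__(self, cfg: CnnConfig, input_len: int):
        if input_len < 2 ** len(cfg.block_channels):
            raise ValueError(
                f"input_len must be >= {2 ** len(cfg.block_channels)}, got {input_len}"
            )
        self.cfg = cfg
        self.input_len = input_len
        self.feature_len = cfg.feature_len(input_len)
        self.dtype = np.dtype(cfg.dtype)
        rng = np.random.default_rng(cfg.seed)
        self.blocks = []
        cin = cfg.in_channels
        for i, cout in enumerate(cfg.block_channels):
            self.blocks.append(
                ResidualBlock(
                    f"block{i}", cin, cout, cfg.block_kernel, cfg.block_stride,
                    cfg.dropout_rate, rng, self.dtype,
                )
            )
            cin = cout
        self.head_conv = Conv1d(
            "head", cin, cfg.head_channels, cfg.head_kernel, 1, 0, rng, self.dtype
        )
        self.head_bn = BatchNorm1d("head_bn", cfg.head_channels, self.dtype)
        self.fc = Linear("fc", self.feature_len * cfg.head_channels, 1, rng, self.dtype)

    # -- plumbing -----------------------------------------------------------
    def params(self):
        out = []
        for b in self.blocks:
            out.extend(b.params())
        out.extend(self.head_conv.params())
        out.extend(self.head_bn.params())
        out.extend(self.fc.params())
        return out

    def n_parameters(self) -> int:
        return int(sum(p.value.size for p in self.params()))

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0

    def state_dict(self) -> dict:
        state = {p.name: p.value.copy() for p in self.params()}
        for i, b in enumerate(self.blocks):
            for tag, bn in (("main", b.bn_main), ("skip", b.bn_skip)):
                state[f"block{i}.{tag}_bn.running_mean"] = bn.running_mean.copy()
                state[f"block{i}.{tag}_bn.running_var"] = bn.running_var.copy()
        state["head_bn.running_mean"] = self.head_bn.running_mean.copy()
        state["head_bn.running_var"] = self.head_bn.running_var.copy()
        return state

    def load_state_dict(self, state: dict) -> None:
        for p in self.params():
            p.value[...] = state[p.name]
        for i, b in enumerate(self.blocks):
            for tag, bn in (("main", b.bn_main), ("skip", b.bn_skip)):
                bn.running_mean[...] = state[f"block{i}.{tag}_bn.running_mean"]
                bn.running_var[...] = state[f"block{i}.{tag}_bn.running_var"]
        self.head_bn.running_mean[...] = state["head_bn.running_mean"]
        self.head_bn.running_var[...] = state["head_bn.running_var"]

    # -- forward/backward ---------------------------------------------------
    def _check_input(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=self.dtype)
        if x.ndim != 3:
            raise ValueError("input must be (batch, channels, length)")
        if x.shape[1] != self.cfg.in_channels:
            raise ValueError(
                f"expected {self.cfg.in_channels} channels, got {x.shape[1]}"
            )
        return x

    def forward_logits(self, x, training=False, rng=None, keep_cache=None):
        x = self._check_input(x)
        keep = training if keep_cache is None else keep_cache
        h = x
        for b in self.blocks:
            h = b.forward(h, training, rng, keep_cache=keep)
        h = self.head_bn.forward(self.head_conv.forward(h, keep_cache=keep), training)
        self._flat_shape = h.shape
        flat = h.reshape(h.shape[0], -1)
        return self.fc.forward(flat, keep_cache=keep)[:, 0]

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.fc.backward(dlogits[:, None].astype(self.dtype))
        d = d.reshape(self._flat_shape)
        d = self.head_conv.backward(self.head_bn.backward(d))
        for b in reversed(self.blocks):
            d = b.backward(d)

    # -- inference ----------------------------------------------------------
    def encode(self, x) -> np.ndarray:
        """Eval-mode flattened feature vector entering the FC layer."""
        x = self._check_input(x)
        h = x
        for b in self.blocks:
            h = b.forward(h, training=False, keep_cache=False)
        h = self.head_bn.forward(self.head_conv.forward(h, keep_cache=False), False)
        return h.reshape(h.shape[0], -1)

    def block_lengths(self, input_len=None) -> list[int]:
        """Per-block output lengths (the downsampling chain)."""
        L = self.input_len if input_len is None else input_len
        out = []
        for _ in self.blocks:
            L = math.ceil(L / self.cfg.block_stride)
            out.append(L)
        return out

    def predict(self, x) -> np.ndarray:
        """Eval-mode sigmoid scores in (0, 1), one per window.

        Clipped one ulp-scale away from the boundaries so saturated logits
        still honour the open-interval contract.
        """
        logits = self.forward_logits(x, training=False, keep_cache=False)
        eps = 1e-12
        return np.clip(expit(logits.astype(np.float64)), eps, 1.0 - eps)


def build_model(cfg: CnnConfig = None, input_len: int = 12000) -> ResNet1d:
    """Construct a seeded :class:`ResNet1d` for the given input length."""
    return ResNet1d(cfg or CnnConfig(), input_len)
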