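"""Core data containers shared across the pipeline.

All signal payloads are plain NumPy arrays in millivolts, shaped
``(n_samples, n_channels)`` for recordings and ``(n_channels, n_samples)``
for extracted windows.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

CONDITIONS = ("baseline", "feeding")
#: label convention: 0 = baseline, 1 = feeding
CONDITION_LABELS = {"baseline": 0, "feeding": 1}


@dataclass
class RawRecording:
    """Multichannel mV time series at the native acquisition rate."""

    subject_id: str
    condition: str
    sample_rate_hz: float
    channels: list[str]
    data: np.ndarray  # (n_samples, n_channels), mV
    duration_s: float
    artifact_log: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(
                f"condition must be one of {CONDITIONS}, got {self.condition!r}"
            )
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (n_samples, n_channels)")
        if self.data.shape[1] != len(self.channels):
            raise ValueError(
                f"data has {self.data.shape[1]} columns but "
                f"{len(self.channels)} channel labels"
            )
        if len(self.channels) < 1:
            raise ValueError("at least one channel required")
        expected = int(round(self.duration_s * self.sample_rate_hz))
        if self.data.shape[0] != expected:
            raise ValueError(
                f"data has {self.data.shape[0]} rows, expected "
                f"{expected} (= duration_s x sample_rate_hz)"
            )

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def label(self) -> int:
        return CONDITION_LABELS[self.condition]

    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sample_rate_hz


@dataclass
class ChannelQC:
    """Per-channel quality metrics and the three-criterion inclusion flag."""

    pct_dropped: float
    pct_interpolated: float
    total_power: float
    passed: bool

    def __post_init__(self) -> None:
        for name in ("pct_dropped", "pct_interpolated"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{name} must be in [0, 100], got {v}")


@dataclass
class CleanRecording:
    """Preprocessed 200 Hz recording plus per-channel QC."""

    subject_id: str
    condition: str
    sample_rate_hz: float
    channels: list[str]
    data: np.ndarray  # (n_samples, n_channels), mV
    qc: dict[str, ChannelQC]
    retained_channels: list[str]
    fingerprint: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate_hz

    @property
    def label(self) -> int:
        return CONDITION_LABELS[self.condition]

    def channel_data(self, names: Optional[list[str]] = None) -> np.ndarray:
        names = self.channels if names is None else names
        idx = [self.channels.index(c) for c in names]
        return self.data[:, idx]


@dataclass
class LabeledWindow:
    """One fixed-duration multichannel segment with a binary condition label."""

    subject_id: str
    label: int
    data: np.ndarray  # (n_channels, n_samples), mV
    window_index: int
    channels: list[str]
    sample_rate_hz: float = 200.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("window data must be 2-D (n_channels, n_samples)")
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class ScoreSet:
    """Per-sample classifier scores in [0, 1] aligned with true labels."""

    scores: np.ndarray
    labels: np.ndarray
    fold_ids: Optional[np.ndarray] = None
    classifier: str = ""
    subject_ids: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.scores.shape != self.labels.shape:
            raise ValueError("scores and labels must be aligned")
        if self.scores.size and (self.scores.min() < 0 or self.scores.max() > 1):
            raise ValueError("scores must lie in [0, 1]")
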