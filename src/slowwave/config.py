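"""YAML configuration loading for the CLI layer.

A config file holds optional sections mapping straight onto the parameter
dataclasses::

    synthetic:
      slow_wave_freq_hz: 0.15
      feeding_tachy_power_fraction: 0.35
      saturation_rate_per_hour: 2.0
      ...
    preprocess: { target_rate_hz: 200, qc_min_power: 1000, ... }
    spectral:   { n_bands: 10, nfft: 16384 }
    cnn:        { dropout_rate: 0.2 }
    train:      { max_epochs: 200, batch_size: 20, learning_rate: 0.001 }
"""
from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

from .preprocess import PreprocessConfig
from .resnet1d import CnnConfig, TrainConfig
from .spectral import BandSpec
from .synth import ArtifactParams, SignalParams, default_signal_params


def _pick(cls, mapping: dict) -> dict:
    names = {f.name for f in dataclasses.fields(cls)}
    return {k: v for k, v in mapping.items() if k in names}


def load_config(path=None) -> dict:
    """Parse a YAML config into parameter objects; missing sections default."""
    raw = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text()) or {}

    synth_raw = raw.get("synthetic", {}) or {}
    base = default_signal_params("baseline")
    feed = default_signal_params("feeding")
    base = dataclasses.replace(base, **_pick(SignalParams, synth_raw))
    feed = dataclasses.replace(feed, **_pick(SignalParams, synth_raw))
    if "baseline_tachy_power_fraction" in synth_raw:
        base = dataclasses.replace(
            base, tachy_power_fraction=synth_raw["baseline_tachy_power_fraction"]
        )
    if "feeding_tachy_power_fraction" in synth_raw:
        feed = dataclasses.replace(
            feed, tachy_power_fraction=synth_raw["feeding_tachy_power_fraction"]
        )
    artifacts = ArtifactParams(**_pick(ArtifactParams, synth_raw))

    spectral_raw = raw.get("spectral", {}) or {}
    cnn_raw = dict(raw.get("cnn", {}) or {})
    if "block_channels" in cnn_raw:
        cnn_raw["block_channels"] = tuple(cnn_raw["block_channels"])
    return {
        "signal_by_condition": {"baseline": base, "feeding": feed},
        "artifacts": artifacts,
        "synthetic_extra": {
            k: synth_raw[k]
            for k in ("duration_s", "sample_rate_hz", "n_channels")
            if k in synth_raw
        },
        "preprocess": PreprocessConfig(**_pick(PreprocessConfig, raw.get("preprocess", {}) or {})),
        "bands": BandSpec(**_pick(BandSpec, spectral_raw)),
        "nfft": spectral_raw.get("nfft", 16384),
        "cnn": CnnConfig(**_pick(CnnConfig, cnn_raw)),
        "train": TrainConfig(**_pick(TrainConfig, raw.get("train", {}) or {})),
    }
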