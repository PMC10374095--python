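"""Shared fixtures: small synthetic study generated once per session.

The study fixture mirrors the target protocol at reduced scale: 4 subjects x
2 conditions, generated natively at 200 Hz (12 min each) so preprocessing
is cheap, with heavy saturation injected into channel 3 of one subject so
the study-wide QC exclusion leaves 3 retained channels.
"""
from __future__ import annotations

import numpy as np
import pytest

from slowwave.preprocess import apply_study_exclusion, run_preprocess
from slowwave.records import LabeledWindow
from slowwave.spectral import featurize_windows
from slowwave.synth import generate_recording
from slowwave.windows import segment_study


def make_sine_window(
    freq_hz: float,
    amp: float = 1.0,
    n_samples: int = 12000,
    rate: float = 200.0,
    label: int = 0,
    n_channels: int = 1,
    phase: float = 0.0,
) -> LabeledWindow:
    t = np.arange(n_samples) / rate
    x = amp * np.sin(2 * np.pi * freq_hz * t + phase)
    return LabeledWindow(
        subject_id="toy",
        label=label,
        data=np.tile(x, (n_channels, 1)),
        window_index=0,
        channels=[f"ch{i + 1}" for i in range(n_channels)],
        sample_rate_hz=rate,
    )


@pytest.fixture(scope="session")
def study_windows():
    """96 one-minute windows (3 retained channels) from a reduced-scale study."""
    recs = []
    for s in range(4):
        for cond in ("baseline", "feeding"):
            rec = generate_recording(
                f"s{s + 1:02d}", cond, duration_s=720, sample_rate_hz=200, seed=7
            )
            if s == 0:
                # saturate 30% of channel 3 -> fails QC -> study-wide exclusion
                n = rec.data.shape[0]
                rec.data[: int(0.3 * n), 2] = 187.5
            recs.append(rec)
    cleans = [run_preprocess(r) for r in recs]
    apply_study_exclusion(cleans)
    windows = segment_study(cleans)
    assert len(windows) == 96
    assert windows[0].channels == ["ch1", "ch2", "ch4"]
    return windows


@pytest.fixture(scope="session")
def study_features(study_windows):
    return featurize_windows(study_windows)
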