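"""Segmentation of cleaned recordings into labeled 1-minute windows and
stratified cross-validation fold planning."""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.model_selection import GroupKFold, StratifiedKFold

from .records import CleanRecording, LabeledWindow


def segment(rec: CleanRecording, window_s: float = 60.0) -> list[LabeledWindow]:
    """Cut a recording into consecutive non-overlapping windows.

    Only QC-retained channels are kept. The trailing remainder shorter than
    one window is discarded; a recording shorter than one window yields an
    empty list with a warning. Concatenating the returned windows
    reproduces the first ``window_s * k`` seconds of the recording exactly.
    """
    n_per = int(round(window_s * rec.sample_rate_hz))
    n_windows = rec.n_samples // n_per
    if n_windows == 0:
        warnings.warn(
            f"recording {rec.subject_id}/{rec.condition} shorter than one "
            f"{window_s}-s window; no windows produced",
            stacklevel=2,
        )
        return []
    data = rec.channel_data(rec.retained_channels)  # (n_samples, C)
    out = []
    for i in range(n_windows):
        chunk = data[i * n_per : (i + 1) * n_per].T  # (C, n_per)
        out.append(
            LabeledWindow(
                subject_id=rec.subject_id,
                label=rec.label,
                data=chunk,
                window_index=i,
                channels=list(rec.retained_channels),
                sample_rate_hz=rec.sample_rate_hz,
            )
        )
    return out


def segment_study(recordings: list[CleanRecording], window_s: float = 60.0) -> list[LabeledWindow]:
    windows: list[LabeledWindow] = []
    for rec in recordings:
        windows.extend(segment(rec, window_s))
    return windows


@dataclass
class FoldPlan:
    """Window -> fold assignment for k-fold cross-validation."""

    n_folds: int
    assignments: np.ndarray  # fold id per window
    seed: int
    stratified: bool

    def __post_init__(self) -> None:
        self.assignments = np.asarray(self.assignments, dtype=int)

    def split(self, fold: int) -> tuple[np.ndarray, np.ndarray]:
        """(train_idx, val_idx) for one fold."""
        val = np.flatnonzero(self.assignments == fold)
        train = np.flatnonzero(self.assignments != fold)
        return train, val

    def __iter__(self):
        for fold in range(self.n_folds):
            yield self.split(fold)


def make_folds(
    windows: list[LabeledWindow],
    n_folds: int = 3,
    seed: int = 0,
    stratified: bool = True,
    group_by_subject: bool = False,
) -> FoldPlan:
    """Deterministic, optionally label-stratified fold assignment.

    ``group_by_subject=True`` keeps each subject's windows within one fold
    (leakage-controlled alternative; off by default, matching the window-level
    protocol that yields 480 pooled samples).
    """
    if n_folds < 2:
        raise ValueError(f"n_folds must be >= 2, got {n_folds}")
    labels = np.array([w.label for w in windows])
    n = len(windows)
    if n == 0:
        raise ValueError("no windows to assign")
    counts = np.bincount(labels, minlength=2)
    if not group_by_subject and n_folds > counts[counts > 0].min():
        raise ValueError(
            f"n_folds={n_folds} exceeds the smallest class count "
            f"({counts[counts > 0].min()})"
        )
    assignments = np.empty(n, dtype=int)
    if group_by_subject:
        groups = np.array([w.subject_id for w in windows])
        splitter = GroupKFold(n_splits=n_folds)
        for fold, (_, val) in enumerate(splitter.split(np.zeros(n), labels, groups)):
            assignments[val] = fold
        stratified = False
    elif stratified:
        splitter = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        for fold, (_, val) in enumerate(splitter.split(np.zeros(n), labels)):
            assignments[val] = fold
    else:
        rng = np.random.default_rng(seed)
        perm = rng.permutation(n)
        for fold, chunk in enumerate(np.array_split(perm, n_folds)):
            assignments[chunk] = fold
    return FoldPlan(
        n_folds=n_folds, assignments=assignments, seed=seed, stratified=stratified
    )


def save_windows(windows: list[LabeledWindow], out_dir) -> Path:
    """Persist windows as one CSV per window plus an index CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, w in enumerate(windows):
        fname = f"window_{i:04d}.csv"
        pd.DataFrame(w.data.T, columns=w.channels).to_csv(
            out_dir / fname, index=False, float_format="%.6f"
        )
        rows.append(
            {
                "subject": w.subject_id,
                "condition": "feeding" if w.label else "baseline",
                "window_index": w.window_index,
                "label": w.label,
                "sample_rate_hz": w.sample_rate_hz,
                "file": fname,
            }
        )
    index = out_dir / "index.csv"
    pd.DataFrame(rows).to_csv(index, index=False)
    return index


def load_windows(out_dir) -> list[LabeledWindow]:
    out_dir = Path(out_dir)
    index = pd.read_csv(out_dir / "index.csv")
    windows = []
    for _, row in index.iterrows():
        df = pd.read_csv(out_dir / row["file"])
        windows.append(
            LabeledWindow(
                subject_id=str(row["subject"]),
                label=int(row["label"]),
                data=df.to_numpy().T,
                window_index=int(row["window_index"]),
                channels=list(df.columns),
                sample_rate_hz=float(row["sample_rate_hz"]),
            )
        )
    return windows
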