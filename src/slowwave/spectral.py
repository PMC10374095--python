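"""Welch PSD estimation, 10-band power features, training-fold z-scoring and
sequential (forward/backward) feature selection.

Feature naming convention: ``"<channel>_band<j>"`` with bands indexed from 0
over equal-width intervals spanning [0.05, 0.7] Hz by default.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import signal as sps
from sklearn.model_selection import StratifiedKFold

from .records import LabeledWindow

logger = logging.getLogger(__name__)


@dataclass
class PsdEstimate:
    freqs_hz: np.ndarray
    power: np.ndarray  # (n_channels, n_bins)
    nfft: int
    normalized: bool
    channels: list[str]


@dataclass
class BandSpec:
    """Equal-width band partition of the frequency range of interest."""

    low_hz: float = 0.05
    high_hz: float = 0.7
    n_bands: int = 10
    edges: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.edges is None:
            self.edges = np.linspace(self.low_hz, self.high_hz, self.n_bands + 1)
        self.edges = np.asarray(self.edges, dtype=float)
        if len(self.edges) != self.n_bands + 1:
            raise ValueError("edges must have n_bands + 1 entries")
        if not np.all(np.diff(self.edges) > 0):
            raise ValueError("edges must be strictly increasing")
        if not (
            np.isclose(self.edges[0], self.low_hz)
            and np.isclose(self.edges[-1], self.high_hz)
        ):
            raise ValueError("edges must span exactly [low_hz, high_hz]")


def welch_psd(
    window: LabeledWindow,
    nfft: int = 16384,
    n_segments: int = 8,
    overlap: float = 0.5,
    normalize: bool = False,
) -> PsdEstimate:
    """Per-channel Welch PSD of one window.

    The window is split into ``n_segments`` Hamming-tapered segments with
    ``overlap`` fractional overlap, each zero-padded to ``nfft`` points
    (bin spacing = rate / nfft). ``normalize=True`` divides each channel by
    its total power so the bins sum to 1.
    """
    x = window.data  # (C, L)
    L = x.shape[1]
    nperseg = int(np.floor(L / (n_segments - (n_segments - 1) * overlap)))
    nperseg = max(min(nperseg, L), 8)
    if nfft < nperseg:
        raise ValueError(f"nfft={nfft} < segment length {nperseg}")
    freqs, psd = sps.welch(
        x,
        fs=window.sample_rate_hz,
        window="hamming",
        nperseg=nperseg,
        noverlap=int(np.floor(nperseg * overlap)),
        nfft=nfft,
        axis=-1,
    )
    if normalize:
        total = psd.sum(axis=-1, keepdims=True)
        total[total == 0] = 1.0
        psd = psd / total
    return PsdEstimate(
        freqs_hz=freqs,
        power=psd,
        nfft=nfft,
        normalized=normalize,
        channels=list(window.channels),
    )


def band_features(
    psd: PsdEstimate, bands: Optional[BandSpec] = None, normalize: bool = True
) -> np.ndarray:
    """Sum PSD bins into bands, per channel -> (n_channels, n_bands).

    Band ``b`` collects bins whose center lies in ``[edge_b, edge_{b+1})``
    (the last band is closed on the right). With ``normalize=True`` each
    channel's PSD is first divided by its total power, so the banded values
    sum to at most 1 (equality iff all power lies inside the band range).
    """
    bands = bands or BandSpec()
    if bands.high_hz > psd.freqs_hz[-1] + 1e-12:
        raise ValueError("band range extends beyond the PSD frequency range")
    power = psd.power
    if normalize and not psd.normalized:
        total = power.sum(axis=-1, keepdims=True)
        total = np.where(total == 0, 1.0, total)
        power = power / total
    out = np.empty((power.shape[0], bands.n_bands))
    for b in range(bands.n_bands):
        lo, hi = bands.edges[b], bands.edges[b + 1]
        if b == bands.n_bands - 1:
            sel = (psd.freqs_hz >= lo) & (psd.freqs_hz <= hi)
        else:
            sel = (psd.freqs_hz >= lo) & (psd.freqs_hz < hi)
        if not np.any(sel):
            raise ValueError(f"band {b} [{lo}, {hi}) Hz contains no PSD bins")
        out[:, b] = power[:, sel].sum(axis=-1)
    return out


@dataclass
class Standardizer:
    mean: np.ndarray
    sd: np.ndarray


@dataclass
class FeatureMatrix:
    """n_samples x n_features band-power features with provenance."""

    values: np.ndarray
    feature_names: list[str]
    labels: np.ndarray
    meta: pd.DataFrame
    standardization: Optional[Standardizer] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.feature_names) != len(set(self.feature_names)):
            raise ValueError("feature names must be unique")
        if self.values.shape[1] != len(self.feature_names):
            raise ValueError("values/feature_names shape mismatch")

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def subset(self, idx: np.ndarray) -> "FeatureMatrix":
        return FeatureMatrix(
            values=self.values[idx],
            feature_names=list(self.feature_names),
            labels=self.labels[idx],
            meta=self.meta.iloc[np.asarray(idx)].reset_index(drop=True),
            standardization=self.standardization,
        )


def featurize_windows(
    windows: list[LabeledWindow],
    bands: Optional[BandSpec] = None,
    nfft: int = 16384,
    normalize: bool = True,
    n_segments: int = 8,
) -> FeatureMatrix:
    """Band-power features for a list of windows (n_windows x C*n_bands)."""
    bands = bands or BandSpec()
    rows, labels, meta = [], [], []
    names: list[str] = []
    for w in windows:
        psd = welch_psd(w, nfft=nfft, n_segments=n_segments)
        feats = band_features(psd, bands, normalize=normalize)
        rows.append(feats.ravel())
        labels.append(w.label)
        meta.append(
            {
                "subject": w.subject_id,
                "condition": "feeding" if w.label else "baseline",
                "window_index": w.window_index,
            }
        )
        if not names:
            names = [
                f"{ch}_band{b}" for ch in w.channels for b in range(bands.n_bands)
            ]
    return FeatureMatrix(
        values=np.array(rows),
        feature_names=names,
        labels=np.array(labels),
        meta=pd.DataFrame(meta),
    )


def fit_standardizer(values: np.ndarray) -> Standardizer:
    """Per-feature mean and sample SD (ddof=1); zero SD replaced by 1."""
    values = np.asarray(values, dtype=float)
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=1) if values.shape[0] > 1 else np.ones(values.shape[1])
    zero = sd == 0
    if np.any(zero):
        warnings.warn(
            f"{int(zero.sum())} zero-variance feature(s); SD replaced by 1",
            stacklevel=2,
        )
        sd = np.where(zero, 1.0, sd)
    return Standardizer(mean=mean, sd=sd)


def apply_standardizer(stats: Standardizer, values: np.ndarray) -> np.ndarray:
    return (np.asarray(values, dtype=float) - stats.mean) / stats.sd


def invert_standardizer(stats: Standardizer, values: np.ndarray) -> np.ndarray:
    return np.asarray(values, dtype=float) * stats.sd + stats.mean


@dataclass
class SelectionResult:
    direction: str
    selected: np.ndarray  # boolean mask over features
    selection_frequency: np.ndarray
    objective_history: list[float]
    feature_names: list[str]
    move_order: list[int] = field(default_factory=list)  # indices added/removed, in order

    @property
    def selected_names(self) -> list[str]:
        return [n for n, s in zip(self.feature_names, self.selected) if s]

    @property
    def first_choice(self) -> Optional[str]:
        """Name of the first feature added (forward) or removed (backward)."""
        if not self.move_order:
            return None
        return self.feature_names[self.move_order[0]]


def _mc_cv_misclassification(
    X: np.ndarray,
    y: np.ndarray,
    classifier_spec,
    k: int,
    n_mc: int,
    rng: np.random.Generator,
) -> float:
    """Monte-Carlo-averaged k-fold misclassification with fold-local z-scoring."""
    from .shallow import train_classifier  # deferred: avoids a cycle

    errs = []
    for _ in range(n_mc):
        skf = StratifiedKFold(
            n_splits=k, shuffle=True, random_state=int(rng.integers(2**31 - 1))
        )
        for tr, va in skf.split(X, y):
            stats = fit_standardizer(X[tr])
            try:
                model = train_classifier(
                    classifier_spec, apply_standardizer(stats, X[tr]), y[tr]
                )
            except Exception as exc:
                logger.warning("classifier failed during selection: %s", exc)
                errs.append(1.0)
                continue
            pred = model.score(apply_standardizer(stats, X[va])) >= 0.5
            errs.append(float(np.mean(pred != y[va])))
    return float(np.mean(errs))


def sequential_select(
    features: FeatureMatrix,
    classifier_spec,
    direction: str = "forward",
    k: int = 3,
    n_mc: int = 100,
    seed: int = 0,
    tol: float = 1e-6,
    max_steps: Optional[int] = None,
) -> SelectionResult:
    """Greedy sequential feature selection minimizing CV misclassification.

    Forward starts from the empty set and adds the best feature each step;
    backward starts from the full set and removes the most dispensable one.
    A step is taken only if it strictly improves the Monte-Carlo-averaged
    ``k``-fold misclassification rate by more than ``tol``.
    """
    if direction not in ("forward", "backward"):
        raise ValueError(f"direction must be 'forward' or 'backward', got {direction}")
    if n_mc < 1:
        raise ValueError(f"n_mc must be >= 1, got {n_mc}")
    y = features.labels
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present for selection")
    X = features.values
    n_feat = X.shape[1]
    master = np.random.default_rng(seed)

    def objective(mask: np.ndarray) -> float:
        if not mask.any():
            # majority-class error rate for the empty set
            return float(1.0 - np.bincount(y).max() / len(y))
        # fresh but seed-derived stream so candidate evaluations share folds
        return _mc_cv_misclassification(
            X[:, mask], y, classifier_spec, k, n_mc, np.random.default_rng(step_seed)
        )

    selected = np.zeros(n_feat, dtype=bool) if direction == "forward" else np.ones(
        n_feat, dtype=bool
    )
    step_seed = int(master.integers(2**31 - 1))
    best_obj = objective(selected)
    history = [best_obj]
    move_order: list[int] = []
    while max_steps is None or len(move_order) < max_steps:
        candidates = np.flatnonzero(~selected if direction == "forward" else selected)
        if candidates.size == 0:
            break
        step_seed = int(master.integers(2**31 - 1))
        scores = []
        for j in candidates:
            trial = selected.copy()
            trial[j] = direction == "forward"
            scores.append(objective(trial))
        best_i = int(np.argmin(scores))
        if scores[best_i] < best_obj - tol:
            j = int(candidates[best_i])
            selected[j] = direction == "forward"
            best_obj = scores[best_i]
            history.append(best_obj)
            move_order.append(j)
        else:
            break
    return SelectionResult(
        direction=direction,
        selected=selected,
        selection_frequency=selected.astype(float),
        objective_history=history,
        feature_names=list(features.feature_names),
        move_order=move_order,
    )


def selection_frequency_map(
    features: FeatureMatrix,
    classifier_specs: dict,
    direction: str = "forward",
    n_repeats: int = 10,
    k: int = 3,
    n_mc: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-classifier fraction of repeats in which each feature was selected.

    Row sums equal each classifier's mean selected-set size by construction.
    """
    rows = {}
    for name, spec in classifier_specs.items():
        masks = []
        for r in range(n_repeats):
            res = sequential_select(
                features, spec, direction=direction, k=k, n_mc=n_mc, seed=seed + r
            )
            masks.append(res.selected.astype(float))
        rows[name] = np.mean(masks, axis=0)
    return pd.DataFrame(rows, index=features.feature_names).T


def features_to_csv(features: FeatureMatrix, path) -> None:
    df = features.meta.copy()
    for i, name in enumerate(features.feature_names):
        df[name] = features.values[:, i]
    df["label"] = features.labels
    df.to_csv(path, index=False)


def features_from_csv(path) -> FeatureMatrix:
    df = pd.read_csv(path)
    meta_cols = [c for c in ("subject", "condition", "window_index") if c in df.columns]
    feat_cols = [c for c in df.columns if c not in meta_cols + ["label"]]
    return FeatureMatrix(
        values=df[feat_cols].to_numpy(),
        feature_names=feat_cols,
        labels=df["label"].to_numpy(),
        meta=df[meta_cols].copy(),
    )
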