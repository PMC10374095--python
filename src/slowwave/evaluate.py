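"""ROC/AUC, thresholded metrics, repeated cross-validation and CSV reports.

Conventions: sensitivity is the true-positive rate on label 1 (feeding
detection), specificity the true-negative rate on label 0 (baseline
detection); predictions use ``score >= threshold`` (boundary inclusive);
ROC ties follow the midpoint convention, so the trapezoidal AUC equals the
pair statistic P(score_pos > score_neg) + 0.5 P(tie).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional

import numpy as np
import pandas as pd
from sklearn import metrics as skm

from .records import ScoreSet
from .windows import make_folds

logger = logging.getLogger(__name__)


@dataclass
class RocCurve:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


@dataclass
class MetricReport:
    """Mean/SD of accuracy, sensitivity and specificity over CV repeats (%)."""

    classifier: str
    threshold: float
    n_repeats: int
    per_repeat: pd.DataFrame  # columns: repeat, accuracy, sensitivity, specificity
    means: dict[str, float] = field(default_factory=dict)
    sds: dict[str, float] = field(default_factory=dict)
    per_subject: Optional[pd.DataFrame] = None
    failed_repeats: list[int] = field(default_factory=list)


def roc_auc(scores: ScoreSet) -> RocCurve:
    """ROC over all distinct thresholds with trapezoidal AUC."""
    labels, s = scores.labels, scores.scores
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC requires both classes present")
    fpr, tpr, thr = skm.roc_curve(labels, s)
    return RocCurve(thresholds=thr, fpr=fpr, tpr=tpr, auc=float(skm.auc(fpr, tpr)))


def pair_count_auc(scores: ScoreSet) -> float:
    """O(n^2) oracle: P(score_pos > score_neg) + 0.5 P(tie)."""
    pos = scores.scores[scores.labels == 1]
    neg = scores.scores[scores.labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("ROC requires both classes present")
    diff = pos[:, None] - neg[None, :]
    return float(((diff > 0).sum() + 0.5 * (diff == 0).sum()) / diff.size)


def threshold_metrics(scores: ScoreSet, threshold: float = 0.5) -> dict[str, float]:
    """Accuracy / sensitivity / specificity (%) at a fixed threshold."""
    labels, s = scores.labels, scores.scores
    if len(np.unique(labels)) < 2:
        raise ValueError("threshold metrics require both classes present")
    pred = (s >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (labels == 1)))
    tn = int(np.sum((pred == 0) & (labels == 0)))
    fp = int(np.sum((pred == 1) & (labels == 0)))
    fn = int(np.sum((pred == 0) & (labels == 1)))
    return {
        "accuracy": 100.0 * (tp + tn) / len(labels),
        "sensitivity": 100.0 * tp / (tp + fn),
        "specificity": 100.0 * tn / (tn + fp),
    }


def repeated_cv(
    make_pipeline: Callable[[], "Pipeline"],
    windows,
    n_repeats: int = 10,
    k: int = 3,
    seed: int = 0,
    threshold: float = 0.5,
    classifier_name: str = "",
    group_by_subject: bool = False,
) -> tuple[MetricReport, ScoreSet]:
    """Repeat k-fold CV with fresh seeded fold plans; aggregate metrics.

    ``make_pipeline()`` returns a fresh object with ``fit(train_idx)`` and
    ``score(val_idx) -> scores`` bound to ``windows``. Failed repeats are
    recorded and excluded rather than aborting the report. Returns the
    report plus the pooled validation scores of the last complete repeat
    (one pooled curve per method).
    """
    subjects = np.array([w.subject_id for w in windows])
    labels = np.array([w.label for w in windows])
    rows, failed = [], []
    pooled_all_scores, pooled_all_labels, pooled_all_subj = [], [], []
    last_pooled: Optional[ScoreSet] = None
    for rep in range(n_repeats):
        try:
            plan = make_folds(
                list(windows), n_folds=k, seed=seed + rep,
                group_by_subject=group_by_subject,
            )
            pool_scores = np.empty(len(windows))
            for train_idx, val_idx in plan:
                pipe = make_pipeline()
                pipe.fit(train_idx)
                pool_scores[val_idx] = pipe.score(val_idx)
            pooled = ScoreSet(
                scores=pool_scores, labels=labels,
                fold_ids=plan.assignments, classifier=classifier_name,
                subject_ids=subjects,
            )
            m = threshold_metrics(pooled, threshold)
            rows.append({"repeat": rep, **m})
            pooled_all_scores.append(pool_scores)
            pooled_all_labels.append(labels)
            pooled_all_subj.append(subjects)
            last_pooled = pooled
        except Exception as exc:
            logger.warning("repeat %d failed: %s", rep, exc)
            failed.append(rep)
    if not rows:
        raise RuntimeError("all CV repeats failed")
    per_repeat = pd.DataFrame(rows)
    means = {c: float(per_repeat[c].mean()) for c in ("accuracy", "sensitivity", "specificity")}
    sds = {c: float(per_repeat[c].std(ddof=1)) if len(per_repeat) > 1 else 0.0
           for c in ("accuracy", "sensitivity", "specificity")}

    # per-subject breakdown from validation scores pooled over all repeats
    all_scores = np.concatenate(pooled_all_scores)
    all_labels = np.concatenate(pooled_all_labels)
    all_subj = np.concatenate(pooled_all_subj)
    subj_rows = []
    for subj in np.unique(all_subj):
        sel = all_subj == subj
        y, s = all_labels[sel], all_scores[sel]
        pred = (s >= threshold).astype(int)
        # a subject may have only one class pooled; report what is defined
        sm = {
            "accuracy": 100.0 * float(np.mean(pred == y)),
            "sensitivity": 100.0 * float(np.mean(pred[y == 1] == 1))
            if (y == 1).any() else np.nan,
            "specificity": 100.0 * float(np.mean(pred[y == 0] == 0))
            if (y == 0).any() else np.nan,
        }
        subj_rows.append({"subject": subj, **sm})
    report = MetricReport(
        classifier=classifier_name,
        threshold=threshold,
        n_repeats=n_repeats,
        per_repeat=per_repeat,
        means=means,
        sds=sds,
        per_subject=pd.DataFrame(subj_rows),
        failed_repeats=failed,
    )
    return report, last_pooled


class Pipeline:
    """Interface expected by :func:`repeated_cv` (duck-typed)."""

    def fit(self, train_idx: np.ndarray) -> None:  # pragma: no cover
        raise NotImplementedError

    def score(self, idx: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class ShallowPipeline(Pipeline):
    """Featurize -> z-score -> (optional selection) -> shallow classifier."""

    def __init__(self, features, spec, selection_mask=None):
        from .spectral import FeatureMatrix  # local import keeps deps one-way

        assert isinstance(features, FeatureMatrix)
        self.features = features
        self.spec = spec
        self.mask = (
            np.ones(features.n_features, dtype=bool)
            if selection_mask is None
            else np.asarray(selection_mask, dtype=bool)
        )
        self._model = None
        self._stats = None
        #: audit trail proving fold hygiene: which sample indices the
        #: training-fold statistics were fit on vs which were scored
        self.audit: dict[str, list[int]] = {"fit": [], "score": []}

    def fit(self, train_idx):
        from .spectral import apply_standardizer, fit_standardizer
        from .shallow import train_classifier

        train_idx = np.asarray(train_idx)
        self.audit["fit"] = [int(i) for i in train_idx]
        X = self.features.values[train_idx][:, self.mask]
        y = self.features.labels[train_idx]
        self._stats = fit_standardizer(X)
        self._model = train_classifier(self.spec, apply_standardizer(self._stats, X), y)

    def score(self, idx):
        from .spectral import apply_standardizer

        idx = np.asarray(idx)
        self.audit["score"].extend(int(i) for i in idx)
        X = self.features.values[idx][:, self.mask]
        return self._model.score(apply_standardizer(self._stats, X))


class CnnPipeline(Pipeline):
    """Train the residual CNN on raw windows; score held-out windows."""

    def __init__(self, windows, cnn_cfg=None, train_cfg=None, val_fraction=0.0):
        from .resnet1d import CnnConfig, TrainConfig

        self.X = np.stack([w.data for w in windows]).astype("float32")
        self.y = np.array([w.label for w in windows], dtype=int)
        self.cnn_cfg = cnn_cfg or CnnConfig(in_channels=self.X.shape[1])
        self.train_cfg = train_cfg or TrainConfig()
        self.val_fraction = val_fraction
        self._model = None

    def fit(self, train_idx):
        from .resnet1d import build_model, train_model

        train_idx = np.asarray(train_idx)
        model = build_model(self.cnn_cfg, input_len=self.X.shape[2])
        if self.val_fraction > 0:
            # optional inner split for early stopping
            rng = np.random.default_rng(self.train_cfg.seed)
            perm = rng.permutation(train_idx)
            n_val = max(int(len(perm) * self.val_fraction), 1)
            val_idx, fit_idx = perm[:n_val], perm[n_val:]
        else:
            # held-out fold unavailable here; early-stop on the training set
            fit_idx = val_idx = train_idx
        self._model, _ = train_model(
            model,
            (self.X[fit_idx], self.y[fit_idx]),
            (self.X[val_idx], self.y[val_idx]),
            self.train_cfg,
        )

    def score(self, idx):
        idx = np.asarray(idx)
        return self._model.predict(self.X[idx])


def render_reports(
    out_dir,
    metric_reports: dict[str, MetricReport],
    roc_curves: Optional[dict[str, RocCurve]] = None,
    selection_frequency: Optional[pd.DataFrame] = None,
    plots: bool = False,
) -> list[Path]:
    """Write CSV reports (and optional PNG plots); returns written paths."""
    if not metric_reports:
        raise ValueError("nothing to report: no evaluated pipelines")
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create report directory {out_dir}: {exc}") from exc
    written = []

    rows = []
    for name, rep in metric_reports.items():
        row = {"classifier": name, "n_repeats": rep.n_repeats, "threshold": rep.threshold}
        for metric in ("accuracy", "sensitivity", "specificity"):
            row[f"{metric}_mean"] = rep.means[metric]
            row[f"{metric}_sd"] = rep.sds[metric]
        rows.append(row)
    path = out_dir / "metrics.csv"
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.6f")
    written.append(path)

    for name, rep in metric_reports.items():
        if rep.per_subject is not None:
            path = out_dir / f"per_subject_{name}.csv"
            rep.per_subject.to_csv(path, index=False, float_format="%.6f")
            written.append(path)

    for name, curve in (roc_curves or {}).items():
        path = out_dir / f"roc_{name}.csv"
        pd.DataFrame(
            {"threshold": curve.thresholds, "fpr": curve.fpr, "tpr": curve.tpr}
        ).assign(auc=curve.auc).to_csv(path, index=False, float_format="%.6f")
        written.append(path)

    if selection_frequency is not None:
        path = out_dir / "selection_frequency.csv"
        selection_frequency.to_csv(path, float_format="%.6f")
        written.append(path)

    if plots and roc_curves:
        written.append(_plot_roc(out_dir, roc_curves))
    return written


def _plot_roc(out_dir: Path, roc_curves: dict[str, RocCurve]) -> Path:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for name, curve in roc_curves.items():
        ax.plot(curve.fpr, curve.tpr, label=f"{name} (AUC={curve.auc:.2f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("False positive rate")
    ax.set_ylabel("True positive rate")
    ax.legend(loc="lower right", fontsize=8)
    path = out_dir / "roc.png"
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return path
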