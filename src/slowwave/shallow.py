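"""Hand-crafted-feature classifiers with posterior scores in [0, 1].

Six kinds are supported: linear/RBF SVM, linear and quadratic discriminant
analysis, (unpenalized) logistic regression and random forest. Margin
classifiers (the SVMs) get a Platt-style sigmoid fitted on training scores
so every model exposes the same ``score() -> [0, 1]`` contract
(1 = feeding).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit
from sklearn.discriminant_analysis import (
    LinearDiscriminantAnalysis,
    QuadraticDiscriminantAnalysis,
)
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import pairwise_distances
from sklearn.svm import SVC

CLASSIFIER_KINDS = ("svm_linear", "svm_rbf", "lda", "qda", "logistic", "random_forest")


@dataclass
class ClassifierSpec:
    kind: str
    hyperparams: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in CLASSIFIER_KINDS:
            raise ValueError(
                f"kind must be one of {CLASSIFIER_KINDS}, got {self.kind!r}"
            )


def default_specs(seed: int = 0) -> dict[str, ClassifierSpec]:
    return {kind: ClassifierSpec(kind=kind, seed=seed) for kind in CLASSIFIER_KINDS}


def _median_heuristic_gamma(X: np.ndarray) -> float:
    """RBF width from the median pairwise distance: gamma = 1 / (2 sigma^2)."""
    n = X.shape[0]
    if n > 500:  # subsample for the heuristic only
        rng = np.random.default_rng(0)
        X = X[rng.choice(n, 500, replace=False)]
    d = pairwise_distances(X)
    med = np.median(d[np.triu_indices_from(d, k=1)])
    if not np.isfinite(med) or med <= 0:
        return 1.0
    return 1.0 / (2.0 * med**2)


@dataclass
class PlattMap:
    """Strictly increasing sigmoid score -> posterior map.

    Parametrized as ``expit(exp(alpha) * s + beta)`` so the slope is always
    positive, which guarantees ROC/AUC of mapped scores equals that of the
    raw margins. Degenerate (constant) margins collapse to a constant 0.5.
    """

    alpha: float
    beta: float
    constant: bool = False

    def __call__(self, s: np.ndarray) -> np.ndarray:
        s = np.asarray(s, dtype=float)
        if self.constant:
            return np.full_like(s, 0.5)
        return expit(np.exp(self.alpha) * s + self.beta)


def score_to_posterior(scores: np.ndarray, labels: np.ndarray) -> PlattMap:
    """Fit a monotone sigmoid posterior map on training-fold margins.

    Uses soft targets (the standard trick against divergence on separable
    margins) and floors the slope so the map stays strictly increasing even
    when the margins carry no, or inverted, class information.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if np.ptp(scores) == 0:
        warnings.warn("degenerate (all-equal) margins; posterior map is constant 0.5",
                      stacklevel=2)
        return PlattMap(alpha=0.0, beta=0.0, constant=True)
    n_pos = labels.sum()
    n_neg = len(labels) - n_pos
    targets = np.where(
        labels > 0.5, (n_pos + 1.0) / (n_pos + 2.0), 1.0 / (n_neg + 2.0)
    )
    scale = np.std(scores)
    alpha_floor = np.log(1e-6 / scale)

    def nll(params):
        a, b = params
        z = np.exp(max(a, alpha_floor)) * scores + b
        return float(np.mean(np.logaddexp(0.0, z) - targets * z))

    best = None
    for a0 in (np.log(1.0 / scale), 0.0):
        res = minimize(nll, x0=[a0, 0.0], method="Nelder-Mead",
                       options={"xatol": 1e-8, "fatol": 1e-12, "maxiter": 2000})
        if best is None or res.fun < best.fun:
            best = res
    return PlattMap(
        alpha=float(max(best.x[0], alpha_floor)), beta=float(best.x[1])
    )


@dataclass
class TrainedModel:
    spec: ClassifierSpec
    estimator: object
    platt: Optional[PlattMap] = None

    def score(self, X: np.ndarray) -> np.ndarray:
        """Posterior-style score in [0, 1]; 1 = feeding."""
        X = np.asarray(X, dtype=float)
        if self.platt is not None:
            return self.platt(self.estimator.decision_function(X))
        proba = self.estimator.predict_proba(X)
        out = proba[:, list(self.estimator.classes_).index(1)]
        if not np.all(np.isfinite(out)):
            raise ValueError(f"{self.spec.kind} produced non-finite scores")
        return out

    def margins(self, X: np.ndarray) -> np.ndarray:
        """Raw decision scores before any posterior mapping."""
        if hasattr(self.estimator, "decision_function"):
            return self.estimator.decision_function(np.asarray(X, dtype=float))
        return self.score(X)


def _build_estimator(spec: ClassifierSpec, X: np.ndarray):
    hp = dict(spec.hyperparams)
    if spec.kind == "svm_linear":
        return SVC(kernel="linear", C=hp.get("C", 1.0))
    if spec.kind == "svm_rbf":
        gamma = hp.get("gamma", _median_heuristic_gamma(X))
        return SVC(kernel="rbf", C=hp.get("C", 1.0), gamma=gamma)
    if spec.kind == "lda":
        return LinearDiscriminantAnalysis(**hp)
    if spec.kind == "qda":
        # normalized band powers are collinear (they sum to ~1 per channel),
        # so an unregularized class covariance is singular at small n
        hp.setdefault("reg_param", 0.1)
        return QuadraticDiscriminantAnalysis(**hp)
    if spec.kind == "logistic":
        return LogisticRegression(penalty=None, max_iter=hp.get("max_iter", 1000))
    if spec.kind == "random_forest":
        return RandomForestClassifier(
            n_estimators=hp.get("n_estimators", 100), random_state=spec.seed
        )
    raise ValueError(f"unknown classifier kind {spec.kind!r}")  # pragma: no cover


def train_classifier(
    spec: ClassifierSpec, X: np.ndarray, y: np.ndarray
) -> TrainedModel:
    """Fit one classifier; returns a model exposing ``score() -> [0, 1]``.

    Margin models additionally get a Platt map fitted on the training fold
    only (validation data never touches the map).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError(f"training labels contain a single class: {classes}")
    if spec.kind == "qda":
        _check_qda_covariances(X, y)
    est = _build_estimator(spec, X)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est.fit(X, y)
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"{spec.kind}: singular covariance ({exc})") from exc
    platt = None
    if spec.kind in ("svm_linear", "svm_rbf"):
        platt = score_to_posterior(est.decision_function(X), y)
    return TrainedModel(spec=spec, estimator=est, platt=platt)


def _check_qda_covariances(X: np.ndarray, y: np.ndarray) -> None:
    """Reject plainly degenerate inputs with a readable message."""
    for cls in np.unique(y):
        Xc = X[y == cls]
        var = Xc.var(axis=0)
        if np.any(var == 0):
            dead = np.flatnonzero(var == 0).tolist()
            raise ValueError(
                f"QDA: covariance of class {cls} is singular "
                f"(zero-variance feature(s) {dead})"
            )
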