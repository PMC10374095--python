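"""Training loop: BCE-with-logits loss, AdamW, patience-based early stopping."""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from ..records import LabeledWindow, ScoreSet
from .network import CnnConfig, ResNet1d


@dataclass
class TrainConfig:
    max_epochs: int = 200
    batch_size: int = 20
    learning_rate: float = 1e-3
    patience: int = 50
    weight_decay: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.patience >= self.max_epochs:
            raise ValueError("patience must be < max_epochs")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclass
class TrainHistory:
    train_loss: list = field(default_factory=list)
    val_loss: list = field(default_factory=list)
    best_epoch: int = 0  # 1-based
    stopped_early: bool = False
    best_val_loss: float = float("inf")

    @property
    def epochs(self) -> int:
        return len(self.val_loss)


class EarlyStopper:
    """Tracks the best validation loss; stops after ``patience`` stale epochs."""

    def __init__(self, patience: int):
        self.patience = patience
        self.best_loss = float("inf")
        self.best_epoch = 0

    def update(self, epoch: int, loss: float) -> bool:
        """Record epoch's validation loss; return True when training should stop."""
        if loss < self.best_loss:
            self.best_loss = loss
            self.best_epoch = epoch
        return epoch - self.best_epoch >= self.patience


def bce_with_logits(logits: np.ndarray, labels: np.ndarray):
    """Mean binary cross-entropy from logits; returns (loss, dloss/dlogits)."""
    z = np.asarray(logits, dtype=np.float64)
    y = np.asarray(labels, dtype=np.float64)
    with np.errstate(invalid="ignore", over="ignore"):
        loss = float(np.mean(np.logaddexp(0.0, z) - y * z))
        grad = (1.0 / (1.0 + np.exp(-z)) - y) / len(z)
    return loss, grad


class AdamW:
    """Adam with decoupled weight decay (applied to decay-flagged params only)."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8, weight_decay=0.01):
        self.params = list(params)
        self.lr, self.betas, self.eps, self.weight_decay = lr, betas, eps, weight_decay
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for i, p in enumerate(self.params):
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            if p.decay and self.weight_decay:
                p.value -= self.lr * self.weight_decay * p.value
            p.value -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(
                p.value.dtype
            )


class DivergenceError(RuntimeError):
    """Raised when training loss becomes non-finite; carries the history."""

    def __init__(self, message: str, history: TrainHistory):
        super().__init__(message)
        self.history = history


def _as_tensor(windows, dtype) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(windows, tuple):
        X, y = windows
        return np.asarray(X, dtype=dtype), np.asarray(y, dtype=int)
    X = np.stack([w.data for w in windows]).astype(dtype)
    y = np.array([w.label for w in windows], dtype=int)
    return X, y


def _eval_loss(model: ResNet1d, X, y, batch_size: int) -> float:
    losses, weights = [], []
    for start in range(0, len(X), batch_size):
        xb, yb = X[start : start + batch_size], y[start : start + batch_size]
        logits = model.forward_logits(xb, training=False, keep_cache=False)
        loss, _ = bce_with_logits(logits, yb)
        losses.append(loss)
        weights.append(len(xb))
    return float(np.average(losses, weights=weights))


def train_model(
    model: ResNet1d,
    train_windows,
    val_windows,
    tcfg: Optional[TrainConfig] = None,
) -> tuple[ResNet1d, TrainHistory]:
    """Train with AdamW + early stopping; returns the best-validation model.

    ``train_windows``/``val_windows`` are either lists of
    :class:`~slowwave.records.LabeledWindow` or ``(X, y)`` tuples with ``X``
    shaped ``(n, channels, length)``. The checkpoint kept (and loaded back
    into the returned model) is the one attaining the minimum validation
    loss; training halts at ``best_epoch + patience`` epochs or
    ``max_epochs``, whichever comes first.
    """
    tcfg = tcfg or TrainConfig()
    Xtr, ytr = _as_tensor(train_windows, model.dtype)
    Xva, yva = _as_tensor(val_windows, model.dtype)
    if len(np.unique(ytr)) < 2:
        raise ValueError("training set must contain both classes")
    if len(Xva) == 0:
        raise ValueError("validation set must be non-empty")

    rng = np.random.default_rng(tcfg.seed)
    opt = AdamW(
        model.params(), lr=tcfg.learning_rate, weight_decay=tcfg.weight_decay
    )
    stopper = EarlyStopper(tcfg.patience)
    history = TrainHistory()
    best_state = model.state_dict()

    for epoch in range(1, tcfg.max_epochs + 1):
        order = rng.permutation(len(Xtr))
        epoch_losses, epoch_sizes = [], []
        for start in range(0, len(order), tcfg.batch_size):
            idx = order[start : start + tcfg.batch_size]
            model.zero_grad()
            logits = model.forward_logits(Xtr[idx], training=True, rng=rng)
            loss, dlogits = bce_with_logits(logits, ytr[idx])
            if not np.isfinite(loss):
                raise DivergenceError(
                    f"training loss diverged at epoch {epoch}", history
                )
            model.backward(dlogits)
            opt.step()
            epoch_losses.append(loss)
            epoch_sizes.append(len(idx))
        history.train_loss.append(float(np.average(epoch_losses, weights=epoch_sizes)))
        val_loss = _eval_loss(model, Xva, yva, tcfg.batch_size)
        history.val_loss.append(val_loss)
        if val_loss < stopper.best_loss:
            best_state = model.state_dict()
        if stopper.update(epoch, val_loss):
            history.stopped_early = True
            break

    history.best_epoch = stopper.best_epoch
    history.best_val_loss = stopper.best_loss
    model.load_state_dict(best_state)
    return model, history


def score_windows(model: ResNet1d, windows, batch_size: int = 20) -> ScoreSet:
    """Eval-mode scores for a list of windows (dropout off, BN running stats)."""
    if isinstance(windows, tuple):
        X, y = _as_tensor(windows, model.dtype)
        subjects = None
    else:
        X, y = _as_tensor(windows, model.dtype)
        subjects = np.array([w.subject_id for w in windows])
    if X.shape[1] != model.cfg.in_channels:
        raise ValueError(
            f"channel-count mismatch: expected {model.cfg.in_channels}, "
            f"got {X.shape[1]}"
        )
    scores = np.concatenate(
        [
            model.predict(X[start : start + batch_size])
            for start in range(0, len(X), batch_size)
        ]
    )
    return ScoreSet(scores=scores, labels=y, classifier="cnn", subject_ids=subjects)


def save_checkpoint(model: ResNet1d, history: TrainHistory, path) -> None:
    """Persist weights (.npz) with a JSON sidecar (config + history)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, **model.state_dict())
    sidecar = {
        "config": {**model.cfg.__dict__, "block_channels": list(model.cfg.block_channels)},
        "input_len": model.input_len,
        "history": {
            "train_loss": history.train_loss,
            "val_loss": history.val_loss,
            "best_epoch": history.best_epoch,
            "stopped_early": history.stopped_early,
            "best_val_loss": history.best_val_loss,
        },
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_checkpoint(path) -> tuple[ResNet1d, dict]:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    cfg_dict = dict(sidecar["config"])
    cfg_dict["block_channels"] = tuple(cfg_dict["block_channels"])
    cfg = CnnConfig(**cfg_dict)
    model = ResNet1d(cfg, sidecar["input_len"])
    with np.load(path if path.suffix == ".npz" else path.with_suffix(".npz")) as data:
        model.load_state_dict({k: data[k] for k in data.files})
    return model, sidecar
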