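"""Training loop, data splits, and evaluation metrics.

Defaults follow the study protocol: Adam with learning rate 1e-4, batch
size 32, a fixed epoch budget with the best-on-validation parameters
retained, a contiguous 6:2:2 ratio split in window order (no shuffling
across the split boundary), and a 16/8 trial split as the alternative.
Metrics are accuracy, macro/binary F1, sample standard deviation across
report groups, and rank-based AUC (ties counted half).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import f1_score as _sk_f1
from sklearn.metrics import roc_auc_score

from . import nn
from .model import ConvBiLSTMAttention
from .types import ConfigurationError, ValidationError

__all__ = [
    "TrainConfig",
    "split_data",
    "fit",
    "f1_score",
    "std",
    "auc",
    "evaluate",
    "EvalReport",
]


@dataclass
class TrainConfig:
    lr: float = 1e-4
    batch_size: int = 32
    epochs: int = 500
    seed: int = 0
    split: str = "ratio-6:2:2"
    train_trials: int = 16  # used by the "trial-16:8" split
    test_trials: int = 8

    def __post_init__(self) -> None:
        if self.lr < 0:
            raise ConfigurationError("lr must be >= 0")
        if self.batch_size < 1:
            raise ConfigurationError("batch_size must be >= 1")
        if self.split not in ("ratio-6:2:2", "trial-16:8"):
            raise ConfigurationError(f"unknown split {self.split!r}")


def split_data(
    X: np.ndarray,
    y: np.ndarray,
    cfg: TrainConfig | None = None,
    trial_ids: np.ndarray | None = None,
):
    """Partition sequences into (train, val, test) per the configured split.

    Ratio mode slices contiguously in time order — the first 60% trains,
    the next 20% validates, the last 20% tests.  Trial mode assigns the
    first ``train_trials`` trial indices to training and the following
    ``test_trials`` to test (validation reuses the test block, mirroring a
    train/test protocol).
    """
    if cfg is None:
        cfg = TrainConfig()
    X = np.asarray(X)
    y = np.asarray(y)
    if len(X) != len(y):
        raise ValidationError("X and y misaligned")
    if cfg.split == "ratio-6:2:2":
        n = len(X)
        a, b = int(n * 0.6), int(n * 0.8)
        if a == 0 or b == a or b == n:
            raise ValidationError(f"too few samples ({n}) for a 6:2:2 split")
        return (X[:a], y[:a]), (X[a:b], y[a:b]), (X[b:], y[b:])
    if trial_ids is None:
        raise ValidationError("trial-16:8 split requires trial_ids")
    trial_ids = np.asarray(trial_ids)
    uniq = np.unique(trial_ids)
    need = cfg.train_trials + cfg.test_trials
    if len(uniq) < need:
        raise ValidationError(f"trial split needs >= {need} trials, got {len(uniq)}")
    train_set = set(uniq[: cfg.train_trials].tolist())
    test_set = set(uniq[cfg.train_trials : need].tolist())
    tr = np.array([t in train_set for t in trial_ids])
    te = np.array([t in test_set for t in trial_ids])
    return (X[tr], y[tr]), (X[te], y[te]), (X[te], y[te])


def fit(
    model: ConvBiLSTMAttention,
    train: tuple[np.ndarray, np.ndarray],
    val: tuple[np.ndarray, np.ndarray] | None,
    cfg: TrainConfig | None = None,
) -> dict:
    """Train with Adam + cross-entropy; retain best-on-validation weights.

    Returns a history dict with per-epoch mean training loss, validation
    loss and validation accuracy.  The retained checkpoint is the one with
    the lowest validation cross-entropy (accuracy saturates early on
    separable data and cannot discriminate between checkpoints).  Training
    is deterministic for a fixed seed.  Divergence (non-finite loss)
    raises with the epoch index.
    """
    if cfg is None:
        cfg = TrainConfig()
    Xtr, ytr = np.asarray(train[0], dtype=np.float64), np.asarray(train[1], dtype=np.int64)
    rng = np.random.default_rng(cfg.seed)
    opt = nn.Adam(model.params(), lr=cfg.lr)
    history = {"loss": [], "val_loss": [], "val_acc": []}
    best_state = model.get_state()
    best_val = np.inf
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(Xtr))
        losses = []
        for start in range(0, len(Xtr), cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            logits, _ = model.forward(Xtr[idx])
            loss = nn.cross_entropy_logits(logits, ytr[idx])
            if not math.isfinite(loss.data):
                raise RuntimeError(f"training diverged (non-finite loss) at epoch {epoch}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        history["loss"].append(float(np.mean(losses)))
        if val is not None and len(val[0]):
            yva = np.asarray(val[1], dtype=np.int64)
            vlogits, _ = model.forward(np.asarray(val[0], dtype=np.float64))
            vloss = float(nn.cross_entropy_logits(vlogits, yva).data)
            vacc = float(np.mean(vlogits.data.argmax(axis=1) == yva))
            history["val_loss"].append(vloss)
            history["val_acc"].append(vacc)
            if vloss < best_val:
                best_val = vloss
                best_state = model.get_state()
    if val is not None and len(val[0]):
        model.set_state(best_state)
    return history


# ---- metrics -------------------------------------------------------------
def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean F1 = 2·P·R/(P+R); 0 by convention when both are 0."""
    if not (0 <= precision <= 1 and 0 <= recall <= 1):
        raise ValueError("precision and recall must lie in [0, 1]")
    if precision == recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def std(values) -> float:
    """Sample standard deviation S = sqrt(Σ(x_i − x̄)²/(N−1))."""
    values = np.asarray(values, dtype=np.float64)
    if values.size < 2:
        raise ValueError("std requires at least two values")
    return float(np.std(values, ddof=1))


def auc(scores, labels) -> float:
    """Rank AUC: probability a positive score ranks above a negative one,
    ties counted half.  Equals the trapezoidal ROC area."""
    labels = np.asarray(labels)
    if len(set(labels.tolist())) < 2:
        raise ValueError("AUC requires both classes present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=np.float64)))


@dataclass
class EvalReport:
    """Per-group and aggregate test metrics; mirrors a subjects × metrics table."""

    group_accuracy: dict[str, float]
    accuracy: float            # mean over groups, percent
    std: float                 # sample std of group accuracies
    f1: float
    auc: float | None
    confusion: np.ndarray
    n_samples: int
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "group_accuracy": self.group_accuracy,
            "accuracy": self.accuracy,
            "std": self.std,
            "f1": self.f1,
            "auc": self.auc,
            "confusion": self.confusion.tolist(),
            "n_samples": self.n_samples,
            **self.extras,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, **kwargs)

    def to_frame(self):
        import pandas as pd

        rows = [{"group": g, "accuracy": a} for g, a in self.group_accuracy.items()]
        return pd.DataFrame(rows)


def evaluate(
    model: ConvBiLSTMAttention,
    test: tuple[np.ndarray, np.ndarray],
    grouping: np.ndarray | None = None,
) -> EvalReport:
    """Accuracy (percent, per group and mean), STD across groups, F1, AUC.

    ``grouping`` assigns each test sequence to a report unit (subject or
    session); with no grouping the whole set is one unit and STD is 0.
    F1 is binary for 2 classes, macro-averaged otherwise; AUC is binary
    only, mean one-vs-rest otherwise.
    """
    X, y = np.asarray(test[0]), np.asarray(test[1], dtype=np.int64)
    if len(X) == 0:
        raise ValidationError("test set is empty")
    pred = model.predict(X)
    proba = model.predict_proba(X)
    n_classes = proba.shape[1]

    if grouping is None:
        grouping = np.zeros(len(y), dtype=np.int64)
    grouping = np.asarray(grouping)
    group_acc = {}
    for g in np.unique(grouping):
        m = grouping == g
        if not m.any():
            continue
        group_acc[str(g)] = float(np.mean(pred[m] == y[m]) * 100.0)
    accs = list(group_acc.values())
    mean_acc = float(np.mean(accs))
    acc_std = std(accs) if len(accs) >= 2 else 0.0

    avg = "binary" if n_classes == 2 else "macro"
    f1 = float(_sk_f1(y, pred, average=avg, zero_division=0))
    auc_val = None
    present = np.unique(y)
    if len(present) >= 2:
        if n_classes == 2:
            auc_val = float(roc_auc_score(y, proba[:, 1]))
        else:
            auc_val = float(
                roc_auc_score(y, proba[:, present] / proba[:, present].sum(1, keepdims=True),
                              multi_class="ovr", labels=present)
                if len(present) == n_classes
                else np.nan
            )
            if math.isnan(auc_val):
                auc_val = None

    conf = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(conf, (y, pred), 1)
    return EvalReport(
        group_accuracy=group_acc,
        accuracy=mean_acc,
        std=float(acc_std),
        f1=f1,
        auc=auc_val,
        confusion=conf,
        n_samples=len(y),
    )
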