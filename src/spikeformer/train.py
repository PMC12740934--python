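"""Training protocol, data splits and class balancing.

Training follows a fixed recipe: Adam at an initial learning rate of 1e-3,
batch size 16, up to 100 epochs with early stopping after 30 epochs without
validation-loss improvement, and reduce-on-plateau learning-rate decay
(factor 0.5, patience 10, floor 1e-5).  The weights from the best-validation
epoch are restored at the end.  Everything is reproducible under a fixed
seed (construct the model with the same seed too: its initialisation and
dropout stream are seeded at build time).

Split protocols:

- ``apnea_cv5``       — five folds over the development recordings,
  stratified by label and grouped by recording so no recording leaks across
  folds.
- ``ucddb_holdout_811`` — 8:1:1 train/validation/test over windows.
- ``bci_session_split`` — train on session T; session E is re-split into 80%
  train-extension and 20% test (test size rounded down).
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedGroupKFold

from .autograd import Tensor
from .model import SpikingTransformerClassifier
from .nn import DTYPE, Adam

__all__ = [
    "TrainConfig",
    "train",
    "binary_cross_entropy_logits",
    "categorical_cross_entropy_logits",
    "split_protocols",
    "oversample_minority",
]


@dataclass(frozen=True)
class TrainConfig:
    lr: float = 1e-3
    batch_size: int = 16
    max_epochs: int = 100
    early_stop_patience: int = 30
    lr_factor: float = 0.5
    lr_patience: int = 10
    min_lr: float = 1e-5
    seed: int = 0

    def __post_init__(self):
        if not self.lr > 0:
            raise ValueError("lr must be positive")
        if not self.early_stop_patience < self.max_epochs:
            raise ValueError("early_stop_patience must be < max_epochs")


def binary_cross_entropy_logits(logits: Tensor, y: np.ndarray) -> Tensor:
    """Numerically stable mean BCE: max(z,0) - z*y + log(1 + exp(-|z|))."""
    y = Tensor(np.asarray(y, dtype=logits.dtype).reshape(logits.shape))
    pos = logits.relu()
    absz = pos + (-logits).relu()
    return (pos - logits * y + ((-absz).exp() + 1.0).log()).mean()


def categorical_cross_entropy_logits(logits: Tensor, y: np.ndarray) -> Tensor:
    """Mean cross-entropy over integer class labels via log-softmax."""
    y = np.asarray(y).astype(int).ravel()
    m = Tensor(logits.data.max(axis=-1, keepdims=True))  # constant shift
    lse = ((logits - m).exp().sum(axis=-1, keepdims=True)).log() + m
    onehot = np.zeros(logits.shape, dtype=logits.dtype)
    onehot[np.arange(len(y)), y] = 1.0
    picked = (logits * Tensor(onehot)).sum(axis=-1, keepdims=True)
    return (lse - picked).mean()


def _epoch_pass(model, X, y, cfg, optimizer=None, rng=None):
    """One pass over (X, y); trains when an optimizer is given."""
    n = len(X)
    order = rng.permutation(n) if rng is not None else np.arange(n)
    losses, correct = [], 0
    binary = model.cfg.n_classes == 1
    for i in range(0, n, cfg.batch_size):
        idx = order[i : i + cfg.batch_size]
        xb = np.asarray(X[idx], dtype=DTYPE)
        yb = y[idx]
        logits = model.forward_logits(xb)
        if binary:
            loss = binary_cross_entropy_logits(logits, yb)
            pred = (logits.data.ravel() >= 0).astype(int)
        else:
            loss = categorical_cross_entropy_logits(logits, yb)
            pred = logits.data.argmax(axis=-1)
        if not np.isfinite(loss.item()):
            raise RuntimeError("NaN/inf loss encountered during training")
        if optimizer is not None:
            model.zero_grad()
            loss.backward()
            optimizer.step()
        losses.append(loss.item() * len(idx))
        correct += int((pred == yb.ravel()).sum())
    return sum(losses) / n, correct / n


def train(
    model: SpikingTransformerClassifier,
    train_set: tuple[np.ndarray, np.ndarray],
    val_set: tuple[np.ndarray, np.ndarray],
    cfg: TrainConfig = TrainConfig(),
    verbose: bool = False,
) -> pd.DataFrame:
    """Fit the model; returns the per-epoch history and restores best weights."""
    Xtr, ytr = train_set
    Xva, yva = val_set
    ytr = np.asarray(ytr)
    yva = np.asarray(yva)
    rng = np.random.default_rng(cfg.seed)
    optimizer = Adam(model.parameters(), lr=cfg.lr)
    best_loss, best_state, best_epoch = np.inf, model.state_dict(), 0
    stop_wait = lr_wait = 0
    rows = []
    for epoch in range(1, cfg.max_epochs + 1):
        model.train()
        tr_loss, tr_acc = _epoch_pass(model, Xtr, ytr, cfg, optimizer, rng)
        model.eval()
        va_loss, va_acc = _epoch_pass(model, Xva, yva, cfg)
        rows.append(
            {
                "epoch": epoch,
                "train_loss": tr_loss,
                "train_acc": tr_acc,
                "val_loss": va_loss,
                "val_acc": va_acc,
                "lr": optimizer.lr,
            }
        )
        if verbose:
            stamp = datetime.now().strftime("%H:%M:%S")
            print(
                f"[{stamp}] epoch {epoch:3d}  train_loss {tr_loss:.4f}"
                f"  train_acc {tr_acc:.3f}  val_loss {va_loss:.4f}"
                f"  val_acc {va_acc:.3f}  lr {optimizer.lr:.2e}"
            )
        if va_loss < best_loss - 1e-12:
            best_loss, best_state, best_epoch = va_loss, model.state_dict(), epoch
            stop_wait = lr_wait = 0
        else:
            stop_wait += 1
            lr_wait += 1
            if lr_wait >= cfg.lr_patience and optimizer.lr > cfg.min_lr:
                optimizer.lr = max(optimizer.lr * cfg.lr_factor, cfg.min_lr)
                lr_wait = 0
            if stop_wait >= cfg.early_stop_patience:
                break
    model.load_state_dict(best_state)
    model.eval()
    history = pd.DataFrame(rows)
    history.attrs["best_epoch"] = best_epoch
    return history


def oversample_minority(
    labels: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Indices that duplicate random minority samples until classes balance.

    Apply to training/validation splits only, never across a test boundary.
    """
    labels = np.asarray(labels).astype(int)
    idx = np.arange(len(labels))
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2 or counts.min() == counts.max():
        return idx
    n_max = counts.max()
    extra = []
    for cls, cnt in zip(classes, counts):
        if cnt < n_max:
            pool = idx[labels == cls]
            extra.append(rng.choice(pool, size=n_max - cnt, replace=True))
    out = np.concatenate([idx, *extra])
    rng.shuffle(out)
    return out


def split_protocols(dataset, protocol: str, seed: int = 0):
    """Deterministic split indices for the three evaluation protocols.

    - ``apnea_cv5``: ``dataset`` is a :class:`~spikeformer.ecg.SegmentSet`;
      returns a list of 5 ``(train_idx, val_idx)`` pairs, stratified by label
      and grouped by recording.
    - ``ucddb_holdout_811``: ``dataset`` is a length or sized object; returns
      ``(train_idx, val_idx, test_idx)`` of sizes floor(0.8n)/floor(0.1n)/rest.
    - ``bci_session_split``: ``dataset`` is ``(n_train_session, n_eval_session)``;
      returns ``(train_idx, extension_idx, test_idx)`` where session E is
      re-split 80/20 with the test share rounded down.
    """
    rng = np.random.default_rng(seed)
    if protocol == "apnea_cv5":
        labels = dataset.labels
        groups = dataset.recording_ids
        skf = StratifiedGroupKFold(n_splits=5, shuffle=True, random_state=seed)
        return [
            (np.asarray(tr), np.asarray(va))
            for tr, va in skf.split(np.zeros(len(labels)), labels, groups)
        ]
    if protocol == "ucddb_holdout_811":
        n = dataset if isinstance(dataset, int) else len(dataset)
        perm = rng.permutation(n)
        n_tr, n_va = int(0.8 * n), int(0.1 * n)
        return perm[:n_tr], perm[n_tr : n_tr + n_va], perm[n_tr + n_va :]
    if protocol == "bci_session_split":
        n_t, n_e = dataset
        perm = rng.permutation(n_e)
        n_ext = int(0.8 * n_e)  # train extension rounded down; rest is test
        return np.arange(n_t), perm[:n_ext], perm[n_ext:]
    raise ValueError(f"unknown protocol: {protocol!r}")
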