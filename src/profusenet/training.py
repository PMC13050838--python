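"""Seeded, reproducible training with plateau LR decay and early stopping."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .features import FeaturizedSplit
from .model import DualCNNBiLSTM


@dataclass(frozen=True)
class TrainConfig:
    lr: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    batch_size: int = 32
    max_epochs: int = 100
    early_stop_patience: int = 10
    plateau_factor: float = 0.5
    plateau_patience: int = 3
    seed: int = 0

    def __post_init__(self):
        if min(self.lr, self.batch_size, self.max_epochs,
               self.early_stop_patience, self.plateau_patience) <= 0:
            raise ValueError("all training hyperparameters must be positive")
        if self.early_stop_patience >= self.max_epochs:
            raise ValueError("patience must be smaller than max_epochs")


@dataclass
class History:
    train_loss: list[float] = field(default_factory=list)
    train_accuracy: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)
    lr_events: list[tuple[int, float]] = field(default_factory=list)
    stopped_epoch: int = 0
    best_epoch: int = 0
    restored_best: bool = False

    def to_dict(self) -> dict:
        return {
            "train_loss": self.train_loss,
            "train_accuracy": self.train_accuracy,
            "val_loss": self.val_loss,
            "val_accuracy": self.val_accuracy,
            "lr_events": self.lr_events,
            "stopped_epoch": self.stopped_epoch,
            "best_epoch": self.best_epoch,
            "restored_best": self.restored_best,
        }


def cross_entropy(probs: np.ndarray, labels_onehot: np.ndarray,
                  eps: float = 1e-12) -> float:
    """Mean categorical cross-entropy over probability rows.

    Probabilities are clipped to [eps, 1 - eps] before taking logs.
    """
    probs = np.atleast_2d(np.asarray(probs, dtype=float))
    y = np.atleast_2d(np.asarray(labels_onehot, dtype=float))
    if probs.shape != y.shape:
        raise ValueError(f"shape mismatch: probs {probs.shape} vs labels {y.shape}")
    clipped = np.clip(probs, eps, 1.0 - eps)
    return float(-(y * np.log(clipped)).sum() / probs.shape[0])


def one_hot(labels: np.ndarray, n_classes: int = 2) -> np.ndarray:
    labels = np.asarray(labels, dtype=int)
    out = np.zeros((labels.shape[0], n_classes))
    out[np.arange(labels.shape[0]), labels] = 1.0
    return out


def _evaluate_split(model: DualCNNBiLSTM, split: FeaturizedSplit,
                    batch_size: int) -> tuple[float, float]:
    """(mean loss, accuracy) on a split, inference mode."""
    n = len(split)
    losses = []
    correct = 0
    for start in range(0, n, batch_size):
        rows = np.arange(start, min(start + batch_size, n))
        probs = model.forward(
            split.token_matrix(rows), split.mask[rows],
            split.fused[rows] if model.spec.use_late_fusion else None,
        )
        y = one_hot(split.labels[rows], model.spec.n_classes)
        losses.append(cross_entropy(probs, y) * len(rows))
        correct += int((probs.argmax(axis=1) == split.labels[rows]).sum())
    return sum(losses) / n, correct / n


def train(
    model: DualCNNBiLSTM,
    train_split: FeaturizedSplit,
    val_split: FeaturizedSplit,
    cfg: TrainConfig = TrainConfig(),
) -> History:
    """Train in place; returns the epoch history.

    Mini-batch order is driven solely by ``cfg.seed``.  Validation loss is
    monitored both for ReduceLROnPlateau-style decay and for early stopping,
    which restores the best weights seen.
    """
    if len(train_split) == 0 or len(val_split) == 0:
        raise ValueError("empty split")
    rng = np.random.default_rng(cfg.seed)
    optimizer = nn.Adam(model.parameter_list(), lr=cfg.lr,
                        beta1=cfg.beta1, beta2=cfg.beta2)
    history = History()
    best_loss = np.inf
    best_weights = model.get_weights()
    epochs_since_best = 0
    plateau_since_best = 0

    n = len(train_split)
    for epoch in range(1, cfg.max_epochs + 1):
        order = rng.permutation(n)
        epoch_loss = 0.0
        correct = 0
        for start in range(0, n, cfg.batch_size):
            rows = order[start : start + cfg.batch_size]
            tokens = nn.Tensor(train_split.token_matrix(rows))
            fused = (
                nn.Tensor(train_split.fused[rows])
                if model.spec.use_late_fusion
                else None
            )
            logits = model.forward_tensor(
                tokens, train_split.mask[rows], fused, train=True, rng=rng
            )
            y = one_hot(train_split.labels[rows], model.spec.n_classes)
            loss = nn.softmax_cross_entropy(logits, y)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}: {loss.data!r}"
                )
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            epoch_loss += float(loss.data) * len(rows)
            correct += int((logits.data.argmax(axis=1) == train_split.labels[rows]).sum())

        history.train_loss.append(epoch_loss / n)
        history.train_accuracy.append(correct / n)
        val_loss, val_acc = _evaluate_split(model, val_split, cfg.batch_size)
        history.val_loss.append(val_loss)
        history.val_accuracy.append(val_acc)

        if val_loss < best_loss:
            best_loss = val_loss
            best_weights = model.get_weights()
            history.best_epoch = epoch
            epochs_since_best = 0
            plateau_since_best = 0
        else:
            epochs_since_best += 1
            plateau_since_best += 1
            if plateau_since_best >= cfg.plateau_patience:
                optimizer.lr *= cfg.plateau_factor
                history.lr_events.append((epoch, optimizer.lr))
                plateau_since_best = 0
            if epochs_since_best >= cfg.early_stop_patience:
                history.stopped_epoch = epoch
                break
    else:
        history.stopped_epoch = cfg.max_epochs

    model.set_weights(best_weights)
    history.restored_best = True
    return history
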