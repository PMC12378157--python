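"""Two-phase training: linear probing of a frozen teacher, then student
distillation with the mixed hard/soft loss.

Optimization follows the reference recipe: Adam at a base learning rate of
0.001 with a multi-step schedule that multiplies by 0.1 at epochs 50 and 75
(0-based, applied from the start of the named epoch), up to 100 epochs with
early stopping on a validation metric (default AUC, patience 15). Because
the teacher is frozen its logits on the training set are deterministic, so
they are computed once and cached rather than recomputed each epoch.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data import DatasetBundle, Preprocessor
from .losses import (DistillConfig, distill_grad, distill_loss,
                     hard_label_grad, hard_label_loss, total_loss)
from .metrics import accuracy, auc, scores_from_logits
from .models import Model, extract_features
from .nn import Adam
from .utils import substream

MONITORS = ("val_auc", "val_acc")


@dataclass(frozen=True)
class TrainConfig(DistillConfig):
    base_lr: float = 1e-3
    milestones: tuple[int, ...] = (50, 75)
    gamma: float = 0.1
    epochs: int = 100
    batch_size: int = 128
    probe_batch_size: int = 32
    patience: int = 15
    monitor: str = "val_auc"
    target_side: int = 224
    normalization: str = "dataset"
    cache_teacher_logits: bool = True
    seed: int = 0

    def __post_init__(self):
        super().__post_init__()
        ms = tuple(self.milestones)
        if any(b <= a for a, b in zip(ms, ms[1:])):
            raise ValueError("milestones must be strictly increasing")
        if ms and ms[-1] >= self.epochs:
            raise ValueError("milestones must be < epochs")
        if not 0 < self.gamma <= 1:
            raise ValueError("gamma must lie in (0, 1]")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.monitor not in MONITORS:
            raise ValueError(f"unknown monitor {self.monitor!r}")


@dataclass
class EpochRecord:
    epoch: int
    lr: float
    hard: float
    distill: float
    total: float
    val_auc: float
    val_acc: float


@dataclass
class TrainingHistory:
    records: list[EpochRecord] = field(default_factory=list)
    best_epoch: int = -1
    stop_reason: str = "completed"

    def monitor_values(self, monitor: str) -> list[float]:
        return [getattr(r, monitor) for r in self.records]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.records])


def lr_at_epoch(cfg: TrainConfig, epoch: int) -> float:
    """base_lr * gamma^(number of milestones <= epoch)."""
    if not 0 <= epoch < cfg.epochs:
        raise ValueError(f"epoch {epoch} out of range [0, {cfg.epochs})")
    drops = sum(1 for m in cfg.milestones if m <= epoch)
    return cfg.base_lr * cfg.gamma ** drops


def early_stop_check(history: TrainingHistory | list[float], patience: int,
                     monitor: str = "val_auc") -> bool:
    """True iff the monitored metric has not improved for ``patience``
    consecutive epochs (ties count as no improvement)."""
    if isinstance(history, TrainingHistory):
        if monitor not in MONITORS:
            raise ValueError(f"unknown metric {monitor!r}")
        values = history.monitor_values(monitor)
    else:
        values = list(history)
    if not values:
        raise ValueError("history is empty")
    best_idx = int(np.argmax(values))  # earliest on ties
    return (len(values) - 1 - best_idx) >= patience


def _val_metrics(head_logits_fn, bundle, task):
    logits = head_logits_fn()
    scores = scores_from_logits(logits, task)
    labels = bundle.val_labels
    return auc(scores, labels, task), accuracy(scores, labels, task)


def fit_linear_probe(teacher: Model, bundle: DatasetBundle, cfg: TrainConfig,
                     preprocess: Preprocessor | None = None) -> tuple[Model, TrainingHistory]:
    """Phase 1: train only the teacher's linear head on frozen features.

    The backbone is bit-untouched; the head with the best validation metric
    is returned. The hard-label loss alone is used — no distillation term.
    """
    if bundle.n("train") == 0 or bundle.n("val") == 0:
        raise ValueError("probe requires non-empty train and val splits")
    if not teacher.frozen_backbone:
        teacher.freeze_backbone()
    if preprocess is None:
        preprocess = Preprocessor(bundle, cfg.target_side, cfg.normalization)
    task = bundle.task
    feats = {s: extract_features(teacher, bundle.images(s), preprocess)
             for s in ("train", "val")}
    head = teacher.head
    opt = Adam([head.W, head.b])
    rng = substream(cfg.seed, "probe", "shuffle")
    history = TrainingHistory()
    best = None
    n = len(feats["train"])
    y = bundle.train_labels
    for epoch in range(cfg.epochs):
        lr = lr_at_epoch(cfg, epoch)
        order = rng.permutation(n)
        hard_sum = 0.0
        for start in range(0, n, cfg.probe_batch_size):
            idx = order[start:start + cfg.probe_batch_size]
            x, yb = feats["train"][idx], y[idx]
            z = x @ head.W.value + head.b.value
            hard_sum += hard_label_loss(z, yb, task) * len(idx)
            g = hard_label_grad(z, yb, task).astype(np.float32)
            opt.zero_grad()
            head.W.grad += x.T @ g
            head.b.grad += g.sum(axis=0)
            opt.step(lr)
        val_auc, val_acc = _val_metrics(
            lambda: feats["val"] @ head.W.value + head.b.value, bundle, task)
        mean_hard = hard_sum / n
        history.records.append(EpochRecord(epoch, lr, mean_hard, 0.0, mean_hard,
                                           val_auc, val_acc))
        values = history.monitor_values(cfg.monitor)
        best_idx = int(np.argmax(values))
        if best_idx == len(values) - 1:
            best = (head.W.value.copy(), head.b.value.copy())
        if early_stop_check(history, cfg.patience, cfg.monitor):
            history.stop_reason = f"early stop (patience {cfg.patience})"
            break
    history.best_epoch = int(np.argmax(history.monitor_values(cfg.monitor)))
    head.W.value, head.b.value = best
    return teacher, history


def train_student(student: Model, bundle: DatasetBundle, cfg: TrainConfig,
                  teacher: Model | None = None,
                  preprocess: Preprocessor | None = None) -> tuple[Model, TrainingHistory]:
    """Train a student; with a teacher this is distillation, without one it
    is plain supervised training (the alpha=1 reduction of the same loop).

    Per batch: teacher logits (no gradient, cached across epochs), student
    logits, LossBreakdown, and an Adam step on d(total)/d(logits) =
    alpha*d(hard) + beta*d(distill). The best-validation parameters are
    restored before returning; ties keep the earlier epoch.
    """
    if preprocess is None:
        preprocess = Preprocessor(bundle, cfg.target_side, cfg.normalization)
    task = bundle.task
    if teacher is not None and teacher.task != task:
        raise ValueError("teacher and bundle tasks disagree")
    x_train = preprocess(bundle.train_images)
    y_train = bundle.train_labels
    x_val = preprocess(bundle.val_images)
    teacher_logits = None
    if teacher is not None:
        from .models import predict_logits
        teacher_logits = predict_logits(teacher, bundle.train_images, preprocess)
    params = student.trainable_params()
    opt = Adam(params)
    rng = substream(cfg.seed, "train", "shuffle")
    history = TrainingHistory()
    best = None
    n = len(x_train)
    for epoch in range(cfg.epochs):
        lr = lr_at_epoch(cfg, epoch)
        order = rng.permutation(n)
        hard_sum = dist_sum = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            xb, yb = x_train[idx], y_train[idx]
            feats = student.backbone.forward(xb, train=True)
            z = student.head.forward(feats, train=True)
            hard = hard_label_loss(z, yb, task)
            gh = hard_label_grad(z, yb, task)
            if teacher is not None:
                tz = teacher_logits[idx]
                dist = distill_loss(tz, z, cfg.temperature, task)
                g = cfg.alpha * gh + cfg.beta * distill_grad(tz, z, cfg.temperature, task)
            else:
                dist = 0.0
                g = gh
            if not (np.isfinite(hard) and np.isfinite(dist)):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}, batch {start // cfg.batch_size}")
            opt.zero_grad()
            dfeat = student.head.backward(g.astype(np.float32))
            student.backbone.backward(dfeat)
            opt.step(lr)
            hard_sum += hard * len(idx)
            dist_sum += dist * len(idx)
        mean_hard, mean_dist = hard_sum / n, dist_sum / n
        breakdown = total_loss(mean_hard, mean_dist, cfg) if teacher is not None \
            else total_loss(mean_hard, 0.0, replace(cfg, alpha=1.0))
        val_logits = student.head.forward(
            student.backbone.forward(x_val, train=False), train=False)
        scores = scores_from_logits(val_logits, task)
        val_auc = auc(scores, bundle.val_labels, task)
        val_acc = accuracy(scores, bundle.val_labels, task)
        history.records.append(EpochRecord(epoch, lr, mean_hard, mean_dist,
                                           breakdown.total, val_auc, val_acc))
        values = history.monitor_values(cfg.monitor)
        if int(np.argmax(values)) == len(values) - 1:
            best = {k: p.value.copy() for k, p in student.named_params().items()}
        if early_stop_check(history, cfg.patience, cfg.monitor):
            history.stop_reason = f"early stop (patience {cfg.patience})"
            break
    history.best_epoch = int(np.argmax(history.monitor_values(cfg.monitor)))
    for k, p in student.named_params().items():
        p.value = best[k]
    return student, history


def distill(teacher: Model, student: Model, bundle: DatasetBundle,
            cfg: TrainConfig,
            preprocess: Preprocessor | None = None) -> tuple[Model, TrainingHistory]:
    """Phase 2: transfer the frozen teacher's softened predictions to the
    student via the mixed loss. The teacher never changes."""
    if not all(not p.trainable for p in teacher.named_params().values()):
        teacher = copy.deepcopy(teacher).freeze_all()
    return train_student(student, bundle, cfg, teacher=teacher,
                         preprocess=preprocess)
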