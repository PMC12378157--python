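"""AUC and ACC under MedMNIST benchmark conventions.

AUC is rank-based (ties count 0.5): the positive-class score for binary
tasks, the unweighted mean of one-vs-rest AUCs over classes present for
multiclass/ordinal, and the unweighted mean of per-label AUCs over labels
with both outcomes present for multilabel. ACC is argmax accuracy for
single-label tasks (ties break to the lowest index) and the mean over
labels of per-label 0.5-threshold accuracy for multilabel; binary ACC
thresholds the positive-class sigmoid at 0.5.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass

import numpy as np
from sklearn.metrics import roc_auc_score

from .data import DatasetBundle, TaskSpec
from .losses import sigmoid, softmax

log = logging.getLogger(__name__)


class UndefinedMetricError(ValueError):
    """The metric is undefined for the given labels (single-outcome)."""


def auc(scores: np.ndarray, labels: np.ndarray, task: TaskSpec) -> float:
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    if scores.ndim == 1:
        scores = scores[:, None]
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    if task.kind == "binary":
        y = labels.reshape(-1)
        if len(np.unique(y)) < 2:
            raise UndefinedMetricError(
                "binary AUC undefined: only one outcome present")
        pos = scores[:, 1] if scores.shape[1] > 1 else scores[:, 0]
        return float(roc_auc_score(y, pos))
    if task.kind == "multilabel":
        y = labels.reshape(scores.shape)
        per_label = []
        for j in range(y.shape[1]):
            if len(np.unique(y[:, j])) < 2:
                log.info("AUC: skipping label %d (single outcome)", j)
                continue
            per_label.append(roc_auc_score(y[:, j], scores[:, j]))
        if not per_label:
            raise UndefinedMetricError("no label has both outcomes present")
        return float(np.mean(per_label))
    # multiclass / ordinal: one-vs-rest macro over classes present
    y = labels.reshape(-1).astype(np.int64)
    per_class = []
    for k in np.unique(y):
        yk = (y == k).astype(int)
        if yk.all() or not yk.any():
            log.info("AUC: skipping class %d (single outcome)", k)
            continue
        per_class.append(roc_auc_score(yk, scores[:, k]))
    if not per_class:
        raise UndefinedMetricError("no class has both outcomes present")
    return float(np.mean(per_class))


def accuracy(scores: np.ndarray, labels: np.ndarray, task: TaskSpec) -> float:
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    if task.kind == "multilabel":
        y = labels.reshape(scores.shape)
        pred = (scores >= 0.5).astype(int)
        return float((pred == y).mean(axis=0).mean())
    y = labels.reshape(-1).astype(np.int64)
    if task.kind == "binary":
        pos = scores[:, 1] if scores.ndim == 2 and scores.shape[1] > 1 else scores.reshape(-1)
        pred = (pos >= 0.5).astype(int)
    else:
        pred = scores.argmax(axis=1)
    return float((pred == y).mean())


def scores_from_logits(logits: np.ndarray, task: TaskSpec) -> np.ndarray:
    """Probability scores at t=1: softmax for single-label multiclass and
    ordinal tasks, per-logit sigmoid for binary and multilabel."""
    if task.kind in ("binary", "multilabel"):
        return sigmoid(logits)
    return softmax(logits, 1.0)


@dataclass(frozen=True)
class MetricsReport:
    model: str
    task: str
    split: str
    n: int
    auc: float
    acc: float

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def evaluate(model, bundle: DatasetBundle, split: str, preprocess=None,
             batch_size: int = 256) -> MetricsReport:
    """Deterministic evaluation of a model on one split of a bundle."""
    from .models import predict_logits  # local import to avoid a cycle

    if model.task != bundle.task:
        raise ValueError(f"model task {model.task} != bundle task {bundle.task}")
    images, labels = bundle.images(split), bundle.labels(split)
    if len(images) == 0:
        raise ValueError(f"split {split!r} is empty")
    logits = predict_logits(model, images, preprocess, batch_size)
    scores = scores_from_logits(logits, bundle.task)
    return MetricsReport(model.arch, bundle.task.kind, split, len(images),
                         auc(scores, labels, bundle.task),
                         accuracy(scores, labels, bundle.task))
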