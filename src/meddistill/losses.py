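"""Temperature-softened distillation losses and hard-label losses.

The student is trained on a convex mixture of two terms, in nats per sample:

    L_total = alpha * L_hard + (1 - alpha) * L_distill

where ``L_hard`` is cross-entropy against the ground-truth label (binary
cross-entropy for binary and multi-label tasks) and ``L_distill`` is the
temperature-scaled forward KL divergence from the teacher's softened
distribution to the student's,

    L_distill = t^2 * KL( softmax(z_T / t) || softmax(z_S / t) ).

The ``t^2`` factor keeps the gradient magnitude of the soft term comparable
across temperatures, so the alpha/beta balance is temperature-invariant.
For multi-label tasks — where a softmax over labels is not meaningful —
soft targets are per-label sigmoid Bernoullis and the loss is the mean
per-label binary KL, likewise ``t^2``-scaled.

All functions accept a single logit vector ``(m,)`` or a batch ``(b, m)``;
batched losses return the per-sample mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import TaskSpec

LOG_FLOOR = 1e-12


@dataclass(frozen=True)
class DistillConfig:
    """Temperature and mixing weight. ``beta`` is always ``1 - alpha``."""

    temperature: float = 2.0
    alpha: float = 0.2

    def __post_init__(self):
        if not self.temperature > 0:
            raise ValueError("temperature must be > 0")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")

    @property
    def beta(self) -> float:
        return 1.0 - self.alpha


@dataclass(frozen=True)
class SoftDistribution:
    """A temperature-softened probability vector (or batch of them)."""

    probs: np.ndarray
    temperature: float


@dataclass(frozen=True)
class LossBreakdown:
    hard: float
    distill: float
    total: float
    alpha: float = field(default=0.2)


def _as_batch(z) -> tuple[np.ndarray, bool]:
    z = np.asarray(z, dtype=np.float64)
    if z.ndim == 1:
        return z[None, :], True
    return z, False


def softmax(z: np.ndarray, t: float = 1.0) -> np.ndarray:
    """Overflow-safe temperature softmax along the last axis."""
    if not t > 0:
        raise ValueError("temperature must be > 0")
    s = np.asarray(z, dtype=np.float64) / t
    s = s - s.max(axis=-1, keepdims=True)
    e = np.exp(s)
    return e / e.sum(axis=-1, keepdims=True)


def sigmoid(z: np.ndarray) -> np.ndarray:
    z = np.asarray(z, dtype=np.float64)
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def temperature_softmax(z, t: float) -> SoftDistribution:
    """Softened distribution P_i = exp(z_i/t) / sum_j exp(z_j/t)."""
    return SoftDistribution(softmax(z, t), t)


def _probs(p) -> np.ndarray:
    return p.probs if isinstance(p, SoftDistribution) else np.asarray(p, dtype=np.float64)


def kl_divergence(p, q) -> float:
    """Forward KL  sum_i p_i ln(p_i / q_i)  with 0 ln 0 := 0; always >= 0."""
    pa, qa = _probs(p), _probs(q)
    if pa.shape != qa.shape:
        raise ValueError("p and q must have the same shape")
    if np.any((pa > 0) & (qa == 0)):
        raise ValueError("support violation: p_i > 0 where q_i = 0")
    mask = pa > 0
    terms = np.zeros_like(pa)
    terms[mask] = pa[mask] * (np.log(np.maximum(pa[mask], LOG_FLOOR))
                              - np.log(np.maximum(qa[mask], LOG_FLOOR)))
    kl = terms.sum(axis=-1)
    return float(kl) if kl.ndim == 0 else float(kl.mean())


def soft_target_kl_loss(teacher_z, student_z, t: float) -> float:
    """t^2-scaled forward KL from teacher to student at temperature t."""
    tz, _ = _as_batch(teacher_z)
    sz, _ = _as_batch(student_z)
    if tz.shape != sz.shape:
        raise ValueError("teacher and student logits must share a shape")
    p = softmax(tz, t)
    q = softmax(sz, t)
    per_sample = (p * (np.log(np.maximum(p, LOG_FLOOR))
                       - np.log(np.maximum(q, LOG_FLOOR)))).sum(axis=-1)
    return float(t * t * per_sample.mean())


def multilabel_soft_loss(teacher_z, student_z, t: float) -> float:
    """Per-label sigmoid soft targets: mean over labels of the t^2-scaled
    binary KL between Bernoulli(sigmoid(z_T/t)) and Bernoulli(sigmoid(z_S/t))."""
    if not t > 0:
        raise ValueError("temperature must be > 0")
    tz, _ = _as_batch(teacher_z)
    sz, _ = _as_batch(student_z)
    if tz.shape != sz.shape:
        raise ValueError("teacher and student logits must share a shape")
    p = sigmoid(tz / t)
    q = sigmoid(sz / t)
    q = np.clip(q, LOG_FLOOR, 1.0 - LOG_FLOOR)
    pc = np.clip(p, LOG_FLOOR, 1.0 - LOG_FLOOR)
    kl = pc * (np.log(pc) - np.log(q)) + (1 - pc) * (np.log1p(-pc) - np.log1p(-q))
    return float(t * t * kl.mean())


def _bce_with_logits(z: np.ndarray, y: np.ndarray) -> np.ndarray:
    # stable elementwise BCE: max(z,0) - z*y + log(1+exp(-|z|))
    return np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))


def _one_hot(y: np.ndarray, m: int) -> np.ndarray:
    out = np.zeros((len(y), m), dtype=np.float64)
    out[np.arange(len(y)), y] = 1.0
    return out


def hard_label_loss(student_z, label, task: TaskSpec) -> float:
    """Ground-truth loss per the task kind.

    Multiclass/ordinal: -ln softmax(z)[y] (i.e. the t=1 hard softmax).
    Binary: mean per-logit BCE against the one-hot target with sigmoids.
    Multilabel: mean per-label BCE against the indicator vector.
    """
    z, _ = _as_batch(student_z)
    m = z.shape[-1]
    if m != task.num_classes:
        raise ValueError(f"logits have {m} classes, task expects {task.num_classes}")
    label = np.asarray(label)
    if task.kind in ("multiclass", "ordinal"):
        y = label.reshape(-1).astype(np.int64)
        if y.min() < 0 or y.max() >= m:
            raise ValueError("label out of range for task")
        logp = np.log(np.maximum(softmax(z, 1.0), LOG_FLOOR))
        return float(-logp[np.arange(len(y)), y].mean())
    if task.kind == "binary":
        y = label.reshape(-1).astype(np.int64)
        if not set(np.unique(y).tolist()) <= {0, 1}:
            raise ValueError("binary labels must be 0/1")
        target = _one_hot(y, 2)
    else:  # multilabel
        target = label.reshape(z.shape).astype(np.float64)
        if not set(np.unique(target).tolist()) <= {0.0, 1.0}:
            raise ValueError("multilabel targets must be 0/1")
    return float(_bce_with_logits(z, target).mean())


def distill_loss(teacher_z, student_z, t: float, task: TaskSpec) -> float:
    """Dispatch: softmax KL for single-label tasks, sigmoid KL for multilabel."""
    if task.kind == "multilabel":
        return multilabel_soft_loss(teacher_z, student_z, t)
    return soft_target_kl_loss(teacher_z, student_z, t)


def total_loss(hard: float, distill: float, cfg: DistillConfig) -> LossBreakdown:
    """Convex mixture alpha*hard + (1-alpha)*distill."""
    if not (np.isfinite(hard) and np.isfinite(distill)):
        raise ValueError("loss components must be finite")
    if hard < 0 or distill < 0:
        raise ValueError("loss components must be >= 0")
    total = cfg.alpha * hard + cfg.beta * distill
    return LossBreakdown(float(hard), float(distill), float(total), cfg.alpha)


# ---------------------------------------------------------------------------
# analytic gradients with respect to the student logits (used by training)


def hard_label_grad(student_z: np.ndarray, label, task: TaskSpec) -> np.ndarray:
    """d L_hard / d z_S for a batch, matching hard_label_loss's mean reduction."""
    z, _ = _as_batch(student_z)
    b, m = z.shape
    if task.kind in ("multiclass", "ordinal"):
        y = np.asarray(label).reshape(-1).astype(np.int64)
        g = softmax(z, 1.0)
        g[np.arange(b), y] -= 1.0
        return g / b
    if task.kind == "binary":
        target = _one_hot(np.asarray(label).reshape(-1).astype(np.int64), 2)
    else:
        target = np.asarray(label).reshape(z.shape).astype(np.float64)
    return (sigmoid(z) - target) / (b * m)


def distill_grad(teacher_z: np.ndarray, student_z: np.ndarray, t: float,
                 task: TaskSpec) -> np.ndarray:
    """d L_distill / d z_S, matching the forward losses' mean reductions."""
    tz, _ = _as_batch(teacher_z)
    sz, _ = _as_batch(student_z)
    b, m = sz.shape
    if task.kind == "multilabel":
        return t * (sigmoid(sz / t) - sigmoid(tz / t)) / (b * m)
    return t * (softmax(sz, t) - softmax(tz, t)) / b
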