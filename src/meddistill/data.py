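"""MedMNIST-style dataset handling.

The on-disk dialect is an NPZ archive with exactly six arrays —
``train_images``, ``train_labels``, ``val_images``, ``val_labels``,
``test_images``, ``test_labels`` — where images are unsigned 8-bit
``n×H×W`` (grayscale) or ``n×H×W×3`` (RGB) and labels are ``n×1`` integer
class indices (single-label tasks) or ``n×L`` 0/1 indicator matrices
(multi-label tasks). The task kind is inferred from the label layout;
ordinal regression is shape-indistinguishable from multi-class and must be
declared explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from skimage.transform import resize as _sk_resize

DIALECT_KEYS = ("train_images", "train_labels", "val_images", "val_labels",
                "test_images", "test_labels")
SPLITS = ("train", "val", "test")
TASK_KINDS = ("binary", "multiclass", "multilabel", "ordinal")
SINGLE_LABEL_KINDS = ("binary", "multiclass", "ordinal")


class DialectError(ValueError):
    """An archive or array violates the NPZ dialect."""


@dataclass(frozen=True)
class TaskSpec:
    """What kind of classification problem the labels describe.

    ``label_layout`` is ``"index"`` for n×1 integer labels and ``"indicator"``
    for n×m 0/1 matrices (multi-label).
    """

    kind: str
    num_classes: int
    label_layout: str = "index"

    def __post_init__(self):
        if self.kind not in TASK_KINDS:
            raise ValueError(f"unknown task kind {self.kind!r}")
        if self.num_classes < 2:
            raise ValueError("num_classes must be >= 2")
        if self.kind == "binary" and (self.num_classes != 2 or self.label_layout != "index"):
            raise ValueError("binary tasks have m=2 with n x 1 labels")
        if self.kind == "multilabel" and self.label_layout != "indicator":
            raise ValueError("multilabel tasks use n x m indicator labels")

    @property
    def is_single_label(self) -> bool:
        return self.kind in SINGLE_LABEL_KINDS


def infer_task_spec(labels: np.ndarray) -> TaskSpec:
    """Infer the task from label shapes and values.

    n×1 over {0,1} → binary; n×1 with >2 distinct integer values →
    multiclass (m = max index + 1); n×L (L>1) over {0,1} → multilabel
    (m = L). Ordinal can never be inferred — it must be declared.
    """
    labels = np.asarray(labels)
    if labels.size == 0:
        raise DialectError("labels are empty")
    if not np.issubdtype(labels.dtype, np.integer):
        if not np.all(labels == np.round(labels)):
            raise DialectError("labels must be integer-valued")
        labels = labels.astype(np.int64)
    if labels.ndim == 1:
        labels = labels[:, None]
    if labels.ndim != 2:
        raise DialectError(f"labels must be 2-D (n x 1 or n x L), got shape {labels.shape}")
    n, width = labels.shape
    values = np.unique(labels)
    if width == 1:
        if values.min() < 0:
            raise DialectError("negative class index in labels")
        if set(values.tolist()) <= {0, 1}:
            return TaskSpec("binary", 2, "index")
        return TaskSpec("multiclass", int(values.max()) + 1, "index")
    if not set(values.tolist()) <= {0, 1}:
        raise DialectError(
            f"n x {width} labels must be 0/1 indicators, found values {values[:5]}")
    return TaskSpec("multilabel", width, "indicator")


@dataclass
class DatasetBundle:
    """Train/val/test images and labels plus the task they define."""

    train_images: np.ndarray
    train_labels: np.ndarray
    val_images: np.ndarray
    val_labels: np.ndarray
    test_images: np.ndarray
    test_labels: np.ndarray
    task: TaskSpec = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.task is None:
            self.task = infer_task_spec(self.train_labels)
        self.validate()

    def images(self, split: str) -> np.ndarray:
        return getattr(self, f"{split}_images")

    def labels(self, split: str) -> np.ndarray:
        return getattr(self, f"{split}_labels")

    def n(self, split: str) -> int:
        return len(self.images(split))

    def with_task(self, task: TaskSpec) -> "DatasetBundle":
        return replace(self, task=task)

    def validate(self) -> None:
        for split in SPLITS:
            imgs, labs = self.images(split), self.labels(split)
            if imgs.dtype != np.uint8:
                raise DialectError(f"{split}_images must be uint8, got {imgs.dtype}")
            if imgs.ndim not in (3, 4) or (imgs.ndim == 4 and imgs.shape[-1] != 3):
                raise DialectError(
                    f"{split}_images must be n x H x W or n x H x W x 3, got {imgs.shape}")
            if len(imgs) != len(labs):
                raise DialectError(
                    f"{split}: {len(imgs)} images but {len(labs)} labels")
            spec_here = infer_task_spec(labs)
            if spec_here.label_layout != self.task.label_layout:
                raise DialectError(f"{split}_labels layout disagrees with task")


def write_npz(bundle: DatasetBundle, path) -> None:
    """Write a bundle in the six-key NPZ dialect (bit-exact round trip)."""
    arrays = {k: getattr(bundle, k) for k in DIALECT_KEYS}
    np.savez(path, **arrays)


def read_npz(path, task_override: str | None = None) -> DatasetBundle:
    """Read a dialect archive; missing/extra keys are reported by name."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with np.load(path) as npz:
        present = set(npz.files)
        missing = [k for k in DIALECT_KEYS if k not in present]
        if missing:
            raise DialectError(f"archive missing required key(s): {', '.join(missing)}")
        extra = sorted(present - set(DIALECT_KEYS))
        if extra:
            raise DialectError(f"archive has unexpected key(s): {', '.join(extra)}")
        arrays = {k: npz[k] for k in DIALECT_KEYS}
    bundle = DatasetBundle(**arrays)
    if task_override is not None:
        if task_override not in TASK_KINDS:
            raise ValueError(f"unknown task override {task_override!r}")
        if task_override == "ordinal":
            if bundle.task.kind not in ("multiclass", "binary"):
                raise DialectError("ordinal override requires n x 1 integer labels")
            bundle = bundle.with_task(
                TaskSpec("ordinal", bundle.task.num_classes, "index"))
        elif task_override != bundle.task.kind:
            raise DialectError(
                f"labels imply {bundle.task.kind}, cannot override to {task_override}")
    return bundle


def load_medmnist_npz(path, task_override: str | None = None) -> DatasetBundle:
    """Load a MedMNIST-style archive with the inferred TaskSpec attached."""
    return read_npz(path, task_override=task_override)


# ---------------------------------------------------------------------------
# preprocessing


@dataclass
class ImageBatch:
    """A normalized, channel-replicated batch ready for a model: (b,3,S,S)."""

    array: np.ndarray
    target_side: int
    normalization: str
    mean: np.ndarray | None = None
    std: np.ndarray | None = None


def compute_normalization_stats(images: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-channel mean/std on the 0-1 intensity scale (after replication)."""
    x = images.astype(np.float32) / 255.0
    if x.ndim == 3:
        x = x[..., None]
    mean = x.mean(axis=(0, 1, 2))
    std = x.std(axis=(0, 1, 2))
    if mean.shape[0] == 1:
        mean = np.repeat(mean, 3)
        std = np.repeat(std, 3)
    return mean.astype(np.float32), np.maximum(std, 1e-6).astype(np.float32)


def preprocess_batch(images: np.ndarray, target_side: int = 224,
                     normalization="none",
                     mean: np.ndarray | None = None,
                     std: np.ndarray | None = None) -> ImageBatch:
    """Resize (bilinear, half-pixel centers), replicate grayscale to RGB,
    and standardize per channel.

    ``normalization``: ``"none"`` (intensities stay on the 0-1 scale),
    ``"fixed"`` (use the supplied ``mean``/``std``). Dataset-derived
    statistics are obtained with :func:`compute_normalization_stats` and
    passed as fixed values — see :class:`Preprocessor`.
    """
    images = np.asarray(images)
    if images.ndim == 3:
        images = images[..., None]
    if images.ndim != 4 or images.shape[-1] not in (1, 3):
        raise DialectError(
            f"unsupported channel count: expected 1 or 3, got shape {images.shape}")
    x = images.astype(np.float32) / 255.0
    b, h, w, c = x.shape
    if (h, w) != (target_side, target_side):
        x = _sk_resize(x, (b, target_side, target_side, c), order=1,
                       anti_aliasing=False, preserve_range=True).astype(np.float32)
    if c == 1:
        x = np.repeat(x, 3, axis=-1)
    if normalization == "fixed":
        if mean is None or std is None:
            raise ValueError("fixed normalization requires mean and std")
        x = (x - np.asarray(mean, np.float32)) / np.maximum(
            np.asarray(std, np.float32), 1e-6)
    elif normalization != "none":
        raise ValueError(f"unknown normalization {normalization!r}")
    x = np.ascontiguousarray(x.transpose(0, 3, 1, 2))
    return ImageBatch(x, target_side, normalization,
                      None if mean is None else np.asarray(mean),
                      None if std is None else np.asarray(std))


class Preprocessor:
    """Preprocessing policy bound to a dataset.

    ``mode="dataset"`` standardizes with per-channel statistics of the train
    split (the default); ``mode="none"`` leaves intensities on the 0-1 scale;
    ``mode="fixed"`` uses caller-supplied statistics.
    """

    def __init__(self, bundle: DatasetBundle | None = None, target_side: int = 224,
                 mode: str = "dataset",
                 mean: np.ndarray | None = None, std: np.ndarray | None = None):
        self.target_side = target_side
        self.mode = mode
        if mode == "dataset":
            if bundle is None:
                raise ValueError("dataset normalization requires a bundle")
            self.mean, self.std = compute_normalization_stats(bundle.train_images)
        elif mode == "fixed":
            if mean is None or std is None:
                raise ValueError("fixed normalization requires mean and std")
            self.mean, self.std = np.asarray(mean, np.float32), np.asarray(std, np.float32)
        elif mode == "none":
            self.mean = self.std = None
        else:
            raise ValueError(f"unknown normalization mode {mode!r}")

    def __call__(self, images: np.ndarray) -> np.ndarray:
        if self.mode == "none":
            return preprocess_batch(images, self.target_side, "none").array
        return preprocess_batch(images, self.target_side, "fixed",
                                mean=self.mean, std=self.std).array
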