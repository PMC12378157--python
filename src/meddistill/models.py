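"""Student and teacher model construction, feature extraction, and
parameter accounting.

Two student architectures are provided: the reference ResNet-50 (its
backbone matches the canonical ImageNet construction parameter-for-
parameter, so with a MedMNIST-sized head it lands at 23M parameters) and a
"tiny" three-block CNN (~53k parameters) for desk-scale experiments and
tests. Teachers pair a frozen feature extractor — a DINOv2-dimension ViT
(S/14, B/14, L/14) or the tiny CNN backbone — with a linear head that is
the only thing trained during probing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from . import nn
from .data import TaskSpec
from .nn.layers import named_params
from .nn.vit import VARIANTS, VisionTransformer, vit_backbone
from .utils import substream

CHECKPOINT_SCHEMA = 1
TINY_WIDTHS = (24, 48, 96)


class TinyCNNBackbone(nn.Layer):
    """Three conv/ReLU blocks with 2x pooling, then global average pooling.

    Purpose-built desk-scale scaffolding: small enough to train in seconds
    on a CPU, deep enough to have a last convolutional block for
    class-activation maps.
    """

    def __init__(self, rng, in_channels=3, widths=TINY_WIDTHS):
        w1, w2, w3 = widths
        # pool-before-ReLU is bit-identical to ReLU-before-pool (max commutes
        # with monotone maps) and applies the activation on 4x fewer elements
        self.body = nn.Sequential(
            nn.Conv2d(in_channels, w1, 3, pad=1, rng=rng, grad_input=False),
            nn.MaxPool2d(2), nn.ReLU(),
            nn.Conv2d(w1, w2, 3, pad=1, rng=rng), nn.MaxPool2d(2), nn.ReLU(),
            nn.Conv2d(w2, w3, 3, pad=1, rng=rng), nn.ReLU(),
        )
        self.pool = nn.GlobalAvgPool()
        self.feature_dim = w3

    def feature_map(self, x, train=False):
        return self.body(x, train)

    def forward(self, x, train=True):
        return self.pool(self.body(x, train), train)

    def backward(self, dy):
        return self.body.backward(self.pool.backward(dy))


@dataclass
class Model:
    """A backbone + linear head pair with a task attached.

    ``forward`` yields ``(b, m)`` logits; ``features`` yields the
    penultimate ``(b, d)`` representation the head consumes.
    """

    arch: str
    backbone: object
    head: nn.Linear
    task: TaskSpec
    frozen_backbone: bool = False

    @property
    def feature_dim(self) -> int:
        return self.backbone.feature_dim

    def features(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return self.backbone.forward(x, train=train)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return self.head.forward(self.features(x, train=train), train=train)

    def named_params(self) -> dict[str, nn.Param]:
        out = {}
        if isinstance(self.backbone, VisionTransformer):
            for k, v in self.backbone.params().items():
                out[f"backbone.{k}"] = v
        else:
            out.update(named_params(self.backbone, "backbone."))
        out.update(named_params(self.head, "head."))
        return out

    def trainable_params(self) -> list[nn.Param]:
        return [p for p in self.named_params().values() if p.trainable]

    def freeze_backbone(self) -> "Model":
        for name, p in self.named_params().items():
            if name.startswith("backbone."):
                p.trainable = False
        self.frozen_backbone = True
        return self

    def freeze_all(self) -> "Model":
        for p in self.named_params().values():
            p.trainable = False
        return self

    def parameter_bytes(self, scope: str = "all") -> bytes:
        """Concatenated parameter payload, for byte-identity checks."""
        chunks = []
        for name in sorted(self.named_params()):
            if scope == "backbone" and not name.startswith("backbone."):
                continue
            chunks.append(self.named_params()[name].value.tobytes())
        return b"".join(chunks)


StudentModel = Model
TeacherModel = Model


def build_student(arch: str, task: TaskSpec, seed: int = 0) -> Model:
    """Construct a trainable student: ``resnet50`` or ``tiny``."""
    rng = substream(seed, "init", "student", arch)
    if arch == "resnet50":
        backbone, head = nn.resnet50(task.num_classes, rng)
        return Model("resnet50", backbone, head, task)
    if arch == "tiny":
        backbone = TinyCNNBackbone(rng)
        head = nn.Linear(backbone.feature_dim, task.num_classes, rng=rng)
        return Model("tiny", backbone, head, task)
    raise ValueError(f"unknown student architecture {arch!r}")


def build_vit_backbone(variant: str, pretrained_weights=None,
                       seed: int = 0) -> VisionTransformer:
    """DINOv2-dimension ViT backbone; optionally load local NPZ weights."""
    backbone = vit_backbone(variant, rng=substream(seed, "init", "teacher", variant))
    if pretrained_weights is not None:
        with np.load(pretrained_weights) as npz:
            backbone.load_state({k: npz[k] for k in npz.files})
    return backbone


def build_teacher(variant: str, task: TaskSpec, pretrained_weights=None,
                  seed: int = 0, backbone=None) -> Model:
    """Frozen-backbone teacher with a trainable linear head.

    ``variant`` is one of ``s14``/``b14``/``l14`` (ViT) or ``tiny``; a
    ready-made backbone (e.g. a supervised-pretrained tiny CNN body) may be
    passed directly.
    """
    if backbone is None:
        if variant == "tiny":
            backbone = TinyCNNBackbone(substream(seed, "init", "teacher", "tiny"))
        else:
            backbone = build_vit_backbone(variant, pretrained_weights, seed=seed)
    head = nn.Linear(backbone.feature_dim, task.num_classes,
                     rng=substream(seed, "init", "teacher-head", variant))
    model = Model(variant, backbone, head, task)
    model.freeze_backbone()
    return model


def count_parameters(model, trainable_only: bool = False) -> int:
    """Exact element count over the model's parameter tensors."""
    if isinstance(model, Model):
        params = model.named_params().values()
    elif isinstance(model, VisionTransformer):
        params = model.params().values()
    else:
        params = named_params(model).values()
    return int(sum(p.size for p in params if (p.trainable or not trainable_only)))


def millions_floor(count: int) -> int:
    """Parameter count floored to whole millions (reporting convention)."""
    return count // 1_000_000


def extract_features(model: Model, images: np.ndarray, preprocess=None,
                     batch_size: int = 256) -> np.ndarray:
    """Penultimate features in evaluation mode, batched; (n, d) float32."""
    chunks = []
    for start in range(0, len(images), batch_size):
        x = images[start:start + batch_size]
        if preprocess is not None:
            x = preprocess(x)
        chunks.append(np.asarray(model.features(x, train=False), dtype=np.float32))
    return np.concatenate(chunks, axis=0)


def predict_logits(model: Model, images: np.ndarray, preprocess=None,
                   batch_size: int = 256) -> np.ndarray:
    feats = extract_features(model, images, preprocess, batch_size)
    return feats @ model.head.W.value + model.head.b.value


# ---------------------------------------------------------------------------
# checkpoints: a single NPZ with a JSON meta record plus named tensors


def save_checkpoint(model: Model, path) -> None:
    meta = dict(schema=CHECKPOINT_SCHEMA, arch=model.arch,
                task_kind=model.task.kind, num_classes=model.task.num_classes,
                label_layout=model.task.label_layout,
                frozen_backbone=model.frozen_backbone)
    arrays = {f"param::{k}": p.value for k, p in model.named_params().items()}
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **arrays)


def load_checkpoint(path) -> Model:
    with np.load(path) as npz:
        meta = json.loads(bytes(npz["__meta__"]).decode())
        arrays = {k[len("param::"):]: npz[k] for k in npz.files if k.startswith("param::")}
    if meta.get("schema") != CHECKPOINT_SCHEMA:
        raise ValueError(f"unsupported checkpoint schema {meta.get('schema')!r}")
    task = TaskSpec(meta["task_kind"], meta["num_classes"], meta["label_layout"])
    arch = meta["arch"]
    if arch in ("resnet50", "tiny"):
        model = build_student(arch, task)
    elif arch in VARIANTS or arch == "tiny-teacher":
        model = build_teacher(arch, task)
    else:
        raise ValueError(f"unknown checkpoint architecture {arch!r}")
    own = model.named_params()
    for name, p in own.items():
        if name not in arrays:
            raise ValueError(f"checkpoint missing tensor {name!r}")
        if arrays[name].shape != p.value.shape:
            raise ValueError(f"checkpoint tensor {name!r} has shape "
                             f"{arrays[name].shape}, expected {p.value.shape}")
        p.value = arrays[name].astype(np.float32)
    if meta.get("frozen_backbone"):
        model.freeze_backbone()
    return model
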