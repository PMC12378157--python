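"""Feature-space 2-D embeddings and class-evidence heatmaps.

Embeddings use t-SNE on penultimate-layer features with a mandatory seed.
Heatmaps use gradient-weighted class-activation mapping on the last
convolutional block: channel weights are the spatially averaged gradients
of the target class score with respect to the block's activations, the
weighted sum is rectified, bilinearly upsampled to the input size, and
max-normalized to [0, 1]. For the architectures here (global average
pooling followed by a linear head) the gradients are exact and cheap to
compute from the head weights' backward pass.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.transform import resize as _sk_resize
from sklearn.manifold import TSNE

from .models import Model


@dataclass
class Embedding2D:
    coords: np.ndarray          # (n, 2)
    labels: np.ndarray | None   # per-row label, if given
    source: str
    seed: int

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.coords, columns=["x", "y"])
        if self.labels is not None:
            lab = np.asarray(self.labels).reshape(len(df), -1)
            if lab.shape[1] == 1:
                df["label"] = lab.reshape(-1)
            else:  # multilabel indicator rows, e.g. "0;1;0"
                df["label"] = [";".join(map(str, row)) for row in lab]
        return df


@dataclass
class Heatmap:
    map: np.ndarray             # (H, W) in [0, 1]
    class_index: int
    degenerate: bool = False    # all-zero relevance before normalization


def embed_features_2d(features: np.ndarray, seed: int, perplexity: float = 30.0,
                      labels: np.ndarray | None = None,
                      source: str = "model") -> Embedding2D:
    """Deterministic t-SNE embedding of an (n, d) feature matrix."""
    features = np.asarray(features, dtype=np.float64)
    n = len(features)
    if n <= 3 * perplexity:
        raise ValueError(
            f"need n > 3*perplexity rows for t-SNE; got n={n}, perplexity={perplexity}")
    tsne = TSNE(n_components=2, perplexity=perplexity, random_state=int(seed),
                init="pca")
    coords = tsne.fit_transform(features)
    return Embedding2D(np.asarray(coords, dtype=np.float64), labels, source, int(seed))


def gradcam_heatmap(model: Model, image: np.ndarray, target_class: int) -> Heatmap:
    """Class-activation heatmap for one preprocessed image (3, S, S)."""
    backbone = model.backbone
    if not hasattr(backbone, "feature_map"):
        raise TypeError(
            f"{model.arch!r} has no convolutional feature map; heatmaps require "
            "a convolutional model")
    m = model.task.num_classes
    if not 0 <= target_class < m:
        raise ValueError(f"class index {target_class} out of range [0, {m})")
    x = np.asarray(image, dtype=np.float32)
    if x.ndim == 3:
        x = x[None]
    side = x.shape[-1]
    A = backbone.feature_map(x, train=False)       # (1, c, h, w)
    _, c, h, w = A.shape
    # d(score)/d(pooled features) via the head, then spread over the pool
    dz = np.zeros((1, m), dtype=np.float32)
    dz[0, target_class] = 1.0
    dpooled = dz @ model.head.W.value.T            # (1, c)
    dA = dpooled[:, :, None, None] / (h * w)       # gradient w.r.t. A
    weights = dA.mean(axis=(2, 3))                 # (1, c)
    cam = np.maximum((weights[:, :, None, None] * A).sum(axis=1)[0], 0.0)
    degenerate = not np.any(cam > 0)
    cam = _sk_resize(cam, (side, side), order=1, anti_aliasing=False,
                     preserve_range=True)
    cam = np.maximum(cam, 0.0)
    peak = cam.max()
    if peak > 0:
        cam = cam / peak
    return Heatmap(cam.astype(np.float64), int(target_class), degenerate)


def heatmap_center_of_mass(hm: Heatmap) -> tuple[float, float]:
    """(row, col) center of mass of the relevance map."""
    total = hm.map.sum()
    if total == 0:
        return ((hm.map.shape[0] - 1) / 2.0, (hm.map.shape[1] - 1) / 2.0)
    rows, cols = np.mgrid[0:hm.map.shape[0], 0:hm.map.shape[1]]
    return float((rows * hm.map).sum() / total), float((cols * hm.map).sum() / total)
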