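"""Vision Transformer constructors with DINOv2 dimensions (forward only).

Patch size 14, qkv bias, per-block layer-scale, class token, and position
embeddings sized for the 37×37 patch grid of the native 518-pixel training
resolution, bicubically interpolated at use time for other input sides.
The teacher role is frozen by design, so no backward pass exists here:
linear probing trains only a head on the features this module extracts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import erf
from skimage.transform import resize as _sk_resize

from .layers import Param

NATIVE_GRID = 37  # 518 / 14

VARIANTS = {
    "s14": dict(embed_dim=384, depth=12, num_heads=6),
    "b14": dict(embed_dim=768, depth=12, num_heads=12),
    "l14": dict(embed_dim=1024, depth=24, num_heads=16),
}


@dataclass
class _Block:
    ln1_g: Param
    ln1_b: Param
    qkv_W: Param
    qkv_b: Param
    proj_W: Param
    proj_b: Param
    ls1: Param
    ln2_g: Param
    ln2_b: Param
    fc1_W: Param
    fc1_b: Param
    fc2_W: Param
    fc2_b: Param
    ls2: Param


def _ln(x, g, b, eps=1e-6):
    mu = x.mean(-1, keepdims=True)
    var = x.var(-1, keepdims=True)
    return g * (x - mu) / np.sqrt(var + eps) + b


def _gelu(x):
    return 0.5 * x * (1.0 + erf(x / np.sqrt(2.0)))


def _softmax(x):
    x = x - x.max(-1, keepdims=True)
    e = np.exp(x)
    return e / e.sum(-1, keepdims=True)


class VisionTransformer:
    """Forward-only ViT feature extractor; features = final class token."""

    patch_size = 14

    def __init__(self, embed_dim: int, depth: int, num_heads: int,
                 rng: np.random.Generator | None = None, init_scale: float = 0.02):
        rng = rng or np.random.default_rng(0)
        d = embed_dim
        self.embed_dim = d
        self.depth = depth
        self.num_heads = num_heads
        p = self.patch_size

        def rnd(*shape):
            return Param(rng.standard_normal(shape, dtype=np.float32) * np.float32(init_scale))

        self.patch_W = rnd(d, 3, p, p)
        self.patch_b = Param(np.zeros(d, dtype=np.float32))
        self.cls_token = rnd(1, 1, d)
        self.pos_embed = rnd(1, NATIVE_GRID * NATIVE_GRID + 1, d)
        self.blocks: list[_Block] = []
        hidden = 4 * d
        for _ in range(depth):
            self.blocks.append(_Block(
                ln1_g=Param(np.ones(d, np.float32)), ln1_b=Param(np.zeros(d, np.float32)),
                qkv_W=rnd(d, 3 * d), qkv_b=Param(np.zeros(3 * d, np.float32)),
                proj_W=rnd(d, d), proj_b=Param(np.zeros(d, np.float32)),
                ls1=Param(np.full(d, 1e-5, np.float32)),
                ln2_g=Param(np.ones(d, np.float32)), ln2_b=Param(np.zeros(d, np.float32)),
                fc1_W=rnd(d, hidden), fc1_b=Param(np.zeros(hidden, np.float32)),
                fc2_W=rnd(hidden, d), fc2_b=Param(np.zeros(d, np.float32)),
                ls2=Param(np.full(d, 1e-5, np.float32)),
            ))
        self.norm_g = Param(np.ones(d, np.float32))
        self.norm_b = Param(np.zeros(d, np.float32))

    @property
    def feature_dim(self) -> int:
        return self.embed_dim

    # -- parameters ------------------------------------------------------
    def params(self) -> dict[str, Param]:
        out = {"patch_W": self.patch_W, "patch_b": self.patch_b,
               "cls_token": self.cls_token, "pos_embed": self.pos_embed}
        for i, blk in enumerate(self.blocks):
            for name, p in vars(blk).items():
                out[f"blocks.{i}.{name}"] = p
        out["norm_g"] = self.norm_g
        out["norm_b"] = self.norm_b
        return out

    def load_state(self, arrays: dict[str, np.ndarray]) -> None:
        """Load pretrained tensors by name; shape mismatches name the tensor."""
        own = self.params()
        for name, p in own.items():
            if name not in arrays:
                raise ValueError(f"missing tensor in weight file: {name}")
            arr = np.asarray(arrays[name])
            if arr.shape != p.value.shape:
                raise ValueError(
                    f"weight/architecture mismatch at tensor '{name}': "
                    f"file has {arr.shape}, architecture expects {p.value.shape}")
            p.value = arr.astype(np.float32)

    # -- forward ---------------------------------------------------------
    def _interp_pos_embed(self, grid: int) -> np.ndarray:
        pe = self.pos_embed.value[0]
        cls_pe, patch_pe = pe[:1], pe[1:]
        if grid == NATIVE_GRID:
            return pe[None]
        field = patch_pe.reshape(NATIVE_GRID, NATIVE_GRID, self.embed_dim)
        field = _sk_resize(field, (grid, grid, self.embed_dim), order=3,
                           anti_aliasing=False, preserve_range=True)
        return np.concatenate(
            [cls_pe, field.reshape(grid * grid, self.embed_dim)], axis=0
        )[None].astype(np.float32)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """(b,3,S,S) → (b, embed_dim) class-token features. S must be a
        multiple of the patch size."""
        b, c, h, w = x.shape
        p = self.patch_size
        if h != w or h % p:
            raise ValueError(f"input side must be a multiple of {p}, got {h}x{w}")
        grid = h // p
        # patch embedding: non-overlapping p×p conv == blockwise matmul
        patches = x.reshape(b, c, grid, p, grid, p).transpose(0, 2, 4, 1, 3, 5)
        patches = patches.reshape(b, grid * grid, c * p * p)
        Wm = self.patch_W.value.reshape(self.embed_dim, -1)
        tok = patches @ Wm.T + self.patch_b.value
        cls = np.broadcast_to(self.cls_token.value, (b, 1, self.embed_dim))
        tok = np.concatenate([cls, tok], axis=1) + self._interp_pos_embed(grid)

        nh = self.num_heads
        dh = self.embed_dim // nh
        n = tok.shape[1]
        for blk in self.blocks:
            y = _ln(tok, blk.ln1_g.value, blk.ln1_b.value)
            qkv = (y @ blk.qkv_W.value + blk.qkv_b.value).reshape(b, n, 3, nh, dh)
            q, k, v = (qkv[:, :, i].transpose(0, 2, 1, 3) for i in range(3))
            att = _softmax(q @ k.transpose(0, 1, 3, 2) / np.sqrt(dh))
            y = (att @ v).transpose(0, 2, 1, 3).reshape(b, n, self.embed_dim)
            tok = tok + blk.ls1.value * (y @ blk.proj_W.value + blk.proj_b.value)
            y = _ln(tok, blk.ln2_g.value, blk.ln2_b.value)
            y = _gelu(y @ blk.fc1_W.value + blk.fc1_b.value) @ blk.fc2_W.value + blk.fc2_b.value
            tok = tok + blk.ls2.value * y
        tok = _ln(tok, self.norm_g.value, self.norm_b.value)
        return tok[:, 0].astype(np.float32)

    __call__ = forward


def vit_backbone(variant: str, rng: np.random.Generator | None = None) -> VisionTransformer:
    key = variant.lower().replace("vit-", "").replace("/", "")
    if key not in VARIANTS:
        raise ValueError(f"unknown ViT variant {variant!r}; choose from {sorted(VARIANTS)}")
    return VisionTransformer(**VARIANTS[key], rng=rng)
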