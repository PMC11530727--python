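"""Comparison-grid building blocks: alternative fusion, personalization,
and multitask strategies, plus the ablation runner.

Fusion variants consume the two encoded modality streams (physical
activity and speech, each a (B, d) embedding) and return a fused (B, d)
embedding.  Personalization variants map the shared macro embedding to a
(possibly participant-specific) representation.  Multitask variants are
the loss combiners in :mod:`moodfuse.objectives`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import FeedForward, Linear, Module, Tensor, concat, stack

FUSION_KINDS = ("basic_concat", "max", "gated", "attention", "solo_attention",
                "cross_modal", "pure_weighted", "druw")
PERSONALIZATION_KINDS = ("basic_ffnn", "transformer_only", "adapter",
                         "macromicro", "none")
MTL_KINDS = ("equal", "fixed_weighted", "multioutput", "druw")
MODALITY_MASKS = ("zcm", "pim", "speech", "all")


@dataclass
class AblationSpec:
    """One cell of the method-comparison grid."""

    fusion: str = "druw"
    personalization: str = "macromicro"
    mtl: str = "druw"
    modality_mask: str = "all"

    def __post_init__(self):
        if self.fusion not in FUSION_KINDS:
            raise ValueError(f"unknown fusion {self.fusion!r}")
        if self.personalization not in PERSONALIZATION_KINDS:
            raise ValueError(f"unknown personalization {self.personalization!r}")
        if self.mtl not in MTL_KINDS:
            raise ValueError(f"unknown mtl {self.mtl!r}")
        if self.modality_mask not in MODALITY_MASKS:
            raise ValueError(f"unknown modality mask {self.modality_mask!r}")


# The 17 method rows of the comparison table (fusion, personalization, mtl),
# "basic" mapping to the benchmark components and "proposed" to DRUW /
# macro-micro / DRUW respectively.
COMPARISON_GRID: tuple[AblationSpec, ...] = tuple(
    AblationSpec(f, p, m) for f, p, m in [
        ("basic_concat", "basic_ffnn", "fixed_weighted"),
        ("max", "basic_ffnn", "fixed_weighted"),
        ("gated", "basic_ffnn", "fixed_weighted"),
        ("attention", "basic_ffnn", "fixed_weighted"),
        ("solo_attention", "basic_ffnn", "fixed_weighted"),
        ("cross_modal", "basic_ffnn", "fixed_weighted"),
        ("druw", "basic_ffnn", "fixed_weighted"),
        ("basic_concat", "transformer_only", "fixed_weighted"),
        ("basic_concat", "adapter", "fixed_weighted"),
        ("basic_concat", "macromicro", "fixed_weighted"),
        ("basic_concat", "basic_ffnn", "equal"),
        ("basic_concat", "basic_ffnn", "multioutput"),
        ("basic_concat", "basic_ffnn", "druw"),
        ("druw", "macromicro", "fixed_weighted"),
        ("basic_concat", "macromicro", "druw"),
        ("druw", "basic_ffnn", "druw"),
        ("druw", "macromicro", "druw"),
    ]
)


# -- fusion variants -----------------------------------------------------------

class ConcatFusion(Module):
    """Pure concatenation: [h_phys; h_speech] projected back to d."""

    def __init__(self, dim: int, rng: np.random.Generator):
        super().__init__()
        self.proj = Linear(2 * dim, dim, rng)

    def __call__(self, h_phys: Tensor, h_speech: Tensor) -> Tensor:
        return self.proj(concat([h_phys, h_speech], axis=-1))


class MaxFusion(Module):
    """Element-wise maximum across modality feature dimensions."""

    def __init__(self, dim: int, rng: np.random.Generator):
        super().__init__()

    def __call__(self, h_phys: Tensor, h_speech: Tensor) -> Tensor:
        return h_phys.maximum(h_speech)


class GatedFusion(Module):
    """g = sigmoid(G [h_phys; h_speech] + b); fused = g*h_phys + (1-g)*h_speech."""

    def __init__(self, dim: int, rng: np.random.Generator):
        super().__init__()
        self.gate = Linear(2 * dim, dim, rng)

    def __call__(self, h_phys: Tensor, h_speech: Tensor) -> Tensor:
        g = self.gate(concat([h_phys, h_speech], axis=-1)).sigmoid()
        return g * h_phys + (1.0 - g) * h_speech


class _SingleHeadAttention(Module):
    """softmax(Q K^T / sqrt(d)) V over a (B, T, d) sequence."""

    def __init__(self, dim: int, rng: np.random.Generator):
        super().__init__()
        self.wq = Linear(dim, dim, rng)
        self.wk = Linear(dim, dim, rng)
        self.wv = Linear(dim, dim, rng)
        self.dim = dim
        self.last_attention: np.ndarray | None = None

    def __call__(self, x: Tensor) -> Tensor:
        scores = (self.wq(x) @ self.wk(x).swapaxes(-1, -2)) * (1.0 / np.sqrt(self.dim))
        att = scores.softmax(axis=-1)
        self.last_attention = att.data
        return att @ self.wv(x)


class AttentionFusion(Module):
    """Attention-based fusion in one of three modes.

    post_concat: self-attention over the 2 modality tokens, mean-pooled.
    solo: each modality re-weighted by its own single-token attention
      before concatenation + projection.
    cross_modal: each modality's query attends to the other's key/value;
      the two outputs are summed.
    """

    def __init__(self, dim: int, rng: np.random.Generator, mode: str = "post_concat"):
        super().__init__()
        if mode not in ("post_concat", "solo", "cross_modal"):
            raise ValueError(f"unknown attention fusion mode {mode!r}")
        self.mode = mode
        self.attn = _SingleHeadAttention(dim, rng)
        if mode in ("solo", "cross_modal"):
            self.attn_speech = _SingleHeadAttention(dim, rng)
        if mode == "solo":
            self.proj = Linear(2 * dim, dim, rng)

    def __call__(self, h_phys: Tensor, h_speech: Tensor) -> Tensor:
        if self.mode == "post_concat":
            seq = stack([h_phys, h_speech], axis=1)
            return self.attn(seq).mean(axis=1)
        if self.mode == "solo":
            a = self.attn(stack([h_phys], axis=1)).mean(axis=1)
            b = self.attn_speech(stack([h_speech], axis=1)).mean(axis=1)
            return self.proj(concat([a, b], axis=-1))
        # cross_modal: each modality's single-token query attends to the
        # other's key/value; the softmax over one key is exactly 1, so the
        # attended output is the other modality's value projection
        out_p = self.attn(stack([h_speech], axis=1)).mean(axis=1)
        out_s = self.attn_speech(stack([h_phys], axis=1)).mean(axis=1)
        return out_p + out_s


def take_token(seq: Tensor, t: int) -> Tensor:
    b, n, d = seq.shape
    picker = np.zeros((n, 1))
    picker[t, 0] = 1.0
    return (seq.swapaxes(1, 2) @ Tensor(picker)).reshape(b, d)


class PureWeightedFusion(Module):
    """Fixed non-negative convex-style weights over the two modalities."""

    def __init__(self, dim: int, rng: np.random.Generator,
                 weights: tuple[float, float] = (0.5, 0.5)):
        super().__init__()
        if any(w < 0 for w in weights):
            raise ValueError("fusion weights must be >= 0")
        self.w = tuple(float(w) for w in weights)

    def __call__(self, h_phys: Tensor, h_speech: Tensor) -> Tensor:
        return h_phys * self.w[0] + h_speech * self.w[1]


# convenience functional forms matching the grid nomenclature ------------------

def basic_concat_fusion(h_phys, h_speech, proj: Linear) -> Tensor:
    return proj(concat([Tensor._wrap(h_phys), Tensor._wrap(h_speech)], axis=-1))


def max_fusion(h_phys, h_speech) -> Tensor:
    return Tensor._wrap(h_phys).maximum(Tensor._wrap(h_speech))


def gated_fusion(h_phys, h_speech, gate: Linear) -> Tensor:
    h_phys, h_speech = Tensor._wrap(h_phys), Tensor._wrap(h_speech)
    g = gate(concat([h_phys, h_speech], axis=-1)).sigmoid()
    return g * h_phys + (1.0 - g) * h_speech


def pure_weighted_fusion(h_phys, h_speech, weights) -> Tensor:
    if any(w < 0 for w in weights):
        raise ValueError("fusion weights must be >= 0")
    return Tensor._wrap(h_phys) * float(weights[0]) + Tensor._wrap(h_speech) * float(weights[1])


def attention_fusion(h_phys, h_speech, module: AttentionFusion) -> Tensor:
    return module(Tensor._wrap(h_phys), Tensor._wrap(h_speech))


def make_fusion(kind: str, dim: int, rng: np.random.Generator) -> Module | None:
    """Instantiate a fusion variant; DRUW is handled inside the model."""
    if kind == "druw":
        return None
    if kind == "basic_concat":
        return ConcatFusion(dim, rng)
    if kind == "max":
        return MaxFusion(dim, rng)
    if kind == "gated":
        return GatedFusion(dim, rng)
    if kind == "attention":
        return AttentionFusion(dim, rng, mode="post_concat")
    if kind == "solo_attention":
        return AttentionFusion(dim, rng, mode="solo")
    if kind == "cross_modal":
        return AttentionFusion(dim, rng, mode="cross_modal")
    if kind == "pure_weighted":
        return PureWeightedFusion(dim, rng)
    raise ValueError(f"unknown fusion kind {kind!r}")


# -- personalization variants ---------------------------------------------------

class Adapter(Module):
    """Bottleneck adapter d -> d/8 -> d with a residual connection.

    The up-projection starts at zero, so the adapter is the identity at
    initialization and personalization grows from the shared solution.
    """

    def __init__(self, dim: int, rng: np.random.Generator, ratio: int = 8):
        super().__init__()
        hidden = max(1, dim // ratio)
        self.down = Linear(dim, hidden, rng)
        self.up = Linear(hidden, dim, rng, zero_init=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x + self.up(self.down(x).relu())


class SharedFFNN(Module):
    """Non-personalized 2-layer FFNN head (the benchmark 'basic' variant)."""

    def __init__(self, dim: int, rng: np.random.Generator, dropout: float = 0.1):
        super().__init__()
        self.net = FeedForward(dim, dim, dim, rng, dropout=dropout)

    def __call__(self, x: Tensor) -> Tensor:
        return self.net(x)


def run_ablation(spec: AblationSpec, dataset, split, train_config,
                 model_config=None, grid_csv=None):
    """Train one grid cell end-to-end and return its test evaluation table.

    ``dataset`` must already be cleaned, label-normalized, and
    standardized; results are optionally appended to ``grid_csv`` in the
    comparison-table layout.
    """
    from dataclasses import replace

    from .model import EmotionModel, ModelConfig
    from .training import evaluate, train

    model_config = model_config or ModelConfig()
    model = EmotionModel(dataset.participants(), dataset.speech_dim,
                         config=model_config, fusion=spec.fusion,
                         personalization=spec.personalization,
                         seed=train_config.seed)
    cfg = replace(train_config, mtl=spec.mtl, modality_mask=spec.modality_mask)
    checkpoint, history = train(model, dataset, split, cfg)
    table = evaluate(model, dataset, split, part="test",
                     modality_mask=spec.modality_mask)
    if grid_csv is not None:
        import os

        import pandas as pd
        row = {"fusion": spec.fusion, "personalization": spec.personalization,
               "multitask": spec.mtl, "modality_mask": spec.modality_mask,
               **{e: v for e, v in zip(table.emotions, table.ccc)},
               "mean": table.mean, "sd": table.sd}
        frame = pd.DataFrame([row])
        frame.to_csv(grid_csv, mode="a", index=False,
                     header=not (os.path.exists(grid_csv) and os.path.getsize(grid_csv) > 0))
    return table
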