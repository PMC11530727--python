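"""Neural-network building blocks on top of the autodiff tensors.

Modules hold :class:`~moodfuse.nn.tensor.Parameter` leaves and recurse
through attributes that are Modules, lists or dicts of Modules.  All
random initialization draws from an explicitly passed numpy Generator so
that model construction is reproducible.
"""

from __future__ import annotations

import numpy as np

from .tensor import Parameter, Tensor, concat, stack

__all__ = [
    "Module",
    "Linear",
    "FeedForward",
    "Dropout",
    "LayerNorm",
    "MultiHeadSelfAttention",
    "TransformerEncoderLayer",
]


class Module:
    """Base class: parameter traversal and train/eval mode switching."""

    def __init__(self):
        self._training = True

    # attribute traversal ---------------------------------------------------

    def _children(self):
        for name, value in vars(self).items():
            if isinstance(value, Module):
                yield name, value
            elif isinstance(value, (list, tuple)):
                for i, v in enumerate(value):
                    if isinstance(v, Module):
                        yield f"{name}.{i}", v
            elif isinstance(value, dict):
                for k, v in value.items():
                    if isinstance(v, Module):
                        yield f"{name}.{k}", v

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            if isinstance(value, Parameter):
                yield prefix + name, value
            elif isinstance(value, (list, tuple)):
                for i, v in enumerate(value):
                    if isinstance(v, Parameter):
                        yield f"{prefix}{name}.{i}", v
            elif isinstance(value, dict):
                for k, v in value.items():
                    if isinstance(v, Parameter):
                        yield f"{prefix}{name}.{k}", v
        for name, child in self._children():
            yield from child.named_parameters(prefix + name + ".")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def train(self):
        self._training = True
        for _, child in self._children():
            child.train()
        return self

    def eval(self):
        self._training = False
        for _, child in self._children():
            child.eval()
        return self

    @property
    def training(self) -> bool:
        return self._training

    # checkpointing ---------------------------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]):
        params = dict(self.named_parameters())
        missing = set(params) - set(state)
        extra = set(state) - set(params)
        if missing or extra:
            raise ValueError(f"state mismatch: missing={sorted(missing)} extra={sorted(extra)}")
        for name, p in params.items():
            arr = np.asarray(state[name], dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()


class Linear(Module):
    """Affine map ``x @ W + b`` with uniform(-1/sqrt(fan_in)) init."""

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator,
                 zero_init: bool = False):
        super().__init__()
        if zero_init:
            w = np.zeros((in_dim, out_dim))
            b = np.zeros(out_dim)
        else:
            bound = 1.0 / np.sqrt(in_dim)
            w = rng.uniform(-bound, bound, size=(in_dim, out_dim))
            b = rng.uniform(-bound, bound, size=out_dim)
        self.weight = Parameter(w)
        self.bias = Parameter(b)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Dropout(Module):
    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self._rng = rng

    def __call__(self, x: Tensor) -> Tensor:
        if not self._training or self.rate == 0.0:
            return x
        keep = 1.0 - self.rate
        mask = (self._rng.random(x.shape) < keep) / keep
        return x * Tensor(mask)


class FeedForward(Module):
    """2-layer feed-forward network: Linear -> ReLU -> Dropout -> Linear."""

    def __init__(self, in_dim: int, hidden_dim: int, out_dim: int,
                 rng: np.random.Generator, dropout: float = 0.1,
                 zero_init_out: bool = False):
        super().__init__()
        self.fc1 = Linear(in_dim, hidden_dim, rng)
        self.fc2 = Linear(hidden_dim, out_dim, rng, zero_init=zero_init_out)
        self.drop = Dropout(dropout, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(self.drop(self.fc1(x).relu()))


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered ** 2).mean(axis=-1, keepdims=True)
        return centered / (var + self.eps).sqrt() * self.gamma + self.beta


class MultiHeadSelfAttention(Module):
    """Standard scaled dot-product self-attention over (B, T, d) sequences."""

    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator):
        super().__init__()
        if dim % n_heads:
            raise ValueError("dim must be divisible by n_heads")
        self.dim = dim
        self.n_heads = n_heads
        self.head_dim = dim // n_heads
        self.wq = Linear(dim, dim, rng)
        self.wk = Linear(dim, dim, rng)
        self.wv = Linear(dim, dim, rng)
        self.wo = Linear(dim, dim, rng)
        self.last_attention: np.ndarray | None = None  # (B, H, T, T), diagnostics

    def _split(self, x: Tensor, batch: int, t: int) -> Tensor:
        return x.reshape(batch, t, self.n_heads, self.head_dim).transpose((0, 2, 1, 3))

    def __call__(self, x: Tensor) -> Tensor:
        batch, t, _ = x.shape
        q = self._split(self.wq(x), batch, t)
        k = self._split(self.wk(x), batch, t)
        v = self._split(self.wv(x), batch, t)
        scores = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(self.head_dim))
        att = scores.softmax(axis=-1)
        self.last_attention = att.data
        out = (att @ v).transpose((0, 2, 1, 3)).reshape(batch, t, self.dim)
        return self.wo(out)


class TransformerEncoderLayer(Module):
    """Post-norm encoder layer: self-attention + position-wise feed-forward."""

    def __init__(self, dim: int, n_heads: int, ff_dim: int,
                 rng: np.random.Generator, dropout: float = 0.1):
        super().__init__()
        self.attn = MultiHeadSelfAttention(dim, n_heads, rng)
        self.norm1 = LayerNorm(dim)
        self.ff1 = Linear(dim, ff_dim, rng)
        self.ff2 = Linear(ff_dim, dim, rng)
        self.drop = Dropout(dropout, rng)
        self.norm2 = LayerNorm(dim)

    def __call__(self, x: Tensor) -> Tensor:
        x = self.norm1(x + self.attn(x))
        ff = self.ff2(self.drop(self.ff1(x).relu()))
        return self.norm2(x + ff)
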