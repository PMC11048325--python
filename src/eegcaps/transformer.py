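"""Inter-slice encoder: Transformer over the T per-slice emotion vectors.

Each time slice's ``n_classes x 16`` class-capsule outputs are flattened
row-major into one token of width ``d_model = n_classes * 16``; the T tokens
of one recognition-cycle sample (T = 4 by default) form the input sequence.
A stack of six post-norm encoder layers — eight-head scaled dot-product
self-attention, then a two-layer ReLU feed-forward block, each sublayer
wrapped in residual + LayerNorm — re-encodes the sequence, and a softmax
head classifies the concatenation of all T encoded tokens.

Sinusoidal positional encoding is added before the first layer by default
(temporal order is the point of this module) and can be disabled for
ablation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .nn import Dropout, LayerNorm, Linear, Module, Tensor, softmax

__all__ = [
    "EncoderConfig",
    "flatten_slices",
    "unflatten_slices",
    "sinusoidal_positions",
    "scaled_dot_attention",
    "MultiHeadSelfAttention",
    "EncoderLayer",
    "TemporalEncoder",
    "ClassifierHead",
]


@dataclass(frozen=True)
class EncoderConfig:
    n_layers: int = 6
    n_heads: int = 8
    n_classes: int = 2
    emotion_caps_dim: int = 16
    ffn_hidden_factor: int = 4   # FFN hidden width = factor * d_model
    dropout: float = 0.1
    T: int = 4                   # slices per recognition-cycle sample
    positional_encoding: str = "sinusoidal"  # or "none"

    @property
    def d_model(self) -> int:
        return self.n_classes * self.emotion_caps_dim

    def __post_init__(self) -> None:
        if self.d_model % self.n_heads != 0:
            raise ValueError(
                f"d_model {self.d_model} must be divisible by n_heads {self.n_heads}"
            )
        if self.T < 1:
            raise ValueError("T must be >= 1")
        if self.positional_encoding not in ("none", "sinusoidal"):
            raise ValueError("positional_encoding must be 'none' or 'sinusoidal'")


def flatten_slices(vectors: np.ndarray) -> np.ndarray:
    """(T, n_classes, dim) emotion vectors -> (T, n_classes * dim) tokens.

    Row-major per slice; tokens are concatenated in temporal order.
    """
    v = np.asarray(vectors)
    if v.ndim != 3:
        raise ValueError("expected (T, n_classes, dim) vectors")
    t, j, d = v.shape
    return v.reshape(t, j * d)


def unflatten_slices(tokens: np.ndarray, n_classes: int) -> np.ndarray:
    """Inverse of :func:`flatten_slices`."""
    t, dm = np.asarray(tokens).shape
    if dm % n_classes != 0:
        raise ValueError("token width not divisible by n_classes")
    return np.asarray(tokens).reshape(t, n_classes, dm // n_classes)


def sinusoidal_positions(t: int, d_model: int) -> np.ndarray:
    """Standard sin/cos positional-encoding table of shape (t, d_model)."""
    pos = np.arange(t)[:, None]
    i = np.arange(d_model // 2)[None, :]
    angles = pos / np.power(10000.0, 2 * i / d_model)
    pe = np.zeros((t, d_model))
    pe[:, 0::2] = np.sin(angles)
    pe[:, 1::2] = np.cos(angles)
    return pe


def scaled_dot_attention(q: Tensor, k: Tensor, v: Tensor) -> Tensor:
    """``softmax(Q K^T / sqrt(d_k)) V``; softmax rows sum to 1."""
    d_k = q.shape[-1]
    scores = (q @ k.transpose(*range(k.ndim - 2), k.ndim - 1, k.ndim - 2)) \
        * (1.0 / math.sqrt(d_k))
    return softmax(scores, axis=-1) @ v


class MultiHeadSelfAttention(Module):
    """Eight (configurable) parallel attentions over learned subspaces."""

    def __init__(self, d_model: int, n_heads: int, rng: np.random.Generator):
        super().__init__()
        if d_model % n_heads != 0:
            raise ValueError("d_model must be divisible by n_heads")
        self.d_model, self.n_heads = d_model, n_heads
        self.d_head = d_model // n_heads
        self.wq = Linear(d_model, d_model, rng)
        self.wk = Linear(d_model, d_model, rng)
        self.wv = Linear(d_model, d_model, rng)
        self.wo = Linear(d_model, d_model, rng)

    def _split(self, x: Tensor, b: int, t: int) -> Tensor:
        return x.reshape(b, t, self.n_heads, self.d_head).transpose(0, 2, 1, 3)

    def forward(self, x: Tensor) -> Tensor:
        b, t, d = x.shape
        q = self._split(self.wq(x), b, t)  # (B, H, T, d_head)
        k = self._split(self.wk(x), b, t)
        v = self._split(self.wv(x), b, t)
        a = scaled_dot_attention(q, k, v)  # (B, H, T, d_head)
        out = a.transpose(0, 2, 1, 3).reshape(b, t, d)  # concat heads
        return self.wo(out)


class EncoderLayer(Module):
    """Post-norm: x1 = LN(x + MHSA(x)); out = LN(x1 + FFN(x1))."""

    def __init__(self, cfg: EncoderConfig, rng: np.random.Generator,
                 dropout_rng: np.random.Generator):
        super().__init__()
        d = cfg.d_model
        hidden = cfg.ffn_hidden_factor * d
        self.mhsa = MultiHeadSelfAttention(d, cfg.n_heads, rng)
        self.ln1 = LayerNorm(d)
        self.ffn1 = Linear(d, hidden, rng)
        self.ffn2 = Linear(hidden, d, rng)
        self.ln2 = LayerNorm(d)
        self.drop1 = Dropout(cfg.dropout, dropout_rng)
        self.drop2 = Dropout(cfg.dropout, dropout_rng)

    def forward(self, x: Tensor) -> Tensor:
        x1 = self.ln1(x + self.drop1(self.mhsa(x)))
        return self.ln2(x1 + self.drop2(self.ffn2(self.ffn1(x1).relu())))


class TemporalEncoder(Module):
    """Positional encoding + a stack of encoder layers."""

    def __init__(self, cfg: EncoderConfig, rng: np.random.Generator,
                 dropout_rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        self.layers = [EncoderLayer(cfg, rng, dropout_rng) for _ in range(cfg.n_layers)]

    def forward(self, x: Tensor) -> Tensor:
        b, t, d = x.shape
        if self.cfg.positional_encoding == "sinusoidal":
            x = x + Tensor(sinusoidal_positions(t, d)[None])
        for layer in self.layers:
            x = layer(x)
        return x


class ClassifierHead(Module):
    """Affine map of the T concatenated encoded tokens to class logits."""

    def __init__(self, d_model: int, t: int, n_classes: int,
                 rng: np.random.Generator):
        super().__init__()
        self.fc = Linear(t * d_model, n_classes, rng)

    def forward(self, x: Tensor) -> Tensor:
        b, t, d = x.shape
        return self.fc(x.reshape(b, t * d))

    def classify(self, x: Tensor) -> Tensor:
        """Softmax class probabilities (each row sums to 1)."""
        return softmax(self.forward(x), axis=-1)
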