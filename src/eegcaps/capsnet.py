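"""Intra-slice encoder: attention-augmented capsule network.

One 3 x 16 x 18 multi-domain feature map passes through

* **ConvReLU** — 256 kernels of size 3 x 3, stride 2, valid padding, ReLU;
  output 256 x 7 x 8;
* **ECA** — efficient channel attention: global average pool to 1 x 1 x C, a
  1-D convolution of channel-adaptive odd size k over the channel axis, and
  sigmoid gating; shape preserved;
* **PrimaryCaps** — 32 convolutional 8-D capsule channels (3 x 3, stride 1),
  with an SE (squeeze-and-excitation) block applied to the 256 convolutional
  planes before the planes are regrouped into 32*5*6 = 960 capsules of
  dimension 8 and squashed;
* **EmotionCaps** — dynamic routing by agreement maps the primary capsules
  to one 16-D capsule per emotion class.

The capsule nonlinearity is the canonical squash
``v = (|s|^2 / (1 + |s|^2)) * s / |s|``, so every capsule norm lies in
[0, 1).  Routing runs a configurable number of iterations (default 3):
coupling coefficients are the softmax over output capsules of agreement
logits, updated by the dot product between prediction vectors and outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Conv2d, Linear, Module, Parameter, Tensor, concat, softmax

__all__ = [
    "CapsNetConfig",
    "EmotionVectors",
    "eca_kernel_size",
    "ECABlock",
    "SEBlock",
    "squash",
    "PrimaryCaps",
    "DynamicRouting",
    "CapsuleEncoder",
]


@dataclass(frozen=True)
class CapsNetConfig:
    """Architecture of the intra-slice encoder.

    The published-scale configuration is the default (256 conv planes,
    32 x 8D capsule channels); smaller widths are valid as long as
    ``primary_caps_channels * primary_caps_dim == conv_out_channels`` so the
    PrimaryCaps stage consumes the convolutional stack cleanly.
    """

    in_channels: int = 3
    conv_out_channels: int = 256
    conv_kernel: int = 3
    conv_stride: int = 2
    primary_caps_channels: int = 32
    primary_caps_dim: int = 8
    primary_conv_kernel: int = 3
    primary_conv_stride: int = 1
    emotion_caps_dim: int = 16
    n_classes: int = 2
    routing_iters: int = 3
    eca_gamma: float = 2.0
    eca_b: float = 1.0
    se_reduction: int = 16
    use_eca: bool = True
    use_se: bool = True

    def __post_init__(self) -> None:
        if self.primary_caps_channels * self.primary_caps_dim != self.conv_out_channels:
            raise ValueError(
                "primary_caps_channels * primary_caps_dim must equal "
                "conv_out_channels "
                f"({self.primary_caps_channels} * {self.primary_caps_dim} != "
                f"{self.conv_out_channels})"
            )
        if self.routing_iters < 1:
            raise ValueError("routing_iters must be >= 1")
        if self.n_classes not in (2, 3):
            raise ValueError("n_classes must be 2 or 3")


@dataclass
class EmotionVectors:
    """Per-slice class-capsule outputs: (n_classes, emotion_caps_dim)."""

    vectors: np.ndarray
    slice_ref: tuple[int, int] | None = None


def eca_kernel_size(C: int, gamma: float = 2.0, b: float = 1.0) -> int:
    """Channel-adaptive odd 1-D kernel size ``k = |log2(C)/gamma + b/gamma|_odd``.

    The magnitude is rounded down to the nearest odd integer not below 1
    (floor if the floor is odd, else floor + 1).
    """
    if C < 1:
        raise ValueError("C must be >= 1")
    t = abs(np.log2(C) / gamma + b / gamma)
    k = int(np.floor(t))
    if k % 2 == 0:
        k += 1
    return max(k, 1)


def squash(s: Tensor, axis: int = -1, eps: float = 1e-12) -> Tensor:
    """``v = (|s|^2 / (1 + |s|^2)) * s / |s|``; maps 0 to 0, norms into [0, 1)."""
    n2 = (s * s).sum(axis=axis, keepdims=True)
    n = (n2 + eps).sqrt()
    return s * (n / (1.0 + n2))


class ECABlock(Module):
    """Efficient channel attention over a (B, C, H, W) stack."""

    def __init__(self, channels: int, rng: np.random.Generator,
                 gamma: float = 2.0, b: float = 1.0):
        super().__init__()
        self.channels = channels
        self.k = eca_kernel_size(channels, gamma, b)
        bound = 1.0 / np.sqrt(self.k)
        self.weight = Parameter(rng.uniform(-bound, bound, size=self.k))

    def forward(self, x: Tensor) -> Tensor:
        b, c = x.shape[0], x.shape[1]
        if c != self.channels:
            raise ValueError(f"expected {self.channels} channels, got {c}")
        z = x.mean(axis=(2, 3))  # (B, C) squeeze
        pad = self.k // 2
        if pad:
            zeros = Tensor(np.zeros((b, pad)))
            zp = concat([zeros, z, zeros], axis=1)
        else:
            zp = z
        y = None
        for t in range(self.k):
            term = self.weight[t] * zp[:, t:t + c]
            y = term if y is None else y + term
        gate = y.sigmoid().reshape(b, c, 1, 1)
        return x * gate


class SEBlock(Module):
    """Squeeze-and-excitation: bottleneck excitation with sigmoid gating."""

    def __init__(self, channels: int, rng: np.random.Generator, reduction: int = 16):
        super().__init__()
        if channels < reduction:
            raise ValueError(
                f"channels ({channels}) must be >= reduction ({reduction})"
            )
        self.channels = channels
        hidden = channels // reduction
        self.fc1 = Linear(channels, hidden, rng, bias=False)
        self.fc2 = Linear(hidden, channels, rng, bias=False)

    def forward(self, x: Tensor) -> Tensor:
        b, c = x.shape[0], x.shape[1]
        if c != self.channels:
            raise ValueError(f"expected {self.channels} channels, got {c}")
        z = x.mean(axis=(2, 3))  # (B, C) squeeze
        s = self.fc2(self.fc1(z).relu()).sigmoid()  # excitation
        return x * s.reshape(b, c, 1, 1)


class PrimaryCaps(Module):
    """Convolutional capsule stage: conv planes -> SE -> capsules -> squash."""

    def __init__(self, cfg: CapsNetConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        self.conv = Conv2d(
            cfg.conv_out_channels, cfg.primary_caps_channels * cfg.primary_caps_dim,
            cfg.primary_conv_kernel, cfg.primary_conv_stride, rng,
        )
        self.se = SEBlock(
            cfg.primary_caps_channels * cfg.primary_caps_dim, rng, cfg.se_reduction
        ) if cfg.use_se else None

    def forward(self, x: Tensor) -> Tensor:
        h = self.conv(x)  # (B, caps*dim, Hp, Wp)
        if self.se is not None:
            h = self.se(h)
        b, planes, hp, wp = h.shape
        caps, dim = self.cfg.primary_caps_channels, self.cfg.primary_caps_dim
        u = h.reshape(b, caps, dim, hp, wp).transpose(0, 1, 3, 4, 2)
        u = u.reshape(b, caps * hp * wp, dim)
        return squash(u, axis=-1)


class DynamicRouting(Module):
    """Routing by agreement from N primary capsules to J class capsules.

    Each (i, j) pair owns a full ``d_out x d_in`` transform; coupling logits
    start at zero, so the first coupling coefficients are uniform 1/J.
    """

    def __init__(self, n_primary: int, d_in: int, n_out: int, d_out: int,
                 iters: int, rng: np.random.Generator, init_scale: float = 0.1):
        super().__init__()
        self.n_primary, self.d_in = n_primary, d_in
        self.n_out, self.d_out = n_out, d_out
        self.iters = iters
        self.weight = Parameter(
            rng.normal(0.0, init_scale, size=(n_primary, n_out * d_out, d_in))
        )

    def forward(self, u: Tensor, return_couplings: bool = False):
        b, n, d = u.shape
        if n != self.n_primary or d != self.d_in:
            raise ValueError(
                f"expected ({self.n_primary}, {self.d_in}) capsules, got ({n}, {d})"
            )
        j, dout = self.n_out, self.d_out
        # prediction vectors u_hat[b, i, j, :] = W_ij @ u[b, i]
        uhat = (self.weight @ u.reshape(b, n, d, 1)).reshape(b, n, j, dout)
        logits = Tensor(np.zeros((b, n, j)))
        couplings = []
        v = None
        for it in range(self.iters):
            c = softmax(logits, axis=2)
            couplings.append(c.data.copy())
            s = (c.reshape(b, n, j, 1) * uhat).sum(axis=1)  # (B, J, dout)
            v = squash(s, axis=-1)
            if it + 1 < self.iters:
                agreement = (uhat * v.reshape(b, 1, j, dout)).sum(axis=-1)
                logits = logits + agreement
        if return_couplings:
            return v, couplings
        return v


class CapsuleEncoder(Module):
    """Map one (or a batch of) 3 x 16 x 18 maps to per-class 16-D vectors."""

    def __init__(self, cfg: CapsNetConfig, rng: np.random.Generator,
                 in_rows: int = 16, in_cols: int = 18):
        super().__init__()
        self.cfg = cfg
        self.in_shape = (cfg.in_channels, in_rows, in_cols)
        self.conv = Conv2d(cfg.in_channels, cfg.conv_out_channels,
                           cfg.conv_kernel, cfg.conv_stride, rng)
        self.eca = ECABlock(cfg.conv_out_channels, rng, cfg.eca_gamma, cfg.eca_b) \
            if cfg.use_eca else None
        self.primary = PrimaryCaps(cfg, rng)

        h1 = (in_rows - cfg.conv_kernel) // cfg.conv_stride + 1
        w1 = (in_cols - cfg.conv_kernel) // cfg.conv_stride + 1
        h2 = (h1 - cfg.primary_conv_kernel) // cfg.primary_conv_stride + 1
        w2 = (w1 - cfg.primary_conv_kernel) // cfg.primary_conv_stride + 1
        self.n_primary = cfg.primary_caps_channels * h2 * w2
        self.routing = DynamicRouting(
            self.n_primary, cfg.primary_caps_dim, cfg.n_classes,
            cfg.emotion_caps_dim, cfg.routing_iters, rng,
        )

    def forward(self, x: Tensor) -> Tensor:
        if tuple(x.shape[1:]) != self.in_shape:
            raise ValueError(
                f"expected input (B, {self.in_shape}), got {tuple(x.shape)}"
            )
        h = self.conv(x).relu()
        if self.eca is not None:
            h = self.eca(h)
        u = self.primary(h)
        return self.routing(u)  # (B, n_classes, emotion_caps_dim)

    def encode_slice(self, feature_map: np.ndarray,
                     slice_ref: tuple[int, int] | None = None) -> EmotionVectors:
        """Convenience single-slice API returning an :class:`EmotionVectors`."""
        x = Tensor(np.asarray(feature_map)[None])
        v = self.forward(x)
        return EmotionVectors(vectors=v.data[0].copy(), slice_ref=slice_ref)
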