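"""End-to-end model: capsule encoder per slice + Transformer across slices.

A recognition-cycle sample is T consecutive 3 x 16 x 18 feature maps.  Every
map is encoded independently by the shared capsule encoder into
``n_classes x 16`` emotion vectors; the T flattened vectors form a sequence
for the temporal encoder; the softmax head classifies the concatenated
encoded tokens.

Ablation switches mirror the architecture study: ``use_eca`` / ``use_se``
drop the channel-attention blocks, and ``use_transformer=False`` replaces
the temporal encoder with direct classification of the flattened slice
vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .capsnet import CapsNetConfig, CapsuleEncoder
from .nn import Module, Tensor, softmax
from .transformer import ClassifierHead, EncoderConfig, TemporalEncoder

__all__ = ["ModelConfig", "EmotionCapsTransformer", "reduced_width_config"]


@dataclass(frozen=True)
class ModelConfig:
    capsnet: CapsNetConfig = field(default_factory=CapsNetConfig)
    encoder: EncoderConfig = field(default_factory=EncoderConfig)
    use_transformer: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.capsnet.n_classes != self.encoder.n_classes:
            raise ValueError("capsnet and encoder disagree on n_classes")
        if self.capsnet.emotion_caps_dim != self.encoder.emotion_caps_dim:
            raise ValueError("capsnet and encoder disagree on emotion_caps_dim")


def reduced_width_config(
    n_classes: int = 2,
    T: int = 4,
    seed: int = 0,
    use_eca: bool = True,
    use_se: bool = True,
    use_transformer: bool = True,
) -> ModelConfig:
    """A narrower configuration for CPU-scale experiments.

    Same architecture, reduced widths: 64 conv planes, 8 capsule channels of
    dimension 8, SE reduction 8; the temporal encoder keeps its full 6
    layers and 8 heads (d_model is small already).
    """
    caps = CapsNetConfig(
        conv_out_channels=64,
        primary_caps_channels=8,
        primary_caps_dim=8,
        n_classes=n_classes,
        se_reduction=8,
        use_eca=use_eca,
        use_se=use_se,
    )
    enc = EncoderConfig(n_classes=n_classes, T=T)
    return ModelConfig(capsnet=caps, encoder=enc, use_transformer=use_transformer, seed=seed)


class EmotionCapsTransformer(Module):
    """The full recognizer; forward maps (B, T, 3, 16, 18) to class logits."""

    def __init__(self, cfg: ModelConfig):
        super().__init__()
        self.cfg = cfg
        seq = np.random.SeedSequence(cfg.seed)
        init_rng, dropout_rng = [np.random.default_rng(s) for s in seq.spawn(2)]
        self.capsule = CapsuleEncoder(cfg.capsnet, init_rng)
        d_model = cfg.encoder.d_model
        if cfg.use_transformer:
            self.encoder = TemporalEncoder(cfg.encoder, init_rng, dropout_rng)
        else:
            self.encoder = None
        self.head = ClassifierHead(d_model, cfg.encoder.T, cfg.capsnet.n_classes, init_rng)

    def forward(self, x) -> Tensor:
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=np.float64))
        b, t = x.shape[0], x.shape[1]
        if t != self.cfg.encoder.T:
            raise ValueError(f"expected T={self.cfg.encoder.T} slices, got {t}")
        maps = x.reshape(b * t, *x.shape[2:])
        v = self.capsule(maps)                       # (B*T, J, 16)
        j, d = v.shape[1], v.shape[2]
        tokens = v.reshape(b, t, j * d)              # flatten + connect in order
        if self.encoder is not None:
            tokens = self.encoder(tokens)
        return self.head(tokens)                     # (B, n_classes) logits

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Class probabilities, computed in eval mode without gradients."""
        was_training = self.training
        self.eval()
        try:
            out = []
            for start in range(0, len(x), batch_size):
                logits = self.forward(np.asarray(x[start:start + batch_size]))
                out.append(softmax(logits, axis=-1).data)
            return np.concatenate(out, axis=0)
        finally:
            self.train(was_training)

    def predict(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        return self.predict_proba(x, batch_size).argmax(axis=1)
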