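"""Synthetic multichannel EEG with known class-conditional band structure.

The generator builds each trial as a sum of band-limited noise components
(one per canonical band: theta, alpha, beta, gamma) plus a broadband white
noise floor.  Emotion-class structure is injected by scaling the amplitude of
one band (``effect_band``) in a chosen subset of channels by
``(1 + class * effect_size)``, so downstream features (band power, DE) carry
a controllable, known class signal.  Everything is reproducible from an
explicit integer seed; there is no global random state.

The band components are produced by filtering independent white noise with
the same order-3 Butterworth bandpass used by the feature-map pipeline, which
guarantees the generator and the pipeline agree on band definitions.

What this emulates — and what it does not: band-limited stochastic activity
with a roughly 1/f amplitude profile and montage-consistent channel naming.
It does not simulate eye-blink/EMG artifacts, volume conduction, or
inter-subject variability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bands import CANONICAL_BANDS, BAND_ORDER, bandpass_filter
from .montages import DEAP32_CHANNEL_ORDER, load_layout
from .recording import MontageError, Recording

__all__ = ["SynthSpec", "generate_recording", "generate_deap_like"]

# Per-band RMS amplitudes (arbitrary microvolt-like units), decaying with
# frequency to mimic the 1/f profile of scalp EEG.
DEFAULT_BAND_AMPLITUDES: dict[str, float] = {
    "theta": 4.0,
    "alpha": 3.0,
    "beta": 1.5,
    "gamma": 1.0,
}

DEFAULT_EFFECT_CHANNELS = ("Fp1", "Fp2", "F3", "F4", "T7", "T8", "P3", "P4")


def _montage_channels(n_channels: int) -> list[str]:
    if n_channels == 32:
        return list(DEAP32_CHANNEL_ORDER)
    if n_channels == 62:
        return list(load_layout("seed62").channels)
    raise ValueError("n_channels must be 32 or 62")


@dataclass
class SynthSpec:
    """Study conditions for one synthetic recording."""

    n_channels: int = 32
    sampling_rate: float = 128.0
    n_trials: int = 20
    trial_duration: float = 40.0  # seconds
    n_classes: int = 2
    effect_channels: tuple[str, ...] = DEFAULT_EFFECT_CHANNELS
    effect_band: str = "gamma"
    effect_size: float = 1.0  # multiplier increment on band amplitude
    noise_sd: float = 1.0  # white-noise floor, signal units
    seed: int = 0
    band_amplitudes: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BAND_AMPLITUDES)
    )

    def validate(self) -> None:
        channels = _montage_channels(self.n_channels)
        unknown = [c for c in self.effect_channels if c not in channels]
        if unknown:
            raise MontageError(f"effect channels not in montage: {unknown}")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.sampling_rate <= 100:
            raise ValueError(
                "sampling_rate must exceed 100 Hz so the 31-50 Hz gamma band "
                "is representable"
            )
        if self.effect_band not in BAND_ORDER:
            raise ValueError(f"unknown effect_band {self.effect_band!r}")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _balanced_labels(n_trials: int, n_classes: int, rng: np.random.Generator) -> np.ndarray:
    """Class labels whose counts differ by at most one, in shuffled order."""
    base = np.arange(n_trials) % n_classes
    return rng.permutation(base)


def generate_recording(spec: SynthSpec) -> Recording:
    """Generate a Recording under the given study conditions.

    Each trial is ``sum_b amp_b * bandlimited_noise_b + noise_sd * white``;
    for a trial of class ``c`` the ``effect_band`` component in
    ``effect_channels`` is scaled by ``(1 + c * effect_size)``.  Labels are
    balanced across classes and the result is bit-reproducible from
    ``spec.seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    channels = _montage_channels(spec.n_channels)
    n_samples = int(round(spec.trial_duration * spec.sampling_rate))
    effect_idx = np.array([channels.index(c) for c in spec.effect_channels], dtype=int)

    y = _balanced_labels(spec.n_trials, spec.n_classes, rng)
    signals = []
    for trial in range(spec.n_trials):
        x = np.zeros((spec.n_channels, n_samples))
        for band in CANONICAL_BANDS:
            white = rng.standard_normal((spec.n_channels, n_samples))
            comp = bandpass_filter(white, band, spec.sampling_rate)
            # normalize each channel's component to unit RMS so band
            # amplitudes are exact, then apply the band amplitude profile
            rms = np.sqrt(np.mean(comp**2, axis=1, keepdims=True))
            comp = comp / np.maximum(rms, 1e-30)
            amp = np.full((spec.n_channels, 1), spec.band_amplitudes[band.name])
            if band.name == spec.effect_band and y[trial] > 0:
                amp[effect_idx] *= 1.0 + y[trial] * spec.effect_size
            x += amp * comp
        if spec.noise_sd > 0:
            x += spec.noise_sd * rng.standard_normal((spec.n_channels, n_samples))
        signals.append(x)

    labels = pd.DataFrame({"y": y.astype(int)})
    return Recording(
        signals=signals,
        sampling_rate=spec.sampling_rate,
        channel_names=channels,
        labels=labels,
        baseline_seconds=0.0,
    )


def generate_deap_like(seed: int) -> Recording:
    """One synthetic subject shaped like a DEAP preprocessed archive.

    40 trials x 32 channels x 8064 samples at 128 Hz (63 s per trial, the
    first 3 s being pre-trial baseline), with valence/arousal ratings drawn
    uniformly from [1, 9].  The class label is *not* attached here — it is
    derived downstream by the threshold rule, mirroring the real label
    pathway.
    """
    spec = SynthSpec(
        n_channels=32,
        sampling_rate=128.0,
        n_trials=40,
        trial_duration=63.0,
        n_classes=2,
        effect_size=0.0,
        seed=seed,
    )
    # effect_size=0: ratings are independent of the signal by construction
    rec = generate_recording(spec)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xDEA7]))
    labels = pd.DataFrame({
        "valence": rng.uniform(1.0, 9.0, size=40),
        "arousal": rng.uniform(1.0, 9.0, size=40),
    })
    return rec.replace(labels=labels, baseline_seconds=3.0)
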