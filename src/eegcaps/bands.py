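"""Canonical EEG frequency bands and Butterworth band filtering.

Four bands are used throughout: theta 4-8 Hz, alpha 8-13 Hz, beta 13-31 Hz
and gamma 31-50 Hz, isolated with a zero-phase order-3 Butterworth bandpass
(applied forward and backward, so band outputs stay time-aligned).  The same
filters are shared by the synthetic generator and the feature-map pipeline so
both agree on what "gamma" means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

__all__ = ["BandSpec", "CANONICAL_BANDS", "BAND_ORDER", "bandpass_filter"]


@dataclass(frozen=True)
class BandSpec:
    name: str
    low: float   # Hz
    high: float  # Hz
    filter_order: int = 3

    def __post_init__(self) -> None:
        if not (0 < self.low < self.high):
            raise ValueError(f"band {self.name!r}: need 0 < low < high")
        if self.filter_order < 1:
            raise ValueError("filter_order must be >= 1")


CANONICAL_BANDS: tuple[BandSpec, ...] = (
    BandSpec("theta", 4.0, 8.0),
    BandSpec("alpha", 8.0, 13.0),
    BandSpec("beta", 13.0, 31.0),
    BandSpec("gamma", 31.0, 50.0),
)

BAND_ORDER: tuple[str, ...] = tuple(b.name for b in CANONICAL_BANDS)


def _band_sos(band: BandSpec, sampling_rate: float) -> np.ndarray:
    nyq = sampling_rate / 2.0
    if band.high >= nyq:
        raise ValueError(
            f"band {band.name!r} upper edge {band.high} Hz is not below the "
            f"Nyquist frequency {nyq} Hz"
        )
    return signal.butter(
        band.filter_order, [band.low / nyq, band.high / nyq],
        btype="bandpass", output="sos",
    )


def bandpass_filter(x: np.ndarray, band: BandSpec, sampling_rate: float) -> np.ndarray:
    """Zero-phase bandpass along the last axis."""
    sos = _band_sos(band, sampling_rate)
    return signal.sosfiltfilt(sos, np.asarray(x, dtype=np.float64), axis=-1)
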