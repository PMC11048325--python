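"""Per-window scalar features: differential entropy, sample entropy, PSD.

Three features summarize each (channel, band, window) signal:

* **Differential entropy (DE)** — under the Gaussian assumption for a short
  band-limited window, ``DE = 1/2 log(2 pi e sigma^2)`` with ``sigma^2`` the
  unbiased sample variance; a log-variance band-power surrogate.
* **Sample entropy (SampEn)** — ``-ln(A/B)`` where ``B`` counts template
  pairs of length ``m`` within Chebyshev tolerance ``r`` and ``A`` counts
  pairs of length ``m+1``; self-matches excluded; lower for regular signals.
* **Power spectral density (PSD)** — the periodogram ``|U(k)|^2 / N`` of the
  window's DFT, reduced to one scalar (mean over positive-frequency bins by
  default; the window is already band-filtered, so the mean tracks in-band
  power).

Parameter defaults follow field convention: natural log for DE; ``m = 2``,
``r = 0.2 * sd`` for SampEn.  A variance floor keeps DE finite on degenerate
constant windows, and an undefined SampEn (no template matches) is returned
as NaN by :func:`sample_entropy` but written into feature tables as a
configurable finite ceiling so downstream tensors stay finite.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .recording import Slice

__all__ = [
    "FeatureConfig",
    "FEATURE_ORDER",
    "differential_entropy",
    "sample_entropy",
    "periodogram",
    "power_spectral_density",
    "window_features",
    "extract_features",
]

logger = logging.getLogger(__name__)

FEATURE_ORDER: tuple[str, ...] = ("DE", "SE", "PSD")


@dataclass(frozen=True)
class FeatureConfig:
    sampen_m: int = 2
    sampen_r_factor: float = 0.2   # tolerance as a multiple of the window sd
    psd_reduction: str = "mean"    # "mean" or "sum" over positive-frequency bins
    log_base: str = "natural"      # "natural" or "base2"
    variance_floor: float = 1e-12
    sampen_ceiling: float = 8.0    # finite stand-in for undefined SampEn in tables

    def __post_init__(self) -> None:
        if self.sampen_m < 1:
            raise ValueError("sampen_m must be >= 1")
        if self.sampen_r_factor <= 0:
            raise ValueError("sampen_r_factor must be positive")
        if self.variance_floor <= 0:
            raise ValueError("variance_floor must be positive")
        if self.psd_reduction not in ("mean", "sum"):
            raise ValueError("psd_reduction must be 'mean' or 'sum'")
        if self.log_base not in ("natural", "base2"):
            raise ValueError("log_base must be 'natural' or 'base2'")


def _log(v, cfg: FeatureConfig):
    return np.log2(v) if cfg.log_base == "base2" else np.log(v)


def differential_entropy(x: np.ndarray, cfg: FeatureConfig = FeatureConfig()) -> float:
    """``1/2 log(2 pi e sigma^2)`` with sigma^2 the unbiased sample variance."""
    x = np.asarray(x, dtype=np.float64)
    if x.size < 2:
        raise ValueError("window must have at least 2 samples")
    var = max(float(np.var(x, ddof=1)), cfg.variance_floor)
    return float(0.5 * _log(2.0 * math.pi * math.e * var, cfg))


def _template_distance_counts(x: np.ndarray, m: int, r: float) -> tuple[int, int]:
    """(B, A): ordered template pairs of length m and m+1 within tolerance r.

    Both counts use the same N - m template start positions (i != j,
    Chebyshev distance), the standard convention.
    """
    n = x.size
    L = n - m
    D = np.abs(x[:, None] - x[None, :])
    Dm = D[:L, :L].copy()
    for t in range(1, m):
        np.maximum(Dm, D[t:t + L, t:t + L], out=Dm)
    Dm1 = np.maximum(Dm, D[m:m + L, m:m + L])
    b = int(np.count_nonzero(Dm <= r)) - L      # drop the i == j diagonal
    a = int(np.count_nonzero(Dm1 <= r)) - L
    return b, a


def sample_entropy(x: np.ndarray, cfg: FeatureConfig = FeatureConfig()) -> float:
    """``-ln(A/B)``; NaN (with a logged warning) when either count is zero."""
    x = np.asarray(x, dtype=np.float64)
    m = cfg.sampen_m
    if x.size <= m + 1:
        raise ValueError(f"window length {x.size} must exceed sampen_m + 1 = {m + 1}")
    r = cfg.sampen_r_factor * float(np.std(x))
    b, a = _template_distance_counts(x, m, r)
    if b == 0 or a == 0:
        logger.warning("sample entropy undefined (B=%d, A=%d); returning NaN", b, a)
        return math.nan
    return float(-math.log(a / b))


def periodogram(x: np.ndarray) -> np.ndarray:
    """Full periodogram ``P(k) = |U(k)|^2 / N`` over all N DFT bins.

    Satisfies Parseval's identity: ``sum_k P(k) == sum_n x(n)^2``.
    """
    x = np.asarray(x, dtype=np.float64)
    U = np.fft.fft(x)
    return (np.abs(U) ** 2) / x.size


def power_spectral_density(x: np.ndarray, cfg: FeatureConfig = FeatureConfig()) -> float:
    """Scalar PSD: periodogram reduced over the positive-frequency bins.

    Positive-frequency bins are ``k = 1 .. N//2`` (DC excluded, Nyquist
    included for even N).
    """
    x = np.asarray(x, dtype=np.float64)
    if x.size < 2:
        raise ValueError("window must have at least 2 samples")
    P = periodogram(x)
    pos = P[1:x.size // 2 + 1]
    return float(pos.mean() if cfg.psd_reduction == "mean" else pos.sum())


def window_features(data: np.ndarray, cfg: FeatureConfig = FeatureConfig()) -> dict[str, np.ndarray]:
    """All three features for every channel of one (n_channels, W) window.

    Undefined SampEn values are replaced by ``cfg.sampen_ceiling`` here so
    table and tensor consumers always see finite values.
    """
    data = np.asarray(data, dtype=np.float64)
    n_ch, w = data.shape
    var = np.maximum(np.var(data, axis=1, ddof=1), cfg.variance_floor)
    de = 0.5 * _log(2.0 * math.pi * math.e * var, cfg)

    U = np.fft.fft(data, axis=1)
    P = (np.abs(U) ** 2) / w
    pos = P[:, 1:w // 2 + 1]
    psd = pos.mean(axis=1) if cfg.psd_reduction == "mean" else pos.sum(axis=1)

    se = np.empty(n_ch)
    for c in range(n_ch):
        v = sample_entropy(data[c], cfg)
        se[c] = cfg.sampen_ceiling if math.isnan(v) else v
    return {"DE": de, "SE": se, "PSD": psd}


def extract_features(slices: list[Slice], cfg: FeatureConfig = FeatureConfig()) -> pd.DataFrame:
    """Feature table over a band-filtered slice set.

    Returns a DataFrame with columns (trial, slice, channel, band, feature,
    value), complete over every (channel x band x feature) key of every
    input slice.  Rows are emitted in a canonical sorted order, so the table
    is invariant to input processing order.
    """
    rows = []
    for sl in slices:
        if sl.band is None:
            raise ValueError(
                f"slice (trial={sl.trial}, index={sl.index}) carries no band identity"
            )
        names = sl.channel_names or [str(i) for i in range(sl.data.shape[0])]
        feats = window_features(sl.data, cfg)
        for feat, vals in feats.items():
            for ch, v in zip(names, vals):
                rows.append((sl.trial, sl.index, ch, sl.band, feat, float(v)))
    df = pd.DataFrame(rows, columns=["trial", "slice", "channel", "band", "feature", "value"])
    return df.sort_values(["trial", "slice", "band", "feature", "channel"]).reset_index(drop=True)
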