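"""Downsampling, baseline trimming, slicing and recognition-cycle grouping.

The preprocessing contract follows the standard per-subject accounting for
DEAP-style data: a 63 s trial at 128 Hz (8064 samples) loses its 3 s
pre-trial baseline, leaving 60 s; non-overlapping 0.5 s windows then give 120
time slices per trial (4800 over 40 trials), and grouping 4 consecutive
slices into one recognition-cycle sample gives 1200 samples.  Remainder
samples and remainder slices are discarded (floor semantics), never padded,
and no slice or group ever mixes data from two trials.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal as sps

from .recording import Recording, Slice, SliceGroup

__all__ = ["SlicePlan", "downsample", "trim_baseline", "slice_trials", "group_samples"]


@dataclass(frozen=True)
class SlicePlan:
    """Windowing plan: 0.5 s windows for DEAP-style data, 1.0 s for SEED-style."""

    window_seconds: float = 0.5
    slices_per_sample: int = 4
    overlap: float = 0.0  # fraction; 0 = non-overlapping (the only supported mode)

    def __post_init__(self) -> None:
        if self.window_seconds <= 0:
            raise ValueError("window_seconds must be positive")
        if self.slices_per_sample < 1:
            raise ValueError("slices_per_sample must be >= 1")
        if self.overlap != 0.0:
            raise ValueError("only non-overlapping windows are supported")

    def window_samples(self, sampling_rate: float) -> int:
        w = self.window_seconds * sampling_rate
        n = int(round(w))
        if abs(w - n) > 1e-9 or n < 1:
            raise ValueError(
                f"window_seconds * sampling_rate = {w} is not a positive integer"
            )
        return n


def downsample(rec: Recording, target_rate: float) -> Recording:
    """Anti-alias filter and resample every trial to ``target_rate``.

    Polyphase resampling is used; the output length is truncated to
    ``floor(n * target_rate / sampling_rate)`` so trial durations are
    preserved to within one sample (and integer decimation is exact).
    """
    if target_rate <= 0:
        raise ValueError("target_rate must be positive")
    if target_rate > rec.sampling_rate:
        raise ValueError("target_rate exceeds the recording's sampling rate")
    if target_rate == rec.sampling_rate:
        return rec.replace(signals=[s.copy() for s in rec.signals])

    frac = Fraction(target_rate / rec.sampling_rate).limit_denominator(10_000)
    up, down = frac.numerator, frac.denominator
    out = []
    for s in rec.signals:
        n_out = int(np.floor(s.shape[1] * target_rate / rec.sampling_rate + 1e-9))
        r = sps.resample_poly(s, up, down, axis=1)
        out.append(r[:, :n_out])
    return rec.replace(signals=out, sampling_rate=float(target_rate))


def trim_baseline(rec: Recording) -> Recording:
    """Drop the leading pre-trial baseline from every trial."""
    n = int(round(rec.baseline_seconds * rec.sampling_rate))
    if n == 0:
        return rec.replace(signals=[s.copy() for s in rec.signals], baseline_seconds=0.0)
    for i, s in enumerate(rec.signals):
        if n > s.shape[1]:
            raise ValueError(
                f"baseline of {rec.baseline_seconds} s ({n} samples) exceeds "
                f"trial {i} length {s.shape[1]}"
            )
    return rec.replace(signals=[s[:, n:].copy() for s in rec.signals], baseline_seconds=0.0)


def slice_trials(rec: Recording, plan: SlicePlan) -> list[Slice]:
    """Cut every trial into contiguous non-overlapping windows.

    Each trial yields ``floor(trial_len / window_len)`` slices; trailing
    remainder samples are discarded.
    """
    if rec.n_trials == 0:
        raise ValueError("recording has no trials")
    win = plan.window_samples(rec.sampling_rate)
    slices: list[Slice] = []
    for trial, s in enumerate(rec.signals):
        n_win = s.shape[1] // win
        label = rec.trial_label(trial)
        for k in range(n_win):
            slices.append(Slice(
                trial=trial,
                index=k,
                data=s[:, k * win:(k + 1) * win],
                label=label,
                channel_names=rec.channel_names,
            ))
    return slices


def group_samples(slices: list[Slice], plan: SlicePlan) -> list[SliceGroup]:
    """Group runs of ``slices_per_sample`` consecutive slices into samples.

    Groups never span trials; leftover slices at the end of a trial are
    discarded.
    """
    t = plan.slices_per_sample
    by_trial: dict[int, list[Slice]] = {}
    for sl in slices:
        by_trial.setdefault(sl.trial, []).append(sl)
    groups: list[SliceGroup] = []
    for trial in sorted(by_trial):
        run = sorted(by_trial[trial], key=lambda sl: sl.index)
        for start in range(0, len(run) - t + 1, t):
            chunk = run[start:start + t]
            groups.append(SliceGroup(
                trial=trial,
                start_index=chunk[0].index,
                slices=chunk,
                label=chunk[0].label,
            ))
    return groups
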