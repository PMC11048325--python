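"""Canonical containers for multichannel EEG.

A :class:`Recording` holds per-trial channel x time arrays together with the
sampling rate, ordered 10-20 channel names and a per-trial label table.  Every
ingestion path (the synthetic generator and the DEAP/SEED adapters) emits this
one container, so the downstream pipeline never needs to know where the data
came from.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

__all__ = ["Recording", "Slice", "SliceGroup", "MontageError"]


class MontageError(ValueError):
    """A channel name does not belong to the declared montage/grid."""


@dataclass
class Recording:
    """Multichannel EEG with trial structure and labels.

    Parameters
    ----------
    signals
        One ``(n_channels, n_samples)`` float array per trial, in microvolts.
        Trials may differ in length but must share the channel count.
    sampling_rate
        Sampling frequency in Hz.
    channel_names
        Ordered, unique 10-20 channel labels; row ``i`` of every trial is the
        channel ``channel_names[i]``.
    labels
        One row per trial.  Columns are a subset of ``{"valence", "arousal",
        "y", "session"}``: continuous self-assessment ratings in [1, 9] and/or
        an integer class label ``y``.
    baseline_seconds
        Leading pre-stimulus baseline recorded at the start of every trial
        (e.g. 3 s in DEAP-style trials); trimmed by preprocessing.
    """

    signals: list[np.ndarray]
    sampling_rate: float
    channel_names: list[str]
    labels: pd.DataFrame = field(default_factory=pd.DataFrame)
    baseline_seconds: float = 0.0

    def __post_init__(self) -> None:
        self.signals = [np.asarray(s, dtype=np.float64) for s in self.signals]
        self.channel_names = list(self.channel_names)
        self.validate()

    # -- contract ---------------------------------------------------------
    def validate(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel_names must be unique")
        n_ch = len(self.channel_names)
        for i, s in enumerate(self.signals):
            if s.ndim != 2 or s.shape[0] != n_ch:
                raise ValueError(
                    f"trial {i} has shape {s.shape}, expected ({n_ch}, n_samples)"
                )
        if len(self.labels) not in (0, len(self.signals)):
            raise ValueError("labels must have one row per trial (or be empty)")

    @property
    def n_trials(self) -> int:
        return len(self.signals)

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)

    def trial_label(self, trial: int):
        """Integer class of a trial, or None when no ``y`` column exists."""
        if "y" in self.labels.columns:
            return int(self.labels["y"].iloc[trial])
        return None

    def replace(self, **kwargs) -> "Recording":
        return dataclasses.replace(self, **kwargs)

    # -- persistence ------------------------------------------------------
    def save(self, path) -> None:
        """Write the container to an HDF5 archive."""
        with h5py.File(path, "w") as f:
            f.attrs["sampling_rate"] = float(self.sampling_rate)
            f.attrs["baseline_seconds"] = float(self.baseline_seconds)
            f.attrs["channel_names"] = [str(c) for c in self.channel_names]
            g = f.create_group("trials")
            for i, s in enumerate(self.signals):
                g.create_dataset(f"{i:04d}", data=s)
            lg = f.create_group("labels")
            for col in self.labels.columns:
                lg.create_dataset(col, data=np.asarray(self.labels[col], dtype=np.float64))

    @classmethod
    def load(cls, path) -> "Recording":
        with h5py.File(path, "r") as f:
            names = [c.decode() if isinstance(c, bytes) else str(c)
                     for c in f.attrs["channel_names"]]
            keys = sorted(f["trials"].keys())
            signals = [f["trials"][k][()] for k in keys]
            cols = {}
            for col in f["labels"]:
                vals = f["labels"][col][()]
                cols[col] = vals.astype(int) if col in ("y", "session") else vals
            labels = pd.DataFrame(cols)
            return cls(
                signals=signals,
                sampling_rate=float(f.attrs["sampling_rate"]),
                channel_names=names,
                labels=labels,
                baseline_seconds=float(f.attrs["baseline_seconds"]),
            )


@dataclass
class Slice:
    """One non-overlapping analysis window of one trial.

    ``band`` is None for broadband slices and a band name ("theta", ...)
    after band decomposition.
    """

    trial: int
    index: int
    data: np.ndarray  # (n_channels, window_samples)
    label: int | None = None
    band: str | None = None
    channel_names: list[str] | None = None


@dataclass
class SliceGroup:
    """T consecutive slices of one trial — one recognition-cycle sample."""

    trial: int
    start_index: int
    slices: list[Slice]
    label: int | None = None

    def __len__(self) -> int:
        return len(self.slices)
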