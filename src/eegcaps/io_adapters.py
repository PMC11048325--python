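"""Readers for DEAP- and SEED-format archives, plus label derivation.

Both adapters emit the canonical :class:`~eegcaps.recording.Recording`
container, so the pipeline has exactly one ingestion path and is
adapter-agnostic beyond this module.

* DEAP preprocessed per-subject archives are pickled dicts with ``data`` of
  shape (40 trials, >=32 channels, 8064 samples at 128 Hz; first 3 s
  pre-trial baseline) and ``labels`` of shape (40, 4): valence, arousal,
  dominance, liking ratings in [1, 9].  Only the first 32 channels are EEG;
  peripheral channels are dropped.
* SEED per-session MATLAB files hold 15 per-clip 62-channel arrays under
  keys ending in ``_eeg<n>`` plus a 15-entry label vector in {-1, 0, 1},
  mapped to {negative, neutral, positive} = {0, 1, 2}.

Label derivation follows the threshold rule: for binary schemes a trial is
the "high" class iff its rating is strictly greater than the threshold
(default 5, the rating-scale median); a rating of exactly 5 is "low".
"""

from __future__ import annotations

import pickle
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import loadmat

from .montages import DEAP32_CHANNEL_ORDER, load_layout
from .recording import Recording

__all__ = [
    "FormatError",
    "LabelRule",
    "read_deap",
    "read_seed",
    "merge_sessions",
    "apply_label_rule",
    "SEED_CLASS_NAMES",
]

SEED_CLASS_NAMES = ("negative", "neutral", "positive")

DEAP_N_TRIALS = 40
DEAP_N_SAMPLES = 8064
DEAP_RATE = 128.0
DEAP_BASELINE_SECONDS = 3.0


class FormatError(ValueError):
    """An input archive does not match the documented dialect."""


@dataclass(frozen=True)
class LabelRule:
    scheme: str = "valence_binary"  # valence_binary | arousal_binary | seed_ternary
    threshold: float = 5.0

    def __post_init__(self) -> None:
        if self.scheme not in ("valence_binary", "arousal_binary", "seed_ternary"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.scheme.endswith("binary") and not (1.0 <= self.threshold <= 9.0):
            raise ValueError("threshold must lie in the rating range [1, 9]")


def read_deap(path) -> Recording:
    """Read one DEAP preprocessed subject archive into a Recording."""
    with open(path, "rb") as f:
        doc = pickle.load(f, encoding="latin1")
    if not isinstance(doc, dict) or "data" not in doc or "labels" not in doc:
        raise FormatError("expected a dict with 'data' and 'labels' keys")
    data = np.asarray(doc["data"], dtype=np.float64)
    ratings = np.asarray(doc["labels"], dtype=np.float64)
    if data.ndim != 3 or data.shape[0] != DEAP_N_TRIALS or data.shape[1] < 32 \
            or data.shape[2] != DEAP_N_SAMPLES:
        raise FormatError(
            f"expected data of shape ({DEAP_N_TRIALS}, >=32, {DEAP_N_SAMPLES}), "
            f"found {data.shape}"
        )
    if ratings.shape[0] != DEAP_N_TRIALS or ratings.shape[1] < 2:
        raise FormatError(
            f"expected a ({DEAP_N_TRIALS}, >=2) rating table, found {ratings.shape}"
        )
    labels = pd.DataFrame({"valence": ratings[:, 0], "arousal": ratings[:, 1]})
    return Recording(
        signals=[data[t, :32] for t in range(DEAP_N_TRIALS)],
        sampling_rate=DEAP_RATE,
        channel_names=list(DEAP32_CHANNEL_ORDER),
        labels=labels,
        baseline_seconds=DEAP_BASELINE_SECONDS,
    )


_SEED_KEY = re.compile(r"_eeg(\d+)$")


def read_seed(path, labels=None, label_path=None, session: int | None = None,
              sampling_rate: float = 1000.0) -> Recording:
    """Read one SEED session file (15 trials, 62 channels) into a Recording.

    ``labels`` may be passed directly as a 15-vector in {-1, 0, 1}, or read
    from the companion ``label.mat`` via ``label_path``.  Trials of unequal
    length are preserved as-is (no padding).
    """
    doc = loadmat(path)
    trials: dict[int, np.ndarray] = {}
    for key, val in doc.items():
        m = _SEED_KEY.search(key)
        if m:
            trials[int(m.group(1))] = np.asarray(val, dtype=np.float64)
    if not trials:
        raise FormatError("no '*_eeg<n>' trial arrays found in file")
    if labels is None:
        if label_path is None:
            raise FormatError("missing label vector: pass labels= or label_path=")
        lab_doc = loadmat(label_path)
        key = next((k for k in lab_doc if not k.startswith("__")), None)
        labels = np.asarray(lab_doc[key]).ravel()
    labels = np.asarray(labels).ravel().astype(int)
    if len(labels) != len(trials):
        raise FormatError(
            f"{len(trials)} trials but {len(labels)} labels"
        )
    if not set(labels) <= {-1, 0, 1}:
        raise FormatError("SEED labels must lie in {-1, 0, 1}")
    order = sorted(trials)
    signals = [trials[i] for i in order]
    n_ch = signals[0].shape[0]
    if n_ch != 62:
        raise FormatError(f"expected 62 channels, found {n_ch}")
    table = {"y": labels + 1}
    if session is not None:
        table["session"] = np.full(len(order), session, dtype=int)
    return Recording(
        signals=signals,
        sampling_rate=sampling_rate,
        channel_names=list(load_layout("seed62").channels),
        labels=pd.DataFrame(table),
        baseline_seconds=0.0,
    )


def merge_sessions(recordings: list[Recording]) -> Recording:
    """Concatenate per-session Recordings (session ids retained in labels)."""
    if not recordings:
        raise ValueError("no recordings to merge")
    first = recordings[0]
    for r in recordings[1:]:
        if r.channel_names != first.channel_names:
            raise FormatError("sessions disagree on channel names")
        if r.sampling_rate != first.sampling_rate:
            raise FormatError("sessions disagree on sampling rate")
    signals = [s for r in recordings for s in r.signals]
    labels = pd.concat([r.labels for r in recordings], ignore_index=True)
    return first.replace(signals=signals, labels=labels)


def apply_label_rule(rec: Recording, rule: LabelRule) -> Recording:
    """Attach integer class labels per trial according to the rule."""
    labels = rec.labels.copy()
    if rule.scheme in ("valence_binary", "arousal_binary"):
        col = rule.scheme.split("_")[0]
        if col not in labels.columns:
            raise ValueError(f"scheme {rule.scheme!r} needs a {col!r} rating column")
        labels["y"] = (labels[col] > rule.threshold).astype(int)
    else:  # seed_ternary
        if "y" not in labels.columns:
            raise ValueError("seed_ternary expects a 'y' column of classes 0/1/2")
        if not set(labels["y"]) <= {0, 1, 2}:
            raise ValueError("seed_ternary classes must be 0, 1 or 2")
        labels["y"] = labels["y"].astype(int)
    return rec.replace(labels=labels)
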