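"""Electrode-topography layouts on the 8 x 9 scalp grid.

Channel names from the international 10-20 system are placed on an 8-row by
9-column matrix that preserves anatomy: frontal rows at the top, left
hemisphere on the left, the midline (z-line) in the centre column.  Two
layouts ship as JSON data files — ``deap32`` (the 32 EEG channels of a
DEAP-style cap) and ``seed62`` (a 62-channel SEED-style cap) — and users can
load their own table with :meth:`ElectrodeLayout.from_json`.

The exact cell assignments are an anatomical convention, not a normative
standard; any injective, complete placement works, and the tables are data,
not code.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

from .recording import MontageError

GRID_ROWS = 8
GRID_COLS = 9

# DEAP preprocessed archives carry 32 EEG channels in this fixed order
# (Geneva ordering), followed by 8 peripheral channels that are not EEG.
DEAP32_CHANNEL_ORDER = [
    "Fp1", "AF3", "F3", "F7", "FC5", "FC1", "C3", "T7", "CP5", "CP1", "P3",
    "P7", "PO3", "O1", "Oz", "Pz", "Fp2", "AF4", "Fz", "F4", "F8", "FC6",
    "FC2", "C4", "T8", "CP6", "CP2", "P4", "P8", "PO4", "O2", "Cz",
]


@dataclass(frozen=True)
class ElectrodeLayout:
    """Injective mapping channel name -> (row, col) on the 8 x 9 grid."""

    name: str
    grid: dict[str, tuple[int, int]]

    def __post_init__(self) -> None:
        cells = list(self.grid.values())
        for ch, (r, c) in self.grid.items():
            if not (0 <= r < GRID_ROWS and 0 <= c < GRID_COLS):
                raise MontageError(f"channel {ch!r} placed off-grid at {(r, c)}")
        if len(set(cells)) != len(cells):
            raise MontageError(f"layout {self.name!r} maps two channels to one cell")

    @property
    def channels(self) -> list[str]:
        return list(self.grid)

    @property
    def n_channels(self) -> int:
        return len(self.grid)

    def position(self, channel: str) -> tuple[int, int]:
        try:
            return self.grid[channel]
        except KeyError:
            raise MontageError(
                f"channel {channel!r} is not in montage {self.name!r}"
            ) from None

    @classmethod
    def from_json(cls, path) -> "ElectrodeLayout":
        with open(path) as f:
            doc = json.load(f)
        return cls._from_doc(doc)

    @classmethod
    def _from_doc(cls, doc: dict) -> "ElectrodeLayout":
        grid = {ch: (int(r), int(c)) for ch, (r, c) in doc["grid"].items()}
        return cls(name=doc["name"], grid=grid)


def load_layout(name: str) -> ElectrodeLayout:
    """Load a packaged layout by name (``deap32`` or ``seed62``)."""
    try:
        text = resources.files("eegcaps.data").joinpath(f"montage_{name}.json").read_text()
    except FileNotFoundError:
        raise MontageError(f"no packaged montage named {name!r}") from None
    return ElectrodeLayout._from_doc(json.loads(text))
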