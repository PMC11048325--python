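"""Assembly of the 3 x 16 x 18 multi-domain feature map.

One map per time slice: each of the four band-filtered copies of the window
is summarized per channel by DE, SampEn and PSD; per-band scalars are placed
on the 8 x 9 electrode-topography grid; the four band grids are tiled 2 x 2
(theta alpha / beta gamma, row-major) into a 16 x 18 matrix; and the three
per-feature matrices are stacked (DE, SE, PSD) into a 3 x 16 x 18 tensor.
Cells with no electrode stay exactly zero (no interpolation).

Because DE (log scale), SampEn (~0-2) and PSD (power units) live on
incommensurate scales, per-feature-channel z-normalization of the occupied
cells is provided; statistics must be fitted on training folds only.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

from .bands import BAND_ORDER, CANONICAL_BANDS, BandSpec, bandpass_filter
from .features import FEATURE_ORDER, FeatureConfig, window_features
from .montages import GRID_COLS, GRID_ROWS, ElectrodeLayout
from .preprocessing import SlicePlan, slice_trials
from .recording import MontageError, Recording, Slice

__all__ = [
    "BAND_TILE_ORDER",
    "MultiDomainFeatureMap",
    "NormalizationStats",
    "bandpass_decompose",
    "map_to_grid",
    "tile_bands",
    "assemble_map",
    "grid_mask",
    "tiled_mask",
    "fit_normalization",
    "normalize_maps",
    "build_feature_maps",
    "build_samples",
    "save_maps",
    "load_maps",
]

# 2x2 placement of the four band grids, row-major: (theta alpha / beta gamma).
BAND_TILE_ORDER: tuple[tuple[str, str], tuple[str, str]] = (
    ("theta", "alpha"),
    ("beta", "gamma"),
)

MAP_SHAPE = (len(FEATURE_ORDER), 2 * GRID_ROWS, 2 * GRID_COLS)  # (3, 16, 18)


@dataclass
class MultiDomainFeatureMap:
    """The model input atom for one time slice."""

    tensor: np.ndarray  # (3, 16, 18)
    slice_ref: tuple[int, int]  # (trial, slice index)
    label: int | None = None
    feature_order: tuple[str, ...] = FEATURE_ORDER
    band_tile_order: tuple[tuple[str, str], tuple[str, str]] = BAND_TILE_ORDER

    def __post_init__(self) -> None:
        self.tensor = np.asarray(self.tensor, dtype=np.float64)
        if self.tensor.shape != MAP_SHAPE:
            raise ValueError(f"map tensor has shape {self.tensor.shape}, expected {MAP_SHAPE}")
        if not np.all(np.isfinite(self.tensor)):
            raise ValueError("map tensor contains non-finite values")


def bandpass_decompose(
    sl: Slice,
    bands: tuple[BandSpec, ...] = CANONICAL_BANDS,
    sampling_rate: float | None = None,
) -> list[Slice]:
    """One zero-phase band-filtered copy of the slice per band."""
    if sampling_rate is None:
        raise ValueError("sampling_rate is required")
    out = []
    for band in bands:
        if sampling_rate <= 2 * band.high:
            raise ValueError(
                f"sampling rate {sampling_rate} Hz violates Nyquist for band "
                f"{band.name!r} (high {band.high} Hz)"
            )
        out.append(Slice(
            trial=sl.trial, index=sl.index,
            data=bandpass_filter(sl.data, band, sampling_rate),
            label=sl.label, band=band.name, channel_names=sl.channel_names,
        ))
    return out


def map_to_grid(values: dict[str, float], layout: ElectrodeLayout) -> np.ndarray:
    """Place channel -> scalar values on the 8 x 9 grid; empty cells are 0."""
    unknown = [c for c in values if c not in layout.grid]
    if unknown:
        raise MontageError(f"channels not in montage {layout.name!r}: {sorted(unknown)}")
    missing = [c for c in layout.grid if c not in values]
    if missing:
        raise MontageError(f"values missing for montage channels: {sorted(missing)}")
    m = np.zeros((GRID_ROWS, GRID_COLS))
    for ch, v in values.items():
        r, c = layout.grid[ch]
        m[r, c] = v
    return m


def tile_bands(
    mats: dict[str, np.ndarray],
    order: tuple[tuple[str, str], tuple[str, str]] = BAND_TILE_ORDER,
) -> np.ndarray:
    """2 x 2 block arrangement of four 8 x 9 band grids into 16 x 18."""
    flat_order = [b for row in order for b in row]
    missing = [b for b in flat_order if b not in mats]
    if missing:
        raise ValueError(f"missing band matrices: {missing}")
    for b in flat_order:
        if np.shape(mats[b]) != (GRID_ROWS, GRID_COLS):
            raise ValueError(f"band {b!r} grid has shape {np.shape(mats[b])}")
    return np.block([[mats[order[0][0]], mats[order[0][1]]],
                     [mats[order[1][0]], mats[order[1][1]]]])


def assemble_map(
    features: pd.DataFrame,
    layout: ElectrodeLayout,
    band_tile_order: tuple[tuple[str, str], tuple[str, str]] = BAND_TILE_ORDER,
) -> MultiDomainFeatureMap:
    """Build one slice's 3 x 16 x 18 tensor from its feature-table rows.

    ``features`` must contain exactly one slice's rows, complete over
    (channel x band x feature).
    """
    refs = features[["trial", "slice"]].drop_duplicates()
    if len(refs) != 1:
        raise ValueError("assemble_map expects rows of exactly one slice")
    trial, sl_idx = int(refs.iloc[0]["trial"]), int(refs.iloc[0]["slice"])

    flat_bands = [b for row in band_tile_order for b in row]
    needed = {(ch, b, f) for ch in layout.channels for b in flat_bands for f in FEATURE_ORDER}
    have = set(zip(features["channel"], features["band"], features["feature"]))
    missing = needed - have
    if missing:
        preview = sorted(missing)[:5]
        raise ValueError(f"incomplete feature coverage; missing {len(missing)} keys, e.g. {preview}")

    planes = []
    idx = features.set_index(["feature", "band", "channel"])["value"].sort_index()
    for feat in FEATURE_ORDER:
        mats = {}
        for b in flat_bands:
            sub = idx.loc[(feat, b)]
            mats[b] = map_to_grid(sub.to_dict(), layout)
        planes.append(tile_bands(mats, band_tile_order))

    label = None
    if "label" in features.columns:
        lab = features["label"].dropna()
        if len(lab):
            label = int(lab.iloc[0])
    return MultiDomainFeatureMap(
        tensor=np.stack(planes), slice_ref=(trial, sl_idx), label=label,
        band_tile_order=band_tile_order,
    )


def grid_mask(layout: ElectrodeLayout) -> np.ndarray:
    """Boolean 8 x 9 mask of cells occupied by an electrode."""
    m = np.zeros((GRID_ROWS, GRID_COLS), dtype=bool)
    for r, c in layout.grid.values():
        m[r, c] = True
    return m


def tiled_mask(layout: ElectrodeLayout) -> np.ndarray:
    """Occupied-cell mask on the 16 x 18 tiled matrix."""
    return np.tile(grid_mask(layout), (2, 2))


@dataclass
class NormalizationStats:
    """Per-feature-channel mean/sd over occupied cells, fitted on training data."""

    mean: np.ndarray  # (3,)
    sd: np.ndarray    # (3,); entries equal to 0 mean "leave unscaled"
    mask: np.ndarray  # (16, 18) bool

    def apply(self, tensor: np.ndarray) -> np.ndarray:
        out = np.zeros_like(tensor)
        for f in range(tensor.shape[0]):
            sd = self.sd[f] if self.sd[f] > 0 else 1.0
            mean = self.mean[f] if self.sd[f] > 0 else 0.0
            out[f][self.mask] = (tensor[f][self.mask] - mean) / sd
        return out


def fit_normalization(maps: list[MultiDomainFeatureMap], layout: ElectrodeLayout) -> NormalizationStats:
    mask = tiled_mask(layout)
    stack = np.stack([m.tensor for m in maps])  # (n, 3, 16, 18)
    vals = stack[:, :, mask]  # (n, 3, n_occupied)
    mean = vals.mean(axis=(0, 2))
    sd = vals.std(axis=(0, 2))
    return NormalizationStats(mean=mean, sd=sd, mask=mask)


def normalize_maps(
    maps: list[MultiDomainFeatureMap], stats: NormalizationStats
) -> list[MultiDomainFeatureMap]:
    """z-score occupied cells per feature channel; structural zeros stay zero."""
    return [
        MultiDomainFeatureMap(
            tensor=stats.apply(m.tensor), slice_ref=m.slice_ref, label=m.label,
            feature_order=m.feature_order, band_tile_order=m.band_tile_order,
        )
        for m in maps
    ]


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def build_feature_maps(
    rec: Recording,
    layout: ElectrodeLayout,
    plan: SlicePlan = SlicePlan(),
    cfg: FeatureConfig = FeatureConfig(),
    bands: tuple[BandSpec, ...] = CANONICAL_BANDS,
) -> list[MultiDomainFeatureMap]:
    """Recording -> one multi-domain feature map per time slice.

    Band filtering runs on whole trials before slicing (equivalent to
    filtering each window, but without per-window filter transients); the
    same window boundaries are then applied to every band.
    """
    if list(rec.channel_names) != list(layout.channels) and \
            set(rec.channel_names) != set(layout.grid):
        raise MontageError(
            f"recording channels do not match montage {layout.name!r}"
        )
    win = plan.window_samples(rec.sampling_rate)
    names = rec.channel_names
    maps: list[MultiDomainFeatureMap] = []
    for trial, sig in enumerate(rec.signals):
        label = rec.trial_label(trial)
        per_band = {
            band.name: bandpass_filter(sig, band, rec.sampling_rate)
            for band in bands
        }
        n_win = sig.shape[1] // win
        for k in range(n_win):
            sl = slice(k * win, (k + 1) * win)
            planes = {feat: {} for feat in FEATURE_ORDER}
            for bname, bsig in per_band.items():
                feats = window_features(bsig[:, sl], cfg)
                for feat in FEATURE_ORDER:
                    planes[feat][bname] = map_to_grid(
                        dict(zip(names, feats[feat])), layout
                    )
            tensor = np.stack([tile_bands(planes[feat]) for feat in FEATURE_ORDER])
            maps.append(MultiDomainFeatureMap(
                tensor=tensor, slice_ref=(trial, k), label=label,
            ))
    return maps


def build_samples(
    maps: list[MultiDomainFeatureMap], slices_per_sample: int = 4
) -> tuple[np.ndarray, np.ndarray, list[tuple[int, int]]]:
    """Group per-slice maps into recognition-cycle samples.

    Returns ``X`` of shape (n_samples, T, 3, 16, 18), integer labels ``y``
    and the (trial, start slice) reference of each sample.  Groups never
    span trials; trailing slices are discarded.
    """
    t = slices_per_sample
    by_trial: dict[int, list[MultiDomainFeatureMap]] = {}
    for m in maps:
        by_trial.setdefault(m.slice_ref[0], []).append(m)
    xs, ys, refs = [], [], []
    for trial in sorted(by_trial):
        run = sorted(by_trial[trial], key=lambda m: m.slice_ref[1])
        for start in range(0, len(run) - t + 1, t):
            chunk = run[start:start + t]
            xs.append(np.stack([m.tensor for m in chunk]))
            ys.append(-1 if chunk[0].label is None else chunk[0].label)
            refs.append((trial, chunk[0].slice_ref[1]))
    return np.stack(xs), np.asarray(ys, dtype=int), refs


# ---------------------------------------------------------------------------
# archive
# ---------------------------------------------------------------------------

def _config_hash(manifest: dict) -> str:
    blob = json.dumps(manifest, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def save_maps(path, maps: list[MultiDomainFeatureMap], layout: ElectrodeLayout,
              extra: dict | None = None) -> None:
    """Tensor store + JSON manifest (layout, band/feature order, config hash)."""
    manifest = {
        "layout": layout.name,
        "feature_order": list(FEATURE_ORDER),
        "band_tile_order": [list(r) for r in BAND_TILE_ORDER],
        "band_order": list(BAND_ORDER),
        **(extra or {}),
    }
    manifest["config_hash"] = _config_hash(manifest)
    tensors = np.stack([m.tensor for m in maps])
    refs = np.array([m.slice_ref for m in maps], dtype=np.int64)
    labels = np.array([-1 if m.label is None else m.label for m in maps], dtype=np.int64)
    with h5py.File(path, "w") as f:
        f.create_dataset("tensors", data=tensors)
        f.create_dataset("slice_refs", data=refs)
        f.create_dataset("labels", data=labels)
        f.attrs["manifest"] = json.dumps(manifest, sort_keys=True)


def load_maps(path) -> tuple[list[MultiDomainFeatureMap], dict]:
    with h5py.File(path, "r") as f:
        tensors = f["tensors"][()]
        refs = f["slice_refs"][()]
        labels = f["labels"][()]
        manifest = json.loads(f.attrs["manifest"])
    maps = [
        MultiDomainFeatureMap(
            tensor=tensors[i], slice_ref=(int(refs[i, 0]), int(refs[i, 1])),
            label=None if labels[i] < 0 else int(labels[i]),
        )
        for i in range(tensors.shape[0])
    ]
    return maps, manifest
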