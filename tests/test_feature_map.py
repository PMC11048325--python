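"""Map geometry: band filtering, grid placement, tiling, stacking, scaling."""

import numpy as np
import pandas as pd
import pytest

import eegcaps as eg
from eegcaps.feature_map import (
    BAND_TILE_ORDER,
    assemble_map,
    bandpass_decompose,
    fit_normalization,
    grid_mask,
    map_to_grid,
    normalize_maps,
    tile_bands,
    tiled_mask,
)
from eegcaps.montages import GRID_COLS, GRID_ROWS
from eegcaps.recording import MontageError, Slice

FLAT_BANDS = [b for row in BAND_TILE_ORDER for b in row]


class TestBandpassDecompose:
    def slice_of(self, data):
        return Slice(trial=0, index=0, data=data, channel_names=None)

    def test_alpha_sinusoid_routing(self):
        t = np.arange(256) / 128.0
        x = np.sin(2 * np.pi * 10.0 * t)[None, :]
        out = {s.band: s.data for s in
               bandpass_decompose(self.slice_of(x), sampling_rate=128.0)}
        amp = {b: np.abs(d).max() for b, d in out.items()}
        assert amp["alpha"] >= 0.90
        assert amp["gamma"] <= 0.05

    def test_zero_signal(self):
        out = bandpass_decompose(self.slice_of(np.zeros((2, 128))), sampling_rate=128.0)
        assert len(out) == 4
        assert all(np.allclose(s.data, 0) for s in out)

    def test_band_powers_bounded_by_input(self):
        x = np.random.default_rng(0).standard_normal((1, 1024))
        out = bandpass_decompose(self.slice_of(x), sampling_rate=128.0)
        band_power = sum(np.sum(s.data**2) for s in out)
        assert band_power < np.sum(x**2)

    def test_nyquist_violation(self):
        with pytest.raises(ValueError):
            bandpass_decompose(self.slice_of(np.zeros((1, 64))), sampling_rate=80.0)


class TestMapToGrid:
    def test_structural_zero_count(self, layout_deap):
        m = map_to_grid({c: 1.0 for c in layout_deap.channels}, layout_deap)
        assert m.shape == (GRID_ROWS, GRID_COLS)
        assert (m == 0).sum() == 72 - 32 == 40
        assert m.sum() == 32

    def test_key_order_irrelevant(self, layout_deap):
        vals = {c: i * 0.5 for i, c in enumerate(layout_deap.channels)}
        rev = dict(reversed(list(vals.items())))
        assert np.array_equal(map_to_grid(vals, layout_deap),
                              map_to_grid(rev, layout_deap))

    def test_unknown_channel_named_in_error(self, layout_deap):
        vals = {c: 0.0 for c in layout_deap.channels}
        vals["XX9"] = 1.0
        with pytest.raises(MontageError, match="XX9"):
            map_to_grid(vals, layout_deap)

    def test_missing_channel_raises(self, layout_deap):
        vals = {c: 0.0 for c in layout_deap.channels[:-1]}
        with pytest.raises(MontageError):
            map_to_grid(vals, layout_deap)


class TestTileBands:
    def test_constant_quadrants(self):
        mats = {b: np.full((8, 9), i + 1.0) for i, b in enumerate(FLAT_BANDS)}
        out = tile_bands(mats)
        assert out.shape == (16, 18)
        quads = [out[:8, :9], out[:8, 9:], out[8:, :9], out[8:, 9:]]
        assert [q.mean() for q in quads] == [1.0, 2.0, 3.0, 4.0]

    def test_roundtrip(self):
        rng = np.random.default_rng(1)
        mats = {b: rng.standard_normal((8, 9)) for b in FLAT_BANDS}
        out = tile_bands(mats)
        assert np.array_equal(out[:8, :9], mats["theta"])
        assert np.array_equal(out[:8, 9:], mats["alpha"])
        assert np.array_equal(out[8:, :9], mats["beta"])
        assert np.array_equal(out[8:, 9:], mats["gamma"])

    def test_missing_band(self):
        mats = {b: np.zeros((8, 9)) for b in FLAT_BANDS[:-1]}
        with pytest.raises(ValueError):
            tile_bands(mats)


def feature_table(layout, fn):
    rows = []
    for ch in layout.channels:
        for b in FLAT_BANDS:
            for f in ("DE", "SE", "PSD"):
                rows.append((0, 0, ch, b, f, fn(ch, b, f)))
    return pd.DataFrame(rows, columns=["trial", "slice", "channel", "band",
                                       "feature", "value"])


class TestAssembleMap:
    def test_shape_and_placement(self, layout_deap):
        values = {(ch, b, f): float(hash((ch, b, f)) % 997) + 1.0
                  for ch in layout_deap.channels for b in FLAT_BANDS
                  for f in ("DE", "SE", "PSD")}
        table = feature_table(layout_deap, lambda ch, b, f: values[(ch, b, f)])
        m = assemble_map(table, layout_deap)
        assert m.tensor.shape == (3, 16, 18)
        r, c = layout_deap.position("Cz")
        offsets = {"theta": (0, 0), "alpha": (0, 9), "beta": (8, 0), "gamma": (8, 9)}
        for fi, f in enumerate(("DE", "SE", "PSD")):
            for b, (dr, dc) in offsets.items():
                assert m.tensor[fi, r + dr, c + dc] == values[("Cz", b, f)]

    def test_same_offset_all_quadrants_and_features(self, layout_deap):
        # a single channel's value sits at one fixed (row, col) offset
        ch0 = layout_deap.channels[0]
        table = feature_table(layout_deap, lambda ch, b, f: 7.0 if ch == ch0 else 0.0)
        m = assemble_map(table, layout_deap)
        r, c = layout_deap.position(ch0)
        for fi in range(3):
            for dr, dc in [(0, 0), (0, 9), (8, 0), (8, 9)]:
                assert m.tensor[fi, r + dr, c + dc] == 7.0
        assert m.tensor.sum() == 7.0 * 12

    def test_zero_table_gives_zero_tensor(self, layout_deap):
        m = assemble_map(feature_table(layout_deap, lambda *a: 0.0), layout_deap)
        assert not m.tensor.any()

    def test_incomplete_coverage_raises(self, layout_deap):
        table = feature_table(layout_deap, lambda *a: 1.0)
        with pytest.raises(ValueError, match="missing"):
            assemble_map(table.iloc[:-5], layout_deap)


class TestNormalization:
    def test_zscore_on_fit_set(self, small_maps, layout_deap):
        stats = fit_normalization(small_maps, layout_deap)
        normed = normalize_maps(small_maps, stats)
        mask = tiled_mask(layout_deap)
        stack = np.stack([m.tensor for m in normed])
        for f in range(3):
            vals = stack[:, f][:, mask]
            assert abs(vals.mean()) < 1e-9
            assert abs(vals.std() - 1.0) < 1e-9
            assert not stack[:, f][:, ~mask].any()  # structural zeros intact

    def test_identity_stats(self, small_maps, layout_deap):
        from eegcaps.feature_map import NormalizationStats
        stats = NormalizationStats(mean=np.zeros(3), sd=np.ones(3),
                                   mask=tiled_mask(layout_deap))
        normed = normalize_maps(small_maps, stats)
        for a, b in zip(small_maps, normed):
            assert np.allclose(a.tensor[:, stats.mask], b.tensor[:, stats.mask])

    def test_heldout_application_deterministic(self, small_maps, layout_deap):
        stats = fit_normalization(small_maps[:20], layout_deap)
        a = normalize_maps(small_maps[20:25], stats)
        b = normalize_maps(small_maps[20:25], stats)
        for ma, mb in zip(a, b):
            assert np.array_equal(ma.tensor, mb.tensor)


class TestPipeline:
    def test_maps_deterministic(self, small_rec, layout_deap, small_maps):
        again = eg.build_feature_maps(small_rec, layout_deap, eg.SlicePlan())
        assert len(again) == len(small_maps)
        for a, b in zip(small_maps, again):
            assert np.array_equal(a.tensor, b.tensor)

    def test_structural_zeros_constant(self, small_maps, layout_deap):
        expected_zero = ~tiled_mask(layout_deap)
        for m in small_maps:
            assert not m.tensor[:, expected_zero].any()
            # occupied DE cells are never exactly zero (log-variance of noise)
            assert np.all(m.tensor[0][tiled_mask(layout_deap)] != 0)

    def test_archive_roundtrip(self, small_maps, layout_deap, tmp_path):
        path = tmp_path / "maps.h5"
        eg.save_maps(path, small_maps, layout_deap, extra={"window_seconds": 0.5})
        loaded, manifest = eg.load_maps(path)
        assert manifest["layout"] == "deap32"
        assert manifest["feature_order"] == ["DE", "SE", "PSD"]
        assert "config_hash" in manifest
        for a, b in zip(small_maps, loaded):
            assert np.array_equal(a.tensor, b.tensor)
            assert a.slice_ref == b.slice_ref
            assert a.label == b.label

    def test_sample_grouping_counts(self, small_maps):
        X, y, refs = eg.build_samples(small_maps, slices_per_sample=4)
        # 6 trials x 8 s x 2 windows/s = 16 slices -> 4 groups per trial
        assert X.shape == (24, 4, 3, 16, 18)
        assert len(y) == 24
        trials = [t for t, _ in refs]
        assert all(trials[i] <= trials[i + 1] for i in range(len(trials) - 1))

    def test_grid_mask_counts(self, layout_deap, layout_seed):
        assert grid_mask(layout_deap).sum() == 32
        assert grid_mask(layout_seed).sum() == 62
        assert tiled_mask(layout_deap).sum() == 4 * 32
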