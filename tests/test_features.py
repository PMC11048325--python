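"""Feature correctness: closed forms, brute-force oracles, DFT identities."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import eegcaps as eg
from eegcaps.features import (
    FeatureConfig,
    differential_entropy,
    extract_features,
    periodogram,
    power_spectral_density,
    sample_entropy,
)
from eegcaps.recording import Slice

CFG = FeatureConfig()


def sampen_bruteforce(x, m, r):
    """Independent O(n^2) double-loop oracle for sample entropy."""
    x = np.asarray(x, float)
    n = len(x)
    b = a = 0
    for i in range(n - m):
        for j in range(n - m):
            if i == j:
                continue
            if max(abs(x[i + t] - x[j + t]) for t in range(m)) <= r:
                b += 1
                if abs(x[i + m] - x[j + m]) <= r:
                    a += 1
    if b == 0 or a == 0:
        return math.nan
    return -math.log(a / b)


class TestDifferentialEntropy:
    def test_standard_normal_closed_form(self):
        x = np.random.default_rng(0).standard_normal(100_000)
        expected = 0.5 * math.log(2 * math.pi * math.e)  # ~1.4189
        assert abs(differential_entropy(x, CFG) - expected) < 0.01

    def test_scaling_law(self):
        x = np.random.default_rng(1).standard_normal(512)
        # DE(a x) - DE(x) = ln|a| exactly (variance scales by a^2)
        diff = differential_entropy(3.0 * x, CFG) - differential_entropy(x, CFG)
        assert abs(diff - math.log(3.0)) < 1e-9

    def test_variance_four_formula(self):
        x = 2.0 * np.random.default_rng(2).standard_normal(100_000)
        expected = 0.5 * math.log(2 * math.pi * math.e * 4.0)
        assert abs(differential_entropy(x, CFG) - expected) < 0.01

    def test_monotone_in_variance(self):
        base = np.random.default_rng(3).standard_normal(256)
        des = [differential_entropy(s * base, CFG) for s in (0.5, 1.0, 2.0, 5.0)]
        assert des == sorted(des)

    def test_log_base_two(self):
        x = np.random.default_rng(4).standard_normal(256)
        nat = differential_entropy(x, CFG)
        two = differential_entropy(x, FeatureConfig(log_base="base2"))
        assert abs(two - nat / math.log(2)) < 1e-12

    def test_constant_window_is_floored(self):
        v = differential_entropy(np.ones(64), CFG)
        assert np.isfinite(v)

    def test_short_window_raises(self):
        with pytest.raises(ValueError):
            differential_entropy(np.array([1.0]), CFG)


class TestSampleEntropy:
    def test_constant_series_is_zero(self):
        assert sample_entropy(np.full(32, 3.7), CFG) == 0.0

    def test_printed_periodic_series_matches_bruteforce(self):
        x = np.array([1, 2, 3, 1, 2, 3, 1, 2, 3, 1, 2, 3], dtype=float)
        cfg = FeatureConfig(sampen_m=2, sampen_r_factor=0.5)
        r = 0.5 * np.std(x)
        expected = sampen_bruteforce(x, 2, r)
        assert sample_entropy(x, cfg) == pytest.approx(expected, abs=1e-12)
        assert expected == 0.0  # perfectly periodic: every m-match extends

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_random_series_matches_bruteforce(self, seed):
        x = np.random.default_rng(seed).standard_normal(60)
        r = CFG.sampen_r_factor * np.std(x)
        assert sample_entropy(x, CFG) == pytest.approx(
            sampen_bruteforce(x, CFG.sampen_m, r), abs=1e-12)

    def test_noise_exceeds_sinusoid(self):
        rng = np.random.default_rng(5)
        noise = rng.uniform(-1, 1, 500)
        sinus = np.sin(2 * np.pi * 5 * np.arange(500) / 500)
        assert sample_entropy(noise, CFG) > sample_entropy(sinus, CFG)

    @given(scale=st.floats(0.1, 100.0))
    @settings(max_examples=20, deadline=None)
    def test_scale_invariance(self, scale):
        x = np.random.default_rng(6).standard_normal(300)
        base = sample_entropy(x, CFG)
        assert math.isfinite(base)
        assert sample_entropy(scale * x, CFG) == pytest.approx(base, rel=1e-9)

    def test_undefined_returns_nan(self):
        # strictly increasing with huge steps: no m+1 template matches at tiny r
        x = np.array([0.0, 10.0, 0.1, 30.0, 0.2, 50.0, 0.3, 70.0, 0.4, 90.0])
        cfg = FeatureConfig(sampen_m=2, sampen_r_factor=1e-6)
        assert math.isnan(sample_entropy(x, cfg))

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            sample_entropy(np.arange(3.0), CFG)


class TestPSD:
    def test_zero_window(self):
        assert power_spectral_density(np.zeros(64), CFG) == 0.0

    @pytest.mark.parametrize("seed", [0, 1])
    def test_parseval(self, seed):
        x = np.random.default_rng(seed).standard_normal(100)
        assert abs(periodogram(x).sum() - np.sum(x**2)) < 1e-9

    def test_sinusoid_total_mass(self):
        n, amp, cycles = 128, 2.5, 7
        x = amp * np.sin(2 * np.pi * cycles * np.arange(n) / n)
        assert periodogram(x).sum() == pytest.approx(n * amp**2 / 2, rel=1e-9)

    def test_mean_vs_sum_reduction(self):
        x = np.random.default_rng(7).standard_normal(64)
        mean = power_spectral_density(x, FeatureConfig(psd_reduction="mean"))
        total = power_spectral_density(x, FeatureConfig(psd_reduction="sum"))
        assert total == pytest.approx(mean * 32)  # 64//2 positive bins

    def test_bandfiltered_mass_concentrates(self):
        rng = np.random.default_rng(8)
        rate = 128.0
        x = rng.standard_normal(int(8 * rate))
        alpha = eg.CANONICAL_BANDS[1]
        filt = eg.bandpass_filter(x, alpha, rate)
        P = np.abs(np.fft.rfft(filt)) ** 2
        freqs = np.fft.rfftfreq(filt.size, 1 / rate)
        in_band = (freqs >= alpha.low) & (freqs <= alpha.high)
        assert P[in_band].sum() / P.sum() >= 0.80


class TestExtractFeatures:
    def band_slices(self, n_ch=32, seed=0):
        rng = np.random.default_rng(seed)
        names = list(eg.DEAP32_CHANNEL_ORDER)[:n_ch]
        sl = Slice(trial=0, index=0, data=rng.standard_normal((n_ch, 64)),
                   label=0, channel_names=names)
        return eg.bandpass_decompose(sl, sampling_rate=128.0)

    def test_cardinality(self):
        table = extract_features(self.band_slices(), CFG)
        assert len(table) == 32 * 4 * 3  # channels x bands x features

    def test_order_invariance(self):
        slices = self.band_slices()
        a = extract_features(slices, CFG)
        b = extract_features(slices[::-1], CFG)
        assert a.equals(b)

    def test_missing_band_raises(self):
        sl = Slice(trial=0, index=0, data=np.zeros((2, 64)),
                   channel_names=["a", "b"])
        with pytest.raises(ValueError):
            extract_features([sl], CFG)

    def test_gamma_effect_localized_to_effect_channels(self, small_rec):
        """Class difference in mean gamma DE appears only in effect channels."""
        spec_channels = set(("Fp1", "Fp2", "F3", "F4", "T7", "T8", "P3", "P4"))
        gamma = eg.CANONICAL_BANDS[3]
        sums = {}
        for t, sig in enumerate(small_rec.signals):
            filt = eg.bandpass_filter(sig, gamma, small_rec.sampling_rate)
            y = small_rec.trial_label(t)
            for k in range(sig.shape[1] // 64):
                feats = eg.window_features(filt[:, k * 64:(k + 1) * 64], CFG)
                sums.setdefault(y, []).append(feats["DE"])
        mean0 = np.mean(sums[0], axis=0)
        mean1 = np.mean(sums[1], axis=0)
        diff = dict(zip(small_rec.channel_names, mean1 - mean0))
        for ch, d in diff.items():
            if ch in spec_channels:
                assert d > 0.3, ch
            else:
                assert abs(d) < 0.15, ch
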