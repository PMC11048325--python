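"""Generate synthetic multichannel EEG with a known class-dependent gamma effect.

Builds a small 32-channel recording in which class-1 trials carry extra
gamma-band (31-50 Hz) amplitude in eight frontal/temporal/parietal channels,
then verifies the effect is visible as a differential-entropy (DE) gap.
"""

import numpy as np

import eegcaps as eg
from eegcaps.features import FeatureConfig, differential_entropy

spec = eg.SynthSpec(n_trials=8, trial_duration=8.0, effect_band="gamma",
                    effect_size=1.0, seed=42)
rec = eg.generate_recording(spec)
print(f"trials: {rec.n_trials}, channels: {rec.n_channels}, "
      f"samples/trial: {rec.signals[0].shape[1]} at {rec.sampling_rate:.0f} Hz")
print(f"class counts: {rec.labels['y'].value_counts().to_dict()}")

# gamma-band DE in the effect channels, per class, over 0.5 s windows
gamma = eg.CANONICAL_BANDS[3]
idx = [rec.channel_names.index(c) for c in spec.effect_channels]
cfg = FeatureConfig()
per_class = {0: [], 1: []}
for t, sig in enumerate(rec.signals):
    filt = eg.bandpass_filter(sig[idx], gamma, rec.sampling_rate)
    for k in range(sig.shape[1] // 64):
        for row in filt[:, k * 64:(k + 1) * 64]:
            per_class[rec.trial_label(t)].append(differential_entropy(row, cfg))

m0, m1 = np.mean(per_class[0]), np.mean(per_class[1])
print(f"mean gamma DE, class 0: {m0:.3f}  class 1: {m1:.3f}  gap: {m1 - m0:.3f}")
print("The positive gap is the injected effect: class-1 gamma amplitude is "
      "doubled (1 + effect_size), so DE rises by about ln(2) = 0.69 minus the "
      "dilution from the broadband noise floor.")
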