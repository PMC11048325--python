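import logging

import numpy as np
import pytest

import eegcaps as eg
from eegcaps.feature_map import tiled_mask
from eegcaps.training import TrainConfig, train_fold

# the per-window SampEn warning on very regular theta windows is expected
logging.getLogger("eegcaps.features").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def layout_deap():
    return eg.load_layout("deap32")


@pytest.fixture(scope="session")
def layout_seed():
    return eg.load_layout("seed62")


@pytest.fixture(scope="session")
def small_rec():
    """6 trials x 8 s of 32-channel EEG with a strong gamma class effect."""
    spec = eg.SynthSpec(n_trials=6, trial_duration=8.0, effect_size=1.5, seed=11)
    return eg.generate_recording(spec)


@pytest.fixture(scope="session")
def small_maps(small_rec, layout_deap):
    return eg.build_feature_maps(small_rec, layout_deap, eg.SlicePlan())


@pytest.fixture(scope="session")
def small_samples(small_maps):
    X, y, refs = eg.build_samples(small_maps)
    return X, y


@pytest.fixture(scope="session")
def deap_like_rec():
    return eg.generate_deap_like(seed=5)


def tiny_model_config(n_classes=2, **kwargs):
    """A very small but structurally complete model for fast tests."""
    caps = eg.CapsNetConfig(
        conv_out_channels=32, primary_caps_channels=4, primary_caps_dim=8,
        n_classes=n_classes, se_reduction=8,
        use_eca=kwargs.pop("use_eca", True), use_se=kwargs.pop("use_se", True),
    )
    enc = eg.EncoderConfig(n_classes=n_classes, n_layers=2, **kwargs.pop("encoder", {}))
    return eg.ModelConfig(capsnet=caps, encoder=enc, **kwargs)


@pytest.fixture(scope="session")
def tiny_trained(small_samples, layout_deap):
    """A tiny model trained briefly on the small synthetic set."""
    X, y = small_samples
    cfg = TrainConfig(learning_rate=2e-3, batch_size=8, max_epochs=30,
                      early_stop_patience=None, seed=2)
    import dataclasses

    res = train_fold(X, y, tiny_model_config(), cfg, mask=tiled_mask(layout_deap))
    model = eg.EmotionCapsTransformer(dataclasses.replace(tiny_model_config(), seed=2))
    model.load_state_dict(res.state)
    return model, res, (X, y)
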