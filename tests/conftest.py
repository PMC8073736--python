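import numpy as np
import pytest

import harkit as hk
from harkit.models import TrainingConfig, train_model


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def walking_stream():
    """A 12 s noise-free walking stream at 50 Hz."""
    from harkit.synthetic import DEFAULT_PRESETS, GenerationConfig
    from dataclasses import replace

    model = replace(DEFAULT_PRESETS[hk.ActivityLabel.WALKING], noise_sd=0.0)
    return hk.generate_activity_stream(model, GenerationConfig(duration=12.0, seed=9))


@pytest.fixture
def frame_60(walking_stream):
    """One canonical 6x60 window frame."""
    return hk.segment_stream(walking_stream)[0]


@pytest.fixture(scope="session")
def small_dataset():
    """Labeled frames from short default-preset streams (all 8 classes)."""
    config = hk.GenerationConfig(duration=60.0, seed=11)
    streams = hk.generate_labeled_dataset(hk.DEFAULT_PRESETS, config, n_streams=8)
    return [f for s in streams for f in hk.segment_stream(s)]


@pytest.fixture(scope="session")
def small_dc_model(small_dataset):
    """A briefly trained DC-CNN shared by evaluation/streaming tests."""
    split = hk.split_dataset(small_dataset, (0.8, 0.1, 0.1), seed=2)
    model, history = train_model(
        hk.build_dc_cnn(), split, TrainingConfig(epochs=10, seed=2))
    return model, history, split
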