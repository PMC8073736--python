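from dataclasses import replace

import numpy as np
import pytest

import harkit as hk
from harkit.labels import DYNAMIC_LABELS, STATIC_LABELS
from harkit.synthetic import (
    DEFAULT_PRESETS,
    GenerationConfig,
    SyntheticActivityModel,
    generate_activity_stream,
    generate_labeled_dataset,
    load_presets,
)


class TestGenerateActivityStream:
    def test_1_2_seconds_at_50hz_gives_60_samples(self):
        config = GenerationConfig(duration=1.2, rate=50.0, seed=0)
        stream = generate_activity_stream(
            DEFAULT_PRESETS[hk.ActivityLabel.WALKING], config)
        assert len(stream) == 60

    def test_same_seed_is_bit_identical(self):
        config = GenerationConfig(duration=5.0, seed=42)
        a = generate_activity_stream(DEFAULT_PRESETS[hk.ActivityLabel.JOGGING], config)
        b = generate_activity_stream(DEFAULT_PRESETS[hk.ActivityLabel.JOGGING], config)
        assert np.array_equal(a.data, b.data) and np.array_equal(a.t, b.t)

    def test_zero_length_request_raises(self):
        with pytest.raises(ValueError):
            GenerationConfig(duration=0.0, seed=0)

    @pytest.mark.parametrize("label", sorted(DYNAMIC_LABELS))
    def test_noise_free_spectrum_peaks_at_fundamental(self, label):
        """Dominant nonzero DFT bin of each driven channel sits at the bin
        nearest the configured fundamental."""
        model = replace(DEFAULT_PRESETS[label], noise_sd=0.0)
        config = GenerationConfig(duration=20.0, seed=5)
        stream = generate_activity_stream(model, config)
        n = len(stream)
        freqs = np.fft.fftfreq(n, d=1 / config.rate)
        expected_bin = np.argmin(np.abs(freqs[: n // 2] - model.fundamental_hz))
        for ch in range(6):
            if model.harmonic_amps[ch] == 0:
                continue
            mags = np.abs(np.fft.fft(stream.data[:, ch]))[: n // 2]
            mags[0] = 0.0  # ignore the gravity/DC component
            assert np.argmax(mags) == expected_bin, (label, ch)

    def test_static_presets_have_much_lower_variance(self):
        config = GenerationConfig(duration=10.0, seed=7)
        var = {}
        for label, model in DEFAULT_PRESETS.items():
            stream = generate_activity_stream(model, config)
            var[label] = stream.data.var(axis=0).mean()
        worst_static = max(var[lab] for lab in STATIC_LABELS)
        best_dynamic = min(var[lab] for lab in DYNAMIC_LABELS)
        assert worst_static * 10 < best_dynamic

    def test_invalid_models_rejected(self):
        with pytest.raises(ValueError, match="unit norm"):
            SyntheticActivityModel(hk.ActivityLabel.STILL, 0.0, (0.0,) * 6,
                                   gravity_axis=(1.0, 1.0, 0.0))
        with pytest.raises(ValueError):
            SyntheticActivityModel(hk.ActivityLabel.STILL, -1.0, (0.0,) * 6)


class TestGenerateLabeledDataset:
    def test_uniform_mix_80_streams_gives_10_per_class(self):
        config = GenerationConfig(duration=1.2, seed=0)
        streams = generate_labeled_dataset(DEFAULT_PRESETS, config, n_streams=80)
        assert len(streams) == 80
        for label in hk.ActivityLabel:
            assert sum(s.label is label for s in streams) == 10

    def test_seeded_run_is_reproducible(self):
        config = GenerationConfig(duration=2.0, seed=13)
        a = generate_labeled_dataset(DEFAULT_PRESETS, config, n_streams=8)
        b = generate_labeled_dataset(DEFAULT_PRESETS, config, n_streams=8)
        assert all(np.array_equal(x.data, y.data) for x, y in zip(a, b))

    def test_missing_class_model_raises(self):
        partial = {lab: m for lab, m in DEFAULT_PRESETS.items()
                   if lab is not hk.ActivityLabel.LYING}
        with pytest.raises(ValueError, match="lying"):
            generate_labeled_dataset(partial, GenerationConfig(seed=0))

    def test_class_mix_proportions_respected(self):
        mix = {lab: 0.0 for lab in hk.ActivityLabel}
        mix[hk.ActivityLabel.WALKING] = 0.75
        mix[hk.ActivityLabel.STILL] = 0.25
        config = GenerationConfig(duration=1.2, seed=0, class_mix=mix)
        streams = generate_labeled_dataset(DEFAULT_PRESETS, config, n_streams=12)
        assert sum(s.label is hk.ActivityLabel.WALKING for s in streams) == 9
        assert sum(s.label is hk.ActivityLabel.STILL for s in streams) == 3

    def test_static_vs_dynamic_linearly_separable(self, small_dataset):
        """Per-window channel means/variances must separate static from
        dynamic classes almost perfectly — the presets are learnable."""
        from sklearn.linear_model import LogisticRegression
        from sklearn.model_selection import StratifiedKFold, cross_val_score
        from sklearn.pipeline import make_pipeline
        from sklearn.preprocessing import StandardScaler

        x = np.array([
            np.concatenate([f.values.mean(axis=1), f.values.var(axis=1)])
            for f in small_dataset])
        y = np.array([f.label in STATIC_LABELS for f in small_dataset])
        clf = make_pipeline(StandardScaler(), LogisticRegression(max_iter=1000))
        cv = StratifiedKFold(n_splits=3, shuffle=True, random_state=0)
        scores = cross_val_score(clf, x, y, cv=cv)
        assert scores.mean() >= 0.99


def test_load_presets_overrides(tmp_path):
    path = tmp_path / "presets.txt"
    path.write_text(
        "walking.fundamental_hz = 1.8\n"
        "# comment line\n"
        "lying.gravity_axis = 0,1,0\n")
    presets = load_presets(path)
    assert presets[hk.ActivityLabel.WALKING].fundamental_hz == 1.8
    assert presets[hk.ActivityLabel.LYING].gravity_axis == (0.0, 1.0, 0.0)
    assert presets[hk.ActivityLabel.JOGGING] == DEFAULT_PRESETS[hk.ActivityLabel.JOGGING]
    with pytest.raises(ValueError, match="unknown field"):
        bad = tmp_path / "bad.txt"
        bad.write_text("walking.bogus = 1\n")
        load_presets(bad)
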