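import numpy as np
import pytest

import harkit as hk
from harkit.models import (
    ARCHITECTURE_BUILDERS,
    TrainingConfig,
    compile_network,
    frames_to_inputs,
    lr_at_step,
    predict,
    train_model,
)
from harkit.structuring import Layout


class TestLearningRateSchedule:
    def test_printed_schedule_values(self):
        config = TrainingConfig()
        assert lr_at_step(0, config) == pytest.approx(1e-4)
        assert lr_at_step(1000, config) == pytest.approx(9e-5)
        assert lr_at_step(2000, config) == pytest.approx(8.1e-5)

    def test_strictly_decreasing_and_exact_at_multiples(self):
        config = TrainingConfig()
        rates = [lr_at_step(s, config) for s in range(0, 5000, 137)]
        assert all(a > b for a, b in zip(rates, rates[1:]))
        for k in range(5):
            assert lr_at_step(1000 * k, config) == pytest.approx(1e-4 * 0.9 ** k)

    def test_staircase_holds_within_step(self):
        config = TrainingConfig(staircase=True)
        assert lr_at_step(999, config) == pytest.approx(1e-4)
        assert lr_at_step(1000, config) == pytest.approx(9e-5)

    def test_negative_step_raises(self):
        with pytest.raises(ValueError):
            lr_at_step(-1)


class TestBuilders:
    def test_sc_cnn_spec(self):
        arch = hk.build_sc_cnn()
        kinds = [s.kind for s in arch.layers]
        assert kinds == ["conv2d", "batch_norm", "relu", "avg_pool",
                        "conv2d", "batch_norm", "relu", "avg_pool",
                        "flatten", "dense", "relu", "dense", "softmax"]
        conv1, conv2 = arch.layers[0], arch.layers[4]
        assert conv1.params["filters"] == 20 and conv1.params["kernel"] == [2, 2]
        assert conv2.params["filters"] == 40 and conv2.params["kernel"] == [3, 3]
        assert arch.layers[3].params["pool"] == [2, 4]
        assert arch.layers[7].params["pool"] == [1, 2]
        assert arch.layers[9].params["units"] == 512

    def test_dc_cnn_spec(self):
        arch = hk.build_dc_cnn()
        assert arch.input_shape == (7, 60, 2)
        assert arch.layers[0].params["in_channels"] == 2  # 2x2x2 first kernels
        dense = [s for s in arch.layers if s.kind == "dense"]
        assert dense[0].params["units"] == 256
        assert dense[-1].params["units"] == 8

    def test_lstm_spec(self):
        arch = hk.build_lstm()
        assert arch.input_shape == (60, 6)  # 60 timesteps of raw IMU samples
        assert arch.layers[0].params["units"] == 100

    def test_convlstm_spec(self):
        arch = hk.build_convlstm()
        spec = arch.layers[0]
        assert spec.params["kernel"] == [1, 3] and spec.params["filters"] == 64

    def test_incompatible_shapes_raise(self):
        with pytest.raises(ValueError):
            hk.build_sc_cnn((14, 60, 2))
        with pytest.raises(ValueError):
            hk.build_dc_cnn((7, 60, 1))
        with pytest.raises(ValueError):
            hk.build_sc_cnn((2, 60, 1))

    @pytest.mark.parametrize("name", sorted(ARCHITECTURE_BUILDERS))
    def test_forward_pass_is_a_probability_vector(self, name, rng):
        arch = ARCHITECTURE_BUILDERS[name]()
        net = compile_network(arch, seed=0)
        x = rng.normal(size=(3,) + tuple(arch.input_shape))
        probs = net.predict_proba(x)
        assert probs.shape == (3, 8)
        assert (probs >= 0).all()
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)

    @pytest.mark.parametrize("name", sorted(ARCHITECTURE_BUILDERS))
    def test_declared_shapes_match_engine_shapes(self, name):
        arch = ARCHITECTURE_BUILDERS[name]()
        net = compile_network(arch, seed=1)
        x = np.zeros((2,) + tuple(arch.input_shape))
        for layer, spec in zip(net.layers, arch.layers):
            x = layer.forward(x, training=True)
            assert x.shape[1:] == tuple(spec.output_shape), spec.kind

    def test_parameter_count_ordering(self):
        counts = {name: ARCHITECTURE_BUILDERS[name]().param_count()
                  for name in ARCHITECTURE_BUILDERS}
        assert (counts["lstm"] < counts["dc_cnn"]
                < counts["sc_cnn"] < counts["convlstm"])


class TestFramesToInputs:
    def test_image_sequence_and_conv_sequence_shapes(self, frame_60):
        frames = [frame_60]
        x, y = frames_to_inputs(frames, hk.build_dc_cnn())
        assert x.shape == (1, 7, 60, 2)
        x, _ = frames_to_inputs(frames, hk.build_sc_cnn())
        assert x.shape == (1, 14, 60, 1)
        x, _ = frames_to_inputs(frames, hk.build_lstm())
        assert x.shape == (1, 60, 6)
        np.testing.assert_array_equal(x[0], frame_60.values.T)
        x, _ = frames_to_inputs(frames, hk.build_convlstm())
        assert x.shape == (1, 4, 1, 15, 6)
        assert y.tolist() == [int(frame_60.label)]

    def test_quantized_path_is_0_255(self, frame_60):
        x, _ = frames_to_inputs([frame_60], hk.build_dc_cnn(), quantize=True)
        assert x.min() >= 0 and x.max() <= 255

    def test_unlabeled_frames_rejected(self, frame_60):
        unlabeled = hk.WindowFrame(frame_60.values)
        with pytest.raises(ValueError, match="label"):
            frames_to_inputs([unlabeled], hk.build_dc_cnn())


class TestTraining:
    def test_history_one_record_per_epoch_and_loss_drops(self, small_dc_model):
        _, history, _ = small_dc_model
        assert len(history) == 10
        assert history.final.train_loss < history.records[0].train_loss

    def test_empty_training_set_raises(self):
        split = hk.DatasetSplit(train=[], validation=[], development=[], seed=0)
        with pytest.raises(ValueError, match="empty"):
            train_model(hk.build_dc_cnn(), split, TrainingConfig(epochs=1))

    def test_validation_tracked_every_epoch(self, small_dc_model):
        _, history, _ = small_dc_model
        assert all(r.val_accuracy is not None for r in history.records)

    def test_training_is_seeded_reproducible(self, small_dataset):
        split = hk.split_dataset(small_dataset[:200], (0.8, 0.1, 0.1), seed=0)
        config = TrainingConfig(epochs=1, seed=5)
        _, h1 = train_model(hk.build_lstm(), split, config)
        _, h2 = train_model(hk.build_lstm(), split, config)
        assert h1.final.train_loss == h2.final.train_loss


class TestPredict:
    def test_probabilities_and_batch_invariance(self, small_dc_model, small_dataset):
        model, _, split = small_dc_model
        frames = split.development[:24]
        probs, labels = predict(model, frames)
        assert probs.shape == (24, 8) and len(labels) == 24
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        half_a, _ = predict(model, frames[:12])
        half_b, _ = predict(model, frames[12:])
        np.testing.assert_allclose(np.vstack([half_a, half_b]), probs, atol=1e-6)

    def test_uniform_probabilities_tie_break_to_lowest_class(self):
        arch = hk.build_dc_cnn()
        net = compile_network(arch, seed=0)
        # zero the final dense stage: all logits equal, probs uniform
        net.layers[-2].w[...] = 0.0
        net.layers[-2].b[...] = 0.0
        probs, labels = predict(net, np.ones((3, 7, 60, 2)))
        np.testing.assert_allclose(probs, 1 / 8, atol=1e-12)
        assert all(lab is hk.ActivityLabel.WALKING for lab in labels)  # index 0

    def test_save_load_round_trip(self, small_dc_model, small_dataset, tmp_path):
        model, _, split = small_dc_model
        frames = split.development[:8]
        before, _ = predict(model, frames)
        model.save(tmp_path / "model")
        loaded = hk.TrainedModel.load(tmp_path / "model")
        after, _ = predict(loaded, frames)
        np.testing.assert_allclose(after, before, atol=1e-12)
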