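import socket

import numpy as np
import pytest

import harkit as hk
from harkit.evaluation import ConfusionMatrix, evaluate, stream_predict
from harkit.labels import ActivityLabel
from harkit.synthetic import DEFAULT_PRESETS, GenerationConfig, generate_activity_stream


# The 8x8 development-set count grid used as an arithmetic fixture for the
# accuracy formula: row = true class, column = predicted class.
DEV_GRID = np.array([
    [185, 0, 3, 1, 0, 0, 0, 0],     # walking
    [0, 87, 0, 1, 0, 0, 0, 0],      # jumping
    [3, 0, 139, 0, 0, 0, 0, 0],     # upstairs
    [0, 0, 0, 116, 0, 0, 0, 0],     # downstairs
    [1, 0, 0, 0, 109, 0, 0, 0],     # jogging
    [1, 0, 0, 0, 0, 141, 0, 0],     # cycling
    [0, 0, 0, 0, 0, 0, 109, 0],     # still
    [0, 0, 0, 0, 0, 0, 0, 104],     # lying
])


class TestConfusionMatrix:
    def test_all_correct_is_diagonal_with_accuracy_one(self):
        y = [i % 8 for i in range(40)]
        m = ConfusionMatrix.from_pairs(y, y)
        assert m.accuracy == 1.0
        assert np.all(m.counts == np.diag(np.diag(m.counts)))

    def test_all_wrong_single_class_has_zero_trace(self):
        y = [i % 8 for i in range(16)]
        pred = [(t + 1) % 8 for t in y]
        m = ConfusionMatrix.from_pairs(y, pred)
        assert np.trace(m.counts) == 0
        assert m.accuracy == 0.0

    def test_published_grid_accuracy_is_trace_over_total(self):
        pairs_true, pairs_pred = [], []
        for t in range(8):
            for p in range(8):
                pairs_true += [t] * DEV_GRID[t, p]
                pairs_pred += [p] * DEV_GRID[t, p]
        m = ConfusionMatrix.from_pairs(pairs_true, pairs_pred)
        assert m.total == 1000
        assert m.accuracy == pytest.approx(np.trace(DEV_GRID) / 1000)
        assert m.accuracy == pytest.approx(0.990)
        # spot-check a recall: walking row 185 correct of 189
        assert m.per_class_recall()[0] == pytest.approx(185 / 189)

    def test_row_sums_are_per_class_counts(self):
        m = ConfusionMatrix(DEV_GRID)
        np.testing.assert_array_equal(
            m.counts.sum(axis=1),
            [189, 88, 142, 116, 110, 142, 109, 104])

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionMatrix(-np.ones((8, 8), dtype=int))


class TestEvaluate:
    def test_accuracy_and_matrix_on_development_set(self, small_dc_model):
        model, _, split = small_dc_model
        acc, matrix = evaluate(model, split.development)
        assert 0.0 <= acc <= 1.0
        assert matrix.total == len(split.development)
        assert acc == pytest.approx(matrix.accuracy)

    def test_permutation_invariance(self, small_dc_model, rng):
        model, _, split = small_dc_model
        frames = split.development[:60]
        acc_a, m_a = evaluate(model, frames)
        perm = rng.permutation(len(frames))
        acc_b, m_b = evaluate(model, [frames[i] for i in perm])
        assert acc_a == acc_b
        np.testing.assert_array_equal(m_a.counts, m_b.counts)

    def test_empty_set_raises(self, small_dc_model):
        model, _, _ = small_dc_model
        with pytest.raises(ValueError, match="empty"):
            evaluate(model, [])


class TestStreamPredict:
    def test_zero_latency_gives_floor_n_over_w_predictions(self, small_dc_model):
        model, _, _ = small_dc_model
        stream = generate_activity_stream(
            DEFAULT_PRESETS[ActivityLabel.WALKING],
            GenerationConfig(duration=2.4, seed=3))
        preds = stream_predict(model, stream, inference_time=0.0)
        assert len(preds) == 2
        assert all(p.dropped_samples == 0 for p in preds)
        assert preds[0].end_time < preds[1].end_time

    def test_80ms_latency_drops_4_samples_per_cycle(self, small_dc_model):
        model, _, _ = small_dc_model
        stream = generate_activity_stream(
            DEFAULT_PRESETS[ActivityLabel.JOGGING],
            GenerationConfig(duration=10.0, seed=3))
        preds = stream_predict(model, stream, inference_time=0.08)
        assert len(preds) == 500 // 64  # 60-sample window + 4 dropped per cycle
        assert all(p.dropped_samples == 4 for p in preds)

    def test_still_stream_classified_still_in_majority(self, small_dc_model):
        model, _, _ = small_dc_model
        stream = generate_activity_stream(
            DEFAULT_PRESETS[ActivityLabel.STILL],
            GenerationConfig(duration=12.0, seed=21))
        preds = stream_predict(model, stream, inference_time=0.08)
        votes = sum(p.label is ActivityLabel.STILL for p in preds)
        assert votes > len(preds) / 2
        assert all(1 / 8 <= p.confidence <= 1.0 for p in preds)

    def test_rate_mismatch_raises(self, small_dc_model):
        model, _, _ = small_dc_model
        stream = generate_activity_stream(
            DEFAULT_PRESETS[ActivityLabel.STILL],
            GenerationConfig(duration=3.0, seed=0, rate=25.0))
        with pytest.raises(ValueError, match="rate"):
            stream_predict(model, stream)


def test_transport_loopback_round_trip(walking_stream):
    """Newline-CSV rows survive a socketpair echo bit-exactly (to the
    printed precision)."""
    from harkit.transport import receive_readings, send_stream

    sub = hk.ActivityStream(data=walking_stream.data[:30],
                            t=walking_stream.t[:30], rate=50.0)
    a, b = socket.socketpair()
    try:
        send_stream(a, sub)
        rows = receive_readings(b, len(sub))
    finally:
        a.close()
        b.close()
    got = np.array([tuple(r) for r in rows])
    np.testing.assert_allclose(got[:, 0], sub.t, atol=5e-7)
    np.testing.assert_allclose(got[:, 1:], sub.data, atol=5e-7)
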