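"""Replay a recording through the drop-while-inferring streaming loop.

The buffer fills to one 60-sample window, the window is classified, and
samples arriving during the modelled 80 ms inference are discarded (4
samples at 50 Hz) before buffering resumes. Windows never overlap in the
real-time loop; overlap is a training-time augmentation.
"""

import harkit as hk
from harkit.models import TrainingConfig, train_model

# quick model
config = hk.GenerationConfig(duration=40.0, seed=11)
streams = hk.generate_labeled_dataset(hk.DEFAULT_PRESETS, config, n_streams=8)
frames = [f for s in streams for f in hk.segment_stream(s)]
split = hk.split_dataset(frames, (0.8, 0.1, 0.1), seed=0)
model, _ = train_model(hk.build_dc_cnn(), split, TrainingConfig(epochs=8, seed=0))

# a fresh 20 s still recording, replayed live
recording = hk.generate_activity_stream(
    hk.DEFAULT_PRESETS[hk.ActivityLabel.STILL],
    hk.GenerationConfig(duration=20.0, seed=99))
predictions = hk.stream_predict(model, recording, inference_time=0.08)

for p in predictions[:6]:
    print(f"t={p.end_time:6.2f}s  {p.label.name.lower():<8} "
          f"confidence={p.confidence:.3f}  dropped={p.dropped_samples}")
correct = sum(p.label is hk.ActivityLabel.STILL for p in predictions)
print(f"... {correct}/{len(predictions)} windows classified as still; "
      f"{sum(p.dropped_samples for p in predictions)} samples dropped in total")
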