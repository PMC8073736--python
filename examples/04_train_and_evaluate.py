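"""Train the DC-CNN on the time-domain double-channel images and evaluate.

A deliberately small run (8 classes x ~66 windows each, 8 epochs) that
still separates the synthetic activities well; the full study conditions
are exercised by scripts/acceptance.py. The confusion matrix rows are true
classes in the fixed label order, columns predicted classes.
"""

import numpy as np

import harkit as hk
from harkit.models import TrainingConfig, train_model

config = hk.GenerationConfig(duration=40.0, seed=11)
streams = hk.generate_labeled_dataset(hk.DEFAULT_PRESETS, config, n_streams=8)
frames = [f for s in streams for f in hk.segment_stream(s)]
split = hk.split_dataset(frames, (0.8, 0.1, 0.1), seed=0)
print(f"{len(frames)} windows -> train/val/dev sizes {split.sizes}")

model, history = train_model(
    hk.build_dc_cnn(), split, TrainingConfig(epochs=8, seed=0), verbose=True)

acc, matrix = hk.evaluate(model, split.development)
print(f"\ndevelopment accuracy: {acc:.3f} on {matrix.total} windows")
print("confusion matrix (rows true, columns predicted):")
print(matrix.counts)
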