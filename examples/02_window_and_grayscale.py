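"""Cut a stream into 1.2 s windows with 50 % overlap; render one as pixels.

A 50 Hz stream yields 60-sample windows; consecutive windows share 30
columns. The grayscale mapping sends the window minimum to 0 and maximum
to 255 — the same normalization used to visualize virtual images.
"""

import harkit as hk

stream = hk.generate_activity_stream(
    hk.DEFAULT_PRESETS[hk.ActivityLabel.WALKING],
    hk.GenerationConfig(duration=10.0, seed=7))

frames = hk.segment_stream(stream, window_seconds=1.2, overlap_fraction=0.5)
print(f"{len(stream)} samples -> {len(frames)} windows of "
      f"{frames[0].width} columns each")
print(f"first window starts at sample {frames[0].origin[1]}, "
      f"second at {frames[1].origin[1]} (hop 30 = 50% overlap)")

img = hk.to_grayscale(frames[0])
print(f"grayscale pixels span {img.pixels.min()}..{img.pixels.max()}")
print("first accelerometer row, every 6th pixel:", img.pixels[0, ::6])
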