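"""The three representations and three virtual-image layouts.

A 6x60 window can be kept in the time domain (TD), transformed to its
two-sided DFT magnitude spectrum (FD), or to concatenated 3-level Haar
wavelet coefficients (WT). Each 3x60 sensor block is then duplicated into
the 7-row x,y,z,x,y,z,x pattern and arranged as a single-plane 14x60 image
(SC) or a two-channel 7x60 image (DC); UNALTERED keeps the raw 6x60 grid.
"""

from itertools import product

import numpy as np

import harkit as hk

stream = hk.generate_activity_stream(
    hk.DEFAULT_PRESETS[hk.ActivityLabel.JOGGING],
    hk.GenerationConfig(duration=5.0, seed=3))
frame = hk.segment_stream(stream)[0]

fd = hk.fd_rows(frame)
peak_bin = int(np.argmax(fd.values[2][1:30])) + 1
print(f"FD: dominant az bin {peak_bin} -> {peak_bin * 50 / 60:.2f} Hz "
      f"(jogging fundamental is 2.5 Hz)")

wt = hk.wt_rows(frame)
print(f"WT: {len(wt.subband_slices)} subbands at column spans "
      f"{wt.subband_slices} (truncated to width 60)")

for tag, layout in product(hk.RepresentationTag, hk.Layout):
    img = hk.frame_to_image(frame, tag, layout)
    print(f"{tag.value.upper()}-{layout.value:<9} -> shape {img.shape}")
# Nine combinations, three geometries: (6,60,1), (14,60,1), (7,60,2).
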