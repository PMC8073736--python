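# Methods

## Pipeline model

The package treats sensor-based activity recognition as image
classification over *virtual images*: 2-D (optionally multi-channel)
numeric grids built from windowed time series. The pipeline assumes

* a waist-worn device logging linear acceleration (m/s²) and angular
  velocity (rad/s) on three axes each, nominally at 50 Hz;
* one activity per recording (labels are per stream, optionally per row);
* activities that are either approximately periodic (walking, jogging,
  jumping, stairs, cycling) or static postures distinguished by device
  orientation (still, lying).

Streams whose inter-sample spacing deviates from 1/rate by more than a
jitter tolerance (default ±20 % of the period) are rejected, never
resampled: silent resampling would change the spectral content that the
FD/WT representations and the class fundamentals rely on.

## Windowing

Window length is `W = round(window_seconds · rate)`; the defaults 1.2 s ×
50 Hz = 60 samples make one window roughly one-to-two motion cycles for
every class. Hop is `H = round(W · (1 − overlap))` with 50 % overlap as the
single augmentation; trailing samples that do not fill a window are
dropped, so every training unit is exactly 6×W. Windows never span
recording boundaries. The window count is `floor((N − W)/H) + 1`, verified
against brute-force enumeration of start indices in the tests.

The grayscale map `v ↦ round(255·(v − min)/(max − min))` (round-half-up) is
a visualization and an optional quantized input path; by default the
networks consume raw sensor values, and batch normalization absorbs scale.
A constant window has no defined affine map and renders all-zero.

## Representations

* **TD** is the identity.
* **FD** is the full two-sided unnormalized DFT magnitude per row. Keeping
  both halves of the spectrum preserves the 6(→7/14)×60 image geometry
  across representations at the cost of mirrored redundancy; no log
  scaling or normalization is applied. Parseval's identity
  (Σ|X_k|² = W·Σx_n²) and equivalence with a direct O(N²) DFT are asserted
  in the tests.
* **WT** is a per-row 3-level multilevel DWT — four subbands
  [cA₃, cD₃, cD₂, cD₁] — with Haar (db1) and symmetric extension by
  default, both configurable. Subbands are concatenated coarse-to-fine and
  truncated (or zero-padded) to width W; for W = 60 under symmetric
  extension the concatenation is 61 wide (8+8+15+30), so exactly one
  trailing detail coefficient is dropped. Subband boundaries are kept in
  metadata. Perfect reconstruction is checked on the pre-truncation
  coefficients; exact energy conservation is checked at dyadic width with
  periodization, where the Haar transform is strictly orthogonal (with
  symmetric extension at non-dyadic widths the coefficient count differs
  from W and strict equality does not hold).

## Structuring

`duplicate_axes` maps a 3×W sensor block to the fixed 7-row pattern
x,y,z,x,y,z,x. The six adjacent row pairs cover each unordered axis pair
exactly twice; the multiplicities are x:3, y:2, z:2 — the printed row order
is implemented as-is, not an equalized duplication, because the pattern is
the method's core and is not configurable. Content conservation (no value
invented or lost, up to those multiplicities) and commutation with row-wise
transforms (duplicate∘f = f∘duplicate) are property-tested; transforms are
applied before duplication, which is equivalent for row-wise transforms.

Layouts: UNALTERED (6,W,1) with accelerometer rows 0–2; SC (14,W,1) with
the accelerometer block on top; DC (7,W,2) with channel 0 accelerometer,
channel 1 gyroscope, so early kernels never mix sensor types.

## Networks and training

The classifiers run on a small numpy engine (`harkit.nn`): stride-1
channels-last convolution, batch normalization (momentum 0.9, ε=1e-5),
ReLU, non-overlapping average pooling with trailing crop, dense, LSTM and
ConvLSTM layers, each with analytic backprop validated against central
differences. Average pooling (not max) is used throughout, matching the
smooth, non-extreme structure of motion windows.

Architectural constants: SC-CNN = conv 20@2×2 → BN → ReLU → pool 2×4 →
conv 40@3×3 → BN → ReLU → pool 1×2 → dense 512 → softmax-8; DC-CNN is the
same with 2×2×2 first kernels and dense 256; LSTM has 100 hidden units over
(60, 6) raw windows feeding the 8-class softmax; ConvLSTM applies 64
kernels of 1×3 over the window reshaped to 4 subsequences of (1, 15, 6),
returns the full hidden sequence and flattens it into a 512-wide dense
stage. Design choices made where the design was genuinely open:

* convolution padding is 'same' and pooling 'valid' (floor); printed
  parameter totals are therefore informational — the resulting counts are
  43,608 (LSTM) < 224,892 (DC-CNN) < 1,015,596 (SC-CNN) < 2,024,712
  (ConvLSTM), and only this ordering is asserted;
* the LSTM consumes the raw 6-feature timestep, not a structured layout;
* the ConvLSTM subsequence split (4×15) and its full-sequence flatten +
  dense-512 head were fixed once so the four models span the intended size
  ordering with the recurrent convolutional model largest;
* mini-batch default is 50 (60 is equally valid and available via
  `TrainingConfig`);
* softmax ties break to the lowest class index (argmax convention).

Training: Adam (β₁=0.9, β₂=0.999), learning rate
`lr(s) = 1e-4 · 0.9^(s/1000)` decayed continuously per optimizer step
(staircase available by flag), ~100 epochs by default. Weight
initialization (Glorot uniform) and shuffling derive from one seed. A
non-finite loss aborts with a diagnostic. Per-epoch validation accuracy and
loss are recorded.

## Evaluation and the real-time loop

Accuracy is trace/total of the 8×8 confusion matrix in the fixed label
encoding; per-class precision/recall are derived from columns/rows.
Evaluation is permutation-invariant.

`stream_predict` simulates the deployment regime deterministically: fill
the buffer to W samples, classify, drop `round(t_inf · rate)` subsequent
samples (the drop-while-inferring policy; 0.08 s at 50 Hz drops 4 samples
per cycle), resume. Streaming windows do not overlap — overlap is a
training-time device — and a stream whose rate differs from the model's
training rate is rejected. A wall-clock mode exists for demos, and a thin
newline-CSV loopback transport (`harkit.transport`) demos the
phone-to-computer path; it is intentionally minimal.

## Synthetic study conditions

The generator emulates labeled 6-channel 50 Hz streams, not biomechanics:
dynamic classes are sums of a class fundamental and two harmonics (relative
amplitudes 1, 0.5, 0.25) with per-channel amplitude profiles, fixed
per-channel phase offsets plus a small random phase jitter, gravity
(9.81 m/s²) on the accelerometer channels and white Gaussian noise; static
classes are gravity plus noise with orthogonal gravity axes. Presets:
walking 1.5 Hz, jogging 2.5 Hz (large amplitudes), jumping 2.0 Hz (dominant
vertical acceleration), upstairs 1.2 Hz, downstairs 1.4 Hz, cycling 1.0 Hz
(gyroscope-dominant), still/lying 0 Hz. Noise levels 0.05 (static) to 0.5
(jogging/jumping).

What passing tests on these conditions show — and do not show: the
pipeline is shape- and information-correct end to end, the networks can
fit separable periodic structure, and the streaming loop behaves as
specified. They do not show human-data performance: real IMU signals have
non-stationary cadence, inter-subject variability, orientation drift and
correlated noise that the generator deliberately omits, so accuracies on
the presets are upper bounds with no claim of transfer.

Problem sizes: the reproduction script and the end-to-end test use 2
streams × 120 s per class (199 windows per stream, 398 per class, 3,184
windows total), a stratified 75/15/10 split, and 30 training epochs — large
enough that the DC-CNN saturates on the presets while the whole run stays
in the minutes range on one CPU.

## Numerical notes and limitations

* All computation is float64; probability sums are exact to ~1e-12.
* Largest-remainder rounding makes split and class-mix counts exact;
  stratified splitting allocates per-class counts partition by partition,
  capped by availability.
* Dataset splits with fewer than 4 frames are resolved as fractions when
  the request is ambiguous between counts and fractions.
* The engine is single-threaded numpy: fine at these model sizes,
  not intended for large-scale training.
* BatchNorm running statistics start at (0, 1); very short training runs
  therefore evaluate with partially burned-in statistics.
* No resampling, no rotation/translation/noise augmentation, no zero-pad
  separators between sensors, and no >2-sensor layouts — all deliberate
  non-goals.
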