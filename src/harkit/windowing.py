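"""Sliding-window segmentation, grayscale mapping and dataset splitting.

A stream is cut into fixed-length frames of ``W = round(window_seconds *
rate)`` samples (1.2 s at 50 Hz gives the canonical 60-column training
unit), with consecutive frames advanced by a hop ``H = round(W * (1 -
overlap))``; the default 50 % overlap is the only augmentation applied.
Trailing samples that do not fill a window are dropped. Windows never span
recording boundaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np

from .labels import ActivityLabel
from .sensor_io import ActivityStream, N_CHANNELS

#: Canonical window length: 1.2 s at 50 Hz.
DEFAULT_WINDOW_SECONDS = 1.2
DEFAULT_OVERLAP = 0.5
DEFAULT_WINDOW_SAMPLES = 60


@dataclass
class WindowFrame:
    """One segmented sample: a 6×W grid of sensor values.

    Rows are ordered (ax, ay, az, gx, gy, gz); columns are time.
    ``origin`` records provenance as ``(stream id, start sample index)`` so
    every window column maps back to its source sample.
    """

    values: np.ndarray
    label: Optional[ActivityLabel] = None
    origin: Tuple[Optional[str], int] = (None, 0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != N_CHANNELS:
            raise ValueError(
                f"frame must have shape ({N_CHANNELS}, W), got {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("frame values must be finite")

    @property
    def width(self) -> int:
        return self.values.shape[1]

    def source_index(self, column: int) -> int:
        """Index of column ``column`` in the source stream."""
        if not 0 <= column < self.width:
            raise IndexError(column)
        return self.origin[1] + column


@dataclass
class GrayscaleImage:
    """An 8-bit grayscale rendering of a frame (or one image plane)."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.dtype.kind not in "iu":
            raise ValueError("pixels must be integers")
        if self.pixels.min(initial=0) < 0 or self.pixels.max(initial=0) > 255:
            raise ValueError("pixels must lie in 0..255")


def window_samples(window_seconds: float, rate: float) -> int:
    """Window length in samples: ``round(window_seconds * rate)``."""
    w = int(round(window_seconds * rate))
    if w < 1:
        raise ValueError("window shorter than one sample")
    return w


def segment_stream(
    stream: ActivityStream,
    window_seconds: float = DEFAULT_WINDOW_SECONDS,
    overlap_fraction: float = DEFAULT_OVERLAP,
) -> List[WindowFrame]:
    """Segment a stream into overlapping fixed-length frames.

    Returns ``floor((N - W) / H) + 1`` frames for a stream of N samples;
    a stream shorter than one window yields an empty list with a warning
    (short recordings are common and should not abort a batch).
    """
    if not 0 <= overlap_fraction < 1:
        raise ValueError("overlap_fraction must lie in [0, 1)")
    w = window_samples(window_seconds, stream.rate)
    hop = int(round(w * (1 - overlap_fraction)))
    hop = max(hop, 1)
    n = len(stream)
    if n < w:
        warnings.warn(
            f"stream of {n} samples is shorter than one {w}-sample window; "
            "no frames produced", stacklevel=2)
        return []
    starts = range(0, n - w + 1, hop)
    channels = stream.channels  # (6, n)
    return [
        WindowFrame(
            values=channels[:, s:s + w].copy(),
            label=stream.label,
            origin=(stream.subject_id, s),
        )
        for s in starts
    ]


def to_grayscale(values: Union[WindowFrame, np.ndarray]) -> GrayscaleImage:
    """Map values affinely to 0..255, min→0 and max→255.

    Rounding is half-up to the nearest integer pixel. A constant input has
    an undefined affine map and is rendered all-zero.
    """
    if isinstance(values, WindowFrame):
        values = values.values
    arr = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("grayscale input must be finite")
    lo, hi = arr.min(), arr.max()
    if hi == lo:
        return GrayscaleImage(np.zeros(arr.shape, dtype=np.uint8))
    scaled = 255.0 * (arr - lo) / (hi - lo)
    return GrayscaleImage(np.floor(scaled + 0.5).astype(np.uint8))  # half-up


@dataclass
class DatasetSplit:
    """Disjoint train/validation/development partitions of window frames."""

    train: List[WindowFrame]
    validation: List[WindowFrame]
    development: List[WindowFrame]
    seed: int

    def __iter__(self):
        return iter((self.train, self.validation, self.development))

    @property
    def sizes(self) -> Tuple[int, int, int]:
        return (len(self.train), len(self.validation), len(self.development))


def _resolve_counts(total: int, counts_or_fractions: Sequence[float]) -> List[int]:
    parts = list(counts_or_fractions)
    if len(parts) != 3:
        raise ValueError("expected exactly three partitions (train, val, dev)")
    if all(float(p).is_integer() for p in parts) and sum(parts) == total and total > 3:
        counts = [int(p) for p in parts]
    elif np.isclose(sum(parts), 1.0, atol=1e-9):
        raw = np.asarray(parts, dtype=float) * total
        counts = np.floor(raw).astype(int)
        rem = total - int(counts.sum())
        order = np.argsort(-(raw - counts), kind="stable")
        counts[order[:rem]] += 1
        counts = counts.tolist()
    else:
        raise ValueError(
            "counts must sum to the number of frames, or fractions must sum to 1")
    if sum(counts) != total:
        raise ValueError(f"requested counts {counts} do not sum to {total}")
    if min(counts) < 0:
        raise ValueError("negative partition size")
    return counts


def split_dataset(
    frames: Sequence[WindowFrame],
    counts_or_fractions: Sequence[float],
    seed: int,
    stratify: bool = True,
) -> DatasetSplit:
    """Randomly split frames into exact-size train/validation/development sets.

    With ``stratify=True`` (default) each partition's class composition
    follows the overall label proportions under largest-remainder rounding,
    while partition sizes still match the request exactly. Deterministic
    given ``seed``.
    """
    total = len(frames)
    counts = _resolve_counts(total, counts_or_fractions)
    rng = np.random.default_rng(seed)

    if stratify and all(f.label is not None for f in frames):
        by_label: dict = {}
        for idx, f in enumerate(frames):
            by_label.setdefault(f.label, []).append(idx)
        pools = {}
        for lab, idxs in sorted(by_label.items()):
            idxs = np.array(idxs)
            rng.shuffle(idxs)
            pools[lab] = list(idxs)
        parts: List[List[int]] = [[], [], []]
        remaining = {lab: len(p) for lab, p in pools.items()}
        left = total
        for pi, count in enumerate(counts[:2]):
            labs = sorted(remaining)
            weights = [remaining[lab] / left for lab in labs]
            raw = np.asarray(weights) * count
            take = np.floor(raw).astype(int)
            short = count - int(take.sum())
            order = np.argsort(-(raw - take), kind="stable")
            for j in order:  # largest remainders first, capped by availability
                if short == 0:
                    break
                if take[j] < remaining[labs[j]]:
                    take[j] += 1
                    short -= 1
            for lab, k in zip(labs, take):
                parts[pi].extend(pools[lab][:k])
                pools[lab] = pools[lab][k:]
                remaining[lab] -= k
            left -= count
        for lab in sorted(pools):
            parts[2].extend(pools[lab])
        for part in parts:
            rng.shuffle(part)  # type: ignore[arg-type]
    else:
        order = np.arange(total)
        rng.shuffle(order)
        parts = [
            list(order[: counts[0]]),
            list(order[counts[0]: counts[0] + counts[1]]),
            list(order[counts[0] + counts[1]:]),
        ]

    train, val, dev = ([frames[int(i)] for i in part] for part in parts)
    split = DatasetSplit(train=train, validation=val, development=dev, seed=seed)
    assert split.sizes == tuple(counts)
    return split
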