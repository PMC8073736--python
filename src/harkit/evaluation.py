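"""Accuracy / confusion-matrix evaluation and simulated real-time inference.

The confusion matrix is an 8×8 count grid in the fixed class encoding
(rows = true label, columns = predicted label); accuracy is its trace over
its total. The streaming loop emulates the on-device regime: the buffer
fills to one window, the window is classified, and samples that arrive
while the (modelled) inference runs are dropped before buffering resumes.
Inference time is an explicit parameter rather than the wall clock so runs
are deterministic; a wall-clock mode exists for demos.
"""

from __future__ import annotations

import time as _time
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np

from .labels import ActivityLabel, N_CLASSES
from .models import TrainedModel, images_to_array, predict
from .sensor_io import ActivityStream
from .structuring import VirtualImage
from .windowing import WindowFrame, window_samples


@dataclass
class ConfusionMatrix:
    """8×8 integer count grid, rows true / columns predicted."""

    counts: np.ndarray = field(
        default_factory=lambda: np.zeros((N_CLASSES, N_CLASSES), dtype=int))

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (N_CLASSES, N_CLASSES):
            raise ValueError(f"expected ({N_CLASSES}, {N_CLASSES}) counts")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @classmethod
    def from_pairs(cls, true_labels: Iterable[int],
                   predicted: Iterable[int]) -> "ConfusionMatrix":
        counts = np.zeros((N_CLASSES, N_CLASSES), dtype=int)
        for t, p in zip(true_labels, predicted, strict=True):
            counts[int(t), int(p)] += 1
        return cls(counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def accuracy(self) -> float:
        if self.total == 0:
            raise ValueError("empty confusion matrix")
        return float(np.trace(self.counts) / self.total)

    def per_class_recall(self) -> np.ndarray:
        row = self.counts.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(row > 0, np.diag(self.counts) / row, np.nan)

    def per_class_precision(self) -> np.ndarray:
        col = self.counts.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(col > 0, np.diag(self.counts) / col, np.nan)

    def to_report(self) -> dict:
        """JSON-serializable report (used by the CLI)."""
        names = [m.name.lower() for m in ActivityLabel]
        return {
            "accuracy": self.accuracy,
            "total": self.total,
            "class_order": names,
            "matrix": self.counts.tolist(),
            "per_class_recall": [
                None if np.isnan(v) else float(v) for v in self.per_class_recall()],
            "per_class_precision": [
                None if np.isnan(v) else float(v) for v in self.per_class_precision()],
        }


def evaluate(
    model: Union[TrainedModel, "object"],
    images: Union[np.ndarray, Sequence[VirtualImage], Sequence[WindowFrame]],
    true_labels: Optional[Sequence[int]] = None,
) -> Tuple[float, ConfusionMatrix]:
    """Accuracy and confusion matrix of a model on a labeled set.

    Labels may be passed explicitly or carried by the images/frames.
    """
    if len(images) == 0:
        raise ValueError("empty evaluation set")
    if true_labels is None:
        carried = [getattr(img, "label", None) for img in images]
        if any(lab is None for lab in carried):
            raise ValueError("evaluation set must be labeled")
        true_labels = [int(lab) for lab in carried]
    if len(true_labels) != len(images):
        raise ValueError("labels and images differ in length")
    _, predicted = predict(model, images)
    matrix = ConfusionMatrix.from_pairs(true_labels, [int(p) for p in predicted])
    return matrix.accuracy, matrix


@dataclass(frozen=True)
class StreamPrediction:
    """One streaming classification: when, what, how confident, at what cost."""

    end_time: float
    label: ActivityLabel
    confidence: float
    dropped_samples: int

    def __post_init__(self) -> None:
        if not 1.0 / N_CLASSES - 1e-9 <= self.confidence <= 1.0 + 1e-9:
            raise ValueError(
                f"confidence {self.confidence} outside [1/{N_CLASSES}, 1]")
        if self.dropped_samples < 0:
            raise ValueError("dropped_samples must be >= 0")


def stream_predict(
    model: TrainedModel,
    stream: ActivityStream,
    window_seconds: float = 1.2,
    inference_time: float = 0.0,
    wall_clock: bool = False,
) -> List[StreamPrediction]:
    """Run the drop-while-inferring streaming loop over a recorded stream.

    The buffer fills to ``W = round(window_seconds * rate)`` samples, the
    window is classified, and ``round(inference_time * rate)`` subsequent
    samples are discarded before buffering resumes (windows never overlap
    in the real-time loop). With ``wall_clock=True`` the measured inference
    time of each window replaces the model parameter.

    Raises if the stream's rate differs from the model's training rate.
    """
    if inference_time < 0:
        raise ValueError("inference_time must be >= 0")
    if not np.isclose(stream.rate, model.rate):
        raise ValueError(
            f"stream rate {stream.rate} Hz does not match the model's "
            f"{model.rate} Hz; streams are never resampled")
    w = window_samples(window_seconds, stream.rate)
    predictions: List[StreamPrediction] = []
    pos = 0
    n = len(stream)
    channels = stream.channels
    while pos + w <= n:
        frame = WindowFrame(channels[:, pos:pos + w].copy(),
                            origin=(stream.subject_id, pos))
        start = _time.perf_counter()
        probs = model.predict_frames([frame])[0]
        elapsed = _time.perf_counter() - start
        t_inf = elapsed if wall_clock else inference_time
        dropped = int(round(t_inf * stream.rate))
        predictions.append(StreamPrediction(
            end_time=float(stream.t[pos + w - 1]),
            label=ActivityLabel(int(probs.argmax())),
            confidence=float(probs.max()),
            dropped_samples=dropped,
        ))
        pos += w + dropped
    return predictions
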