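"""Reading, writing and validating 6-channel IMU streams.

The on-disk format is the smartphone-logger CSV dialect::

    t,ax,ay,az,gx,gy,gz[,label]

with a comma separator, ``.`` decimal point, UTF-8 encoding and six decimal
places on write. ``t`` is seconds since stream start, ``ax..az`` linear
acceleration in m/s² and ``gx..gz`` angular velocity in rad/s. One recording
holds one activity; the label may come from the optional ``label`` column
(constant over the file) or from the file name (stem starting with the
activity name, e.g. ``walking_s01.csv``).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd

from .labels import ActivityLabel

CHANNEL_NAMES = ("ax", "ay", "az", "gx", "gy", "gz")
N_CHANNELS = len(CHANNEL_NAMES)
CSV_COLUMNS = ("t",) + CHANNEL_NAMES
CSV_DECIMALS = 6

#: Default sampling rate of the recording app, Hz.
DEFAULT_RATE = 50.0

#: Default timestamp jitter tolerance, as a fraction of the sample period.
DEFAULT_JITTER_TOL = 0.2


class StreamFormatError(ValueError):
    """The file does not match the declared CSV dialect."""


class StreamValidationError(ValueError):
    """The stream content violates an invariant (timing, finiteness...)."""


class EmptyStreamError(StreamFormatError):
    """The file contains a header but no samples."""


class SensorReading(NamedTuple):
    """A single timestamped 6-channel sample."""

    t: float
    ax: float
    ay: float
    az: float
    gx: float
    gy: float
    gz: float


@dataclass
class ActivityStream:
    """An ordered 6-channel sensor sequence sampled at a nominal rate.

    Parameters
    ----------
    data
        Array of shape ``(n, 6)`` in channel order ``ax, ay, az, gx, gy, gz``.
    t
        Timestamps in seconds, shape ``(n,)``, strictly increasing.
    rate
        Nominal sampling rate in Hz.
    label
        Optional activity label for the whole recording.
    subject_id
        Optional recording/subject identifier (used as the stream id in
        window provenance).
    """

    data: np.ndarray
    t: np.ndarray
    rate: float = DEFAULT_RATE
    label: Optional[ActivityLabel] = None
    subject_id: Optional[str] = None
    jitter_tol: float = field(default=DEFAULT_JITTER_TOL, repr=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.t = np.asarray(self.t, dtype=float)
        self.validate()

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        if self.rate <= 0:
            raise StreamValidationError(f"rate must be positive, got {self.rate}")
        if self.data.ndim != 2 or self.data.shape[1] != N_CHANNELS:
            raise StreamValidationError(
                f"data must have shape (n, {N_CHANNELS}), got {self.data.shape}"
            )
        if self.t.shape != (len(self.data),):
            raise StreamValidationError("t and data lengths differ")
        if not np.all(np.isfinite(self.data)):
            raise StreamValidationError("non-finite channel values")
        if len(self.t):
            if not np.all(np.isfinite(self.t)) or self.t[0] < 0:
                raise StreamValidationError("timestamps must be finite and non-negative")
            dt = np.diff(self.t)
            if np.any(dt <= 0):
                raise StreamValidationError("timestamps must be strictly increasing")
            period = 1.0 / self.rate
            if np.any(np.abs(dt - period) > self.jitter_tol * period):
                worst = float(np.max(np.abs(dt - period)))
                raise StreamValidationError(
                    f"inter-sample spacing deviates from 1/rate by up to {worst:.6g} s, "
                    f"beyond the ±{self.jitter_tol:.0%} jitter tolerance; "
                    "streams are rejected rather than resampled"
                )

    # -- sequence protocol ----------------------------------------------
    def __len__(self) -> int:
        return len(self.data)

    def __getitem__(self, i: int) -> SensorReading:
        return SensorReading(float(self.t[i]), *map(float, self.data[i]))

    def __iter__(self) -> Iterator[SensorReading]:
        for i in range(len(self)):
            yield self[i]

    @property
    def duration(self) -> float:
        """Recording length in seconds (0 for an empty stream)."""
        return float(self.t[-1] - self.t[0]) if len(self) else 0.0

    @property
    def channels(self) -> np.ndarray:
        """Channel-major view of the data, shape ``(6, n)``."""
        return self.data.T

    @classmethod
    def from_readings(
        cls,
        readings: Sequence[SensorReading],
        rate: float = DEFAULT_RATE,
        label: Optional[ActivityLabel] = None,
        subject_id: Optional[str] = None,
        jitter_tol: float = DEFAULT_JITTER_TOL,
    ) -> "ActivityStream":
        arr = np.array([tuple(r) for r in readings], dtype=float).reshape(-1, 7)
        return cls(
            data=arr[:, 1:], t=arr[:, 0], rate=rate, label=label,
            subject_id=subject_id, jitter_tol=jitter_tol,
        )


def _label_from_filename(path: Path) -> Optional[ActivityLabel]:
    stem = path.stem.lower()
    for member in ActivityLabel:
        name = member.name.lower()
        if stem == name or stem.startswith(name + "_") or stem.startswith(name + "-"):
            return member
    return None


def read_stream_csv(
    path: os.PathLike | str,
    expected_rate: float = DEFAULT_RATE,
    jitter_tol: float = DEFAULT_JITTER_TOL,
) -> ActivityStream:
    """Read and validate one recording in the smartphone CSV dialect.

    The label is taken from the ``label`` column if present (it must be
    constant over the file), else from the file-name convention, else left
    unset.

    Raises
    ------
    StreamFormatError
        Missing/extra columns, or an unreadable body.
    EmptyStreamError
        Header-only file.
    StreamValidationError
        Non-monotonic timestamps or spacing outside the jitter tolerance.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, encoding="utf-8")
    except pd.errors.EmptyDataError:
        raise StreamFormatError(f"{path}: no header found") from None

    cols = tuple(df.columns)
    if cols not in (CSV_COLUMNS, CSV_COLUMNS + ("label",)):
        raise StreamFormatError(
            f"{path}: header {list(cols)} does not match the dialect "
            f"{list(CSV_COLUMNS)} with optional trailing 'label'"
        )
    if len(df) == 0:
        raise EmptyStreamError(f"{path}: header-only file, no samples")

    label: Optional[ActivityLabel] = None
    if "label" in df.columns:
        uniq = df["label"].astype(str).str.strip().str.lower().unique()
        if len(uniq) != 1:
            raise StreamFormatError(
                f"{path}: label column is not constant ({sorted(uniq)}); "
                "one recording holds one activity"
            )
        label = ActivityLabel.from_name(uniq[0])
    else:
        label = _label_from_filename(path)

    values = df[list(CSV_COLUMNS)].to_numpy(dtype=float)
    return ActivityStream(
        data=values[:, 1:],
        t=values[:, 0],
        rate=expected_rate,
        label=label,
        subject_id=path.stem,
        jitter_tol=jitter_tol,
    )


def write_stream_csv(stream: ActivityStream, path: os.PathLike | str) -> None:
    """Write a stream in the dialect, lossless to 6 decimal places.

    An empty stream yields a header-only file. The label, if set, is written
    as a constant trailing column.
    """
    path = Path(path)
    df = pd.DataFrame(
        np.column_stack([stream.t, stream.data]) if len(stream) else
        np.empty((0, 7)),
        columns=list(CSV_COLUMNS),
    )
    if stream.label is not None:
        df["label"] = stream.label.name.lower()
    df.to_csv(path, index=False, float_format=f"%.{CSV_DECIMALS}f", encoding="utf-8")


def stream_info(stream: ActivityStream) -> dict:
    """Summary dict used by the CLI ``har io info`` verb."""
    return {
        "samples": len(stream),
        "rate_hz": stream.rate,
        "duration_s": round(stream.duration, 6),
        "label": stream.label.name.lower() if stream.label is not None else None,
        "subject_id": stream.subject_id,
        "channel_means": {
            name: round(float(m), 6)
            for name, m in zip(CHANNEL_NAMES, stream.data.mean(axis=0))
        } if len(stream) else {},
    }
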