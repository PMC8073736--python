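"""Virtual-image layouts: unaltered, single-channel and double-channel.

The core restructuring duplicates a sensor's three axis rows into the
seven-row pattern ``x, y, z, x, y, z, x``, so that every unordered axis
pair (xy, yz, zx) appears in adjacent rows — twice each across the six
adjacent pairs — and a small 2×2 convolution kernel sees every pairwise
correlation before pooling shrinks the grid.

Three layouts are built from a (possibly transformed) 6×W window:

* ``UNALTERED`` — the raw 6×W grid as one image plane, accelerometer rows
  0–2 on top of gyroscope rows 3–5;
* ``SC`` (single-channel) — both sensors' 7-row duplicated blocks stacked
  vertically into a 14×W plane, accelerometer block on top;
* ``DC`` (double-channel) — the two 7-row blocks side by side as the two
  channels of a 7×W image (channel 0 accelerometer, channel 1 gyroscope),
  so early kernels never mix sensor types.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional, Tuple, Union

import numpy as np

from .labels import ActivityLabel
from .representations import (
    ReprRows,
    RepresentationTag,
    apply_representation,
)
from .windowing import WindowFrame

#: The axis-duplication row pattern.
AXIS_PATTERN = (0, 1, 2, 0, 1, 2, 0)


class Layout(Enum):
    """Virtual-image structuring, with (rows, channels) per layout."""

    UNALTERED = "unaltered"
    SC = "sc"
    DC = "dc"


_LAYOUT_GEOMETRY = {
    Layout.UNALTERED: (6, 1),
    Layout.SC: (14, 1),
    Layout.DC: (7, 2),
}


def layout_shape(layout: Layout, width: int) -> Tuple[int, int, int]:
    """Declared (H, W, C) for a layout at a given window width."""
    h, c = _LAYOUT_GEOMETRY[layout]
    return (h, width, c)


@dataclass
class VirtualImage:
    """A structured 2-D(+channel) grid ready for network input.

    ``values`` has shape (H, W, C) matching the layout exactly.
    """

    values: np.ndarray
    layout: Layout
    representation: RepresentationTag
    label: Optional[ActivityLabel] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError(f"expected (H, W, C), got shape {self.values.shape}")
        expected = layout_shape(self.layout, self.values.shape[1])
        if self.values.shape != expected:
            raise ValueError(
                f"{self.layout.name} image must have shape {expected}, "
                f"got {self.values.shape}")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.values.shape


def duplicate_axes(sensor_rows: np.ndarray) -> np.ndarray:
    """Restructure a sensor's 3×W axis rows into the 7×W duplicated grid.

    Output row order is ``x, y, z, x, y, z, x``: rows 0, 3, 6 are copies of
    input row 0; rows 1, 4 of row 1; rows 2, 5 of row 2.
    """
    rows = np.asarray(sensor_rows, dtype=float)
    if rows.ndim != 2 or rows.shape[0] != 3:
        raise ValueError(f"expected a 3×W grid, got shape {rows.shape}")
    return rows[list(AXIS_PATTERN)].copy()


def _check_7xw(name: str, rows: np.ndarray) -> np.ndarray:
    rows = np.asarray(rows, dtype=float)
    if rows.ndim != 2 or rows.shape[0] != 7:
        raise ValueError(f"{name} must be a 7×W grid, got shape {rows.shape}")
    return rows


def build_unaltered(
    rows6: np.ndarray,
    tag: RepresentationTag = RepresentationTag.TD,
    label: Optional[ActivityLabel] = None,
) -> VirtualImage:
    """The plain 6×W single-plane image; row order preserved."""
    rows = np.asarray(rows6, dtype=float)
    if rows.ndim != 2 or rows.shape[0] != 6:
        raise ValueError(f"expected a 6×W grid, got shape {rows.shape}")
    return VirtualImage(rows[..., np.newaxis].copy(), Layout.UNALTERED, tag, label)


def build_single_channel(
    acc7: np.ndarray,
    gyr7: np.ndarray,
    tag: RepresentationTag = RepresentationTag.TD,
    label: Optional[ActivityLabel] = None,
) -> VirtualImage:
    """Stack the two duplicated blocks vertically into a 14×W plane."""
    acc7, gyr7 = _check_7xw("acc7", acc7), _check_7xw("gyr7", gyr7)
    if acc7.shape != gyr7.shape:
        raise ValueError(f"shape mismatch: {acc7.shape} vs {gyr7.shape}")
    return VirtualImage(
        np.vstack([acc7, gyr7])[..., np.newaxis], Layout.SC, tag, label)


def build_double_channel(
    acc7: np.ndarray,
    gyr7: np.ndarray,
    tag: RepresentationTag = RepresentationTag.TD,
    label: Optional[ActivityLabel] = None,
) -> VirtualImage:
    """Stack the two duplicated blocks as the channels of a 7×W image."""
    acc7, gyr7 = _check_7xw("acc7", acc7), _check_7xw("gyr7", gyr7)
    if acc7.shape != gyr7.shape:
        raise ValueError(f"shape mismatch: {acc7.shape} vs {gyr7.shape}")
    return VirtualImage(np.stack([acc7, gyr7], axis=-1), Layout.DC, tag, label)


def frame_to_image(
    frame: Union[WindowFrame, ReprRows],
    representation: RepresentationTag = RepresentationTag.TD,
    layout: Layout = Layout.DC,
    **repr_kwargs,
) -> VirtualImage:
    """Compose representation and structuring into one virtual image.

    The row-wise transform is applied to the raw 6×W frame first and the
    3×W sensor blocks (accelerometer rows 0–2, gyroscope rows 3–5) are then
    duplicated and arranged; for row-wise transforms the two orders are
    equivalent.
    """
    label = frame.label if isinstance(frame, WindowFrame) else None
    if isinstance(frame, ReprRows):
        if frame.tag is not representation:
            raise ValueError(
                f"rows already carry tag {frame.tag}, asked for {representation}")
        rows = frame.values
    else:
        rows = apply_representation(frame, representation, **repr_kwargs).values
    if rows.shape[0] != 6:
        raise ValueError(f"expected 6 rows, got {rows.shape[0]}")

    if layout is Layout.UNALTERED:
        return build_unaltered(rows, representation, label)
    acc7 = duplicate_axes(rows[0:3])
    gyr7 = duplicate_axes(rows[3:6])
    if layout is Layout.SC:
        return build_single_channel(acc7, gyr7, representation, label)
    if layout is Layout.DC:
        return build_double_channel(acc7, gyr7, representation, label)
    raise ValueError(f"unknown layout {layout!r}")
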