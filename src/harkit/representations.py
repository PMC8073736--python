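"""Window representations: time domain, Fourier magnitude, wavelet coefficients.

Each transform maps a 6×W window row-wise to another 6×W grid so that the
virtual-image geometry is independent of the representation chosen:

* **TD** — the raw time series, unchanged.
* **FD** — per-row magnitude of the full unnormalized length-W DFT
  (two-sided spectrum, so the image keeps its width; for real input the
  row is symmetric about W/2).
* **WT** — per-row multilevel discrete wavelet decomposition (default:
  3-level Haar, symmetric extension), subbands concatenated as
  ``[approx_L, detail_L, ..., detail_1]`` and truncated / zero-padded to
  width W. Subband boundaries are reported so nothing is silently
  conflated.

No log-scaling or normalization is applied to FD magnitudes; the networks'
batch normalization handles scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import List, Optional, Tuple, Union

import numpy as np
import pywt

from .windowing import WindowFrame

DEFAULT_WAVELET = "haar"
DEFAULT_WAVELET_MODE = "symmetric"
DEFAULT_WAVELET_LEVELS = 3


class RepresentationTag(Enum):
    """Which transform produced a grid of rows."""

    TD = "td"
    FD = "fd"
    WT = "wt"


@dataclass
class ReprRows:
    """A 6×W grid of transformed rows plus its representation tag.

    For WT, ``subband_slices`` gives the column span of each subband in the
    pre-truncation concatenation order ``[approx_L, detail_L, ..., detail_1]``
    (spans past W were truncated away).
    """

    values: np.ndarray
    tag: RepresentationTag
    subband_slices: Optional[List[Tuple[int, int]]] = field(default=None)


def _rows_of(frame: Union[WindowFrame, np.ndarray]) -> np.ndarray:
    rows = frame.values if isinstance(frame, WindowFrame) else np.asarray(frame, float)
    if rows.ndim != 2:
        raise ValueError(f"expected a 2-D row grid, got shape {rows.shape}")
    return rows


def td_rows(frame: Union[WindowFrame, np.ndarray]) -> ReprRows:
    """Identity representation: the raw time-series rows."""
    return ReprRows(values=_rows_of(frame).copy(), tag=RepresentationTag.TD)


def fd_rows(frame: Union[WindowFrame, np.ndarray]) -> ReprRows:
    """Row-wise two-sided DFT magnitude, unnormalized, width-preserving."""
    rows = _rows_of(frame)
    if rows.shape[1] < 2:
        raise ValueError("FD representation needs at least 2 columns")
    return ReprRows(values=np.abs(np.fft.fft(rows, axis=1)), tag=RepresentationTag.FD)


def wt_decompose(
    rows: np.ndarray,
    wavelet: str = DEFAULT_WAVELET,
    mode: str = DEFAULT_WAVELET_MODE,
    levels: int = DEFAULT_WAVELET_LEVELS,
) -> List[List[np.ndarray]]:
    """Per-row multilevel DWT, returned as pywt coefficient lists.

    Each inner list is ``[cA_L, cD_L, ..., cD_1]`` and reconstructs the row
    exactly through ``pywt.waverec``.
    """
    rows = np.asarray(rows, dtype=float)
    if rows.shape[1] < 2 ** levels:
        raise ValueError(
            f"{levels}-level decomposition needs at least {2 ** levels} columns, "
            f"got {rows.shape[1]}")
    return [pywt.wavedec(row, wavelet, mode=mode, level=levels) for row in rows]


def wt_rows(
    frame: Union[WindowFrame, np.ndarray],
    levels: int = DEFAULT_WAVELET_LEVELS,
    wavelet: str = DEFAULT_WAVELET,
    mode: str = DEFAULT_WAVELET_MODE,
) -> ReprRows:
    """Row-wise multilevel wavelet decomposition, shaped back to 6×W.

    A 3-level decomposition yields 4 subbands per row. Their concatenation
    (width 61 for W=60 under symmetric extension) is truncated — or
    zero-padded, for short concatenations — to width W; the original
    subband spans are kept in ``subband_slices``.
    """
    rows = _rows_of(frame)
    w = rows.shape[1]
    coeff_rows = wt_decompose(rows, wavelet=wavelet, mode=mode, levels=levels)

    lengths = [len(c) for c in coeff_rows[0]]
    bounds, start = [], 0
    for ln in lengths:
        bounds.append((start, start + ln))
        start += ln

    out = np.zeros((rows.shape[0], w))
    for i, coeffs in enumerate(coeff_rows):
        concat = np.concatenate(coeffs)
        out[i, : min(w, len(concat))] = concat[:w]
    return ReprRows(values=out, tag=RepresentationTag.WT, subband_slices=bounds)


def apply_representation(
    frame: Union[WindowFrame, np.ndarray],
    tag: RepresentationTag,
    **kwargs,
) -> ReprRows:
    """Dispatch on a representation tag."""
    if tag is RepresentationTag.TD:
        return td_rows(frame)
    if tag is RepresentationTag.FD:
        return fd_rows(frame)
    if tag is RepresentationTag.WT:
        return wt_rows(frame, **kwargs)
    raise ValueError(f"unknown representation {tag!r}")
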