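"""Versioned on-disk containers for window frames and virtual images.

Both containers are numpy ``.npz`` archives with a format-version field:

* frame archive (v1): ``values`` (N, 6, W), ``labels`` (N,) int8 with -1
  for unlabeled, ``stream_ids`` (N,) str, ``starts`` (N,) int,
  ``representation`` (str tag of the rows: ``td``/``fd``/``wt``).
* image archive (v1): ``values`` (N, H, W, C), ``labels`` (N,) int8,
  ``layout`` and ``representation`` string tags.
"""

from __future__ import annotations

from pathlib import Path
from typing import List, Sequence, Tuple

import numpy as np

from .labels import ActivityLabel
from .representations import RepresentationTag
from .structuring import Layout, VirtualImage
from .windowing import WindowFrame

FORMAT_VERSION = 1


def _labels_array(items) -> np.ndarray:
    return np.array(
        [-1 if item.label is None else int(item.label) for item in items],
        dtype=np.int8)


def save_frames(path, frames: Sequence[WindowFrame],
                representation: RepresentationTag = RepresentationTag.TD) -> None:
    if not frames:
        raise ValueError("nothing to save: no frames")
    widths = {f.width for f in frames}
    if len(widths) != 1:
        raise ValueError(f"frames have mixed widths {sorted(widths)}")
    np.savez(
        Path(path),
        version=FORMAT_VERSION,
        kind="frames",
        representation=representation.value,
        values=np.stack([f.values for f in frames]),
        labels=_labels_array(frames),
        stream_ids=np.array([f.origin[0] or "" for f in frames]),
        starts=np.array([f.origin[1] for f in frames], dtype=np.int64),
    )


def load_frames(path) -> Tuple[List[WindowFrame], RepresentationTag]:
    with np.load(Path(path), allow_pickle=False) as data:
        _check(data, "frames")
        tag = RepresentationTag(str(data["representation"]))
        frames = [
            WindowFrame(
                values=data["values"][i],
                label=None if data["labels"][i] < 0
                else ActivityLabel(int(data["labels"][i])),
                origin=(str(data["stream_ids"][i]) or None,
                        int(data["starts"][i])),
            )
            for i in range(len(data["values"]))
        ]
    return frames, tag


def save_images(path, images: Sequence[VirtualImage]) -> None:
    if not images:
        raise ValueError("nothing to save: no images")
    layouts = {img.layout for img in images}
    tags = {img.representation for img in images}
    if len(layouts) != 1 or len(tags) != 1:
        raise ValueError("an image archive holds one layout and one representation")
    np.savez(
        Path(path),
        version=FORMAT_VERSION,
        kind="images",
        layout=next(iter(layouts)).value,
        representation=next(iter(tags)).value,
        values=np.stack([img.values for img in images]),
        labels=_labels_array(images),
    )


def load_images(path) -> List[VirtualImage]:
    with np.load(Path(path), allow_pickle=False) as data:
        _check(data, "images")
        layout = Layout(str(data["layout"]))
        tag = RepresentationTag(str(data["representation"]))
        return [
            VirtualImage(
                values=data["values"][i],
                layout=layout,
                representation=tag,
                label=None if data["labels"][i] < 0
                else ActivityLabel(int(data["labels"][i])),
            )
            for i in range(len(data["values"]))
        ]


def _check(data, expected_kind: str) -> None:
    if int(data["version"]) != FORMAT_VERSION:
        raise ValueError(f"unsupported archive version {data['version']}")
    if str(data["kind"]) != expected_kind:
        raise ValueError(f"expected a {expected_kind} archive, got {data['kind']}")
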