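"""Frame and stack I/O: 16-bit TIFF images with JSON metadata sidecars.

A frame written as ``foo.tif`` gets its metadata in ``foo.json``; a stack is
a multi-page TIFF whose sidecar holds the per-page metadata list in page
order.  Round trips are lossless (bit-exact pixels, identical metadata).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import List, Sequence, Union

import numpy as np
import tifffile

from .microscope import Frame

__all__ = [
    "sidecar_path",
    "write_frame",
    "read_frame",
    "write_stack",
    "read_stack",
    "write_png_preview",
]


def sidecar_path(path: Union[str, Path]) -> Path:
    return Path(path).with_suffix(".json")


def write_frame(path: Union[str, Path], frame: Frame) -> Path:
    """Write one frame as 16-bit TIFF plus JSON sidecar; returns the TIFF path."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, frame.pixels)
    with open(sidecar_path(path), "w") as fh:
        json.dump(frame.metadata, fh, indent=2, sort_keys=True)
    return path


def read_frame(path: Union[str, Path]) -> Frame:
    pixels = tifffile.imread(path)
    side = sidecar_path(path)
    metadata = {}
    if side.exists():
        with open(side) as fh:
            metadata = json.load(fh)
    return Frame(pixels=np.asarray(pixels, dtype=np.uint16), metadata=metadata)


def write_stack(path: Union[str, Path], frames: Sequence[Frame]) -> Path:
    """Write frames as a multi-page TIFF (page order preserved) + sidecar."""
    if not frames:
        raise ValueError("empty stack")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.stack([f.pixels for f in frames]))
    with open(sidecar_path(path), "w") as fh:
        json.dump([f.metadata for f in frames], fh, indent=2, sort_keys=True)
    return path


def read_stack(path: Union[str, Path]) -> List[Frame]:
    pages = tifffile.imread(path)
    side = sidecar_path(path)
    metas = [{} for _ in range(pages.shape[0])]
    if side.exists():
        with open(side) as fh:
            metas = json.load(fh)
    return [
        Frame(pixels=np.asarray(p, dtype=np.uint16), metadata=m)
        for p, m in zip(pages, metas)
    ]


def write_png_preview(path: Union[str, Path], image: np.ndarray) -> Path:
    """Write an 8-bit display-normalised PNG preview."""
    import imageio.v3 as iio

    from .contrast import normalize_for_display

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(path, normalize_for_display(image))
    return path
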