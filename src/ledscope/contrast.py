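"""Post-acquisition contrast processing.

Pseudo-phase contrast is the normalised difference of two images taken under
opposite-side oblique illumination: per pixel ``(a - b) / (a + b + eps)``.
It is antisymmetric in the operand order, bounded in [-1, 1] for
non-negative inputs, and its sign tracks the sign of the phase gradient
along the illumination axis.  Flat-field correction and display
normalisation are generic utilities for the same pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Union

import numpy as np

from .microscope import Frame

__all__ = [
    "ContrastImage",
    "pseudo_phase",
    "flat_field_correct",
    "normalize_for_display",
]

ImageLike = Union[Frame, np.ndarray]


@dataclass
class ContrastImage:
    """A derived contrast map plus the identifiers of its source frames."""

    values: np.ndarray
    provenance: List[str] = field(default_factory=list)
    kind: str = "contrast"


def _as_luminance(img: ImageLike) -> np.ndarray:
    if isinstance(img, Frame):
        return img.luminance
    a = np.asarray(img, dtype=float)
    return a if a.ndim == 2 else a.mean(axis=2)


def _provenance(img: ImageLike, fallback: str) -> str:
    if isinstance(img, Frame):
        return f"frame_{img.metadata.get('frame_index', '?')}"
    return fallback


def pseudo_phase(
    frame_a: ImageLike, frame_b: ImageLike, epsilon: float = 1.0
) -> ContrastImage:
    """Normalised difference (a - b)/(a + b + epsilon) of an oblique pair.

    Colour inputs are converted to luminance first.  Pixels where both
    images are zero are defined as 0.  ``epsilon`` (default 1 count) guards
    the division; with ``epsilon=0`` the 0/0 case is still mapped to 0.
    """
    a = _as_luminance(frame_a)
    b = _as_luminance(frame_b)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if a.min() < 0 or b.min() < 0:
        raise ValueError("pseudo_phase expects non-negative images")
    denom = a + b + epsilon
    values = np.divide(a - b, denom, out=np.zeros_like(a), where=denom > 0)
    return ContrastImage(
        values=values,
        provenance=[_provenance(frame_a, "a"), _provenance(frame_b, "b")],
        kind="pseudo_phase",
    )


def flat_field_correct(
    image: ImageLike, reference: ImageLike, epsilon: float = 1.0
) -> ContrastImage:
    """Divide an image by an empty-field reference and rescale to unit mean.

    Removes static shading (vignetting, uneven illumination).  Works per
    channel for colour inputs.  Invariant, up to the rescale, to any global
    gain applied to the image.
    """
    img = (image.pixels if isinstance(image, Frame) else np.asarray(image)).astype(float)
    ref = (reference.pixels if isinstance(reference, Frame) else np.asarray(reference)).astype(float)
    if img.shape != ref.shape:
        raise ValueError(f"shape mismatch: {img.shape} vs {ref.shape}")
    ratio = img / (ref + epsilon)
    mean = ratio.mean()
    if mean > 0:
        ratio = ratio / mean
    return ContrastImage(
        values=ratio,
        provenance=[_provenance(image, "image"), _provenance(reference, "reference")],
        kind="flat_field",
    )


def normalize_for_display(image: Union[ImageLike, ContrastImage]) -> np.ndarray:
    """Min-max stretch to uint8 for previews.

    Constant images map to mid-gray (128); otherwise the minimum maps to 0
    and the maximum to 255, preserving rank order.
    """
    if isinstance(image, ContrastImage):
        a = np.asarray(image.values, dtype=float)
    elif isinstance(image, Frame):
        a = image.pixels.astype(float)
    else:
        a = np.asarray(image, dtype=float)
    lo, hi = float(a.min()), float(a.max())
    if hi == lo:
        return np.full(a.shape, 128, dtype=np.uint8)
    return np.clip(np.round((a - lo) / (hi - lo) * 255), 0, 255).astype(np.uint8)
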