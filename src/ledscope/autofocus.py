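"""Coarse and fine autofocus.

Coarse focus homes the Z drive against its microswitch and applies the fixed
per-lens offset from the lens table.  Fine focus scans a symmetric grid of Z
positions, scores each image with a sharpness metric, and moves to the
position with the highest score.

The default metric is the normalised variance, var(I)/mean(I)^2 of the
luminance: zero for a constant image, invariant under global intensity
scaling (so a focus ramp in illumination brightness does not masquerade as a
focus peak), and monotonically degraded by blur.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, List, Sequence, Union

import numpy as np

from .geometry import LensSpec
from .microscope import Frame, Microscope

__all__ = [
    "FlatSceneError",
    "FocusScanResult",
    "focus_metric",
    "coarse_focus",
    "fine_autofocus",
    "scan_focus",
]


class FlatSceneError(RuntimeError):
    """Every scan position scored identically: no focus found."""


@dataclass
class FocusScanResult:
    """Outcome of a metric scan: the positions, their scores, the winner."""

    z_positions: List[int]
    scores: List[float]
    best_z: int
    unimodal: bool

    def __post_init__(self) -> None:
        if len(self.z_positions) != len(self.scores):
            raise ValueError("positions and scores must have equal length")
        if self.best_z not in self.z_positions:
            raise ValueError("best_z must be one of the scanned positions")


def focus_metric(image: Union[Frame, np.ndarray], kind: str = "normalized_variance") -> float:
    """Sharpness score >= 0 of an image (luminance of colour inputs).

    ``normalized_variance`` (default): var/mean^2, scale-invariant.
    ``variance``: plain variance.  ``tenengrad``: mean squared Sobel
    gradient magnitude.
    """
    a = image.luminance if isinstance(image, Frame) else np.asarray(image, dtype=float)
    if a.ndim == 3:
        a = a.mean(axis=2)
    if a.size == 0:
        raise ValueError("empty image")
    if kind == "normalized_variance":
        mu = a.mean()
        return float(a.var() / (mu * mu)) if mu > 0 else 0.0
    if kind == "variance":
        return float(a.var())
    if kind == "tenengrad":
        from scipy.ndimage import sobel

        gx, gy = sobel(a, axis=1), sobel(a, axis=0)
        return float(np.mean(gx * gx + gy * gy))
    raise ValueError(f"unknown focus metric {kind!r}")


def coarse_focus(microscope: Microscope, lens: LensSpec) -> int:
    """Move to the lens's expected focus: the fixed offset from home.

    Requires a homed focus drive; returns the commanded Z in motor units.
    """
    microscope.set_lens(lens)
    microscope.move_focus(lens.coarse_offset_units)
    return lens.coarse_offset_units


def _is_unimodal(scores: Sequence[float]) -> bool:
    s = np.asarray(scores, dtype=float)
    k = int(np.argmax(s))
    return bool(np.all(np.diff(s[: k + 1]) >= 0) and np.all(np.diff(s[k:]) <= 0))


def fine_autofocus(
    acquire: Callable[[int], Union[Frame, np.ndarray]],
    z_center: int,
    half_range: int,
    step: int,
    metric: str = "normalized_variance",
    parabolic_refine: bool = False,
) -> FocusScanResult:
    """Metric-scan autofocus over an inclusive arithmetic Z grid.

    ``acquire(z)`` must move the instrument to ``z`` (motor units) and return
    the image seen there.  The grid is z_center - half_range .. z_center +
    half_range in steps of ``step``; the scan returns the position with the
    highest score (ties broken toward lower z) and leaves the instrument
    there by a final ``acquire(best_z)`` call.

    With ``parabolic_refine`` the returned ``best_z`` is the vertex of a
    parabola through the top score and its neighbours, rounded to an integer
    unit (off by default: the plain argmax is the documented behaviour).
    """
    if step <= 0:
        raise ValueError("step must be positive")
    if half_range < 0:
        raise ValueError("half_range must be >= 0")
    z_positions = list(range(z_center - half_range, z_center + half_range + 1, step))
    scores = [focus_metric(acquire(z), kind=metric) for z in z_positions]
    if len(scores) > 1 and len(set(scores)) == 1:
        raise FlatSceneError("no focus found: flat response over the scan range")
    k = int(np.argmax(scores))  # first maximum -> lowest z on ties
    best_z = z_positions[k]
    if parabolic_refine and 0 < k < len(scores) - 1:
        y0, y1, y2 = scores[k - 1], scores[k], scores[k + 1]
        denom = y0 - 2 * y1 + y2
        if denom < 0:
            best_z = round(z_positions[k] + 0.5 * step * (y0 - y2) / denom)
    acquire(best_z)
    return FocusScanResult(
        z_positions=z_positions,
        scores=scores,
        best_z=int(best_z),
        unimodal=_is_unimodal(scores),
    )


def scan_focus(
    microscope: Microscope,
    z_center: int,
    half_range: int,
    step: int,
    exposure_ms: float = 10.0,
    metric: str = "normalized_variance",
) -> FocusScanResult:
    """Convenience wrapper binding :func:`fine_autofocus` to a microscope."""

    def acquire(z: int) -> Frame:
        microscope.move_focus(z)
        return microscope.capture(exposure_ms)

    return fine_autofocus(acquire, z_center, half_range, step, metric=metric)
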