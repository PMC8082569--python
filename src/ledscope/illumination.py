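"""Illumination pattern generators for the LED array and the LED ring.

An :class:`IlluminationPattern` is an ``(n_rows, n_cols, 3)`` array of RGB
intensities in [0, 1] — the common currency of all transmitted-light contrast
modes: brightfield (all LEDs), oblique (one-sided strips), darkfield (only
LEDs outside the objective's NA cone) and the oblique pairs used for
pseudo-phase contrast.  A :class:`RingPattern` holds per-LED colours for the
RGB ring together with its angular sector annotation (Rheinberg and
reflected-light modes).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Literal, Sequence, Tuple

import numpy as np

from .geometry import LedArraySpec, LedRingSpec, LensSpec, led_sine

__all__ = [
    "IlluminationPattern",
    "RingPattern",
    "DarkfieldImpossibleError",
    "SectorError",
    "brightfield_pattern",
    "oblique_pattern",
    "darkfield_pattern",
    "pseudo_phase_pair",
    "rheinberg_pattern",
    "reflected_pattern",
]

Side = Literal["left", "right", "top", "bottom"]
RGB = Tuple[float, float, float]

WHITE: RGB = (1.0, 1.0, 1.0)


class DarkfieldImpossibleError(ValueError):
    """No LED lies outside the lens NA cone with this geometry."""


class SectorError(ValueError):
    """Ring sectors do not partition the circle."""


@dataclass(frozen=True)
class IlluminationPattern:
    """Per-LED RGB intensity grid for the planar array."""

    grid: np.ndarray  # (n_rows, n_cols, 3) in [0, 1]
    label: str

    def __post_init__(self) -> None:
        g = np.asarray(self.grid, dtype=float)
        if g.ndim != 3 or g.shape[2] != 3:
            raise ValueError(f"pattern grid must be (rows, cols, 3), got {g.shape}")
        if not np.isfinite(g).all() or g.min() < 0 or g.max() > 1:
            raise ValueError("pattern intensities must be finite and in [0, 1]")
        object.__setattr__(self, "grid", g)

    @property
    def lit_mask(self) -> np.ndarray:
        """Boolean (rows, cols) mask of LEDs with any nonzero channel."""
        return self.grid.max(axis=2) > 0

    @property
    def n_lit(self) -> int:
        return int(self.lit_mask.sum())

    def to_jsonable(self) -> dict:
        return {"label": self.label, "grid": self.grid.tolist()}

    @classmethod
    def from_jsonable(cls, d: dict) -> "IlluminationPattern":
        return cls(grid=np.asarray(d["grid"], dtype=float), label=d["label"])


@dataclass(frozen=True)
class RingPattern:
    """Per-LED RGB intensities for the LED ring, plus sector annotation.

    LED k sits at angle 360*k/n degrees, measured counter-clockwise from the
    +x axis.  Sectors are half-open [start, end) and partition [0, 360).
    """

    colors: np.ndarray  # (n_leds, 3) in [0, 1]
    sectors: List[Tuple[float, float, RGB]]
    label: str
    position: str = "sample_side"

    def __post_init__(self) -> None:
        c = np.asarray(self.colors, dtype=float)
        if c.ndim != 2 or c.shape[1] != 3:
            raise ValueError("ring colors must be (n_leds, 3)")
        if not np.isfinite(c).all() or c.min() < 0 or c.max() > 1:
            raise ValueError("ring intensities must be finite and in [0, 1]")
        object.__setattr__(self, "colors", c)

    @property
    def n_leds(self) -> int:
        return self.colors.shape[0]

    def to_jsonable(self) -> dict:
        return {
            "label": self.label,
            "position": self.position,
            "colors": self.colors.tolist(),
            "sectors": [[s, e, list(rgb)] for s, e, rgb in self.sectors],
        }


def brightfield_pattern(array: LedArraySpec) -> IlluminationPattern:
    """Every LED white at full intensity: basic brightfield illumination."""
    grid = np.ones((array.n_rows, array.n_cols, 3))
    return IlluminationPattern(grid=grid, label="brightfield")


def _strip_mask(array: LedArraySpec, side: Side, strip_width: int) -> np.ndarray:
    n = array.n_cols if side in ("left", "right") else array.n_rows
    if not 1 <= strip_width <= n:
        raise ValueError(f"strip_width {strip_width} out of range 1..{n} for side {side!r}")
    mask = np.zeros((array.n_rows, array.n_cols), dtype=bool)
    if side == "left":
        mask[:, :strip_width] = True
    elif side == "right":
        mask[:, array.n_cols - strip_width :] = True
    elif side == "top":
        mask[:strip_width, :] = True
    elif side == "bottom":
        mask[array.n_rows - strip_width :, :] = True
    else:  # pragma: no cover - Literal guards this
        raise ValueError(f"unknown side {side!r}")
    return mask


def oblique_pattern(
    array: LedArraySpec, side: Side, strip_width: int = 2
) -> IlluminationPattern:
    """Light only the outermost ``strip_width`` rows/columns on one side.

    One-sided illumination gives relief-like contrast proportional to the
    directional gradient of the sample's optical path length.
    """
    mask = _strip_mask(array, side, strip_width)
    grid = np.zeros((array.n_rows, array.n_cols, 3))
    grid[mask] = 1.0
    return IlluminationPattern(grid=grid, label=f"oblique_{side}_{strip_width}")


def darkfield_pattern(array: LedArraySpec, lens: LensSpec) -> IlluminationPattern:
    """Light exactly the LEDs whose illumination angle falls outside the lens
    NA cone; only scattered light then reaches the detector.

    Raises :class:`DarkfieldImpossibleError` if every LED is inside the cone.
    """
    grid = np.zeros((array.n_rows, array.n_cols, 3))
    any_lit = False
    for r in range(array.n_rows):
        for c in range(array.n_cols):
            if led_sine(r, c, array) > lens.na:
                grid[r, c] = 1.0
                any_lit = True
    if not any_lit:
        raise DarkfieldImpossibleError(
            f"darkfield impossible with this geometry: all LEDs inside NA {lens.na}"
        )
    return IlluminationPattern(grid=grid, label=f"darkfield_na{lens.na}")


def pseudo_phase_pair(
    array: LedArraySpec,
    axis: Literal["horizontal", "vertical"] = "horizontal",
    strip_width: int = 2,
) -> Tuple[IlluminationPattern, IlluminationPattern]:
    """Opposite-side oblique pair for pseudo-phase contrast.

    ``horizontal`` returns (left, right) strips; ``vertical`` (top, bottom).
    The two patterns are mirror images across the chosen axis.
    """
    if axis == "horizontal":
        return (
            oblique_pattern(array, "left", strip_width),
            oblique_pattern(array, "right", strip_width),
        )
    if axis == "vertical":
        return (
            oblique_pattern(array, "top", strip_width),
            oblique_pattern(array, "bottom", strip_width),
        )
    raise ValueError(f"axis must be 'horizontal' or 'vertical', got {axis!r}")


def _validate_sectors(sectors: Sequence[Tuple[float, float, RGB]]) -> list:
    if not sectors:
        raise SectorError("at least one sector required")
    ordered = sorted(sectors, key=lambda s: s[0])
    for start, end, _ in ordered:
        if not (0 <= start < 360) or not (start < end <= 360):
            raise SectorError(
                f"sector ({start}, {end}) must satisfy 0 <= start < end <= 360"
            )
    if ordered[0][0] != 0:
        raise SectorError("sectors must start at 0 degrees")
    for (s0, e0, _), (s1, _, _) in zip(ordered, ordered[1:]):
        if e0 < s1:
            raise SectorError(f"gap between {e0} and {s1} degrees")
        if e0 > s1:
            raise SectorError(f"sectors overlap between {s1} and {e0} degrees")
    if ordered[-1][1] != 360:
        raise SectorError("sectors must end at 360 degrees")
    return ordered


def rheinberg_pattern(
    ring: LedRingSpec, sectors: Sequence[Tuple[float, float, RGB]]
) -> RingPattern:
    """Colour each ring LED by the half-open [start, end) sector containing
    its angular position (degrees CCW from +x); an LED exactly on a boundary
    belongs to the sector whose start it equals."""
    ordered = _validate_sectors(sectors)
    colors = np.zeros((ring.n_leds, 3))
    for k in range(ring.n_leds):
        angle = (360.0 * k / ring.n_leds) % 360.0
        for start, end, rgb in ordered:
            if start <= angle < end:
                colors[k] = rgb
                break
    return RingPattern(
        colors=colors,
        sectors=[(float(s), float(e), tuple(rgb)) for s, e, rgb in ordered],
        label="rheinberg",
        position=ring.position,
    )


def reflected_pattern(ring: LedRingSpec, colour: RGB = WHITE) -> RingPattern:
    """All ring LEDs at one colour — reflected-light (epi) illumination when
    the ring sits beneath the objective."""
    colors = np.tile(np.asarray(colour, dtype=float), (ring.n_leds, 1))
    return RingPattern(
        colors=colors,
        sectors=[(0.0, 360.0, tuple(float(c) for c in colour))],
        label="reflected",
        position=ring.position,
    )
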