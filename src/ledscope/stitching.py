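"""Content-based tile stitching and extended depth of field.

Registration uses frequency-domain normalised cross-correlation restricted
to the pair's expected overlap: the overlap strip of one tile (inset by the
search radius) is matched as a template inside the neighbouring tile, so
the translation search is bounded to a window around the plan's nominal
offset and the NCC peak value is a natural confidence score.  Tile
positions are propagated from the anchor tile along the snake acquisition
order; low-confidence pairs fall back to the nominal step.  Overlaps are
linearly feathered, so a stitch of exact, noise-free tiles reproduces the
source scene pixel for pixel.

Extended depth of field composites a Z-stack by choosing, per pixel, the
slice with the highest local (windowed) variance of luminance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.ndimage import uniform_filter

from .acquisition import TilePlan, TilePosition
from .microscope import Frame

__all__ = [
    "OverlapError",
    "Mosaic",
    "EdofResult",
    "pairwise_offset",
    "stitch",
    "extended_focus",
]

TileLike = Union[Frame, np.ndarray]


class OverlapError(ValueError):
    """Tiles do not overlap enough under the nominal offset."""


@dataclass
class Mosaic:
    """Stitched image with per-tile refined placements.

    ``offsets_px`` maps (row, col) to the tile's top-left corner (dy, dx)
    in mosaic coordinates relative to the anchor tile; ``confidence`` maps
    each registered pair to its peak-dominance score in [0, 1].
    """

    image: np.ndarray
    offsets_px: Dict[Tuple[int, int], Tuple[int, int]]
    confidence: Dict[Tuple[Tuple[int, int], Tuple[int, int]], float]
    coverage: Optional[np.ndarray] = None  # bool mask: pixels under >=1 tile


@dataclass
class EdofResult:
    """All-in-focus composite and the per-pixel chosen slice index."""

    composite: np.ndarray
    index_map: np.ndarray


def _pixels(t: TileLike) -> np.ndarray:
    return (t.pixels if isinstance(t, Frame) else np.asarray(t)).astype(float)


def _lum(t: TileLike) -> np.ndarray:
    a = _pixels(t)
    return a if a.ndim == 2 else a.mean(axis=2)


def pairwise_offset(
    tile_a: TileLike,
    tile_b: TileLike,
    nominal: Tuple[int, int],
    search_radius: Optional[int] = None,
    min_overlap: float = 0.10,
) -> Tuple[int, int, float]:
    """Measure the translation of ``tile_b`` relative to ``tile_a``.

    ``nominal`` is the expected (dy, dx) in pixels (tile_b's scene position
    minus tile_a's).  The correlation peak is searched only within
    ``search_radius`` (default 10% of the tile size) of the nominal offset.
    Returns ``(dy, dx, confidence)`` where confidence in [0, 1] is the NCC
    value at the chosen peak; values below ~0.3 indicate registration
    failure (e.g. featureless or pure-noise overlap).

    Raises :class:`OverlapError` if the nominal offset leaves less than
    ``min_overlap`` of the tile area in common.
    """
    a = _lum(tile_a)
    b = _lum(tile_b)
    if a.shape != b.shape:
        raise ValueError(f"tile shapes differ: {a.shape} vs {b.shape}")
    H, W = a.shape
    dy0, dx0 = int(round(nominal[0])), int(round(nominal[1]))
    ov_h, ov_w = H - abs(dy0), W - abs(dx0)
    if ov_h <= 0 or ov_w <= 0 or ov_h * ov_w < min_overlap * H * W:
        raise OverlapError(
            f"nominal offset ({dy0}, {dx0}) leaves <{min_overlap:.0%} overlap"
        )
    if search_radius is None:
        search_radius = max(2, round(0.10 * min(H, W)))
    radius = int(search_radius)
    for n, d0 in ((H, dy0), (W, dx0)):
        lim = n - abs(d0) - 5 if d0 != 0 else (n - 5) // 2
        radius = min(radius, lim)
    radius = max(1, radius)

    # template: a's overlap region, inset by the search radius only on the
    # side facing b's edge; the search region extends into b's interior so
    # the whole overlap strip contributes content.
    def axis_windows(n: int, d0: int) -> Tuple[int, int, int, int]:
        if d0 > 0:
            return d0 + radius, n, 0, min(n, n - d0 + radius)
        if d0 < 0:
            return 0, n + d0 - radius, max(0, -d0 - radius), n
        return radius, n - radius, 0, n

    ty0, ty1, sy0, sy1 = axis_windows(H, dy0)
    tx0, tx1, sx0, sx1 = axis_windows(W, dx0)
    template = a[ty0:ty1, tx0:tx1]
    search = b[sy0:sy1, sx0:sx1]
    # featureless (or numerically near-constant) overlap is unregistrable:
    # NCC normalisation degenerates, so report the nominal with confidence 0
    floor = 1e-4 * max(1.0, abs(float(template.mean())))
    if template.std() <= floor or search.std() <= floor:
        return dy0, dx0, 0.0
    from skimage.feature import match_template

    ncc = match_template(search, template)
    k = np.unravel_index(int(np.argmax(ncc)), ncc.shape)
    # template top-left sits at (ty0, tx0) in a and lands at search-region
    # index k in b, so the measured offset is the difference
    dy = ty0 - (sy0 + int(k[0]))
    dx = tx0 - (sx0 + int(k[1]))
    confidence = float(np.clip(ncc[k], 0.0, 1.0))
    return dy, dx, confidence


def _ramp(n: int, band: int) -> np.ndarray:
    """Feather weight profile: linear ramp over ``band`` px at both ends."""
    edge = np.minimum(np.arange(1, n + 1), np.arange(n, 0, -1))
    return np.minimum(edge, band) / band


def _as_tile_dict(
    tiles: Union[Dict[Tuple[int, int], TileLike], Sequence[Tuple[TilePosition, TileLike]]],
) -> Dict[Tuple[int, int], TileLike]:
    if isinstance(tiles, dict):
        return dict(tiles)
    return {(p.row, p.col): f for p, f in tiles}


def stitch(
    tiles: Union[Dict[Tuple[int, int], TileLike], Sequence[Tuple[TilePosition, TileLike]]],
    plan: TilePlan,
    search_radius: Optional[int] = None,
    confidence_threshold: float = 0.3,
    refine: bool = True,
) -> Mosaic:
    """Assemble a mosaic from a complete tile set captured under ``plan``.

    The first tile in capture order anchors the mosaic.  Each subsequent
    tile is registered against its predecessor in snake order with
    :func:`pairwise_offset` around the plan's nominal step; pairs whose
    confidence falls below ``confidence_threshold`` (and all pairs when
    ``refine`` is False) use the nominal step instead.  Overlap bands are
    linearly feathered.
    """
    tile_map = _as_tile_dict(tiles)
    missing = [
        (r, c)
        for r in range(plan.rows)
        for c in range(plan.cols)
        if (r, c) not in tile_map
    ]
    if missing:
        raise ValueError(f"missing tiles: {missing}")

    first = _pixels(tile_map[(plan.positions[0].row, plan.positions[0].col)])
    th, tw = first.shape[:2]
    fov_w, fov_h = plan.tile_fov_mm
    scale_x = tw / fov_w  # px per mm
    scale_y = th / fov_h
    step_x_px = plan.step_mm[0] * scale_x
    step_y_px = plan.step_mm[1] * scale_y

    def nominal_px(r: int, c: int) -> np.ndarray:
        return np.array([r * step_y_px, c * step_x_px])

    offsets: Dict[Tuple[int, int], Tuple[int, int]] = {}
    confidence: Dict[Tuple[Tuple[int, int], Tuple[int, int]], float] = {}
    order = [(p.row, p.col) for p in plan.positions]
    offsets[order[0]] = (0, 0)
    for prev, curr in zip(order, order[1:]):
        delta = nominal_px(*curr) - nominal_px(*prev)
        delta_int = (int(round(delta[0])), int(round(delta[1])))
        use = delta_int
        if refine:
            dy, dx, conf = pairwise_offset(
                tile_map[prev], tile_map[curr], delta_int, search_radius
            )
            confidence[(prev, curr)] = conf
            if conf >= confidence_threshold:
                use = (dy, dx)
        py, px = offsets[prev]
        offsets[curr] = (py + use[0], px + use[1])

    min_y = min(o[0] for o in offsets.values())
    min_x = min(o[1] for o in offsets.values())
    offsets = {k: (o[0] - min_y, o[1] - min_x) for k, o in offsets.items()}
    canvas_h = max(o[0] for o in offsets.values()) + th
    canvas_w = max(o[1] for o in offsets.values()) + tw

    band_y = max(1, int(round(th - step_y_px))) if plan.rows > 1 else 1
    band_x = max(1, int(round(tw - step_x_px))) if plan.cols > 1 else 1
    w2d = np.outer(_ramp(th, band_y), _ramp(tw, band_x))

    nchan = 1 if first.ndim == 2 else first.shape[2]
    acc = np.zeros((canvas_h, canvas_w, nchan))
    wacc = np.zeros((canvas_h, canvas_w))
    for key, (oy, ox) in offsets.items():
        img = _pixels(tile_map[key])
        if img.ndim == 2:
            img = img[..., None]
        acc[oy : oy + th, ox : ox + tw] += img * w2d[..., None]
        wacc[oy : oy + th, ox : ox + tw] += w2d
    with np.errstate(invalid="ignore"):
        out = np.where(wacc[..., None] > 0, acc / np.maximum(wacc, 1e-12)[..., None], 0.0)
    if first.ndim == 2:
        out = out[..., 0]
    return Mosaic(
        image=out, offsets_px=offsets, confidence=confidence, coverage=wacc > 0
    )


def extended_focus(
    stack: Union[Sequence[TileLike], np.ndarray], window: int = 9
) -> EdofResult:
    """Composite a Z-stack by per-pixel local sharpness.

    For each pixel, the slice whose luminance has the highest variance in a
    ``window`` x ``window`` neighbourhood is selected (ties go to the lower
    slice index); the composite takes its value from that slice.
    """
    imgs = [_pixels(s) for s in stack]
    if not imgs:
        raise ValueError("empty stack")
    shapes = {im.shape for im in imgs}
    if len(shapes) > 1:
        raise ValueError(f"slice shapes differ: {shapes}")
    lums = [im if im.ndim == 2 else im.mean(axis=2) for im in imgs]
    sharp = np.stack(
        [
            uniform_filter(l * l, window) - uniform_filter(l, window) ** 2
            for l in lums
        ]
    )
    index_map = np.argmax(sharp, axis=0)
    arr = np.stack(imgs)  # (n, H, W[, C])
    if arr.ndim == 4:
        composite = np.take_along_axis(
            arr, index_map[None, ..., None], axis=0
        )[0]
    else:
        composite = np.take_along_axis(arr, index_map[None, ...], axis=0)[0]
    return EdofResult(composite=composite, index_map=index_map)
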