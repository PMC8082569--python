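"""Acquisition planning and orchestration: Z-series, snake-by-rows tile
grids, and time-lapse.

A :class:`TilePlan` lays out a rows x cols mosaic in "snake by rows"
(boustrophedon) order: row 0 left-to-right, row 1 right-to-left, and so on,
minimising stage travel.  The centre-to-centre step is ``(1 - overlap) *
FOV`` per axis, so the mosaic extent per axis is ``FOV * (N - (N-1) *
overlap)``.  Stage positions are quantised to integer motor units toward
zero; the sub-unit residuals are recorded for the stitcher.
"""

from __future__ import annotations

import math
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

from .geometry import (
    LensSpec,
    MotorCalibration,
    SensorSpec,
    field_of_view,
)
from .microscope import Frame, Microscope

__all__ = [
    "PlanError",
    "ZPlan",
    "TilePosition",
    "TilePlan",
    "plan_z_series",
    "plan_tiles",
    "run_timelapse",
    "acquire_zstack",
    "acquire_mosaic",
]


class PlanError(ValueError):
    """The requested plan violates stage or focus travel limits."""


class ZPlan(BaseModel):
    """Arithmetic Z series: ``count`` positions from ``start_units`` in steps
    of ``step_units`` (motor units)."""

    model_config = ConfigDict(frozen=True)

    start_units: int
    step_units: int
    count: int = Field(ge=1)

    @property
    def positions(self) -> List[int]:
        return [self.start_units + k * self.step_units for k in range(self.count)]

    @property
    def span_units(self) -> int:
        return abs(self.step_units) * (self.count - 1)


class TilePosition(BaseModel):
    model_config = ConfigDict(frozen=True)

    row: int
    col: int
    x_units: int
    y_units: int
    residual_x_units: float = 0.0
    residual_y_units: float = 0.0


class TilePlan(BaseModel):
    """Ordered snake-by-rows mosaic plan."""

    model_config = ConfigDict(frozen=True)

    rows: int = Field(ge=1)
    cols: int = Field(ge=1)
    overlap_fraction: float = Field(ge=0, lt=1)
    tile_fov_mm: Tuple[float, float]  # (width, height)
    positions: List[TilePosition]

    @property
    def step_mm(self) -> Tuple[float, float]:
        return (
            (1 - self.overlap_fraction) * self.tile_fov_mm[0],
            (1 - self.overlap_fraction) * self.tile_fov_mm[1],
        )

    def position_of(self, row: int, col: int) -> TilePosition:
        for p in self.positions:
            if p.row == row and p.col == col:
                return p
        raise KeyError((row, col))


def plan_z_series(
    start: int, step: int, count: int, calib: MotorCalibration
) -> ZPlan:
    """Plan a Z series with user-defined start, step and count.

    Every position must lie inside the Z range (0 .. z_range_mm).
    """
    if count < 1:
        raise PlanError("count must be >= 1")
    if step == 0 and count > 1:
        raise PlanError("step must be nonzero for multi-position series")
    z_max = calib.z_range_mm * calib.z_units_per_mm
    plan = ZPlan(start_units=start, step_units=step, count=count)
    for z in plan.positions:
        if not 0 <= z <= z_max:
            raise PlanError(f"z position {z} outside 0..{z_max:g} units")
    return plan


def plan_tiles(
    rows: int,
    cols: int,
    overlap_fraction: float,
    calib: MotorCalibration,
    lens: Optional[LensSpec] = None,
    sensor: Optional[SensorSpec] = None,
    tile_fov_mm: Optional[Tuple[float, float]] = None,
    origin_units: Tuple[int, int] = (0, 0),
) -> TilePlan:
    """Plan a rows x cols snake-by-rows mosaic.

    The tile field of view comes either from ``tile_fov_mm`` directly or
    from the lens/sensor pair.  ``origin_units`` is the stage position of
    the top-left tile centre (default: stage centre).  The plan is refused,
    naming the violating axis, if any tile would extend beyond the stage
    travel.
    """
    if rows < 1 or cols < 1:
        raise PlanError("rows and cols must be >= 1")
    if not 0 <= overlap_fraction < 1:
        raise PlanError("overlap_fraction must be in [0, 1)")
    if tile_fov_mm is None:
        if lens is None or sensor is None:
            raise PlanError("provide tile_fov_mm or both lens and sensor")
        tile_fov_mm = field_of_view(lens, sensor)
    fov_w, fov_h = tile_fov_mm
    step_x_mm = (1 - overlap_fraction) * fov_w
    step_y_mm = (1 - overlap_fraction) * fov_h

    half_travel = calib.xy_travel_mm / 2
    ox_mm = origin_units[0] / calib.xy_units_per_mm
    oy_mm = origin_units[1] / calib.xy_units_per_mm
    for axis, o_mm, n, step_mm, fov_mm in (
        ("x", ox_mm, cols, step_x_mm, fov_w),
        ("y", oy_mm, rows, step_y_mm, fov_h),
    ):
        lo = o_mm - fov_mm / 2
        hi = o_mm + (n - 1) * step_mm + fov_mm / 2
        if lo < -half_travel or hi > half_travel:
            raise PlanError(
                f"mosaic exceeds stage travel on {axis}: extent "
                f"[{lo:.3f}, {hi:.3f}] mm vs +/-{half_travel:g} mm"
            )

    positions: List[TilePosition] = []
    for r in range(rows):
        col_order = range(cols) if r % 2 == 0 else range(cols - 1, -1, -1)
        for c in col_order:
            x_mm = ox_mm + c * step_x_mm
            y_mm = oy_mm + r * step_y_mm
            # quantise toward zero (after trimming float noise at 1e-6 units);
            # keep the residual for the stitcher
            x_u = math.trunc(round(x_mm * calib.xy_units_per_mm, 6))
            y_u = math.trunc(round(y_mm * calib.xy_units_per_mm, 6))
            positions.append(
                TilePosition(
                    row=r,
                    col=c,
                    x_units=x_u,
                    y_units=y_u,
                    residual_x_units=x_mm * calib.xy_units_per_mm - x_u,
                    residual_y_units=y_mm * calib.xy_units_per_mm - y_u,
                )
            )
    return TilePlan(
        rows=rows,
        cols=cols,
        overlap_fraction=overlap_fraction,
        tile_fov_mm=(fov_w, fov_h),
        positions=positions,
    )


def run_timelapse(
    capture: Callable[[], Frame],
    interval_s: float,
    n_frames: int,
    exposure_ms: float = 10.0,
    on_interval: Optional[Callable[[float], None]] = None,
) -> List[Frame]:
    """Capture ``n_frames`` at a nominal ``interval_s`` spacing.

    ``capture`` produces one frame; ``on_interval(seconds)``, if given, is
    called between frames to advance time (the virtual microscope's clock,
    or a real sleep on hardware).  Nominal timestamps start + k*interval are
    recorded in each frame's metadata as ``timelapse_nominal_s``.
    """
    if n_frames < 1:
        raise PlanError("n_frames must be >= 1")
    if interval_s * 1000.0 < exposure_ms:
        raise PlanError(
            f"interval {interval_s}s shorter than exposure {exposure_ms}ms"
        )
    frames: List[Frame] = []
    for k in range(n_frames):
        frame = capture()
        start = frames[0].metadata["timestamp_s"] if frames else frame.metadata["timestamp_s"]
        frame.metadata["timelapse_index"] = k
        frame.metadata["timelapse_nominal_s"] = start + k * interval_s
        frames.append(frame)
        if k < n_frames - 1 and on_interval is not None:
            on_interval(max(interval_s - exposure_ms / 1000.0, 0.0))
    return frames


def acquire_zstack(
    microscope: Microscope, plan: ZPlan, exposure_ms: float = 10.0
) -> List[Frame]:
    """Capture the Z series in plan order (one frame per position)."""
    frames = []
    for z in plan.positions:
        microscope.move_focus(z)
        frames.append(microscope.capture(exposure_ms))
    return frames


def _sag_compensation_units(microscope: Microscope, x_units: int, y_units: int) -> int:
    """Z correction (motor units) for the flexure-arc drop at a stage
    position, when the backend exposes its calibration and flexure geometry
    (the virtual microscope does); zero otherwise."""
    calib = getattr(microscope, "calib", None)
    flex = getattr(microscope, "flexure", None)
    if calib is None or flex is None:
        return 0
    from .geometry import flexure_sag

    d_mm = float(np.hypot(x_units / calib.xy_units_per_mm, y_units / calib.xy_units_per_mm))
    return round(flexure_sag(d_mm, flex) * calib.z_units_per_mm)


def acquire_mosaic(
    microscope: Microscope,
    plan: TilePlan,
    exposure_ms: float = 10.0,
    jitter_units: Optional[Sequence[Tuple[int, int]]] = None,
    compensate_sag: bool = True,
) -> List[Tuple[TilePosition, Frame]]:
    """Visit every tile position in snake order and capture a frame.

    ``jitter_units``, if given, adds a per-tile (dx, dy) stage error to the
    commanded position — used to emulate imperfect repeatability when
    validating the stitcher.  With ``compensate_sag`` (default), the focus
    is raised per tile by the known flexure-arc drop at that stage position,
    keeping the whole mosaic in focus.  Returns (position, frame) pairs in
    capture order.
    """
    base_z = microscope.state.focus_z_units
    out: List[Tuple[TilePosition, Frame]] = []
    for i, pos in enumerate(plan.positions):
        jx, jy = jitter_units[i] if jitter_units is not None else (0, 0)
        microscope.move_stage(pos.x_units + jx, pos.y_units + jy)
        if compensate_sag:
            comp = _sag_compensation_units(microscope, pos.x_units + jx, pos.y_units + jy)
            microscope.move_focus(base_z + comp)
        out.append((pos, microscope.capture(exposure_ms)))
    return out
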