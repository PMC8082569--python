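"""Static optical and mechanical geometry.

Everything in this module is closed-form: fields of view of finite-conjugate
objectives, illumination angles of the LEDs in a planar array, motor-unit
calibrations and the arc kinematics of a flexure stage.  These functions are
pure and cheap; the simulator and the planners build on them.

Conventions
-----------
* Lengths are millimetres unless a name says otherwise (``pixel_pitch_um``).
* The LED array is centred on the optical axis; for even grid dimensions the
  four central LEDs sit half a pitch off axis.
* Angles of incidence are expressed through their sine, so they compare
  directly with a numerical aperture.
"""

from __future__ import annotations

import math
from typing import Literal, Tuple

from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = [
    "LensSpec",
    "SensorSpec",
    "LedArraySpec",
    "LedRingSpec",
    "MotorCalibration",
    "FlexureSpec",
    "DEFAULT_LENSES",
    "field_of_view",
    "led_offset_mm",
    "led_sine",
    "classify_led",
    "z_units_to_mm",
    "mm_to_z_units",
    "xy_units_to_mm",
    "mm_to_xy_units",
    "flexure_sag",
]


class _Spec(BaseModel):
    model_config = ConfigDict(frozen=True, extra="forbid")


class LensSpec(_Spec):
    """A finite-conjugate dry objective.

    ``coarse_offset_units`` is the Z motor offset from the home switch to the
    expected sample focus for this lens; ``parfocal_mm`` is metadata only.
    """

    name: str
    magnification: float = Field(gt=0)
    na: float = Field(gt=0, lt=1)
    coarse_offset_units: int = Field(default=0, ge=0)
    parfocal_mm: float = Field(default=45.0, gt=0)


class SensorSpec(_Spec):
    """Camera sensor geometry (pixel grid and pitch)."""

    width_px: int = Field(gt=0)
    height_px: int = Field(gt=0)
    pixel_pitch_um: float = Field(gt=0)

    @property
    def width_mm(self) -> float:
        return self.width_px * self.pixel_pitch_um / 1000.0

    @property
    def height_mm(self) -> float:
        return self.height_px * self.pixel_pitch_um / 1000.0


class LedArraySpec(_Spec):
    """Planar LED array in the illumination pupil, centred on the axis."""

    n_rows: int = Field(default=8, ge=1)
    n_cols: int = Field(default=8, ge=1)
    pitch_mm: float = Field(default=4.0, gt=0)
    height_mm: float = Field(default=25.0, gt=0)


class LedRingSpec(_Spec):
    """Circular RGB LED ring, either beneath the objective (reflected light)
    or on the sample side (Rheinberg-style transmitted colour contrast)."""

    n_leds: int = Field(default=12, ge=3)
    radius_mm: float = Field(default=20.0, gt=0)
    position: Literal["below_objective", "sample_side"] = "sample_side"


class MotorCalibration(_Spec):
    """Motor-unit calibrations and travel limits.

    The Z axis is calibrated at 1000 units/mm (100 units per 0.1 mm); XY uses
    the same scale by default.  Travel limits: 4 mm Z range from the home
    switch, 3 mm total XY travel per axis (i.e. +/-1.5 mm about centre).
    """

    z_units_per_mm: float = Field(default=1000.0, gt=0)
    xy_units_per_mm: float = Field(default=1000.0, gt=0)
    z_range_mm: float = Field(default=4.0, gt=0)
    xy_travel_mm: float = Field(default=3.0, gt=0)


class FlexureSpec(_Spec):
    """Parallel-beam flexure stage: lateral travel follows a slight arc."""

    length_mm: float = Field(default=30.0, gt=0)
    travel_mm: float = Field(default=3.0, gt=0)

    @model_validator(mode="after")
    def _travel_within_reach(self) -> "FlexureSpec":
        if not self.travel_mm < 2 * self.length_mm:
            raise ValueError("travel_mm must be smaller than twice the flexure length")
        return self


#: Default objective table: low-cost finite-conjugate dry lenses.  The coarse
#: focus offsets are instrument calibrations, not optical constants; the
#: defaults here are plausible mid-range values within the 4 mm Z travel.
DEFAULT_LENSES: dict[str, LensSpec] = {
    "4x": LensSpec(name="4x", magnification=4, na=0.12, coarse_offset_units=1500),
    "10x": LensSpec(name="10x", magnification=10, na=0.25, coarse_offset_units=1800),
    "25x": LensSpec(name="25x", magnification=25, na=0.35, coarse_offset_units=2000),
    "40x": LensSpec(name="40x", magnification=40, na=0.65, coarse_offset_units=2100),
}


def field_of_view(lens: LensSpec, sensor: SensorSpec) -> Tuple[float, float]:
    """Sample-plane field of view (width_mm, height_mm).

    A finite-conjugate objective projects the sample directly onto the sensor
    at its nominal magnification, so the FOV is the sensor's physical extent
    divided by the magnification.
    """
    return (sensor.width_mm / lens.magnification, sensor.height_mm / lens.magnification)


def led_offset_mm(row: int, col: int, array: LedArraySpec) -> Tuple[float, float]:
    """Lateral (x, y) offset of an LED centre from the optical axis, in mm.

    The grid is centred on the axis, so even dimensions put every LED half a
    pitch off the axis.  Raises ``IndexError`` for indices outside the grid.
    """
    if not (0 <= row < array.n_rows and 0 <= col < array.n_cols):
        raise IndexError(
            f"LED index ({row}, {col}) outside {array.n_rows}x{array.n_cols} grid"
        )
    x = (col - (array.n_cols - 1) / 2) * array.pitch_mm
    y = (row - (array.n_rows - 1) / 2) * array.pitch_mm
    return x, y


def led_sine(row: int, col: int, array: LedArraySpec) -> float:
    """Sine of the angle between the axis and the ray from an LED to the
    on-axis sample point: r / sqrt(r^2 + h^2), in [0, 1)."""
    x, y = led_offset_mm(row, col, array)
    r = math.hypot(x, y)
    return r / math.hypot(r, array.height_mm)


def classify_led(
    row: int, col: int, array: LedArraySpec, lens: LensSpec
) -> Literal["inside_na", "outside_na"]:
    """Classify an LED against the lens acceptance cone.

    An LED exactly on the NA boundary counts as inside, so darkfield patterns
    (built from the outside set) never include boundary LEDs.
    """
    return "inside_na" if led_sine(row, col, array) <= lens.na else "outside_na"


def z_units_to_mm(units: int, calib: MotorCalibration) -> float:
    """Convert Z motor units to mm (default calibration: 100 units = 0.1 mm)."""
    return units / calib.z_units_per_mm


def mm_to_z_units(mm: float, calib: MotorCalibration) -> int:
    """Convert mm to the nearest integer Z motor unit (inverse of
    :func:`z_units_to_mm` on integer units)."""
    return round(mm * calib.z_units_per_mm)


def xy_units_to_mm(units: int, calib: MotorCalibration) -> float:
    return units / calib.xy_units_per_mm


def mm_to_xy_units(mm: float, calib: MotorCalibration) -> int:
    return round(mm * calib.xy_units_per_mm)


def flexure_sag(d_mm: float, flex: FlexureSpec) -> float:
    """Vertical drop of the flexure platform at lateral deflection ``d_mm``.

    The platform tip travels on a circular arc of radius equal to the beam
    length L, so the sag is L - sqrt(L^2 - d^2): zero on axis, symmetric,
    and second order in d (hence "slight arc").
    """
    L = flex.length_mm
    if abs(d_mm) >= L:
        raise ValueError(f"deflection {d_mm} mm exceeds flexure length {L} mm")
    return L - math.sqrt(L * L - d_mm * d_mm)
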