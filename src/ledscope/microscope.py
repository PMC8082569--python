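"""Hardware-abstraction contract and the virtual microscope backend.

:class:`Microscope` is the minimal control surface an instrument must offer:
home the focus drive, move the XY stage and Z focus in integer motor units,
select illumination, operate the lid/fluorescence interlock, and capture a
frame.  :class:`VirtualMicroscope` implements it against a synthetic
:class:`~ledscope.phantoms.Phantom`, with stage limits, the flexure-arc focus
perturbation, defocus blur and optional seeded shot/read noise, so every
acquisition protocol can be exercised with no hardware attached.

Forward model (per colour channel c, expected counts before quantisation)::

    I_c = I0 * t * [ B_c * tint_c * exp(-A) * max(0, 1 + kappa * grad(phi).s)
                     + D_c * S ]                      (transmitted modes)
    I_c = I0 * t * ring_c * S                          (reflected ring)
    I_c = I0 * t * [ sum_f exc(f) * em_c(f) * F_f + leak ]   (fluorescence)

where t is the exposure, A/phi/S/F are the phantom's absorbance, phase,
scatter and fluorophore maps (each blurred by a Gaussian whose width grows
linearly with that layer's defocus), B_c and D_c are the summed intensities
of the LEDs inside and outside the lens NA cone (normalised by the grid
size) and s is the intensity-weighted mean tilt (sine) vector of the lit
in-NA LEDs.  This is a first-order geometric-optics caricature, not wave
optics: it reproduces the qualitative behaviour of the real contrast modes
(phase invisible in brightfield, signed relief under oblique illumination,
scatter-only darkfield) and is deterministic per seed.
"""

from __future__ import annotations

import abc
import datetime as _dt
from dataclasses import dataclass, field as dc_field, replace
from typing import Optional, Tuple, Union

import numpy as np
from scipy.ndimage import gaussian_filter

from .geometry import (
    FlexureSpec,
    LedArraySpec,
    LedRingSpec,
    LensSpec,
    MotorCalibration,
    DEFAULT_LENSES,
    flexure_sag,
    led_offset_mm,
    led_sine,
)
from .illumination import IlluminationPattern, RingPattern, brightfield_pattern
from .phantoms import COLOUR_RGB, Phantom

__all__ = [
    "MicroscopeError",
    "NotHomedError",
    "StageLimitError",
    "FocusLimitError",
    "InterlockError",
    "RenderError",
    "FluorescenceIllumination",
    "FlexiLamp",
    "MicroscopeState",
    "Frame",
    "Microscope",
    "VirtualMicroscope",
    "render",
]


class MicroscopeError(RuntimeError):
    pass


class NotHomedError(MicroscopeError):
    """Motion was requested before the focus drive found its home switch."""


class StageLimitError(MicroscopeError):
    """Target position outside the XY travel; the stage did not move."""


class FocusLimitError(MicroscopeError):
    """Target position outside the Z range; the focus did not move."""


class InterlockError(MicroscopeError):
    """The lid interlock refused to enable the fluorescence LED."""


class RenderError(MicroscopeError):
    """The phantom does not cover the field of view, or the state is invalid."""


@dataclass(frozen=True)
class FluorescenceIllumination:
    """Epi-fluorescence mode: one excitation LED plus a long-pass emission
    filter.  Emission of every fluorophore excited by ``excitation`` is
    collected into its emission colour channel."""

    excitation: str = "blue"


@dataclass(frozen=True)
class FlexiLamp:
    """Auxiliary gooseneck lamp, modelled as a single large-angle oblique
    source at azimuth ``azimuth_deg`` (CCW from +x) with tilt sine
    ``tilt_sine``."""

    azimuth_deg: float = 0.0
    tilt_sine: float = 0.5


Illumination = Union[IlluminationPattern, RingPattern, FluorescenceIllumination, FlexiLamp]


@dataclass(frozen=True)
class MicroscopeState:
    """Snapshot of the full instrument state at capture time."""

    stage_x_units: int = 0
    stage_y_units: int = 0
    focus_z_units: int = 0
    homed: bool = False
    lens: LensSpec = DEFAULT_LENSES["10x"]
    illumination: Optional[Illumination] = None
    lid_open: bool = False
    fluor_led_on: bool = False
    seed: int = 0

    def validate(self, calib: MotorCalibration) -> None:
        half = calib.xy_travel_mm / 2 * calib.xy_units_per_mm
        if abs(self.stage_x_units) > half or abs(self.stage_y_units) > half:
            raise RenderError("stage position outside travel")
        if not 0 <= self.focus_z_units <= calib.z_range_mm * calib.z_units_per_mm:
            raise RenderError("focus position outside Z range")
        if self.fluor_led_on and self.lid_open:
            raise RenderError("fluorescence LED on with the lid open")


@dataclass
class Frame:
    """One captured image (16-bit, H x W x 3) plus acquisition metadata."""

    pixels: np.ndarray
    metadata: dict

    def __post_init__(self) -> None:
        p = np.asarray(self.pixels)
        if p.dtype != np.uint16:
            raise ValueError("frame pixels must be uint16")
        if p.ndim not in (2, 3):
            raise ValueError("frame pixels must be 2D or 3-channel")
        self.pixels = p

    @property
    def luminance(self) -> np.ndarray:
        """Channel-mean image as float."""
        p = self.pixels.astype(float)
        return p if p.ndim == 2 else p.mean(axis=2)


class Microscope(abc.ABC):
    """Hardware-abstraction contract: stage + focus + illuminator + camera."""

    @abc.abstractmethod
    def home_focus(self) -> None: ...

    @abc.abstractmethod
    def move_stage(self, x_units: int, y_units: int) -> None: ...

    @abc.abstractmethod
    def move_focus(self, z_units: int) -> None: ...

    @abc.abstractmethod
    def set_lens(self, lens: LensSpec) -> None: ...

    @abc.abstractmethod
    def set_illumination(self, illumination: Illumination) -> None: ...

    @abc.abstractmethod
    def open_lid(self) -> None: ...

    @abc.abstractmethod
    def close_lid(self) -> None: ...

    @abc.abstractmethod
    def set_fluorescence_led(self, on: bool) -> None: ...

    @abc.abstractmethod
    def capture(self, exposure_ms: float = 10.0) -> Frame: ...

    @property
    @abc.abstractmethod
    def state(self) -> MicroscopeState: ...


def _pattern_decomposition(
    pattern: IlluminationPattern, array: LedArraySpec, lens: LensSpec
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Split an LED-array pattern into brightfield weight B (per channel),
    darkfield weight D (per channel) and the mean tilt vector s of the lit
    in-NA LEDs (intensity weighted, components are sines)."""
    n_total = array.n_rows * array.n_cols
    B = np.zeros(3)
    D = np.zeros(3)
    tilt = np.zeros(2)
    w_sum = 0.0
    for r in range(array.n_rows):
        for c in range(array.n_cols):
            rgb = pattern.grid[r, c]
            w = float(rgb.mean())
            if w == 0.0:
                continue
            s = led_sine(r, c, array)
            if s <= lens.na:
                B += rgb
                x, y = led_offset_mm(r, c, array)
                hyp = np.hypot(np.hypot(x, y), array.height_mm)
                tilt += w * np.array([x / hyp, y / hyp])
                w_sum += w
            else:
                D += rgb
    if w_sum > 0:
        tilt /= w_sum
    return B / n_total, D / n_total, tilt


def _crop_window(
    phantom: Phantom,
    state: MicroscopeState,
    calib: MotorCalibration,
    frame_shape: Tuple[int, int],
) -> Tuple[slice, slice]:
    """Pixel window of the phantom seen at the current stage position.

    Stage +x moves the viewing window +x across the sample (image content
    translates left).  The window must lie fully inside the phantom.
    """
    fh, fw = frame_shape
    ph, pw = phantom.shape
    dx_px = round(state.stage_x_units / calib.xy_units_per_mm * 1000 / phantom.pixel_size_um)
    dy_px = round(state.stage_y_units / calib.xy_units_per_mm * 1000 / phantom.pixel_size_um)
    r0 = ph // 2 + dy_px - fh // 2
    c0 = pw // 2 + dx_px - fw // 2
    if r0 < 0 or c0 < 0 or r0 + fh > ph or c0 + fw > pw:
        raise RenderError(
            f"phantom ({ph}x{pw} px) does not cover the field of view at stage "
            f"({state.stage_x_units}, {state.stage_y_units}) units"
        )
    return slice(r0, r0 + fh), slice(c0, c0 + fw)


def _maybe_blur(m: np.ndarray, sigma_px: float) -> np.ndarray:
    # blur below ~1/3 px is unresolvable by the pixel grid; treat as in focus
    return m if sigma_px < 0.3 else gaussian_filter(m, sigma_px, mode="reflect")


def render(
    phantom: Phantom,
    state: MicroscopeState,
    exposure_ms: float = 10.0,
    noise: bool = False,
    *,
    array: LedArraySpec = LedArraySpec(),
    calib: MotorCalibration = MotorCalibration(),
    flexure: FlexureSpec = FlexureSpec(),
    frame_shape: Tuple[int, int] = (192, 256),
    base_counts_per_ms: float = 100.0,
    kappa: float = 0.2,
    defocus_um_per_um: float = 0.5,
    max_blur_px: float = 40.0,
    read_noise_counts: float = 2.0,
    fluor_leakage: float = 0.01,
    rng: Optional[np.random.Generator] = None,
    timestamp_s: float = 0.0,
    frame_index: int = 0,
) -> Frame:
    """Render a frame of ``phantom`` under the given instrument state.

    Deterministic for a fixed ``rng`` seed; with ``noise`` off, the expected
    counts are linear in ``exposure_ms`` until the 16-bit clip.
    """
    if exposure_ms <= 0:
        raise ValueError("exposure_ms must be positive")
    state.validate(calib)
    illum = state.illumination if state.illumination is not None else brightfield_pattern(array)
    rows, cols = _crop_window(phantom, state, calib, frame_shape)
    fh, fw = frame_shape

    # effective focus includes the flexure-arc sag at this stage deflection
    x_mm = state.stage_x_units / calib.xy_units_per_mm
    y_mm = state.stage_y_units / calib.xy_units_per_mm
    sag_mm = flexure_sag(float(np.hypot(x_mm, y_mm)), flexure)
    focus_mm = state.focus_z_units / calib.z_units_per_mm - sag_mm

    def layer_sigma(layer) -> float:
        plane_mm = state.lens.coarse_offset_units / calib.z_units_per_mm + layer.z_mm
        sigma_um = defocus_um_per_um * abs(focus_mm - plane_mm) * 1000.0
        return min(sigma_um / phantom.pixel_size_um, max_blur_px)

    tint = np.asarray(phantom.colour_tint if phantom.colour_tint else (1.0, 1.0, 1.0))
    I0 = base_counts_per_ms * exposure_ms
    expected = np.zeros((fh, fw, 3))

    if isinstance(illum, (IlluminationPattern, FlexiLamp)):
        if isinstance(illum, FlexiLamp):
            B = np.ones(3)
            D = np.zeros(3)
            az = np.deg2rad(illum.azimuth_deg)
            tilt = illum.tilt_sine * np.array([np.cos(az), np.sin(az)])
        else:
            B, D, tilt = _pattern_decomposition(illum, array, state.lens)
        absorb = np.zeros((fh, fw))
        grad_term = np.zeros((fh, fw))
        scatter = np.zeros((fh, fw))
        for layer in phantom.layers:
            sig = layer_sigma(layer)
            if layer.absorbance is not None:
                absorb += _maybe_blur(layer.absorbance[rows, cols], sig)
            if layer.phase is not None and tilt.any():
                gy, gx = np.gradient(_maybe_blur(layer.phase[rows, cols], sig))
                grad_term += gx * tilt[0] + gy * tilt[1]
            if layer.scatter is not None and D.any():
                scatter += _maybe_blur(layer.scatter[rows, cols], sig)
        trans = np.exp(-absorb) * np.clip(1.0 + kappa * grad_term, 0.0, None)
        expected = I0 * (
            trans[..., None] * (B * tint)[None, None, :]
            + scatter[..., None] * D[None, None, :]
        )
    elif isinstance(illum, RingPattern):
        mean_rgb = illum.colors.mean(axis=0)
        scatter = np.zeros((fh, fw))
        for layer in phantom.layers:
            if layer.scatter is not None:
                scatter += _maybe_blur(layer.scatter[rows, cols], layer_sigma(layer))
        expected = I0 * scatter[..., None] * mean_rgb[None, None, :]
    elif isinstance(illum, FluorescenceIllumination):
        signal = np.zeros((fh, fw, 3))
        if state.fluor_led_on:
            for layer in phantom.layers:
                sig = layer_sigma(layer)
                for fl in layer.fluorophores.values():
                    if fl.excitation != illum.excitation:
                        continue
                    em = np.asarray(COLOUR_RGB.get(fl.emission, (0.0, 1.0, 0.0)))
                    signal += _maybe_blur(fl.map[rows, cols], sig)[..., None] * em
        expected = I0 * (signal + fluor_leakage)
    else:  # pragma: no cover
        raise RenderError(f"unsupported illumination {type(illum).__name__}")

    if noise:
        if rng is None:
            rng = np.random.default_rng(state.seed)
        counts = rng.poisson(np.clip(expected, 0, None)).astype(float)
        counts += rng.normal(0.0, read_noise_counts, size=counts.shape)
    else:
        counts = expected
    pixels = np.clip(np.round(counts), 0, 65535).astype(np.uint16)

    if isinstance(illum, (IlluminationPattern, RingPattern)):
        illum_meta = illum.to_jsonable()
    elif isinstance(illum, FluorescenceIllumination):
        illum_meta = {"label": "fluorescence", "excitation": illum.excitation}
    else:
        illum_meta = {
            "label": "flexi_lamp",
            "azimuth_deg": illum.azimuth_deg,
            "tilt_sine": illum.tilt_sine,
        }
    metadata = {
        "schema_version": 1,
        "timestamp_s": float(timestamp_s),
        "timestamp_iso": _dt.datetime.fromtimestamp(
            timestamp_s, tz=_dt.timezone.utc
        ).isoformat(),
        "exposure_ms": float(exposure_ms),
        "frame_index": int(frame_index),
        "seed": int(state.seed),
        "noise": bool(noise),
        "lens": state.lens.model_dump(),
        "stage_x_units": int(state.stage_x_units),
        "stage_y_units": int(state.stage_y_units),
        "focus_z_units": int(state.focus_z_units),
        "homed": bool(state.homed),
        "lid_open": bool(state.lid_open),
        "fluor_led_on": bool(state.fluor_led_on),
        "illumination": illum_meta,
        "phantom": phantom.name,
        "pixel_size_um": float(phantom.pixel_size_um),
    }
    return Frame(pixels=pixels, metadata=metadata)


class VirtualMicroscope(Microscope):
    """Simulator backend: a :class:`Microscope` whose camera renders a
    phantom.

    Motion policy: any stage or focus motion before :meth:`home_focus` raises
    :class:`NotHomedError`; out-of-range targets are refused with no motion.
    The lid interlock is hard: enabling the fluorescence LED with the lid
    open raises, and opening the lid forces the LED off.

    Captures are deterministic: the noise stream for frame *k* is seeded by
    ``(seed, k)``, and timestamps come from a virtual clock that starts at 0
    and advances by each exposure, so identical command sequences reproduce
    bit-identical frames and metadata.
    """

    def __init__(
        self,
        phantom: Optional[Phantom] = None,
        lens: LensSpec = DEFAULT_LENSES["10x"],
        array: LedArraySpec = LedArraySpec(),
        ring: LedRingSpec = LedRingSpec(),
        calib: MotorCalibration = MotorCalibration(),
        flexure: FlexureSpec = FlexureSpec(),
        frame_shape: Tuple[int, int] = (192, 256),
        base_counts_per_ms: float = 100.0,
        kappa: float = 0.2,
        defocus_um_per_um: float = 0.5,
        max_blur_px: float = 40.0,
        noise: bool = False,
        read_noise_counts: float = 2.0,
        seed: int = 0,
    ) -> None:
        self.phantom = phantom
        self.array = array
        self.ring = ring
        self.calib = calib
        self.flexure = flexure
        self.frame_shape = tuple(frame_shape)
        self.base_counts_per_ms = base_counts_per_ms
        self.kappa = kappa
        self.defocus_um_per_um = defocus_um_per_um
        self.max_blur_px = max_blur_px
        self.noise = noise
        self.read_noise_counts = read_noise_counts
        self.seed = int(seed)
        self._lens = lens
        self._illumination: Illumination = brightfield_pattern(array)
        self._x = 0
        self._y = 0
        self._z = 0
        self._homed = False
        self._lid_open = False
        self._fluor_on = False
        self._frame_index = 0
        self._clock_s = 0.0

    # -- state ----------------------------------------------------------
    @property
    def state(self) -> MicroscopeState:
        return MicroscopeState(
            stage_x_units=self._x,
            stage_y_units=self._y,
            focus_z_units=self._z,
            homed=self._homed,
            lens=self._lens,
            illumination=self._illumination,
            lid_open=self._lid_open,
            fluor_led_on=self._fluor_on,
            seed=self.seed,
        )

    @property
    def fov_mm(self) -> Tuple[float, float]:
        """Simulated field of view (width, height) in mm at the sample."""
        if self.phantom is None:
            raise RenderError("no phantom loaded")
        fh, fw = self.frame_shape
        return (
            fw * self.phantom.pixel_size_um / 1000.0,
            fh * self.phantom.pixel_size_um / 1000.0,
        )

    # -- motion ---------------------------------------------------------
    def home_focus(self) -> None:
        self._z = 0
        self._homed = True

    def _require_homed(self) -> None:
        if not self._homed:
            raise NotHomedError("home the focus drive before moving")

    def move_stage(self, x_units: int, y_units: int) -> None:
        self._require_homed()
        half = self.calib.xy_travel_mm / 2 * self.calib.xy_units_per_mm
        for name, u in (("x", x_units), ("y", y_units)):
            if abs(u) > half:
                raise StageLimitError(
                    f"{name} target {u} units exceeds +/-{half:g} units travel"
                )
        self._x, self._y = int(x_units), int(y_units)

    def move_focus(self, z_units: int) -> None:
        self._require_homed()
        z_max = self.calib.z_range_mm * self.calib.z_units_per_mm
        if not 0 <= z_units <= z_max:
            raise FocusLimitError(f"z target {z_units} outside 0..{z_max:g} units")
        self._z = int(z_units)

    # -- configuration --------------------------------------------------
    def set_lens(self, lens: LensSpec) -> None:
        self._lens = lens

    def set_illumination(self, illumination: Illumination) -> None:
        self._illumination = illumination

    # -- lid / interlock ------------------------------------------------
    def open_lid(self) -> None:
        self._lid_open = True
        self._fluor_on = False  # interlock: opening the lid cuts the LED

    def close_lid(self) -> None:
        self._lid_open = False

    def set_fluorescence_led(self, on: bool) -> None:
        if on and self._lid_open:
            raise InterlockError("lid open: fluorescence LED blocked by interlock")
        self._fluor_on = bool(on)

    # -- camera ---------------------------------------------------------
    def capture(self, exposure_ms: float = 10.0) -> Frame:
        if self.phantom is None:
            raise RenderError("no phantom loaded")
        rng = np.random.default_rng([self.seed, self._frame_index]) if self.noise else None
        frame = render(
            self.phantom,
            self.state,
            exposure_ms=exposure_ms,
            noise=self.noise,
            array=self.array,
            calib=self.calib,
            flexure=self.flexure,
            frame_shape=self.frame_shape,
            base_counts_per_ms=self.base_counts_per_ms,
            kappa=self.kappa,
            defocus_um_per_um=self.defocus_um_per_um,
            max_blur_px=self.max_blur_px,
            read_noise_counts=self.read_noise_counts,
            rng=rng,
            timestamp_s=self._clock_s,
            frame_index=self._frame_index,
        )
        self._frame_index += 1
        self._clock_s += exposure_ms / 1000.0
        return frame

    def advance_clock(self, seconds: float) -> None:
        """Advance the virtual acquisition clock (used by time-lapse)."""
        if seconds < 0:
            raise ValueError("cannot rewind the clock")
        self._clock_s += seconds
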