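"""Run configuration: the single YAML/JSON document that fixes the
instrument geometry, calibrations, simulator settings and phantom choice.

All nested specs re-use the pydantic models of :mod:`ledscope.geometry`, so
a config file is validated field by field on load (unknown keys are
rejected) and round-trips losslessly.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Literal, Optional, Tuple, Union

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .geometry import (
    DEFAULT_LENSES,
    FlexureSpec,
    LedArraySpec,
    LedRingSpec,
    LensSpec,
    MotorCalibration,
    SensorSpec,
)
from .microscope import VirtualMicroscope
from .phantoms import (
    Phantom,
    make_blob_field,
    make_dye_puddles,
    make_fibre_mesh,
    make_graticule,
    make_phase_ramp,
)

__all__ = [
    "SimulatorConfig",
    "PhantomConfig",
    "RunConfig",
    "default_config",
    "load_config",
    "save_config",
    "build_phantom",
    "build_microscope",
]

#: Default sensor: the named 8-megapixel CMOS format (3280 x 2464 px at
#: 1.12 um pitch).  The physical size is not an instrument calibration, so
#: it is overridable in config.
DEFAULT_SENSOR = SensorSpec(width_px=3280, height_px=2464, pixel_pitch_um=1.12)


class SimulatorConfig(BaseModel):
    """Virtual-camera and forward-model settings."""

    model_config = ConfigDict(extra="forbid")

    frame_height_px: int = Field(default=192, gt=0)
    frame_width_px: int = Field(default=256, gt=0)
    base_counts_per_ms: float = Field(default=100.0, gt=0)
    kappa: float = Field(default=0.2, ge=0)
    defocus_um_per_um: float = Field(default=0.5, ge=0)
    max_blur_px: float = Field(default=40.0, gt=0)
    noise: bool = False
    read_noise_counts: float = Field(default=2.0, ge=0)
    seed: int = 0
    exposure_ms: float = Field(default=10.0, gt=0)


class PhantomConfig(BaseModel):
    """Which synthetic specimen to load and with what parameters."""

    model_config = ConfigDict(extra="forbid")

    kind: Literal[
        "blob_field", "graticule", "fibre_mesh", "phase_ramp", "dye_puddles"
    ] = "blob_field"
    size_px: Tuple[int, int] = (256, 256)
    pixel_size_um: float = Field(default=2.0, gt=0)
    params: dict = Field(default_factory=dict)


class RunConfig(BaseModel):
    """Complete run configuration."""

    model_config = ConfigDict(extra="forbid")

    lenses: Dict[str, LensSpec] = Field(default_factory=lambda: dict(DEFAULT_LENSES))
    default_lens: str = "10x"
    sensor: SensorSpec = DEFAULT_SENSOR
    led_array: LedArraySpec = LedArraySpec()
    led_ring: LedRingSpec = LedRingSpec()
    calibration: MotorCalibration = MotorCalibration()
    flexure: FlexureSpec = FlexureSpec()
    simulator: SimulatorConfig = SimulatorConfig()
    phantom: PhantomConfig = PhantomConfig()

    def lens(self, name: Optional[str] = None) -> LensSpec:
        key = name or self.default_lens
        if key not in self.lenses:
            raise KeyError(
                f"unknown lens {key!r}; available: {sorted(self.lenses)}"
            )
        return self.lenses[key]


def default_config() -> RunConfig:
    return RunConfig()


def load_config(path: Union[str, Path]) -> RunConfig:
    """Load and validate a YAML (or JSON) run configuration."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return RunConfig.model_validate(data or {})


def save_config(config: RunConfig, path: Union[str, Path]) -> None:
    path = Path(path)
    data = json.loads(config.model_dump_json())
    with open(path, "w") as fh:
        if path.suffix == ".json":
            json.dump(data, fh, indent=2)
        else:
            yaml.safe_dump(data, fh, sort_keys=False)


_PHANTOM_BUILDERS = {
    "blob_field": make_blob_field,
    "graticule": make_graticule,
    "fibre_mesh": make_fibre_mesh,
    "phase_ramp": make_phase_ramp,
    "dye_puddles": make_dye_puddles,
}


def build_phantom(config: RunConfig) -> Phantom:
    pc = config.phantom
    builder = _PHANTOM_BUILDERS[pc.kind]
    return builder(size_px=tuple(pc.size_px), pixel_size_um=pc.pixel_size_um, **pc.params)


def build_microscope(
    config: RunConfig, phantom: Optional[Phantom] = None
) -> VirtualMicroscope:
    """Instantiate the simulator backend described by a config."""
    sim = config.simulator
    return VirtualMicroscope(
        phantom=phantom if phantom is not None else build_phantom(config),
        lens=config.lens(),
        array=config.led_array,
        ring=config.led_ring,
        calib=config.calibration,
        flexure=config.flexure,
        frame_shape=(sim.frame_height_px, sim.frame_width_px),
        base_counts_per_ms=sim.base_counts_per_ms,
        kappa=sim.kappa,
        defocus_um_per_um=sim.defocus_um_per_um,
        max_blur_px=sim.max_blur_px,
        noise=sim.noise,
        read_noise_counts=sim.read_noise_counts,
        seed=sim.seed,
    )
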