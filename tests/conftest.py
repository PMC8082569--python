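import numpy as np
import pytest

from ledscope import (
    DEFAULT_LENSES,
    LedArraySpec,
    MotorCalibration,
    VirtualMicroscope,
    make_blob_field,
    make_fibre_mesh,
)


@pytest.fixture(scope="session")
def array():
    return LedArraySpec()


@pytest.fixture(scope="session")
def calib():
    return MotorCalibration()


@pytest.fixture(scope="session")
def lenses():
    return DEFAULT_LENSES


@pytest.fixture(scope="session")
def fibre_phantom():
    """Dense textured specimen: every overlap strip carries content."""
    return make_fibre_mesh(seed=5, density=0.15, size_px=(512, 512), pixel_size_um=2.0)


@pytest.fixture()
def blob_scope():
    """Small in-focus microscope over a blob field, ready to capture."""
    scope = VirtualMicroscope(
        phantom=make_blob_field(n=25, seed=1, size_px=(256, 256)),
        frame_shape=(96, 96),
    )
    scope.home_focus()
    scope.move_focus(DEFAULT_LENSES["10x"].coarse_offset_units)
    return scope


def brute_force_led_classes(array, na):
    """Independent trigonometric classification of every LED (oracle)."""
    import math

    outside = set()
    for r in range(array.n_rows):
        for c in range(array.n_cols):
            x = (c - (array.n_cols - 1) / 2) * array.pitch_mm
            y = (r - (array.n_rows - 1) / 2) * array.pitch_mm
            rad = math.sqrt(x * x + y * y)
            if rad / math.sqrt(rad * rad + array.height_mm**2) > na:
                outside.add((r, c))
    return outside
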