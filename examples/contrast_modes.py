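"""Render one specimen under the main contrast modes.

A pollen-like blob field is imaged in brightfield (absorption contrast),
darkfield (scatter only, dark background) and fluorescence (blue excitation,
emission into the green channel).  A transparent phase ramp shows why
oblique illumination matters: it is invisible in brightfield, but the
normalised difference of two opposite oblique images (pseudo-phase) reads
out its gradient.
"""

import numpy as np

from ledscope import (
    DEFAULT_LENSES,
    FluorescenceIllumination,
    VirtualMicroscope,
    darkfield_pattern,
    make_blob_field,
    make_phase_ramp,
    pseudo_phase,
    pseudo_phase_pair,
)

lens4 = DEFAULT_LENSES["4x"]
scope = VirtualMicroscope(
    phantom=make_blob_field(n=20, seed=0, size_px=(256, 256)),
    lens=lens4, frame_shape=(128, 128),
)
scope.home_focus()
scope.move_focus(lens4.coarse_offset_units)

bf = scope.capture().luminance
print(f"brightfield: background {bf.max():.0f} counts, darkest blob {bf.min():.0f}")

scope.set_illumination(darkfield_pattern(scope.array, lens4))
df = scope.capture().luminance
print(f"darkfield:   background {df.min():.0f} counts, brightest scatterer {df.max():.0f}")

scope.set_illumination(FluorescenceIllumination(excitation="blue"))
scope.close_lid()
scope.set_fluorescence_led(True)
fl = scope.capture().pixels
print(f"fluorescence: green-channel peak {fl[..., 1].max()} vs red leakage {fl[..., 0].max()}")

# pseudo-phase on a transparent wedge, 40x so the strips sit inside the NA cone
lens40 = DEFAULT_LENSES["40x"]
wedge = VirtualMicroscope(
    phantom=make_phase_ramp(direction_deg=0, slope_rad_per_um=0.02, size_px=(128, 128)),
    lens=lens40, frame_shape=(96, 96),
)
wedge.home_focus()
wedge.move_focus(lens40.coarse_offset_units)
print(f"phase ramp in brightfield: std {wedge.capture().luminance.std():.2f} (invisible)")
left, right = pseudo_phase_pair(wedge.array)
wedge.set_illumination(left)
fa = wedge.capture(200.0)
wedge.set_illumination(right)
fb = wedge.capture(200.0)
pp = pseudo_phase(fa, fb).values
print(f"pseudo-phase mean {pp.mean():+.4f}: sign encodes the gradient direction")
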