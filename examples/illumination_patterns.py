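"""Generate the LED-array patterns behind each contrast mode.

For each objective we count how many of the 64 LEDs fall outside its
acceptance cone — those are the LEDs a darkfield pattern lights.  With the
40x (NA 0.65) every LED is inside the cone, so darkfield is geometrically
impossible with the default array.
"""

from ledscope import (
    DEFAULT_LENSES,
    LedArraySpec,
    brightfield_pattern,
    darkfield_pattern,
    oblique_pattern,
    pseudo_phase_pair,
)
from ledscope.illumination import DarkfieldImpossibleError

array = LedArraySpec()  # 8x8, 4 mm pitch, 25 mm below the sample

print(f"brightfield: {brightfield_pattern(array).n_lit} LEDs lit")
print(f"oblique left strip (width 2): {oblique_pattern(array, 'left', 2).n_lit} LEDs lit")
left, right = pseudo_phase_pair(array)
print(f"pseudo-phase pair: {left.n_lit} + {right.n_lit} LEDs, mirror strips")

for name, lens in DEFAULT_LENSES.items():
    try:
        pat = darkfield_pattern(array, lens)
        print(f"darkfield with {name} (NA {lens.na}): {pat.n_lit}/64 LEDs outside the cone")
    except DarkfieldImpossibleError:
        print(f"darkfield with {name} (NA {lens.na}): impossible, all LEDs inside the cone")
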