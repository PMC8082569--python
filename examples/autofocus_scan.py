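"""Coarse + fine autofocus on a specimen at an unknown height.

The specimen layer is displaced 0.4 mm above the lens's nominal focus.
Coarse focus applies the fixed per-lens offset from home; the fine scan
steps through Z scoring each image with the normalised variance and moves
to the best position.
"""

from ledscope import DEFAULT_LENSES, VirtualMicroscope, coarse_focus, make_blob_field, scan_focus

lens = DEFAULT_LENSES["10x"]
true_offset_mm = 0.4
scope = VirtualMicroscope(
    phantom=make_blob_field(n=25, seed=3, size_px=(128, 128), z_mm=true_offset_mm),
    frame_shape=(96, 96),
)
scope.home_focus()
coarse_focus(scope, lens)
print(f"coarse focus: z = {scope.state.focus_z_units} units (lens table offset)")

result = scan_focus(scope, z_center=2000, half_range=1000, step=50)
z_true = lens.coarse_offset_units + true_offset_mm * 1000
print(f"fine scan over {len(result.z_positions)} positions, unimodal={result.unimodal}")
for z, s in list(zip(result.z_positions, result.scores))[::8]:
    print(f"  z={z:5d}  score={s:.4f}")
print(f"best z = {result.best_z} units; true focus = {z_true:.0f} units "
      f"(error {abs(result.best_z - z_true):.0f} units, step was 50)")
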