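# Methods

This note documents the models, numerical choices and limitations behind
`ledscope`: what the simulator computes, why its defaults are what they
are, and what passing the test suite does and does not demonstrate about a
physical instrument.

## Instrument geometry

The package models an inverted microscope with finite-conjugate dry
objectives that image the sample directly onto the camera, so the
sample-plane field of view is the sensor's physical extent divided by the
magnification.  The default sensor is the named 8-megapixel CMOS format
(3280 × 2464 px at 1.12 µm pitch); its physical size is public information
about the part, not an instrument calibration, and is overridable in
config.

Transmitted illumination comes from an 8×8 white LED array centred on the
optical axis.  The array's pitch (4 mm) and height above the sample
(25 mm) are **assumptions** — they are mechanical properties of a
particular build, not published constants — and both are config fields.
With these defaults the corner LED illuminates at sin θ ≈ 0.62, so
darkfield is available for the 0.12/0.25/0.35 NA lenses but not for the
0.65 NA lens, whose acceptance cone swallows the whole array.  An LED
exactly on the NA boundary counts as *inside*, so darkfield patterns never
include boundary LEDs (conservative darkfield); no angular margin beyond
the NA is applied.

Motor calibrations: the Z drive is treated as exactly 1000 units/mm (the
instrument's nominal 100 units per 0.1 mm), with a 4 mm range from the
home switch; the XY flexure stage travels 3 mm per axis (±1.5 mm about the
centred origin).  Only the Z calibration is a published value; XY uses the
same scale as a default.  Per-lens coarse-focus offsets are instrument
calibrations; the defaults (1500/1800/2000/2100 units for 4×–40×) are
plausible mid-range values chosen once and used consistently by the tests
and phantoms.

The flexure stage's platform travels on a circular arc of radius equal to
the beam length L (default 30 mm), so a lateral deflection *d* lowers the
platform by L − √(L² − d²) — about 3 µm at 0.43 mm deflection.  The
simulator applies this sag as a focus perturbation at every render.  The
mosaic orchestrator (`acquire_mosaic`) compensates it by default: the
backend exposes its calibration and flexure geometry, so the commanded
focus is raised per tile by the known sag, as a real instrument driver
would.  Residual error is below half a motor unit (≤ 0.25 px of blur at
the default pixel size), which the renderer treats as in focus (see
below).

## Forward model

The renderer is a first-order geometric-optics caricature, chosen to
reproduce the *qualitative* behaviour of each contrast mode rather than
wave optics.  Per colour channel c, with exposure *t* and base flux I₀
(default 100 counts/ms):

* transmitted modes:
  `I_c = I0·t·[ B_c·tint_c·exp(−A)·max(0, 1 + κ·∇φ·s) + D_c·S ]`
* reflected ring: `I_c = I0·t·ring_c·S`
* fluorescence: `I_c = I0·t·[ Σ_f exc(f)·em_c(f)·F_f + leak ]`, with
  `leak = 0.01` and the signal term present only while the excitation LED
  is on.

Here A, φ, S, F are the phantom's absorbance, phase, scatter and
fluorophore maps; B_c and D_c are the summed intensities of the pattern's
LEDs inside and outside the lens NA cone, normalised by the grid size; and
**s** is the intensity-weighted mean tilt (sine) vector of the lit
inside-NA LEDs.  Consequences worth noting:

* a symmetric pattern (brightfield) has **s** = 0, so pure phase objects
  are invisible — the motivating failure that oblique illumination fixes;
* a pattern entirely outside the NA cone has B = 0: the background is
  exactly zero and only scatter is imaged (darkfield);
* the oblique gradient term is linear with gain κ (default 0.2), clipped
  so intensities stay non-negative.  With the default array geometry the
  outermost strips lie outside the NA of the low-NA lenses and therefore
  render as darkfield; gradient-contrast demonstrations use the 40× lens
  (whole array inside NA 0.65) or wider strips.  This is a real geometric
  property of sharp-cutoff models, not an implementation accident.

Layers defocus independently: a layer at axial distance Δz from the
current focus is blurred with a Gaussian of width
σ_µm = 0.5·|Δz|·1000·(µm/mm), capped at 40 px so far-out-of-focus planes
saturate to "fully blurred" instead of demanding unbounded kernels.  Blur
below 0.3 px is skipped — it is unresolvable by the pixel grid and would
otherwise leak sub-quantisation artefacts into exact-reassembly checks.
Defocus is applied to the cropped field with reflective boundaries.

Noise, when enabled, is Poisson shot noise on the expected counts (gain
1 count/e⁻) plus Gaussian read noise (σ = 2 counts), generated from a
stream seeded by `(seed, frame_index)` and recorded in metadata.  Pixels
are rounded and clipped to 16 bits.  Timestamps come from a **virtual
clock** that starts at zero and advances by each exposure (and by the
interval during time-lapse), so a command sequence re-run with the same
config and seed reproduces every output file bit for bit, metadata
included.

Stage sign convention: +x moves the viewing window +x across the specimen,
so image content translates left.  Image arrays are row-major with the
origin top-left; crops are half-open.

## Phantoms

The synthetic specimens emulate the classic test samples of such an
instrument: a stage graticule (absorbing rulings at a known pitch), fields
of pollen-like discs (absorbing + scattering + blue-excited green
autofluorescence), a fibre mesh emulating dye-stained lens tissue
(fluorescent and absorbing only on fibres; chords are added until the
requested coverage is reached), adjacent green/red dye puddles, and pure
phase ramps for validating gradient contrast.  They model planar layers
with independent axial positions; they do **not** model 3-D structure
within a layer, spectral emission curves, photobleaching, or optical
aberrations, so passing tests demonstrate correctness of the *control and
processing* pipeline, not photometric realism.

The stitching tests use the fibre mesh deliberately: registering a
translation requires texture in every overlap strip, and a sparse random
blob field can legitimately present a featureless (unregistrable) overlap,
for which the correct behaviour is the low-confidence fallback, not a
recovered offset.

## Autofocus

The sharpness metric is the normalised variance var/mean² of luminance:
zero for constant images, invariant under global intensity scaling, and
monotonically degraded by blur.  Plain variance and Tenengrad are
available behind a keyword.  The fine scan evaluates an inclusive
arithmetic grid, breaks ties toward lower Z, raises "no focus found" when
the response is flat, and leaves the instrument at the best position.  An
optional parabolic refinement of the top three points exists but is off by
default — the documented behaviour is the plain arg-max.  Parameter
recovery is validated over 20 seeded phantoms with true focus uniform in
the central 2 mm of the 4 mm range, scanned at 50-unit steps: the error
stays within one step without noise and two steps with noise.

## Tiling, stitching, extended focus

Tile grids are planned in snake-by-rows order with per-axis
centre-to-centre step (1 − overlap)·FOV; the same overlap fraction applies
to both axes.  Stage targets are quantised toward zero to integer motor
units (after trimming float noise at 10⁻⁶ units) and the sub-unit
residuals are stored in the plan for the stitcher.  Plans that would
exceed the stage travel are refused naming the violating axis.

Pairwise registration matches the overlap strip of one tile, inset by the
search radius on the side facing the neighbour's edge, as a normalised
cross-correlation template inside the neighbour (computed in the frequency
domain via `skimage.feature.match_template`).  The search is bounded to a
window around the plan's nominal offset (default radius 10% of the tile
size) and the NCC peak value serves as the confidence score.  A whitened
phase-correlation variant was evaluated and rejected: on smooth, sparse
simulated content the whitened spectrum is dominated by the shared
window-frame discontinuity, producing a spurious zero-lag peak, whereas
bounded NCC is exact there; `phase_cross_correlation` is retained as an
independent cross-check in the tests on broadband content.  Near-constant
templates (relative contrast ≤ 10⁻⁴) are reported unregistrable with
confidence 0.

Global placement propagates pair offsets from the anchor tile along the
snake order; pairs with confidence below 0.3 fall back to the nominal
step.  No global least-squares adjustment is performed — at 3×3/5×5 scale
the chain is short and the simpler scheme is fully verifiable.  Overlap
bands are feathered linearly, so a stitch of exact tiles reproduces the
source scene pixel for pixel by construction.

Extended depth of field selects, per pixel, the slice with the highest
luminance variance in a 9×9 window (ties to the lower slice index) and
composites values from the chosen slices.  No pyramid fusion is applied.
Background pixels, where all slices tie at zero variance, default to slice
0; the permutation-invariance property therefore holds on content pixels.

## Problem sizes

The shipped tests and the acceptance script run the simulator at reduced
frame sizes (48–128 px tiles over 256–512 px phantoms, 21-slice stacks,
3×3 mosaics, 20-phantom autofocus sweeps).  These sizes were chosen as the
smallest at which every validated property is comfortably measurable
(e.g. registration strips of ≈38×128 px with guaranteed texture, blur
dynamics spanning sharp to saturated within the 4 mm Z range); the library
itself has no size assumptions beyond memory.

## Known limitations

* No pupil-plane wave propagation, aberrations, vignetting or Bayer
  mosaic; the 160 mm tube-length optics are geometry only (parfocal
  distance is metadata).
* Rheinberg ring rendering uses the mean ring colour for scatterers; the
  per-sector colouring of differently oriented structures is annotated in
  the pattern but not modelled by the orientation-free scatter map.
* The auxiliary gooseneck lamp is modelled as a single fixed large-angle
  oblique source, not a physical lamp.
* Polarised-light imaging and real stepper/GPIO drivers are out of scope;
  the hardware-abstraction contract is the integration point for the
  latter.
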