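"""Synthetic specimens ("phantoms") for the virtual microscope.

A phantom is a stack of planar layers, each at its own axial position, with
per-pixel maps of the physical properties the simulator renders:

* ``absorbance`` — optical density, attenuates transmitted light as exp(-A);
* ``phase``      — optical path length in radians; invisible in brightfield,
                   visible through its gradient under oblique illumination;
* ``scatter``    — scattering strength; the only signal in darkfield and
                   reflected-light modes;
* fluorophores   — named emission maps with excitation/emission colours.

The generators emulate classic test specimens: a graticule scale, fields of
pollen-like blobs, a fibre mesh stained with fluorescent dye, dye puddles,
and pure phase ramps for validating gradient contrast.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Dict, List, Optional, Tuple

import numpy as np

__all__ = [
    "Fluorophore",
    "PhantomLayer",
    "Phantom",
    "make_graticule",
    "make_blob_field",
    "make_fibre_mesh",
    "make_phase_ramp",
    "make_dye_puddles",
]

RGB = Tuple[float, float, float]

#: Nominal RGB weights used to couple LED colours to fluorophore excitation.
COLOUR_RGB: Dict[str, RGB] = {
    "blue": (0.0, 0.0, 1.0),
    "green": (0.0, 1.0, 0.0),
    "red": (1.0, 0.0, 0.0),
    "white": (1.0, 1.0, 1.0),
}


@dataclass
class Fluorophore:
    """A named fluorophore map with its excitation and emission colours."""

    map: np.ndarray  # (H, W) >= 0
    excitation: str = "blue"
    emission: str = "green"


@dataclass
class PhantomLayer:
    """One planar specimen layer at axial position ``z_mm`` (relative to the
    nominal sample plane of the current lens)."""

    shape: Tuple[int, int]
    z_mm: float = 0.0
    absorbance: Optional[np.ndarray] = None
    phase: Optional[np.ndarray] = None
    scatter: Optional[np.ndarray] = None
    fluorophores: Dict[str, Fluorophore] = dc_field(default_factory=dict)
    meta: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("absorbance", "phase", "scatter"):
            m = getattr(self, name)
            if m is None:
                continue
            m = np.asarray(m, dtype=float)
            if m.shape != tuple(self.shape):
                raise ValueError(f"{name} map shape {m.shape} != layer shape {self.shape}")
            if not np.isfinite(m).all():
                raise ValueError(f"{name} map contains non-finite values")
            if name != "phase" and m.min() < 0:
                raise ValueError(f"{name} map must be non-negative")
            setattr(self, name, m)
        for fname, fl in self.fluorophores.items():
            fl.map = np.asarray(fl.map, dtype=float)
            if fl.map.shape != tuple(self.shape):
                raise ValueError(f"fluorophore {fname!r} shape mismatch")
            if not np.isfinite(fl.map).all() or fl.map.min() < 0:
                raise ValueError(f"fluorophore {fname!r} map must be finite and >= 0")

    def get(self, name: str) -> np.ndarray:
        """Map by name, zeros if absent."""
        m = getattr(self, name)
        return m if m is not None else np.zeros(self.shape)


@dataclass
class Phantom:
    """Ground-truth synthetic sample: one or more layers on a common pixel
    grid with physical pixel size ``pixel_size_um`` at the sample plane."""

    pixel_size_um: float
    layers: List[PhantomLayer]
    colour_tint: Optional[RGB] = None
    name: str = "phantom"

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if not self.layers:
            raise ValueError("phantom needs at least one layer")
        shapes = {tuple(l.shape) for l in self.layers}
        if len(shapes) > 1:
            raise ValueError(f"layer shapes differ: {shapes}")

    @property
    def shape(self) -> Tuple[int, int]:
        return tuple(self.layers[0].shape)

    @property
    def extent_um(self) -> Tuple[float, float]:
        h, w = self.shape
        return (h * self.pixel_size_um, w * self.pixel_size_um)


def _empty_layer(size_px: Tuple[int, int], z_mm: float = 0.0) -> PhantomLayer:
    return PhantomLayer(shape=tuple(size_px), z_mm=z_mm)


def make_graticule(
    pitch_um: float = 100.0,
    line_width_um: float = 10.0,
    size_px: Tuple[int, int] = (256, 256),
    pixel_size_um: float = 2.0,
    absorbance: float = 2.0,
) -> Phantom:
    """Stage-graticule phantom: dark vertical rulings every ``pitch_um``.

    Line k is centred at x = k * pitch_um; lines whose centre lies inside the
    canvas are drawn, so the count is floor(extent / pitch) + 1 when the
    extent is not an exact multiple of the pitch.  Absorbance is zero between
    lines.
    """
    h, w = size_px
    x_um = (np.arange(w) + 0.5) * pixel_size_um
    nearest = np.round(x_um / pitch_um) * pitch_um
    on_line = (np.abs(x_um - nearest) < line_width_um / 2) & (
        nearest < w * pixel_size_um
    )
    amap = np.zeros((h, w))
    amap[:, on_line] = absorbance
    n_lines = int(np.floor((w * pixel_size_um - 1e-9) / pitch_um)) + 1
    layer = PhantomLayer(shape=(h, w), absorbance=amap, meta={"n_lines": n_lines})
    return Phantom(pixel_size_um=pixel_size_um, layers=[layer], name="graticule")


def _add_blobs(
    rng: np.random.Generator,
    shape: Tuple[int, int],
    n: int,
    radius_um: Tuple[float, float],
    pixel_size_um: float,
    amplitude: float,
) -> Tuple[np.ndarray, np.ndarray]:
    """Sum of soft-edged discs; returns (map, centres_px (n, 2) as (row, col))."""
    h, w = shape
    m = np.zeros(shape)
    yy, xx = np.mgrid[0:h, 0:w]
    r_lo, r_hi = radius_um
    centres = np.empty((n, 2))
    margin_px = r_hi / pixel_size_um
    for i in range(n):
        cy = rng.uniform(margin_px, h - margin_px)
        cx = rng.uniform(margin_px, w - margin_px)
        r_px = rng.uniform(r_lo, r_hi) / pixel_size_um
        d2 = (yy - cy) ** 2 + (xx - cx) ** 2
        # soft disc: flat core, sigmoid skirt over ~1 px
        from scipy.special import expit

        m += amplitude * expit(-(np.sqrt(d2) - r_px) / 0.75)
        centres[i] = (cy, cx)
    return m, centres


def make_blob_field(
    n: int = 30,
    radius_um: Tuple[float, float] = (8.0, 20.0),
    seed: int = 0,
    size_px: Tuple[int, int] = (256, 256),
    pixel_size_um: float = 2.0,
    z_mm: float = 0.0,
    absorbance: float = 1.0,
    scatter: float = 1.0,
    autofluorescence: float = 0.5,
) -> Phantom:
    """Pollen-grain-like field: ``n`` random discs that absorb, scatter and
    autofluoresce (blue excitation, green emission).  Deterministic per seed;
    centres recorded in the layer's ``meta['centres_px']``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    amap, centres = _add_blobs(rng, tuple(size_px), n, radius_um, pixel_size_um, 1.0)
    fluor = {}
    if autofluorescence > 0:
        fluor["autofluorescence"] = Fluorophore(
            map=autofluorescence * amap, excitation="blue", emission="green"
        )
    layer = PhantomLayer(
        shape=tuple(size_px),
        z_mm=z_mm,
        absorbance=absorbance * amap,
        scatter=scatter * amap,
        fluorophores=fluor,
        meta={"centres_px": centres, "n_blobs": n, "seed": seed},
    )
    return Phantom(pixel_size_um=pixel_size_um, layers=[layer], name="blob_field")


def make_fibre_mesh(
    seed: int = 0,
    density: float = 0.10,
    fluorophore_colour: str = "green",
    size_px: Tuple[int, int] = (256, 256),
    pixel_size_um: float = 2.0,
    fibre_width_px: int = 2,
    brightness: float = 1.0,
    absorbance: float = 1.0,
) -> Phantom:
    """Lens-tissue-like mesh of random fibres stained with a fluorescent dye.

    Random chords are added until the fraction of covered pixels reaches the
    requested ``density`` (so the realised coverage slightly overshoots it).
    The fluorophore map is nonzero exactly on the fibres.
    """
    from skimage.draw import line as sk_line
    from skimage.morphology import dilation, footprint_rectangle

    if not 0 < density < 1:
        raise ValueError("density must be in (0, 1)")
    rng = np.random.default_rng(seed)
    h, w = size_px
    mask = np.zeros((h, w), dtype=bool)
    foot = footprint_rectangle((fibre_width_px, fibre_width_px))
    target = density * h * w
    for _ in range(10000):
        if mask.sum() >= target:
            break
        r0, r1 = rng.integers(0, h, 2)
        c0, c1 = rng.integers(0, w, 2)
        seg = np.zeros((h, w), dtype=bool)
        rr, cc = sk_line(int(r0), int(c0), int(r1), int(c1))
        seg[rr, cc] = True
        mask |= dilation(seg, foot)
    fmap = brightness * mask.astype(float)
    layer = PhantomLayer(
        shape=(h, w),
        absorbance=absorbance * mask.astype(float),
        fluorophores={
            "dye": Fluorophore(map=fmap, excitation="blue", emission=fluorophore_colour)
        },
        meta={"coverage": float(mask.mean()), "seed": seed},
    )
    return Phantom(pixel_size_um=pixel_size_um, layers=[layer], name="fibre_mesh")


def make_phase_ramp(
    direction_deg: float = 0.0,
    slope_rad_per_um: float = 0.01,
    size_px: Tuple[int, int] = (256, 256),
    pixel_size_um: float = 2.0,
) -> Phantom:
    """Pure phase-gradient object: a transparent wedge.

    The phase increases linearly along ``direction_deg`` (CCW from +x, i.e.
    image columns) at ``slope_rad_per_um``; absorbance and scatter are zero,
    so the phantom is invisible in brightfield and darkfield and shows up
    only through oblique/pseudo-phase contrast.
    """
    h, w = size_px
    yy, xx = np.mgrid[0:h, 0:w]
    theta = np.deg2rad(direction_deg)
    coord_um = (xx * np.cos(theta) + yy * np.sin(theta)) * pixel_size_um
    phase = slope_rad_per_um * coord_um
    layer = PhantomLayer(shape=(h, w), phase=phase)
    return Phantom(pixel_size_um=pixel_size_um, layers=[layer], name="phase_ramp")


def make_dye_puddles(
    size_px: Tuple[int, int] = (256, 256),
    pixel_size_um: float = 2.0,
    brightness: float = 1.0,
) -> Phantom:
    """Two adjacent dried-down dye puddles (green- and red-emitting), both
    excited by the blue LED — a fluorescence alignment target."""
    h, w = size_px
    yy, xx = np.mgrid[0:h, 0:w]

    def puddle(cy, cx, r):
        return brightness / (1.0 + np.exp((np.hypot(yy - cy, xx - cx) - r) / 2.0))

    g = puddle(h / 2, w / 3, min(h, w) / 6)
    r = puddle(h / 2, 2 * w / 3, min(h, w) / 6)
    layer = PhantomLayer(
        shape=(h, w),
        absorbance=0.2 * (g + r),
        fluorophores={
            "green_dye": Fluorophore(map=g, excitation="blue", emission="green"),
            "red_dye": Fluorophore(map=r, excitation="blue", emission="red"),
        },
    )
    return Phantom(pixel_size_um=pixel_size_um, layers=[layer], name="dye_puddles")
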