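"""Pairwise registration, mosaic assembly and extended depth of field."""

import numpy as np
import pytest

from ledscope import (
    MotorCalibration,
    VirtualMicroscope,
    acquire_zstack,
    extended_focus,
    focus_metric,
    make_blob_field,
    pairwise_offset,
    plan_tiles,
    plan_z_series,
    stitch,
)
from ledscope.phantoms import Phantom
from ledscope.stitching import OverlapError

CALIB = MotorCalibration()


@pytest.fixture(scope="module")
def scene(fibre_phantom):
    """One noise-free render of the fibre-mesh phantom, used as the ground
    truth from which tiles are cropped."""
    m = VirtualMicroscope(phantom=fibre_phantom, frame_shape=(480, 480))
    m.home_focus()
    m.move_focus(1800)
    return m.capture(600.0).pixels.astype(float).mean(axis=2)


class TestPairwiseOffset:
    def test_identical_tiles_zero_shift_full_confidence(self, scene):
        tile = scene[:128, :128]
        assert pairwise_offset(tile, tile, (0, 0)) == (0, 0, pytest.approx(1.0, abs=1e-6))

    def test_known_70px_step_recovered_within_1px(self, scene):
        a = scene[100:228, 50:178]
        b = scene[100:228, 120:248]  # true offset (0, 70)
        dy, dx, conf = pairwise_offset(a, b, (0, 72))
        assert abs(dy - 0) <= 1 and abs(dx - 70) <= 1
        assert conf > 0.9

    def test_antisymmetric_within_1px(self, scene):
        a = scene[100:228, 50:178]
        b = scene[97:225, 117:245]
        d_ab = pairwise_offset(a, b, (-3, 67))
        d_ba = pairwise_offset(b, a, (3, -67))
        assert abs(d_ab[0] + d_ba[0]) <= 1 and abs(d_ab[1] + d_ba[1]) <= 1

    @pytest.mark.parametrize("seed", range(10))
    def test_pure_noise_pairs_flagged_low_confidence(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(500, 30, (128, 128))
        b = rng.normal(500, 30, (128, 128))
        _, _, conf = pairwise_offset(a, b, (0, 90))
        assert conf < 0.3

    def test_featureless_overlap_returns_nominal_zero_confidence(self):
        flat = np.full((128, 128), 500.0)
        dy, dx, conf = pairwise_offset(flat, flat, (0, 90))
        assert (dy, dx, conf) == (0, 90, 0.0)

    def test_insufficient_overlap_rejected(self, scene):
        a = scene[:128, :128]
        with pytest.raises(OverlapError):
            pairwise_offset(a, a, (0, 125))

    def test_cross_check_against_skimage_phase_correlation(self):
        # independent oracle on broadband content where both methods apply
        from skimage.registration import phase_cross_correlation

        rng = np.random.default_rng(0)
        scene = rng.uniform(0, 1, (200, 200))
        a = scene[40:168, 20:148]
        b = scene[36:164, 25:153]  # true (dy, dx) = (-4, 5)
        shift, *_ = phase_cross_correlation(a, b)
        dy, dx, _ = pairwise_offset(a, b, (0, 0))
        # skimage's registration shift equals b's scene offset in our convention
        assert (dy, dx) == (int(shift[0]), int(shift[1])) == (-4, 5)


def _crop_tiles(scene, plan, step_px, tile=128, jitter=None, margin=10):
    tiles = {}
    for i, p in enumerate(plan.positions):
        jy, jx = jitter[i] if jitter else (0, 0)
        r0 = margin + p.row * step_px + jy
        c0 = margin + p.col * step_px + jx
        tiles[(p.row, p.col)] = scene[r0 : r0 + tile, c0 : c0 + tile]
    return tiles


class TestStitch:
    def test_single_tile_mosaic_is_the_tile(self, scene):
        plan = plan_tiles(1, 1, 0.3, CALIB, tile_fov_mm=(0.256, 0.256))
        tile = scene[:128, :128]
        mos = stitch({(0, 0): tile}, plan)
        assert np.allclose(mos.image, tile)

    def test_missing_tiles_rejected(self, scene):
        plan = plan_tiles(2, 2, 0.3, CALIB, tile_fov_mm=(0.256, 0.256))
        with pytest.raises(ValueError, match="missing"):
            stitch({(0, 0): scene[:128, :128]}, plan)

    def test_exact_reassembly_of_noise_free_crops(self, scene):
        plan = plan_tiles(3, 3, 0.3, CALIB, tile_fov_mm=(0.256, 0.256))
        step_px = 90  # round(0.7 * 128)
        tiles = _crop_tiles(scene, plan, step_px, margin=0)
        mos = stitch(tiles, plan)
        src = scene[: 2 * step_px + 128, : 2 * step_px + 128]
        assert np.abs(mos.image - src).max() < 1e-9

    def test_jittered_tiles_placed_exactly(self, scene):
        plan = plan_tiles(3, 3, 0.3, CALIB, tile_fov_mm=(0.256, 0.256))
        step_px = 90
        rng = np.random.default_rng(11)
        jitter = [(int(rng.integers(-3, 4)), int(rng.integers(-3, 4))) for _ in range(9)]
        tiles = _crop_tiles(scene, plan, step_px, jitter=jitter)
        mos = stitch(tiles, plan)
        a_off = mos.offsets_px[(0, 0)]
        for i, p in enumerate(plan.positions):
            true_rel = (
                p.row * step_px + jitter[i][0] - jitter[0][0],
                p.col * step_px + jitter[i][1] - jitter[0][1],
            )
            o = mos.offsets_px[(p.row, p.col)]
            rel = (o[0] - a_off[0], o[1] - a_off[1])
            assert abs(rel[0] - true_rel[0]) <= 1 and abs(rel[1] - true_rel[1]) <= 1

    def test_refine_off_uses_nominal_grid(self, scene):
        plan = plan_tiles(2, 2, 0.3, CALIB, tile_fov_mm=(0.256, 0.256))
        tiles = _crop_tiles(scene, plan, 90, margin=0)
        mos = stitch(tiles, plan, refine=False)
        assert mos.offsets_px == {(0, 0): (0, 0), (0, 1): (0, 90), (1, 0): (90, 0), (1, 1): (90, 90)}


def two_plane_phantom():
    l0 = make_blob_field(n=12, seed=1, size_px=(160, 160), pixel_size_um=4.0, z_mm=0.0).layers[0]
    l1 = make_blob_field(n=12, seed=2, size_px=(160, 160), pixel_size_um=4.0, z_mm=1.0).layers[0]
    return Phantom(pixel_size_um=4.0, layers=[l0, l1])


class TestExtendedFocus:
    def test_identical_slices_give_constant_index_map(self):
        rng = np.random.default_rng(0)
        s = rng.uniform(0, 100, (32, 32))
        res = extended_focus([s, s.copy(), s.copy()])
        assert np.all(res.index_map == 0)
        assert np.allclose(res.composite, s)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            extended_focus([np.zeros((8, 8)), np.zeros((9, 8))])

    def test_two_plane_stack_assigns_pixels_to_their_plane(self):
        ph = two_plane_phantom()
        m = VirtualMicroscope(phantom=ph, frame_shape=(128, 128))
        m.home_focus()
        plan = plan_z_series(1300, 100, 21, CALIB)  # brackets 1800 and 2800
        frames = acquire_zstack(m, plan)
        res = extended_focus(frames)
        crop = slice(16, 144)
        in0 = ph.layers[0].absorbance[crop, crop] > 0.3
        in1 = ph.layers[1].absorbance[crop, crop] > 0.3
        only0, only1 = in0 & ~in1, in1 & ~in0
        # layer planes sit at slices 5 (z=1800) and 15 (z=2800)
        acc0 = (np.abs(res.index_map[only0] - 5) <= 1).mean()
        acc1 = (np.abs(res.index_map[only1] - 15) <= 1).mean()
        assert acc0 >= 0.95 and acc1 >= 0.95

    def test_composite_at_least_as_sharp_as_any_slice(self):
        ph = two_plane_phantom()
        m = VirtualMicroscope(phantom=ph, frame_shape=(128, 128))
        m.home_focus()
        frames = acquire_zstack(m, plan_z_series(1300, 100, 21, CALIB))
        best_slice = max(focus_metric(f) for f in frames)
        assert focus_metric(res := extended_focus(frames).composite) >= best_slice - 1e-6
        assert res.shape[:2] == (128, 128)

    def test_index_map_permutation_invariant(self):
        ph = two_plane_phantom()
        m = VirtualMicroscope(phantom=ph, frame_shape=(96, 96))
        m.home_focus()
        frames = acquire_zstack(m, plan_z_series(1600, 200, 7, CALIB))
        fwd = extended_focus(frames)
        perm = [3, 0, 6, 1, 5, 2, 4]
        rev = extended_focus([frames[i] for i in perm])
        relabel = np.array(perm)[rev.index_map]
        # ties (featureless background) are broken by slice order, so compare
        # only where the stack actually varies
        lum = np.stack([f.luminance for f in frames])
        content = np.ptp(lum, axis=0) > 0.02 * np.ptp(lum)
        assert np.array_equal(relabel[content], fwd.index_map[content])
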