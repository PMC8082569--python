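"""Virtual microscope: state machine, safety interlock, and forward model."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ledscope import (
    DEFAULT_LENSES,
    FluorescenceIllumination,
    InterlockError,
    LedArraySpec,
    NotHomedError,
    Phantom,
    PhantomLayer,
    StageLimitError,
    VirtualMicroscope,
    brightfield_pattern,
    darkfield_pattern,
    make_blob_field,
    make_graticule,
    make_phase_ramp,
    pseudo_phase,
    pseudo_phase_pair,
)
from ledscope.microscope import FocusLimitError, RenderError


def empty_phantom(size=96):
    return Phantom(pixel_size_um=2.0, layers=[PhantomLayer(shape=(size, size))])


def scope_with(phantom, **kw):
    m = VirtualMicroscope(phantom=phantom, frame_shape=(64, 64), **kw)
    m.home_focus()
    m.move_focus(m.state.lens.coarse_offset_units)
    return m


class TestMotionPolicy:
    def test_moves_before_homing_rejected(self):
        m = VirtualMicroscope(phantom=empty_phantom())
        with pytest.raises(NotHomedError):
            m.move_stage(0, 0)
        with pytest.raises(NotHomedError):
            m.move_focus(100)

    def test_home_is_idempotent_and_zeroes_focus(self):
        m = VirtualMicroscope(phantom=empty_phantom())
        m.home_focus()
        m.move_focus(500)
        m.home_focus()
        m.home_focus()
        assert m.state.focus_z_units == 0 and m.state.homed

    def test_stage_accepts_full_travel_and_refuses_beyond(self):
        m = VirtualMicroscope(phantom=empty_phantom())
        m.home_focus()
        m.move_stage(1500, -1500)  # +/-1.5 mm at 1000 units/mm
        assert (m.state.stage_x_units, m.state.stage_y_units) == (1500, -1500)
        with pytest.raises(StageLimitError):
            m.move_stage(1501, 0)
        # refused move leaves position unchanged
        assert (m.state.stage_x_units, m.state.stage_y_units) == (1500, -1500)

    def test_focus_range_enforced(self):
        m = VirtualMicroscope(phantom=empty_phantom())
        m.home_focus()
        m.move_focus(4000)
        with pytest.raises(FocusLimitError):
            m.move_focus(4001)
        with pytest.raises(FocusLimitError):
            m.move_focus(-1)


class TestInterlock:
    def test_enable_with_lid_closed(self):
        m = VirtualMicroscope(phantom=empty_phantom())
        m.close_lid()
        m.set_fluorescence_led(True)
        assert m.state.fluor_led_on

    def test_enable_with_lid_open_refused(self):
        m = VirtualMicroscope(phantom=empty_phantom())
        m.open_lid()
        with pytest.raises(InterlockError):
            m.set_fluorescence_led(True)
        assert not m.state.fluor_led_on

    def test_opening_lid_forces_led_off(self):
        m = VirtualMicroscope(phantom=empty_phantom())
        m.close_lid()
        m.set_fluorescence_led(True)
        m.open_lid()
        assert not m.state.fluor_led_on

    @given(st.lists(st.sampled_from(["open", "close", "on", "off"]), max_size=40))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_led_never_on_with_lid_open_over_any_sequence(self, ops):
        m = VirtualMicroscope(phantom=empty_phantom())
        for op in ops:
            if op == "open":
                m.open_lid()
            elif op == "close":
                m.close_lid()
            elif op == "on":
                try:
                    m.set_fluorescence_led(True)
                except InterlockError:
                    pass
            else:
                m.set_fluorescence_led(False)
            assert not (m.state.fluor_led_on and m.state.lid_open)


class TestForwardModel:
    def test_empty_phantom_brightfield_is_uniform_at_base_level(self):
        from ledscope import classify_led

        m = scope_with(empty_phantom())
        f = m.capture(10.0)
        # base level = I0 * fraction of the array inside the lens NA cone
        inside = sum(
            classify_led(r, c, m.array, m.state.lens) == "inside_na"
            for r in range(8)
            for c in range(8)
        )
        assert np.all(f.pixels == round(1000 * inside / 64))

    def test_empty_phantom_darkfield_is_black(self):
        m = scope_with(empty_phantom())
        m.set_illumination(darkfield_pattern(m.array, DEFAULT_LENSES["4x"]))
        m.set_lens(DEFAULT_LENSES["4x"])
        assert np.all(m.capture().pixels == 0)

    def test_darkfield_signal_zero_where_scatter_zero(self):
        ph = make_blob_field(n=5, seed=0, size_px=(96, 96), absorbance=0.0)
        m = scope_with(ph, lens=DEFAULT_LENSES["4x"])
        m.set_lens(DEFAULT_LENSES["4x"])
        m.move_focus(DEFAULT_LENSES["4x"].coarse_offset_units)
        m.set_illumination(darkfield_pattern(m.array, DEFAULT_LENSES["4x"]))
        f = m.capture()
        scatter = ph.layers[0].scatter[16:80, 16:80]
        assert f.pixels[scatter < 1e-6].max() <= 1

    def test_fluorescence_without_fluorophores_is_background(self):
        m = scope_with(empty_phantom())
        m.set_illumination(FluorescenceIllumination())
        m.close_lid()
        m.set_fluorescence_led(True)
        f = m.capture(10.0)
        assert np.all(f.pixels == 10)  # 1% leakage of base level

    def test_fluorescence_with_led_off_is_background_not_error(self):
        ph = make_blob_field(n=5, seed=0, size_px=(96, 96))
        m = scope_with(ph)
        m.set_illumination(FluorescenceIllumination())
        f = m.capture(10.0)
        assert f.pixels.max() <= 10

    def test_brightfield_blind_to_pure_phase_objects(self):
        # the motivating failure: transparent specimens show no contrast
        ph = make_phase_ramp(slope_rad_per_um=0.05, size_px=(96, 96))
        m = scope_with(ph, lens=DEFAULT_LENSES["40x"])
        m.move_focus(DEFAULT_LENSES["40x"].coarse_offset_units)
        f = m.capture()
        assert f.pixels.std() == 0.0

    def test_oblique_pair_sign_tracks_phase_ramp_direction(self):
        lens = DEFAULT_LENSES["40x"]  # whole array inside NA 0.65
        for direction, sign in [(0, -1), (180, 1)]:
            ph = make_phase_ramp(direction_deg=direction, slope_rad_per_um=0.02, size_px=(96, 96))
            m = scope_with(ph, lens=lens)
            m.move_focus(lens.coarse_offset_units)
            left, right = pseudo_phase_pair(m.array)
            m.set_illumination(left)
            fa = m.capture()
            m.set_illumination(right)
            fb = m.capture()
            pp = pseudo_phase(fa, fb)
            assert np.sign(pp.values.mean()) == sign

    def test_exposure_linearity_before_clipping(self):
        ph = make_blob_field(n=8, seed=2, size_px=(96, 96))
        m = scope_with(ph)
        a = m.capture(5.0).pixels.astype(int)
        b = m.capture(10.0).pixels.astype(int)
        assert np.abs(b - 2 * a).max() <= 1  # rounding only

    def test_defocus_blurs_the_image(self):
        from ledscope import focus_metric

        ph = make_blob_field(n=8, seed=2, size_px=(96, 96))
        m = scope_with(ph)
        sharp = focus_metric(m.capture())
        m.move_focus(m.state.lens.coarse_offset_units + 500)
        assert focus_metric(m.capture()) < sharp

    def test_bit_identical_determinism_with_noise(self):
        def one():
            m = scope_with(make_blob_field(n=8, seed=2, size_px=(96, 96)), noise=True, seed=7)
            return m.capture(10.0)

        f1, f2 = one(), one()
        assert np.array_equal(f1.pixels, f2.pixels)
        assert f1.metadata == f2.metadata

    def test_different_seed_changes_noise(self):
        ph = make_blob_field(n=8, seed=2, size_px=(96, 96))
        a = scope_with(ph, noise=True, seed=1).capture()
        b = scope_with(ph, noise=True, seed=2).capture()
        assert not np.array_equal(a.pixels, b.pixels)

    def test_stage_translation_moves_content_left(self):
        ph = make_graticule(pitch_um=64, line_width_um=16, size_px=(128, 128))
        m = scope_with(ph)
        a = m.capture().luminance
        m.move_stage(20, 0)  # +0.02 mm = 10 px at 2 um/px
        b = m.capture().luminance
        assert np.allclose(a[:, 10:], b[:, :-10])

    def test_fov_not_covered_by_phantom_is_an_error(self):
        m = scope_with(empty_phantom(size=96))
        m.move_stage(1000, 0)  # 500 px off centre, phantom only 96 px wide
        with pytest.raises(RenderError):
            m.capture()

    def test_metadata_records_full_state(self):
        m = scope_with(make_blob_field(n=3, seed=0, size_px=(96, 96)))
        m.set_illumination(brightfield_pattern(LedArraySpec()))
        meta = m.capture(12.5).metadata
        for key in (
            "exposure_ms", "focus_z_units", "stage_x_units", "lens",
            "illumination", "timestamp_iso", "seed", "noise", "homed",
        ):
            assert key in meta
        assert meta["exposure_ms"] == 12.5
        assert meta["lens"]["name"] == "10x"
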