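"""Filtering, image/volume assembly and quality metrics."""

import numpy as np
import pytest

from mmfpam import (ExcitationFocus, FilterSpec, PAImage, SensorModel,
                    SpeckleImage, assemble_volume_acoustic,
                    assemble_volume_optical, axial_resolution,
                    enhancement_factor, fluence, lateral_resolution_esf,
                    lowpass, make_scan_grid, mip, power_ratio, profile_fwhm,
                    simulate_frame, time_to_depth)
from mmfpam.acoustics import PAFrameSet, PATimeSeries
from mmfpam.imaging import fit_gaussian_fwhm
from mmfpam.phantoms import AbsorberMap

from test_acoustics import _point_phantom


def _frames_from(traces, step=1.0, fov=4.0, dt=4.0, t0=0.0):
    grid = make_scan_grid(fov, step)
    traces = np.asarray(traces, dtype=float)
    assert traces.shape[0] == grid.n_positions
    return PAFrameSet(traces, dt, t0, grid)


class TestLowpass:
    def test_dc_passband_identity(self):
        ts = PATimeSeries(np.full(256, 3.0), 4.0)
        out = lowpass(ts, FilterSpec(20.0))
        assert np.allclose(out.samples, 3.0, rtol=1e-6)

    def test_out_of_band_tone_attenuated(self):
        t = np.arange(2048) * 4.0
        tone = np.sin(2e-3 * np.pi * 40.0 * t)          # 40 MHz
        out = lowpass(PATimeSeries(tone, 4.0), FilterSpec(20.0))
        mid = slice(256, -256)
        atten = 20 * np.log10(np.abs(out.samples[mid]).max()
                              / np.abs(tone[mid]).max())
        assert atten <= -12.0

    def test_zero_phase_preserves_peak_position(self):
        from scipy.signal import hilbert

        from mmfpam import sensor_impulse_response

        ts = sensor_impulse_response(SensorModel())
        out = lowpass(ts, FilterSpec(20.0))
        p0 = np.argmax(np.abs(hilbert(ts.samples)))
        p1 = np.argmax(np.abs(hilbert(out.samples)))
        assert abs(int(p0) - int(p1)) <= 1

    def test_cutoff_above_nyquist_rejected(self):
        ts = PATimeSeries(np.zeros(64), 4.0)             # Nyquist 125 MHz
        with pytest.raises(ValueError, match="Nyquist"):
            lowpass(ts, FilterSpec(200.0))


class TestTimeToDepth:
    def test_unit_arithmetic_and_linearity(self):
        assert time_to_depth(0.0) == 0.0
        assert time_to_depth(1000.0) == pytest.approx(1485.0)
        assert time_to_depth(2 * 7.0) == pytest.approx(2 * time_to_depth(7.0))


class TestMIP:
    def test_zero_traces_zero_image(self):
        fs = _frames_from(np.zeros((13, 64)))
        img = mip(fs, filter_spec=None)
        assert np.all(img.values == 0)
        assert img.mask.sum() == 13

    def test_single_impulse_single_pixel(self):
        traces = np.zeros((13, 64))
        traces[6, 20] = 5.0
        img = mip(_frames_from(traces), filter_spec=None)
        assert (img.values > 1e-3 * img.values.max()).sum() == 1

    def test_max_merge_associativity(self):
        rng = np.random.default_rng(0)
        a = np.abs(rng.normal(size=(13, 64)))
        b = np.abs(rng.normal(size=(13, 64)))
        merged = mip(_frames_from(np.maximum(a, b)), filter_spec=None,
                     detect="positive")
        pix = np.maximum(
            mip(_frames_from(a), filter_spec=None, detect="positive").values,
            mip(_frames_from(b), filter_spec=None, detect="positive").values)
        assert np.allclose(merged.values, pix)

    def test_empty_frame_set_rejected(self):
        grid = make_scan_grid(4.0, 1.0)
        fs = PAFrameSet(np.zeros((grid.n_positions, 0)), 4.0, 0.0, grid)
        with pytest.raises(ValueError):
            mip(PAFrameSet(np.zeros((0, 10)), 4.0, 0.0, grid))


class TestAcousticVolume:
    def test_point_absorber_depth_recovered(self):
        p = _point_phantom(150.0, extent=(8, 8, 260))
        grid = make_scan_grid(4.0, 1.0)
        fs = simulate_frame(p, grid, ExcitationFocus(axial_fwhm_um=1000.0),
                            SensorModel())
        vol = assemble_volume_acoustic(fs)
        iy, ix = vol.values.shape[0] // 2, vol.values.shape[1] // 2
        zpk = vol.z_coords_um[np.argmax(vol.values[iy, ix])]
        assert zpk == pytest.approx(150.0, abs=vol.z_pitch_um)

    def test_known_depths_recovered_across_random_phantoms(self):
        rng = np.random.default_rng(7)
        grid = make_scan_grid(2.0, 1.0)
        for _ in range(10):
            z_true = float(rng.uniform(60, 220))
            p = _point_phantom(z_true, extent=(8, 8, 260))
            fs = simulate_frame(p, grid,
                                ExcitationFocus(axial_fwhm_um=1000.0),
                                SensorModel())
            vol = assemble_volume_acoustic(fs)
            iy, ix = vol.values.shape[0] // 2, vol.values.shape[1] // 2
            zpk = vol.z_coords_um[np.argmax(vol.values[iy, ix])]
            assert zpk == pytest.approx(z_true, abs=1.5 * vol.z_pitch_um)

    def test_empty_frames_zero_volume(self):
        fs = _frames_from(np.zeros((13, 64)))
        assert not assemble_volume_acoustic(fs).values.any()

    def test_mip_of_volume_matches_2d_mip(self):
        p = _point_phantom(100.0, extent=(8, 8, 200))
        grid = make_scan_grid(4.0, 1.0)
        fs = simulate_frame(p, grid, ExcitationFocus(), SensorModel())
        vol = assemble_volume_acoustic(fs, detect="positive")
        img = mip(fs, detect="positive")
        assert np.allclose(vol.values.max(axis=2), img.values)


class TestOpticalVolume:
    @pytest.mark.parametrize("n_planes,span", [(5, 20.0), (21, 100.0)])
    def test_depth_span(self, n_planes, span):
        img = PAImage(np.ones((3, 3)), 1.0, (0, 0))
        planes = [PAImage(np.ones((3, 3)), 1.0, (0, 0), plane_z_um=5.0 * i)
                  for i in range(n_planes)]
        vol = assemble_volume_optical(planes)
        assert vol.z_span_um == pytest.approx(span)
        assert vol.values.shape[2] == n_planes

    def test_single_plane_embeds_as_volume(self):
        img = PAImage(np.ones((3, 4)), 1.0, (0, 0))
        vol = assemble_volume_optical([img])
        assert vol.values.shape == (3, 4, 1)

    def test_mismatched_grids_rejected(self):
        a = PAImage(np.ones((3, 3)), 1.0, (0, 0), plane_z_um=0)
        b = PAImage(np.ones((4, 4)), 1.0, (0, 0), plane_z_um=5)
        with pytest.raises(ValueError, match="grid"):
            assemble_volume_optical([a, b])


def _synthetic_focus_image(shape=(64, 64), peak=769.0, fwhm_px=2.0,
                           bg=1.0, seed=0):
    rng = np.random.default_rng(seed)
    yy, xx = np.indices(shape)
    c = (shape[0] // 2, shape[1] // 2)
    sigma = fwhm_px / 2.3548
    spot = peak * np.exp(-((yy - c[0]) ** 2 + (xx - c[1]) ** 2)
                         / (2 * sigma**2))
    background = bg * np.ones(shape) if seed is None else \
        rng.exponential(bg, shape)
    background *= bg / background.mean()
    return SpeckleImage(spot + background), c


class TestFocusMetrics:
    def test_uniform_image_ef_one(self):
        img = SpeckleImage(np.ones((32, 32)))
        assert enhancement_factor(img, (16, 16), 2.0) == pytest.approx(1.0)

    def test_constructed_peak_on_unit_background(self):
        img, c = _synthetic_focus_image(peak=769.0, bg=1.0)
        ef = enhancement_factor(img, c, 2.0)
        assert ef == pytest.approx(769.0, rel=0.05)

    def test_masking_focal_disc_raises_ef_over_global_mean(self):
        img, c = _synthetic_focus_image(peak=100.0)
        ef = enhancement_factor(img, c, 2.0)
        naive = img.intensity.max() / img.intensity.mean()
        assert ef > naive

    def test_power_ratio_delta_and_uniform(self):
        delta = np.zeros((33, 33))
        delta[16, 16] = 7.0
        assert power_ratio(SpeckleImage(delta), (16, 16), 2.0) \
            == pytest.approx(1.0)
        uni = SpeckleImage(np.ones((65, 65)))
        yy, xx = np.indices((65, 65))
        core = (yy - 32) ** 2 + (xx - 32) ** 2 <= 30**2
        fwhm = 10.0
        expected = np.pi * (fwhm / 2) ** 2 / core.sum()
        assert power_ratio(uni, (32, 32), fwhm, core) \
            == pytest.approx(expected, rel=0.1)

    def test_power_ratio_never_exceeds_one(self):
        img, c = _synthetic_focus_image()
        assert power_ratio(img, c, 5.0) <= 1.0


class TestProfileFWHM:
    def test_discrete_gaussian(self):
        x = np.arange(101)
        prof = np.exp(-((x - 50.0) ** 2) / (2 * 2.0**2))
        got = profile_fwhm(prof, pixel_pitch_um=0.1)
        assert got == pytest.approx(0.471, rel=0.02)

    def test_impulse_at_most_one_pixel(self):
        prof = np.zeros(21)
        prof[10] = 1.0
        assert profile_fwhm(prof, pixel_pitch_um=1.0) <= 1.0

    def test_amplitude_scale_invariance(self):
        x = np.arange(101)
        prof = np.exp(-((x - 50.0) ** 2) / (2 * 3.0**2))
        a = profile_fwhm(prof, pixel_pitch_um=1.0)
        b = profile_fwhm(7.7 * prof, pixel_pitch_um=1.0)
        assert a == pytest.approx(b)

    def test_no_half_crossing_rejected(self):
        with pytest.raises(ValueError):
            profile_fwhm(np.ones(11), pixel_pitch_um=1.0)


def _blurred_edge_image(sigma_um, pitch_um=0.25, size=120):
    from scipy.ndimage import gaussian_filter1d

    step = np.zeros(size)
    step[size // 2:] = 1.0
    esf = gaussian_filter1d(step, sigma_um / pitch_um, mode="nearest")
    img = np.tile(esf, (30, 1))
    return PAImage(img, pitch_um, (0, 0))


class TestLateralResolutionESF:
    def test_gaussian_blurred_step_recovers_width(self):
        img = _blurred_edge_image(1.0)
        res = lateral_resolution_esf(img, (slice(5, 25), slice(None)))
        assert res == pytest.approx(2.355, rel=0.05)

    def test_monotone_in_blur(self):
        widths = [lateral_resolution_esf(_blurred_edge_image(s),
                                         (slice(5, 25), slice(None)))
                  for s in (0.5, 1.0, 2.0)]
        assert widths[0] < widths[1] < widths[2]

    def test_invariant_to_amplitude(self):
        img = _blurred_edge_image(1.0)
        big = PAImage(100 * img.values, img.pixel_pitch_um, img.origin_um)
        a = lateral_resolution_esf(img, (slice(5, 25), slice(None)))
        b = lateral_resolution_esf(big, (slice(5, 25), slice(None)))
        assert a == pytest.approx(b, rel=1e-6)

    def test_too_few_profiles_rejected(self):
        img = _blurred_edge_image(1.0)
        with pytest.raises(ValueError, match="adjacent"):
            lateral_resolution_esf(img, (slice(0, 4), slice(None)))


class TestAxialResolution:
    def test_multi_lobed_profile_rejected(self):
        from mmfpam.imaging import PAVolume

        z = np.arange(60) * 5.0
        prof = (np.exp(-(z - 100) ** 2 / 200.0)
                + np.exp(-(z - 250) ** 2 / 200.0))
        vol = PAVolume(np.tile(prof, (1, 1, 1)), 1.0, 5.0, 0.0, "optical")
        with pytest.raises(ValueError, match="multi-lobed"):
            axial_resolution(vol, (0, 0))

    def test_gaussian_fit_recovers_width(self):
        x = np.arange(0, 200, 5.0)
        y = 3.0 * np.exp(-(x - 90) ** 2 / (2 * 12.0**2)) + 0.1
        assert fit_gaussian_fwhm(x, y) == pytest.approx(2.3548 * 12, rel=0.01)


class TestFluence:
    def test_printed_focus_fluence(self):
        assert fluence(20.0, 1.2) == pytest.approx(1.77, abs=0.01)

    def test_zero_energy_and_diameter_scaling(self):
        assert fluence(0.0, 1.2) == 0.0
        assert fluence(20.0, 2.4) == pytest.approx(fluence(20.0, 1.2) / 4)

    def test_zero_diameter_rejected(self):
        with pytest.raises(ValueError):
            fluence(20.0, 0.0)
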