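"""Spectrum extraction, Richardson-Lucy deconvolution, fluorescence
baseline, band maps, false color, and ROI series."""

import warnings

import numpy as np
import pytest
from scipy import ndimage

import opmraman as om
from opmraman import spectral as sp
from opmraman import synthetic as syn
from opmraman.errors import InvalidInputError


class TestExtractSpectra:
    def test_zero_frame_gives_zero_spectra(self, cal_model, shift_grid):
        fr = om.HyperspectralFrame(np.zeros((120, 48)))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            spectra = sp.extract_spectra(fr, cal_model, shift_grid)
        assert len(spectra) == 48
        assert all(np.all(s.intensities == 0) for s in spectra)

    def test_noiseless_recovery_within_2pct(self):
        # vanishing beam: extraction inverts the forward model directly
        cfg = om.InstrumentConfig(beam_fwhm_center=0.05, beam_fwhm_edge=0.05)
        model = syn.default_calibration(120, 48, cfg)
        noise = syn.NoiseModel(read_noise_sd=0.0, shot_noise=False)
        fr = syn.render_hyperspectral_frame({"water": np.ones(48)}, model,
                                            cfg, noise,
                                            gain=1.0 / cfg.frame_exposure)
        grid = om.make_shift_grid(0, 3400, 20)
        mat = sp.extract_spectrum_matrix(fr, model, grid, warn_partial=False)
        truth = syn.SPECTRAL_LIBRARY["water"].evaluate(grid)
        assert np.abs(mat[24] - truth).max() / truth.max() < 0.02

    def test_grating_tilt_correction_aligns_columns(self, cal_model):
        cfg = om.InstrumentConfig()
        noise = syn.NoiseModel(read_noise_sd=0.0, shot_noise=False)
        fr = syn.render_hyperspectral_frame({"PS": np.ones(48)}, cal_model,
                                            cfg, noise, gain=100)
        grid = om.make_shift_grid(0, 3400, 20)
        mat = sp.extract_spectrum_matrix(fr, cal_model, grid)
        assert np.corrcoef(mat[5], mat[40])[0, 1] > 0.999

    def test_partial_coverage_warns(self, cal_model):
        fr = om.HyperspectralFrame(np.ones((120, 48)))
        with pytest.warns(UserWarning, match="coverage"):
            sp.extract_spectrum_matrix(fr, cal_model,
                                       om.make_shift_grid(-500, 3400, 20))


def _beam_sigma_bins(model, cfg, grid):
    fwhm_nm = cfg.beam_fwhm_center / cfg.y_pixel_pitch * model.dispersion
    fwhm_cm1 = om.fwhm_nm_to_cm1(fwhm_nm, float(np.median(grid)),
                                 model.excitation_nm)
    return fwhm_cm1 / (2 * np.sqrt(2 * np.log(2))) / (grid[1] - grid[0])


class TestRichardsonLucy:
    def test_delta_kernel_is_identity(self):
        x = np.random.default_rng(0).random(100)
        assert np.allclose(sp.richardson_lucy_1d(x, 0.0), x)

    def test_narrows_blurred_peak(self):
        x = np.arange(300.0)
        peak = np.exp(-0.5 * ((x - 150) / 5.0) ** 2)
        blurred = ndimage.gaussian_filter1d(peak, 5.0)
        dec = sp.richardson_lucy_1d(blurred, 5.0, iterations=30, tol=0.0)

        def fwhm(v):
            above = np.nonzero(v >= v.max() / 2)[0]
            return above[-1] - above[0]

        true_w = fwhm(peak)
        assert fwhm(dec) < fwhm(blurred)
        assert fwhm(dec) < 1.2 * true_w

    def test_flux_conserved_and_nonnegative(self):
        rng = np.random.default_rng(1)
        x = np.abs(ndimage.gaussian_filter1d(rng.random(200), 3.0))
        dec = sp.richardson_lucy_1d(x, 5.0, iterations=15)
        assert np.all(dec >= 0)
        assert dec.sum() == pytest.approx(x.sum(), rel=0.01)

    def test_matches_reference_implementation(self):
        """Independent cross-check against skimage's Richardson-Lucy."""
        from skimage.restoration import richardson_lucy as sk_rl

        x = np.arange(256.0)
        signal = (np.exp(-0.5 * ((x - 90) / 5.0) ** 2)
                  + 0.6 * np.exp(-0.5 * ((x - 170) / 7.0) ** 2))
        blurred = ndimage.gaussian_filter1d(signal, 6.0)
        sigma = 6.0
        half = int(np.ceil(4 * sigma))
        k = np.exp(-0.5 * (np.arange(-half, half + 1) / sigma) ** 2)
        k /= k.sum()
        # compare at convergence: the implementations use different
        # initial estimates (data vs flat), which only agree in the limit
        ours = sp.richardson_lucy_1d(blurred, sigma, iterations=50, tol=0.0)
        theirs = sk_rl(blurred, k, num_iter=50, clip=False)
        inner = slice(40, 216)  # boundary policies differ (reflect vs zero)
        assert np.abs(ours[inner] - theirs[inner]).max() < 1e-3 * signal.max()

    def test_negative_input_rejected(self):
        with pytest.raises(InvalidInputError):
            sp.richardson_lucy_1d(np.array([-1.0, 2.0]), 2.0)

    def test_deconvolve_beam_on_frame_and_spectrum(self, cal_model):
        cfg = om.InstrumentConfig()
        noise = syn.NoiseModel(read_noise_sd=0.0, shot_noise=False)
        fr = syn.render_hyperspectral_frame({"PS": np.ones(48)}, cal_model,
                                            cfg, noise, gain=100)
        out = sp.deconvolve_beam(fr, cfg.deconvolution_fwhm, cal_model, cfg)
        assert out.pixels.shape == fr.pixels.shape
        assert np.all(out.pixels >= 0)
        grid = om.make_shift_grid(0, 3400, 20)
        spec = sp.extract_spectra(fr, cal_model, grid)[24]
        dspec = sp.deconvolve_beam(spec, cfg.deconvolution_fwhm, cal_model, cfg)
        # deconvolution sharpens: the PS fingerprint peak grows
        assert dspec.intensities.max() > spec.intensities.max()
        with pytest.raises(InvalidInputError):
            sp.deconvolve_beam(spec, 0.0, cal_model, cfg)


class TestFluorescenceSubtraction:
    def test_decomposition_is_exact(self, shift_grid):
        rng = np.random.default_rng(2)
        y = np.abs(rng.random(len(shift_grid))) + 0.1
        raman, base = sp.subtract_fluorescence(om.Spectrum(shift_grid, y))
        assert np.array_equal(raman.intensities + base.intensities, y)

    def test_zero_input(self, shift_grid):
        raman, base = sp.subtract_fluorescence(
            om.Spectrum(shift_grid, np.zeros(len(shift_grid))))
        assert np.all(raman.intensities == 0) and np.all(base.intensities == 0)

    def test_peak_free_smooth_input_goes_to_baseline(self, shift_grid):
        u = shift_grid / shift_grid.max()
        y = 0.8 + 0.2 * u - 0.1 * u**2
        raman, base = sp.subtract_fluorescence(om.Spectrum(shift_grid, y))
        rms = np.sqrt((raman.intensities**2).mean())
        assert rms < 0.02 * y.max()

    def test_peak_areas_recovered_within_10pct(self, shift_grid):
        u = shift_grid / shift_grid.max()
        base = 0.8 + 0.3 * u - 0.2 * u**2
        peaks = [(1160.0, 25.0, 1.2), (2880.0, 40.0, 0.8)]
        y = base + sum(a * np.exp(-0.5 * ((shift_grid - c) / w) ** 2)
                       for c, w, a in peaks)
        raman, _ = sp.subtract_fluorescence(om.Spectrum(shift_grid, y))
        for c, w, a in peaks:
            m = np.abs(shift_grid - c) < 4 * w
            true_area = (a * np.exp(-0.5 * ((shift_grid[m] - c) / w) ** 2)).sum()
            assert raman.intensities[m].sum() == pytest.approx(true_area,
                                                               rel=0.10)

    def test_polynomial_method_available(self, shift_grid):
        u = shift_grid / shift_grid.max()
        y = 1.0 + 0.5 * u + np.exp(-0.5 * ((shift_grid - 1500) / 30.0) ** 2)
        raman, base = sp.subtract_fluorescence(om.Spectrum(shift_grid, y),
                                               method="polynomial")
        assert raman.intensities.max() == pytest.approx(1.0, abs=0.15)

    def test_unknown_method_rejected(self, shift_grid):
        with pytest.raises(InvalidInputError):
            sp.subtract_fluorescence(
                om.Spectrum(shift_grid, np.ones(len(shift_grid))),
                method="magic")


class TestBandMaps:
    def test_constant_spectrum_maps_to_constant(self, shift_grid):
        cube = np.full((4, 5, len(shift_grid)), 3.5)
        band = sp.BandDefinition("b", center=1640.0)
        assert np.all(sp.band_intensity_map(cube, shift_grid, band) == 3.5)

    def test_single_bin_peak_in_5_bin_window(self):
        grid = om.make_shift_grid(1000, 2000, 20)
        cube = np.zeros((1, 1, len(grid)))
        cube[0, 0, np.searchsorted(grid, 1500)] = 1.0
        band = sp.BandDefinition("b", center=1500.0, half_width=40.0)
        # window [1460, 1540] holds 5 bins, one of them = 1
        assert sp.band_intensity_map(cube, grid, band)[0, 0] == pytest.approx(0.2)

    def test_peak_outside_window_gives_zero(self, shift_grid):
        cube = np.zeros((2, 2, len(shift_grid)))
        cube[..., np.searchsorted(shift_grid, 2880)] = 1.0
        band = sp.BandDefinition("b", center=1160.0)
        assert np.all(sp.band_intensity_map(cube, shift_grid, band) == 0)

    def test_linearity_without_baseline_subtraction(self, shift_grid):
        rng = np.random.default_rng(3)
        s1 = rng.random((3, 4, len(shift_grid)))
        s2 = rng.random((3, 4, len(shift_grid)))
        band = sp.BandDefinition("b", center=2880.0)
        m = sp.band_intensity_map(2.0 * s1 + 3.0 * s2, shift_grid, band)
        expected = (2.0 * sp.band_intensity_map(s1, shift_grid, band)
                    + 3.0 * sp.band_intensity_map(s2, shift_grid, band))
        assert np.allclose(m, expected)

    def test_empty_window_rejected(self, shift_grid):
        cube = np.zeros((1, 1, len(shift_grid)))
        band = sp.BandDefinition("b", window=(5000.0, 5100.0))
        with pytest.raises(InvalidInputError):
            sp.band_intensity_map(cube, shift_grid, band)

    def test_end_to_end_linearity_in_concentration(self, cal_model, shift_grid):
        """Doubling a compound's concentration doubles its band-map value
        (after baseline subtraction) within 5%."""
        cfg = om.InstrumentConfig()
        noise = syn.NoiseModel(read_noise_sd=0.0, shot_noise=False)
        band = sp.BandDefinition("car", center=1160.0, subtract_baseline=True)
        vals = []
        for conc in (1.0, 2.0):
            fr = syn.render_hyperspectral_frame(
                {"carotenoids": conc * np.ones(48)}, cal_model, cfg, noise,
                gain=100)
            mat = sp.extract_spectrum_matrix(fr, cal_model, shift_grid,
                                             warn_partial=False)
            vals.append(sp.band_intensity_map(mat[None], shift_grid, band)[0, 24])
        assert vals[1] / vals[0] == pytest.approx(2.0, rel=0.05)


class TestFalseColor:
    def test_identical_maps_give_gray(self):
        m = np.random.default_rng(4).random((6, 6))
        rgb = sp.compose_false_color([m, m, m])
        assert np.allclose(rgb[..., 0], rgb[..., 1])
        assert np.allclose(rgb[..., 1], rgb[..., 2])

    def test_single_channel_monochrome(self):
        m = np.random.default_rng(5).random((4, 4))
        z = np.zeros_like(m)
        with pytest.warns(UserWarning):
            rgb = sp.compose_false_color([m, z, z])
        assert rgb[..., 0].max() == 1.0
        assert np.all(rgb[..., 1:] == 0)

    def test_series_max_normalization_preserves_temporal_change(self):
        a = np.full((2, 3, 3), 1.0)
        a[1] = 2.0  # band doubles between frames
        with pytest.warns(UserWarning):
            rgb = sp.compose_false_color([a, np.zeros_like(a), np.zeros_like(a)])
        assert rgb[1, 0, 0, 0] == pytest.approx(2 * rgb[0, 0, 0, 0])

    def test_shape_mismatch_rejected(self):
        with pytest.raises(InvalidInputError):
            sp.compose_false_color([np.zeros((2, 2)), np.zeros((3, 3)),
                                    np.zeros((2, 2))])


class TestRoiTimeSeries:
    def test_static_series_normalizes_to_one(self):
        maps = {"car": np.full((5, 8, 8), 2.0)}
        out = sp.roi_time_series(maps, (2, 5, 2, 5))
        assert np.allclose(out["car"], 1.0)

    def test_growing_band_is_monotone(self):
        t = np.arange(6, dtype=float) + 1.0
        maps = {"car": t[:, None, None] * np.ones((6, 4, 4))}
        out = sp.roi_time_series(maps, (0, 4, 0, 4))
        assert np.all(np.diff(out["car"]) > 0)
        assert out["car"][-1] == 1.0

    def test_single_pixel_roi(self):
        stack = np.random.default_rng(6).random((4, 5, 5))
        out = sp.roi_time_series({"b": stack}, (2, 3, 3, 4))
        expected = stack[:, 2, 3] / stack[:, 2, 3].max()
        assert np.allclose(out["b"], expected)

    def test_empty_roi_rejected(self):
        with pytest.raises(InvalidInputError):
            sp.roi_time_series({"b": np.zeros((2, 4, 4))}, (1, 1, 0, 2))
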