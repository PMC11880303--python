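import dataclasses
import math

import numpy as np
import pytest

from aggphot import (
    DegenerateInputError,
    InputError,
    IntensityImage,
    LineProfile,
    ROI,
    compute_sbr,
    extract_line_profile,
    fit_profile_fwhm,
    roi_timecourse,
)
from aggphot.imaging import FWHM_PER_SIGMA, read_image, write_image
from aggphot.synthetic import (
    TimeCourseConfig,
    VesselImageConfig,
    gen_timecourse_images,
    gen_vessel_image,
    preset,
    tumor_roi,
)


def _flat_image(level=100.0, shape=(32, 32), pixel=0.05):
    return IntensityImage(np.full(shape, level), pixel)


class TestExtractLineProfile:
    def test_constant_image_gives_constant_profile(self):
        prof = extract_line_profile(_flat_image(), (16, 2), (16, 29), width_px=3)
        np.testing.assert_allclose(prof.intensities, 100.0)

    def test_axis_aligned_profile_matches_analytic_ridge(self):
        cfg = VesselImageConfig(poisson=False, read_noise_sd=0.0)
        img = gen_vessel_image(cfg)
        p0, p1 = cfg.profile_line
        prof = extract_line_profile(img, p0, p1, width_px=1)
        sigma = cfg.vessel_fwhm_mm / FWHM_PER_SIGMA
        crest = cfg.crest_col * cfg.pixel_size_mm
        analytic = cfg.background_level + cfg.peak_level * np.exp(
            -((prof.positions_mm - crest) ** 2) / (2 * sigma**2)
        )
        np.testing.assert_allclose(prof.intensities, analytic, atol=1e-6)

    def test_width_averaging_identical_on_translation_invariant_image(self):
        cfg = VesselImageConfig(poisson=False, read_noise_sd=0.0)
        img = gen_vessel_image(cfg)
        row = cfg.shape[0] // 2
        p0, p1 = (row, 3), (row, cfg.shape[1] - 4)
        w1 = extract_line_profile(img, p0, p1, width_px=1)
        w5 = extract_line_profile(img, p0, p1, width_px=5)
        np.testing.assert_allclose(w1.intensities, w5.intensities, atol=1e-9)

    def test_commutes_with_transposition_for_axis_aligned_lines(self):
        rng = np.random.default_rng(0)
        img = IntensityImage(rng.uniform(0, 1000, (40, 40)), 0.05)
        imgT = IntensityImage(img.pixels.T.copy(), 0.05)
        prof = extract_line_profile(img, (20, 2), (20, 37), width_px=1)
        profT = extract_line_profile(imgT, (2, 20), (37, 20), width_px=1)
        np.testing.assert_allclose(prof.intensities, profT.intensities)

    def test_out_of_bounds_endpoint_rejected(self):
        with pytest.raises(InputError):
            extract_line_profile(_flat_image(), (16, 2), (16, 40))

    def test_even_width_rejected(self):
        with pytest.raises(InputError):
            extract_line_profile(_flat_image(), (16, 2), (16, 29), width_px=2)


class TestFitProfileFwhm:
    def test_noiseless_gaussian_closed_form(self):
        x = np.linspace(0, 10, 201)
        y = 5.0 * np.exp(-((x - 5.0) ** 2) / 2.0) + 1.0  # sigma = 1 mm
        fit = fit_profile_fwhm(LineProfile(x, y))
        assert fit.fwhm_mm == pytest.approx(2.3548, abs=1e-4)
        assert fit.fwhm_mm / fit.sigma_mm == pytest.approx(2 * math.sqrt(2 * math.log(2)), rel=1e-12)

    @pytest.mark.parametrize("true_fwhm, tol", [(0.25, 0.02), (0.49, 0.03)])
    def test_vessel_width_recovered_from_noisy_fixture(self, true_fwhm, tol):
        cfg = dataclasses.replace(preset("nir2b_vessel"), vessel_fwhm_mm=true_fwhm)
        vals = []
        for seed in range(1, 6):
            img = gen_vessel_image(cfg, seed=seed)
            p0, p1 = cfg.profile_line
            vals.append(fit_profile_fwhm(extract_line_profile(img, p0, p1, width_px=5)).fwhm_mm)
        assert np.mean(vals) == pytest.approx(true_fwhm, abs=tol)

    def test_gain_and_offset_invariance(self):
        cfg = preset("nir2b_vessel")
        img = gen_vessel_image(cfg, seed=2)
        p0, p1 = cfg.profile_line
        prof = extract_line_profile(img, p0, p1, width_px=5)
        shifted = LineProfile(prof.positions_mm, 3.0 * prof.intensities + 50.0)
        f0 = fit_profile_fwhm(prof)
        f1 = fit_profile_fwhm(shifted)
        assert f1.fwhm_mm == pytest.approx(f0.fwhm_mm, rel=1e-6)

    def test_recovery_error_below_eight_percent_across_width_grid(self):
        errs = []
        for true_fwhm in (0.2, 0.3, 0.4, 0.5, 0.6):
            cfg = dataclasses.replace(preset("nir2b_vessel"), vessel_fwhm_mm=true_fwhm)
            for seed in (1, 2, 3):
                img = gen_vessel_image(cfg, seed=seed)
                p0, p1 = cfg.profile_line
                got = fit_profile_fwhm(extract_line_profile(img, p0, p1, width_px=5)).fwhm_mm
                errs.append(abs(got - true_fwhm) / true_fwhm)
        assert np.mean(errs) < 0.08

    def test_flat_profile_rejected(self):
        x = np.linspace(0, 5, 50)
        with pytest.raises(Exception):
            fit_profile_fwhm(LineProfile(x, np.full_like(x, 7.0)))


class TestComputeSbr:
    def test_uniform_image_unity(self):
        img = _flat_image(500.0)
        res = compute_sbr(img, ROI(0, 10, 0, 10), ROI(20, 30, 20, 30))
        assert res.sbr == pytest.approx(1.0)

    def test_invariant_under_gain(self):
        cfg = preset("nir2b_vessel")
        img = gen_vessel_image(cfg, seed=4)
        scaled = IntensityImage(img.pixels * 11.0, img.pixel_size_mm)
        s0 = compute_sbr(img, cfg.signal_roi, cfg.background_roi).sbr
        s1 = compute_sbr(scaled, cfg.signal_roi, cfg.background_roi).sbr
        assert s1 == pytest.approx(s0, rel=1e-12)

    def test_noiseless_ridge_ratio_exact(self):
        cfg = VesselImageConfig(poisson=False, read_noise_sd=0.0)
        img = gen_vessel_image(cfg)
        res = compute_sbr(img, cfg.signal_roi, cfg.background_roi)
        expected = (cfg.background_level + cfg.peak_level) / cfg.background_level
        assert res.sbr == pytest.approx(expected, rel=1e-9)

    def test_overlapping_rois_rejected(self):
        img = _flat_image()
        with pytest.raises(InputError):
            compute_sbr(img, ROI(0, 10, 0, 10), ROI(5, 15, 5, 15))

    def test_zero_background_rejected(self):
        img = IntensityImage(np.pad(np.ones((16, 16)), ((0, 16), (0, 16))), 0.05)
        with pytest.raises(DegenerateInputError):
            compute_sbr(img, ROI(0, 10, 0, 10), ROI(20, 30, 20, 30))


class TestRoiTimecourse:
    def test_uptake_series_peaks_at_24h(self):
        base = preset("nir2b_vessel")
        images = gen_timecourse_images(preset("tumor_course"), base, seed=1)
        tc = roi_timecourse(images, tumor_roi(base))
        assert tc.peak_time_h == 24.0

    def test_onset_and_washout_ordering(self):
        base = preset("nir2b_vessel")
        images = gen_timecourse_images(preset("tumor_course"), base, seed=2)
        tc = roi_timecourse(images, tumor_roi(base))
        by_t = dict(zip(tc.times_h, tc.intensities))
        assert by_t[6.0] > by_t[0.0]
        assert by_t[0.0] < by_t[36.0] < by_t[24.0]

    def test_monotone_series_peaks_at_last_time(self):
        imgs = [
            IntensityImage(np.full((16, 16), 10.0 * (i + 1)), 0.05, time_h=float(t))
            for i, t in enumerate((0, 6, 12))
        ]
        tc = roi_timecourse(imgs, ROI(2, 10, 2, 10))
        assert tc.peak_time_h == 12.0

    def test_geometry_mismatch_rejected(self):
        imgs = [
            IntensityImage(np.full((16, 16), 10.0), 0.05, time_h=0.0),
            IntensityImage(np.full((16, 16), 10.0), 0.05, time_h=6.0),
            IntensityImage(np.full((32, 32), 10.0), 0.05, time_h=12.0),
        ]
        with pytest.raises(InputError):
            roi_timecourse(imgs, ROI(2, 10, 2, 10))


class TestImageIO:
    def test_tiff_round_trip(self, tmp_path):
        cfg = preset("nir2b_vessel")
        img = gen_vessel_image(cfg, seed=1)
        path = tmp_path / "vessel.tif"
        write_image(img, path)
        back = read_image(path, pixel_size_mm=cfg.pixel_size_mm)
        assert back.shape == img.shape
        np.testing.assert_allclose(back.pixels, np.clip(np.round(img.pixels), 0, 65535), atol=0)
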