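import numpy as np
import pytest

from trisynapse import localize, simulate
from trisynapse.frames import FrameStack, add_spot


def _blank_stack(n_frames=1, size=64, bg=5.0, px=100.0):
    a = np.full((n_frames, size, size), bg)
    return a, np.full_like(a, bg), px


def _stack(a, b, px=100.0, channel="GLT1", z=None):
    return FrameStack(a, b, pixel_size_nm=px, channel=channel, z_samples_nm=z)


class TestDiffractionLimit:
    def test_reference_values(self):
        assert localize.diffraction_limit(500, 1.25) == pytest.approx(200.0)
        assert localize.diffraction_limit(600, 1.2) == pytest.approx(250.0)

    def test_higher_aperture_resolves_finer(self):
        d = [localize.diffraction_limit(600, na) for na in (0.8, 1.0, 1.2, 1.49)]
        assert all(x > y for x, y in zip(d, d[1:]))

    def test_rejects_nonpositive_inputs(self):
        with pytest.raises(ValueError):
            localize.diffraction_limit(0, 1.2)
        with pytest.raises(ValueError):
            localize.diffraction_limit(600, -1)


class TestDetect:
    def test_blank_frames_yield_no_candidates(self):
        a, b, px = _blank_stack(n_frames=3)
        cands = localize.detect_spots(_stack(a, b, px), threshold_photons=50.0)
        assert all(len(c) == 0 for c in cands)

    def test_single_bright_spot_found_within_one_pixel(self):
        a, b, px = _blank_stack()
        add_spot(a[0], 20.3, 31.7, 1.5, 2000.0)
        add_spot(b[0], 20.3, 31.7, 1.5, 2000.0)
        [cands] = localize.detect_spots(_stack(a, b, px), threshold_photons=50.0)
        assert len(cands) == 1
        r, c = cands[0]
        assert abs(r - 31.7) <= 1.0 and abs(c - 20.3) <= 1.0

    def test_two_separated_spots_both_found(self):
        a, b, px = _blank_stack()
        for x, y in ((15.0, 15.0), (35.0, 15.0)):  # 20 px apart
            add_spot(a[0], x, y, 1.5, 2000.0)
            add_spot(b[0], x, y, 1.5, 2000.0)
        [cands] = localize.detect_spots(_stack(a, b, px), threshold_photons=50.0)
        assert len(cands) == 2


class TestFit:
    def test_noiseless_spot_centre_recovered_to_hundredth_pixel(self):
        a, b, px = _blank_stack()
        add_spot(a[0], 20.3, 11.7, 1.5, 2000.0)  # sigma 1.5 px = 150 nm
        add_spot(b[0], 20.3, 11.7, 1.5, 2000.0)
        fit = localize.fit_spot(_stack(a, b, px), 0, (12, 20))
        assert fit.converged
        assert abs(fit.x_a_nm / px - 20.3) < 0.02
        assert abs(fit.y_a_nm / px - 11.7) < 0.02
        assert abs(fit.width_a_nm - 150.0) < 2.0

    def test_flat_window_does_not_converge(self):
        a, b, px = _blank_stack()
        fit = localize.fit_spot(_stack(a, b, px), 0, (30, 30))
        assert not fit.converged

    def test_window_clipped_at_border_does_not_converge(self):
        a, b, px = _blank_stack()
        add_spot(a[0], 2.0, 2.0, 1.5, 2000.0)
        fit = localize.fit_spot(_stack(a, b, px), 0, (2, 2))
        assert not fit.converged

    def test_fit_conserves_photons_noiselessly(self):
        a, b, px = _blank_stack()
        add_spot(a[0], 25.5, 25.5, 1.5, 2000.0)
        add_spot(b[0], 25.5, 25.5, 1.5, 2000.0)
        fit = localize.fit_spot(_stack(a, b, px), 0, (25, 25))
        assert fit.photons_a == pytest.approx(2000.0, rel=0.05)

    def test_poisson_noise_precision_scales_with_photons(self):
        rng = np.random.default_rng(0)
        px, sigma_px, photons = 100.0, 1.5, 500.0
        errs = []
        for _ in range(40):
            a, b, _ = _blank_stack()
            add_spot(a[0], 30.5, 30.5, sigma_px, photons)
            add_spot(b[0], 30.5, 30.5, sigma_px, photons)
            a = rng.poisson(a).astype(float)
            b = rng.poisson(b).astype(float)
            fit = localize.fit_spot(_stack(a, b, px), 0, (30, 30))
            if fit.converged:
                errs.append(fit.x_a_nm / px - 30.5)
        rms = np.sqrt(np.mean(np.square(errs)))
        expected = sigma_px / np.sqrt(photons)
        assert rms < 2 * expected * 2  # within a factor 2 of the CRLB-style bound


class TestCalibration:
    def test_recovered_widths_match_generative_model(self, bead_calibration):
        cal, cfg = bead_calibration
        want_a, want_b = simulate.psf_widths(cfg, cal.z_samples_nm)
        np.testing.assert_allclose(cal.width_a_samples_nm, want_a, rtol=0.05)
        np.testing.assert_allclose(cal.width_b_samples_nm, want_b, rtol=0.05)

    def test_valid_range_covers_a_micron(self, bead_calibration):
        cal, _ = bead_calibration
        lo, hi = cal.valid_range_nm
        assert hi - lo >= 1000.0

    def test_equal_widths_map_to_focus(self, bead_calibration):
        cal, _ = bead_calibration
        assert abs(cal.z_from_widths(160.0, 160.0)) < 25.0

    def test_inversion_is_exact_on_calibration_samples(self, bead_calibration):
        cal, _ = bead_calibration
        lo, hi = cal.valid_range_nm
        for z, wa, wb in zip(
            cal.z_samples_nm, cal.width_a_samples_nm, cal.width_b_samples_nm
        ):
            if lo <= z <= hi:
                assert cal.z_from_widths(wa, wb) == pytest.approx(z, abs=1e-6)

    def test_non_monotone_ratio_is_rejected(self):
        z = np.arange(10) * 100.0
        w = np.full(10, 150.0)
        with pytest.raises(localize.CalibrationError):
            localize.PSFCalibration("x", z, w, w)

    def test_json_round_trip(self, bead_calibration, tmp_path):
        cal, _ = bead_calibration
        path = tmp_path / "cal.json"
        cal.to_json(path)
        back = localize.PSFCalibration.from_json(path)
        assert back.valid_range_nm == cal.valid_range_nm
        np.testing.assert_allclose(back.width_a_samples_nm, cal.width_a_samples_nm)


class TestLocalizeStack:
    def test_empty_stack_gives_empty_table(self, bead_calibration):
        cal, cfg = bead_calibration
        a, b, px = _blank_stack()
        table = localize.localize_stack(_stack(a, b, px), cal)
        assert len(table) == 0

    def test_z_recovered_within_50nm_at_1000_photons(self, bead_calibration):
        cal, cfg = bead_calibration
        rng = np.random.default_rng(5)
        errors = []
        for trial in range(10):
            a, b, px = _blank_stack()
            z_true = 300.0
            wa, wb = simulate.psf_widths(cfg, z_true)
            add_spot(a[0], 30.5, 30.5, float(wa) / px, 500.0)
            add_spot(b[0], 30.5, 30.5, float(wb) / px, 500.0)
            a = rng.poisson(a).astype(float)
            b = rng.poisson(b).astype(float)
            table = localize.localize_stack(_stack(a, b, px), cal, threshold_photons=30.0)
            if len(table) == 1:
                errors.append(table.df["z_nm"].iloc[0] - z_true)
        assert len(errors) >= 8
        assert abs(np.mean(errors)) < 50.0
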