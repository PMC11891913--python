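import numpy as np
import pytest

import memassay as ma
from memassay.meta import ValidationError


def flat_spectrum(value=7.0, lo=400.0, hi=650.0):
    wl = np.arange(lo, hi + 1.0)
    return ma.EmissionSpectrum(wl, np.full(wl.size, value))


class TestBackgroundSubtract:
    def test_self_subtraction_is_zero(self):
        sp = flat_spectrum(42.0)
        out = ma.background_subtract(sp, sp)
        assert np.all(out.intensities == 0.0)

    def test_constant_offset_removed(self):
        sp = flat_spectrum(150.0)
        bg = flat_spectrum(100.0)
        out = ma.background_subtract(sp, bg)
        assert np.all(out.intensities == 50.0)

    def test_negative_residuals_preserved(self):
        sp = flat_spectrum(90.0)
        bg = flat_spectrum(100.0)
        out = ma.background_subtract(sp, bg)
        assert np.all(out.intensities == -10.0)

    def test_generator_baseline_recovery(self):
        spectra, _ = ma.simulate_spectra("laurdan", [0.3], noise_sd=0.0)
        sp = spectra[0]
        offset = ma.EmissionSpectrum(sp.wavelengths,
                                     sp.intensities + 100.0)
        bg = ma.EmissionSpectrum(sp.wavelengths,
                                 np.full(sp.wavelengths.size, 100.0))
        out = ma.background_subtract(offset, bg)
        np.testing.assert_allclose(out.intensities, sp.intensities,
                                   atol=1e-12)

    def test_non_overlapping_grid_rejected(self):
        sp = flat_spectrum(lo=400, hi=650)
        bg = flat_spectrum(lo=500, hi=650)
        with pytest.raises(ValidationError, match="cover"):
            ma.background_subtract(sp, bg)


class TestBandIntensity:
    def test_flat_spectrum_both_modes(self):
        sp = flat_spectrum(7.0)
        assert ma.band_intensity(sp, 520.0, "peak") == 7.0
        assert ma.band_intensity(sp, 520.0, "interp") == 7.0

    def test_triangular_peak_apex(self):
        wl = np.arange(500.0, 541.0)
        inten = np.maximum(0.0, 10.0 - np.abs(wl - 520.0))
        sp = ma.EmissionSpectrum(wl, inten)
        assert ma.band_intensity(sp, 520.0, "peak") == 10.0

    def test_interp_matches_gaussian_closed_form(self):
        spectra, _ = ma.simulate_spectra("laurdan", [0.2], noise_sd=0.0,
                                         amplitude=1.0)
        sp = spectra[0]
        from memassay.synth import LAURDAN_BAND_SD, _laurdan_amplitudes
        a440, a490 = _laurdan_amplitudes(0.2)
        expected = (a440 + a490 * np.exp(-0.5 * (50.0 / LAURDAN_BAND_SD) ** 2))
        assert ma.band_intensity(sp, 440.0, "interp") == pytest.approx(
            expected, rel=1e-9)

    def test_window_outside_grid_rejected(self):
        sp = flat_spectrum(lo=500, hi=560)
        with pytest.raises(ValidationError, match="window"):
            ma.band_intensity(sp, 580.0, "peak")


class TestGP:
    @pytest.mark.parametrize("i440,i490,expected", [
        (5.0, 5.0, 0.0), (5.0, 0.0, 1.0), (2.0, 1.0, 1.0 / 3.0)])
    def test_direct_arithmetic(self, i440, i490, expected):
        wl = np.array([430.0, 440.0, 450.0, 480.0, 490.0, 500.0])
        inten = np.array([i440, i440, i440, i490, i490, i490])
        res = ma.gp(ma.EmissionSpectrum(wl, inten))
        assert res.GP == pytest.approx(expected, rel=1e-12)

    def test_zero_total_intensity_rejected(self):
        sp = flat_spectrum(0.0)
        with pytest.raises(ValidationError, match="GP undefined"):
            ma.gp(sp)

    def test_gain_invariance(self):
        spectra, _ = ma.simulate_spectra("laurdan", [0.33], noise_sd=0.0)
        sp = spectra[0]
        scaled = ma.EmissionSpectrum(sp.wavelengths, sp.intensities * 37.5)
        assert ma.gp(scaled).GP == pytest.approx(ma.gp(sp).GP, rel=1e-12)


class TestDeltaGP:
    def test_constant_series_zero(self):
        spectra, _ = ma.simulate_spectra("laurdan", [0.3, 0.3, 0.3],
                                         noise_sd=0.0)
        out = ma.delta_gp([ma.gp(sp) for sp in spectra])
        assert all(r.delta_GP == pytest.approx(0.0, abs=1e-12) for r in out)

    def test_step_trajectory(self):
        spectra, _ = ma.simulate_spectra("laurdan", [0.30, 0.38],
                                         noise_sd=0.0)
        out = ma.delta_gp([ma.gp(sp) for sp in spectra])
        assert out[1].delta_GP == pytest.approx(0.08, abs=1e-9)
        assert out[0].GP0 == pytest.approx(0.30, abs=1e-9)

    def test_order_invariance(self):
        spectra, _ = ma.simulate_spectra("laurdan", [0.30, 0.34, 0.38],
                                         noise_sd=0.0)
        results = [ma.gp(sp) for sp in spectra]
        fwd = ma.delta_gp(results)
        rev = ma.delta_gp(results[::-1])
        assert {r.time_min: r.delta_GP for r in fwd} == {
            r.time_min: r.delta_GP for r in rev}

    def test_missing_reference_rejected(self):
        spectra, _ = ma.simulate_spectra("laurdan", [0.3, 0.35],
                                         times=[10.0, 20.0], noise_sd=0.0)
        with pytest.raises(ValidationError, match="reference"):
            ma.delta_gp([ma.gp(sp) for sp in spectra])


class TestFret:
    def test_equal_bands_ratio_one(self):
        wl = np.arange(480.0, 651.0)
        inten = (np.exp(-0.5 * ((wl - 520.0) / 10.0) ** 2)
                 + np.exp(-0.5 * ((wl - 580.0) / 10.0) ** 2))
        res = ma.fret_ratio(ma.EmissionSpectrum(wl, inten))
        assert res.R == pytest.approx(1.0, rel=1e-9)

    def test_donor_twice_acceptor(self):
        wl = np.arange(480.0, 651.0)
        inten = (2.0 * np.exp(-0.5 * ((wl - 520.0) / 10.0) ** 2)
                 + np.exp(-0.5 * ((wl - 580.0) / 10.0) ** 2))
        res = ma.fret_ratio(ma.EmissionSpectrum(wl, inten))
        # tiny cross-talk between the 10 nm bands limits the agreement
        assert res.R == pytest.approx(2.0, rel=1e-6)

    def test_triton_gives_largest_ratio(self):
        spectra, truth = ma.simulate_spectra("fret", [0.0, 0.5, 1.0],
                                             noise_sd=0.0)
        ratios = [ma.fret_ratio(sp).R for sp in spectra]
        assert np.argmax(ratios) == truth["triton_index"]


class TestLME:
    def test_endpoints(self):
        assert ma.lme(0.5, 0.5, 3.0)[0] == 0.0
        assert ma.lme(3.0, 0.5, 3.0)[0] == 1.0

    def test_degenerate_normalization_rejected(self):
        with pytest.raises(ValidationError, match="degenerate"):
            ma.lme(1.0, 0.5, 0.5)

    def test_above_theoretical_max_flagged(self):
        value, flags = ma.lme(2.0, 0.5, 3.0)
        assert value == 0.6
        assert "above_theoretical_max" in flags

    def test_complete_single_round_fusion_reaches_max(self):
        spectra, _ = ma.simulate_spectra("fret", [0.0, 1.0], noise_sd=0.0)
        out = ma.lme_series(spectra[:-1], spectra[-1])
        assert out[-1].LME == pytest.approx(0.4, abs=1e-3)

    def test_rescaling_invariance(self):
        spectra, _ = ma.simulate_spectra("fret", [0.0, 0.6], noise_sd=0.0)
        scaled = [ma.EmissionSpectrum(sp.wavelengths, sp.intensities * 11.0,
                                      time_min=sp.time_min)
                  for sp in spectra]
        a = ma.lme_series(spectra[:-1], spectra[-1])
        b = ma.lme_series(scaled[:-1], scaled[-1])
        assert b[-1].LME == pytest.approx(a[-1].LME, rel=1e-12)

    def test_monotone_in_fused_fraction(self):
        phis = [0.0, 0.2, 0.5, 0.8, 1.0]
        spectra, _ = ma.simulate_spectra("fret", phis, noise_sd=0.0)
        out = ma.lme_series(spectra[:-1], spectra[-1])
        values = [r.LME for r in out]
        assert all(b > a for a, b in zip(values, values[1:]))


class TestTheoreticalMax:
    def test_paper_mixture(self):
        assert ma.theoretical_lme_max(0.2) == pytest.approx(0.4, abs=1e-12)

    def test_all_labeled_gives_zero(self):
        assert ma.theoretical_lme_max(1.0) == 0.0

    def test_dilute_label_limit_half(self):
        assert ma.theoretical_lme_max(1e-9) == pytest.approx(0.5, abs=1e-8)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            ma.theoretical_lme_max(0.0)


class TestIntensityLoss:
    def test_constant_series_unflagged(self):
        spectra, _ = ma.simulate_spectra("fret", [0.0, 0.0, 0.0],
                                         noise_sd=0.0, include_triton=False)
        flags = ma.flag_intensity_loss(spectra)
        assert all(not f for f in flags)

    def test_drop_below_half_flagged(self):
        spectra, _ = ma.simulate_spectra("fret", [0.0, 0.0], noise_sd=0.0,
                                         include_triton=False)
        dimmed = ma.EmissionSpectrum(spectra[1].wavelengths,
                                     spectra[1].intensities * 0.49,
                                     time_min=10.0)
        flags = ma.flag_intensity_loss([spectra[0], dimmed])
        assert "nbd_loss_gt_50pct" in flags[1]
        assert not flags[0]

    def test_attenuation_scenario_flags_attenuated_points_only(self):
        spectra, _ = ma.simulate_spectra(
            "fret", [0.0, 0.2, 0.2, 0.2], times=[0.0, 10.0, 20.0, 30.0],
            noise_sd=0.0, include_triton=False,
            attenuation={"factor": 0.3, "from_time": 20.0})
        flags = ma.flag_intensity_loss(spectra)
        assert [bool(f) for f in flags] == [False, False, True, True]

    def test_no_preaddition_spectrum_rejected(self):
        spectra, _ = ma.simulate_spectra("fret", [0.2], times=[10.0],
                                         noise_sd=0.0, include_triton=False)
        with pytest.raises(ValidationError, match="pre-addition"):
            ma.flag_intensity_loss(spectra)
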