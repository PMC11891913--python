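import numpy as np
import pytest

import memassay as ma
from memassay.meta import ValidationError

from conftest import biexp_grid_oracle


class TestBiexponentialFit:
    def test_noiseless_recovery(self, noiseless_decay):
        decay, truth = noiseless_decay
        fit = ma.fit_biexponential(decay)
        acq = decay.acquisition_s
        assert fit.B_E * acq == pytest.approx(truth["B_E"], rel=1e-6)
        assert fit.B_F * acq == pytest.approx(truth["B_F"], rel=1e-6)
        assert fit.tau_E == pytest.approx(truth["tau_E"], rel=1e-6)
        assert fit.tau_F == pytest.approx(truth["tau_F"], rel=1e-6)
        assert fit.tau_E < fit.tau_F

    def test_matches_grid_search_oracle(self, noiseless_decay):
        """Poisson MLE vs an independent lifetime grid search with linear
        amplitude solves, on noiseless data."""
        decay, _ = noiseless_decay
        fit = ma.fit_biexponential(decay)
        b_e, t_e, b_f, t_f = biexp_grid_oracle(decay)
        acq = decay.acquisition_s
        assert fit.tau_E == pytest.approx(t_e, rel=1e-6)
        assert fit.tau_F == pytest.approx(t_f, rel=1e-6)
        assert fit.B_E * acq == pytest.approx(b_e, rel=1e-6)
        assert fit.B_F * acq == pytest.approx(b_f, rel=1e-6)

    def test_single_exponential_collapses_degenerate(self):
        decay, _ = ma.simulate_decay(1.0, 0.0, poisson=False)
        fit = ma.fit_biexponential(decay)
        assert fit.B_E < 0.01 * fit.B_F
        assert "degenerate" in fit.qc_flags

    def test_poisson_amplitude_fraction_bias(self):
        """Seed-averaged amplitude-fraction bias below 1% at 1e6 counts."""
        fracs = []
        for seed in range(20):
            decay, truth = ma.simulate_decay(0.4, 0.0, seed=seed)
            fit = ma.fit_biexponential(decay)
            fracs.append(fit.B_F / (fit.B_F + fit.B_E))
        true_frac = truth["B_F"] / (truth["B_F"] + truth["B_E"])
        assert abs(np.mean(fracs) - true_frac) < 0.01

    def test_low_counts_flagged(self):
        decay, _ = ma.simulate_decay(0.5, 0.0, total_counts=5e3, seed=1)
        fit = ma.fit_biexponential(decay)
        assert "low_counts" in fit.qc_flags

    def test_fix_tauf_pins_free_lifetime(self, noiseless_decay):
        decay, _ = noiseless_decay
        fit = ma.fit_biexponential(decay, fix_tauf=4.2)
        assert fit.tau_F == pytest.approx(4.2, abs=1e-9)

    def test_acquisition_normalization(self):
        """Amplitudes are reported per second of acquisition."""
        d1, _ = ma.simulate_decay(0.3, 0.0, poisson=False, acquisition_s=30.0)
        d2, _ = ma.simulate_decay(0.3, 0.0, poisson=False, acquisition_s=60.0)
        f1, f2 = ma.fit_biexponential(d1), ma.fit_biexponential(d2)
        assert f1.B_F * 30.0 == pytest.approx(f2.B_F * 60.0, rel=1e-6)


class TestQstat:
    def test_no_static_quenching_gives_unity(self):
        intact, _ = ma.simulate_decay(0.0, 0.0, poisson=False)
        release, _ = ma.simulate_decay(1.0, 0.0, poisson=False)
        q, flags = ma.calibrate_qstat(ma.fit_biexponential(intact),
                                      ma.fit_biexponential(release))
        assert q == pytest.approx(1.0, abs=1e-6)
        assert not flags

    def test_dark_fraction_half_gives_two(self):
        intact, _ = ma.simulate_decay(0.0, 0.5, poisson=False)
        release, _ = ma.simulate_decay(1.0, 0.5, poisson=False)
        q, flags = ma.calibrate_qstat(ma.fit_biexponential(intact),
                                      ma.fit_biexponential(release))
        assert q == pytest.approx(2.0, abs=1e-6)
        assert not flags

    def test_pipetting_loss_flagged(self):
        intact, _ = ma.simulate_decay(0.0, 0.0, poisson=False)
        release, _ = ma.simulate_decay(1.0, 0.0, scale=0.9, poisson=False)
        q, flags = ma.calibrate_qstat(ma.fit_biexponential(intact),
                                      ma.fit_biexponential(release))
        assert q == pytest.approx(0.9, abs=1e-6)
        assert "qstat_lt_1" in flags

    def test_no_entrapped_amplitude_rejected(self):
        released, _ = ma.simulate_decay(1.0, 0.0, poisson=False)
        fit = ma.fit_biexponential(released)
        with pytest.raises(ValidationError, match="entrapped"):
            ma.calibrate_qstat(fit, fit)


class TestLeakageTotal:
    def test_sample_equal_to_reference_is_zero(self, noiseless_decay):
        decay, _ = noiseless_decay
        fit = ma.fit_biexponential(decay)
        res = ma.leakage_total(fit, fit, 2.0)
        assert res.L_total == 0.0

    def test_full_release_is_one(self):
        ref, _ = ma.simulate_decay(0.0, 0.5, poisson=False)
        full, _ = ma.simulate_decay(1.0, 0.5, poisson=False)
        res = ma.leakage_total(ma.fit_biexponential(full),
                               ma.fit_biexponential(ref), 2.0)
        assert res.L_total == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("true_leak", [0.0, 0.25, 0.5, 0.75, 1.0])
    def test_poisson_recovery_bias(self, true_leak):
        """|bias| < 0.02 over 20 Poisson realizations at each leak level."""
        values = []
        for seed in range(20):
            decay, _ = ma.simulate_decay(true_leak, 0.5, seed=1000 + seed)
            ref, _ = ma.simulate_decay(0.0, 0.5, seed=7000 + seed)
            res = ma.leakage_total(ma.fit_biexponential(decay),
                                   ma.fit_biexponential(ref), 2.0)
            values.append(res.L_total)
        assert abs(np.mean(values) - true_leak) < 0.02

    def test_sum_of_b_conserved_with_calibrated_qstat(self):
        """With the correct Q_stat the Sum of B is constant across leak
        levels generated from the same total calcein."""
        sums = []
        for leak in (0.0, 0.3, 0.6, 1.0):
            decay, _ = ma.simulate_decay(leak, 0.5, poisson=False)
            fit = ma.fit_biexponential(decay)
            sums.append(fit.B_F + 2.0 * fit.B_E)
        np.testing.assert_allclose(sums, sums[0], rtol=1e-5)

    def test_acquisition_rescale_invariance(self):
        decay, _ = ma.simulate_decay(0.5, 0.5, poisson=False)
        ref, _ = ma.simulate_decay(0.0, 0.5, poisson=False)
        res1 = ma.leakage_total(ma.fit_biexponential(decay),
                                ma.fit_biexponential(ref), 2.0)
        decay.acquisition_s = 120.0
        ref.acquisition_s = 120.0
        res2 = ma.leakage_total(ma.fit_biexponential(decay),
                                ma.fit_biexponential(ref), 2.0)
        assert res2.L_total == pytest.approx(res1.L_total, rel=1e-9)

    def test_fully_leaked_reference_rejected(self):
        full, _ = ma.simulate_decay(1.0, 0.0, poisson=False)
        fit = ma.fit_biexponential(full)
        with pytest.raises(ValidationError, match="reference"):
            ma.leakage_total(fit, fit, 1.0)


class TestSumOfBQC:
    def _result(self, sum_of_b, ref=100.0):
        return ma.LeakageResult(L_total=0.1, L_total_raw=0.1, B_F0=1.0,
                                Q_stat=2.0, sum_of_B=sum_of_b,
                                sum_of_B_ref=ref)

    def test_constant_sum_not_flagged(self):
        out = ma.sum_of_b_qc([self._result(100.0), self._result(99.0)])
        assert all("sum_of_b_drop_gt_20pct" not in r.qc_flags for r in out)

    def test_drop_to_79_percent_flagged(self):
        out = ma.sum_of_b_qc([self._result(79.0), self._result(81.0)])
        assert "sum_of_b_drop_gt_20pct" in out[0].qc_flags
        assert "sum_of_b_drop_gt_20pct" not in out[1].qc_flags

    def test_attenuation_scenario_flag_appears_and_clears(self):
        ref, _ = ma.simulate_decay(0.0, 0.5, seed=11)
        ref_fit = ma.fit_biexponential(ref)
        attenuated, _ = ma.simulate_decay(0.3, 0.5, scale=0.5, seed=12)
        clean, _ = ma.simulate_decay(0.3, 0.5, seed=12)
        results = [ma.leakage_total(ma.fit_biexponential(d), ref_fit, 2.0)
                   for d in (attenuated, clean)]
        out = ma.sum_of_b_qc(results)
        assert "sum_of_b_drop_gt_20pct" in out[0].qc_flags
        assert "sum_of_b_drop_gt_20pct" not in out[1].qc_flags


class TestClassification:
    def test_all_or_none_series(self):
        fits = []
        for i, (conc, leak) in enumerate([(0, 0.0), (1, 0.0), (3, 0.05),
                                          (5, 0.15), (10, 0.35), (30, 0.5),
                                          (100, 0.6)]):
            decay, _ = ma.simulate_decay(leak, 0.5, seed=200 + i)
            fits.append((conc, ma.fit_biexponential(decay)))
        assert ma.classify_leakage_mode(fits, q_stat=2.0) == "all_or_none"

    def test_graded_series(self):
        fits = []
        taus = [(0, 0.4), (1, 0.45), (3, 0.6), (5, 0.9), (10, 1.3),
                (30, 1.7), (100, 2.0)]
        for i, (conc, tau_e) in enumerate(taus):
            decay, _ = ma.simulate_decay(0.2, 0.5, tau_e=tau_e, seed=300 + i)
            fits.append((conc, ma.fit_biexponential(decay)))
        assert ma.classify_leakage_mode(fits, q_stat=2.0) == "graded"

    def test_flat_series_indeterminate(self):
        fits = []
        for i, conc in enumerate([0, 1, 3, 10]):
            decay, _ = ma.simulate_decay(0.0, 0.5, seed=400 + i)
            fits.append((conc, ma.fit_biexponential(decay)))
        assert ma.classify_leakage_mode(fits, q_stat=2.0) == "indeterminate"

    def test_too_few_points_rejected(self):
        decay, _ = ma.simulate_decay(0.0, 0.5, seed=1)
        fit = ma.fit_biexponential(decay)
        with pytest.raises(ValidationError, match="3"):
            ma.classify_leakage_mode([(0, fit), (1, fit)])
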