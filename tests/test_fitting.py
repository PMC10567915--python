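"""Time-domain fitter: recovery, constraints, CRLB calibration, SNR, QC."""

import math
from types import SimpleNamespace

import numpy as np
import pandas as pd
import pytest

import mrsquant as mq
from mrsquant.config import QCConfig
from mrsquant.errors import ConstraintSpecificationError, SchemaError
from mrsquant.fitting import (FitOptions, PriorConstraint, compute_crlb,
                              estimate_noise_sd, fit_time_domain, qc_filter,
                              spectrum_snr)
from mrsquant.spectral import Multiplet, synthesize


def _single(amplitude=1.0, shift=1.2, damping=6.0, phase=25.0):
    return mq.ResonanceSpec("line", shift, amplitude, damping, phase)


class TestRecovery:
    def test_noiseless_single_lorentzian_exact(self, p_acq):
        truth = _single()
        fid = mq.simulate_fid([truth], p_acq)
        fit = fit_time_domain(fid, [mq.ResonanceSpec("line", 1.2, 1.0, 5.0, 0.0)])
        row = fit.params.loc["line"]
        assert row["amplitude"] == pytest.approx(1.0, rel=1e-6)
        assert row["shift_ppm"] == pytest.approx(1.2, abs=1e-6)
        assert row["damping_hz"] == pytest.approx(6.0, rel=1e-6)
        assert row["phase_deg"] == pytest.approx(25.0, abs=1e-4)
        assert fit.converged

    def test_doublet_with_ratio_and_offset_links(self, p_acq):
        """gATP doublet built from two ratio/offset-linked singlets: total
        amplitude recovered to 1e-6 with J fixed at truth via the shift link."""
        j_ppm = 16.0 / p_acq.nucleus_freq_mhz
        truth = mq.ResonanceSpec("gATP", -2.5, 2.0, 5.0, multiplet=Multiplet(2, 16.0))
        fid = mq.simulate_fid([truth], p_acq)
        model = [mq.ResonanceSpec("g1", -2.5 - j_ppm / 2, 1.0, 4.0, 0.0),
                 mq.ResonanceSpec("g2", -2.5 + j_ppm / 2, 1.0, 4.0, 0.0)]
        constraints = [PriorConstraint("g2", "amplitude", "ratio", ("g1", 1.0)),
                       PriorConstraint("g2", "shift", "offset", ("g1", j_ppm))]
        fit = fit_time_domain(fid, model, constraints)
        total = fit.amplitude("g1") + fit.amplitude("g2")
        assert total == pytest.approx(2.0, rel=1e-6)
        assert fit.amplitude("g1") == pytest.approx(fit.amplitude("g2"), rel=1e-9)

    def test_self_consistency_full_model(self, p_acq, p_truth, p_prior, p_constraints):
        """Fitting the model's own noiseless output leaves ~zero residual."""
        fid = mq.simulate_fid(p_truth, p_acq)
        fit = fit_time_domain(fid, p_prior, p_constraints)
        signal_norm = float(np.linalg.norm(
            np.concatenate([fid.samples.real, fid.samples.imag])))
        assert fit.residual_norm < 1e-8 * signal_norm

    def test_grid_search_oracle(self, p_acq):
        """On a 3-parameter problem the fit matches a dense grid search."""
        truth = mq.ResonanceSpec("x", 0.8, 1.3, 7.0, 0.0)
        fid = mq.simulate_fid([truth], p_acq, noise_sd=0.05, seed=4)
        fit = fit_time_domain(fid, [mq.ResonanceSpec("x", 0.8, 1.0, 5.0, 0.0)],
                              [PriorConstraint("x", "phase", "fix", 0.0)])
        t = p_acq.times()
        data = fid.samples
        best = (np.inf, None, None)
        shifts = np.linspace(0.7, 0.9, 41)
        dampings = np.linspace(5.0, 9.0, 41)
        for sh in shifts:
            for d in dampings:
                basis = np.exp((-math.pi * d + 2j * math.pi * p_acq.ppm_to_hz(sh)) * t)
                a = max(0.0, float(np.real(np.vdot(basis, data))
                                   / np.real(np.vdot(basis, basis))))
                cost = float(np.sum(np.abs(data - a * basis) ** 2))
                if cost < best[0]:
                    best = (cost, sh, d)
        fit_cost = fit.residual_norm ** 2
        assert fit_cost <= best[0] + 1e-9
        assert fit.shift("x") == pytest.approx(best[1], abs=shifts[1] - shifts[0])
        assert fit.params.loc["x", "damping_hz"] == pytest.approx(
            best[2], abs=dampings[1] - dampings[0])

    def test_monte_carlo_single_resonance_calibration(self, p_acq):
        """200 noisy replicates: unbiased within 2 SEM, SD within 20% of CRLB."""
        truth = _single(amplitude=1.0, shift=0.0, damping=5.0, phase=0.0)
        sigma = 0.01
        crlb = compute_crlb(p_acq, [truth], sigma)
        sd_amp = crlb.loc["line", "sd_amplitude"]
        rng = np.random.default_rng(99)
        estimates = []
        for _ in range(200):
            fid = mq.simulate_fid([truth], p_acq, sigma, seed=int(rng.integers(2**31)))
            fit = fit_time_domain(fid, [mq.ResonanceSpec("line", 0.0, 1.0, 5.0, 0.0)])
            estimates.append(fit.amplitude("line"))
        estimates = np.asarray(estimates)
        sem = estimates.std(ddof=1) / np.sqrt(estimates.size)
        assert abs(estimates.mean() - 1.0) < 2 * sem
        assert estimates.std(ddof=1) == pytest.approx(sd_amp, rel=0.20)


class TestConstraints:
    def test_constraint_satisfaction_to_1e9(self, p_acq):
        truth = [mq.ResonanceSpec("a", 2.0, 1.0, 5.0),
                 mq.ResonanceSpec("b", 1.0, 0.6, 7.0)]
        fid = mq.simulate_fid(truth, p_acq, noise_sd=0.05, seed=11)
        constraints = [PriorConstraint("b", "amplitude", "ratio", ("a", 0.6)),
                       PriorConstraint("b", "shift", "offset", ("a", -1.0)),
                       PriorConstraint("a", "damping", "fix", 5.0),
                       PriorConstraint("b", "phase", "fix", 0.0)]
        fit = fit_time_domain(fid, [mq.ResonanceSpec("a", 2.0, 1.0, 5.0, 0.0),
                                    mq.ResonanceSpec("b", 1.0, 1.0, 7.0, 0.0)],
                              constraints)
        pa, pb = fit.params.loc["a"], fit.params.loc["b"]
        assert pb["amplitude"] == pytest.approx(0.6 * pa["amplitude"], rel=1e-9)
        assert pb["shift_ppm"] == pytest.approx(pa["shift_ppm"] - 1.0, abs=1e-9)
        assert pa["damping_hz"] == 5.0
        assert pb["phase_deg"] == 0.0

    def test_linked_sd_scales_with_ratio(self, p_acq):
        truth = [mq.ResonanceSpec("a", 2.0, 1.0, 5.0),
                 mq.ResonanceSpec("b", 1.0, 0.5, 5.0)]
        cons = [PriorConstraint("b", "amplitude", "ratio", ("a", 0.5))]
        crlb = compute_crlb(p_acq, truth, 0.1, cons)
        assert crlb.loc["b", "sd_amplitude"] == pytest.approx(
            0.5 * crlb.loc["a", "sd_amplitude"], rel=1e-9)

    @pytest.mark.parametrize("bad", [
        [PriorConstraint("a", "amplitude", "ratio", ("ghost", 0.5))],
        [PriorConstraint("a", "amplitude", "ratio", ("a", 0.5))],
        [PriorConstraint("a", "amplitude", "ratio", ("b", 0.5)),
         PriorConstraint("b", "amplitude", "ratio", ("c", 0.5))],
    ])
    def test_invalid_constraint_sets(self, p_acq, bad):
        model = [mq.ResonanceSpec("a", 2.0), mq.ResonanceSpec("b", 1.0),
                 mq.ResonanceSpec("c", 0.0)]
        fid = mq.simulate_fid(model, p_acq)
        with pytest.raises(ConstraintSpecificationError):
            fit_time_domain(fid, model, bad)

    def test_ratio_only_for_amplitudes(self):
        with pytest.raises(ConstraintSpecificationError):
            PriorConstraint("a", "shift", "ratio", ("b", 0.5))
        with pytest.raises(ConstraintSpecificationError):
            PriorConstraint("a", "amplitude", "offset", ("b", 0.5))

    def test_no_free_parameters_rejected(self, p_acq):
        model = [mq.ResonanceSpec("a", 0.0)]
        cons = [PriorConstraint("a", p, "fix", 0.0 if p != "damping" else 5.0)
                for p in ("amplitude", "shift", "damping", "phase")]
        fid = mq.simulate_fid(model, p_acq)
        with pytest.raises(ConstraintSpecificationError):
            fit_time_domain(fid, model, cons)

    def test_fid_too_short(self, p_acq, p_truth):
        acq_small = mq.AcquisitionParams(1200, 2.3, 60, 2000, 64, 49.9, "phosphorus")
        fid = mq.simulate_fid(p_truth, acq_small)
        with pytest.raises(SchemaError):
            fit_time_domain(fid, p_truth)


class TestCRLB:
    def test_linear_scaling_and_noiseless_limit(self, p_acq, p_truth):
        c1 = compute_crlb(p_acq, p_truth, 0.05)
        c2 = compute_crlb(p_acq, p_truth, 0.10)
        np.testing.assert_allclose(c2.to_numpy(), 2.0 * c1.to_numpy(), rtol=1e-9)
        c0 = compute_crlb(p_acq, p_truth, 0.0)
        assert float(c0.to_numpy().max()) == 0.0

    def test_closed_form_single_sinusoid_oracle(self, p_acq):
        """Fisher information of one damped sinusoid assembled from closed-form
        geometric sums matches the generic Jacobian-based CRLB within 1%."""
        amp, shift, damping, sigma = 1.7, 0.9, 6.0, 0.05
        n = p_acq.vector_size
        dt = p_acq.dwell_s
        q = math.exp(-2.0 * math.pi * damping * dt)
        s0 = (1 - q ** n) / (1 - q)
        s1 = dt * q * (1 - n * q ** (n - 1) + (n - 1) * q ** n) / (1 - q) ** 2
        inf_sum2 = q * (1 + q) / (1 - q) ** 3
        tail2 = q ** n * (inf_sum2 + 2 * n * q / (1 - q) ** 2 + n * n / (1 - q))
        s2 = dt * dt * (inf_sum2 - tail2)
        k_f = 2.0 * math.pi * p_acq.nucleus_freq_mhz   # rad/s per ppm
        k_d = math.pi
        fisher = np.array([
            [s0, 0.0, -amp * k_d * s1, 0.0],
            [0.0, amp**2 * k_f**2 * s2, 0.0, amp**2 * k_f * s1],
            [-amp * k_d * s1, 0.0, amp**2 * k_d**2 * s2, 0.0],
            [0.0, amp**2 * k_f * s1, 0.0, amp**2 * s0],
        ]) / sigma**2
        sd_oracle = np.sqrt(np.diag(np.linalg.inv(fisher)))
        crlb = compute_crlb(p_acq, [mq.ResonanceSpec("x", shift, amp, damping)], sigma)
        got = crlb.loc["x", ["sd_amplitude", "sd_shift_ppm", "sd_damping_hz"]].to_numpy()
        np.testing.assert_allclose(got, sd_oracle[:3], rtol=0.01)
        assert math.radians(crlb.loc["x", "sd_phase_deg"]) == pytest.approx(
            sd_oracle[3], rel=0.01)

    def test_crlb_calibration_across_snr(self, p_acq):
        """Empirical SD / CRLB in [0.8, 1.3] for an isolated resonance, SNR 5-50."""
        truth = _single(amplitude=1.0, shift=0.0, damping=5.0, phase=0.0)
        rng = np.random.default_rng(17)
        for sigma in (0.2, 0.05, 0.02):  # spans spectral SNR roughly 5-50
            crlb = compute_crlb(p_acq, [truth], sigma).loc["line", "sd_amplitude"]
            est = []
            for _ in range(200):
                fid = mq.simulate_fid([truth], p_acq, sigma,
                                      seed=int(rng.integers(2**31)))
                fit = fit_time_domain(fid, [mq.ResonanceSpec("line", 0.0, 1.0, 5.0, 0.0)])
                est.append(fit.amplitude("line"))
            ratio = np.std(est, ddof=1) / crlb
            assert 0.8 <= ratio <= 1.3

    def test_singular_information_reports_infinite_sd(self, p_acq):
        """Two exactly coincident lines cannot be separated: infinite sd."""
        model = [mq.ResonanceSpec("a", 1.0, 1.0, 5.0),
                 mq.ResonanceSpec("b", 1.0, 1.0, 5.0)]
        crlb = compute_crlb(p_acq, model, 0.05)
        assert np.isinf(crlb.loc["a", "sd_amplitude"])
        assert np.isinf(crlb.loc["b", "sd_amplitude"])


class TestNoiseEstimate:
    def test_tail_estimate_recovers_noise_sd(self, p_acq, p_truth):
        fid = mq.simulate_fid(p_truth, p_acq, noise_sd=0.5, seed=3)
        assert estimate_noise_sd(fid) == pytest.approx(0.5, rel=0.2)


class TestSNR:
    def test_noiseless_snr_infinite(self, p_acq, p_truth, p_prior, p_constraints):
        fid = mq.simulate_fid(p_truth, p_acq)
        fit = fit_time_domain(fid, p_prior, p_constraints)
        assert np.isinf(fit.spectrum_snr) or fit.spectrum_snr > 1e6

    def test_snr_linear_in_amplitude(self, p_acq, p_truth):
        """Doubling all amplitudes at fixed noise doubles the SNR within 5%."""
        sigma = mq.noise_sd_for_snr(p_truth, p_acq, 15.0)
        doubled = [mq.ResonanceSpec(r.name, r.shift_ppm, 2 * r.amplitude,
                                    r.damping_hz, r.phase_deg, r.multiplet)
                   for r in p_truth]
        fid1 = mq.simulate_fid(p_truth, p_acq, sigma, seed=8)
        fid2 = mq.simulate_fid(doubled, p_acq, sigma, seed=8)
        snr1, _ = spectrum_snr(fid1, model=p_truth)
        snr2, _ = spectrum_snr(fid2, model=doubled)
        assert snr2 == pytest.approx(2 * snr1, rel=0.05)

    def test_pure_noise_snr_below_threshold(self, p_acq, p_prior, p_constraints):
        """Fitting the standard model to signal-free noise: SNR < 3 in >= 95/100."""
        below = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            samples = (rng.normal(0, 1.0, p_acq.vector_size)
                       + 1j * rng.normal(0, 1.0, p_acq.vector_size))
            fid = mq.FidRecord(samples, p_acq)
            fit = fit_time_domain(fid, p_prior, p_constraints)
            if fit.spectrum_snr < 3.0:
                below += 1
        assert below >= 95


class TestQC:
    @staticmethod
    def _fake_fit(snr, rel_errors):
        params = pd.DataFrame({
            "amplitude": [1.0] * len(rel_errors),
            "relative_error": list(rel_errors.values()),
        }, index=list(rel_errors.keys()))
        return SimpleNamespace(spectrum_snr=snr, params=params)

    def test_low_snr_spectrum_rejected(self):
        verdict = qc_filter(self._fake_fit(2.9, {"PCr": 0.05}), "phosphorus")
        assert not verdict.spectrum_ok

    def test_snr_exactly_three_rejected(self):
        assert not qc_filter(self._fake_fit(3.0, {"PCr": 0.05}), "phosphorus").spectrum_ok

    def test_phosphorus_peak_exclusion_keeps_spectrum(self):
        verdict = qc_filter(self._fake_fit(10.0, {"PCr": 0.05, "NAD": 1.2}),
                            "phosphorus")
        assert verdict.spectrum_ok
        assert verdict.excluded_peaks == ["NAD"]

    def test_proton_percent_sd_rejection(self):
        verdict = qc_filter(self._fake_fit(10.0, {"tCr": 0.05, "tCho": 0.25}), "proton")
        assert not verdict.spectrum_ok
        assert any("tCho" in r for r in verdict.reasons)

    def test_proton_pass(self):
        verdict = qc_filter(self._fake_fit(10.0, {"tNAA": 0.02, "tCr": 0.05,
                                                  "tCho": 0.10}), "proton")
        assert verdict.spectrum_ok and not verdict.reasons


class TestDiagnostics:
    def test_non_convergence_flagged_not_raised(self, p_acq, p_truth, p_prior):
        sigma = mq.noise_sd_for_snr(p_truth, p_acq, 10.0)
        fid = mq.simulate_fid(p_truth, p_acq, sigma, seed=1)
        fit = fit_time_domain(fid, p_prior, options=FitOptions(max_nfev=1))
        assert fit.converged is False

    def test_summary_mentions_all_resonances(self, p_acq, p_truth, p_prior):
        fid = mq.simulate_fid(p_truth, p_acq)
        fit = fit_time_domain(fid, p_prior)
        text = fit.summary()
        for r in p_truth:
            assert r.name in text
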