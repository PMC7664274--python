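"""GHK permeability, Boltzmann fits, I-V extraction, ramp analysis."""

import dataclasses

import numpy as np
import pytest

from ephysepi import synthetic as sd
from ephysepi import voltage_clamp as vc


CTX = vc.GHKContext(valence=1, c_in_mm=10.0, c_out_mm=30.0,
                    temperature_k=295.0)


class TestGHK:
    def test_round_trip_inversion_is_exact(self):
        """P -> I -> P recovers permeability to 1e-10 relative at every
        non-reversal voltage in [-120, +30] mV."""
        p_true = 1e-5
        erev = CTX.reversal_mv()
        for e in np.arange(-120.0, 31.0, 1.0):
            if abs(e - erev) < 1.0:
                continue
            i = vc.ghk_current_density(p_true, e, CTX)
            assert vc.ghk_permeability(i, e, CTX) == pytest.approx(
                p_true, rel=1e-10)

    def test_zero_mv_with_symmetric_concentrations_is_singular(self):
        ctx = vc.GHKContext(c_in_mm=30.0, c_out_mm=30.0)
        assert vc.ghk_current_density(1e-5, 0.0, ctx) == pytest.approx(0.0)
        with pytest.raises(vc.ReversalError):
            vc.ghk_permeability(0.0, 0.0, ctx)

    def test_continuity_at_the_zero_mv_limit(self):
        """The removable singularity at E = 0: the analytic limit and the
        full form agree to 1e-6 relative just off zero."""
        p = 1e-5
        i_limit = vc.ghk_current_density(p, 0.0, CTX)
        for e in (1e-6, -1e-6):
            i = vc.ghk_current_density(p, e, CTX)
            assert abs(i - i_limit) / abs(i_limit) < 1e-6
            assert vc.ghk_permeability(i, e, CTX) == pytest.approx(p, rel=1e-6)

    def test_reversal_potential_is_nernstian(self):
        assert CTX.reversal_mv() == pytest.approx(
            CTX.rt_over_f_mv * np.log(3.0), rel=1e-12)


class TestBoltzmannFit:
    def test_noiseless_recovery(self):
        v = np.arange(-80.0, -5.0, 5.0)
        y = 1.0 / (1.0 + np.exp((-35.45 - v) / 6.47))
        fit = vc.fit_boltzmann(v, y, "activation")
        assert fit.v_half_mv == pytest.approx(-35.45, abs=0.01)
        assert fit.k_mv == pytest.approx(6.47, abs=0.01)

    def test_inactivation_direction(self):
        v = np.arange(-120.0, -19.0, 10.0)
        y = 1.0 / (1.0 + np.exp((v + 58.56) / 5.30))
        fit = vc.fit_boltzmann(v, y, "inactivation")
        assert fit.v_half_mv == pytest.approx(-58.56, abs=0.01)
        assert fit.k_mv == pytest.approx(5.30, abs=0.01)

    def test_wrong_direction_shows_in_residual(self):
        v = np.arange(-80.0, -5.0, 5.0)
        y = 1.0 / (1.0 + np.exp((-35.45 - v) / 6.47))
        good = vc.fit_boltzmann(v, y, "activation")
        bad = vc.fit_boltzmann(v, y, "inactivation")
        assert bad.residual > 10 * max(good.residual, 1e-6)

    def test_flat_data_rejected(self):
        with pytest.raises(vc.FitError, match="flat"):
            vc.fit_boltzmann(np.arange(5.0), np.ones(5), "activation")

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="5 points"):
            vc.fit_boltzmann(np.arange(4.0), np.arange(4.0), "activation")

    def test_mean_vhalf_error_under_noise(self):
        """500 noisy replicates (SD 0.02, 12-point grid): mean absolute
        half-activation error below 0.5 mV."""
        rng = np.random.default_rng(42)
        v = np.linspace(-70.0, -10.0, 12)
        y0 = 1.0 / (1.0 + np.exp((-35.45 - v) / 6.47))
        errs = []
        for _ in range(500):
            fit = vc.fit_boltzmann(v, y0 + rng.normal(0, 0.02, v.size),
                                   "activation")
            errs.append(abs(fit.v_half_mv + 35.45))
        assert np.mean(errs) < 0.5


class TestPeakIV:
    def test_zero_current_recording_gives_zero_densities(self):
        truth = dataclasses.replace(sd.DISSOCIATED_WT, pmax_cm_per_s=0.0)
        rec = sd.simulate_ina_step_family(truth, noise_sd_pa=0.0, seed=0)
        iv = vc.peak_iv(rec, reference_mv=-25.0)
        np.testing.assert_allclose(iv.peak_density_pa_pf, 0.0)

    def test_density_ratio_tracks_permeability_scaling(self):
        """A 0.65-scaled family yields 0.65 +/- 0.02 of the wild-type
        density at the reference voltage."""
        scaled = dataclasses.replace(
            sd.DISSOCIATED_WT,
            pmax_cm_per_s=0.65 * sd.DISSOCIATED_WT.pmax_cm_per_s)
        a = vc.peak_iv(sd.simulate_ina_step_family(
            sd.DISSOCIATED_WT, seed=1), reference_mv=-25.0)
        b = vc.peak_iv(sd.simulate_ina_step_family(scaled, seed=2),
                       reference_mv=-25.0)
        ratio = b.reference_density_pa_pf / a.reference_density_pa_pf
        assert ratio == pytest.approx(0.65, abs=0.02)

    def test_missing_reference_voltage_rejected(self):
        rec = sd.simulate_ina_step_family(sd.DISSOCIATED_WT, seed=0)
        with pytest.raises(ValueError, match="-33"):
            vc.peak_iv(rec, reference_mv=-33.0)

    def test_activation_fit_invariant_to_pmax_scaling(self):
        fits = []
        for scale in (1.0, 0.3):
            truth = dataclasses.replace(
                sd.DISSOCIATED_WT,
                pmax_cm_per_s=scale * sd.DISSOCIATED_WT.pmax_cm_per_s)
            rec = sd.simulate_ina_step_family(truth, noise_sd_pa=0.0, seed=0)
            iv = vc.peak_iv(rec, reference_mv=-25.0)
            _, _, fit = vc.activation_permeability(iv, truth.ghk)
            fits.append(fit)
        assert fits[0].v_half_mv == pytest.approx(fits[1].v_half_mv,
                                                  abs=1e-6)


class TestAvailability:
    def test_noiseless_inactivation_recovery_and_monotonicity(self):
        rec = sd.simulate_availability_family(sd.DISSOCIATED_WT,
                                              noise_sd_pa=0.0, seed=0)
        v, y, fit = vc.availability_curve(rec)
        assert y[0] == pytest.approx(1.0, abs=0.01)  # -120 mV prepulse
        assert np.all(np.diff(y) <= 1e-9)  # monotone decreasing
        assert fit.v_half_mv == pytest.approx(-58.56, abs=0.1)
        assert fit.k_mv == pytest.approx(5.30, abs=0.1)

    def test_empty_family_rejected(self):
        truth = dataclasses.replace(sd.DISSOCIATED_WT, pmax_cm_per_s=0.0)
        rec = sd.simulate_availability_family(truth, noise_sd_pa=0.0, seed=0)
        with pytest.raises(ValueError, match="cannot normalize"):
            vc.availability_curve(rec)


class TestAnalyzeRamp:
    def test_density_within_5pct_of_closed_form(self):
        trials = sd.simulate_ramp(sd.RAMP_WT, seed=0)
        res = vc.analyze_ramp(trials, sd.RAMP_WT.capacitance_pf,
                              ctx=sd.RAMP_WT.ghk)
        truth = sd.persistent_density(sd.RAMP_WT, -20.0)
        assert res.density_at_ref_pa_pf == pytest.approx(truth, rel=0.05)
        assert res.activation.v_half_mv == pytest.approx(-47.70, abs=1.0)

    def test_transient_excision_changes_little(self):
        """Injected escaping transients shift the density by < 1%
        relative to the clean trace."""
        clean = sd.simulate_ramp(sd.RAMP_WT, seed=3)
        dirty = sd.simulate_ramp(sd.RAMP_WT, seed=3, inject_transients=3)
        rc = vc.analyze_ramp(clean, sd.RAMP_WT.capacitance_pf)
        rd = vc.analyze_ramp(dirty, sd.RAMP_WT.capacitance_pf)
        assert rd.excised_fraction > 0
        rel = abs(rd.density_at_ref_pa_pf - rc.density_at_ref_pa_pf) \
            / abs(rc.density_at_ref_pa_pf)
        assert rel < 0.01

    def test_zero_persistent_reads_as_noise(self):
        truth = dataclasses.replace(sd.RAMP_WT, persistent_fraction=0.0)
        trials = sd.simulate_ramp(truth, noise_sd_pa=2.0, seed=1)
        res = vc.analyze_ramp(trials, truth.capacitance_pf,
                              fit_activation=False)
        assert abs(res.density_at_ref_pa_pf) < 3 * 2.0 / truth.capacitance_pf

    def test_unusable_trace_rejected(self):
        trials = sd.simulate_ramp(sd.RAMP_WT, n_trials=1, seed=0,
                                  noise_sd_pa=0.5)
        # bury a quarter of the ramp under transients
        n = trials[0].samples.size
        rng = np.random.default_rng(0)
        spikes = np.zeros(n)
        idx = rng.choice(n - 4, 2000, replace=False)
        spikes[idx] = -300.0
        trials[0].samples = trials[0].samples + spikes
        with pytest.raises(ValueError, match="unusable"):
            vc.analyze_ramp(trials, sd.RAMP_WT.capacitance_pf)


class TestNucleatedPatchQC:
    @pytest.mark.parametrize("ra,rin,ok,reason", [
        (15.0, 2000.0, True, ""),
        (21.0, 2000.0, False, "Ra"),
        (15.0, 500.0, False, "Rin"),
    ])
    def test_inclusion_rule(self, ra, rin, ok, reason):
        rec = sd.simulate_ina_step_family(sd.PATCH_WT, seed=0)
        rec.access_resistance_mohm = ra
        rec.input_resistance_mohm = rin
        assert vc.nucleated_patch_qc(rec) == (ok, reason)

    def test_missing_fields_rejected(self):
        rec = sd.simulate_ina_step_family(sd.PATCH_WT, seed=0)
        rec.access_resistance_mohm = None
        with pytest.raises(ValueError, match="resistance"):
            vc.nucleated_patch_qc(rec)
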