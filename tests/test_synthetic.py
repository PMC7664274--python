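"""Ground-truth generators: neuron model, channel families, events,
survival cohorts."""

import dataclasses

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from ephysepi import synthetic as sd
from ephysepi import stats_survival as st
from tests.conftest import brute_force_spike_count


class TestCurrentClampGenerator:
    def test_zero_step_rests_at_preset_resting_state(self):
        """No stimulus: no 0 mV crossing, RMP within 2 mV of the model's
        resting point."""
        preset = sd.get_preset("FS")
        rec = sd.simulate_current_clamp(
            preset, sd.StepProtocol(start_pa=0, stop_pa=0), seed=0)
        v = rec.sweeps[0].samples
        assert v.max() < 0.0
        assert np.mean(v) == pytest.approx(preset.resting_potential(), abs=2.0)

    def test_sodium_loss_lowers_spike_count_at_strong_drive(self):
        """Scaling the sodium conductances to 0.65 strictly lowers the
        300 pA spike count (re-simulation oracle at both scales)."""
        proto = sd.StepProtocol(start_pa=300, stop_pa=300)
        wt = sd.simulate_current_clamp(sd.get_preset("FS"), proto, seed=1)
        null = sd.simulate_current_clamp(sd.knockout_preset("FS"), proto,
                                         seed=1)
        n_wt = brute_force_spike_count(wt.sweeps[0].samples)
        n_null = brute_force_spike_count(null.sweeps[0].samples)
        assert n_null < n_wt

    def test_layer6_reaches_depolarization_block(self, l6_families):
        """At 200 pA the layer-6 preset fires then fails: after the last
        full spike the voltage stays below 0 mV on a depolarized plateau."""
        sweep = l6_families["wt"].sweep_by_amplitude(200.0)
        v = sweep.samples
        fs = sweep.sampling_rate
        assert brute_force_spike_count(v) >= 1
        late = v[int(0.7 * fs):int(1.1 * fs)]  # late in the 1-s step
        assert late.max() < 0.0
        assert late.mean() > -60.0  # blocked plateau, not repolarized

    @pytest.mark.parametrize("preset_id,amp", [("FS", 100.0),
                                               ("RS-layer6", 80.0)])
    def test_spike_count_invariant_to_halving_the_step(self, preset_id, amp):
        proto = sd.StepProtocol(start_pa=amp, stop_pa=amp)
        a = sd.simulate_current_clamp(preset_id, proto, noise_sd_mv=0, seed=0)
        b = sd.simulate_current_clamp(preset_id, proto, noise_sd_mv=0, seed=0,
                                      dt_ms=0.005)
        assert (brute_force_spike_count(a.sweeps[0].samples)
                == brute_force_spike_count(b.sweeps[0].samples))

    def test_monotone_f_i_curve_up_to_block(self, fs_cohorts):
        """Wild-type FS counts are non-decreasing over the step family."""
        for rec in fs_cohorts["wt"][:4]:
            counts = [brute_force_spike_count(s.samples)
                      for s in rec.sweeps if s.command.amplitude > 0]
            assert all(b >= a for a, b in zip(counts, counts[1:]))

    def test_deterministic_given_seed(self):
        proto = sd.StepProtocol(start_pa=50, stop_pa=60)
        a = sd.simulate_current_clamp("FS", proto, seed=7)
        b = sd.simulate_current_clamp("FS", proto, seed=7)
        c = sd.simulate_current_clamp("FS", proto, seed=8)
        for s1, s2 in zip(a.sweeps, b.sweeps):
            np.testing.assert_array_equal(s1.samples, s2.samples)
        assert not np.array_equal(a.sweeps[0].samples, c.sweeps[0].samples)

    def test_errors(self):
        with pytest.raises(KeyError, match="unknown preset"):
            sd.simulate_current_clamp("RS-layer9")
        with pytest.raises(ValueError, match="sampling rate"):
            sd.simulate_current_clamp(
                "FS", sd.StepProtocol(sampling_rate=0.0))


class TestChannelFamilyGenerator:
    def test_zero_permeability_gives_flat_sweeps(self):
        truth = dataclasses.replace(sd.DISSOCIATED_WT, pmax_cm_per_s=0.0)
        rec = sd.simulate_ina_step_family(truth, noise_sd_pa=0.0, seed=0)
        for s in rec.sweeps:
            np.testing.assert_array_equal(s.samples, np.zeros_like(s.samples))

    def test_noiseless_peaks_match_kinetic_integration_oracle(self):
        """Peaks of the generated traces match direct numerical
        integration of the gating ODEs within 0.5% at every step."""
        truth = sd.DISSOCIATED_WT
        rec = sd.simulate_ina_step_family(truth, noise_sd_pa=0.0, seed=0)
        for s in rec.sweeps:
            v = s.command.amplitude
            m0, h0 = truth.m_inf(-120.0), truth.h_inf(-120.0)

            def gating(t, y, v=v):
                m, h = y
                return [(truth.m_inf(v) - m) / sd.TAU_M_MS,
                        (truth.h_inf(v) - h) / sd.TAU_H_MS]

            t_ms = s.time_s * 1e3
            sol = solve_ivp(gating, (0, t_ms[-1]), [m0, h0], t_eval=t_ms,
                            rtol=1e-10, atol=1e-12)
            open_f = sol.y[0] * sol.y[1]
            dens = truth.pmax_cm_per_s * open_f * truth.ghk.flux_factor(v)
            dens = dens + (truth.pmax_cm_per_s * truth.persistent_fraction
                           * truth.m_inf(v) * truth.ghk.flux_factor(v))
            oracle = dens * truth.capacitance_pf
            peak_sim = s.samples[np.argmax(np.abs(s.samples))]
            peak_orc = oracle[np.argmax(np.abs(oracle))]
            if abs(peak_orc) > 1.0:  # skip numerically empty steps
                assert peak_sim == pytest.approx(peak_orc, rel=5e-3)

    def test_full_availability_at_hyperpolarized_prepulse(self):
        rec = sd.simulate_availability_family(sd.DISSOCIATED_WT,
                                              noise_sd_pa=0.0, seed=0)
        peaks = {s.command.prepulse_mv: np.max(np.abs(s.samples))
                 for s in rec.sweeps}
        assert peaks[-120.0] == pytest.approx(max(peaks.values()), rel=0.01)

    def test_out_of_range_steps_rejected(self):
        with pytest.raises(ValueError, match=r"\[-120, \+60\]"):
            sd.simulate_ina_step_family(sd.DISSOCIATED_WT,
                                        steps_mv=np.array([-130.0]))


class TestRampGenerator:
    def test_zero_persistent_fraction_is_noise_only(self):
        truth = dataclasses.replace(sd.RAMP_WT, persistent_fraction=0.0)
        trials = sd.simulate_ramp(truth, noise_sd_pa=2.0, seed=0)
        avg = np.mean([t.samples for t in trials], axis=0)
        assert np.abs(avg).max() < 3 * 2.0

    def test_analytic_density_matches_ghk_closed_form(self):
        """The generator's ground-truth density at -20 mV is the GHK
        closed form evaluated there."""
        truth = sd.RAMP_WT
        d = sd.persistent_density(truth, -20.0)
        expected = (truth.pmax_cm_per_s * truth.persistent_fraction
                    * truth.m_inf(-20.0) * truth.ghk.flux_factor(-20.0))
        assert d == pytest.approx(expected, rel=1e-12)
        assert d == pytest.approx(-10.30, abs=0.01)

    def test_trial_averaging_reduces_variance(self):
        trials = sd.simulate_ramp(sd.RAMP_WT, n_trials=4, seed=1)
        n = trials[0].samples.size
        base = sd.persistent_density(sd.RAMP_WT,
                                     -120.0 + 150.0 * np.arange(n) / n)
        avg = np.mean([t.samples for t in trials], axis=0)
        resid_avg = avg - base * sd.RAMP_WT.capacitance_pf
        resid_one = trials[0].samples - base * sd.RAMP_WT.capacitance_pf
        assert resid_avg.var() < resid_one.var()

    def test_inconsistent_ramp_bounds_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            sd.simulate_ramp(sd.RAMP_WT, duration_s=2.0)


class TestSynapticGenerator:
    def test_zero_rate_means_no_events(self):
        sim = sd.simulate_sipsc(sd.SynapticTruth(rate_hz=0.0, duration_s=10,
                                                 seed=0))
        assert sim.onsets_s.size == 0

    def test_event_count_is_poisson(self):
        """Mean count over 50 seeds within 3 SD of rate x duration."""
        counts = [
            sd.draw_synaptic_events(
                sd.SynapticTruth(rate_hz=3.8, duration_s=300.0),
                np.random.default_rng(s))[0].size
            for s in range(50)
        ]
        expected = 3.8 * 300.0
        assert abs(np.mean(counts) - expected) < 3 * np.sqrt(expected / 50)

    def test_degenerate_amplitudes(self):
        sim = sd.simulate_sipsc(sd.SynapticTruth(amp_mean_pa=35.0,
                                                 amp_sd_pa=0.0,
                                                 duration_s=30, seed=1))
        assert np.all(sim.amplitudes_pa == 35.0)

    def test_bad_kernel_rejected(self):
        with pytest.raises(ValueError, match="decay > rise"):
            sd.SynapticTruth(rise_ms=8.0, decay_ms=0.5)


class TestSurvivalGenerator:
    def test_degenerate_hazard_is_deterministic(self):
        h = np.zeros(30)
        h[18] = 1.0
        recs = sd.simulate_survival({"g": (h, 12)}, seed=0)
        assert all(r.day == 18 and r.event for r in recs)
        _, median = st.km_estimate(recs, "g")
        assert median == 18

    def test_all_censored_leaves_median_undefined(self):
        recs = sd.simulate_survival({"g": (np.zeros(30), 10)}, seed=0,
                                    censor_day=90)
        assert not any(r.event for r in recs)
        _, median = st.km_estimate(recs, "g")
        assert median is None

    def test_negative_hazard_rejected(self):
        with pytest.raises(ValueError, match="negative hazard"):
            sd.simulate_survival({"g": (np.array([-0.1]), 5)}, seed=0)

    def test_separated_cohorts_power_the_logrank_test(self):
        """Cohorts targeted at medians 18 vs 25 days (n=60/62) reject at
        alpha = 1e-4 in >= 95% of 200 replicates."""
        h1, h2 = sd.discrete_hazard(18, 2.0), sd.discrete_hazard(25, 3.0)
        hits = 0
        for rep in range(200):
            recs = sd.simulate_survival({"a": (h1, 60), "b": (h2, 62)},
                                        seed=rep)
            _, p = st.logrank(recs)
            hits += p < 1e-4
        assert hits >= 0.95 * 200
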