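# Methods

This note documents the models, numerical choices and deliberate design
decisions behind `ephysepi`, and what the synthetic validation does and
does not establish about real recordings.

## Neuron model (current-clamp generator)

A single compartment with four currents (units mV, ms, pA, nS, pF):

    C dV/dt = I_inj − g_L(V−E_L) − g_Na m∞(V)³ h (V−E_Na)
              − g_NaP p∞(V)(V−E_Na) − g_K n⁴ (V−E_K)

Transient-sodium activation is instantaneous (m = m∞), inactivation h
and the delayed-rectifier gate n follow first-order kinetics with
Wang–Buzsáki-style rate functions; each preset carries a voltage shift
(spike threshold placement) and gating temperature factors φ_h, φ_n
(fast-spiking presets use φ = 4, regular-spiking φ = 1).  The persistent
sodium current is a non-inactivating fraction of g_Na with a
hyperpolarized activation midpoint (−48 mV relative), which supplies the
subthreshold boost that lets high-resistance pyramidal presets reach
rheobase inside the 200 pA protocol.

Presets are calibrated to the cell classes of the study:

| preset | C (pF) | R_in (MΩ) | rest (mV) | g_Na/g_K (nS) | role |
|---|---|---|---|---|---|
| FS | 21.7 | 214 | −72.5 | 600/250 | fast-spiking PV⁺ interneuron |
| RS-layer5 | 52.2 | 92 | −85 | 900/300 | layer-5 pyramidal |
| RS-layer6 | 19.5 | 461 | −82 | 420/70 | layer-6 pyramidal, early block |
| RS-subiculum | 32.8 | 136 | −78 | 650/250 | subicular pyramidal |

Passive values (capacitance, input resistance, rest) match the measured
group means; the small g_K of the layer-6 preset is what produces
near-total depolarization block by 150–200 pA.  The genotype contrast is
a conductance scale on both sodium conductances: 0.65 for fast-spiking
cells (≈35% loss) and 0.60 for layer-6 (≈40% loss), the layer-6 null
preset additionally carrying the measured passive shifts (capacitance
−25%, leak reduced to raise input resistance, depolarized rest).
Cell-to-cell variability in cohorts is lognormal jitter (CV 8%) on
capacitance and conductances plus ±1 mV of resting jitter.

**What the presets reproduce / don't.**  They reproduce the *structure*
of the published phenotype — narrow FS spikes (half-widths 0.5–0.7 ms,
inside the 0.5–1.2 ms band bracketing the reported 0.79 ms mean), large
AHPs, non-adapting FS trains, the null FS firing deficit, low-current
hyperexcitability plus earlier block in the null layer-6 preset.
Absolute pyramidal firing rates, however, run ~3× the printed means:
the minimal model has no adaptation currents (I_M, I_AHP), which real
pyramidal cells use to fire at 20–25 Hz.  Printed firing-rate means are
therefore never used as numerical oracles; cohort tests assert the
genotype *contrasts*.

**Integration.**  Fixed step dt = 0.01 ms.  Gates advance by exponential
Euler; the voltage advances by an exponential-Euler predictor with a
trapezoidal corrector on the voltage-dependent conductances
(second-order accurate, unconditionally stable).  Spike counts are
invariant to halving the step — except within a sweep sitting exactly at
the depolarization-block bifurcation, where the count is intrinsically
an unstable function of any perturbation; step-halving checks therefore
use sweeps away from the block boundary.  The initial state is the
resting fixed point (Brent root of the steady-state I–V), recording is
decimated to 20 kHz, and Gaussian noise (default SD 0.2 mV) is added to
the recorded trace only, never to the dynamics, so counts are
deterministic given the seed.

## Channel-family generator (voltage clamp)

Under an ideal clamp each step makes the gating ODEs linear with
constant coefficients, so m(t) and h(t) are evaluated from their exact
exponential solutions — no integration error.  The open-channel current
density is P_max·m·h times the GHK flux factor, scaled by capacitance;
activation uses first-power m with a Boltzmann steady state, so that the
analysis-side permeability normalization recovers the generating V½ and
k essentially exactly (0.01 mV on noiseless data).  The relaxation time
constants are voltage-independent and well separated (τ_m = 0.08 ms,
τ_h = 10 ms): the peak open fraction is then m∞(V)·h₀ to ≈5% with a
nearly voltage-independent suppression factor that cancels under
normalization.  τ_h is deliberately slower than real transient I_Na
decay; the generator trades kinetic realism for an exactly invertible
peak, which is the property the fitting stage needs to be validated
against.  Generator parameter sets take the published gating values and
are calibrated so the analytic peak density equals the published group
mean (e.g. −399.52 pA/pF at −25 mV for wild-type dissociated cells);
null variants scale P_max by the printed density ratios with gating
untouched.

The availability protocol (unstated in the source methods) is 500 ms
prepulses from −120 to −10 mV in 10 mV steps followed by a test pulse at
the peak-current voltage — the standard design.  Ramps are quasi-static
(activation τ ≪ ramp speed), carrying only the persistent component plus
optional injected "escaping" transients (sub-millisecond, tens of σ) for
the excision stage to remove.

## Analysis-side numerical choices

* **dv/dt** by centered differences at the native rate; threshold = the
  *latest* sub-to-suprathreshold crossing before the 0 mV crossing
  (robust to slow depolarizing ramps).  A dv/dt episode stays eligible
  until the voltage collapses 2 mV below its threshold sample (the
  margin defeats single-sample noise dips); collapse without a 0 mV
  crossing and ≥ 10 mV of rise is recorded as a failed AP.  Re-arming
  requires both V < 0 mV and dv/dt < 10 mV/ms to have occurred since the
  previous spike, not necessarily simultaneously.  Failures are excluded
  from all counts.
* **Half-width baseline** is threshold-to-peak amplitude.  The
  alternative (AHP-to-peak) gives systematically different values; this
  choice is fixed package-wide and stated here prominently.
* **Block index** is reported as 1 − N(I_top)/N_max (an index that is 0
  without attenuation and ~1 at total block); the source tables describe
  a ratio but print values only consistent with the complement.
* **Peak I–V window** is 0.2–10 ms after step onset (excludes the
  capacitive transient); no P/N leak subtraction is applied — leak is
  absent in the simulator and this is a stated limitation for real data.
* **Boltzmann fits** run bounded least squares with starting values at
  the half-maximum crossing and k = 5 mV; flat data (< 20% dynamic
  range) and non-convergence raise, never silently default.  Activation
  is fitted on GHK permeability, excluding steps within 10 mV of the
  reversal potential where the flux factor vanishes.
* **Ramp excision** flags |dI/dt| > 8 robust (MAD-based) SDs, expands
  each run by 0.5 ms to local baseline, and interpolates linearly;
  a trace with > 20% excised is rejected as unusable.  Density at
  −20 mV is the mean over a ±1 mV window of the four-trial average.
* **GHK** treats the E = 0 removable singularity by its analytic limit
  I = PzF([S]ᵢ−[S]ₒ) below |zFE/RT| < 10⁻⁸; inversion at the reversal
  potential raises a dedicated error.  Concentrations are converted
  internally so densities in pA/pF correspond to the usual 1 µF/cm²
  specific capacitance; permeabilities are reported in cm/s.
* **Synaptic detection** replaces the original interactive
  visual curation (irreproducible) with a deterministic two-stage
  matched filter: a sliding least-squares fit of the biexponential
  template *plus a local baseline* gives an amplitude score; peaks above
  max(10 pA, 5 robust SDs of the score) are accepted largest-first with
  greedy subtraction of each accepted event's score response (the score
  of this slow template stays elevated for ~1 decay constant, which a
  plain local-maximum scan double-counts), a 3 ms onset refractory, a
  local rescan for events uncovered by subtraction, and a raw-trace
  validation gate (max(5 pA, 3 robust SDs) at the template's peak
  latency) that rejects subtraction artifacts.  Reported amplitude is
  baseline-to-peak: median of the preceding 5 ms vs the lightly smoothed
  (0.25 ms boxcar) trace at the template peak latency — a point read, to
  avoid the positive bias of a max over a noisy window.  Measured
  performance on study-condition traces: |frequency bias| < 2.5%,
  amplitude bias < 1%, zero false events on noise-only traces.
* **Cells with < 100 events** contribute to pooled ECDFs by sampling
  with replacement (without replacement above 100); zero-event cells are
  excluded with a warning.
* **Welch gate**: the source marks Welch per row without stating a rule;
  the package uses Welch iff the two-sided F-test p < 0.05, and either
  test can be forced.  The FDR family is the set of comparisons within
  one results table (per-table, as in the source's table-wise
  correction); the BKY two-stage step-up is implemented directly
  (stage 1 at q/(1+q) estimates m₀, stage 2 re-runs the step-up at
  q′·m/m₀) and is cross-checked against the statsmodels implementation
  in the tests.
* **Kaplan–Meier median** is the first day with S(t) ≤ 0.5 (with a 10⁻⁹
  tolerance against product-limit rounding), None when survival never
  reaches 0.5.  Log-rank ties use the standard hypergeometric variance.
* **Junction potentials** use the Henderson equation with true
  mobilities proportional to limiting equivalent conductivities (CRC
  values; organic/buffer ions per the tables used by common junction
  calculators).  Recipes are dissociated salt-by-salt; HEPES contributes
  its pH-dependent anion fraction (pKa 7.55) and electroneutrality is
  closed with the stated titration counter-ion.  The ±1 mV acceptance
  band reflects mobility-table drift between calculators; activity
  corrections and temperature-dependent mobilities are out of scope.

## Synthetic-data defaults (the simulated study conditions)

Current steps: 1 s, 10 pA increments, −20→300 pA (FS) or −20→200 pA
(pyramidal), 20 kHz.  Voltage-clamp steps: −120→+30 mV in 5 mV from
−120 mV holding, 50 kHz, 50 ms.  Ramps: 150 mV/3 s, four trials, 20 kHz.
sIPSC traces: 5 min at 20 kHz, Poisson rates 3.81 Hz (wild type) and
1.38 Hz (null), amplitudes N(35, 10²) pA truncated at zero, kernel
0.5/8 ms, noise SD 3 pA (SNR ≈ 12; the unbiasedness checks also run at
SNR 5).  Cells within a cohort share the generating rate (between-cell
rate heterogeneity of real cohorts is not modelled, which makes the
frequency comparison cleaner than in vivo).  Survival: discretized
normal hazards with medians 18 (SD 2) and 25 days (SD 3), n = 60/62.
Cohort sizes default to the study's (11/11 FS, 10/8 dissociated, 10/10
patches, 9/7 ramps, 12/12 sIPSC).

Some long-running validations use reduced problem sizes chosen as the
package's own test-design decision: noise-only false-positive checks use
30–60 s traces, the end-to-end detection replicate of the sIPSC cohort
comparison uses 60 s recordings (the 100-replicate structural check runs
on the event statistics at the full 300 s), and pipeline determinism
tests run scaled cohorts.  The full-size study (`run_study` defaults)
runs in about a minute.

## What passing tests do and do not show

The suite establishes that every analysis stage is correct against
independent oracles (closed forms, brute-force scans, direct ODE
integration, hand-worked tables, a second FDR implementation) and that
the full pipeline recovers known generator truths at the study's cohort
sizes.  It does not establish robustness to real-recording pathologies
the generators omit: series-resistance and space-clamp artifacts,
imperfect leak subtraction, electrode drift, overlapping-event shapes
beyond a fixed kernel, bridge-balance errors, or between-cell biological
heterogeneity beyond the modelled jitter.  ABF ingestion is supported
(via the optional `pyabf`) but untested against hardware files here.
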