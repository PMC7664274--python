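# ephysepi

Quantification pipeline for patch-clamp studies of **EIEE52**, the early
infantile developmental and epileptic encephalopathy caused by biallelic
loss of *SCN1B* (the voltage-gated sodium channel β1/β1B subunit).  In the
*Scn1b*‑null mouse model, cortical fast-spiking PV⁺ interneurons become
hypoexcitable with reduced sodium-current density, subpopulations of
pyramidal neurons show low-current hyperexcitability with early
depolarization block, inhibitory synaptic input onto layer-6 pyramidal
neurons collapses in frequency, and animals die of SUDEP in the third
postnatal week.  This package implements every quantitative step of that
phenotype battery as a tested, reusable library, and ships simulators
that generate each recording class with known ground truth so the entire
pipeline is verifiable without any animal data.

Intended users: cellular electrophysiologists and computational
neuroscientists who want a reproducible, scriptable replacement for the
usual mix of interactive analysis tools (spike quantification, I–V and
gating analysis, event detection, multiple-comparison bookkeeping).

## What it computes

**Action potentials (current clamp).**  An AP is the voltage crossing
0 mV subsequent to dv/dt exceeding 10 mV/ms; the threshold is the voltage
at the last sub-to-suprathreshold dv/dt crossing before the 0 mV
crossing.  Per spike: threshold, peak, peak dv/dt, half-width
(threshold-to-peak half-amplitude), AHP (post-spike minimum minus that
spike's threshold).  Per cell: RMP, input resistance (Ohm's law on a
−10 pA step read at 250 ms), f–I spike counts, maximal firing rate,
rheobase, spike-frequency adaptation (last ISI / second ISI), the
low-current area under the f–I curve up to 50 pA, and the
depolarization-block index 1 − N(I_max)/N_max with AP failure defined as
a maximum below 0 mV.  QC follows the study: reject when access
resistance > 20 MΩ or RMP > −64.3 mV.

**Sodium currents (voltage clamp).**  Peak I–V from step families
(−120 → +30 mV from −120 mV holding), with the voltage dependence of
activation computed on *permeability* via the GHK current equation

    I_s = P_s · z² EF²/RT · ([S]ᵢ − [S]ₒ·e^(−zFE/RT)) / (1 − e^(−zFE/RT)),

normalized and fitted with a Boltzmann y = 1/(1 + exp((V½ − V)/k)); the
availability (steady-state inactivation) curve is fitted with the
mirrored form.  Persistent I_Na is analysed on slow ramps (150 mV / 3 s):
residual transient spikes are excised by linear interpolation, four
trials are averaged, and density is read at −20 mV.

**Synaptic events.**  sIPSCs are detected with a deterministic matched
filter (sliding least-squares fit of a biexponential template plus local
baseline, greedy subtraction of accepted events) with the study's 10 pA
amplitude floor; per-cell frequency/amplitude means, pooled
100-events-per-cell cumulative distributions, and the two-sample
Kolmogorov–Smirnov test.

**Statistics and survival.**  Unpaired two-tailed t-tests with an F-test
gate choosing Welch's correction, D'Agostino–Pearson normality per
group, Benjamini–Krieger–Yekutieli two-stage FDR at q = 0.05 across each
results table, Kaplan–Meier medians and the Mantel–Cox log-rank test.

**Solutions.**  Liquid junction potentials from printed solution recipes
via the Henderson equation with standard limiting ionic mobilities
(`ephysepi.solutions`).

**Simulators** (`ephysepi.synthetic`) generate all of the above with
ground truth: a single-compartment conductance model (m³h transient Na,
persistent Na, delayed-rectifier K, leak) with fast-spiking and
regular-spiking presets and a genotype conductance scale; exact-solution
GHK channel families; persistent-current ramps; Poisson synaptic traces;
discrete-hazard survival cohorts.

## Worked example

Junction potentials for the study's printed recipes:

```bash
$ python analysis/05_junction_potentials.py
                 pipette              bath  ljp_mv
    K-gluconate internal              ACSF   14.33
CsCl Na-channel internal 30 mM Na external    2.39
CsCl Na-channel internal              ACSF    3.94
```

The 14.33 mV K-gluconate/ACSF offset is what makes a −80 mV reading a
true −94.3 mV after offline correction.  The full synthetic study runs
from one config:

```bash
$ python analysis/04_sipsc.py --seed 0
       frequency_hz  mean_amplitude_pa
group
null       1.374722          35.119766
wt         3.770278          34.930372

frequency fold change (wt/null): 2.74 (Welch p = 2.56e-27)
amplitude: p = 0.28, pooled-ECDF KS p = 0.36 — amplitudes
indistinguishable, so the deficit is presynaptic event frequency.
```

Twelve wild-type cells at 3.81 Hz vs twelve null cells at 1.38 Hz,
detected blind by the matched filter, recover a ~2.7-fold frequency
deficit with amplitudes statistically indistinguishable — the study's
disinhibition signature.  The other drivers follow the same pattern:
`01_survival.py` (Kaplan–Meier medians 18 vs 25 days, log-rank),
`02_fs_excitability.py` (FS cohort comparison table with FDR stars),
`03_sodium_currents.py` (≈30%/≈38%/≈35% density reductions in
dissociated cells, nucleated patches and ramps, gating unchanged).
Everything can also be driven in one call:

```python
from ephysepi import run_study, StudyConfig
result = run_study(StudyConfig(seed=1))
print(result.table_excitability)
```

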