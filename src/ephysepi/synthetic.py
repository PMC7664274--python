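"""Synthetic patch-clamp recordings with known ground truth.

Every input class the analysis stages consume can be generated here:

* current-clamp step families from a single-compartment conductance
  model (fast-spiking and regular-spiking presets, with a genotype
  conductance scale emulating sodium-channel loss),
* ideal-voltage-clamp sodium-current step families whose open-channel
  current follows the Goldman-Hodgkin-Katz flux equation, so that the
  permeability analysis can recover the generating parameters exactly,
* slow voltage ramps carrying only the persistent (non-inactivating)
  sodium component,
* gap-free synaptic traces with Poisson event trains, and
* discrete-time survival cohorts.

All generators are deterministic given their seed, and additive Gaussian
noise is applied to the recorded signal only, never to the dynamics.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from . import _hh
from .trace_io import CommandWaveform, EpisodicRecording, Sweep
from .voltage_clamp import GHKContext
from .stats_survival import SurvivalRecord

__all__ = [
    "NeuronPreset", "ChannelTruth", "SynapticTruth",
    "get_preset", "knockout_preset", "cohort_presets", "PRESET_IDS",
    "StepProtocol", "simulate_current_clamp",
    "simulate_ina_step_family", "simulate_availability_family",
    "simulate_ramp", "persistent_density",
    "simulate_sipsc", "draw_synaptic_events", "SynapticSimulation",
    "simulate_survival", "discrete_hazard",
    "DISSOCIATED_WT", "DISSOCIATED_NULL", "PATCH_WT", "PATCH_NULL",
    "RAMP_WT", "RAMP_NULL",
]


# --- neuron presets --------------------------------------------------------

@dataclass(frozen=True)
class NeuronPreset:
    """Single-compartment model parameters for one cell class.

    The genotype contrast is carried by ``g_scale``, a multiplicative
    factor on both sodium conductances (1.0 = wild type).
    """

    preset_id: str
    capacitance_pf: float
    leak_ns: float
    leak_mv: float
    gna_ns: float
    gk_ns: float
    persistent_fraction: float
    v_shift_mv: float = 0.0
    phi_h: float = 1.0
    phi_n: float = 1.0
    g_scale: float = 1.0
    ena_mv: float = 55.0
    ek_mv: float = -90.0

    def __post_init__(self):
        if self.capacitance_pf <= 0:
            raise ValueError("capacitance must be positive")
        if min(self.leak_ns, self.gna_ns, self.gk_ns) < 0:
            raise ValueError("conductances must be non-negative")
        if self.persistent_fraction < 0:
            raise ValueError("persistent fraction must be non-negative")
        if not 0 < self.g_scale <= 1:
            raise ValueError("g_scale must be in (0, 1]")

    @property
    def gnap_ns(self) -> float:
        return self.persistent_fraction * self.gna_ns

    def _hh_args(self):
        return (
            self.capacitance_pf, self.leak_ns, self.leak_mv,
            self.gna_ns * self.g_scale, self.ena_mv,
            self.gk_ns, self.ek_mv,
            self.gnap_ns * self.g_scale, self.v_shift_mv,
        )

    def resting_potential(self) -> float:
        """Zero-current membrane potential of the preset (mV)."""
        return _hh.resting_state(*self._hh_args())[0]


# Calibrated so fast-spiking traces show narrow spikes (half-width in the
# 0.5-1.2 ms band), large AHPs and sustained firing to 300 pA, and so the
# layer-6 preset reaches depolarization block within the 200 pA protocol.
_PRESETS = {
    "FS": NeuronPreset("FS", 21.7, 4.67, -72.5, 600.0, 250.0, 0.0,
                       v_shift_mv=0.0, phi_h=4.0, phi_n=4.0),
    "RS-layer5": NeuronPreset("RS-layer5", 52.2, 10.9, -85.5, 900.0, 300.0,
                              12.0 / 900.0, v_shift_mv=-8.0),
    "RS-layer6": NeuronPreset("RS-layer6", 19.5, 2.17, -82.5, 420.0, 70.0,
                              3.0 / 420.0, v_shift_mv=-5.0),
    "RS-subiculum": NeuronPreset("RS-subiculum", 32.8, 7.37, -79.3, 650.0,
                                 250.0, 7.0 / 650.0, v_shift_mv=-8.0),
}
PRESET_IDS = tuple(_PRESETS)


def get_preset(preset_id: str) -> NeuronPreset:
    try:
        return _PRESETS[preset_id]
    except KeyError:
        raise KeyError(
            f"unknown preset {preset_id!r}; known: {', '.join(PRESET_IDS)}"
        ) from None


def knockout_preset(preset_id: str) -> NeuronPreset:
    """Sodium-channel-null variant of a preset.

    Fast-spiking cells lose ~35% of sodium conductance; layer-6
    pyramidal cells lose ~40% and additionally show the measured passive
    shifts (smaller capacitance, higher input resistance, depolarized
    rest).  Subicular cells carry the passive shifts only; layer-5 cells
    were the least affected population and are left unchanged.
    """
    p = get_preset(preset_id)
    if preset_id == "FS":
        return dataclasses.replace(p, g_scale=0.65)
    if preset_id == "RS-layer6":
        return dataclasses.replace(
            p, g_scale=0.60, capacitance_pf=p.capacitance_pf * 0.75,
            leak_ns=p.leak_ns * 461.6 / 669.4, leak_mv=-77.5,
        )
    if preset_id == "RS-subiculum":
        return dataclasses.replace(
            p, capacitance_pf=p.capacitance_pf * 27.5 / 32.8,
            leak_ns=p.leak_ns * 135.7 / 247.0, leak_mv=-76.3,
        )
    return p


def cohort_presets(
    preset: NeuronPreset, n: int, seed: int, cv: float = 0.08,
    rmp_jitter_mv: float = 1.0,
) -> list[NeuronPreset]:
    """A cohort of ``n`` cells: lognormal jitter on passive and active
    conductances (coefficient of variation ``cv``) and a small normal
    jitter on the leak reversal, emulating cell-to-cell variability."""
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(np.log1p(cv**2))
    cells = []
    for _ in range(n):
        f = rng.lognormal(-sigma**2 / 2, sigma, size=4)
        cells.append(dataclasses.replace(
            preset,
            capacitance_pf=preset.capacitance_pf * f[0],
            leak_ns=preset.leak_ns * f[1],
            gna_ns=preset.gna_ns * f[2],
            gk_ns=preset.gk_ns * f[3],
            leak_mv=preset.leak_mv + rng.normal(0, rmp_jitter_mv),
        ))
    return cells


# --- current clamp ---------------------------------------------------------

@dataclass(frozen=True)
class StepProtocol:
    """Current-step family: 1-s injections in 10 pA increments with a
    pre-stimulus baseline, as used for repetitive-firing recordings."""

    start_pa: float = -20.0
    stop_pa: float = 300.0
    increment_pa: float = 10.0
    onset_s: float = 0.1
    duration_s: float = 1.0
    total_s: float = 1.5
    sampling_rate: float = 20_000.0

    def amplitudes(self) -> np.ndarray:
        n = int(round((self.stop_pa - self.start_pa) / self.increment_pa)) + 1
        return self.start_pa + self.increment_pa * np.arange(n)


FS_PROTOCOL = StepProtocol(stop_pa=300.0)
PYRAMIDAL_PROTOCOL = StepProtocol(stop_pa=200.0)


def simulate_current_clamp(
    preset: NeuronPreset | str,
    protocol: StepProtocol = FS_PROTOCOL,
    noise_sd_mv: float = 0.2,
    seed: int = 0,
    dt_ms: float = _hh.DT_MS,
    group: str = "",
    cell_id: str = "",
    access_resistance_mohm: float = 12.0,
) -> EpisodicRecording:
    """Simulate a whole-cell current-clamp step family.

    One voltage sweep per current step; deterministic given the seed.
    Voltages are produced directly in junction-corrected space (the
    recording is marked corrected).
    """
    if isinstance(preset, str):
        preset = get_preset(preset)
    if protocol.sampling_rate <= 0:
        raise ValueError("sampling rate must be positive")
    if protocol.increment_pa <= 0:
        raise ValueError("step increment must be positive")
    decim = int(round(1000.0 / protocol.sampling_rate / dt_ms))
    if decim < 1:
        raise ValueError("integration step exceeds the sampling interval")

    rng = np.random.default_rng(seed)
    args = preset._hh_args()
    v0, h0, n0 = _hh.resting_state(*args)
    n_steps = int(round(protocol.total_s * 1000.0 / dt_ms))
    i0 = int(round(protocol.onset_s * 1000.0 / dt_ms))
    i1 = int(round((protocol.onset_s + protocol.duration_s) * 1000.0 / dt_ms))

    sweeps = []
    for idx, amp in enumerate(protocol.amplitudes()):
        i_inj = np.zeros(n_steps)
        i_inj[i0:i1] = amp
        v = _hh.integrate_cc(
            i_inj, dt_ms, decim, *args, preset.phi_h, preset.phi_n,
            v0, h0, n0,
        )
        if noise_sd_mv > 0:
            v = v + rng.normal(0.0, noise_sd_mv, v.size)
        cmd = CommandWaveform(
            kind="step", amplitude=float(amp), onset_s=protocol.onset_s,
            duration_s=protocol.duration_s, units="pA",
        )
        sweeps.append(Sweep(v, protocol.sampling_rate, "voltage", cmd, idx))

    return EpisodicRecording(
        sweeps=sweeps,
        cell_id=cell_id or f"{preset.preset_id}-seed{seed}",
        group=group,
        corrected=True,
        junction_potential_mv=14.3,
        capacitance_pf=preset.capacitance_pf,
        access_resistance_mohm=access_resistance_mohm,
        protocol={
            "kind": "current-steps",
            "increment_pa": protocol.increment_pa,
            "start_pa": protocol.start_pa,
            "stop_pa": protocol.stop_pa,
            "step_duration_s": protocol.duration_s,
        },
        truth={
            "preset": dataclasses.asdict(preset),
            "resting_potential_mv": v0,
            "seed": int(seed),
        },
    )


# --- voltage-clamp channel families ---------------------------------------

#: Activation and inactivation relaxation time constants (ms).  Chosen
#: well-separated (tau_h >> tau_m) so the peak open fraction at each step
#: is m_inf * h0 to high accuracy and Boltzmann fits of peak permeability
#: recover the generating half-activation voltage.
TAU_M_MS = 0.08
TAU_H_MS = 10.0


@dataclass(frozen=True)
class ChannelTruth:
    """Ground-truth sodium-channel parameters for the voltage-clamp
    generators (GHK open-channel flux, Boltzmann gating)."""

    pmax_cm_per_s: float
    act_vhalf_mv: float
    act_k_mv: float
    inact_vhalf_mv: float
    inact_k_mv: float
    persistent_fraction: float = 0.0
    na_in_mm: float = 10.0
    na_out_mm: float = 30.0
    temperature_k: float = 295.0
    capacitance_pf: float = 8.0

    def __post_init__(self):
        if self.act_k_mv <= 0 or self.inact_k_mv <= 0:
            raise ValueError("slope factors must be positive")
        if self.na_in_mm <= 0 or self.na_out_mm <= 0:
            raise ValueError("concentrations must be positive")
        if self.pmax_cm_per_s < 0:
            raise ValueError("permeability must be non-negative")

    @property
    def ghk(self) -> GHKContext:
        return GHKContext(
            valence=1, c_in_mm=self.na_in_mm, c_out_mm=self.na_out_mm,
            temperature_k=self.temperature_k,
        )

    def m_inf(self, v_mv):
        return 1.0 / (1.0 + np.exp((self.act_vhalf_mv - v_mv) / self.act_k_mv))

    def h_inf(self, v_mv):
        return 1.0 / (1.0 + np.exp((v_mv - self.inact_vhalf_mv) / self.inact_k_mv))

    def open_fraction(self, v_mv, t_ms, m0=0.0, h0=1.0):
        """Transient-channel open fraction m(t) h(t) under an ideal step."""
        minf, hinf = self.m_inf(v_mv), self.h_inf(v_mv)
        m = minf + (m0 - minf) * np.exp(-np.asarray(t_ms) / TAU_M_MS)
        h = hinf + (h0 - hinf) * np.exp(-np.asarray(t_ms) / TAU_H_MS)
        return m * h

    def peak_open_fraction(self, v_mv, h0=1.0) -> float:
        """Analytic maximum of m(t) h(t) during a step to ``v_mv``."""
        res = minimize_scalar(
            lambda t: -self.open_fraction(v_mv, t, 0.0, h0),
            bounds=(0.0, 8.0 * TAU_H_MS), method="bounded",
            options={"xatol": 1e-6},
        )
        return -res.fun

    def peak_density(self, v_mv, h0=1.0) -> float:
        """Analytic peak transient current density (pA/pF) at a step."""
        return (self.pmax_cm_per_s * self.peak_open_fraction(v_mv, h0)
                * self.ghk.flux_factor(v_mv))


def _pmax_for_peak_density(
    target_pa_pf: float, v_ref_mv: float, act_vhalf: float, act_k: float,
    inact_vhalf: float, inact_k: float, na_in: float, na_out: float,
) -> float:
    probe = ChannelTruth(1.0, act_vhalf, act_k, inact_vhalf, inact_k,
                         na_in_mm=na_in, na_out_mm=na_out)
    return target_pa_pf / probe.peak_density(v_ref_mv)


# Generator parameter sets taken from the study's printed group values:
# dissociated interneurons (peak density at -25 mV, reduced-sodium bath),
# layer-6 nucleated patches (peak at -20 mV, ACSF bath) and layer-6
# persistent-current ramps (density at -20 mV).  The null variants scale
# P_max by the printed density ratios with gating untouched.
DISSOCIATED_WT = ChannelTruth(
    pmax_cm_per_s=_pmax_for_peak_density(
        -399.52, -25.0, -35.45, 6.47, -58.56, 5.30, 10.0, 30.0),
    act_vhalf_mv=-35.45, act_k_mv=6.47,
    inact_vhalf_mv=-58.56, inact_k_mv=5.30,
    na_in_mm=10.0, na_out_mm=30.0, capacitance_pf=7.52,
)
DISSOCIATED_NULL = dataclasses.replace(
    DISSOCIATED_WT,
    pmax_cm_per_s=DISSOCIATED_WT.pmax_cm_per_s * 280.39 / 399.52,
    capacitance_pf=8.36,
)
PATCH_WT = ChannelTruth(
    pmax_cm_per_s=_pmax_for_peak_density(
        -218.33, -20.0, -38.75, 6.03, -67.10, 5.20, 10.0, 151.0),
    act_vhalf_mv=-38.75, act_k_mv=6.03,
    inact_vhalf_mv=-67.10, inact_k_mv=5.20,
    na_in_mm=10.0, na_out_mm=151.0, capacitance_pf=1.23,
)
PATCH_NULL = dataclasses.replace(
    PATCH_WT,
    pmax_cm_per_s=PATCH_WT.pmax_cm_per_s * 134.36 / 218.33,
    capacitance_pf=1.16,
)


def _ramp_truth(density_at_minus20: float, cap: float) -> ChannelTruth:
    base = ChannelTruth(1.0, -47.70, 5.54, -67.10, 5.20,
                        persistent_fraction=1.0, na_in_mm=10.0,
                        na_out_mm=151.0, capacitance_pf=cap)
    d_unit = base.m_inf(-20.0) * base.ghk.flux_factor(-20.0)
    # keep the transient pool at the nucleated-patch magnitude
    pmax = PATCH_WT.pmax_cm_per_s
    return ChannelTruth(
        pmax, -47.70, 5.54, -67.10, 5.20,
        persistent_fraction=density_at_minus20 / (d_unit * pmax),
        na_in_mm=10.0, na_out_mm=151.0, capacitance_pf=cap,
    )


RAMP_WT = _ramp_truth(-10.30, 20.90)
RAMP_NULL = _ramp_truth(-6.70, 16.63)


def simulate_ina_step_family(
    truth: ChannelTruth,
    steps_mv: np.ndarray | None = None,
    noise_sd_pa: float = 10.0,
    seed: int = 0,
    holding_mv: float = -120.0,
    step_duration_s: float = 0.05,
    sampling_rate: float = 50_000.0,
    group: str = "",
    cell_id: str = "",
) -> EpisodicRecording:
    """Ideal-voltage-clamp sodium-current step family.

    Gating relaxes along its exact exponential solutions (voltage is
    constant within a step), so with zero noise the traces are the
    analytic solution of the kinetic model and the peak at each step
    matches direct kinetic integration.
    """
    if steps_mv is None:
        steps_mv = np.arange(-120.0, 35.0, 5.0)
    steps_mv = np.asarray(steps_mv, dtype=float)
    if steps_mv.min() < -120.0 or steps_mv.max() > 60.0:
        raise ValueError("step voltages must lie within [-120, +60] mV")

    rng = np.random.default_rng(seed)
    t_ms = np.arange(int(round(step_duration_s * sampling_rate))) / sampling_rate * 1e3
    m0 = truth.m_inf(holding_mv)
    h0 = truth.h_inf(holding_mv)
    cap = truth.capacitance_pf
    sweeps = []
    for idx, v in enumerate(steps_mv):
        open_f = truth.open_fraction(v, t_ms, m0=m0, h0=h0)
        dens = truth.pmax_cm_per_s * open_f * truth.ghk.flux_factor(v)
        if truth.persistent_fraction > 0:
            dens = dens + (truth.pmax_cm_per_s * truth.persistent_fraction
                           * truth.m_inf(v) * truth.ghk.flux_factor(v))
        i_pa = dens * cap
        if noise_sd_pa > 0:
            i_pa = i_pa + rng.normal(0.0, noise_sd_pa, i_pa.size)
        cmd = CommandWaveform(kind="step", amplitude=float(v), onset_s=0.0,
                              duration_s=step_duration_s, units="mV",
                              holding=holding_mv)
        sweeps.append(Sweep(i_pa, sampling_rate, "current", cmd, idx))

    return EpisodicRecording(
        sweeps=sweeps, cell_id=cell_id or f"vc-seed{seed}", group=group,
        corrected=False, capacitance_pf=cap, access_resistance_mohm=10.0,
        input_resistance_mohm=2000.0,
        protocol={"kind": "vc-steps", "holding_mv": holding_mv,
                  "steps_mv": steps_mv.tolist()},
        truth={"channel": dataclasses.asdict(truth), "seed": int(seed)},
    )


def simulate_availability_family(
    truth: ChannelTruth,
    prepulses_mv: np.ndarray | None = None,
    prepulse_s: float = 0.5,
    test_mv: float | None = None,
    noise_sd_pa: float = 10.0,
    seed: int = 0,
    step_duration_s: float = 0.05,
    sampling_rate: float = 50_000.0,
    group: str = "",
    cell_id: str = "",
) -> EpisodicRecording:
    """Steady-state inactivation protocol: 500-ms conditioning prepulses
    followed by a fixed test pulse near the peak-current voltage.  Only
    the test-pulse segment is recorded (one sweep per prepulse)."""
    if prepulses_mv is None:
        prepulses_mv = np.arange(-120.0, -5.0, 10.0)
    prepulses_mv = np.asarray(prepulses_mv, dtype=float)
    if test_mv is None:
        test_mv = -20.0
    rng = np.random.default_rng(seed)
    t_ms = np.arange(int(round(step_duration_s * sampling_rate))) / sampling_rate * 1e3
    cap = truth.capacitance_pf
    sweeps = []
    for idx, vpre in enumerate(prepulses_mv):
        hinf = truth.h_inf(vpre)
        h0 = hinf + (1.0 - hinf) * np.exp(-prepulse_s * 1e3 / TAU_H_MS)
        m0 = truth.m_inf(vpre)
        open_f = truth.open_fraction(test_mv, t_ms, m0=m0, h0=h0)
        dens = truth.pmax_cm_per_s * open_f * truth.ghk.flux_factor(test_mv)
        i_pa = dens * cap
        if noise_sd_pa > 0:
            i_pa = i_pa + rng.normal(0.0, noise_sd_pa, i_pa.size)
        cmd = CommandWaveform(kind="step", amplitude=float(test_mv),
                              onset_s=0.0, duration_s=step_duration_s,
                              units="mV", holding=-120.0,
                              prepulse_mv=float(vpre), prepulse_s=prepulse_s)
        sweeps.append(Sweep(i_pa, sampling_rate, "current", cmd, idx))
    return EpisodicRecording(
        sweeps=sweeps, cell_id=cell_id or f"avail-seed{seed}", group=group,
        corrected=False, capacitance_pf=cap, access_resistance_mohm=10.0,
        input_resistance_mohm=2000.0,
        protocol={"kind": "vc-availability", "test_mv": test_mv,
                  "prepulse_s": prepulse_s,
                  "prepulses_mv": prepulses_mv.tolist()},
        truth={"channel": dataclasses.asdict(truth), "seed": int(seed)},
    )


def persistent_density(truth: ChannelTruth, v_mv: float) -> float:
    """Closed-form persistent current density (pA/pF) at a ramp voltage."""
    return (truth.pmax_cm_per_s * truth.persistent_fraction
            * truth.m_inf(v_mv) * truth.ghk.flux_factor(v_mv))


def simulate_ramp(
    truth: ChannelTruth,
    n_trials: int = 4,
    noise_sd_pa: float = 4.0,
    seed: int = 0,
    start_mv: float = -120.0,
    end_mv: float = 30.0,
    duration_s: float = 3.0,
    sampling_rate: float = 20_000.0,
    inject_transients: int = 0,
) -> list[Sweep]:
    """Slow-voltage-ramp trials (150 mV over 3 s) carrying the
    persistent sodium component, optionally contaminated with brief
    escaping transient spikes for the excision stage to remove."""
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rate = (end_mv - start_mv) / duration_s
    if abs(rate - 50.0) > 1e-6:
        raise ValueError(
            f"ramp bounds inconsistent with duration: {rate:g} mV/s != 50 mV/s"
        )
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * sampling_rate))
    t = np.arange(n) / sampling_rate
    v = start_mv + (end_mv - start_mv) * t / duration_s
    dens = (truth.pmax_cm_per_s * truth.persistent_fraction
            * truth.m_inf(v) * truth.ghk.flux_factor(v))
    base = dens * truth.capacitance_pf
    cmd = CommandWaveform(kind="ramp", start_mv=start_mv, end_mv=end_mv,
                          duration_s=duration_s, units="mV",
                          holding=start_mv)
    sweeps = []
    for trial in range(n_trials):
        i_pa = base.copy()
        for k in range(inject_transients):
            # escaping action currents: sub-millisecond, large; the first
            # lands on the -20 mV reading so excision is actually load-bearing
            at = 2.0 if k == 0 else rng.uniform(0.8, 2.4)
            width = rng.uniform(0.05e-3, 0.2e-3)
            amp = rng.uniform(50, 150) * max(noise_sd_pa, 1.0)
            i_pa -= amp * np.exp(-0.5 * ((t - at) / width) ** 2)
        if noise_sd_pa > 0:
            i_pa = i_pa + rng.normal(0.0, noise_sd_pa, n)
        sweeps.append(Sweep(i_pa, sampling_rate, "current", cmd, trial))
    return sweeps


# --- synaptic traces -------------------------------------------------------

@dataclass(frozen=True)
class SynapticTruth:
    """Ground truth for gap-free spontaneous-IPSC traces: Poisson onsets,
    normal amplitudes (pA), a biexponential kernel, Gaussian baseline
    noise.  The study's wild-type condition is ~3.8 Hz / ~35 pA over
    5 minutes; the null condition keeps amplitudes and lowers the rate."""

    rate_hz: float = 3.81
    amp_mean_pa: float = 35.0
    amp_sd_pa: float = 10.0
    rise_ms: float = 0.5
    decay_ms: float = 8.0
    noise_sd_pa: float = 3.0
    duration_s: float = 300.0
    sampling_rate: float = 20_000.0
    seed: int = 0

    def __post_init__(self):
        if self.rate_hz < 0:
            raise ValueError("rate must be non-negative")
        if not (self.decay_ms > self.rise_ms > 0):
            raise ValueError("kernel requires decay > rise > 0")
        if self.duration_s <= 0:
            raise ValueError("duration must be positive")


@dataclass
class SynapticSimulation:
    sweep: Sweep
    onsets_s: np.ndarray
    amplitudes_pa: np.ndarray
    truth: SynapticTruth


def biexp_kernel(rise_ms: float, decay_ms: float, sampling_rate: float,
                 length_ms: float | None = None) -> np.ndarray:
    """Unit-peak biexponential kernel exp(-t/decay) - exp(-t/rise)."""
    if length_ms is None:
        length_ms = 8.0 * decay_ms
    t = np.arange(int(round(length_ms * sampling_rate / 1e3))) / sampling_rate * 1e3
    k = np.exp(-t / decay_ms) - np.exp(-t / rise_ms)
    return k / k.max()


def draw_synaptic_events(truth: SynapticTruth, rng: np.random.Generator):
    """Poisson onsets and positive-truncated normal amplitudes."""
    n = rng.poisson(truth.rate_hz * truth.duration_s)
    onsets = np.sort(rng.uniform(0.0, truth.duration_s, n))
    amps = truth.amp_mean_pa + truth.amp_sd_pa * rng.standard_normal(n)
    bad = amps <= 0
    while bad.any():  # truncation at zero; negligible mass for study values
        amps[bad] = truth.amp_mean_pa + truth.amp_sd_pa * rng.standard_normal(
            int(bad.sum()))
        bad = amps <= 0
    return onsets, amps


def simulate_sipsc(truth: SynapticTruth) -> SynapticSimulation:
    """Gap-free inward synaptic-current trace with its ground truth."""
    rng = np.random.default_rng(truth.seed)
    onsets, amps = draw_synaptic_events(truth, rng)
    fs = truth.sampling_rate
    n = int(round(truth.duration_s * fs))
    kern = biexp_kernel(truth.rise_ms, truth.decay_ms, fs)
    trace = np.zeros(n + kern.size)
    for t0, a in zip(onsets, amps):
        i0 = int(round(t0 * fs))
        trace[i0:i0 + kern.size] -= a * kern  # inward (negative) events
    trace = trace[:n]
    if truth.noise_sd_pa > 0:
        trace = trace + rng.normal(0.0, truth.noise_sd_pa, n)
    sweep = Sweep(trace, fs, "current", CommandWaveform(kind="gapfree"))
    return SynapticSimulation(sweep, onsets, amps, truth)


# --- survival --------------------------------------------------------------

def discrete_hazard(median_day: int, spread_days: float,
                    max_day: int = 45) -> np.ndarray:
    """Per-day death hazard whose event-time distribution is a
    discretized normal centred on ``median_day``."""
    from scipy.stats import norm

    days = np.arange(max_day + 1)
    pmf = norm.pdf(days, loc=median_day, scale=spread_days)
    pmf /= pmf.sum()
    surv = np.concatenate([[1.0], 1.0 - np.cumsum(pmf)])[:-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        h = np.where(surv > 1e-12, pmf / surv, 1.0)
    return np.clip(h, 0.0, 1.0)


def simulate_survival(
    groups: dict[str, tuple[np.ndarray, int]],
    seed: int = 0,
    censor_day: int | None = None,
) -> list[SurvivalRecord]:
    """Draw survival cohorts from per-group discrete daily hazards.

    ``groups`` maps a label to ``(hazard, n)`` where ``hazard[d]`` is the
    probability of death on day ``d`` given survival to that day.
    Subjects alive past the hazard profile (or past ``censor_day``) are
    censored.
    """
    rng = np.random.default_rng(seed)
    records = []
    for label, (hazard, n) in groups.items():
        hazard = np.asarray(hazard, dtype=float)
        if (hazard < 0).any():
            raise ValueError(f"negative hazard in group {label!r}")
        if (hazard > 1).any():
            raise ValueError(f"hazard > 1 in group {label!r}")
        if n < 1:
            raise ValueError(f"group {label!r} must have n >= 1")
        last = hazard.size - 1 if censor_day is None else censor_day
        for j in range(n):
            day_of_death = None
            for d in range(hazard.size):
                if censor_day is not None and d >= censor_day:
                    break
                if rng.random() < hazard[d]:
                    day_of_death = d
                    break
            if day_of_death is None:
                records.append(SurvivalRecord(f"{label}-{j}", label, last, False))
            else:
                records.append(SurvivalRecord(f"{label}-{j}", label,
                                              day_of_death, True))
    return records
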