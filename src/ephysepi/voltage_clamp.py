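"""Sodium-current analysis: I-V curves, GHK permeability, Boltzmann
gating fits, and persistent-current ramp analysis.

The voltage dependence of activation is analysed on permeability, not
chord conductance: the measured peak current density I_s (pA/pF) at a
step potential E is converted to a permeability P_s (cm/s) with the
Goldman-Hodgkin-Katz current equation

    I_s = P_s z^2 (E F^2 / RT) ([S]_i - [S]_o e^{-zFE/RT}) / (1 - e^{-zFE/RT})

and the normalized P_s(E) (or the availability curve h(V)) is fitted
with a two-parameter Boltzmann.  Current densities assume the usual
1 uF/cm^2 specific membrane capacitance, which makes pA/pF and uA/cm^2
interchangeable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "GHKContext", "IVCurve", "BoltzmannFit", "RampResult",
    "ghk_current_density", "ghk_permeability", "fit_boltzmann",
    "peak_iv", "activation_permeability", "availability_curve",
    "analyze_ramp", "nucleated_patch_qc", "FitError", "ReversalError",
]

FARADAY = 96485.33212  # C/mol
GAS_CONSTANT = 8.31446261815324  # J/(mol K)


class FitError(RuntimeError):
    """Curve fit failed to converge or the data cannot constrain it."""


class ReversalError(ValueError):
    """GHK inversion requested at (or numerically at) the reversal."""


@dataclass(frozen=True)
class GHKContext:
    """Permeant-ion context for the GHK current equation.

    Concentrations in mM, temperature in K.  ``flux_factor`` returns the
    bracketed GHK factor in (pA/pF) per (cm/s), so that
    ``I = P * flux_factor(E)``.
    """

    valence: int = 1
    c_in_mm: float = 10.0
    c_out_mm: float = 30.0
    temperature_k: float = 295.0

    def __post_init__(self):
        if self.c_in_mm <= 0 or self.c_out_mm <= 0:
            raise ValueError("concentrations must be positive")
        if self.temperature_k <= 0:
            raise ValueError("temperature must be positive")

    @property
    def rt_over_f_mv(self) -> float:
        return GAS_CONSTANT * self.temperature_k / FARADAY * 1e3

    def reversal_mv(self) -> float:
        return self.rt_over_f_mv / self.valence * math.log(
            self.c_out_mm / self.c_in_mm
        )

    def flux_factor(self, e_mv):
        """GHK factor (pA/pF per cm/s): current density per permeability.

        The removable singularity at E = 0 is evaluated by its analytic
        limit I = P z F ([S]_i - [S]_o).
        """
        e_mv = np.asarray(e_mv, dtype=float)
        z = self.valence
        ci = self.c_in_mm * 1e-6  # mol/cm^3
        co = self.c_out_mm * 1e-6
        x = z * e_mv / self.rt_over_f_mv  # zFE/RT, dimensionless
        e_volt = e_mv * 1e-3
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            ex = np.exp(-x)
            bracket = (ci - co * ex) / (1.0 - ex)
            main = (z * z * FARADAY**2 * e_volt
                    / (GAS_CONSTANT * self.temperature_k)) * bracket
        limit = z * FARADAY * (ci - co)
        out = np.where(np.abs(x) < 1e-8, limit, main) * 1e6  # A/cm^2 -> pA/pF
        return out if out.ndim else float(out)


def ghk_current_density(p_cm_per_s, e_mv, ctx: GHKContext):
    """Forward GHK: current density (pA/pF) of an open-channel
    permeability at membrane potential ``e_mv``."""
    return p_cm_per_s * ctx.flux_factor(e_mv)


def ghk_permeability(i_density_pa_pf, e_mv, ctx: GHKContext):
    """Invert the GHK current equation for permeability (cm/s).

    Raises :class:`ReversalError` when ``e_mv`` sits at the reversal
    potential (zero flux factor), where permeability is undefined.
    """
    factor = ctx.flux_factor(e_mv)
    scale = abs(ctx.flux_factor(ctx.reversal_mv() + 25.0)) + 1e-30
    if np.any(np.abs(np.asarray(factor)) < 1e-9 * scale):
        raise ReversalError(
            f"membrane potential {e_mv} mV is at the reversal potential "
            f"({ctx.reversal_mv():.2f} mV); permeability undefined"
        )
    return i_density_pa_pf / factor


# --- Boltzmann fits --------------------------------------------------------

@dataclass(frozen=True)
class BoltzmannFit:
    v_half_mv: float
    k_mv: float
    amplitude: float
    direction: str  # "activation" | "inactivation"
    residual: float
    converged: bool = True

    def __call__(self, v_mv):
        v_mv = np.asarray(v_mv, dtype=float)
        if self.direction == "activation":
            return self.amplitude / (1.0 + np.exp((self.v_half_mv - v_mv) / self.k_mv))
        return self.amplitude / (1.0 + np.exp((v_mv - self.v_half_mv) / self.k_mv))


def fit_boltzmann(v_mv, y, direction: str = "activation") -> BoltzmannFit:
    """Least-squares Boltzmann fit of a normalized gating curve.

    Activation: y = A / (1 + exp((V1/2 - V)/k)); inactivation flips the
    sign of the exponent.  Starting values: V1/2 at the half-maximum
    crossing, k = 5 mV, A = max(y).

    Raises :class:`FitError` on flat data (< 0.2 dynamic range relative
    to max) or non-convergence.
    """
    v = np.asarray(v_mv, dtype=float)
    y = np.asarray(y, dtype=float)
    if direction not in ("activation", "inactivation"):
        raise ValueError(f"unknown direction {direction!r}")
    if v.size < 5:
        raise ValueError("need at least 5 points spanning the transition")
    ymax = np.max(np.abs(y))
    if ymax == 0 or (np.max(y) - np.min(y)) < 0.2 * ymax:
        raise FitError("data too flat to constrain a Boltzmann fit")

    sign = 1.0 if direction == "activation" else -1.0

    def model(vv, vh, k, a):
        return a / (1.0 + np.exp(sign * (vh - vv) / k))

    half = 0.5 * (np.max(y) + np.min(y))
    v0 = float(v[np.argmin(np.abs(y - half))])
    try:
        popt, _ = curve_fit(
            model, v, y, p0=[v0, 5.0, float(np.max(y))],
            bounds=([-150.0, 0.05, 0.0], [100.0, 60.0, 10.0 * ymax]),
            maxfev=10_000,
        )
    except (RuntimeError, ValueError) as e:
        raise FitError(f"Boltzmann fit did not converge: {e}") from e
    resid = float(np.sqrt(np.mean((model(v, *popt) - y) ** 2)))
    return BoltzmannFit(float(popt[0]), float(popt[1]), float(popt[2]),
                        direction, resid)


# --- I-V analysis ----------------------------------------------------------

@dataclass
class IVCurve:
    step_mv: np.ndarray
    peak_density_pa_pf: np.ndarray
    capacitance_pf: float
    reference_mv: float
    reference_density_pa_pf: float
    peak_voltage_mv: float = field(init=False)

    def __post_init__(self):
        self.peak_voltage_mv = float(
            self.step_mv[np.argmin(self.peak_density_pa_pf)]
        )


def peak_iv(
    recording,
    window_s: tuple[float, float] = (0.0002, 0.010),
    reference_mv: float = -25.0,
) -> IVCurve:
    """Peak inward current density per step of a voltage-clamp family.

    The peak is the signed extremum of largest magnitude inside the
    detection window after step onset (the window excludes the
    capacitive-transient region), divided by whole-cell capacitance.
    The density at ``reference_mv`` must exist in the protocol.
    """
    if recording.channel != "current":
        raise TypeError("peak_iv expects a current-channel recording")
    cap = recording.capacitance_pf
    if cap is None or cap <= 0:
        raise ValueError("recording lacks a positive capacitance")
    steps, peaks = [], []
    for s in recording.sweeps:
        if s.command.kind != "step" or s.command.units != "mV":
            continue
        i0 = int(round((s.command.onset_s + window_s[0]) * s.sampling_rate))
        i1 = int(round((s.command.onset_s + window_s[1]) * s.sampling_rate))
        seg = s.samples[i0:max(i1, i0 + 1)]
        peak = seg[np.argmax(np.abs(seg))]
        steps.append(s.command.amplitude)
        peaks.append(peak / cap)
    steps = np.asarray(steps)
    peaks = np.asarray(peaks)
    order = np.argsort(steps)
    steps, peaks = steps[order], peaks[order]
    at_ref = np.isclose(steps, reference_mv, atol=1e-6)
    if not at_ref.any():
        raise ValueError(
            f"reference voltage {reference_mv} mV absent from the protocol"
        )
    return IVCurve(steps, peaks, cap, reference_mv, float(peaks[at_ref][0]))


def activation_permeability(
    iv: IVCurve, ctx: GHKContext, exclusion_mv: float = 10.0,
    fit: bool = True,
):
    """Normalized GHK permeability of the peak I-V and its activation fit.

    Steps within ``exclusion_mv`` of the reversal potential are dropped
    (the GHK bracket vanishes there) along with steps above it, then
    P(V) is normalized to its maximum.  Because normalization divides
    out P_max, the curve is invariant to permeability scaling.
    """
    erev = ctx.reversal_mv()
    keep = iv.step_mv < erev - exclusion_mv
    v = iv.step_mv[keep]
    p = np.array([
        ghk_permeability(d, vv, ctx)
        for d, vv in zip(iv.peak_density_pa_pf[keep], v)
    ])
    pmax = np.max(np.abs(p))
    if pmax == 0:
        raise FitError("no measurable permeability in the family")
    y = np.abs(p) / pmax
    result = fit_boltzmann(v, y, "activation") if fit else None
    return v, y, result


def availability_curve(recording):
    """Steady-state inactivation: normalized test-pulse peaks vs
    prepulse voltage, with the inactivation Boltzmann fit."""
    if recording.channel != "current":
        raise TypeError("availability_curve expects a current recording")
    prepulses, peaks = [], []
    for s in recording.sweeps:
        if s.command.prepulse_mv is None:
            continue
        seg = s.samples
        peaks.append(seg[np.argmax(np.abs(seg))])
        prepulses.append(s.command.prepulse_mv)
    prepulses = np.asarray(prepulses)
    peaks = np.asarray(peaks, dtype=float)
    order = np.argsort(prepulses)
    prepulses, peaks = prepulses[order], peaks[order]
    pmax = np.max(np.abs(peaks))
    if pmax < 1e-12:
        raise ValueError("all test-pulse peaks are ~0; cannot normalize")
    y = np.abs(peaks) / pmax
    fit = fit_boltzmann(prepulses, y, "inactivation")
    return prepulses, y, fit


# --- persistent-current ramps ---------------------------------------------

@dataclass
class RampResult:
    averaged_pa: np.ndarray
    voltage_mv: np.ndarray
    density_at_ref_pa_pf: float
    reference_mv: float
    n_trials: int
    activation: BoltzmannFit | None
    excised_fraction: float


def _excise_transients(i_pa: np.ndarray, sampling_rate: float,
                       criterion_sd: float) -> tuple[np.ndarray, float]:
    """Replace fast transient spikes by linear interpolation.

    Transients are flagged where |dI/dt| exceeds ``criterion_sd`` times
    the robust (MAD-based) SD of dI/dt; flagged runs are expanded by
    0.5 ms on both sides to reach local baseline.
    """
    di = np.diff(i_pa)
    mad = np.median(np.abs(di - np.median(di)))
    robust_sd = 1.4826 * mad
    if robust_sd == 0:
        return i_pa.copy(), 0.0
    bad = np.zeros(i_pa.size, dtype=bool)
    hits = np.where(np.abs(di) > criterion_sd * robust_sd)[0]
    margin = max(1, int(round(0.5e-3 * sampling_rate)))
    for i in hits:
        bad[max(0, i - margin):min(i_pa.size, i + 2 + margin)] = True
    frac = bad.mean()
    if frac == 0:
        return i_pa.copy(), 0.0
    out = i_pa.copy()
    idx = np.arange(i_pa.size)
    out[bad] = np.interp(idx[bad], idx[~bad], i_pa[~bad])
    return out, float(frac)


def analyze_ramp(
    trials,
    capacitance_pf: float,
    criterion_sd: float = 8.0,
    reference_mv: float = -20.0,
    ctx: GHKContext | None = None,
    fit_activation: bool = True,
) -> RampResult:
    """Persistent-current ramp analysis.

    Residual transient spikes are excised from each trial (linear
    interpolation across |dI/dt| outliers), trials are averaged, and the
    persistent density is read at the reference ramp voltage (mean over
    a +/-1 mV window).  When a GHK context is supplied, the averaged
    trace is converted to normalized permeability over the sub-reversal
    range and fitted with an activation Boltzmann.
    """
    trials = list(trials)
    if not trials:
        raise ValueError("need at least one ramp trial")
    cmd = trials[0].command
    if cmd.kind != "ramp":
        raise TypeError("analyze_ramp expects ramp-command sweeps")
    fs = trials[0].sampling_rate
    cleaned = []
    worst = 0.0
    for s in trials:
        c, frac = _excise_transients(s.samples, fs, criterion_sd)
        if frac > 0.20:
            raise ValueError(
                f"transient span covers {frac:.0%} of the ramp; trace unusable"
            )
        worst = max(worst, frac)
        cleaned.append(c)
    avg = np.mean(cleaned, axis=0)
    n = avg.size
    v = cmd.start_mv + (cmd.end_mv - cmd.start_mv) * np.arange(n) / n
    sel = np.abs(v - reference_mv) <= 1.0
    if not sel.any():
        raise ValueError(f"reference voltage {reference_mv} mV not on the ramp")
    density = float(np.mean(avg[sel]) / capacitance_pf)

    fit = None
    if fit_activation and ctx is not None:
        erev = ctx.reversal_mv()
        keep = (v >= -100.0) & (v <= min(-5.0, erev - 10.0))
        dens = avg[keep] / capacitance_pf
        perm = np.array([ghk_permeability(d, vv, ctx)
                         for d, vv in zip(dens, v[keep])])
        pmax = np.max(np.abs(perm))
        if pmax > 0:
            # decimate for the fit; the ramp is heavily oversampled
            vv, yy = v[keep][::40], (np.abs(perm) / pmax)[::40]
            fit = fit_boltzmann(vv, yy, "activation")
    return RampResult(avg, v, density, reference_mv, len(trials), fit, worst)


def nucleated_patch_qc(recording) -> tuple[bool, str]:
    """Nucleated-patch inclusion rule: access resistance <= 20 MOhm and
    input (seal) resistance >= 1 GOhm.  Returns (passed, reason)."""
    ra = recording.access_resistance_mohm
    rin = recording.input_resistance_mohm
    if ra is None or rin is None:
        raise ValueError("recording lacks access/input resistance fields")
    if ra > 20.0:
        return False, "Ra"
    if rin < 1000.0:
        return False, "Rin"
    return True, ""
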