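"""Action-potential detection and current-clamp excitability metrics.

An action potential is defined operationally: the membrane voltage must
cross 0 mV after dv/dt has exceeded 10 mV/ms, and the threshold is the
voltage at the last sub-to-suprathreshold dv/dt crossing preceding the
0 mV crossing.  Between spikes the detector re-arms only once the
voltage has fallen back below 0 mV and dv/dt below the criterion, which
prevents double counting on noisy repolarizations.  Depolarizations
that pass the dv/dt criterion but never reach 0 mV are "failed" spikes
(depolarization block); they are recorded but excluded from counts.

dv/dt is computed by centered finite differences on the recorded trace
at its native sampling rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trace_io import EpisodicRecording, Sweep

__all__ = [
    "APEvent", "TrainMetrics", "PassiveProperties",
    "detect_aps", "ap_features", "passive_properties", "train_metrics",
    "summarize_cells", "auc_low_current", "block_index", "sfa_ratio",
    "DVDT_THRESHOLD_MV_MS", "PEAK_CRITERION_MV",
]

DVDT_THRESHOLD_MV_MS = 10.0
PEAK_CRITERION_MV = 0.0
RMP_QC_CUTOFF_MV = -64.3
RA_QC_CUTOFF_MOHM = 20.0


@dataclass
class APEvent:
    threshold_time_s: float
    threshold_mv: float
    peak_time_s: float
    peak_mv: float
    valid: bool = True  # peak reached 0 mV
    peak_dvdt_mv_ms: float | None = None
    half_width_ms: float | None = None
    ahp_mv: float | None = None
    missing: tuple[str, ...] = ()

    def __post_init__(self):
        if self.valid and self.peak_mv <= self.threshold_mv:
            raise ValueError("peak voltage must exceed threshold voltage")


def _dvdt(v: np.ndarray, fs: float) -> np.ndarray:
    """Centered-difference dv/dt in mV/ms (one-sided at the ends)."""
    return np.gradient(v) * fs / 1e3


def detect_aps(
    sweep: Sweep,
    dvdt_thresh: float = DVDT_THRESHOLD_MV_MS,
    peak_criterion: float = PEAK_CRITERION_MV,
    include_failures: bool = False,
) -> list[APEvent]:
    """Detect action potentials in one voltage sweep.

    Returns time-ordered, non-overlapping events; with
    ``include_failures`` the suprathreshold depolarizations whose
    maximum stays below ``peak_criterion`` are appended as invalid
    events (their "peak" is the local maximum reached).
    """
    if sweep.channel != "voltage":
        raise TypeError("detect_aps expects a voltage sweep")
    if sweep.sampling_rate < 10_000:
        raise ValueError("sampling rate must be >= 10 kHz")
    v = sweep.samples
    fs = sweep.sampling_rate
    dv = _dvdt(v, fs)
    supra = dv >= dvdt_thresh
    n = v.size

    events: list[APEvent] = []
    failures: list[APEvent] = []
    # re-arm flags: both must have been satisfied (not necessarily at the
    # same sample) since the previous spike before a new event can open
    seen_below_peak = True
    seen_sub_dvdt = True
    last_crossing = None  # latest sub->supra dv/dt crossing while re-armed
    i = 1
    while i < n:
        if v[i] < peak_criterion:
            seen_below_peak = True
        if not supra[i]:
            seen_sub_dvdt = True
        if last_crossing is not None and v[i] < v[last_crossing] - 2.0:
            # depolarization collapsed below its own threshold (with a
            # 2 mV noise-hysteresis margin) without a 0 mV crossing:
            # a failed spike if it rose appreciably
            pk = last_crossing + int(np.argmax(v[last_crossing:i + 1]))
            if v[pk] - v[last_crossing] >= 10.0:
                failures.append(APEvent(
                    threshold_time_s=last_crossing / fs,
                    threshold_mv=float(v[last_crossing]),
                    peak_time_s=pk / fs, peak_mv=float(v[pk]),
                    valid=False,
                ))
            last_crossing = None
        if supra[i] and not supra[i - 1] and seen_below_peak and seen_sub_dvdt:
            # latest sub->supra dv/dt crossing wins as the threshold
            last_crossing = i
        if v[i] >= peak_criterion > v[i - 1] and last_crossing is not None:
            # confirmed spike: 0 mV crossing subsequent to the dv/dt
            # criterion (dv/dt need not still exceed it at the crossing)
            j = i
            while j < n and v[j] >= peak_criterion:
                j += 1
            peak_idx = i + int(np.argmax(v[i:j])) if j > i else i
            events.append(APEvent(
                threshold_time_s=last_crossing / fs,
                threshold_mv=float(v[last_crossing]),
                peak_time_s=peak_idx / fs, peak_mv=float(v[peak_idx]),
                valid=True,
            ))
            seen_below_peak = False
            seen_sub_dvdt = False
            last_crossing = None
            i = j
            continue
        i += 1
    if last_crossing is not None:
        # unresolved depolarization at sweep end
        pk = last_crossing + int(np.argmax(v[last_crossing:]))
        if v[pk] - v[last_crossing] >= 10.0 and v[pk] < peak_criterion:
            failures.append(APEvent(
                threshold_time_s=last_crossing / fs,
                threshold_mv=float(v[last_crossing]),
                peak_time_s=pk / fs, peak_mv=float(v[pk]), valid=False,
            ))

    if include_failures:
        events = sorted(events + failures, key=lambda e: e.threshold_time_s)
    return events


def _interp_crossing(t0, t1, v0, v1, level):
    if v1 == v0:
        return t0
    return t0 + (level - v0) / (v1 - v0) * (t1 - t0)


def ap_features(
    sweep: Sweep,
    events: list[APEvent],
    step_end_s: float | None = None,
) -> list[APEvent]:
    """Complete detected events with half-width, peak dv/dt and AHP.

    Half-width: time between the half-amplitude crossings, amplitude
    measured threshold-to-peak.  AHP: minimum voltage between this peak
    and the next event's threshold (or the step end) minus this event's
    threshold.  Features that would require samples beyond the sweep are
    flagged missing rather than extrapolated.
    """
    v = sweep.samples
    fs = sweep.sampling_rate
    dv = _dvdt(v, fs)
    n = v.size
    out = []
    valid = [e for e in events if e.valid]
    for pos, e in enumerate(events):
        if not e.valid:
            out.append(e)
            continue
        missing = []
        th_i = int(round(e.threshold_time_s * fs))
        pk_i = int(round(e.peak_time_s * fs))
        half = 0.5 * (e.threshold_mv + e.peak_mv)
        # rising crossing
        rise = None
        for i in range(pk_i, th_i, -1):
            if v[i - 1] < half <= v[i]:
                rise = _interp_crossing((i - 1) / fs, i / fs, v[i - 1], v[i], half)
                break
        # falling crossing
        fall = None
        for i in range(pk_i + 1, n):
            if v[i] <= half < v[i - 1]:
                fall = _interp_crossing((i - 1) / fs, i / fs, v[i - 1], v[i], half)
                break
        if rise is not None and fall is not None:
            e.half_width_ms = (fall - rise) * 1e3
        else:
            missing.append("half_width")
        e.peak_dvdt_mv_ms = float(np.max(dv[th_i:pk_i + 1]))
        # AHP window: peak -> next valid event's threshold or step end
        nxt = None
        vi = valid.index(e)
        if vi + 1 < len(valid):
            nxt = int(round(valid[vi + 1].threshold_time_s * fs))
        end_i = n if step_end_s is None else min(n, int(round(step_end_s * fs)))
        win_end = nxt if nxt is not None else end_i
        if win_end > pk_i + 1:
            e.ahp_mv = float(np.min(v[pk_i + 1:win_end]) - e.threshold_mv)
        else:
            missing.append("ahp")
        e.missing = tuple(missing)
        out.append(e)
    return out


@dataclass
class PassiveProperties:
    rmp_mv: float
    input_resistance_mohm: float | None
    capacitance_pf: float | None
    access_resistance_mohm: float | None
    qc_pass: bool
    qc_reason: str = ""


def passive_properties(
    recording: EpisodicRecording,
    rmp_window_s: float = 0.1,
    rin_at_s: float = 0.25,
    rin_step_pa: float = -10.0,
) -> PassiveProperties:
    """RMP, input resistance and the study's current-clamp QC gate.

    RMP is the mean voltage over the first 100 ms of the 0 pA sweep;
    input resistance is Ohm's law on the -10 pA step deflection read
    250 ms into the step (5-ms average for noise immunity).  QC fails
    when access resistance > 20 MOhm or RMP > -64.3 mV.
    """
    if not recording.corrected:
        raise ValueError("current-clamp analysis requires a "
                         "junction-corrected recording")
    try:
        zero = recording.sweep_by_amplitude(0.0)
    except KeyError:
        raise ValueError("recording lacks a 0 pA epoch") from None
    fs = zero.sampling_rate
    rmp = float(np.mean(zero.samples[: int(rmp_window_s * fs)]))

    rin = None
    try:
        step = recording.sweep_by_amplitude(rin_step_pa)
    except KeyError:
        step = None
    if step is not None:
        at = step.command.onset_s + rin_at_s
        i0 = int((at - 0.0025) * fs)
        i1 = int((at + 0.0025) * fs)
        v_def = float(np.mean(step.samples[i0:i1]))
        rin = (v_def - rmp) / rin_step_pa * 1e3  # mV/pA -> MOhm

    ra = recording.access_resistance_mohm
    qc, reason = True, ""
    if ra is not None and ra > RA_QC_CUTOFF_MOHM:
        qc, reason = False, "Ra"
    elif rmp > RMP_QC_CUTOFF_MV:
        qc, reason = False, "RMP"
    return PassiveProperties(rmp, rin, recording.capacitance_pf, ra, qc, reason)


# --- train metrics ---------------------------------------------------------

def auc_low_current(counts: dict[float, int], upto_pa: float = 50.0,
                    grid_pa: float = 10.0) -> float:
    """Trapezoidal area under the spike-count vs injected-current curve
    from 0 to ``upto_pa`` on the protocol grid (missing grid points count
    as zero).  Units: AP*pA."""
    grid = np.arange(0.0, upto_pa + grid_pa / 2, grid_pa)
    y = np.array([counts.get(g, 0) for g in grid], dtype=float)
    return float(np.trapezoid(y, grid))


def block_index(counts: dict[float, int]) -> float | None:
    """Depolarization-block index: 1 - count at the highest injection
    over the maximum count (0 when firing never attenuates)."""
    pos = {a: c for a, c in counts.items() if a > 0}
    if not pos:
        return None
    top = pos[max(pos)]
    mx = max(pos.values())
    if mx == 0:
        return None
    return 1.0 - top / mx


def sfa_ratio(peak_times_s: np.ndarray) -> float | None:
    """Spike-frequency adaptation: last interspike interval over the
    second; needs at least 3 ISIs."""
    isi = np.diff(np.asarray(peak_times_s))
    if isi.size < 3:
        return None
    return float(isi[-1] / isi[1])


ANALYSIS_RULES = ("fs", "layer5", "layer6", "subiculum")


@dataclass
class TrainMetrics:
    counts: dict[float, int]
    max_rate_hz: float
    rheobase_pa: float | None
    sfa: float | None
    block: float | None
    auc_50: float
    analysis_current_pa: float | None
    first_ap: APEvent | None = None
    train_mean: dict[str, float] = field(default_factory=dict)
    n_failures: int = 0


def train_metrics(
    recording: EpisodicRecording,
    analysis_rule: str = "fs",
    dvdt_thresh: float = DVDT_THRESHOLD_MV_MS,
) -> TrainMetrics:
    """Spike counts per injection and the derived train metrics.

    Counts include only full APs (maximum >= 0 mV); failures are
    tallied separately.  Max firing rate is the maximum count over the
    1-s steps; adaptation (SFA) is measured on the max-rate sweep.
    The sweep used for train AP parameters follows ``analysis_rule``:
    20 pA above the repetitive-firing (> 3 APs) threshold for
    fast-spiking cells, a fixed 100 pA for layer-6 or 150 pA for
    layer-5/subicular pyramidal cells.
    """
    if analysis_rule not in ANALYSIS_RULES:
        raise ValueError(f"unknown analysis rule {analysis_rule!r}")
    step_sweeps = [s for s in recording.sweeps if s.command.kind == "step"]
    if sum(1 for s in step_sweeps if s.command.amplitude > 0) < 2:
        raise ValueError("need at least two positive-current sweeps")

    counts: dict[float, int] = {}
    failures = 0
    events_by_amp: dict[float, list[APEvent]] = {}
    dur = step_sweeps[0].command.duration_s
    for s in step_sweeps:
        evs = detect_aps(s, dvdt_thresh=dvdt_thresh, include_failures=True)
        valid = [e for e in evs if e.valid]
        failures += len(evs) - len(valid)
        counts[s.command.amplitude] = len(valid)
        events_by_amp[s.command.amplitude] = valid

    pos = {a: c for a, c in counts.items() if a > 0}
    max_count = max(pos.values()) if pos else 0
    max_rate = max_count / dur
    fired = [a for a, c in counts.items() if c >= 1 and a > 0]
    rheobase = min(fired) if fired else None

    sfa = None
    if max_count > 0:
        best_amp = min(a for a, c in pos.items() if c == max_count)
        sfa = sfa_ratio([e.peak_time_s for e in events_by_amp[best_amp]])

    if analysis_rule == "fs":
        rep = sorted(a for a, c in pos.items() if c > 3)
        analysis_amp = rep[0] + 20.0 if rep else None
    elif analysis_rule == "layer6":
        analysis_amp = 100.0
    else:
        analysis_amp = 150.0

    first_ap = None
    train_mean: dict[str, float] = {}
    if analysis_amp is not None and analysis_amp in events_by_amp:
        sweep = next(s for s in step_sweeps
                     if s.command.amplitude == analysis_amp)
        end = sweep.command.onset_s + sweep.command.duration_s
        evs = ap_features(sweep, events_by_amp[analysis_amp], step_end_s=end)
        evs = [e for e in evs if e.valid]
        if evs:
            first_ap = evs[0]
            train = evs[1:] if len(evs) > 1 else evs
            train_mean = {
                "peak_mv": float(np.mean([e.peak_mv for e in train])),
                "peak_dvdt_mv_ms": float(np.mean(
                    [e.peak_dvdt_mv_ms for e in train
                     if e.peak_dvdt_mv_ms is not None])),
                "threshold_mv": float(np.mean([e.threshold_mv for e in train])),
                "half_width_ms": float(np.mean(
                    [e.half_width_ms for e in train
                     if e.half_width_ms is not None])),
                "ahp_mv": float(np.mean(
                    [e.ahp_mv for e in train if e.ahp_mv is not None])),
            }

    return TrainMetrics(
        counts=counts, max_rate_hz=max_rate, rheobase_pa=rheobase, sfa=sfa,
        block=block_index(counts), auc_50=auc_low_current(counts),
        analysis_current_pa=analysis_amp, first_ap=first_ap,
        train_mean=train_mean, n_failures=failures,
    )


def summarize_cells(cells) -> pd.DataFrame:
    """Tidy per-cell metric table.

    ``cells`` is an iterable of ``(cell_id, group, {metric: value})``
    entries; the result has one row per cell per metric (None values are
    dropped).  Duplicate cell ids and empty input are errors.
    """
    cells = list(cells)
    if not cells:
        raise ValueError("no cells to summarize")
    ids = [c[0] for c in cells]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate cell ids: {', '.join(dupes)}")
    rows = []
    for cid, group, metrics in cells:
        for metric, value in metrics.items():
            if value is None:
                continue
            rows.append({"cell_id": cid, "group": group,
                         "metric": metric, "value": float(value)})
    return pd.DataFrame(rows)
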