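"""Study-shaped orchestration: simulate cohorts, analyze, compare, report.

:func:`run_study` executes the whole synthetic study from one
declarative config (a dict or a YAML path): fast-spiking current-clamp
cohorts, dissociated-neuron and nucleated-patch sodium-current families,
persistent-current ramps, sIPSC traces and survival cohorts, at the
study's cohort sizes by default.  All randomness derives from a single
seed, so a rerun with an identical config is identical.

:func:`make_demo_dataset` writes the same synthetic study to disk in the
native format with a manifest, so the file-reading path of the pipeline
can be exercised end to end.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import current_clamp as cc
from . import stats_survival as st
from . import synaptic as syn
from . import synthetic as sd
from . import trace_io
from . import voltage_clamp as vc

__all__ = ["StudyConfig", "StudyResult", "run_study", "make_demo_dataset"]


@dataclass
class StudyConfig:
    """Cohort sizes and analysis settings; defaults match the study."""

    seed: int = 0
    n_fs: tuple[int, int] = (11, 11)          # WT / null FS interneurons
    n_dissociated: tuple[int, int] = (10, 8)  # WT / null dissociated cells
    n_patch: tuple[int, int] = (10, 10)       # WT / null nucleated patches
    n_ramp: tuple[int, int] = (9, 7)          # WT / null ramp cells
    n_sipsc: tuple[int, int] = (12, 12)       # WT / null sIPSC cells
    n_survival: tuple[int, int] = (60, 62)    # null / PV-Cre subjects
    sipsc_duration_s: float = 300.0
    fdr_q: float = 0.05
    output_dir: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for k in ("n_fs", "n_dissociated", "n_patch", "n_ramp", "n_sipsc",
                  "n_survival"):
            if k in raw:
                raw[k] = tuple(raw[k])
        return cls(**raw)


@dataclass
class StudyResult:
    per_cell: pd.DataFrame
    table_excitability: pd.DataFrame
    table_ina: pd.DataFrame
    sipsc: pd.DataFrame
    sipsc_ks: dict
    survival: pd.DataFrame
    log: dict = field(default_factory=dict)


def _spawn_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def _fs_cohort_metrics(config: StudyConfig, seed: int, log: dict):
    rows, comparisons = [], []
    per_group_values: dict[str, dict[str, list[float]]] = {}
    seeds = _spawn_seeds(seed, 2)
    for (group, preset, n, s0) in (
        ("wt", sd.get_preset("FS"), config.n_fs[0], seeds[0]),
        ("null", sd.knockout_preset("FS"), config.n_fs[1], seeds[1]),
    ):
        cells = sd.cohort_presets(preset, n, s0)
        cell_seeds = _spawn_seeds(s0, n)
        for j, cell in enumerate(cells):
            rec = sd.simulate_current_clamp(
                cell, sd.FS_PROTOCOL, seed=cell_seeds[j], group=group,
                cell_id=f"fs-{group}-{j}",
            )
            passive = cc.passive_properties(rec)
            if not passive.qc_pass:
                log.setdefault("qc_exclusions", []).append(
                    {"cell": rec.cell_id, "reason": passive.qc_reason})
                continue
            tm = cc.train_metrics(rec, "fs")
            metrics = {
                "rmp_mv": passive.rmp_mv,
                "input_resistance_mohm": passive.input_resistance_mohm,
                "capacitance_pf": rec.capacitance_pf,
                "max_rate_hz": tm.max_rate_hz,
                "rheobase_pa": tm.rheobase_pa,
                "sfa": tm.sfa,
                "block": tm.block,
                "auc_50": tm.auc_50,
                "train_half_width_ms": tm.train_mean.get("half_width_ms"),
                "train_ahp_mv": tm.train_mean.get("ahp_mv"),
                "train_threshold_mv": tm.train_mean.get("threshold_mv"),
                "train_peak_dvdt": tm.train_mean.get("peak_dvdt_mv_ms"),
            }
            rows.append((rec.cell_id, group, metrics))
            for k, v in metrics.items():
                if v is not None:
                    per_group_values.setdefault(k, {}).setdefault(
                        group, []).append(v)
    tidy = cc.summarize_cells(rows)
    for metric, groups in per_group_values.items():
        if len(groups.get("wt", [])) >= 3 and len(groups.get("null", [])) >= 3:
            try:
                comparisons.append(st.compare_groups(
                    groups["wt"], groups["null"], metric=metric,
                    group_a="wt", group_b="null"))
            except ValueError:
                pass
    table = (st.build_results_table(comparisons, q=config.fdr_q)
             if comparisons else pd.DataFrame())
    return tidy, table


def _ina_tables(config: StudyConfig, seed: int, log: dict):
    rows = []
    seeds = _spawn_seeds(seed, 6)
    scenarios = [
        ("dissociated", sd.DISSOCIATED_WT, sd.DISSOCIATED_NULL,
         config.n_dissociated, -25.0, seeds[0:2]),
        ("patch", sd.PATCH_WT, sd.PATCH_NULL, config.n_patch, -20.0,
         seeds[2:4]),
    ]
    for name, wt_truth, null_truth, (n_wt, n_null), ref, (s_wt, s_null) in scenarios:
        for group, truth, n, s0 in (("wt", wt_truth, n_wt, s_wt),
                                    ("null", null_truth, n_null, s_null)):
            cell_seeds = _spawn_seeds(s0, n)
            for j in range(n):
                rec = sd.simulate_ina_step_family(
                    truth, seed=cell_seeds[j], group=group,
                    cell_id=f"{name}-{group}-{j}",
                    noise_sd_pa=10.0 if name == "dissociated" else 3.0,
                )
                if name == "patch":
                    ok, reason = vc.nucleated_patch_qc(rec)
                    if not ok:
                        log.setdefault("qc_exclusions", []).append(
                            {"cell": rec.cell_id, "reason": reason})
                        continue
                iv = vc.peak_iv(rec, reference_mv=ref)
                _, _, act = vc.activation_permeability(iv, truth.ghk)
                avail = sd.simulate_availability_family(
                    truth, seed=cell_seeds[j] + 1, test_mv=ref,
                    noise_sd_pa=10.0 if name == "dissociated" else 3.0,
                )
                _, _, inact = vc.availability_curve(avail)
                rows.append({
                    "scenario": name, "group": group, "cell_id": rec.cell_id,
                    "peak_density_pa_pf": iv.reference_density_pa_pf,
                    "capacitance_pf": rec.capacitance_pf,
                    "act_vhalf_mv": act.v_half_mv, "act_k_mv": act.k_mv,
                    "inact_vhalf_mv": inact.v_half_mv,
                    "inact_k_mv": inact.k_mv,
                })
    # persistent ramps
    for group, truth, n, s0 in (("wt", sd.RAMP_WT, config.n_ramp[0], seeds[4]),
                                ("null", sd.RAMP_NULL, config.n_ramp[1],
                                 seeds[5])):
        cell_seeds = _spawn_seeds(s0, n)
        for j in range(n):
            trials = sd.simulate_ramp(truth, n_trials=4, seed=cell_seeds[j])
            res = vc.analyze_ramp(trials, truth.capacitance_pf,
                                  ctx=truth.ghk)
            rows.append({
                "scenario": "ramp", "group": group,
                "cell_id": f"ramp-{group}-{j}",
                "peak_density_pa_pf": res.density_at_ref_pa_pf,
                "capacitance_pf": truth.capacitance_pf,
                "act_vhalf_mv": res.activation.v_half_mv
                if res.activation else None,
                "act_k_mv": res.activation.k_mv if res.activation else None,
                "inact_vhalf_mv": None, "inact_k_mv": None,
            })
    return pd.DataFrame(rows)


def _sipsc_results(config: StudyConfig, seed: int):
    seeds = _spawn_seeds(seed, 2)
    summaries: dict[str, list[syn.CellEventSummary]] = {"wt": [], "null": []}
    rows = []
    for group, rate, s0, n in (("wt", 3.81, seeds[0], config.n_sipsc[0]),
                               ("null", 1.38, seeds[1], config.n_sipsc[1])):
        cell_seeds = _spawn_seeds(s0, n)
        for j in range(n):
            truth = sd.SynapticTruth(
                rate_hz=rate, duration_s=config.sipsc_duration_s,
                seed=cell_seeds[j],
            )
            sim = sd.simulate_sipsc(truth)
            events = syn.detect_events(sim.sweep)
            summ = syn.summarize_cell(events, truth.duration_s,
                                      cell_id=f"sipsc-{group}-{j}",
                                      group=group)
            summaries[group].append(summ)
            rows.append({
                "cell_id": summ.cell_id, "group": group,
                "n_events": summ.n_events,
                "frequency_hz": summ.frequency_hz,
                "mean_amplitude_pa": summ.mean_amplitude_pa,
                "true_n_events": sim.onsets_s.size,
            })
    pool_wt, _ = syn.pooled_ecdf(summaries["wt"], seed=seeds[0])
    pool_null, _ = syn.pooled_ecdf(summaries["null"], seed=seeds[1])
    d, p = syn.ks_compare(pool_wt, pool_null)
    f_wt = [s.frequency_hz for s in summaries["wt"]]
    f_null = [s.frequency_hz for s in summaries["null"]]
    ks = {"amplitude_ks_d": d, "amplitude_ks_p": p,
          "fold_frequency": float(np.mean(f_wt) / np.mean(f_null))}
    if min(len(f_wt), len(f_null)) >= 3:
        freq_cmp = st.compare_groups(f_wt, f_null, metric="sipsc_frequency",
                                     group_a="wt", group_b="null")
        amp_cmp = st.compare_groups(
            [s.mean_amplitude_pa for s in summaries["wt"]],
            [s.mean_amplitude_pa for s in summaries["null"]],
            metric="sipsc_amplitude", group_a="wt", group_b="null")
        ks.update({"frequency_welch_p": freq_cmp.p_value,
                   "frequency_test": freq_cmp.test_used,
                   "amplitude_p": amp_cmp.p_value})
    return pd.DataFrame(rows), ks


def _survival_results(config: StudyConfig, seed: int):
    records = sd.simulate_survival(
        {
            "null": (sd.discrete_hazard(18, 2.0), config.n_survival[0]),
            "pv_cre": (sd.discrete_hazard(25, 3.0), config.n_survival[1]),
        },
        seed=seed,
    )
    rows = []
    for g in ("null", "pv_cre"):
        _, median = st.km_estimate(records, g)
        rows.append({"group": g,
                     "n": sum(r.group == g for r in records),
                     "median_day": median})
    chi2, p = st.logrank(records)
    out = pd.DataFrame(rows)
    out["logrank_chi2"] = chi2
    out["logrank_p"] = p
    return out


def run_study(config: StudyConfig | dict | str | Path | None = None) -> StudyResult:
    """Run the full synthetic study and return its result tables.

    ``config`` may be a :class:`StudyConfig`, a mapping of its fields, a
    YAML path, or None for the study defaults.  When ``output_dir`` is
    set, result tables and the run log are written there as CSV/JSON.
    """
    if config is None:
        config = StudyConfig()
    elif isinstance(config, (str, Path)):
        config = StudyConfig.from_yaml(config)
    elif isinstance(config, dict):
        config = StudyConfig(**{k: tuple(v) if k.startswith("n_") else v
                                for k, v in config.items()})
    log: dict = {"seed": config.seed,
                 "config": dataclasses.asdict(config),
                 "qc_exclusions": []}
    seeds = _spawn_seeds(config.seed, 4)
    per_cell, table_exc = _fs_cohort_metrics(config, seeds[0], log)
    table_ina = _ina_tables(config, seeds[1], log)
    sipsc, ks = _sipsc_results(config, seeds[2])
    survival = _survival_results(config, seeds[3])
    result = StudyResult(per_cell, table_exc, table_ina, sipsc, ks,
                         survival, log)

    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        per_cell.to_csv(out / "fs_per_cell.csv", index=False)
        table_exc.to_csv(out / "table_excitability.csv", index=False)
        table_ina.to_csv(out / "table_ina.csv", index=False)
        sipsc.to_csv(out / "sipsc_cells.csv", index=False)
        survival.to_csv(out / "survival.csv", index=False)
        (out / "run_log.json").write_text(json.dumps(
            {**log, "sipsc_ks": ks}, indent=1, default=str))
    return result


# --- on-disk demo dataset --------------------------------------------------

def make_demo_dataset(
    out_dir: str | Path,
    seed: int = 0,
    n_fs: tuple[int, int] = (11, 11),
    n_dissociated: tuple[int, int] = (10, 8),
    n_patch: tuple[int, int] = (10, 10),
    n_sipsc: tuple[int, int] = (12, 12),
    n_survival: tuple[int, int] = (60, 62),
    sipsc_duration_s: float = 300.0,
) -> pd.DataFrame:
    """Write a synthetic study to disk (native HDF5 + CSV manifest).

    Defaults are the study's cohort sizes.  Returns the manifest, which
    lists one row per recording (path, group, cell type, recording mode)
    plus the survival table path.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _spawn_seeds(seed, 4)
    manifest = []

    cell_seeds = _spawn_seeds(seeds[0], sum(n_fs) + 2)
    k = 0
    for group, preset, n in (("wt", sd.get_preset("FS"), n_fs[0]),
                             ("null", sd.knockout_preset("FS"), n_fs[1])):
        if n == 0:
            continue
        for cell in sd.cohort_presets(preset, n, cell_seeds[k]):
            rec = sd.simulate_current_clamp(
                cell, sd.FS_PROTOCOL, seed=cell_seeds[k], group=group,
                cell_id=f"fs-{group}-{k}")
            path = out / f"{rec.cell_id}.h5"
            trace_io.write_recording(rec, path)
            manifest.append({"path": str(path), "group": group,
                             "cell_type": "FS", "mode": "current-clamp"})
            k += 1

    cell_seeds = _spawn_seeds(seeds[1], sum(n_dissociated) + sum(n_patch))
    k = 0
    for name, wt, null, (n_wt, n_null) in (
        ("dissociated", sd.DISSOCIATED_WT, sd.DISSOCIATED_NULL, n_dissociated),
        ("patch", sd.PATCH_WT, sd.PATCH_NULL, n_patch),
    ):
        for group, truth, n in (("wt", wt, n_wt), ("null", null, n_null)):
            for _ in range(n):
                rec = sd.simulate_ina_step_family(
                    truth, seed=cell_seeds[k], group=group,
                    cell_id=f"{name}-{group}-{k}")
                path = out / f"{rec.cell_id}.h5"
                trace_io.write_recording(rec, path)
                manifest.append({"path": str(path), "group": group,
                                 "cell_type": name, "mode": "voltage-clamp"})
                k += 1

    cell_seeds = _spawn_seeds(seeds[2], sum(n_sipsc))
    k = 0
    for group, rate, n in (("wt", 3.81, n_sipsc[0]),
                           ("null", 1.38, n_sipsc[1])):
        for _ in range(n):
            sim = sd.simulate_sipsc(sd.SynapticTruth(
                rate_hz=rate, duration_s=sipsc_duration_s,
                seed=cell_seeds[k]))
            rec = trace_io.EpisodicRecording(
                sweeps=[sim.sweep], cell_id=f"sipsc-{group}-{k}", group=group,
                truth={"onsets_s": sim.onsets_s.tolist(),
                       "amplitudes_pa": sim.amplitudes_pa.tolist(),
                       "rate_hz": rate})
            path = out / f"{rec.cell_id}.h5"
            trace_io.write_recording(rec, path)
            manifest.append({"path": str(path), "group": group,
                             "cell_type": "layer6", "mode": "sipsc"})
            k += 1

    records = sd.simulate_survival(
        {"null": (sd.discrete_hazard(18, 2.0), n_survival[0]),
         "pv_cre": (sd.discrete_hazard(25, 3.0), n_survival[1])},
        seed=seeds[3])
    surv = pd.DataFrame([dataclasses.asdict(r) for r in records])
    surv.to_csv(out / "survival_records.csv", index=False)

    mf = pd.DataFrame(manifest)
    mf.to_csv(out / "manifest.csv", index=False)
    return mf
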