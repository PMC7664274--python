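"""Episodic-recording containers and native file formats.

A :class:`Sweep` is one sampled trace (membrane voltage in mV or membrane
current in pA) plus a description of the command waveform that elicited
it.  An :class:`EpisodicRecording` is an ordered family of sweeps sharing
a sampling rate and channel kind, with the per-cell metadata the analysis
stages need (capacitance, access resistance, junction potential, genotype
group).

Internal conventions: voltages mV, currents pA, time seconds
(sweep-relative, sample 0 at t = 0).  All unit conversion happens at the
file boundary.

Native formats:

* HDF5 (preferred): datasets ``/sweeps/{i}/samples`` with sweep attrs
  (``rate``, ``channel``, ``command`` JSON) and recording-level root
  attrs; lossless round-trip.
* CSV directory: one ``sweep_NNN.csv`` per sweep plus a ``protocol.json``
  sidecar holding everything that is not a sample.

ABF (Axon Binary Format) v2 files can be read when the optional ``pyabf``
dependency is installed; writing ABF is refused.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "CommandWaveform",
    "Sweep",
    "EpisodicRecording",
    "read_recording",
    "write_recording",
    "apply_junction_correction",
    "RecordingIOError",
    "AlreadyCorrectedError",
]


class RecordingIOError(IOError):
    """Unreadable/unwritable recording file; message names the path."""


class AlreadyCorrectedError(ValueError):
    """Junction correction applied twice."""


@dataclass(frozen=True)
class CommandWaveform:
    """Descriptor of the command applied during one sweep.

    ``kind`` is one of ``"step"`` (amplitude in pA or mV relative to
    baseline/holding, onset and duration in s), ``"ramp"``
    (start/end in mV over ``duration_s``) or ``"gapfree"``.
    ``prepulse_mv``/``prepulse_s`` describe a conditioning pulse that
    precedes the test step (availability protocols).
    """

    kind: str = "gapfree"
    amplitude: float = 0.0
    onset_s: float = 0.0
    duration_s: float = 0.0
    units: str = "pA"
    holding: float = 0.0
    start_mv: float = 0.0
    end_mv: float = 0.0
    prepulse_mv: float | None = None
    prepulse_s: float | None = None

    def __post_init__(self):
        if self.kind not in ("step", "ramp", "gapfree"):
            raise ValueError(f"unknown command kind {self.kind!r}")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "CommandWaveform":
        return cls(**json.loads(s))


@dataclass
class Sweep:
    samples: np.ndarray
    sampling_rate: float
    channel: str  # "voltage" | "current"
    command: CommandWaveform = field(default_factory=CommandWaveform)
    index: int = 0

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.channel not in ("voltage", "current"):
            raise ValueError(f"unknown channel kind {self.channel!r}")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("non-finite samples")
        if self.command.kind != "gapfree":
            dur = self.command.onset_s + self.command.duration_s
            if dur > self.duration_s + 1e-9:
                raise ValueError("command extends beyond the trace")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sampling_rate

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.sampling_rate


@dataclass
class EpisodicRecording:
    sweeps: list[Sweep]
    cell_id: str = ""
    group: str = ""
    junction_potential_mv: float = 0.0
    corrected: bool = False
    capacitance_pf: float | None = None
    access_resistance_mohm: float | None = None
    input_resistance_mohm: float | None = None
    protocol: dict = field(default_factory=dict)
    truth: dict = field(default_factory=dict)  # generator ground truth

    def __post_init__(self):
        if not self.sweeps:
            raise ValueError("recording must contain at least one sweep")
        rates = {s.sampling_rate for s in self.sweeps}
        if len(rates) != 1:
            raise ValueError("sweeps must share one sampling rate")
        kinds = {s.channel for s in self.sweeps}
        if len(kinds) != 1:
            raise ValueError("sweeps must share one channel kind")
        amps = [s.command.amplitude for s in self.sweeps
                if s.command.kind == "step"]
        if len(amps) > 2:
            incs = np.diff(sorted(amps))
            if incs.size and not np.allclose(incs, incs[0], atol=1e-6):
                raise ValueError("step increments must be uniform")

    @property
    def sampling_rate(self) -> float:
        return self.sweeps[0].sampling_rate

    @property
    def channel(self) -> str:
        return self.sweeps[0].channel

    def sweep_by_amplitude(self, amplitude: float, atol: float = 1e-6) -> Sweep:
        for s in self.sweeps:
            if s.command.kind == "step" and math.isclose(
                s.command.amplitude, amplitude, abs_tol=atol
            ):
                return s
        raise KeyError(f"no step sweep with amplitude {amplitude}")


def apply_junction_correction(
    recording: EpisodicRecording, ljp_mv: float
) -> EpisodicRecording:
    """Shift all voltages (samples and commands) by -LJP; set the flag.

    Raises :class:`AlreadyCorrectedError` on a second call.
    """
    if recording.corrected:
        raise AlreadyCorrectedError(
            f"recording {recording.cell_id!r} is already junction-corrected"
        )
    sweeps = []
    for s in recording.sweeps:
        cmd = s.command
        if s.channel == "voltage" or cmd.units == "mV" or cmd.kind == "ramp":
            cmd = dataclasses.replace(
                cmd,
                holding=cmd.holding - ljp_mv if cmd.units == "mV" else cmd.holding,
                amplitude=cmd.amplitude - ljp_mv
                if cmd.kind == "step" and cmd.units == "mV" else cmd.amplitude,
                start_mv=cmd.start_mv - ljp_mv if cmd.kind == "ramp" else cmd.start_mv,
                end_mv=cmd.end_mv - ljp_mv if cmd.kind == "ramp" else cmd.end_mv,
                prepulse_mv=cmd.prepulse_mv - ljp_mv
                if cmd.prepulse_mv is not None else None,
            )
        samples = s.samples - ljp_mv if s.channel == "voltage" else s.samples.copy()
        sweeps.append(Sweep(samples, s.sampling_rate, s.channel, cmd, s.index))
    return dataclasses.replace(
        recording,
        sweeps=sweeps,
        junction_potential_mv=ljp_mv,
        corrected=True,
        protocol=dict(recording.protocol),
        truth=dict(recording.truth),
    )


# --- serialization ---------------------------------------------------------

_META_KEYS = (
    "cell_id", "group", "junction_potential_mv", "corrected",
    "capacitance_pf", "access_resistance_mohm", "input_resistance_mohm",
)


def _meta_dict(rec: EpisodicRecording) -> dict:
    meta = {k: getattr(rec, k) for k in _META_KEYS}
    meta["protocol"] = rec.protocol
    meta["truth"] = rec.truth
    return meta


def _rec_from_parts(sweeps: list[Sweep], meta: dict) -> EpisodicRecording:
    return EpisodicRecording(
        sweeps=sweeps,
        protocol=meta.get("protocol", {}) or {},
        truth=meta.get("truth", {}) or {},
        **{k: meta.get(k) for k in _META_KEYS if meta.get(k) is not None},
    )


def write_recording(
    recording: EpisodicRecording, path: str | Path, format: str = "hdf5"
) -> None:
    """Write a recording losslessly in a native format.

    ``format`` is ``"hdf5"`` or ``"csv"``; ABF writing is refused.
    """
    path = Path(path)
    if format == "abf":
        raise RecordingIOError("ABF is read-only; refusing to write ABF")
    if format == "hdf5":
        import h5py

        try:
            with h5py.File(path, "w") as f:
                f.attrs["meta"] = json.dumps(_meta_dict(recording))
                grp = f.create_group("sweeps")
                for i, s in enumerate(recording.sweeps):
                    g = grp.create_group(str(i))
                    g.create_dataset("samples", data=s.samples)
                    g.attrs["rate"] = s.sampling_rate
                    g.attrs["channel"] = s.channel
                    g.attrs["command"] = s.command.to_json()
                    g.attrs["index"] = s.index
        except OSError as e:
            raise RecordingIOError(f"cannot write {path}: {e}") from e
    elif format == "csv":
        try:
            path.mkdir(parents=True, exist_ok=True)
            sidecar = {
                "meta": _meta_dict(recording),
                "sweeps": [
                    {
                        "file": f"sweep_{i:03d}.csv",
                        "rate": s.sampling_rate,
                        "channel": s.channel,
                        "command": json.loads(s.command.to_json()),
                        "index": s.index,
                    }
                    for i, s in enumerate(recording.sweeps)
                ],
            }
            (path / "protocol.json").write_text(json.dumps(sidecar, indent=1))
            for i, s in enumerate(recording.sweeps):
                np.savetxt(path / f"sweep_{i:03d}.csv", s.samples, fmt="%.17g")
        except OSError as e:
            raise RecordingIOError(f"cannot write {path}: {e}") from e
    else:
        raise ValueError(f"unknown native format {format!r}")


def read_recording(path: str | Path, format: str | None = None) -> EpisodicRecording:
    """Read a recording; format inferred from the path when not given.

    Supported: ``"hdf5"``, ``"csv"`` (directory with ``protocol.json``
    sidecar) and ``"abf"`` (requires the optional ``pyabf`` package).
    """
    path = Path(path)
    if not path.exists():
        raise RecordingIOError(f"no such recording: {path}")
    if format is None:
        if path.suffix in (".h5", ".hdf5"):
            format = "hdf5"
        elif path.suffix == ".abf":
            format = "abf"
        elif path.is_dir():
            format = "csv"
        else:
            raise RecordingIOError(f"cannot infer format of {path}")

    if format == "hdf5":
        import h5py

        try:
            with h5py.File(path, "r") as f:
                meta = json.loads(f.attrs["meta"])
                sweeps = []
                for i in sorted(f["sweeps"], key=int):
                    g = f["sweeps"][i]
                    sweeps.append(
                        Sweep(
                            g["samples"][...],
                            float(g.attrs["rate"]),
                            str(g.attrs["channel"]),
                            CommandWaveform.from_json(g.attrs["command"]),
                            int(g.attrs["index"]),
                        )
                    )
        except (OSError, KeyError) as e:
            raise RecordingIOError(f"cannot read {path}: {e}") from e
        return _rec_from_parts(sweeps, meta)

    if format == "csv":
        sidecar = path / "protocol.json"
        if not sidecar.exists():
            raise RecordingIOError(f"missing sidecar {sidecar}")
        spec = json.loads(sidecar.read_text())
        sweeps = []
        for entry in spec["sweeps"]:
            fp = path / entry["file"]
            if not fp.exists():
                raise RecordingIOError(f"missing sweep file {fp}")
            sweeps.append(
                Sweep(
                    np.loadtxt(fp, ndmin=1),
                    float(entry["rate"]),
                    entry["channel"],
                    CommandWaveform(**entry["command"]),
                    int(entry["index"]),
                )
            )
        return _rec_from_parts(sweeps, spec["meta"])

    if format == "abf":
        try:
            import pyabf  # noqa: F401
        except ImportError as e:
            raise RecordingIOError(
                "reading ABF requires the optional 'pyabf' dependency "
                "(pip install ephysepi[abf])"
            ) from e
        return _read_abf(path)

    raise ValueError(f"unknown format {format!r}")


def _read_abf(path: Path) -> EpisodicRecording:  # pragma: no cover - optional
    import pyabf

    abf = pyabf.ABF(str(path))
    sweeps = []
    for i in abf.sweepList:
        abf.setSweep(i)
        units = abf.sweepUnitsY.lower()
        if "v" in units:
            channel = "voltage"
            scale = 1.0 if units == "mv" else 1e3
        elif "a" in units:
            channel = "current"
            scale = {"pa": 1.0, "na": 1e3}.get(units)
            if scale is None:
                raise RecordingIOError(
                    f"{path}: ambiguous current units {abf.sweepUnitsY!r}"
                )
        else:
            raise RecordingIOError(
                f"{path}: ambiguous sweep units {abf.sweepUnitsY!r}"
            )
        sweeps.append(
            Sweep(abf.sweepY * scale, float(abf.dataRate), channel, index=i)
        )
    return EpisodicRecording(sweeps=sweeps, cell_id=path.stem)
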