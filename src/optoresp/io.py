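"""File formats and their in-memory containers.

Everything is plain text so that recordings stay human-auditable:

* spike trains — two-column delimited text ``unit_id  spike_time_s`` with an
  optional ``# duration <unit_id> <seconds>`` header per unit;
* stimulus protocols — JSON listing events once (a "train" event is stored as
  a single row and expanded to its five pulse onsets on demand);
* voltage-clamp sweeps — delimited text with a time column followed by one
  current column per sweep, plus a JSON sidecar carrying the sampling rate,
  pulse times and holding potential.

All time stamps are seconds.  Analysis windows throughout the package are
half-open ``[start, end)`` so a spike sitting exactly on a bin edge is counted
once.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "FormatError",
    "SpikeTrain",
    "StimulusEvent",
    "StimulusProtocol",
    "Sweep",
    "read_spike_trains",
    "write_spike_trains",
    "read_protocol",
    "write_protocol",
    "read_sweeps",
    "write_sweeps",
]

#: maximum light power (mW) probed in the stimulation protocols; events above
#: this are flagged as out of the calibrated range, not rejected.
MAX_TESTED_POWER_MW = 8.0

_TIME_DECIMALS = 9  # round-trip losslessness target, 1 ns


class FormatError(ValueError):
    """Raised when a file violates the format contract.

    Carries the offending line number when one is known.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


@dataclass(frozen=True)
class SpikeTrain:
    """Sorted spike times of one unit over one recording.

    Parameters
    ----------
    unit_id : str
        Identifier of the sorted unit.
    spike_times : ndarray
        Spike times in seconds, non-decreasing, all within ``[0, duration]``.
    duration : float
        Length of the recording in seconds.
    """

    unit_id: str
    spike_times: np.ndarray
    duration: float

    def __post_init__(self):
        times = np.asarray(self.spike_times, dtype=float)
        object.__setattr__(self, "spike_times", times)
        if times.ndim != 1:
            raise ValueError("spike_times must be one-dimensional")
        if times.size and np.any(np.diff(times) < 0):
            raise ValueError(f"unit {self.unit_id}: spike times not sorted")
        if times.size and (times[0] < 0 or times[-1] > self.duration):
            raise ValueError(
                f"unit {self.unit_id}: spike times outside [0, {self.duration}]"
            )

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times.size)

    def mean_rate(self) -> float:
        """Overall firing rate in Hz."""
        return self.n_spikes / self.duration if self.duration > 0 else 0.0


@dataclass(frozen=True)
class StimulusEvent:
    """One stimulation event: a single pulse or a pulse train."""

    onset: float  # s, onset of the (first) pulse
    kind: str = "single"  # "single" | "train"
    power_mW: float | None = None

    def __post_init__(self):
        if self.kind not in ("single", "train"):
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.power_mW is not None and self.power_mW < 0:
            raise ValueError("power_mW must be >= 0")


@dataclass(frozen=True)
class StimulusProtocol:
    """Light-stimulation protocol.

    Defaults encode the standard design: 1-ms pulses, single pulses every 5 s,
    five-pulse 20-Hz trains (50-ms spacing) every 10 s.
    """

    events: tuple[StimulusEvent, ...]
    pulse_width: float = 0.001
    train_pulse_count: int = 5
    train_interval: float = 0.05
    single_event_spacing: float = 5.0
    train_event_spacing: float = 10.0

    def __post_init__(self):
        events = tuple(self.events)
        object.__setattr__(self, "events", events)
        onsets = [e.onset for e in events]
        if any(b < a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("protocol events must be sorted by onset")

    @property
    def onsets(self) -> np.ndarray:
        """Event onsets (first pulse of a train), seconds."""
        return np.array([e.onset for e in self.events], dtype=float)

    def pulse_onsets(self, event: StimulusEvent) -> np.ndarray:
        """All pulse onsets of one event (a train expands to 5 pulses)."""
        if event.kind == "train":
            return event.onset + self.train_interval * np.arange(
                self.train_pulse_count, dtype=float
            )
        return np.array([event.onset])

    def all_pulse_onsets(self) -> np.ndarray:
        """Every individual pulse onset in the protocol, sorted."""
        if not self.events:
            return np.empty(0)
        return np.concatenate([self.pulse_onsets(e) for e in self.events])

    def over_power_limit(self) -> bool:
        """True if any event exceeds the maximum tested light power (8 mW)."""
        return any(
            e.power_mW is not None and e.power_mW > MAX_TESTED_POWER_MW
            for e in self.events
        )


@dataclass(frozen=True)
class Sweep:
    """One voltage-clamp current trace.

    ``samples`` are membrane currents in pA (inward currents are negative
    deflections); ``pulse_times`` are light-pulse onsets in seconds from the
    start of the sweep.
    """

    samples: np.ndarray
    sampling_rate: float = 10_000.0
    pulse_times: tuple[float, ...] = ()
    holding_potential: float = -60.0  # mV, metadata

    def __post_init__(self):
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        object.__setattr__(self, "pulse_times", tuple(self.pulse_times))
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")
        span = samples.size / self.sampling_rate
        for t in self.pulse_times:
            if not 0 <= t < span:
                raise ValueError(f"pulse time {t} s outside sweep span {span} s")

    @property
    def duration(self) -> float:
        return self.samples.size / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.sampling_rate


# ---------------------------------------------------------------------------
# spike trains


def write_spike_trains(trains: Iterable[SpikeTrain], path: str | Path) -> None:
    path = Path(path)
    trains = list(trains)
    with path.open("w") as fh:
        for tr in trains:
            fh.write(f"# duration {tr.unit_id} {tr.duration:.{_TIME_DECIMALS}f}\n")
        for tr in trains:
            for t in tr.spike_times:
                fh.write(f"{tr.unit_id}\t{t:.{_TIME_DECIMALS}f}\n")


def read_spike_trains(path: str | Path) -> list[SpikeTrain]:
    path = Path(path)
    durations: dict[str, float] = {}
    spikes: dict[str, list[float]] = {}
    order: list[str] = []

    def remember(unit: str):
        if unit not in spikes:
            spikes[unit] = []
            order.append(unit)

    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                parts = line[1:].split()
                if parts[:1] == ["duration"]:
                    if len(parts) != 3:
                        raise FormatError("malformed duration header", lineno)
                    durations[parts[1]] = float(parts[2])
                    remember(parts[1])
                continue
            parts = line.split()
            if len(parts) != 2:
                raise FormatError(f"expected 2 columns, got {len(parts)}", lineno)
            unit, t_str = parts
            try:
                t = float(t_str)
            except ValueError:
                raise FormatError(f"bad spike time {t_str!r}", lineno) from None
            if t < 0:
                raise FormatError(f"negative spike time {t}", lineno)
            remember(unit)
            if spikes[unit] and t < spikes[unit][-1]:
                raise FormatError(f"unsorted spike time for unit {unit!r}", lineno)
            spikes[unit].append(t)

    out = []
    for unit in order:
        times = np.array(spikes[unit], dtype=float)
        duration = durations.get(unit, float(times[-1]) if times.size else 0.0)
        if times.size and times[-1] > duration:
            raise FormatError(
                f"unit {unit!r}: spike at {times[-1]} s beyond duration {duration} s"
            )
        out.append(SpikeTrain(unit_id=unit, spike_times=times, duration=duration))
    return out


# ---------------------------------------------------------------------------
# protocols


def write_protocol(protocol: StimulusProtocol, path: str | Path) -> None:
    doc = {
        "pulse_width_s": protocol.pulse_width,
        "train_pulse_count": protocol.train_pulse_count,
        "train_interval_s": protocol.train_interval,
        "single_event_spacing_s": protocol.single_event_spacing,
        "train_event_spacing_s": protocol.train_event_spacing,
        "events": [
            {"onset_s": e.onset, "kind": e.kind, "power_mW": e.power_mW}
            for e in protocol.events
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1) + "\n")


def read_protocol(path: str | Path) -> StimulusProtocol:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"invalid JSON: {exc}") from None
    if "events" not in doc:
        raise FormatError("protocol JSON missing 'events'")
    events = []
    for i, ev in enumerate(doc["events"]):
        try:
            events.append(
                StimulusEvent(
                    onset=float(ev["onset_s"]),
                    kind=ev.get("kind", "single"),
                    power_mW=(
                        None if ev.get("power_mW") is None else float(ev["power_mW"])
                    ),
                )
            )
        except (KeyError, ValueError) as exc:
            raise FormatError(f"event {i}: {exc}") from None
    kwargs = {}
    for key, attr in [
        ("pulse_width_s", "pulse_width"),
        ("train_pulse_count", "train_pulse_count"),
        ("train_interval_s", "train_interval"),
        ("single_event_spacing_s", "single_event_spacing"),
        ("train_event_spacing_s", "train_event_spacing"),
    ]:
        if key in doc:
            kwargs[attr] = doc[key]
    return StimulusProtocol(events=tuple(events), **kwargs)


# ---------------------------------------------------------------------------
# sweeps


def write_sweeps(sweeps: Sequence[Sweep], path: str | Path) -> None:
    """Write sweeps of one cell: a data file plus a ``.json`` sidecar.

    All sweeps must share their sampling rate, length and pulse times.
    """
    path = Path(path)
    sweeps = list(sweeps)
    if not sweeps:
        raise ValueError("no sweeps to write")
    first = sweeps[0]
    for s in sweeps[1:]:
        if (
            s.sampling_rate != first.sampling_rate
            or s.samples.size != first.samples.size
            or s.pulse_times != first.pulse_times
        ):
            raise ValueError("sweeps in one file must share rate, length and pulses")
    times = first.times
    data = np.column_stack([times] + [s.samples for s in sweeps])
    header = "time_s\t" + "\t".join(f"sweep_{i}_pA" for i in range(len(sweeps)))
    np.savetxt(path, data, fmt="%.9f", delimiter="\t", header=header)
    sidecar = {
        "sampling_rate_hz": first.sampling_rate,
        "pulse_times_s": list(first.pulse_times),
        "holding_potential_mV": first.holding_potential,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1) + "\n")


def read_sweeps(path: str | Path) -> list[Sweep]:
    path = Path(path)
    sidecar_path = path.with_suffix(".json")
    sidecar = {}
    if sidecar_path.exists():
        try:
            sidecar = json.loads(sidecar_path.read_text())
        except json.JSONDecodeError as exc:
            raise FormatError(f"invalid sidecar JSON: {exc}") from None
    rate = float(sidecar.get("sampling_rate_hz", 10_000.0))
    pulses = tuple(float(t) for t in sidecar.get("pulse_times_s", ()))
    holding = float(sidecar.get("holding_potential_mV", -60.0))
    try:
        data = np.loadtxt(path, delimiter="\t")
    except ValueError as exc:
        raise FormatError(f"malformed sweep table: {exc}") from None
    if data.ndim == 1:
        data = data[:, None]
    if data.shape[1] < 2:
        raise FormatError("sweep file needs a time column and >=1 current column")
    return [
        Sweep(
            samples=data[:, k],
            sampling_rate=rate,
            pulse_times=pulses,
            holding_potential=holding,
        )
        for k in range(1, data.shape[1])
    ]
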