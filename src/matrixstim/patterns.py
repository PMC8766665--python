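"""Spatiotemporal stimulation patterns and protocol builders.

The central abstraction is the :class:`StimulationMatrix` — an ordered list
of (time, voltage, electrode) stimulation events played out across a planar
multi-electrode array.  Builders construct the standard protocols used for
slice electrophysiology: voltage-mapping scans, tetanic bursts, associative
(strong→weak) pairing, "moving bar" column sweeps, row-major sequence scans,
and channel-shuffled unpatterned controls.

Conventions
-----------
* Event onsets are stored as integer microseconds (no float drift in sorting
  or codec slotting); helper accessors report milliseconds.
* Stimuli are charge-balanced biphasic square pulses: a positive phase
  followed by a negative phase of equal width and magnitude.  Amplitudes are
  limited to the stimulator's 0–4.5 V range in each direction.
* Simultaneous events are allowed (simultaneity is a feature); ties are
  serialized by ascending channel index.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .arrays import ElectrodeArray, mea_8x8

__all__ = [
    "MAX_AMPLITUDE_V",
    "StimEvent",
    "StimulationMatrix",
    "make_biphasic_pulse",
    "build_mapping_scan",
    "build_tetanus",
    "build_pairing",
    "build_moving_bar",
    "build_sequence_scan",
    "build_unpatterned_control",
    "pattern_duration",
    "merge",
]

#: Stimulator output limit, volts in each direction of the biphasic pulse.
MAX_AMPLITUDE_V = 4.5

US_PER_S = 1_000_000
US_PER_MS = 1_000


class PatternValidationError(ValueError):
    """A stimulation pattern violates a stimulator constraint."""


@dataclass(frozen=True, order=True)
class StimEvent:
    """One stimulation pulse: a biphasic square pulse on one electrode.

    Sort order is (onset, channel) so that simultaneous events serialize by
    ascending channel index.
    """

    onset_us: int
    channel: int
    amplitude_v: float = field(compare=False, default=3.0)
    phase_width_us: int = field(compare=False, default=1000)
    shape: str = field(compare=False, default="biphasic_square")
    #: optional (dt_us, volts) table for shape == "arbitrary"
    waveform: tuple[tuple[int, float], ...] | None = field(compare=False, default=None)

    def __post_init__(self) -> None:
        object.__setattr__(self, "onset_us", int(self.onset_us))
        object.__setattr__(self, "channel", int(self.channel))
        object.__setattr__(self, "phase_width_us", int(self.phase_width_us))

    @property
    def onset_ms(self) -> float:
        return self.onset_us / US_PER_MS

    @property
    def duration_us(self) -> int:
        """Total pulse duration (both phases, or the waveform table span)."""
        if self.shape == "arbitrary" and self.waveform:
            return sum(dt for dt, _ in self.waveform)
        return 2 * self.phase_width_us

    @property
    def end_us(self) -> int:
        return self.onset_us + self.duration_us

    def violations(self) -> list[str]:
        out = []
        if self.onset_us < 0:
            out.append(f"event on channel {self.channel}: onset {self.onset_us} us < 0")
        if not 0.0 <= self.amplitude_v <= MAX_AMPLITUDE_V:
            out.append(
                f"event on channel {self.channel} at {self.onset_us} us: amplitude "
                f"{self.amplitude_v} V outside [0, {MAX_AMPLITUDE_V}] V limit"
            )
        if self.phase_width_us <= 0:
            out.append(f"event on channel {self.channel}: phase width must be > 0 us")
        return out

    def segments(self) -> list[tuple[int, int, float]]:
        """Piecewise-constant voltage segments as (t_start_us, t_end_us, volts)."""
        if self.shape == "arbitrary" and self.waveform:
            segs, t = [], self.onset_us
            for dt_us, v in self.waveform:
                segs.append((t, t + int(dt_us), float(v)))
                t += int(dt_us)
            return segs
        return make_biphasic_pulse(
            self.channel, self.onset_us, self.amplitude_v, self.phase_width_us
        )


def make_biphasic_pulse(
    channel: int, onset_us: int, amplitude_v: float, phase_width_us: int
) -> list[tuple[int, int, float]]:
    """Charge-balanced biphasic square pulse as voltage segments.

    Returns ``[(t0, t1, +A), (t1, t2, -A)]`` with equal phase widths, so the
    signed voltage-time integral over the pulse is zero.

    Raises
    ------
    PatternValidationError
        If the amplitude exceeds the stimulator's 4.5 V per-direction limit.
    """
    if not 0.0 <= amplitude_v <= MAX_AMPLITUDE_V:
        raise PatternValidationError(
            f"amplitude {amplitude_v} V outside the stimulator limit [0, {MAX_AMPLITUDE_V}] V"
        )
    if phase_width_us <= 0:
        raise PatternValidationError("phase width must be positive")
    onset_us = int(onset_us)
    phase_width_us = int(phase_width_us)
    t1 = onset_us + phase_width_us
    t2 = t1 + phase_width_us
    return [(onset_us, t1, +float(amplitude_v)), (t1, t2, -float(amplitude_v))]


@dataclass
class StimulationMatrix:
    """Ordered set of stimulation events on one electrode array."""

    events: list[StimEvent]
    array: ElectrodeArray
    label: str = ""

    def __post_init__(self) -> None:
        self.events = sorted(self.events)

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    @property
    def channels(self) -> set[int]:
        return {e.channel for e in self.events}

    def onsets_us(self) -> np.ndarray:
        return np.array([e.onset_us for e in self.events], dtype=np.int64)

    def onsets_ms(self) -> np.ndarray:
        return self.onsets_us() / US_PER_MS

    def validate(self) -> list[str]:
        """All constraint violations (empty list for a valid matrix)."""
        out: list[str] = []
        for e in self.events:
            out.extend(e.violations())
            if not 0 <= e.channel < self.array.n_channels:
                out.append(
                    f"event at {e.onset_us} us: channel {e.channel} not on the "
                    f"{self.array.n_rows}x{self.array.n_cols} array"
                )
        for a, b in zip(self.events, self.events[1:]):
            if b.onset_us < a.onset_us:
                out.append("events not sorted by onset")
                break
        return out

    def duration_us(self) -> int:
        """Last pulse end minus first onset; 0 for an empty matrix."""
        if not self.events:
            return 0
        return max(e.end_us for e in self.events) - self.events[0].onset_us

    def shifted(self, dt_us: int) -> "StimulationMatrix":
        return StimulationMatrix(
            [replace(e, onset_us=e.onset_us + int(dt_us)) for e in self.events],
            self.array,
            self.label,
        )

    # ---------------------------------------------------------------- io
    def to_dict(self) -> dict:
        return {
            "schema_version": 1,
            "kind": "stimulation_matrix",
            "label": self.label,
            "array": self.array.to_dict(),
            "events": [
                {
                    "onset_us": e.onset_us,
                    "channel": e.channel,
                    "amplitude_v": e.amplitude_v,
                    "phase_width_us": e.phase_width_us,
                    "shape": e.shape,
                    **({"waveform": [list(w) for w in e.waveform]} if e.waveform else {}),
                }
                for e in self.events
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StimulationMatrix":
        if d.get("schema_version") != 1:
            raise PatternValidationError(
                f"unsupported pattern schema version {d.get('schema_version')!r}"
            )
        events = [
            StimEvent(
                onset_us=ev["onset_us"],
                channel=ev["channel"],
                amplitude_v=float(ev["amplitude_v"]),
                phase_width_us=ev.get("phase_width_us", 1000),
                shape=ev.get("shape", "biphasic_square"),
                waveform=tuple(tuple(w) for w in ev["waveform"]) if ev.get("waveform") else None,
            )
            for ev in d["events"]
        ]
        return cls(events, ElectrodeArray.from_dict(d["array"]), d.get("label", ""))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "StimulationMatrix":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def to_csv(self, path: str | Path) -> None:
        """Interchange CSV: onset_us, channel, amplitude_v, phase_width_us."""
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["onset_us", "channel", "amplitude_v", "phase_width_us"])
            for e in self.events:
                w.writerow([e.onset_us, e.channel, e.amplitude_v, e.phase_width_us])

    @classmethod
    def from_csv(cls, path: str | Path, array: ElectrodeArray | None = None) -> "StimulationMatrix":
        array = array or mea_8x8()
        events = []
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                events.append(
                    StimEvent(
                        onset_us=int(row["onset_us"]),
                        channel=int(row["channel"]),
                        amplitude_v=float(row["amplitude_v"]),
                        phase_width_us=int(row.get("phase_width_us", 1000)),
                    )
                )
        return cls(events, array)


def pattern_duration(matrix: StimulationMatrix) -> int:
    """Pattern duration in us (last pulse end minus first onset)."""
    return matrix.duration_us()


def merge(*matrices: StimulationMatrix, label: str = "merged") -> StimulationMatrix:
    """Merge matrices on a shared array, preserving all events, re-sorted by onset."""
    if not matrices:
        raise PatternValidationError("merge requires at least one matrix")
    array = matrices[0].array
    events = [e for m in matrices for e in m.events]
    return StimulationMatrix(events, array, label)


# --------------------------------------------------------------- builders

def build_mapping_scan(
    array: ElectrodeArray,
    v_min: float = 2.0,
    v_max: float = 4.5,
    v_step: float = 0.5,
    rate_hz: float = 0.33,
    phase_width_us: int = 1000,
) -> StimulationMatrix:
    """Voltage-mapping scan: one pulse per (electrode, voltage) combination.

    Electrodes are visited in channel order; within an electrode voltages
    ascend from ``v_min`` to ``v_max``; consecutive pulses are spaced at
    ``1/rate_hz`` (default 0.33 Hz, ~3.03 s between pulses).
    """
    if array.n_channels < 1:
        raise PatternValidationError("mapping scan requires a non-empty array")
    if v_min > v_max:
        raise PatternValidationError("v_min must not exceed v_max")
    if rate_hz <= 0:
        raise PatternValidationError("stimulation rate must be positive")
    n_levels = int(math.floor((v_max - v_min) / v_step + 1e-9)) + 1 if v_step > 0 else 1
    voltages = [v_min + i * v_step for i in range(n_levels)]
    interval_us = round(US_PER_S / rate_hz)
    events, k = [], 0
    for ch in range(array.n_channels):
        for v in voltages:
            events.append(StimEvent(k * interval_us, ch, v, phase_width_us))
            k += 1
    return StimulationMatrix(events, array, label="mapping_scan")


def build_tetanus(
    channel: int,
    array: ElectrodeArray | None = None,
    n_bursts: int = 10,
    pulses_per_burst: int = 4,
    intra_burst_rate_hz: float = 100.0,
    inter_burst_gap_ms: float = 150.0,
    amplitude_v: float = 4.0,
    phase_width_us: int = 1000,
) -> StimulationMatrix:
    """Tetanic burst stimulation on a single site.

    Defaults: 10 bursts of 4 pulses at 100 Hz (10 ms onset-to-onset within a
    burst), with a 150 ms silent gap between the end of one burst and the
    onset of the next.
    """
    array = array or mea_8x8()
    if n_bursts < 1 or pulses_per_burst < 1:
        raise PatternValidationError("tetanus needs at least one burst of one pulse")
    if intra_burst_rate_hz <= 0:
        raise PatternValidationError("intra-burst rate must be positive")
    intra_us = round(US_PER_S / intra_burst_rate_hz)
    gap_us = round(inter_burst_gap_ms * US_PER_MS)
    events, t = [], 0
    for _ in range(n_bursts):
        for p in range(pulses_per_burst):
            events.append(StimEvent(t + p * intra_us, channel, amplitude_v, phase_width_us))
        burst_end = events[-1].end_us
        t = burst_end + gap_us
    return StimulationMatrix(events, array, label="tetanus")


def build_pairing(
    strong_channel: int,
    weak_channel: int,
    array: ElectrodeArray | None = None,
    interval_ms: float = 15.0,
    n_reps: int = 100,
    rep_rate_hz: float = 0.2,
    amplitude_v: float = 3.0,
    phase_width_us: int = 1000,
) -> StimulationMatrix:
    """Associative pairing: strong-site pulse then weak-site pulse.

    Each repetition stimulates the strong site, then the weak site
    ``interval_ms`` later (default 15 ms); repetitions are clocked
    onset-to-onset at ``rep_rate_hz`` (default 0.2 Hz, one pair every 5 s),
    repeated ``n_reps`` times (default 100).
    """
    array = array or mea_8x8()
    if strong_channel == weak_channel:
        raise PatternValidationError("strong and weak pairing sites must be distinct channels")
    rep_us = round(US_PER_S / rep_rate_hz)
    offset_us = round(interval_ms * US_PER_MS)
    events = []
    for k in range(n_reps):
        t = k * rep_us
        events.append(StimEvent(t, strong_channel, amplitude_v, phase_width_us))
        events.append(StimEvent(t + offset_us, weak_channel, amplitude_v, phase_width_us))
    return StimulationMatrix(events, array, label="associative_pairing")


def build_moving_bar(
    array: ElectrodeArray,
    inter_column_interval_ms: float = 80.0,
    pulse_amplitude_v: float = 3.5,
    n_reps: int = 100,
    rep_interval_s: float = 10.0,
    direction: str = "ltr",
    phase_width_us: int = 1000,
) -> StimulationMatrix:
    """Moving-bar sweep: whole columns fire in synchrony, stepping across.

    Column k fires at ``k * interval`` within a sweep; the sweep period is
    ``n_cols * interval`` (640 ms for 8 columns at 80 ms; 800 ms at 100 ms),
    repeated every ``rep_interval_s`` (default 10 s) for ``n_reps`` sweeps.
    ``direction`` is ``"ltr"`` (left-to-right) or ``"rtl"``.
    """
    if inter_column_interval_ms <= 0:
        raise PatternValidationError("inter-column interval must be positive")
    if direction not in ("ltr", "rtl"):
        raise PatternValidationError(f"unknown direction {direction!r}; use 'ltr' or 'rtl'")
    cols = list(range(array.n_cols))
    if direction == "rtl":
        cols = cols[::-1]
    step_us = round(inter_column_interval_ms * US_PER_MS)
    rep_us = round(rep_interval_s * US_PER_S)
    events = []
    for rep in range(n_reps):
        t0 = rep * rep_us
        for k, col in enumerate(cols):
            for ch in array.column_channels(col):
                events.append(StimEvent(t0 + k * step_us, ch, pulse_amplitude_v, phase_width_us))
    return StimulationMatrix(events, array, label="moving_bar")


def sweep_period_us(array: ElectrodeArray, inter_column_interval_ms: float) -> int:
    """Moving-bar sweep period: n_cols x inter-column interval (trailing interval included)."""
    return array.n_cols * round(inter_column_interval_ms * US_PER_MS)


def build_sequence_scan(
    array: ElectrodeArray,
    roi_channels: Sequence[int],
    per_pin_amplitude_v: float = 4.0,
    inter_stim_interval_s: float = 5.0,
    stim_per_pin: int = 1,
    n_sweeps: int = 1,
    phase_width_us: int = 1000,
) -> StimulationMatrix:
    """Row-major sequential scan over assayed sites.

    Sites are visited left-to-right across each row, then the next row down,
    one stimulus (or ``stim_per_pin`` consecutive stimuli) per site at the
    default 5 s inter-stimulus interval.  The training variant repeats the
    whole sweep ``n_sweeps`` times without pause (6 sweeps at default
    training settings).
    """
    if not roi_channels:
        raise PatternValidationError("sequence scan requires at least one ROI channel")
    ordered = sorted(roi_channels, key=lambda ch: array.rowcol_of(ch))
    step_us = round(inter_stim_interval_s * US_PER_S)
    events, k = [], 0
    for _ in range(n_sweeps):
        for ch in ordered:
            for _ in range(stim_per_pin):
                events.append(StimEvent(k * step_us, ch, per_pin_amplitude_v, phase_width_us))
                k += 1
    return StimulationMatrix(events, array, label="sequence_scan")


def build_unpatterned_control(
    reference: StimulationMatrix, seed: int, channels: Sequence[int] | None = None
) -> StimulationMatrix:
    """Unpatterned control: same onsets and amplitudes, channels randomized.

    Preserves the event count and the multiset of (onset, amplitude) pairs of
    the reference pattern; each event's channel is redrawn uniformly at
    random (seeded) from ``channels`` (default: all channels of the array).
    """
    if not reference.events:
        raise PatternValidationError("unpatterned control requires a nonempty reference pattern")
    rng = np.random.default_rng(seed)
    pool = list(channels) if channels is not None else list(range(reference.array.n_channels))
    new_channels = rng.choice(pool, size=len(reference.events), replace=True)
    events = [
        replace(e, channel=int(ch)) for e, ch in zip(reference.events, new_channels)
    ]
    return StimulationMatrix(events, reference.array, label="unpatterned_control")
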