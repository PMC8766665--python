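"""Time-division multiplexing codec for the digital→analog stimulation chain.

A stimulation pattern is compiled into a clocked stream of (address,
voltage-code) words: a single DAC produces one intermingled bipolar
waveform while an address bus routes each voltage to its electrode, whose
sample-and-hold keeps that voltage until the next update.  ``encode``
produces the word stream, ``reconstruct`` recovers the per-channel
zero-order-hold waveforms, and ``roundtrip_check`` bounds the timing and
quantization error of the whole chain.

With the default 6 address bits / 8 voltage bits, the codec drives
2**6 = 64 channels with 256 voltage levels over ±4.5 V; one additional
address bit doubles the channel capacity (7 bits → 128 channels).
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .patterns import StimulationMatrix

__all__ = [
    "CodecConfig",
    "MuxWord",
    "ChannelWaveform",
    "channel_capacity",
    "quantize_voltage",
    "dequantize",
    "encode",
    "reconstruct",
    "roundtrip_check",
]


class CodecError(ValueError):
    """A matrix cannot be represented under the given codec configuration."""


@dataclass(frozen=True)
class CodecConfig:
    """Digital word format and clocking of the multiplexed stimulator.

    ``slot_clock_hz`` is the rate at which (address, code) words are issued;
    at the default 1 MHz each word occupies a 1 us slot and a full 64-channel
    refresh cycle takes 64 us.
    """

    address_bits: int = 6
    voltage_bits: int = 8
    v_full_scale: float = 4.5
    slot_clock_hz: float = 1_000_000.0
    strict: bool = True  # error (vs saturate) on over-range voltages

    @property
    def capacity(self) -> int:
        return channel_capacity(self.address_bits)

    @property
    def code_max(self) -> int:
        return 2**self.voltage_bits - 1

    @property
    def slot_period_us(self) -> float:
        return 1e6 / self.slot_clock_hz

    @property
    def lsb_v(self) -> float:
        """Voltage step of one code: full bipolar span over the code range."""
        return 2 * self.v_full_scale / self.code_max

    def to_dict(self) -> dict:
        return {
            "address_bits": self.address_bits,
            "voltage_bits": self.voltage_bits,
            "v_full_scale": self.v_full_scale,
            "slot_clock_hz": self.slot_clock_hz,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CodecConfig":
        return cls(
            address_bits=int(d["address_bits"]),
            voltage_bits=int(d["voltage_bits"]),
            v_full_scale=float(d["v_full_scale"]),
            slot_clock_hz=float(d["slot_clock_hz"]),
        )


@dataclass(frozen=True)
class MuxWord:
    """One clocked word: deliver ``code`` to the channel at ``address``."""

    slot_index: int
    address: int
    code: int

    def time_us(self, config: CodecConfig) -> float:
        return self.slot_index * config.slot_period_us


@dataclass
class ChannelWaveform:
    """Zero-order-hold waveform of one channel: (time_us, held volts) steps."""

    channel: int
    steps: list[tuple[float, float]]  # sorted by time; value holds until next step

    def value_at(self, t_us: float) -> float:
        """Held voltage at time t (0 V before the first update)."""
        v = 0.0
        for st, sv in self.steps:
            if st <= t_us:
                v = sv
            else:
                break
        return v

    def sample(self, times_us: np.ndarray) -> np.ndarray:
        if not self.steps:
            return np.zeros_like(np.asarray(times_us, dtype=float))
        st = np.array([s[0] for s in self.steps])
        sv = np.array([s[1] for s in self.steps])
        idx = np.searchsorted(st, times_us, side="right") - 1
        out = np.where(idx >= 0, sv[np.clip(idx, 0, None)], 0.0)
        return out


def channel_capacity(address_bits: int) -> int:
    """Number of addressable channels: 2**address_bits (6 → 64, 7 → 128)."""
    if address_bits < 0:
        raise CodecError("address_bits must be non-negative")
    return 2**address_bits


def quantize_voltage(v: float, config: CodecConfig | None = None) -> int:
    """Bipolar mid-tread code: round-half-up of the scaled voltage.

    −v_fs maps to code 0, +v_fs to the top code, 0 V to the mid-code
    (128 at 8 bits).  Over-range voltages raise in strict mode and saturate
    otherwise.
    """
    config = config or CodecConfig()
    vfs = config.v_full_scale
    if abs(v) > vfs:
        if config.strict:
            raise CodecError(f"voltage {v} V outside full scale ±{vfs} V")
        v = max(-vfs, min(vfs, v))
    x = (v + vfs) / (2 * vfs) * config.code_max
    return int(math.floor(x + 0.5))


def dequantize(code: int, config: CodecConfig | None = None) -> float:
    """Voltage represented by a code (inverse of :func:`quantize_voltage`)."""
    config = config or CodecConfig()
    if not 0 <= code <= config.code_max:
        raise CodecError(f"code {code} outside [0, {config.code_max}]")
    return code / config.code_max * 2 * config.v_full_scale - config.v_full_scale


def _edges(matrix: StimulationMatrix) -> list[tuple[int, int, float]]:
    """All waveform edges as (time_us, channel, target volts), time-sorted.

    Each biphasic pulse contributes three edges: +A at onset, −A at the
    phase boundary, and a return to 0 V at pulse end.  Simultaneous edges
    order by ascending channel.
    """
    edges: dict[tuple[int, int], float] = {}
    for e in matrix.events:
        segs = e.segments()
        for t0, _t1, v in segs:
            edges[(t0, e.channel)] = v
        edges[(segs[-1][1], e.channel)] = 0.0
    return [(t, ch, v) for (t, ch), v in sorted(edges.items())]


def encode(matrix: StimulationMatrix, config: CodecConfig | None = None) -> list[MuxWord]:
    """Compile a stimulation matrix into a monotone stream of mux words.

    Every waveform edge becomes one word; the word's slot is the nearest
    slot at-or-after the previous word's slot (edges never reorder).
    Simultaneous edges on different channels serialize within one refresh
    cycle in ascending channel order.
    """
    config = config or CodecConfig()
    bad = [ch for ch in matrix.channels if ch >= config.capacity]
    if bad:
        need = max(bad).bit_length()
        raise CodecError(
            f"channels {sorted(bad)} exceed the {config.capacity}-channel capacity "
            f"of {config.address_bits} address bits; need at least {need} address bits"
        )
    words: list[MuxWord] = []
    next_free = 0
    for t_us, ch, v in _edges(matrix):
        nominal = round(t_us * config.slot_clock_hz / 1e6)
        slot = max(nominal, next_free)
        words.append(MuxWord(slot_index=slot, address=ch, code=quantize_voltage(v, config)))
        next_free = slot + 1
    return words


def reconstruct(
    words: list[MuxWord], config: CodecConfig | None = None, channels: list[int] | None = None
) -> dict[int, ChannelWaveform]:
    """Per-channel sample-and-hold waveforms from a word stream.

    Each channel's waveform is the zero-order hold of its own words;
    channels never addressed hold 0 V throughout.
    """
    config = config or CodecConfig()
    out: dict[int, ChannelWaveform] = {}
    for ch in channels or []:
        out[ch] = ChannelWaveform(ch, [])
    for w in sorted(words, key=lambda w: w.slot_index):
        wf = out.setdefault(w.address, ChannelWaveform(w.address, []))
        wf.steps.append((w.time_us(config), dequantize(w.code, config)))
    return out


@dataclass
class RoundTripReport:
    max_time_error_us: float
    max_voltage_error_v: float
    n_words: int
    n_events: int


def roundtrip_check(matrix: StimulationMatrix, config: CodecConfig | None = None) -> RoundTripReport:
    """Encode + reconstruct a matrix and bound the error against the ideal.

    Timing error is measured per waveform edge (slot time vs ideal edge
    time); voltage error is measured at the held level after each edge.
    At default clocking both are bounded by one slot period and half an LSB
    (plus one extra slot per simultaneous edge sharing the same instant).
    """
    config = config or CodecConfig()
    words = encode(matrix, config)
    recon = reconstruct(words, config)
    edges = _edges(matrix)
    max_dt = 0.0
    max_dv = 0.0
    # encode() emits words in _edges() order, so pair them positionally
    for (t_us, ch, v), w in zip(edges, words):
        assert w.address == ch
        max_dt = max(max_dt, abs(w.time_us(config) - t_us))
        max_dv = max(max_dv, abs(dequantize(w.code, config) - v))
    # sanity: reconstruction agrees with the words it came from
    for ch, wf in recon.items():
        for t, v in wf.steps:
            assert abs(wf.value_at(t) - v) < 1e-12
    return RoundTripReport(
        max_time_error_us=max_dt,
        max_voltage_error_v=max_dv,
        n_words=len(words),
        n_events=len(matrix),
    )


# -------------------------------------------------------------------- io

def stream_to_csv(words: list[MuxWord], path: str | Path, config: CodecConfig | None = None) -> None:
    """Serialize a word stream as CSV (slot, address, code) + JSON header."""
    config = config or CodecConfig()
    path = Path(path)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["slot_index", "address", "code"])
        for word in words:
            w.writerow([word.slot_index, word.address, word.code])
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(config.to_dict(), indent=1, sort_keys=True)
    )


def stream_from_csv(path: str | Path) -> tuple[list[MuxWord], CodecConfig]:
    path = Path(path)
    header = path.with_suffix(path.suffix + ".json")
    config = CodecConfig.from_dict(json.loads(header.read_text())) if header.exists() else CodecConfig()
    words = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            words.append(MuxWord(int(row["slot_index"]), int(row["address"]), int(row["code"])))
    return words, config
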