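"""Phenomenological virtual cortical slice on a planar electrode array.

This module simulates the input–output behavior a slice exhibits under
patterned extracellular stimulation, at the level of the measured
contracts rather than membrane biophysics:

* **Activation**: a neuron fires one spike per stimulus pulse iff the pulse
  amplitude reaches the neuron's voltage threshold *and* the neuron lies
  within the amplitude-dependent activation radius of the stimulated
  electrode — the "all or none" threshold behavior, with concentric
  activation maps that grow with stimulus intensity.
* **Transmission**: presynaptic spikes deposit delayed EPSCs into a patched
  cell; summed synchronous drive above a threshold fires the patched cell
  (superthreshold, "strong" input), below it produces a subthreshold EPSP
  ("weak" input).  Responses are heterogeneous across electrodes (weak,
  strong, direct activation, or none).
* **Plasticity**: three induction rules — homosynaptic tetanic
  potentiation, associative capture of a weak input paired shortly after a
  strong input's evoked spike, and network-level sequence potentiation of
  per-site response gains.  All are gated off by combined AMPA+NMDA
  blockade (NBQX + AP5).
* **Readout**: patched-cell traces (current or voltage clamp at 10 kHz),
  per-neuron spike times, and calcium-indicator movies with per-neuron
  Gaussian footprints, lamp flicker, and photobleaching.

Spike latencies carry truncated-Gaussian jitter (sigma 0.2 ms, clipped at
+/-0.45 ms) so that the across-trial latency spread of repeated identical
stimulation stays below 1 ms by construction.

Everything is deterministic under (seed, inputs).
"""

from __future__ import annotations

import copy
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .arrays import ElectrodeArray, mea_8x8
from .patterns import StimulationMatrix, US_PER_MS

__all__ = [
    "ActivationParams",
    "SliceParams",
    "Neuron",
    "Synapse",
    "Pharmacology",
    "PlasticityState",
    "VirtualSlice",
    "ReadoutConfig",
    "CalciumConfig",
    "Recording",
    "generate_slice",
    "activation_radius",
    "simulate",
    "apply_plasticity",
    "classify_inputs",
    "find_strong_weak",
]


# ------------------------------------------------------------ parameters

@dataclass(frozen=True)
class ActivationParams:
    """Saturating growth of the effective activation radius with voltage.

    r(V) = r_max * (V - v0)^alpha / ((V - v0)^alpha + k^alpha) for V > v0,
    else 0.  Defaults give r(3 V) = 200 um and r(4 V) = 320 um, i.e.
    concentric activation contours expanding with stimulus intensity over
    the 2–4.5 V mapping range.
    """

    v0: float = 2.0          # V, global minimum voltage for any activation
    r_max_um: float = 400.0  # um, asymptotic radius
    k: float = 1.0           # V, half-saturation scale above v0
    alpha: float = 2.0       # steepness


@dataclass(frozen=True)
class SliceParams:
    """Tunable phenomenology of the virtual slice."""

    # spiking
    base_latency_ms: float = 3.0
    jitter_sigma_ms: float = 0.2
    jitter_clip_ms: float = 0.45  # bounds across-trial latency range at 0.9 ms
    refractory_ms: float = 5.0
    # synaptic drive onto the patched cell
    drive_threshold_pa: float = 100.0  # summed EPSC needed to fire the patched cell
    spike_lag_ms: float = 1.5          # EPSP-to-spike delay once drive is superthreshold
    response_window_ms: float = 50.0   # integration window per stimulus
    epsc_rise_ms: float = 1.0
    epsc_decay_ms: float = 8.0
    mv_per_pa: float = 0.1             # EPSP size per pA of EPSC drive (current clamp)
    # noise (rendered traces)
    vc_noise_pa: float = 2.0
    cc_noise_mv: float = 0.3
    # plasticity
    pairing_window_ms: float = 15.0
    pairing_n_full: int = 100          # pairings for full associative credit
    consolidation_tau_min: float = 6.0  # efficacy saturates well within 30 min
    associative_mult_max: float = 4.0
    tetanus_gain: float = 1.5
    sequence_gain_per_credit: float = 0.08
    sequence_adjacency_pitch: float = 1.5   # x array pitch
    sequence_max_gap_s: float = 10.0
    gain_cap: float = 3.0
    inhibitory_damping: float = 0.8    # calcium response damping without bicuculline
    activation: ActivationParams = field(default_factory=ActivationParams)


def activation_radius(voltage_v: float, params: ActivationParams | None = None) -> float:
    """Effective activation radius (um), monotone non-decreasing in voltage."""
    p = params or ActivationParams()
    if voltage_v < 0:
        raise ValueError("stimulus voltage must be non-negative")
    dv = voltage_v - p.v0
    if dv <= 0:
        return 0.0
    num = dv**p.alpha
    return p.r_max_um * num / (num + p.k**p.alpha)


# ------------------------------------------------------------ slice data

@dataclass
class Neuron:
    id: int
    x_um: float
    y_um: float
    threshold_v: float        # electrode amplitude needed at zero distance
    refractory_ms: float = 5.0
    is_patched: bool = False


@dataclass
class Synapse:
    """Connection from a presynaptic neuron onto the patched cell."""

    pre_id: int
    weight_pa: float   # baseline EPSC amplitude
    delay_ms: float    # spike-to-EPSC-onset delay (non-immediate onset)


@dataclass(frozen=True)
class Pharmacology:
    """Bath drug condition flags.

    ttx blocks all spiking; nbqx blocks AMPA EPSCs; nbqx together with ap5
    blocks plasticity induction; bicuculline removes inhibitory damping of
    calcium responses.
    """

    ttx: bool = False
    nbqx: bool = False
    ap5: bool = False
    bicuculline: bool = False


@dataclass
class PlasticityState:
    """Per-synapse efficacy multipliers and per-site network response gains."""

    syn_multiplier: np.ndarray      # one per synapse onto the patched cell
    roi_gain: np.ndarray            # one per electrode channel
    pairing_credit: dict[int, int] = field(default_factory=dict)  # channel -> pairings

    def to_dict(self) -> dict:
        return {
            "syn_multiplier": self.syn_multiplier.tolist(),
            "roi_gain": self.roi_gain.tolist(),
            "pairing_credit": {str(k): v for k, v in self.pairing_credit.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PlasticityState":
        return cls(
            syn_multiplier=np.asarray(d["syn_multiplier"], dtype=float),
            roi_gain=np.asarray(d["roi_gain"], dtype=float),
            pairing_credit={int(k): int(v) for k, v in d.get("pairing_credit", {}).items()},
        )


@dataclass
class VirtualSlice:
    array: ElectrodeArray
    neurons: list[Neuron]
    synapses: list[Synapse]           # all onto the patched cell
    patched_id: int | None
    params: SliceParams = field(default_factory=SliceParams)
    state: PlasticityState | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.state is None:
            self.state = PlasticityState(
                syn_multiplier=np.ones(len(self.synapses)),
                roi_gain=np.ones(self.array.n_channels),
            )

    @property
    def patched(self) -> Neuron | None:
        if self.patched_id is None:
            return None
        return self.neurons[self.patched_id]

    def neuron_positions(self) -> np.ndarray:
        return np.array([[n.x_um, n.y_um] for n in self.neurons]).reshape(-1, 2)

    def nearest_channel(self, x_um: float, y_um: float) -> int:
        pos = self.array.positions()
        d = np.hypot(pos[:, 0] - x_um, pos[:, 1] - y_um)
        return int(np.argmin(d))

    # ------------------------------------------------------------- io
    def to_dict(self) -> dict:
        return {
            "schema_version": 1,
            "kind": "virtual_slice",
            "seed": self.seed,
            "array": self.array.to_dict(),
            "patched_id": self.patched_id,
            "neurons": [asdict(n) for n in self.neurons],
            "synapses": [asdict(s) for s in self.synapses],
            "state": self.state.to_dict(),
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True))

    @classmethod
    def from_dict(cls, d: dict) -> "VirtualSlice":
        return cls(
            array=ElectrodeArray.from_dict(d["array"]),
            neurons=[Neuron(**n) for n in d["neurons"]],
            synapses=[Synapse(**s) for s in d["synapses"]],
            patched_id=d["patched_id"],
            state=PlasticityState.from_dict(d["state"]),
            seed=d.get("seed", 0),
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "VirtualSlice":
        return cls.from_dict(json.loads(Path(path).read_text()))


def generate_slice(
    seed: int,
    array: ElectrodeArray | None = None,
    n_neurons: int = 150,
    connection_lambda_um: float = 500.0,
    weight_scale_pa: float = 60.0,
    weight_min_pa: float = 10.0,
    params: SliceParams | None = None,
) -> VirtualSlice:
    """Seeded random slice with a patched cell near the array center.

    Neuron positions are uniform over the array footprint (plus half a pitch
    of margin); spike thresholds are uniform on [2, 4.5] V; the patched cell
    sits just off the central electrode with a threshold in [2, 2.8] V so a
    3 V test pulse on the adjacent pin reliably fires it.  Every other
    neuron connects onto the patched cell with probability
    exp(-distance / connection_lambda_um) and an exponential weight
    distribution, producing the mix of weak, strong, direct, and absent
    inputs seen when mapping electrodes at a fixed test voltage.
    """
    array = array or mea_8x8()
    params = params or SliceParams()
    rng = np.random.default_rng(seed)
    lo = -array.pitch_um / 2
    hi_x = (array.n_cols - 0.5) * array.pitch_um
    hi_y = (array.n_rows - 0.5) * array.pitch_um
    neurons: list[Neuron] = []
    patched_id: int | None = None
    if n_neurons >= 1:
        center_ch = array.channel_of(array.n_rows // 2, array.n_cols // 2)
        cx, cy = array.position_um(center_ch)
        neurons.append(
            Neuron(
                id=0,
                x_um=cx + 30.0,
                y_um=cy + 20.0,
                threshold_v=float(rng.uniform(2.0, 2.8)),
                refractory_ms=params.refractory_ms,
                is_patched=True,
            )
        )
        patched_id = 0
    for i in range(1, n_neurons):
        neurons.append(
            Neuron(
                id=i,
                x_um=float(rng.uniform(lo, hi_x)),
                y_um=float(rng.uniform(lo, hi_y)),
                threshold_v=float(rng.uniform(2.0, 4.5)),
                refractory_ms=params.refractory_ms,
            )
        )
    synapses: list[Synapse] = []
    if patched_id is not None:
        px, py = neurons[patched_id].x_um, neurons[patched_id].y_um
        for n in neurons:
            if n.is_patched:
                continue
            d = math.hypot(n.x_um - px, n.y_um - py)
            if rng.uniform() < math.exp(-d / connection_lambda_um):
                synapses.append(
                    Synapse(
                        pre_id=n.id,
                        weight_pa=float(weight_min_pa + rng.exponential(weight_scale_pa)),
                        delay_ms=float(rng.uniform(2.0, 6.0)),
                    )
                )
    return VirtualSlice(
        array=array, neurons=neurons, synapses=synapses, patched_id=patched_id,
        params=params, seed=seed,
    )


# ------------------------------------------------------------ simulation

@dataclass(frozen=True)
class CalciumConfig:
    """Calcium-movie rendering: indicator dynamics, optics, and artifacts."""

    frame_rate_hz: float = 10.0
    shape: tuple[int, int] = (256, 256)
    margin_um: float = 200.0
    footprint_sigma_um: float = 40.0
    transient_peak_dff: float = 0.5    # per spike, at the neuron's own pixels
    amplitude_cv: float = 0.15         # trial-to-trial transient amplitude variability
    rise_tau_s: float = 0.1
    decay_tau_s: float = 1.5
    baseline: float = 100.0            # background fluorescence counts
    neuron_brightness: float = 60.0    # resting indicator load per neuron
    flicker_sigma: float = 0.02        # multiplicative per-frame lamp flicker
    bleach_tau_s: float = 600.0        # monotone photobleaching time constant
    pixel_noise: float = 0.5


@dataclass(frozen=True)
class ReadoutConfig:
    """What to record during a simulation."""

    mode: str = "current_clamp"   # "current_clamp" | "voltage_clamp" | "none"
    fs_hz: float = 10_000.0
    post_ms: float = 200.0        # recording tail after the last pulse
    calcium: CalciumConfig | None = None
    render_noise: bool = True


@dataclass
class Recording:
    """Output of one simulation run.

    ``trace`` is the patched-cell recording (mV in current clamp, pA in
    voltage clamp) sampled at ``fs_hz``; spike/EPSC ground truth from the
    generator is carried alongside for analysis validation.
    """

    mode: str
    fs_hz: float
    duration_ms: float
    trace: np.ndarray | None
    stim_onsets_ms: np.ndarray
    stim_channels: np.ndarray
    stim_amplitudes: np.ndarray
    spike_times_ms: dict[int, np.ndarray]        # per neuron id
    patched_spikes_ms: np.ndarray
    patched_direct_ms: np.ndarray                # direct-activation subset
    epsc_truth: list[tuple[float, float]]        # (arrival ms, amplitude pA)
    evoked_drive_pa: np.ndarray | None = None    # per-stimulus summed EPSC drive
    movie: np.ndarray | None = None              # (frames, H, W)
    frame_times_s: np.ndarray | None = None

    def times_ms(self) -> np.ndarray:
        n = len(self.trace) if self.trace is not None else 0
        return np.arange(n) / self.fs_hz * 1e3


def _truncated_jitter(rng: np.random.Generator, p: SliceParams) -> float:
    j = rng.normal(0.0, p.jitter_sigma_ms)
    return float(np.clip(j, -p.jitter_clip_ms, p.jitter_clip_ms))


def _simulate_events(
    slc: VirtualSlice,
    matrix: StimulationMatrix,
    pharm: Pharmacology,
    rng: np.random.Generator,
):
    """Event-level simulation: who spikes when, and what arrives at the patched cell.

    Returns (spikes, patched_spikes, patched_direct, epscs) where spikes is a
    dict neuron id -> list of ms times, and epscs is a list of
    (arrival_ms, amplitude_pA, synapse_index, stim_index).
    """
    p = slc.params
    positions = slc.neuron_positions()
    thresholds = np.array([n.threshold_v for n in slc.neurons])
    n_neurons = len(slc.neurons)
    last_spike = np.full(n_neurons, -np.inf)
    spikes: dict[int, list[float]] = {n.id: [] for n in slc.neurons}
    patched_spikes: list[float] = []
    patched_direct: list[float] = []
    epscs: list[tuple[float, float, int, int]] = []
    syn_by_pre: dict[int, list[int]] = {}
    for i, s in enumerate(slc.synapses):
        syn_by_pre.setdefault(s.pre_id, []).append(i)
    roi_gain = slc.state.roi_gain
    mult = slc.state.syn_multiplier
    pre_channel = {
        s.pre_id: slc.nearest_channel(
            slc.neurons[s.pre_id].x_um, slc.neurons[s.pre_id].y_um
        )
        for s in slc.synapses
    }

    pend_drive: list[tuple[float, float]] = []  # patched EPSP arrivals awaiting threshold

    for stim_idx, ev in enumerate(matrix.events):
        if pharm.ttx or n_neurons == 0:
            continue
        t_ms = ev.onset_ms
        ex, ey = slc.array.position_um(ev.channel)
        r = activation_radius(ev.amplitude_v, p.activation)
        d = np.hypot(positions[:, 0] - ex, positions[:, 1] - ey)
        hit = (ev.amplitude_v >= thresholds) & (d <= r)
        event_drive: list[tuple[float, float]] = []
        for nid in np.flatnonzero(hit):
            nid = int(nid)
            if t_ms - last_spike[nid] < slc.neurons[nid].refractory_ms:
                continue
            st = t_ms + p.base_latency_ms + _truncated_jitter(rng, p)
            last_spike[nid] = st
            spikes[nid].append(st)
            if nid == slc.patched_id:
                patched_spikes.append(st)
                patched_direct.append(st)
                continue
            if pharm.nbqx:
                continue
            for si in syn_by_pre.get(nid, ()):
                syn = slc.synapses[si]
                amp = syn.weight_pa * mult[si] * roi_gain[pre_channel[syn.pre_id]]
                arrival = st + syn.delay_ms
                epscs.append((arrival, amp, si, stim_idx))
                event_drive.append((arrival, amp))
        # synaptic recruitment of the patched cell: synchronous drive from this
        # stimulus crossing threshold fires it (unless refractory)
        if event_drive and slc.patched_id is not None:
            total = sum(a for _, a in event_drive)
            if total >= p.drive_threshold_pa:
                first = min(t for t, _ in event_drive)
                st = first + p.spike_lag_ms + _truncated_jitter(rng, p)
                pid = slc.patched_id
                if st - last_spike[pid] >= slc.neurons[pid].refractory_ms:
                    last_spike[pid] = st
                    spikes[pid].append(st)
                    patched_spikes.append(st)

    return spikes, sorted(patched_spikes), sorted(patched_direct), epscs


def _epsc_kernel(fs_hz: float, p: SliceParams) -> np.ndarray:
    """Difference-of-exponentials EPSC waveform, normalized to unit peak."""
    t = np.arange(0, 8 * p.epsc_decay_ms, 1e3 / fs_hz) / 1e3  # s
    tr, td = p.epsc_rise_ms / 1e3, p.epsc_decay_ms / 1e3
    k = np.exp(-t / td) - np.exp(-t / tr)
    return k / k.max()


def _add_at(trace: np.ndarray, start_idx: int, kernel: np.ndarray, scale: float) -> None:
    if start_idx >= len(trace):
        return
    end = min(len(trace), start_idx + len(kernel))
    if start_idx < 0:
        kernel = kernel[-start_idx:]
        start_idx = 0
        end = min(len(trace), start_idx + len(kernel))
    trace[start_idx:end] += scale * kernel[: end - start_idx]


def _spike_waveform(fs_hz: float) -> np.ndarray:
    """Stereotyped action-potential deflection above rest (mV), ~1.5 ms."""
    n_rise = max(1, int(0.3e-3 * fs_hz))
    n_fall = max(1, int(0.7e-3 * fs_hz))
    n_ahp = max(1, int(0.5e-3 * fs_hz))
    up = np.linspace(0, 95.0, n_rise)
    down = np.linspace(95.0, -5.0, n_fall)
    ahp = np.linspace(-5.0, 0.0, n_ahp)
    return np.concatenate([up, down, ahp])


def _artifact_waveform(fs_hz: float, scale: float) -> np.ndarray:
    """Sharp biphasic stimulus artifact, ~0.6 ms total."""
    n = max(1, int(0.3e-3 * fs_hz))
    return np.concatenate([np.full(n, scale), np.full(n, -scale)])


def simulate(
    slc: VirtualSlice,
    matrix: StimulationMatrix,
    pharm: Pharmacology | None = None,
    readout: ReadoutConfig | None = None,
    seed: int = 0,
) -> Recording:
    """Run a stimulation pattern through the virtual slice.

    Deterministic under (slice, matrix, pharm, readout, seed).  Raises if a
    patched-cell readout is requested but the slice has no patched cell.
    """
    pharm = pharm or Pharmacology()
    readout = readout or ReadoutConfig()
    p = slc.params
    if readout.mode in ("current_clamp", "voltage_clamp") and slc.patched_id is None:
        raise ValueError("patched-cell readout requested but the slice has no patched cell")
    rng = np.random.default_rng(seed)
    spikes, patched_spikes, patched_direct, epscs = _simulate_events(slc, matrix, pharm, rng)
    # record from t=0 through the last pulse end plus the tail
    end_ms = max((e.end_us for e in matrix.events), default=0) / US_PER_MS
    dur_ms = end_ms + readout.post_ms

    trace = None
    if readout.mode in ("current_clamp", "voltage_clamp"):
        n = int(dur_ms * readout.fs_hz / 1e3) + 1
        trace = np.zeros(n)
        fs = readout.fs_hz
        ker = _epsc_kernel(fs, p)
        art = _artifact_waveform(fs, 1.0)
        if readout.mode == "voltage_clamp":
            for arrival, amp, _si, _ev in epscs:
                _add_at(trace, int(arrival * fs / 1e3), ker, -amp)  # inward current
            for ev in matrix.events:
                _add_at(trace, int(ev.onset_ms * fs / 1e3), art, 500.0 * ev.amplitude_v / 3.0)
            # direct activation escapes the clamp as a clipped fast transient
            for t in patched_direct:
                esc = -800.0 * np.exp(-np.arange(int(3e-3 * fs)) / (1e-3 * fs))
                _add_at(trace, int(t * fs / 1e3), esc, 1.0)
            if readout.render_noise:
                trace += rng.normal(0, p.vc_noise_pa, n)
        else:
            trace += -65.0
            for arrival, amp, _si, _ev in epscs:
                _add_at(trace, int(arrival * fs / 1e3), ker, amp * p.mv_per_pa)
            spk = _spike_waveform(fs)
            for t in patched_spikes:
                _add_at(trace, int(t * fs / 1e3), spk, 1.0)
            for ev in matrix.events:
                _add_at(trace, int(ev.onset_ms * fs / 1e3), art, 10.0 * ev.amplitude_v / 3.0)
            if readout.render_noise:
                trace += rng.normal(0, p.cc_noise_mv, n)

    movie = None
    frame_times = None
    if readout.calcium is not None:
        movie, frame_times = _render_calcium(slc, spikes, dur_ms, pharm, readout.calcium, rng)

    drive = np.zeros(len(matrix.events))
    for _t, amp, _si, ev_idx in epscs:
        drive[ev_idx] += amp

    return Recording(
        mode=readout.mode,
        fs_hz=readout.fs_hz,
        duration_ms=dur_ms,
        trace=trace,
        stim_onsets_ms=matrix.onsets_ms(),
        stim_channels=np.array([e.channel for e in matrix.events], dtype=int),
        stim_amplitudes=np.array([e.amplitude_v for e in matrix.events]),
        spike_times_ms={k: np.array(v) for k, v in spikes.items()},
        patched_spikes_ms=np.array(patched_spikes),
        patched_direct_ms=np.array(patched_direct),
        epsc_truth=[(t, a) for t, a, _, _ in sorted(epscs)],
        evoked_drive_pa=drive,
        movie=movie,
        frame_times_s=frame_times,
    )


def movie_geometry(
    array: ElectrodeArray, cfg: CalciumConfig
) -> tuple[float, float, float]:
    """(x0_um, y0_um, um_per_px) of the field of view covering the array."""
    w_um = (array.n_cols - 1) * array.pitch_um + 2 * cfg.margin_um
    h_um = (array.n_rows - 1) * array.pitch_um + 2 * cfg.margin_um
    um_per_px = max(w_um / cfg.shape[1], h_um / cfg.shape[0])
    return -cfg.margin_um, -cfg.margin_um, um_per_px


def _render_calcium(
    slc: VirtualSlice,
    spikes: dict[int, list[float]],
    dur_ms: float,
    pharm: Pharmacology,
    cfg: CalciumConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    h, w = cfg.shape
    x0, y0, um_per_px = movie_geometry(slc.array, cfg)
    n_frames = max(2, int(dur_ms / 1e3 * cfg.frame_rate_hz) + 1)
    ft = np.arange(n_frames) / cfg.frame_rate_hz
    yy, xx = np.mgrid[0:h, 0:w]
    px_x = x0 + xx * um_per_px
    px_y = y0 + yy * um_per_px
    damp = 1.0 if pharm.bicuculline else slc.params.inhibitory_damping

    n_neurons = len(slc.neurons)
    footprints = np.zeros((n_neurons, h * w))
    traces = np.zeros((n_neurons, n_frames))
    for i, n in enumerate(slc.neurons):
        fp = np.exp(
            -((px_x - n.x_um) ** 2 + (px_y - n.y_um) ** 2)
            / (2 * cfg.footprint_sigma_um**2)
        )
        footprints[i] = fp.ravel()
        gain = slc.state.roi_gain[slc.nearest_channel(n.x_um, n.y_um)]
        c = np.zeros(n_frames)
        for st_ms in spikes.get(n.id, ()):  # fast rise, exponential decay
            dt = ft - st_ms / 1e3
            m = dt > 0
            # calcium transients vary trial to trial
            a = max(0.0, 1.0 + rng.normal(0.0, cfg.amplitude_cv))
            c[m] += a * (1 - np.exp(-dt[m] / cfg.rise_tau_s)) * np.exp(-dt[m] / cfg.decay_tau_s)
        traces[i] = 1.0 + cfg.transient_peak_dff * damp * gain * c

    static = cfg.baseline + cfg.neuron_brightness * footprints.sum(axis=0)
    dyn = (traces.T - 1.0) @ (cfg.neuron_brightness * footprints)
    frames = static[None, :] + dyn
    flicker = 1.0 + rng.normal(0, cfg.flicker_sigma, n_frames)
    bleach = np.exp(-ft / cfg.bleach_tau_s)
    frames *= (flicker * bleach)[:, None]
    if cfg.pixel_noise > 0:
        frames += rng.normal(0, cfg.pixel_noise, frames.shape)
    return frames.reshape(n_frames, h, w), ft


def synthesize_epsc_trace(
    event_times_ms: np.ndarray,
    amplitudes_pa: np.ndarray,
    duration_ms: float,
    fs_hz: float = 10_000.0,
    noise_pa: float = 2.0,
    stim_onsets_ms: np.ndarray | None = None,
    stim_amplitude_v: float = 3.0,
    seed: int = 0,
    params: SliceParams | None = None,
) -> np.ndarray:
    """Voltage-clamp trace with EPSCs at known times and amplitudes.

    Ground-truth generator for validating event detection: inward EPSCs with
    the slice's kernel shape, optional biphasic stimulus artifacts, and
    Gaussian recording noise.
    """
    p = params or SliceParams()
    rng = np.random.default_rng(seed)
    n = int(duration_ms * fs_hz / 1e3) + 1
    trace = np.zeros(n)
    ker = _epsc_kernel(fs_hz, p)
    for t, a in zip(np.asarray(event_times_ms, float), np.asarray(amplitudes_pa, float)):
        _add_at(trace, int(t * fs_hz / 1e3), ker, -a)
    if stim_onsets_ms is not None:
        art = _artifact_waveform(fs_hz, 1.0)
        for t in np.asarray(stim_onsets_ms, float):
            _add_at(trace, int(t * fs_hz / 1e3), art, 500.0 * stim_amplitude_v / 3.0)
    if noise_pa > 0:
        trace += rng.normal(0, noise_pa, n)
    return trace


# ------------------------------------------------------- input classification

@dataclass(frozen=True)
class InputClass:
    channel: int
    category: str      # "direct" | "strong" | "weak" | "none"
    drive_pa: float    # summed effective EPSC drive at the test voltage


def _recruited_synapses(slc: VirtualSlice, channel: int, amplitude_v: float) -> list[int]:
    """Indices of synapses whose presynaptic neuron fires for this stimulus."""
    p = slc.params
    ex, ey = slc.array.position_um(channel)
    r = activation_radius(amplitude_v, p.activation)
    out = []
    for i, s in enumerate(slc.synapses):
        n = slc.neurons[s.pre_id]
        if n.threshold_v <= amplitude_v and math.hypot(n.x_um - ex, n.y_um - ey) <= r:
            out.append(i)
    return out


def classify_inputs(
    slc: VirtualSlice,
    test_voltage: float = 3.0,
    min_weak_pa: float = 30.0,
) -> dict[int, InputClass]:
    """Classify every electrode as a direct / strong / weak / silent input.

    Direct: the stimulus activates the patched cell itself (immediate-onset
    response).  Strong: summed synaptic drive reaches the patched cell's
    firing threshold.  Weak: detectable subthreshold synaptic drive
    (>= min_weak_pa).  Mirrors the experimental search for input sites at a
    fixed test voltage.
    """
    p = slc.params
    out = {}
    patched = slc.patched
    r = activation_radius(test_voltage, p.activation)
    mult = slc.state.syn_multiplier
    gains = slc.state.roi_gain
    for ch in range(slc.array.n_channels):
        ex, ey = slc.array.position_um(ch)
        direct = False
        if patched is not None:
            d = math.hypot(patched.x_um - ex, patched.y_um - ey)
            direct = patched.threshold_v <= test_voltage and d <= r
        drive = 0.0
        for si in _recruited_synapses(slc, ch, test_voltage):
            s = slc.synapses[si]
            pre = slc.neurons[s.pre_id]
            drive += s.weight_pa * mult[si] * gains[slc.nearest_channel(pre.x_um, pre.y_um)]
        if direct:
            cat = "direct"
        elif drive >= p.drive_threshold_pa:
            cat = "strong"
        elif drive >= min_weak_pa:
            cat = "weak"
        else:
            cat = "none"
        out[ch] = InputClass(channel=ch, category=cat, drive_pa=drive)
    return out


def find_strong_weak(
    slc: VirtualSlice, test_voltage: float = 3.0, min_weak_pa: float = 30.0
) -> tuple[int, int]:
    """Pick the strongest superthreshold input and the best subthreshold one.

    Raises ``LookupError`` if the slice offers no such pair at this voltage.
    """
    classes = classify_inputs(slc, test_voltage, min_weak_pa)
    strong = [c for c in classes.values() if c.category == "strong"]
    weak = [c for c in classes.values() if c.category == "weak"]
    if not strong or not weak:
        raise LookupError(
            f"no strong/weak input pair discoverable at {test_voltage} V "
            f"({len(strong)} strong, {len(weak)} weak sites)"
        )
    strong_ch = max(strong, key=lambda c: c.drive_pa).channel
    weak_ch = max(weak, key=lambda c: c.drive_pa).channel
    return strong_ch, weak_ch


# ------------------------------------------------------------- plasticity

def apply_plasticity(
    slc: VirtualSlice,
    matrix: StimulationMatrix,
    rule: str,
    pharm: Pharmacology | None = None,
    seed: int = 0,
    consolidate_min: float = 30.0,
) -> PlasticityState:
    """Run an induction protocol and update the slice's plasticity state.

    Rules
    -----
    ``"tetanus"``
        Homosynaptic potentiation: synapses recruited by the tetanized
        channel(s) gain a fixed multiplier.
    ``"associative"``
        Associative capture: each stimulus falling within the pairing
        window (default 15 ms) after a patched-cell spike evoked by a
        *different* input earns pairing credit for its channel; credited
        channels' recruited synapses then potentiate along a saturating
        exponential of the consolidation time, reaching the full multiplier
        within ~30 min at full credit (100 pairings).
    ``"sequence"``
        Network sequence potentiation: a site earns credit whenever it is
        stimulated at the end of a spatially contiguous chain of three
        events (consecutive inter-event steps within 1.5 electrode pitches
        and 10 s); per-site response gains grow with credit.  The moving-bar
        sweep potentiates under the same rule.

    All rules are no-ops under combined NBQX + AP5 (or NBQX alone for the
    synaptic rules, since induction requires transmission) and under TTX.
    The state is updated in place on the slice and returned.
    """
    pharm = pharm or Pharmacology()
    p = slc.params
    state = slc.state
    blocked = pharm.ttx or (pharm.nbqx and pharm.ap5)
    if rule not in ("tetanus", "associative", "sequence"):
        raise ValueError(f"unknown plasticity rule {rule!r}")
    if blocked or not matrix.events:
        return state

    if rule == "tetanus":
        if pharm.nbqx:
            return state
        for ch in sorted(matrix.channels):
            amp = max(e.amplitude_v for e in matrix.events if e.channel == ch)
            for si in _recruited_synapses(slc, ch, amp):
                state.syn_multiplier[si] = min(
                    p.associative_mult_max, state.syn_multiplier[si] * p.tetanus_gain
                )
        return state

    if rule == "associative":
        if pharm.nbqx:
            return state
        rng = np.random.default_rng(seed)
        _spk, patched_spikes, patched_direct, _epscs = _simulate_events(
            slc, matrix, pharm, rng
        )
        evoked = np.array(sorted(set(patched_spikes) - set(patched_direct)))
        credits: dict[int, int] = {}
        for ev in matrix.events:
            if evoked.size == 0:
                break
            dt = ev.onset_ms - evoked
            if np.any((dt >= 0) & (dt <= p.pairing_window_ms)):
                credits[ev.channel] = credits.get(ev.channel, 0) + 1
        for ch, n_cred in credits.items():
            state.pairing_credit[ch] = state.pairing_credit.get(ch, 0) + n_cred
            f = min(1.0, state.pairing_credit[ch] / p.pairing_n_full)
            growth = 1.0 - math.exp(-consolidate_min / p.consolidation_tau_min)
            target = 1.0 + (p.associative_mult_max - 1.0) * f * growth
            amp = max(e.amplitude_v for e in matrix.events if e.channel == ch)
            for si in _recruited_synapses(slc, ch, amp):
                state.syn_multiplier[si] = max(state.syn_multiplier[si], target)
        return state

    # sequence rule
    events = matrix.events
    pos = {ch: slc.array.position_um(ch) for ch in matrix.channels}
    max_d = p.sequence_adjacency_pitch * slc.array.pitch_um
    max_gap_ms = p.sequence_max_gap_s * 1e3

    def _adjacent(a, b) -> bool:
        (ax, ay), (bx, by) = pos[a.channel], pos[b.channel]
        return (
            math.hypot(ax - bx, ay - by) <= max_d
            and 0 <= (b.onset_ms - a.onset_ms) <= max_gap_ms
            and a.channel != b.channel
        )

    credits = np.zeros(slc.array.n_channels)
    for i in range(2, len(events)):
        if _adjacent(events[i - 2], events[i - 1]) and _adjacent(events[i - 1], events[i]):
            credits[events[i].channel] += 1
    state.roi_gain = np.minimum(
        p.gain_cap, state.roi_gain + p.sequence_gain_per_credit * credits
    )
    return state


def copy_slice(slc: VirtualSlice) -> VirtualSlice:
    """Deep copy (fresh plasticity state) for before/after comparisons."""
    return copy.deepcopy(slc)
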