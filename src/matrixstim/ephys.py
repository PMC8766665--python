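"""Automated detection and mapping of spikes and EPSCs from patched-cell traces.

Detection uses automated thresholds (median + k*MAD of the filtered
derivative for EPSCs, fixed voltage crossing with refractory lockout for
spikes) with a per-event accept flag standing in for post-hoc manual
verification.  Mapping operations assemble per-electrode activation maps
from voltage-mapping scans: boolean evoked-spike maps by stimulus voltage,
mean EPSC amplitude maps with direct-activation sites flagged, and the
mean spike-evoking distance as a function of stimulus intensity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .arrays import ElectrodeArray
from .patterns import StimulationMatrix
from .slice_sim import Recording

__all__ = [
    "EventDetection",
    "ActivationMap",
    "detect_spikes",
    "detect_epscs",
    "efficacy",
    "spiking_map",
    "radius_curve",
    "epsc_map",
    "latency_jitter",
]


@dataclass
class EventDetection:
    """Detected events with amplitudes and the threshold that found them."""

    times_ms: np.ndarray
    amplitudes: np.ndarray            # pA for EPSCs, mV peak for spikes
    threshold: float
    accept: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.accept is None:
            self.accept = np.ones(len(self.times_ms), dtype=bool)

    def __len__(self) -> int:
        return len(self.times_ms)

    def accepted(self) -> "EventDetection":
        m = self.accept.astype(bool)
        return EventDetection(self.times_ms[m], self.amplitudes[m], self.threshold)


def detect_spikes(
    trace: np.ndarray,
    fs_hz: float,
    threshold_mv: float | None = None,
    refractory_ms: float = 2.0,
) -> EventDetection:
    """Threshold-crossing spike detection with refractory lockout.

    The default threshold sits 30 mV above the trace median (robust to DC
    offset), which separates full-height action potentials from EPSPs and
    stimulus artifacts.  Deterministic.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.size == 0:
        return EventDetection(np.array([]), np.array([]), np.nan)
    thr = float(np.median(trace) + 30.0) if threshold_mv is None else float(threshold_mv)
    above = trace >= thr
    crossings = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    lockout = int(refractory_ms * fs_hz / 1e3)
    times, amps = [], []
    last = -lockout - 1
    for idx in crossings:
        if idx - last <= lockout:
            continue
        last = idx
        seg = trace[idx : idx + lockout + 1]
        times.append(idx / fs_hz * 1e3)
        amps.append(float(seg.max()))
    return EventDetection(np.array(times), np.array(amps), thr)


def _blank_artifacts(
    trace: np.ndarray, fs_hz: float, stim_onsets_ms: np.ndarray | None, blank_ms: float
) -> np.ndarray:
    """Replace a post-stimulus window with a linear bridge (artifact blanking)."""
    if stim_onsets_ms is None or len(stim_onsets_ms) == 0:
        return trace
    out = trace.copy()
    n = len(out)
    half = int(round(blank_ms * fs_hz / 1e3))
    for t_ms in np.asarray(stim_onsets_ms, dtype=float):
        i0 = max(0, int(t_ms * fs_hz / 1e3) - 2)
        i1 = min(n - 1, i0 + 2 * half + 2)
        if i1 <= i0:
            continue
        out[i0 : i1 + 1] = np.linspace(out[i0], out[i1], i1 - i0 + 1)
    return out


def detect_epscs(
    trace: np.ndarray,
    fs_hz: float,
    stim_onsets_ms: np.ndarray | None = None,
    blank_ms: float = 2.0,
    lowpass_hz: float = 1000.0,
    k_mad: float = 5.0,
    diff_lag_ms: float = 1.0,
    min_separation_ms: float = 5.0,
    peak_window_ms: float = 15.0,
    min_amp_pa: float = 8.0,
    k_amp: float = 6.0,
) -> EventDetection:
    """Detect inward EPSCs in a voltage-clamp current trace (pA).

    Pipeline: blank a 2x``blank_ms`` window around each stimulus onset
    (stimulus artifacts), low-pass filter at 1 kHz, then threshold the
    negative-going finite difference taken over the EPSC rise timescale
    (``diff_lag_ms``) at median − k*MAD.  Event amplitude is the local
    pre-onset baseline minus the trough within the peak window; events
    smaller than max(``min_amp_pa``, ``k_amp`` × the robust trace noise)
    are kept but flagged unaccepted.  Deterministic; DC-offset invariant.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.size < 32:
        return EventDetection(np.array([]), np.array([]), np.nan)
    x = _blank_artifacts(trace, fs_hz, stim_onsets_ms, blank_ms)
    nyq = fs_hz / 2
    if lowpass_hz < nyq:
        sos = signal.butter(4, lowpass_hz / nyq, output="sos")
        x = signal.sosfiltfilt(sos, x)
    lag = max(1, int(diff_lag_ms * fs_hz / 1e3))
    dx = x[lag:] - x[:-lag]  # drop over one rise time
    med = np.median(dx)
    mad = np.median(np.abs(dx - med)) + 1e-12
    thr = med - k_mad * mad
    below = dx <= thr
    onsets = np.flatnonzero(below[1:] & ~below[:-1]) + 1
    sep = int(min_separation_ms * fs_hz / 1e3)
    win = int(peak_window_ms * fs_hz / 1e3)
    base_win = int(2e-3 * fs_hz)
    times, amps = [], []
    last = -sep - 1
    for idx in onsets:
        if idx - last <= sep:
            continue
        last = idx
        trough = float(x[idx : idx + win].min())
        base = float(np.median(x[max(0, idx - base_win) : idx + 1]))
        amp = base - trough
        if amp <= 0:
            continue
        times.append(idx / fs_hz * 1e3)
        amps.append(amp)
    sigma = 1.4826 * float(np.median(np.abs(x - np.median(x))))
    amp_floor = max(min_amp_pa, k_amp * sigma)
    amps_arr = np.array(amps)
    return EventDetection(
        np.array(times), amps_arr, thr, accept=amps_arr >= amp_floor
    )


def efficacy(
    stim_onsets_ms: np.ndarray, spike_times_ms: np.ndarray, window_ms: float = 50.0
) -> float:
    """Percent of stimuli followed by at least one spike within the window."""
    stim = np.asarray(stim_onsets_ms, dtype=float)
    spikes = np.asarray(spike_times_ms, dtype=float)
    if stim.size == 0:
        raise ValueError("efficacy requires at least one stimulus")
    hits = 0
    for t in stim:
        if np.any((spikes >= t) & (spikes <= t + window_ms)):
            hits += 1
    return 100.0 * hits / stim.size


@dataclass
class ActivationMap:
    """Per-electrode responses on the array grid.

    ``grids`` maps each stimulus voltage to an (n_rows, n_cols) array —
    boolean for evoked-spike maps, amplitude (pA) for EPSC maps.
    """

    array: ElectrodeArray
    grids: dict[float, np.ndarray]
    patched_rowcol: tuple[int, int] | None = None
    direct: np.ndarray | None = None    # boolean grid of direct-activation sites

    @property
    def voltages(self) -> list[float]:
        return sorted(self.grids)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for v, g in sorted(self.grids.items()):
            for r in range(self.array.n_rows):
                for c in range(self.array.n_cols):
                    rows.append({"voltage_v": v, "row": r + 1, "col": c + 1, "value": g[r, c]})
        return pd.DataFrame(rows)


def spiking_map(
    matrix: StimulationMatrix,
    spike_times_ms: np.ndarray,
    window_ms: float = 50.0,
    patched_rowcol: tuple[int, int] | None = None,
) -> ActivationMap:
    """Evoked-spike map of a voltage-mapping scan: per (electrode, voltage) booleans."""
    array = matrix.array
    voltages = sorted({e.amplitude_v for e in matrix.events})
    grids = {v: np.zeros((array.n_rows, array.n_cols), dtype=bool) for v in voltages}
    spikes = np.asarray(spike_times_ms, dtype=float)
    for e in matrix.events:
        r, c = array.rowcol_of(e.channel)
        hit = np.any((spikes >= e.onset_ms) & (spikes <= e.onset_ms + window_ms))
        if hit:
            grids[e.amplitude_v][r, c] = True
    return ActivationMap(array=array, grids=grids, patched_rowcol=patched_rowcol)


def radius_curve(
    amap: ActivationMap, patched_xy_um: tuple[float, float]
) -> pd.DataFrame:
    """Mean distance of spike-evoking electrodes from the patched cell, per voltage."""
    px, py = patched_xy_um
    pos = amap.array.positions()
    rows = []
    for v in amap.voltages:
        g = amap.grids[v]
        dists = []
        for ch in range(amap.array.n_channels):
            r, c = amap.array.rowcol_of(ch)
            if g[r, c]:
                dists.append(float(np.hypot(pos[ch, 0] - px, pos[ch, 1] - py)))
        rows.append(
            {"voltage_v": v, "mean_distance_um": float(np.mean(dists)) if dists else np.nan,
             "n_sites": len(dists)}
        )
    return pd.DataFrame(rows)


def epsc_map(
    matrix: StimulationMatrix,
    detection: EventDetection,
    response_window_ms: float = 50.0,
    direct_times_ms: np.ndarray | None = None,
) -> ActivationMap:
    """Mean evoked EPSC amplitude per electrode from a mapping scan.

    An electrode's value is the mean amplitude of accepted EPSCs detected
    within the response window after its stimuli; sites whose stimuli
    coincide with direct-activation transients are flagged.
    """
    array = matrix.array
    det = detection.accepted()
    amp_grid = np.zeros((array.n_rows, array.n_cols))
    cnt_grid = np.zeros((array.n_rows, array.n_cols))
    direct_grid = np.zeros((array.n_rows, array.n_cols), dtype=bool)
    direct = np.asarray(direct_times_ms, dtype=float) if direct_times_ms is not None else None
    for e in matrix.events:
        r, c = array.rowcol_of(e.channel)
        m = (det.times_ms >= e.onset_ms) & (det.times_ms <= e.onset_ms + response_window_ms)
        if np.any(m):
            amp_grid[r, c] += det.amplitudes[m].max()
            cnt_grid[r, c] += 1
        if direct is not None and np.any(
            (direct >= e.onset_ms) & (direct <= e.onset_ms + response_window_ms)
        ):
            direct_grid[r, c] = True
    with np.errstate(invalid="ignore"):
        mean_grid = np.where(cnt_grid > 0, amp_grid / np.maximum(cnt_grid, 1), 0.0)
    voltages = sorted({e.amplitude_v for e in matrix.events})
    v = voltages[-1] if voltages else 0.0
    return ActivationMap(array=array, grids={v: mean_grid}, direct=direct_grid)


def latency_jitter(latencies_ms: np.ndarray) -> tuple[float, float, float]:
    """(mean, range, sd) of evoked-spike latencies across repeated trials (ms)."""
    lat = np.asarray(latencies_ms, dtype=float)
    if lat.size == 0:
        raise ValueError("latency_jitter requires at least one trial latency")
    return float(lat.mean()), float(lat.max() - lat.min()), float(lat.std(ddof=0))


def evoked_latencies(
    recording: Recording, detection: EventDetection | None = None, window_ms: float = 50.0
) -> np.ndarray:
    """Per-stimulus first-spike latency (ms) from a repeated-trial recording.

    Uses detected spikes when a detection is given, otherwise the
    recording's ground-truth patched spike times.  Stimuli with no evoked
    spike are skipped.
    """
    spikes = (
        detection.accepted().times_ms if detection is not None else recording.patched_spikes_ms
    )
    out = []
    for t in recording.stim_onsets_ms:
        m = (spikes >= t) & (spikes <= t + window_ms)
        if np.any(m):
            out.append(float(spikes[m].min() - t))
    return np.array(out)
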