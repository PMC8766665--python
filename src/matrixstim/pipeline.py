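"""End-to-end experiments on a virtual slice.

Combines pattern building, simulation, and analysis into the three
headline protocols — associative capture of a weak input, moving-bar
sweep training, and the sequence-training network assay (with unpatterned
and synaptic-blocker control arms) — plus a seeded demo that writes a
machine-readable summary.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import ephys, imaging, patterns
from .arrays import mea_8x8
from .patterns import StimulationMatrix, StimEvent
from .slice_sim import (
    CalciumConfig,
    Pharmacology,
    ReadoutConfig,
    VirtualSlice,
    apply_plasticity,
    copy_slice,
    find_strong_weak,
    generate_slice,
    simulate,
)

__all__ = [
    "RunConfig",
    "measure_input_efficacy",
    "latency_jitter_experiment",
    "associative_capture_experiment",
    "sequence_assay",
    "moving_bar_experiment",
    "run_demo",
]

#: 28 assayed sites: a 4x7 block of electrodes in the array interior.
DEFAULT_ROI_CHANNELS = tuple(
    r * 8 + c for r in range(2, 6) for c in range(0, 7)
)


@dataclass
class RunConfig:
    """Everything needed to reproduce a demo run."""

    seed: int = 0
    n_neurons: int = 150
    movie_shape: tuple[int, int] = (64, 64)
    frame_rate_hz: float = 10.0
    roi_channels: tuple[int, ...] = DEFAULT_ROI_CHANNELS
    n_test_stimuli: int = 6
    outdir: str = "matrixstim_demo"

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]


def _test_matrix(
    slc: VirtualSlice, channel: int, n_stim: int, rate_hz: float, amplitude_v: float
) -> StimulationMatrix:
    step_us = round(1e6 / rate_hz)
    events = [StimEvent(k * step_us, channel, amplitude_v) for k in range(n_stim)]
    return StimulationMatrix(events, slc.array, label=f"test_ch{channel}")


def measure_input_efficacy(
    slc: VirtualSlice,
    channel: int,
    n_stim: int = 6,
    rate_hz: float = 1.0,
    amplitude_v: float = 3.0,
    pharm: Pharmacology | None = None,
    seed: int = 0,
) -> float:
    """Input efficacy: % of test stimuli (default 6 at 1 Hz) evoking a spike.

    Spikes are detected from the rendered current-clamp trace, not read from
    the generator.
    """
    matrix = _test_matrix(slc, channel, n_stim, rate_hz, amplitude_v)
    rec = simulate(slc, matrix, pharm, ReadoutConfig(mode="current_clamp"), seed=seed)
    det = ephys.detect_spikes(rec.trace, rec.fs_hz)
    return ephys.efficacy(rec.stim_onsets_ms, det.accepted().times_ms)


def latency_jitter_experiment(
    slc: VirtualSlice,
    n_trials: int = 50,
    amplitude_v: float = 3.0,
    rate_hz: float = 1.0,
    seed: int = 0,
) -> tuple[float, float, float]:
    """(mean, range, sd) of evoked-spike latency over repeated identical pulses.

    Stimulates the electrode nearest the patched cell with ``n_trials``
    identical 1 ms biphasic pulses and measures per-trial first-spike
    latency from detected spikes.
    """
    patched = slc.patched
    if patched is None:
        raise ValueError("latency experiment requires a patched cell")
    channel = slc.nearest_channel(patched.x_um, patched.y_um)
    matrix = _test_matrix(slc, channel, n_trials, rate_hz, amplitude_v)
    rec = simulate(slc, matrix, None, ReadoutConfig(mode="current_clamp"), seed=seed)
    det = ephys.detect_spikes(rec.trace, rec.fs_hz)
    lats = ephys.evoked_latencies(rec, det)
    if len(lats) < n_trials:
        raise RuntimeError(f"only {len(lats)}/{n_trials} trials evoked a detected spike")
    return ephys.latency_jitter(lats)


def associative_capture_experiment(
    slc: VirtualSlice,
    seed: int = 0,
    pharm: Pharmacology | None = None,
    n_test: int = 6,
    test_amplitude_v: float = 3.0,
    consolidate_min: float = 30.0,
) -> dict:
    """Full associative-capture protocol on one slice.

    Identifies a strong (superthreshold) and weak (subthreshold) input,
    measures baseline efficacies with test stimuli at 1 Hz, runs the
    default pairing (strong then weak, 15 ms apart, 100 reps at 0.2 Hz),
    consolidates, and re-measures.
    """
    strong_ch, weak_ch = find_strong_weak(slc, test_amplitude_v)
    res = {
        "strong_channel": strong_ch,
        "weak_channel": weak_ch,
        "strong_label": slc.array.label_of(strong_ch),
        "weak_label": slc.array.label_of(weak_ch),
    }
    res["weak_efficacy_pre_pct"] = measure_input_efficacy(
        slc, weak_ch, n_test, amplitude_v=test_amplitude_v, pharm=pharm, seed=seed
    )
    res["strong_efficacy_pre_pct"] = measure_input_efficacy(
        slc, strong_ch, n_test, amplitude_v=test_amplitude_v, pharm=pharm, seed=seed + 1
    )
    pairing = patterns.build_pairing(
        strong_ch, weak_ch, slc.array, amplitude_v=test_amplitude_v
    )
    apply_plasticity(
        slc, pairing, "associative", pharm, seed=seed + 2, consolidate_min=consolidate_min
    )
    res["weak_efficacy_post_pct"] = measure_input_efficacy(
        slc, weak_ch, n_test, amplitude_v=test_amplitude_v, pharm=pharm, seed=seed + 3
    )
    res["strong_efficacy_post_pct"] = measure_input_efficacy(
        slc, strong_ch, n_test, amplitude_v=test_amplitude_v, pharm=pharm, seed=seed + 4
    )
    res["n_pairings"] = len(pairing) // 2
    return res


def _scan_dff(
    slc: VirtualSlice,
    scan: StimulationMatrix,
    rois: imaging.ROISet,
    calcium: CalciumConfig,
    pharm: Pharmacology | None,
    seed: int,
    lead_in_s: float = 2.0,
):
    """Run a sequence scan with imaging and return each ROI's own-stimulus DFF.

    The scan is delayed by ``lead_in_s`` so the first stimulus has a full
    pre-stimulus baseline window.
    """
    rec = simulate(
        slc, scan.shifted(round(lead_in_s * 1e6)), pharm,
        ReadoutConfig(mode="none", calcium=calcium), seed=seed,
    )
    traces = imaging.extract_traces(rec.movie, rois)
    traces = imaging.correct_flicker(traces)
    onsets_s = rec.stim_onsets_ms / 1e3
    traces = imaging.correct_bleach(traces, rec.frame_times_s, onsets_s)
    dff = imaging.compute_dff(traces, rec.frame_times_s, onsets_s)
    own = dff[
        dff.apply(lambda row: rec.stim_channels[int(row.stimulus)] == row.roi, axis=1)
    ]
    return own, dff, rec


def sequence_assay(
    slc: VirtualSlice,
    roi_channels: list[int] | None = None,
    train_pharm: Pharmacology | None = None,
    unpatterned: bool = False,
    calcium: CalciumConfig | None = None,
    n_training_sweeps: int = 6,
    seed: int = 0,
    train: bool = True,
) -> imaging.AssayResult:
    """Before/after sequence-training network assay (the automated Fig-style assay).

    Acquires a baseline row-major sequence-scan response map over the
    assayed ROIs, trains with ``n_training_sweeps`` uninterrupted sweeps
    (or a channel-shuffled unpatterned control with the same stimulus count
    and intensities), and compares the post-training map per ROI with a
    paired two-tailed t-test.  ``train_pharm`` applies during training only
    (e.g. NBQX+AP5 blockade); scans run drug-free.
    """
    roi_channels = list(roi_channels or DEFAULT_ROI_CHANNELS)
    calcium = calcium or CalciumConfig(shape=(64, 64))
    rois = imaging.make_rois(slc.array, roi_channels, calcium)
    scan = patterns.build_sequence_scan(slc.array, roi_channels)
    before, _, _ = _scan_dff(slc, scan, rois, calcium, None, seed)
    if train:
        training = patterns.build_sequence_scan(
            slc.array, roi_channels, n_sweeps=n_training_sweeps
        )
        if unpatterned:
            training = patterns.build_unpatterned_control(training, seed=seed + 17)
        apply_plasticity(slc, training, "sequence", train_pharm, seed=seed + 1)
    after, _, _ = _scan_dff(slc, scan, rois, calcium, None, seed + 2)
    return imaging.network_assay(before, after)


def moving_bar_experiment(
    slc: VirtualSlice,
    n_training_sweeps: int = 100,
    inter_column_interval_ms: float = 80.0,
    seed: int = 0,
) -> dict:
    """Moving-bar entrainment: patched-cell response before vs after sweep training.

    Measures the peak depolarization of the patched cell during one bar
    sweep, trains with repeated sweeps under the sequence rule, and
    re-measures.
    """
    probe = patterns.build_moving_bar(
        slc.array, inter_column_interval_ms, n_reps=1
    )
    def _peak_response(s: VirtualSlice, sd: int) -> float:
        rec = simulate(s, probe, None, ReadoutConfig(mode="current_clamp"), seed=sd)
        return float(rec.trace.max() - np.median(rec.trace))

    before = _peak_response(slc, seed)
    training = patterns.build_moving_bar(
        slc.array, inter_column_interval_ms, n_reps=n_training_sweeps
    )
    apply_plasticity(slc, training, "sequence", None, seed=seed + 1)
    after = _peak_response(slc, seed + 2)
    return {
        "sweep_period_ms": patterns.sweep_period_us(slc.array, inter_column_interval_ms) / 1e3,
        "n_training_sweeps": n_training_sweeps,
        "peak_response_before_mv": before,
        "peak_response_after_mv": after,
    }


def run_demo(config: RunConfig, outdir: str | Path | None = None) -> dict:
    """Seeded end-to-end demo: build → simulate → analyze → assay.

    Runs associative capture, moving-bar training, and the sequence assay
    (with unpatterned and NBQX+AP5 control arms) on virtual slices derived
    from one seed, writes pattern files and a JSON summary, and returns the
    summary dict.
    """
    outdir = Path(outdir or config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    calcium = CalciumConfig(shape=config.movie_shape, frame_rate_hz=config.frame_rate_hz)
    summary: dict = {"seed": config.seed, "config_hash": config.config_hash()}

    slc = generate_slice(config.seed, n_neurons=config.n_neurons)
    summary["associative_capture"] = associative_capture_experiment(
        copy_slice(slc), seed=config.seed, n_test=config.n_test_stimuli
    )
    summary["moving_bar"] = moving_bar_experiment(copy_slice(slc), seed=config.seed)

    assay = {}
    arms = {
        "patterned": dict(train_pharm=None, unpatterned=False),
        "unpatterned": dict(train_pharm=None, unpatterned=True),
        "nbqx_ap5": dict(train_pharm=Pharmacology(nbqx=True, ap5=True), unpatterned=False),
    }
    for name, kw in arms.items():
        res = sequence_assay(
            copy_slice(slc), list(config.roi_channels), calcium=calcium,
            seed=config.seed, **kw,
        )
        assay[name] = res.to_dict()
    # washout rescue: train once under blockade, then again drug-free
    rescue_slc = copy_slice(slc)
    sequence_assay(
        rescue_slc, list(config.roi_channels),
        train_pharm=Pharmacology(nbqx=True, ap5=True, bicuculline=True),
        calcium=calcium, seed=config.seed,
    )
    rescue = sequence_assay(
        rescue_slc, list(config.roi_channels), calcium=calcium, seed=config.seed + 100
    )
    assay["washout_rescue"] = rescue.to_dict()
    summary["sequence_assay"] = assay

    # artifacts
    patterns.build_pairing(
        summary["associative_capture"]["strong_channel"],
        summary["associative_capture"]["weak_channel"],
        slc.array,
    ).to_json(outdir / "pairing_pattern.json")
    patterns.build_moving_bar(slc.array, n_reps=1).to_json(outdir / "moving_bar_pattern.json")
    slc.to_json(outdir / "slice.json")
    (outdir / "summary.json").write_text(
        json.dumps(summary, indent=1, sort_keys=True, default=float)
    )
    return summary
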