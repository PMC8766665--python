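"""Virtual slice: activation, transmission, pharmacology, plasticity rules."""

import numpy as np
import pytest

from matrixstim import (
    Pharmacology,
    ReadoutConfig,
    activation_radius,
    apply_plasticity,
    build_pairing,
    build_sequence_scan,
    build_tetanus,
    classify_inputs,
    find_strong_weak,
    generate_slice,
    mea_8x8,
    simulate,
)
from matrixstim.patterns import StimEvent, StimulationMatrix
from matrixstim.slice_sim import VirtualSlice, copy_slice


def pulse_train(slc, channel, n, amplitude_v=3.0, period_ms=1000.0):
    events = [
        StimEvent(round(k * period_ms * 1000), channel, amplitude_v) for k in range(n)
    ]
    return StimulationMatrix(events, slc.array)


def nearest_electrode(slc):
    p = slc.patched
    return slc.nearest_channel(p.x_um, p.y_um)


class TestActivationRadius:
    def test_zero_below_minimum_voltage(self):
        assert activation_radius(0.0) == 0.0
        assert activation_radius(2.0) == 0.0

    def test_grows_with_voltage(self):
        assert activation_radius(2.0) < activation_radius(4.0)

    def test_monotone_on_dense_grid(self):
        v = np.linspace(0, 4.5, 500)
        r = np.array([activation_radius(x) for x in v])
        assert np.all(np.diff(r) >= 0)


class TestGeneration:
    def test_same_seed_identical_slice(self):
        a, b = generate_slice(7), generate_slice(7)
        assert a.to_dict() == b.to_dict()

    def test_empty_slice_simulates_silence(self):
        slc = generate_slice(0, n_neurons=0)
        rec = simulate(slc, pulse_train_empty(slc), readout=ReadoutConfig(mode="none"))
        assert all(len(v) == 0 for v in rec.spike_times_ms.values())

    def test_patched_readout_requires_patched_cell(self):
        slc = generate_slice(0, n_neurons=0)
        with pytest.raises(ValueError, match="patched"):
            simulate(slc, pulse_train_empty(slc))

    def test_strong_and_weak_inputs_discoverable_across_seeds(self):
        # Monte-Carlo over 100 seeds: a central patched cell should offer
        # at least one superthreshold and one subthreshold input site
        found = sum(
            1 for seed in range(100) if _has_strong_weak(generate_slice(seed))
        )
        assert found >= 90

    def test_serialization_roundtrip(self, tmp_path, slice1):
        path = tmp_path / "slice.json"
        slice1.to_json(path)
        back = VirtualSlice.from_json(path)
        assert back.to_dict() == slice1.to_dict()


def _has_strong_weak(slc):
    try:
        find_strong_weak(slc)
        return True
    except LookupError:
        return False


def pulse_train_empty(slc):
    return StimulationMatrix([StimEvent(0, 0, 3.0)], slc.array)


class TestSpiking:
    def test_one_spike_per_pulse_on_adjacent_electrode(self, slice1):
        m = pulse_train(slice1, nearest_electrode(slice1), 5)
        rec = simulate(slice1, m, seed=0)
        assert len(rec.patched_spikes_ms) == 5

    def test_ttx_abolishes_spiking(self, slice1):
        m = pulse_train(slice1, nearest_electrode(slice1), 5)
        rec = simulate(slice1, m, Pharmacology(ttx=True), seed=0)
        assert len(rec.patched_spikes_ms) == 0
        assert all(len(v) == 0 for v in rec.spike_times_ms.values())

    def test_determinism_under_seed(self, slice1):
        m = pulse_train(slice1, nearest_electrode(slice1), 3)
        a = simulate(slice1, m, seed=5)
        b = simulate(slice1, m, seed=5)
        assert np.array_equal(a.patched_spikes_ms, b.patched_spikes_ms)
        assert np.array_equal(a.trace, b.trace)

    def test_all_or_none_threshold_step(self, slice1):
        # spike probability vs amplitude is a step: zero below the effective
        # threshold, one spike per pulse above it
        ch = nearest_electrode(slice1)
        responded = []
        for v in np.arange(2.0, 4.51, 0.1):
            rec = simulate(
                slice1, pulse_train(slice1, ch, 1, amplitude_v=float(v)),
                Pharmacology(nbqx=True), readout=ReadoutConfig(mode="none"), seed=0,
            )
            responded.append(len(rec.patched_spikes_ms) > 0)
        arr = np.array(responded)
        assert not arr[0] and arr[-1]
        # once active, stays active (single upward step)
        first = int(np.argmax(arr))
        assert arr[first:].all() and not arr[:first].any()

    def test_latency_spread_under_1ms_over_50_trials(self, slice1):
        m = pulse_train(slice1, nearest_electrode(slice1), 50)
        rec = simulate(slice1, m, readout=ReadoutConfig(mode="none"), seed=11)
        lats = rec.patched_spikes_ms - rec.stim_onsets_ms
        assert len(lats) == 50
        assert lats.max() - lats.min() < 1.0


class TestTransmission:
    def test_epscs_from_distant_electrode(self, slice1):
        strong, weak = find_strong_weak(slice1)
        rec = simulate(
            slice1, pulse_train(slice1, weak, 3),
            readout=ReadoutConfig(mode="voltage_clamp"), seed=0,
        )
        assert len(rec.epsc_truth) > 0
        assert rec.evoked_drive_pa.min() > 0

    def test_nbqx_abolishes_epscs(self, slice1):
        strong, weak = find_strong_weak(slice1)
        rec = simulate(
            slice1, pulse_train(slice1, weak, 3), Pharmacology(nbqx=True),
            readout=ReadoutConfig(mode="voltage_clamp"), seed=0,
        )
        assert len(rec.epsc_truth) == 0

    def test_synaptic_delay_nonimmediate(self, slice1):
        strong, _ = find_strong_weak(slice1)
        rec = simulate(
            slice1, pulse_train(slice1, strong, 1),
            readout=ReadoutConfig(mode="none"), seed=0,
        )
        arrivals = np.array([t for t, _ in rec.epsc_truth])
        assert np.all(arrivals >= 5.0)  # latency + synaptic delay

    def test_unrelated_channel_independence(self, slice1):
        # adding stimulation on a remote silent channel does not change the
        # response to the probed channel
        strong, _ = find_strong_weak(slice1)
        classes = classify_inputs(slice1)
        silent = [c.channel for c in classes.values() if c.category == "none"]
        far = silent[0]
        probe = pulse_train(slice1, strong, 2)
        both = StimulationMatrix(
            probe.events + [StimEvent(500_000_000, far, 3.0)], slice1.array
        )
        a = simulate(slice1, probe, readout=ReadoutConfig(mode="none"), seed=4)
        b = simulate(slice1, both, readout=ReadoutConfig(mode="none"), seed=4)
        assert np.array_equal(a.patched_spikes_ms, b.patched_spikes_ms)
        assert a.epsc_truth == b.epsc_truth[: len(a.epsc_truth)]


class TestAssociativePlasticity:
    def test_weak_input_reaches_full_efficacy(self, slice1):
        strong, weak = find_strong_weak(slice1)
        drive_before = classify_inputs(slice1)[weak].drive_pa
        pairing = build_pairing(strong, weak, slice1.array)
        apply_plasticity(slice1, pairing, "associative", seed=0)
        drive_after = classify_inputs(slice1)[weak].drive_pa
        assert drive_before < slice1.params.drive_threshold_pa
        assert drive_after >= slice1.params.drive_threshold_pa

    def test_zero_reps_no_change(self, slice1):
        strong, weak = find_strong_weak(slice1)
        before = slice1.state.syn_multiplier.copy()
        pairing = build_pairing(strong, weak, slice1.array, n_reps=0)
        apply_plasticity(slice1, pairing, "associative", seed=0)
        assert np.array_equal(slice1.state.syn_multiplier, before)

    def test_unpaired_interval_no_change(self, slice1):
        # stimuli far outside the pairing window leave efficacy untouched
        strong, weak = find_strong_weak(slice1)
        before = slice1.state.syn_multiplier.copy()
        pairing = build_pairing(strong, weak, slice1.array, interval_ms=500.0)
        apply_plasticity(slice1, pairing, "associative", seed=0)
        assert np.array_equal(slice1.state.syn_multiplier, before)

    def test_efficacy_monotone_in_repetitions(self, slice1):
        strong, weak = find_strong_weak(slice1)
        drives = []
        for n_reps in (10, 40, 100):
            s = copy_slice(slice1)
            pairing = build_pairing(strong, weak, s.array, n_reps=n_reps)
            apply_plasticity(s, pairing, "associative", seed=0)
            drives.append(classify_inputs(s)[weak].drive_pa)
        assert drives[0] <= drives[1] <= drives[2]

    def test_blocked_by_nbqx_ap5(self, slice1):
        strong, weak = find_strong_weak(slice1)
        before = slice1.state.syn_multiplier.copy()
        pairing = build_pairing(strong, weak, slice1.array)
        apply_plasticity(
            slice1, pairing, "associative", Pharmacology(nbqx=True, ap5=True), seed=0
        )
        assert np.array_equal(slice1.state.syn_multiplier, before)


class TestTetanusAndSequence:
    def test_tetanus_potentiates_recruited_synapses(self, slice1):
        strong, _ = find_strong_weak(slice1)
        before = classify_inputs(slice1)[strong].drive_pa
        apply_plasticity(slice1, build_tetanus(strong, slice1.array, amplitude_v=3.0),
                         "tetanus", seed=0)
        after = classify_inputs(slice1)[strong].drive_pa
        assert after == pytest.approx(before * slice1.params.tetanus_gain, rel=1e-6)

    def test_sequence_training_raises_roi_gains(self, slice1):
        rois = [r * 8 + c for r in range(2, 6) for c in range(7)]
        m = build_sequence_scan(slice1.array, rois, n_sweeps=6)
        apply_plasticity(slice1, m, "sequence", seed=0)
        assert slice1.state.roi_gain.max() > 1.0

    def test_sequence_blocked_by_nbqx_ap5(self, slice1):
        rois = [r * 8 + c for r in range(2, 6) for c in range(7)]
        m = build_sequence_scan(slice1.array, rois, n_sweeps=6)
        apply_plasticity(slice1, m, "sequence", Pharmacology(nbqx=True, ap5=True), seed=0)
        assert np.array_equal(slice1.state.roi_gain, np.ones(64))

    def test_multipliers_bounded(self, slice1):
        strong, _ = find_strong_weak(slice1)
        tet = build_tetanus(strong, slice1.array, amplitude_v=3.0)
        for _ in range(10):
            apply_plasticity(slice1, tet, "tetanus", seed=0)
        assert slice1.state.syn_multiplier.max() <= slice1.params.associative_mult_max

    def test_unknown_rule_rejected(self, slice1):
        with pytest.raises(ValueError, match="rule"):
            apply_plasticity(slice1, pulse_train(slice1, 0, 1), "hebb", seed=0)


class TestCalcium:
    def test_movie_rendered_and_aligned(self, slice1):
        from matrixstim import CalciumConfig

        m = pulse_train(slice1, nearest_electrode(slice1), 2, period_ms=2000.0)
        rec = simulate(
            slice1, m,
            readout=ReadoutConfig(mode="none", calcium=CalciumConfig(shape=(32, 32))),
            seed=0,
        )
        assert rec.movie.shape[1:] == (32, 32)
        assert rec.frame_times_s[-1] >= m.duration_us() / 1e6
        assert np.all(rec.movie.mean(axis=(1, 2)) > 0)

    def test_bleach_makes_brightness_decay(self, slice1):
        from matrixstim import CalciumConfig

        cfg = CalciumConfig(shape=(16, 16), flicker_sigma=0.0, pixel_noise=0.0,
                            bleach_tau_s=50.0)
        m = StimulationMatrix([StimEvent(60_000_000, 0, 0.0)], slice1.array)
        rec = simulate(slice1, m, readout=ReadoutConfig(mode="none", calcium=cfg), seed=0)
        mean = rec.movie.mean(axis=(1, 2))
        assert np.all(np.diff(mean) < 0)
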