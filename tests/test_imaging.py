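"""Calcium-movie analysis: traces, corrections, ΔF/F, maps, assay statistics."""

import numpy as np
import pandas as pd
import pytest

from matrixstim import (
    CalciumConfig,
    ReadoutConfig,
    compute_dff,
    correct_bleach,
    correct_flicker,
    extract_traces,
    make_rois,
    network_assay,
    population_map,
    response_map,
    simulate,
)
from matrixstim.imaging import save_heatmap
from matrixstim.patterns import StimEvent, StimulationMatrix


def synthetic_movie(
    n_frames=300,
    shape=(32, 32),
    frame_rate=10.0,
    roi_px=((8, 8), (8, 24), (24, 8), (24, 24)),
    dff_true=0.30,
    stim_every_s=6.0,
    flicker_sigma=0.05,
    bleach_tau_s=100.0,
    noise=0.2,
    seed=0,
):
    """Movie with disc ROIs whose pixels carry transients of known ΔF/F.

    Each stimulus drives one ROI (cycling) with a transient peaking at
    ``dff_true``; the whole movie is multiplied by per-frame flicker and an
    exponential bleach, plus white pixel noise.  Returns (movie, frame
    times, stim onsets, stim ROI order, roi pixel centers).
    """
    rng = np.random.default_rng(seed)
    h, w = shape
    t = np.arange(n_frames) / frame_rate
    base = np.full(shape, 100.0)
    masks = []
    for cy, cx in roi_px:
        yy, xx = np.mgrid[0:h, 0:w]
        m = ((xx - cx) ** 2 + (yy - cy) ** 2) <= 9
        base[m] += 50.0
        masks.append(m)
    onsets = np.arange(2.0, t[-1] - 2.0, stim_every_s)
    stim_rois = [k % len(roi_px) for k in range(len(onsets))]
    movie = np.repeat(base[None], n_frames, axis=0)
    for onset, k in zip(onsets, stim_rois):
        dt = t - onset
        resp = np.where(dt > 0, (1 - np.exp(-dt / 0.1)) * np.exp(-dt / 1.0), 0.0)
        resp = dff_true * resp / resp.max()
        movie[:, masks[k]] *= (1 + resp)[:, None]
    flicker = 1 + rng.normal(0, flicker_sigma, n_frames)
    bleach = np.exp(-t / bleach_tau_s)
    movie *= (flicker * bleach)[:, None, None]
    movie += rng.normal(0, noise, movie.shape)
    return movie, t, onsets, stim_rois, roi_px


def _rois_at(pixels, shape):
    from matrixstim.imaging import ROISet

    table = pd.DataFrame(
        [{"roi": i, "x_px": cx, "y_px": cy, "radius_px": 3.0,
          "x_um": cx * 10.0, "y_um": cy * 10.0}
         for i, (cy, cx) in enumerate(pixels)]
    )
    return ROISet(table=table, frame_shape=shape)


class TestExtractTraces:
    def test_uniform_movie_constant_traces(self):
        movie = np.full((20, 16, 16), 7.0)
        rois = _rois_at([(8, 8)], (16, 16))
        tr = extract_traces(movie, rois)
        assert np.allclose(tr[0], 7.0)

    def test_single_bright_roi_isolated(self):
        movie = np.full((5, 32, 32), 10.0)
        movie[:, 6:11, 6:11] = 100.0
        rois = _rois_at([(8, 8), (24, 24)], (32, 32))
        tr = extract_traces(movie, rois)
        assert tr[0].mean() > 5 * tr[1].mean()

    def test_simulator_traces_track_spiking(self, slice1):
        ch = slice1.nearest_channel(slice1.patched.x_um, slice1.patched.y_um)
        quiet = slice1.array.n_channels - 1 if ch != slice1.array.n_channels - 1 else 0
        m = StimulationMatrix(
            [StimEvent(2_000_000 + k * 3_000_000, ch, 4.0) for k in range(3)],
            slice1.array,
        )
        cfg = CalciumConfig(shape=(48, 48))
        rec = simulate(slice1, m, readout=ReadoutConfig(mode="none", calcium=cfg), seed=0)
        rois = make_rois(slice1.array, [ch, quiet], cfg)
        tr = extract_traces(rec.movie, rois)
        tr = correct_bleach(correct_flicker(tr), rec.frame_times_s, rec.stim_onsets_ms / 1e3)
        dff = compute_dff(tr, rec.frame_times_s, rec.stim_onsets_ms / 1e3)
        stim_resp = dff[dff.roi == ch]["dff_percent"].mean()
        far_resp = dff[dff.roi == quiet]["dff_percent"].mean()
        assert stim_resp > 3.0 and stim_resp > 5 * abs(far_resp)


class TestCorrections:
    def test_flicker_variance_reduced_tenfold(self):
        rng = np.random.default_rng(0)
        flicker = 1 + rng.normal(0, 0.05, 400)
        levels = np.array([80.0, 120.0, 150.0, 220.0, 95.0])
        traces = pd.DataFrame(np.outer(flicker, levels))
        out = correct_flicker(traces)
        var_before = (traces / traces.mean()).mean(axis=1).var()
        var_after = (out / out.mean()).mean(axis=1).var()
        assert var_before / max(var_after, 1e-18) >= 10

    def test_no_artifact_input_unchanged(self):
        traces = pd.DataFrame({0: np.full(100, 50.0), 1: np.full(100, 80.0)})
        out = correct_flicker(traces)
        assert np.allclose(out, traces, rtol=1e-9)

    def test_pure_decay_flattens(self):
        t = np.arange(300) / 10.0
        y = 120.0 * np.exp(-t / 40.0) + 5.0
        traces = pd.DataFrame({0: y})
        out = correct_bleach(traces, t)
        rel = out[0].to_numpy() / out[0].iloc[0]
        assert np.max(np.abs(rel - 1)) < 0.02

    def test_flat_input_survives_bleach_fit(self):
        t = np.arange(200) / 10.0
        traces = pd.DataFrame({0: np.full(200, 90.0)})
        out = correct_bleach(traces, t)
        assert np.allclose(out[0], 90.0, rtol=1e-3)

    def test_corrections_commute_with_transients(self):
        # applying corrections before vs after adding a stimulus-locked
        # transient changes the measured dff by only a small tolerance
        movie, t, onsets, stim_rois, roi_px = synthetic_movie(noise=0.0, seed=2)
        rois = _rois_at(roi_px, (32, 32))
        tr = extract_traces(movie, rois)
        corr = correct_bleach(correct_flicker(tr), t, onsets)
        dff = compute_dff(corr, t, onsets)
        own = dff[[stim_rois[int(s)] == r for s, r in zip(dff.stimulus, dff.roi)]]
        assert own["dff_percent"].mean() == pytest.approx(30.0, rel=0.1)


class TestDff:
    def test_formula(self):
        t = np.arange(40) / 10.0
        y = np.full(40, 100.0)
        y[21:25] = 150.0
        dff = compute_dff(pd.DataFrame({0: y}), t, np.array([2.0]))
        assert dff["dff_percent"].iloc[0] == pytest.approx(50.0)

    def test_no_event_near_zero(self):
        rng = np.random.default_rng(1)
        y = 100.0 + rng.normal(0, 0.3, 100)
        dff = compute_dff(pd.DataFrame({0: y}), np.arange(100) / 10.0, np.array([5.0]))
        assert abs(dff["dff_percent"].iloc[0]) < 2.0

    def test_recovery_within_10pct_under_flicker_and_bleach(self):
        movie, t, onsets, stim_rois, roi_px = synthetic_movie(seed=4)
        rois = _rois_at(roi_px, (32, 32))
        tr = extract_traces(movie, rois)
        corr = correct_bleach(correct_flicker(tr), t, onsets)
        dff = compute_dff(corr, t, onsets)
        own = dff[[stim_rois[int(s)] == r for s, r in zip(dff.stimulus, dff.roi)]]
        assert own["dff_percent"].mean() == pytest.approx(30.0, rel=0.10)

    def test_scale_invariance(self):
        movie, t, onsets, stim_rois, roi_px = synthetic_movie(seed=5, noise=0.0)
        rois = _rois_at(roi_px, (32, 32))
        d1 = compute_dff(extract_traces(movie, rois), t, onsets)
        d2 = compute_dff(extract_traces(movie * 3.7, rois), t, onsets)
        assert np.allclose(d1["dff_percent"], d2["dff_percent"], rtol=1e-9)

    def test_nonpositive_baseline_rejected(self):
        t = np.arange(40) / 10.0
        y = np.zeros(40)
        with pytest.raises(ValueError, match="baseline"):
            compute_dff(pd.DataFrame({0: y}), t, np.array([2.0]))


def _dff_row(array, channel, value):
    return {"stimulus": 0, "onset_s": 0.0, "roi": channel,
            "baseline_f": 100.0, "peak_f": 100.0 + value, "dff_percent": value}


class TestResponseMaps:
    def test_single_responsive_roi_is_argmax(self, array8):
        rows = [_dff_row(array8, ch, 1.0) for ch in range(64)]
        rows[19]["dff_percent"] = 40.0
        m = response_map(pd.DataFrame(rows), array8, stim_channel=19)
        assert m.argmax_rowcol() == array8.rowcol_of(19)

    def test_interpolation_passes_through_measured_values(self, array8):
        rng = np.random.default_rng(0)
        rows = [_dff_row(array8, ch, float(rng.uniform(0, 20))) for ch in range(64)]
        m = response_map(pd.DataFrame(rows), array8, upsample=8)
        for ch in (0, 13, 63):
            r, c = array8.rowcol_of(ch)
            assert m.field[r * 8, c * 8] == pytest.approx(m.grid[r, c])

    def test_maps_follow_stimulated_electrode(self, slice1):
        cfg = CalciumConfig(shape=(48, 48))
        chans = [slice1.array.channel_of(3, 2), slice1.array.channel_of(3, 5),
                 slice1.array.channel_of(5, 3)]
        rois = make_rois(slice1.array, calcium=cfg)
        for ch in chans:
            m = StimulationMatrix([StimEvent(2_000_000, ch, 4.5)], slice1.array)
            rec = simulate(slice1, m, readout=ReadoutConfig(mode="none", calcium=cfg), seed=1)
            tr = correct_bleach(
                correct_flicker(extract_traces(rec.movie, rois)),
                rec.frame_times_s, rec.stim_onsets_ms / 1e3,
            )
            dff = compute_dff(tr, rec.frame_times_s, rec.stim_onsets_ms / 1e3)
            rmap = response_map(dff, slice1.array, stim_channel=ch)
            r, c = rmap.argmax_rowcol()
            sr, sc = slice1.array.rowcol_of(ch)
            assert abs(r - sr) <= 1 and abs(c - sc) <= 1

    def test_repeated_stimulus_maps_correlate(self, slice1):
        cfg = CalciumConfig(shape=(48, 48))
        ch = slice1.array.channel_of(4, 4)
        m = StimulationMatrix(
            [StimEvent(2_000_000 + k * 5_000_000, ch, 4.5) for k in range(3)],
            slice1.array,
        )
        rec = simulate(slice1, m, readout=ReadoutConfig(mode="none", calcium=cfg), seed=2)
        rois = make_rois(slice1.array, calcium=cfg)
        tr = correct_bleach(
            correct_flicker(extract_traces(rec.movie, rois)),
            rec.frame_times_s, rec.stim_onsets_ms / 1e3,
        )
        dff = compute_dff(tr, rec.frame_times_s, rec.stim_onsets_ms / 1e3)
        grids = [
            response_map(dff[dff.stimulus == k], slice1.array).grid.ravel()
            for k in range(3)
        ]
        for a in range(3):
            for b in range(a + 1, 3):
                assert np.corrcoef(grids[a], grids[b])[0, 1] > 0.9

    def test_population_alignment_identity_for_single_map(self, array8):
        rows = [_dff_row(array8, ch, float(ch)) for ch in range(64)]
        m = response_map(pd.DataFrame(rows), array8, stim_channel=array8.channel_of(0, 0))
        pop = population_map([m])
        assert pop.at_offset(0, 0) == m.grid[0, 0]
        assert pop.at_offset(7, 7) == m.grid[7, 7]

    def test_population_translated_responses_align(self, array8):
        # identical response profile translated with the stimulated electrode
        maps = []
        for ch in (array8.channel_of(3, 3), array8.channel_of(4, 5), array8.channel_of(2, 6)):
            sr, sc = array8.rowcol_of(ch)
            rows = []
            for roi in range(64):
                r, c = array8.rowcol_of(roi)
                val = 50.0 if (r, c) == (sr, sc) else 10.0 / (1 + abs(r - sr) + abs(c - sc))
                rows.append(_dff_row(array8, roi, val))
            maps.append(response_map(pd.DataFrame(rows), array8, stim_channel=ch))
        pop = population_map(maps)
        assert pop.at_offset(0, 0) == pytest.approx(50.0)
        center = pop.at_offset(0, 0)
        for dr, dc in ((0, 1), (1, 0), (0, -1), (-1, 0)):
            assert pop.at_offset(dr, dc) < center

    def test_heatmap_renders(self, tmp_path, array8):
        rows = [_dff_row(array8, ch, float(ch)) for ch in range(64)]
        m = response_map(pd.DataFrame(rows), array8)
        out = tmp_path / "map.png"
        save_heatmap(m.grid, out)
        assert out.stat().st_size > 0


class TestNetworkAssay:
    def _table(self, values):
        return pd.DataFrame(
            [{"stimulus": i, "roi": i, "dff_percent": v, "baseline_f": 100.0,
              "peak_f": 100.0 + v, "onset_s": float(i)} for i, v in enumerate(values)]
        )

    def test_identical_tables_ratio_one_p_one(self):
        t = self._table([10.0, 12.0, 9.0])
        res = network_assay(t, t.copy())
        assert res.mean_ratio == 1.0 and res.p_value == 1.0

    def test_hand_computed_t_statistic(self):
        # before (10, 12, 11) → after (20, 24, 22): diffs (10, 12, 11),
        # t = 11 / (1/sqrt(3)) = 19.0526; two-tailed p with 2 df:
        # p = 1 − t/sqrt(t²+2) = 0.0027435 (closed form for df = 2)
        res = network_assay(self._table([10.0, 12.0, 11.0]), self._table([20.0, 24.0, 22.0]))
        assert res.mean_ratio == pytest.approx(2.0)
        assert res.t_statistic == pytest.approx(19.052559, rel=1e-6)
        assert res.p_value == pytest.approx(0.0027435, abs=1e-5)

    def test_mismatched_rois_rejected(self):
        a = self._table([1.0, 2.0])
        b = self._table([1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="ROI"):
            network_assay(a, b)

    def test_null_rejection_rate_calibrated(self, _base_slice):
        # with plasticity off, before/after maps differ only by noise:
        # the paired test's rejection rate at alpha = 0.05 stays near nominal
        from matrixstim import build_sequence_scan
        from matrixstim.pipeline import _scan_dff
        from matrixstim.slice_sim import copy_slice

        rois = [r * 8 + c for r in range(3, 5) for c in range(1, 7)]
        cal = CalciumConfig(shape=(32, 32))
        roiset = make_rois(_base_slice.array, rois, cal)
        scan = build_sequence_scan(_base_slice.array, rois, inter_stim_interval_s=2.0)
        rejected = 0
        n_runs = 200
        for k in range(n_runs):
            b, _, _ = _scan_dff(copy_slice(_base_slice), scan, roiset, cal, None, 1000 + 2 * k)
            a, _, _ = _scan_dff(copy_slice(_base_slice), scan, roiset, cal, None, 1001 + 2 * k)
            rejected += network_assay(b, a).p_value < 0.05
        assert 0.01 <= rejected / n_runs <= 0.10
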