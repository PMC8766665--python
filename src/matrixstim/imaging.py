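"""Calcium-movie "network assay": ROI traces, corrections, ΔF/F, maps, statistics.

The assay tracks mean fluorescence in a circular ROI around each assayed
electrode, corrects the traces for common-mode lamp flicker (division by
the normalized per-frame global median) and dye photobleaching (single
exponential fit on stimulus-free samples, divided out), computes the
stimulus-locked ΔF/F%% per (stimulus, ROI) pair from a pre-stimulus
baseline window and a post-stimulus peak window, assembles interpolated
response maps and electrode-aligned population maps, and compares
before/after-training responses per ROI with a paired two-tailed t-test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from pathlib import Path
from scipy import interpolate, optimize, stats

from .arrays import ElectrodeArray
from .slice_sim import CalciumConfig, movie_geometry

__all__ = [
    "ROISet",
    "make_rois",
    "extract_traces",
    "correct_flicker",
    "correct_bleach",
    "compute_dff",
    "response_map",
    "population_map",
    "network_assay",
    "ResponseMap",
    "PopulationMap",
    "AssayResult",
]


@dataclass
class ROISet:
    """Circular ROIs around assayed electrodes.

    ``table`` columns: roi (int id == linked electrode channel), x_px, y_px,
    radius_px, x_um, y_um.
    """

    table: pd.DataFrame
    frame_shape: tuple[int, int]

    @property
    def channels(self) -> list[int]:
        return [int(c) for c in self.table["roi"]]

    def __len__(self) -> int:
        return len(self.table)


def make_rois(
    array: ElectrodeArray,
    channels: list[int] | None = None,
    calcium: CalciumConfig | None = None,
    radius_um: float = 80.0,
) -> ROISet:
    """One ROI per assayed electrode, placed at the electrode's pixel position."""
    cfg = calcium or CalciumConfig()
    x0, y0, um_per_px = movie_geometry(array, cfg)
    h, w = cfg.shape
    rows = []
    for ch in channels if channels is not None else range(array.n_channels):
        ex, ey = array.position_um(ch)
        x_px = (ex - x0) / um_per_px
        y_px = (ey - y0) / um_per_px
        if not (0 <= x_px < w and 0 <= y_px < h):
            raise ValueError(f"ROI for channel {ch} falls outside the frame")
        rows.append(
            {"roi": ch, "x_px": x_px, "y_px": y_px,
             "radius_px": radius_um / um_per_px, "x_um": ex, "y_um": ey}
        )
    return ROISet(table=pd.DataFrame(rows), frame_shape=cfg.shape)


def extract_traces(movie: np.ndarray, rois: ROISet) -> pd.DataFrame:
    """Mean fluorescence per ROI per frame; columns are ROI ids."""
    movie = np.asarray(movie)
    n_frames, h, w = movie.shape
    yy, xx = np.mgrid[0:h, 0:w]
    flat = movie.reshape(n_frames, -1)
    data = {}
    for row in rois.table.itertuples():
        mask = ((xx - row.x_px) ** 2 + (yy - row.y_px) ** 2) <= row.radius_px**2
        idx = np.flatnonzero(mask.ravel())
        if idx.size == 0:  # degenerate tiny ROI: nearest pixel
            idx = np.array([int(round(row.y_px)) * w + int(round(row.x_px))])
        data[int(row.roi)] = flat[:, idx].mean(axis=1)
    return pd.DataFrame(data)


def correct_flicker(traces: pd.DataFrame) -> pd.DataFrame:
    """Divide out common-mode lamp flicker.

    The per-frame flicker estimate is the median across ROIs of each ROI's
    trace normalized by its own median brightness — robust to a minority of
    ROIs carrying stimulus responses.
    """
    norm = traces / traces.median(axis=0)
    common = norm.median(axis=1).replace(0, np.nan).ffill().bfill()
    return traces.div(common, axis=0)


def correct_bleach(
    traces: pd.DataFrame,
    frame_times_s: np.ndarray,
    stim_onsets_s: np.ndarray | None = None,
    exclude_post_s: float = 3.0,
) -> pd.DataFrame:
    """Divide out monotone photobleaching, per ROI.

    A single exponential ``a * exp(-t/tau) + c`` is fit to stimulus-free
    samples (everything outside ``exclude_post_s`` after each stimulus) and
    divided out after normalizing to its initial value, so an event-free
    decaying trace becomes flat.  Falls back to no correction when the fit
    cannot improve on a flat baseline.
    """
    t = np.asarray(frame_times_s, dtype=float)
    mask = np.ones(len(t), dtype=bool)
    if stim_onsets_s is not None:
        for s in np.asarray(stim_onsets_s, dtype=float):
            mask &= ~((t >= s) & (t <= s + exclude_post_s))
    if mask.sum() < 4:
        mask = np.ones(len(t), dtype=bool)
    out = {}
    for col in traces.columns:
        y = traces[col].to_numpy(dtype=float)
        yb, tb = y[mask], t[mask]
        f0 = np.median(yb[: max(1, len(yb) // 10)])
        tau0 = max(t[-1], 1.0)

        def model(tt, a, tau, c):
            return a * np.exp(-tt / tau) + c

        try:
            popt, _ = optimize.curve_fit(
                model, tb, yb,
                p0=[max(f0 - yb[-1], 1e-3), tau0, min(yb[-1], f0)],
                bounds=([0, 1e-3, -np.inf], [np.inf, np.inf, np.inf]),
                maxfev=5000,
            )
            fit = model(t, *popt)
            if fit[0] <= 0 or np.any(fit <= 0):
                raise RuntimeError
            out[col] = y / (fit / fit[0])
        except Exception:
            out[col] = y
    return pd.DataFrame(out, index=traces.index)


def compute_dff(
    traces: pd.DataFrame,
    frame_times_s: np.ndarray,
    stim_onsets_s: np.ndarray,
    baseline_s: float = 0.5,
    peak_s: float = 1.0,
) -> pd.DataFrame:
    """Stimulus-locked ΔF/F%% per (stimulus, ROI).

    baseline = mean over the ``baseline_s`` window before the stimulus;
    peak = max over the ``peak_s`` window after it;
    dff_percent = 100 * (peak − baseline) / baseline.
    """
    t = np.asarray(frame_times_s, dtype=float)
    rows = []
    for k, s in enumerate(np.asarray(stim_onsets_s, dtype=float)):
        pre = (t >= s - baseline_s) & (t < s)
        post = (t >= s) & (t <= s + peak_s)
        if not pre.any() or not post.any():
            continue
        for col in traces.columns:
            y = traces[col].to_numpy(dtype=float)
            base = float(y[pre].mean())
            peak = float(y[post].max())
            if base <= 0:
                raise ValueError(f"non-positive baseline for ROI {col} at stimulus {k}")
            rows.append(
                {"stimulus": k, "onset_s": s, "roi": int(col),
                 "baseline_f": base, "peak_f": peak,
                 "dff_percent": 100.0 * (peak - base) / base}
            )
    return pd.DataFrame(rows)


@dataclass
class ResponseMap:
    """ΔF/F%% responses to one stimulus, on the electrode grid + interpolated field."""

    array: ElectrodeArray
    grid: np.ndarray                  # (n_rows, n_cols), NaN where not assayed
    field: np.ndarray                 # bilinear upsampling of the grid
    stim_channel: int | None = None

    def argmax_rowcol(self) -> tuple[int, int]:
        g = np.where(np.isnan(self.grid), -np.inf, self.grid)
        return tuple(int(i) for i in np.unravel_index(np.argmax(g), g.shape))


def response_map(
    dff_events: pd.DataFrame,
    array: ElectrodeArray,
    stim_channel: int | None = None,
    upsample: int = 8,
) -> ResponseMap:
    """Grid + bilinearly interpolated map of per-ROI ΔF/F for one stimulus.

    ``dff_events`` holds one row per ROI (the rows of a DFF table for a
    single stimulus).  The interpolated field passes through the measured
    ROI values.
    """
    grid = np.full((array.n_rows, array.n_cols), np.nan)
    for row in dff_events.itertuples():
        r, c = array.rowcol_of(int(row.roi))
        grid[r, c] = row.dff_percent
    filled = np.where(np.isnan(grid), np.nanmin(grid) if np.isfinite(np.nanmin(grid)) else 0.0, grid)
    rr = np.arange(array.n_rows)
    cc = np.arange(array.n_cols)
    interp = interpolate.RegularGridInterpolator(
        (rr, cc), filled, method="linear", bounds_error=False, fill_value=None
    )
    # step 1/upsample so every electrode node lies exactly on a field sample
    fr = np.linspace(0, array.n_rows - 1, (array.n_rows - 1) * upsample + 1)
    fc = np.linspace(0, array.n_cols - 1, (array.n_cols - 1) * upsample + 1)
    mesh = np.stack(np.meshgrid(fr, fc, indexing="ij"), axis=-1)
    field = interp(mesh)
    return ResponseMap(array=array, grid=grid, field=field, stim_channel=stim_channel)


@dataclass
class PopulationMap:
    """Response maps aligned on the stimulation electrode and averaged.

    ``aligned_mean`` is indexed by (row offset, col offset) from the
    stimulated electrode; offsets span ±(n_rows−1), ±(n_cols−1).
    """

    aligned_mean: np.ndarray
    aligned_count: np.ndarray
    row_offsets: np.ndarray
    col_offsets: np.ndarray

    def at_offset(self, dr: int, dc: int) -> float:
        i = int(np.flatnonzero(self.row_offsets == dr)[0])
        j = int(np.flatnonzero(self.col_offsets == dc)[0])
        return float(self.aligned_mean[i, j])


def population_map(maps: list[ResponseMap]) -> PopulationMap:
    """Align response maps on their stimulation electrodes and average."""
    if not maps:
        raise ValueError("population_map requires at least one response map")
    array = maps[0].array
    n_r, n_c = array.n_rows, array.n_cols
    row_off = np.arange(-(n_r - 1), n_r)
    col_off = np.arange(-(n_c - 1), n_c)
    acc = np.zeros((len(row_off), len(col_off)))
    cnt = np.zeros_like(acc)
    for m in maps:
        if m.stim_channel is None:
            raise ValueError("response map lacks a stimulation channel for alignment")
        sr, sc = array.rowcol_of(m.stim_channel)
        for r in range(n_r):
            for c in range(n_c):
                v = m.grid[r, c]
                if np.isnan(v):
                    continue
                i = (r - sr) + (n_r - 1)
                j = (c - sc) + (n_c - 1)
                acc[i, j] += v
                cnt[i, j] += 1
    with np.errstate(invalid="ignore"):
        mean = np.where(cnt > 0, acc / np.maximum(cnt, 1), np.nan)
    return PopulationMap(aligned_mean=mean, aligned_count=cnt, row_offsets=row_off, col_offsets=col_off)


@dataclass
class AssayResult:
    """Before/after network comparison across ROIs."""

    per_roi: pd.DataFrame          # roi, before, after, ratio
    mean_ratio: float
    t_statistic: float
    p_value: float
    n_rois: int

    @property
    def median_ratio(self) -> float:
        """Robust central after/before ratio (stable when weak ROIs make
        individual ratios noisy)."""
        return float(self.per_roi["ratio"].median())

    def to_dict(self) -> dict:
        return {
            "n_rois": self.n_rois,
            "mean_ratio": self.mean_ratio,
            "median_ratio": self.median_ratio,
            "t_statistic": self.t_statistic,
            "p_value": self.p_value,
        }


def network_assay(before: pd.DataFrame, after: pd.DataFrame) -> AssayResult:
    """Paired before/after comparison of per-ROI responses.

    ``before`` and ``after`` are DFF tables over the same ROI set (one
    response per ROI, e.g. each ROI's response to its own stimulation in a
    sequence scan; repeated stimuli are averaged per ROI first).  Reports
    per-ROI after/before ratios, their mean, and a paired two-tailed t-test
    across ROIs.
    """
    b = before.groupby("roi")["dff_percent"].mean()
    a = after.groupby("roi")["dff_percent"].mean()
    if set(b.index) != set(a.index):
        raise ValueError("before/after ROI sets do not match")
    b, a = b.sort_index(), a.sort_index()
    ratio = a / b
    diffs = a.to_numpy() - b.to_numpy()
    if np.allclose(diffs, 0.0):
        t_stat, p = 0.0, 1.0
    else:
        t_stat, p = stats.ttest_rel(a.to_numpy(), b.to_numpy())
    per_roi = pd.DataFrame({"roi": b.index, "before": b.to_numpy(),
                            "after": a.to_numpy(), "ratio": ratio.to_numpy()})
    return AssayResult(
        per_roi=per_roi,
        mean_ratio=float(ratio.mean()),
        t_statistic=float(t_stat),
        p_value=float(p),
        n_rois=len(b),
    )


def save_heatmap(grid: np.ndarray, path: str | Path, title: str = "") -> None:
    """Render a response grid to an image file (for reports)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    im = ax.imshow(grid, cmap="viridis")
    fig.colorbar(im, ax=ax, label="dF/F %")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
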