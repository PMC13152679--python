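"""Grid-mask ROI analysis of evoked release movies.

A non-overlapping square grid (8×8 pixels by default) is tiled over the
ΔF/F movie; each square's trace is the spatial mean of its pixels.  A square
is called an active ROI when its peak post-stimulus ΔF/F exceeds the
baseline mean by more than k standard deviations (k = 2), with baseline
statistics computed per square on its own pre-stimulus ΔF/F frames — the
spatial heterogeneity of release is exactly what the analysis is after, so
no pooling across squares.  With repeated stimulations, peaks and baseline
statistics are averaged across trials per square before thresholding.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import MovieStack, Trace

logger = logging.getLogger(__name__)

__all__ = [
    "GridMask",
    "GridTraces",
    "GridResponseMap",
    "ConditionComparison",
    "apply_grid",
    "detect_active_rois",
    "integrated_response",
    "compare_conditions",
    "save_heatmap",
]

DEFAULT_RESPONSE_WINDOW_S = 30.0


@dataclass(frozen=True)
class GridMask:
    """Geometry of the square tiling (anchored at the top-left pixel)."""

    square_px: int
    n_rows: int
    n_cols: int
    pixel_size: float

    @property
    def square_um(self) -> float:
        return self.square_px * self.pixel_size

    def bounds(self, row: int, col: int) -> tuple[int, int, int, int]:
        """(y0, y1, x0, x1) pixel bounds of one square (half-open)."""
        s = self.square_px
        return row * s, (row + 1) * s, col * s, (col + 1) * s


@dataclass
class GridTraces:
    """Per-square mean ΔF/F traces: array (n_rows, n_cols, T)."""

    traces: np.ndarray
    frame_rate: float
    mask: GridMask
    stim_frames: tuple[int, ...] = ()

    @property
    def n_frames(self) -> int:
        return self.traces.shape[2]

    def square(self, row: int, col: int) -> Trace:
        return Trace(self.traces[row, col], self.frame_rate)


@dataclass
class GridResponseMap:
    """Per-square baseline statistics, peak responses and activity calls."""

    baseline_mean: np.ndarray
    baseline_sd: np.ndarray
    peak: np.ndarray
    active: np.ndarray
    degenerate: np.ndarray
    traces: np.ndarray  # trial-mean ΔF/F traces, (n_rows, n_cols, T)
    frame_rate: float
    mask: GridMask
    stim_frame: int
    response_window: tuple[int, int]
    k: float

    @property
    def n_squares(self) -> int:
        return self.active.size

    @property
    def n_active(self) -> int:
        return int(self.active.sum())

    @property
    def percent_active(self) -> float:
        return 100.0 * self.n_active / self.n_squares

    def integrated_peak(self) -> float:
        """Peak of the spatial-mean ΔF/F trace within the response window."""
        field = self.traces.mean(axis=(0, 1))
        lo, hi = self.response_window
        return float(field[lo:hi].max())

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for r in range(self.mask.n_rows):
            for c in range(self.mask.n_cols):
                rows.append(
                    {
                        "row": r,
                        "col": c,
                        "baseline_mean": self.baseline_mean[r, c],
                        "baseline_sd": self.baseline_sd[r, c],
                        "peak": self.peak[r, c],
                        "active": bool(self.active[r, c]),
                        "degenerate": bool(self.degenerate[r, c]),
                    }
                )
        return pd.DataFrame(rows)


def apply_grid(dff: MovieStack, square_px: int = 8) -> tuple[GridTraces, GridMask]:
    """Tile the movie with non-overlapping squares and average each square.

    The tiling is anchored at the top-left pixel; trailing rows/columns that
    do not fill a whole square are discarded (logged), so every square has
    identical area.
    """
    if square_px < 1:
        raise ValueError("square_px must be >= 1")
    t, h, w = dff.data.shape
    if h < square_px or w < square_px:
        raise ValueError(f"image {h}×{w} smaller than square_px={square_px}")
    n_rows, n_cols = h // square_px, w // square_px
    dropped = (h - n_rows * square_px) * w + (w - n_cols * square_px) * n_rows * square_px
    if dropped:
        logger.info(
            "apply_grid: discarding %d edge pixels outside the %d×%d tiling",
            dropped, n_rows, n_cols,
        )
    trimmed = dff.data[:, : n_rows * square_px, : n_cols * square_px].astype(float)
    # (T, R, s, C, s) -> mean over the two square axes -> (R, C, T)
    blocks = trimmed.reshape(t, n_rows, square_px, n_cols, square_px)
    traces = blocks.mean(axis=(2, 4)).transpose(1, 2, 0)
    mask = GridMask(square_px, n_rows, n_cols, dff.pixel_size)
    return GridTraces(traces, dff.frame_rate, mask, dff.stim_frames), mask


def detect_active_rois(
    grid: GridTraces | list[GridTraces],
    stim_frame: int,
    k: float = 2.0,
    response_window: tuple[int, int] | None = None,
) -> GridResponseMap:
    """Call active ROIs by the k-SD criterion (k = 2 by default).

    Per square, the baseline mean and sample SD are computed over the ΔF/F
    frames before ``stim_frame`` and the peak is the maximum ΔF/F within
    ``response_window`` (default: stimulus to stimulus + 30 s).  A square is
    active iff peak > mean + k·SD (strict).  When several trials are given,
    per-trial peaks and baseline statistics are averaged per square before
    thresholding.  Squares with zero baseline SD in every trial are flagged
    degenerate; a fully constant square can never be active because the
    inequality is strict.
    """
    trials = grid if isinstance(grid, list) else [grid]
    if not trials:
        raise ValueError("no grid traces supplied")
    shape = trials[0].traces.shape
    fr = trials[0].frame_rate
    mask = trials[0].mask
    for tr in trials[1:]:
        if tr.traces.shape != shape or tr.mask != mask:
            raise ValueError("trials must share grid geometry")
    n_frames = shape[2]
    if not 3 <= stim_frame < n_frames:
        raise ValueError("stim_frame must leave at least 3 baseline frames")
    if response_window is None:
        hi = min(n_frames, stim_frame + int(round(DEFAULT_RESPONSE_WINDOW_S * fr)) + 1)
        response_window = (stim_frame, hi)
    lo, hi = response_window
    if lo < stim_frame or hi <= lo or hi > n_frames:
        raise ValueError(f"invalid response window {response_window}")

    means, sds, peaks = [], [], []
    for tr in trials:
        base = tr.traces[:, :, :stim_frame]
        means.append(base.mean(axis=2))
        sds.append(base.std(axis=2, ddof=1))
        peaks.append(tr.traces[:, :, lo:hi].max(axis=2))
    baseline_mean = np.mean(means, axis=0)
    baseline_sd = np.mean(sds, axis=0)
    peak = np.mean(peaks, axis=0)
    degenerate = np.all([s == 0 for s in sds], axis=0)
    active = peak > baseline_mean + k * baseline_sd
    if degenerate.any():
        logger.warning(
            "detect_active_rois: %d squares have zero baseline SD", int(degenerate.sum())
        )
    mean_traces = np.mean([tr.traces for tr in trials], axis=0)
    return GridResponseMap(
        baseline_mean=baseline_mean,
        baseline_sd=baseline_sd,
        peak=peak,
        active=active,
        degenerate=degenerate,
        traces=mean_traces,
        frame_rate=fr,
        mask=mask,
        stim_frame=stim_frame,
        response_window=(lo, hi),
        k=k,
    )


def integrated_response(
    dff: MovieStack, window: tuple[int, int]
) -> tuple[Trace, float]:
    """Spatial mean over the full field per frame, plus its peak in a window."""
    lo, hi = window
    if not 0 <= lo < hi <= dff.n_frames:
        raise ValueError(f"window {window} outside movie of {dff.n_frames} frames")
    trace = dff.mean_trace()
    return trace, float(trace.values[lo:hi].max())


@dataclass
class ConditionComparison:
    """Active-ROI percentage and integrated peak ΔF/F, before vs after.

    ``delta_*`` are fractional changes relative to the *before* condition
    ((after − before)/before); a −0.7 ROI delta reads as a 70% reduction.
    """

    percent_active_before: float
    percent_active_after: float
    integrated_peak_before: float
    integrated_peak_after: float
    delta_percent_active: float
    delta_integrated_peak: float


def save_heatmap(rmap: GridResponseMap, path, what: str = "peak") -> None:
    """Write a per-square heat map (peak ΔF/F or active mask) as PNG.

    Requires matplotlib (the ``plot`` extra); the analysis itself never
    depends on it.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if what == "peak":
        img, label = rmap.peak, "peak ΔF/F"
    elif what == "active":
        img, label = rmap.active.astype(float), "active ROI"
    else:
        raise ValueError(f"unknown heat-map kind {what!r}")
    fig, ax = plt.subplots(figsize=(4, 4))
    im = ax.imshow(img, cmap="inferno", interpolation="nearest")
    ax.set_xlabel("grid column")
    ax.set_ylabel("grid row")
    fig.colorbar(im, ax=ax, label=label)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def _frac_change(before: float, after: float) -> float:
    if before == 0:
        return 0.0 if after == 0 else np.inf
    return (after - before) / before


def compare_conditions(
    before: GridResponseMap, after: GridResponseMap
) -> ConditionComparison:
    """Compare two conditions square by square (e.g. control vs quinpirole).

    Both maps must share grid geometry and stimulus protocol; squares are
    paired by grid index.
    """
    if before.mask != after.mask or before.traces.shape != after.traces.shape:
        raise ValueError("grid geometry mismatch between conditions")
    if before.stim_frame != after.stim_frame or before.response_window != after.response_window:
        raise ValueError("stimulus protocol mismatch between conditions")
    pb, pa = before.percent_active, after.percent_active
    ib, ia = before.integrated_peak(), after.integrated_peak()
    return ConditionComparison(
        percent_active_before=pb,
        percent_active_after=pa,
        integrated_peak_before=ib,
        integrated_peak_after=ia,
        delta_percent_active=_frac_change(pb, pa),
        delta_integrated_peak=_frac_change(ib, ia),
    )
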