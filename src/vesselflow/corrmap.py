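"""ROI-grid binning and signed lagged cross-correlation maps.

The movie is tiled into square ROIs by block averaging; each ROI trace is
correlated against a reference trace (another ROI or a pupil diameter
trace) over integer lags within a sliding window.  The lag maximizing the
absolute coefficient is chosen but the *signed* coefficient is reported,
so anticorrelated vessel populations appear with opposite signs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["RoiGrid", "CorrelationMap", "bin_rois", "lagged_max_correlation", "correlation_map"]


@dataclass
class RoiGrid:
    """Grid of per-ROI mean-intensity traces, shape (rows, cols, T)."""

    traces: np.ndarray
    roi_px: int
    pixel_size: float
    frame_interval: float

    @property
    def shape(self) -> tuple[int, int]:
        return self.traces.shape[:2]


@dataclass
class CorrelationMap:
    """Signed coefficients and best lags per ROI."""

    cc: np.ndarray  # (rows, cols) in [-1, 1]
    lag: np.ndarray  # (rows, cols) frames
    valid: np.ndarray  # False where the ROI trace was constant
    reference: str = ""


def bin_rois(movie, roi_px: int = 16) -> RoiGrid:
    """Block-average the movie into square ROIs of ``roi_px`` pixels.

    Trailing rows/columns that do not fill a block are cropped.
    """
    data = np.asarray(movie.data, dtype=float)
    T, h, w = data.shape
    rows, cols = h // roi_px, w // roi_px
    if rows == 0 or cols == 0:
        raise ValueError(f"frame {h}x{w} smaller than one {roi_px}-px ROI")
    d = data[:, : rows * roi_px, : cols * roi_px]
    blocks = d.reshape(T, rows, roi_px, cols, roi_px).mean(axis=(2, 4))
    traces = np.moveaxis(blocks, 0, -1)  # (rows, cols, T)
    return RoiGrid(traces=traces, roi_px=roi_px, pixel_size=movie.pixel_size,
                   frame_interval=movie.frame_interval)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom == 0:
        return np.nan
    return float((a * b).sum() / denom)


def lagged_max_correlation(x: np.ndarray, y: np.ndarray,
                           max_lag: int = 10) -> tuple[float, int]:
    """Signed Pearson coefficient at the lag maximizing |coefficient|.

    Lag L > 0 means ``y`` lags (is delayed relative to) ``x`` by L frames;
    the coefficient at each lag is computed over the overlapping samples.
    Ties go to the smaller |lag|.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("series must have equal length")
    if x.size <= 2 * max_lag:
        raise ValueError(f"series length {x.size} must exceed 2*max_lag = {2 * max_lag}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant series: correlation undefined")
    best_cc, best_lag = 0.0, 0
    have = False
    # visit lags in order of increasing |lag| so ties keep the smaller one
    for a in range(max_lag + 1):
        for lag in ([a] if a == 0 else [a, -a]):
            if lag >= 0:
                xx, yy = x[: x.size - lag], y[lag:]
            else:
                xx, yy = x[-lag:], y[: y.size + lag]
            cc = _pearson(xx, yy)
            if np.isnan(cc):
                continue
            if not have or abs(cc) > abs(best_cc):
                best_cc, best_lag, have = cc, lag, True
    if not have:
        raise ValueError("correlation undefined at every lag")
    return best_cc, best_lag


def correlation_map(grid: RoiGrid, reference: np.ndarray, max_lag: int = 10,
                    reference_interval: float | None = None,
                    label: str = "") -> CorrelationMap:
    """Signed lagged correlation of every ROI trace against a reference.

    ROI traces are median-baseline ΔF/F-normalized before correlation
    (Pearson is affine-invariant, but this keeps traces inspectable).
    A reference sampled on a different timebase is linearly resampled
    onto the grid's frame times.  Constant ROIs get cc = 0 and are
    flagged invalid.
    """
    rows, cols, T = grid.traces.shape
    reference = np.asarray(reference, dtype=float)
    if reference_interval is not None and reference_interval != grid.frame_interval:
        t_grid = np.arange(T) * grid.frame_interval
        t_ref = np.arange(reference.size) * reference_interval
        reference = np.interp(t_grid, t_ref, reference)
    if reference.size != T:
        raise ValueError("reference length does not match the grid timebase")
    cc = np.zeros((rows, cols))
    lag = np.zeros((rows, cols), dtype=int)
    valid = np.ones((rows, cols), dtype=bool)
    for r in range(rows):
        for c in range(cols):
            trace = grid.traces[r, c]
            if np.ptp(trace) == 0:
                cc[r, c] = 0.0
                valid[r, c] = False
                continue
            baseline = np.median(trace)
            if baseline > 0:
                trace = (trace - baseline) / baseline
            cc[r, c], lag[r, c] = lagged_max_correlation(trace, reference, max_lag)
    return CorrelationMap(cc=cc, lag=lag, valid=valid, reference=label)
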