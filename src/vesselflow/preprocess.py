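"""Registration, smoothing, binning and normalization steps applied
before any measurement."""

from __future__ import annotations

import warnings

import numpy as np
from scipy.ndimage import uniform_filter1d

from vesselflow.core import Movie

__all__ = [
    "register_rigid",
    "moving_average",
    "temporal_bin",
    "subtract_local_background",
    "sqrt_display_normalize",
]


def _translate(frame: np.ndarray, dy: int, dx: int, fill: float) -> np.ndarray:
    out = np.full_like(frame, fill)
    h, w = frame.shape
    out[max(dy, 0):min(h + dy, h), max(dx, 0):min(w + dx, w)] = \
        frame[max(-dy, 0):min(h - dy, h), max(-dx, 0):min(w - dx, w)]
    return out


def _best_shift(ref_f: np.ndarray, frame: np.ndarray, shape: tuple[int, int]) -> tuple[int, int]:
    """Integer (dy, dx) by which ``frame`` is displaced relative to the reference.

    Argmax of the circular cross-correlation (FFT); exact ties broken
    toward the smaller |shift|.
    """
    cc = np.fft.irfft2(ref_f * np.conj(np.fft.rfft2(frame)), s=shape)
    # wrap indices to signed shifts
    peak = cc.max()
    candidates = np.argwhere(np.isclose(cc, peak, rtol=0, atol=1e-9 * max(abs(peak), 1.0)))
    h, w = shape
    best = None
    best_key = None
    for r, c in candidates:
        dy = int(r) if r <= h // 2 else int(r) - h
        dx = int(c) if c <= w // 2 else int(c) - w
        key = (abs(dy) + abs(dx), abs(dy), abs(dx), dy, dx)
        if best_key is None or key < best_key:
            best_key = key
            best = (dy, dx)
    return best


def register_rigid(movie: Movie, n_reference: int = 30) -> tuple[Movie, np.ndarray]:
    """Remove rigid lateral motion by integer-pixel translation.

    Each frame is translated to maximize its cross-correlation with a
    reference (the mean of the first ``n_reference`` frames).  Returns the
    registered movie and the (T, 2) array of (dy, dx) corrections applied
    to each frame; out-of-field pixels are filled with the frame median.
    """
    data = np.asarray(movie.data, dtype=float)
    T = data.shape[0]
    if T < 2:
        raise ValueError("registration needs at least 2 frames")
    if np.ptp(data) == 0:
        warnings.warn("all-constant movie: registration returns zero shifts")
        return movie.with_data(data.copy()), np.zeros((T, 2), dtype=int)
    shape = data.shape[1:]
    # build the reference progressively: each of the first frames is
    # registered against the mean of the frames already registered, so the
    # reference is sharp and anchored to frame 0's position
    n_ref = min(n_reference, T)
    accum = data[0].copy()
    for f in range(1, n_ref):
        ref = accum / f
        ref_f = np.fft.rfft2(ref - ref.mean())
        dy, dx = _best_shift(ref_f, data[f] - data[f].mean(), shape)
        accum += _translate(data[f], dy, dx, float(np.median(data[f])))
    ref = accum / n_ref
    ref_f = np.fft.rfft2(ref - ref.mean())
    out = np.empty_like(data)
    shifts = np.zeros((T, 2), dtype=int)
    for f in range(T):
        dy, dx = _best_shift(ref_f, data[f] - data[f].mean(), shape)
        # the frame sits at (-dy, -dx) relative to the reference; undo it
        shifts[f] = (dy, dx)
        fill = float(np.median(data[f]))
        out[f] = _translate(data[f], dy, dx, fill)
    return movie.with_data(out), shifts


def moving_average(series: np.ndarray, window: int, axis: int = 0) -> np.ndarray:
    """Centered moving average with truncated windows at the edges.

    ``window`` must be odd so the window is symmetric; length preserved.
    Works on 1D traces and on movies (``axis=0`` averages over frames).
    """
    series = np.asarray(series, dtype=float)
    n = series.shape[axis]
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be a positive odd integer, got {window}")
    if window > n:
        raise ValueError(f"window {window} exceeds series length {n}")
    summed = uniform_filter1d(series, window, axis=axis, mode="constant", cval=0.0) * window
    counts = uniform_filter1d(np.ones(n), window, mode="constant", cval=0.0) * window
    shape = [1] * series.ndim
    shape[axis] = n
    return summed / counts.reshape(shape)


def temporal_bin(movie: Movie, bin_seconds: float) -> Movie:
    """Non-overlapping temporal mean bins; the trailing partial bin is dropped."""
    if bin_seconds < movie.frame_interval:
        raise ValueError("bin length must be at least one frame interval")
    per_bin = int(round(bin_seconds / movie.frame_interval))
    n_bins = movie.n_frames // per_bin
    if n_bins == 0:
        raise ValueError("movie shorter than one bin")
    d = movie.data[: n_bins * per_bin]
    binned = d.reshape(n_bins, per_bin, *d.shape[1:]).mean(axis=1)
    return movie.with_data(binned, frame_interval=per_bin * movie.frame_interval)


def _roi_mean(data: np.ndarray, roi: tuple[int, int, int, int]) -> np.ndarray:
    r0, r1, c0, c1 = roi
    region = data[:, r0:r1, c0:c1]
    if region.size == 0:
        raise ValueError(f"empty ROI {roi}")
    return region.mean(axis=(1, 2))


def _rois_disjoint(a: tuple[int, int, int, int], b: tuple[int, int, int, int]) -> bool:
    return a[1] <= b[0] or b[1] <= a[0] or a[3] <= b[2] or b[3] <= a[2]


def subtract_local_background(movie: Movie, capillary_roi: tuple[int, int, int, int],
                              bg_roi: tuple[int, int, int, int]) -> Movie:
    """Frame-by-frame subtraction of a nearby background ROI's mean, adding
    back the session-averaged background so absolute levels are preserved.

    ROIs are (row0, row1, col0, col1); the vessel ROI and background ROI
    must be disjoint.  The correction is applied to the whole frame so any
    downstream ROI extraction sees it.
    """
    if not _rois_disjoint(capillary_roi, bg_roi):
        raise ValueError("capillary ROI and background ROI must be disjoint")
    _roi_mean(movie.data, capillary_roi)  # validates non-emptiness
    bg = _roi_mean(movie.data, bg_roi)
    out = movie.data - bg[:, None, None] + bg.mean()
    return movie.with_data(out)


def sqrt_display_normalize(image: np.ndarray) -> np.ndarray:
    """Square-root display normalization mapped to [0, 1].

    Negatives are clipped to 0 before the square root; a constant image
    maps to all zeros with a warning.
    """
    image = np.asarray(image, dtype=float)
    root = np.sqrt(np.clip(image, 0.0, None))
    lo, hi = root.min(), root.max()
    if hi == lo:
        warnings.warn("constant image: sqrt display normalization returns zeros")
        return np.zeros_like(root)
    return (root - lo) / (hi - lo)
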