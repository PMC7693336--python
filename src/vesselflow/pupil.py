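"""Pupil diameter extraction from infrared eye videos.

Each frame is binarized below an automatic threshold, the largest dark
connected component is kept, and an oval is fitted from its second
moments.  The axis-aligned *width* of the fitted oval is used as pupil
diameter (less sensitive to squinting/blinking than the height).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import binary_fill_holes
from skimage.filters import threshold_minimum
from skimage.measure import label, regionprops

from vesselflow.core import Movie

__all__ = ["PupilOval", "PupilTrace", "segment_pupil", "pupil_diameter_trace"]


@dataclass
class PupilOval:
    center: tuple[float, float]  # (row, col)
    width: float  # axis-aligned horizontal extent, px
    height: float  # axis-aligned vertical extent, px
    angle: float  # principal-axis orientation, rad


@dataclass
class PupilTrace:
    """Per-frame pupil geometry; invalid frames are interpolated."""

    t: np.ndarray  # s
    width: np.ndarray  # px (or mm if calibrated upstream)
    height: np.ndarray = None
    center: np.ndarray = None  # (T, 2) row/col
    valid: np.ndarray = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.width = np.asarray(self.width, dtype=float)
        if self.valid is None:
            self.valid = np.ones(self.t.shape, dtype=bool)


def _auto_threshold(frame: np.ndarray) -> float:
    """Histogram-valley threshold with a low-quantile fallback."""
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return float(threshold_minimum(frame))
    except RuntimeError:
        return float(np.percentile(frame, 5.0))


def segment_pupil(frame: np.ndarray, min_area: int = 25) -> PupilOval | None:
    """Fit the pupil of one frame as an oval; ``None`` if no dark blob found.

    The oval is the moment-matched ellipse of the largest dark component
    (holes filled, so a specular reflection inside the pupil does not bias
    the fit).  For a uniform ellipse the variance along an axis is
    (semi-axis)^2 / 4, so the axis-aligned full extents are
    4*sqrt(var_col) and 4*sqrt(var_row).
    """
    frame = np.asarray(frame, dtype=float)
    if np.ptp(frame) == 0:
        return None
    thr = _auto_threshold(frame)
    mask = frame <= thr
    if not mask.any() or mask.all():
        return None
    mask = binary_fill_holes(mask)
    labels = label(mask)
    props = regionprops(labels)
    best = max(props, key=lambda p: p.area)
    if best.area < min_area:
        return None
    coords = best.coords.astype(float)
    cy, cx = coords.mean(axis=0)
    var_r = coords[:, 0].var()
    var_c = coords[:, 1].var()
    cov_rc = ((coords[:, 0] - cy) * (coords[:, 1] - cx)).mean()
    angle = 0.5 * np.arctan2(2.0 * cov_rc, var_c - var_r)
    return PupilOval(center=(float(cy), float(cx)),
                     width=4.0 * float(np.sqrt(var_c)),
                     height=4.0 * float(np.sqrt(var_r)),
                     angle=float(angle))


def pupil_diameter_trace(video: Movie, min_area: int = 25) -> PupilTrace:
    """Per-frame pupil width; invalid frames linearly interpolated."""
    T = video.n_frames
    width = np.full(T, np.nan)
    height = np.full(T, np.nan)
    center = np.full((T, 2), np.nan)
    valid = np.zeros(T, dtype=bool)
    for f in range(T):
        oval = segment_pupil(video.data[f], min_area=min_area)
        if oval is None:
            continue
        width[f] = oval.width
        height[f] = oval.height
        center[f] = oval.center
        valid[f] = True
    if not valid.any():
        raise ValueError("no valid pupil frame found in the video")
    idx = np.arange(T)
    good = idx[valid]
    for arr in (width, height, center[:, 0], center[:, 1]):
        arr[~valid] = np.interp(idx[~valid], good, arr[good])
    return PupilTrace(t=video.times, width=width, height=height,
                      center=center, valid=valid)
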