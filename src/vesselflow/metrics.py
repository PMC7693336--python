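"""Size and brightness measurement of vessel segments and their dynamics.

The probe geometry mirrors the manual workflow: a short line drawn
perpendicular to a vessel, 1-pixel thick for static size/brightness
readouts and 10-pixel thick for diameter time series, plus a nearby
vessel-free rectangle used to derive a common intensity threshold
(mean + 3 standard deviations of the background).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates
from scipy.stats import pearsonr

from vesselflow.core import Movie, Stack
from vesselflow.optics import NoCrossingError, fwhm_of_profile

__all__ = [
    "SegmentProbe",
    "common_threshold",
    "sample_line",
    "bessel_segment_measure",
    "gaussian_cross_section_measure",
    "diameter_timeseries",
    "dff",
    "size_brightness_correlation",
    "temporal_variation_map",
]


@dataclass
class SegmentProbe:
    """Measurement line perpendicular to a vessel.

    ``p0``/``p1`` are (x, y) pixel coordinates; ``thickness`` is the probe
    width in pixels (1 for static size, 10 for time series);
    ``bg_region`` is a vessel-free (row0, row1, col0, col1) rectangle.
    """

    p0: tuple[float, float]
    p1: tuple[float, float]
    thickness: int = 1
    bg_region: tuple[int, int, int, int] | None = None

    def __post_init__(self) -> None:
        if self.thickness < 1:
            raise ValueError("probe thickness must be >= 1")
        if np.allclose(self.p0, self.p1):
            raise ValueError("probe endpoints must be distinct")


def common_threshold(image: np.ndarray, bg_region: tuple[int, int, int, int]) -> float:
    """Background mean + 3 sample standard deviations."""
    r0, r1, c0, c1 = bg_region
    bg = np.asarray(image, dtype=float)[r0:r1, c0:c1]
    if bg.size == 0:
        raise ValueError(f"empty background region {bg_region}")
    if bg.size == 1:
        return float(bg.ravel()[0])
    return float(bg.mean() + 3.0 * bg.std(ddof=1))


def _line_coords(p0, p1, offset: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
    """(rows, cols) sampled at 1-pixel arc steps, optionally offset along
    the line normal by ``offset`` pixels."""
    x0, y0 = p0
    x1, y1 = p1
    length = float(np.hypot(x1 - x0, y1 - y0))
    n = int(round(length)) + 1
    frac = np.linspace(0.0, 1.0, n)
    xs = x0 + frac * (x1 - x0)
    ys = y0 + frac * (y1 - y0)
    if offset != 0.0:
        nx, ny = -(y1 - y0) / length, (x1 - x0) / length
        xs = xs + offset * nx
        ys = ys + offset * ny
    return ys, xs


def sample_line(image: np.ndarray, p0, p1, offset: float = 0.0) -> np.ndarray:
    """Bilinear intensity profile along a line at 1-pixel steps."""
    image = np.asarray(image, dtype=float)
    rows, cols = _line_coords(p0, p1, offset)
    h, w = image.shape
    if rows.min() < -0.5 or rows.max() > h - 0.5 or cols.min() < -0.5 or cols.max() > w - 0.5:
        raise ValueError("probe line falls outside the image")
    return map_coordinates(image, np.vstack([rows, cols]), order=1, mode="nearest")


def bessel_segment_measure(image: np.ndarray, probe: SegmentProbe,
                           threshold: float | None = None) -> tuple[float, int]:
    """(brightness, size) of a vessel crossing a 1-pixel probe line.

    Brightness is the brightest sampled pixel; size is the number of line
    pixels at or above the common threshold.
    """
    if probe.thickness != 1:
        raise ValueError("static segment measurement uses a 1-pixel-thick probe")
    if threshold is None:
        if probe.bg_region is None:
            raise ValueError("probe needs a bg_region when no threshold is given")
        threshold = common_threshold(image, probe.bg_region)
    profile = sample_line(image, probe.p0, probe.p1)
    return float(profile.max()), int(np.count_nonzero(profile >= threshold))


def gaussian_cross_section_measure(stack: Stack, probe: SegmentProbe) -> tuple[float, float]:
    """(brightness, size_µm) from the axial reslice of a thin-focus stack.

    The stack is resliced along the probe line over all z planes;
    brightness is the maximum of the 2D cross-section and size is the
    largest per-row FWHM (µm) found in it.
    """
    section = np.vstack([
        sample_line(stack.data[z], probe.p0, probe.p1) for z in range(stack.n_planes)
    ])
    brightness = float(section.max())
    s_um = np.arange(section.shape[1]) * stack.pixel_size
    widest = 0.0
    for row in section:
        if np.ptp(row) == 0:
            continue
        try:
            widest = max(widest, fwhm_of_profile(s_um, row))
        except NoCrossingError:
            continue
    if widest == 0.0:
        warnings.warn("no vessel cross-section found along the reslice; size = 0")
    return brightness, widest


def diameter_timeseries(movie: Movie, probe: SegmentProbe,
                        bg_region: tuple[int, int, int, int] | None = None,
                        threshold: float | None = None) -> np.ndarray:
    """Per-frame vessel diameter (µm) from a thick thresholded probe.

    Per frame, the count of probe-patch pixels at or above the background
    threshold (mean + 3 sd of ``bg_region``, recomputed each frame, or a
    fixed ``threshold`` override) is divided by the probe thickness and
    scaled by the pixel size, turning the pixel count into a length.
    """
    bg_region = bg_region if bg_region is not None else probe.bg_region
    if bg_region is None and threshold is None:
        raise ValueError("a background region or explicit threshold is required")
    offsets = np.arange(probe.thickness) - (probe.thickness - 1) / 2.0
    T = movie.n_frames
    out = np.empty(T)
    any_above = False
    for f in range(T):
        frame = movie.data[f]
        thr = threshold if threshold is not None else common_threshold(frame, bg_region)
        count = 0
        for off in offsets:
            profile = sample_line(frame, probe.p0, probe.p1, offset=off)
            count += int(np.count_nonzero(profile >= thr))
        any_above = any_above or count > 0
        out[f] = count / probe.thickness * movie.pixel_size
    if not any_above:
        warnings.warn("threshold exceeds lumen intensity on every frame; diameters are 0")
    return out


def dff(trace: np.ndarray) -> np.ndarray:
    """Fractional change (x - F) / F with F the median of the trace."""
    trace = np.asarray(trace, dtype=float)
    baseline = float(np.median(trace))
    if baseline <= 0:
        raise ValueError(f"trace median must be positive, got {baseline}")
    return (trace - baseline) / baseline


def size_brightness_correlation(sizes: np.ndarray, brightness: np.ndarray) -> float:
    """R² of the least-squares linear fit of brightness against size."""
    sizes = np.asarray(sizes, dtype=float)
    brightness = np.asarray(brightness, dtype=float)
    if sizes.size < 3:
        raise ValueError("need at least 3 (size, brightness) pairs")
    if np.ptp(sizes) == 0 or np.ptp(brightness) == 0:
        raise ValueError("zero variance in sizes or brightness; R² undefined")
    r = pearsonr(sizes, brightness).statistic
    return float(r * r)


def temporal_variation_map(movie: Movie, dim_fraction: float = 0.8) -> np.ndarray:
    """Per-pixel std/mean of the time stack, dimmest pixels blacked out.

    Pixels whose temporal mean falls below the ``dim_fraction`` quantile
    of the mean image (the dimmest 80% by default) are set to 0, as are
    zero-mean pixels.
    """
    data = np.asarray(movie.data, dtype=float)
    if data.shape[0] < 2:
        raise ValueError("need at least 2 frames")
    mean = data.mean(axis=0)
    sd = data.std(axis=0, ddof=1)
    out = np.zeros_like(mean)
    nonzero = mean > 0
    out[nonzero] = sd[nonzero] / mean[nonzero]
    cutoff = np.quantile(mean, dim_fraction)
    out[mean < cutoff] = 0.0
    return out
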