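"""Calibrated image containers shared across the pipeline.

Axis conventions: movies are (frame, row, column), stacks are
(depth, row, column).  Row index increases downward, indices are 0-based,
physical positions are in micrometres with the origin at the volume corner.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["Movie", "Stack"]


def _check_positive(name: str, value: float) -> None:
    if not np.isfinite(value) or value <= 0:
        raise ValueError(f"{name} must be positive and finite, got {value!r}")


@dataclass
class Movie:
    """A time series of 2D frames with physical calibration.

    Parameters
    ----------
    data : ndarray, shape (T, Y, X)
        Non-negative intensities.
    pixel_size : float
        Lateral sampling in µm/pixel.
    frame_interval : float
        Time between frames in seconds.
    """

    data: np.ndarray
    pixel_size: float
    frame_interval: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"movie data must be 3D (T, Y, X), got shape {self.data.shape}")
        _check_positive("pixel_size", self.pixel_size)
        _check_positive("frame_interval", self.frame_interval)

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def frame_rate(self) -> float:
        return 1.0 / self.frame_interval

    @property
    def times(self) -> np.ndarray:
        """Frame times in seconds."""
        return np.arange(self.n_frames) * self.frame_interval

    def with_data(self, data: np.ndarray, frame_interval: float | None = None) -> "Movie":
        """Copy of this movie with new pixel data (and optionally timing)."""
        out = replace(self, data=data)
        if frame_interval is not None:
            out.frame_interval = frame_interval
        return out


@dataclass
class Stack:
    """A z-stack with physical calibration.

    Parameters
    ----------
    data : ndarray, shape (Z, Y, X)
    pixel_size : float
        Lateral sampling in µm/pixel.
    z_step : float
        Axial sampling in µm/plane.
    """

    data: np.ndarray
    pixel_size: float
    z_step: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"stack data must be 3D (Z, Y, X), got shape {self.data.shape}")
        _check_positive("pixel_size", self.pixel_size)
        _check_positive("z_step", self.z_step)

    @property
    def n_planes(self) -> int:
        return self.data.shape[0]
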