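"""Phantom scene configuration."""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np

__all__ = ["SceneConfig"]


@dataclass
class SceneConfig:
    """Parameters of a synthetic vascular scene.

    All lengths are in µm, speeds in mm/s, rates in Hz.  The seed fully
    determines every random draw (network geometry, noise, motion).

    Notes
    -----
    ``noise_photons`` is the photon count generated per µm of weighted dye
    path at the detector; 0 disables Poisson noise entirely.  A 10-µm
    lumen chord at the default 5 photons/µm therefore peaks near 50
    photons.
    """

    volume_size: tuple[float, float, float] = (200.0, 200.0, 100.0)  # (x, y, z) µm
    pixel_size: float = 1.0
    frame_rate: float = 15.0
    duration: float = 20.0
    n_pial: int = 2
    n_penetrating: int = 1
    n_capillaries: int = 2
    pial_radius: tuple[float, float] = (4.0, 8.0)
    penetrating_radius: tuple[float, float] = (3.0, 6.0)
    capillary_radius: tuple[float, float] = (1.5, 2.9)
    rbc_speeds: tuple[float, ...] | None = None  # mm/s, cycled over segments
    rbc_speed_range: tuple[float, float] = (0.3, 3.0)
    rbc_spacing: float = 25.0  # mean µm between RBC centers along a segment
    rbc_radius: float = 2.8  # µm, capped at 80% of local vessel radius
    vasomotion_freq: float = 0.1
    vasomotion_amp: float = 0.0  # fractional radius modulation
    population_signs: tuple[int, ...] | None = None  # ±1 per vessel, cycled
    arousal_coupling: float = 0.0  # fractional radius gain per unit arousal
    noise_photons: float = 5.0
    background: float = 0.2  # µm-equivalent uniform background signal
    lateral_blur_fwhm: float = 0.65  # µm, lateral PSF of the rendered focus
    motion_amplitude: float = 0.0  # µm, rigid lateral drift
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.volume_size) != 3 or any(v <= 0 for v in self.volume_size):
            raise ValueError(f"volume_size must be 3 positive lengths, got {self.volume_size}")
        for name in ("pixel_size", "frame_rate", "duration", "rbc_spacing", "rbc_radius"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("vasomotion_freq",):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("n_pial", "n_penetrating", "n_capillaries"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.noise_photons < 0 or self.background < 0 or self.motion_amplitude < 0:
            raise ValueError("noise_photons, background and motion_amplitude must be >= 0")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration * self.frame_rate))

    @property
    def frame_interval(self) -> float:
        return 1.0 / self.frame_rate

    @property
    def frame_shape(self) -> tuple[int, int]:
        """(rows, cols) of the rendered frames."""
        x, y, _ = self.volume_size
        return (int(round(y / self.pixel_size)), int(round(x / self.pixel_size)))

    def rng(self, stream: str = "scene") -> np.random.Generator:
        """Named deterministic random stream derived from the seed."""
        # zlib.crc32 is stable across processes, unlike hash() on str
        ss = np.random.SeedSequence([self.seed, zlib.crc32(stream.encode())])
        return np.random.default_rng(ss)
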