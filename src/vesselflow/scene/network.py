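"""Vessel network geometry and ground-truth dynamics for the phantom.

Vessel classes: pial segments run horizontally near the top of the
volume, penetrating segments dive vertically, capillaries follow a
bounded 3D random walk.  Each segment carries a radius time series

    r_i(t) = r0_i * (1 + A sin(2 pi f t + phi_i) + sign_i * g * a(t)),

where a(t) is a smoothed, standardized arousal trace shared by all
segments.  Unlabeled RBCs advect along each centerline at the segment's
constant speed, recirculating by wrap-around so the streak flux is
stationary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

from vesselflow.scene.config import SceneConfig

__all__ = ["VesselSegment", "VesselNetwork", "GroundTruth", "build_network", "arousal_trace"]


@dataclass
class VesselSegment:
    id: int
    kind: str  # "pial" | "penetrating" | "capillary"
    centerline: np.ndarray  # (N, 3) µm, columns (x, y, z)
    base_radius: float  # µm
    radius_t: np.ndarray  # (T,) µm
    speed: float  # mm/s
    sign: int  # ±1 population label

    def __post_init__(self) -> None:
        self.centerline = np.asarray(self.centerline, dtype=float)
        if self.centerline.ndim != 2 or self.centerline.shape[1] != 3 or len(self.centerline) < 2:
            raise ValueError("centerline must be an (N>=2, 3) array")
        if np.any(self.radius_t <= 0):
            raise ValueError("radius_t must stay positive")

    @property
    def cum_length(self) -> np.ndarray:
        """Cumulative 3D arc length (µm) at each centerline point."""
        d = np.linalg.norm(np.diff(self.centerline, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(d)])

    @property
    def length(self) -> float:
        return float(self.cum_length[-1])

    def point_at(self, s: np.ndarray) -> np.ndarray:
        """3D points (µm) at arc positions ``s`` (µm), wrapped to the segment."""
        s = np.asarray(s, dtype=float) % self.length
        cum = self.cum_length
        out = np.empty((s.size, 3))
        for k in range(3):
            out[:, k] = np.interp(s, cum, self.centerline[:, k])
        return out


@dataclass
class VesselNetwork:
    segments: list[VesselSegment]
    volume_size: tuple[float, float, float]

    def __iter__(self):
        return iter(self.segments)

    def __len__(self) -> int:
        return len(self.segments)


@dataclass
class GroundTruth:
    """Known state of the phantom at every frame."""

    times: np.ndarray  # (T,) s
    arousal: np.ndarray  # (T,) standardized arousal trace
    diameters: np.ndarray  # (n_seg, T) µm, 2 * radius_t
    speeds: np.ndarray  # (n_seg,) mm/s
    signs: np.ndarray  # (n_seg,) ±1
    rbc_offsets: list[np.ndarray] = field(default_factory=list)  # µm initial arc positions

    def rbc_positions(self, seg: VesselSegment, frame: int, dt: float) -> np.ndarray:
        """3D RBC centers (µm) of ``seg`` at a frame (speed mm/s -> µm/s)."""
        s = self.rbc_offsets[seg.id] + seg.speed * 1000.0 * frame * dt
        return seg.point_at(s)


def arousal_trace(n_frames: int, frame_rate: float, rng: np.random.Generator,
                  smooth_seconds: float = 3.0) -> np.ndarray:
    """Smoothed standardized random trace emulating slow arousal drift."""
    raw = rng.standard_normal(n_frames)
    smooth = gaussian_filter1d(raw, sigma=max(smooth_seconds * frame_rate, 1.0), mode="reflect")
    sd = smooth.std()
    if sd == 0:
        return np.zeros(n_frames)
    return (smooth - smooth.mean()) / sd


def _capillary_walk(rng: np.random.Generator, start: np.ndarray, bounds: np.ndarray,
                    n_steps: int = 12, step: float = 10.0) -> np.ndarray:
    """Tortuous random-walk centerline, reflected at the volume bounds."""
    direction = rng.standard_normal(3)
    direction /= np.linalg.norm(direction)
    points = [start.copy()]
    p = start.copy()
    for _ in range(n_steps):
        direction = direction + 0.6 * rng.standard_normal(3)
        direction /= np.linalg.norm(direction)
        p = p + step * direction
        for k in range(3):  # reflect off walls, keep a margin
            lo, hi = 2.0, bounds[k] - 2.0
            if p[k] < lo:
                p[k] = 2 * lo - p[k]
                direction[k] *= -1
            elif p[k] > hi:
                p[k] = 2 * hi - p[k]
                direction[k] *= -1
        points.append(p.copy())
    return np.asarray(points)


def build_network(config: SceneConfig) -> tuple[VesselNetwork, GroundTruth]:
    """Deterministically generate a vessel network and its ground truth."""
    rng = config.rng("network")
    X, Y, Z = config.volume_size
    n_total = config.n_pial + config.n_penetrating + config.n_capillaries
    if n_total == 0:
        truth = GroundTruth(
            times=np.arange(config.n_frames) * config.frame_interval,
            arousal=arousal_trace(config.n_frames, config.frame_rate, config.rng("arousal")),
            diameters=np.zeros((0, config.n_frames)),
            speeds=np.zeros(0),
            signs=np.zeros(0, dtype=int),
        )
        return VesselNetwork([], config.volume_size), truth

    min_extent = min(X, Y)
    if min_extent < 20.0 or Z < 6.0:
        raise ValueError(f"volume {config.volume_size} too small for vessel generation")

    T = config.n_frames
    t = np.arange(T) * config.frame_interval
    arousal = arousal_trace(T, config.frame_rate, config.rng("arousal"))

    geoms: list[tuple[str, np.ndarray, float]] = []
    # pial: horizontal lines near the top of the volume, along x with y jitter
    for _ in range(config.n_pial):
        r = rng.uniform(*config.pial_radius)
        z0 = rng.uniform(0.06, 0.14) * Z + r
        y0 = rng.uniform(0.15, 0.85) * Y
        y1 = np.clip(y0 + rng.uniform(-0.15, 0.15) * Y, 2.0, Y - 2.0)
        line = np.array([[2.0, y0, z0], [X - 2.0, y1, z0]])
        geoms.append(("pial", line, r))
    # penetrating: vertical lines spanning the depth
    for _ in range(config.n_penetrating):
        r = rng.uniform(*config.penetrating_radius)
        x0 = rng.uniform(0.15, 0.85) * X
        y0 = rng.uniform(0.15, 0.85) * Y
        line = np.array([[x0, y0, 2.0], [x0, y0, Z - 2.0]])
        geoms.append(("penetrating", line, r))
    # capillaries: tortuous walks in the bulk
    for _ in range(config.n_capillaries):
        r = rng.uniform(*config.capillary_radius)
        start = np.array([
            rng.uniform(0.2, 0.8) * X,
            rng.uniform(0.2, 0.8) * Y,
            rng.uniform(0.3, 0.7) * Z,
        ])
        line = _capillary_walk(rng, start, np.array([X, Y, Z]))
        geoms.append(("capillary", line, r))

    signs_cfg = config.population_signs
    speeds_cfg = config.rbc_speeds
    segments: list[VesselSegment] = []
    speeds = np.empty(n_total)
    signs = np.empty(n_total, dtype=int)
    diameters = np.empty((n_total, T))
    phases = rng.uniform(0, 2 * np.pi, n_total)
    for i, (kind, line, r0) in enumerate(geoms):
        sign = signs_cfg[i % len(signs_cfg)] if signs_cfg else (1 if i % 2 == 0 else -1)
        speed = (speeds_cfg[i % len(speeds_cfg)] if speeds_cfg
                 else float(rng.uniform(*config.rbc_speed_range)))
        mod = (1.0
               + config.vasomotion_amp * np.sin(2 * np.pi * config.vasomotion_freq * t + phases[i])
               + sign * config.arousal_coupling * arousal)
        radius_t = np.clip(r0 * mod, 0.1 * r0, None)
        seg = VesselSegment(i, kind, line, r0, radius_t, speed, sign)
        segments.append(seg)
        speeds[i] = speed
        signs[i] = sign
        diameters[i] = 2 * radius_t

    truth = GroundTruth(times=t, arousal=arousal, diameters=diameters,
                        speeds=speeds, signs=signs)
    rbc_rng = config.rng("rbc")
    for seg in segments:
        n_rbc = max(int(round(seg.length / config.rbc_spacing)), 1)
        offsets = np.sort(rbc_rng.uniform(0, seg.length, n_rbc))
        truth.rbc_offsets.append(offsets)
    return VesselNetwork(segments, config.volume_size), truth
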