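"""Ready-made single-purpose phantom scenes used by tests, examples and
the acceptance report."""

from __future__ import annotations

import numpy as np

from vesselflow.scene.config import SceneConfig
from vesselflow.scene.network import GroundTruth, VesselNetwork, VesselSegment

__all__ = ["cylinder_scene", "flow_scene", "dilating_vessel_scene"]


def _truth_for(segments: list[VesselSegment], config: SceneConfig,
               rbc_spacing: float | None) -> GroundTruth:
    T = config.n_frames
    truth = GroundTruth(
        times=np.arange(T) * config.frame_interval,
        arousal=np.zeros(T),
        diameters=np.array([2.0 * s.radius_t for s in segments]),
        speeds=np.array([s.speed for s in segments]),
        signs=np.array([s.sign for s in segments]),
    )
    rng = config.rng("rbc")
    for seg in segments:
        if rbc_spacing is None or not np.isfinite(rbc_spacing):
            truth.rbc_offsets.append(np.empty(0))
        else:
            n = max(int(round(seg.length / rbc_spacing)), 1)
            truth.rbc_offsets.append(np.sort(rng.uniform(0, seg.length, n)))
    return truth


def cylinder_scene(diameter: float, config: SceneConfig, z: float | None = None,
                   y: float | None = None, tilt: float = 0.0,
                   with_rbcs: bool = False) -> tuple[VesselNetwork, GroundTruth]:
    """One straight horizontal cylinder spanning the volume along x.

    ``tilt`` (µm) offsets the far end in y, so the vessel is not
    pixel-grid aligned; ``z`` defaults to mid-depth.
    """
    X, Y, Z = config.volume_size
    zc = Z / 2.0 if z is None else z
    yc = Y / 2.0 if y is None else y
    T = config.n_frames
    line = np.array([[2.0, yc - tilt / 2.0, zc], [X - 2.0, yc + tilt / 2.0, zc]])
    seg = VesselSegment(0, "pial", line, diameter / 2.0,
                        np.full(T, diameter / 2.0), 1.0, 1)
    truth = _truth_for([seg], config,
                       config.rbc_spacing if with_rbcs else None)
    return VesselNetwork([seg], config.volume_size), truth


def flow_scene(speed: float, config: SceneConfig, orientation: str = "in_plane",
               radius: float = 4.0) -> tuple[VesselNetwork, GroundTruth]:
    """A single RBC-carrying vessel at a known speed (mm/s).

    ``orientation="in_plane"`` runs along x at mid-depth;
    ``"descending_45"`` drops through the volume at 45 degrees so its 3D
    length is sqrt(2) times its 2D projection.
    """
    X, Y, Z = config.volume_size
    T = config.n_frames
    if orientation == "in_plane":
        line = np.array([[2.0, Y / 2.0, Z / 2.0], [X - 2.0, Y / 2.0, Z / 2.0]])
    elif orientation == "descending_45":
        dz = Z - 14.0
        x0 = (X - dz) / 2.0
        if x0 <= 2.0:
            raise ValueError("volume too short in x for a 45-degree descent")
        line = np.array([[x0, Y / 2.0, 7.0], [x0 + dz, Y / 2.0, Z - 7.0]])
    else:
        raise ValueError(f"unknown orientation {orientation!r}")
    seg = VesselSegment(0, "pial", line, radius, np.full(T, radius), speed, 1)
    truth = _truth_for([seg], config, config.rbc_spacing)
    return VesselNetwork([seg], config.volume_size), truth


def dilating_vessel_scene(config: SceneConfig, base_diameter: float = 10.0,
                          amp: float = 0.1, freq: float = 0.1,
                          tilt: float = 6.0) -> tuple[VesselNetwork, GroundTruth]:
    """A tilted horizontal vessel with sinusoidal vasomotion of known
    amplitude and frequency, carrying a few RBCs."""
    X, Y, Z = config.volume_size
    T = config.n_frames
    t = np.arange(T) * config.frame_interval
    r0 = base_diameter / 2.0
    radius_t = r0 * (1.0 + amp * np.sin(2.0 * np.pi * freq * t))
    line = np.array([[2.0, Y / 2.0 - tilt / 2.0, Z / 2.0],
                     [X - 2.0, Y / 2.0 + tilt / 2.0, Z / 2.0]])
    seg = VesselSegment(0, "pial", line, r0, radius_t, 1.0, 1)
    truth = _truth_for([seg], config, config.rbc_spacing)
    return VesselNetwork([seg], config.volume_size), truth
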