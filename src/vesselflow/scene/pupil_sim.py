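"""Synthetic infrared pupil video driven by the arousal trace.

The pupil diameter follows the arousal trace through a first-order
low-pass filter (time constant of seconds — the pupil is slower than the
vessels), and each frame shows a dark filled ellipse on a brighter iris
background with Gaussian sensor noise.
"""

from __future__ import annotations

import numpy as np

from vesselflow.core import Movie
from vesselflow.pupil import PupilTrace
from vesselflow.scene.config import SceneConfig
from vesselflow.scene.network import GroundTruth

__all__ = ["simulate_pupil", "pupil_response"]


def pupil_response(arousal: np.ndarray, dt: float, tau: float,
                   base: float, gain: float) -> np.ndarray:
    """First-order low-pass of an affine map of the arousal trace.

    dp/dt = (base + gain * a(t) - p) / tau, discretized explicitly.
    """
    target = base + gain * np.asarray(arousal, dtype=float)
    p = np.empty_like(target)
    p[0] = target[0]
    coef = dt / tau
    for i in range(1, target.size):
        p[i] = p[i - 1] + coef * (target[i] - p[i - 1])
    return p


def simulate_pupil(truth: GroundTruth, config: SceneConfig,
                   frame_shape: tuple[int, int] = (96, 128),
                   tau: float = 2.0, base_width: float = 40.0,
                   gain: float = 12.0, aspect: float = 0.7,
                   iris_level: float = 200.0, pupil_level: float = 20.0,
                   noise_sd: float = 3.0) -> tuple[Movie, PupilTrace]:
    """Render an eye video and return it with the ground-truth trace.

    ``base_width``/``gain`` are in pixels; the ellipse is clipped so it
    always fits inside the frame.
    """
    rows, cols = frame_shape
    dt = config.frame_interval
    p = pupil_response(truth.arousal, dt, tau, base_width, gain)
    max_width = min(cols - 4, (rows - 4) / aspect)
    p = np.clip(p, 6.0, max_width)

    cy, cx = rows / 2.0, cols / 2.0
    yy, xx = np.mgrid[0:rows, 0:cols]
    rng = config.rng("pupil-noise")
    frames = np.empty((config.n_frames, rows, cols), dtype=np.float32)
    for f in range(config.n_frames):
        a = p[f] / 2.0  # semi-axis, horizontal
        b = aspect * a
        # soft-edged ellipse: ~1 px anti-aliasing band
        r = np.sqrt(((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2)
        edge = np.clip((r - 1.0) * a, 0.0, 1.0)  # 0 inside, 1 outside
        img = pupil_level + (iris_level - pupil_level) * edge
        if noise_sd > 0:
            img = img + rng.normal(0.0, noise_sd, img.shape)
        frames[f] = img
    video = Movie(frames, pixel_size=config.pixel_size, frame_interval=dt)
    trace = PupilTrace(t=truth.times, width=p.copy(),
                       height=aspect * p, center=np.tile([cy, cx], (p.size, 1)))
    return video, trace
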