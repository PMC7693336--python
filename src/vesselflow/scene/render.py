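"""Renderers turning a vessel network into calibrated image series.

The dye-filled lumen of every vessel is modeled as a capsule around its
centerline.  For each pixel column (x, y) the renderer computes the exact
z-interval(s) where the column passes through the lumen and integrates
the axial excitation weight W(z) over them, so the signal equals the
weighted dye path length in µm.  RBCs are dye-excluding spheres riding on
the centerline; their chord is subtracted the same way.  The raw image is
then blurred by the lateral PSF, offset by a uniform background and, if
requested, converted to Poisson photon counts.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.ndimage import gaussian_filter

from vesselflow.core import Movie, Stack
from vesselflow.optics import AxialProfile
from vesselflow.scene.config import SceneConfig
from vesselflow.scene.network import GroundTruth, VesselNetwork

__all__ = [
    "render_bessel_projection",
    "render_gaussian_plane",
    "render_gaussian_stack",
    "apply_motion",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


class _WeightCdf:
    """Cumulative integral of an axial weight on a fine z grid."""

    def __init__(self, z_fine: np.ndarray, weight: np.ndarray):
        self.z = z_fine
        self.cdf = np.concatenate([[0.0], cumulative_trapezoid(weight, z_fine)])

    def __call__(self, z: np.ndarray) -> np.ndarray:
        return np.interp(z, self.z, self.cdf)


def _bessel_weight_cdf(profile: AxialProfile, depth: float, step: float = 0.05) -> _WeightCdf:
    two_photon = profile.two_photon()
    z_fine = np.arange(0.0, depth + step, step)
    w = np.interp(z_fine - depth / 2.0, two_photon.z, two_photon.intensity, left=0.0, right=0.0)
    return _WeightCdf(z_fine, w)


def _gaussian_weight_cdf(z_plane: float, fwhm: float, depth: float,
                         step: float = 0.02) -> _WeightCdf:
    z_fine = np.arange(0.0, depth + step, step)
    sigma = fwhm * _FWHM_TO_SIGMA
    w = np.exp(-0.5 * ((z_fine - z_plane) / sigma) ** 2)
    return _WeightCdf(z_fine, w)


def _add_capsule(raw: np.ndarray, xs: np.ndarray, ys: np.ndarray,
                 p0: np.ndarray, p1: np.ndarray, radius: float,
                 wcdf: _WeightCdf, zmax: float, pixel_size: float,
                 margin: float) -> None:
    """Accumulate the weighted z-chord of one straight capsule into ``raw``."""
    lo_x = min(p0[0], p1[0]) - radius - margin
    hi_x = max(p0[0], p1[0]) + radius + margin
    lo_y = min(p0[1], p1[1]) - radius - margin
    hi_y = max(p0[1], p1[1]) + radius + margin
    c0 = max(int(lo_x / pixel_size), 0)
    c1 = min(int(hi_x / pixel_size) + 2, raw.shape[1])
    r0 = max(int(lo_y / pixel_size), 0)
    r1 = min(int(hi_y / pixel_size) + 2, raw.shape[0])
    if c0 >= c1 or r0 >= r1:
        return
    X = xs[c0:c1][None, :]
    Y = ys[r0:r1][:, None]

    d = p1 - p0
    length = float(np.linalg.norm(d))
    u = d / length
    A = X - p0[0]
    B = Y - p0[1]
    s0 = A * u[0] + B * u[1]
    uz = u[2]
    r2 = radius * radius
    alpha = 1.0 - uz * uz
    if alpha < 1e-12:
        # vertical capsule: in/out is decided purely in the xy plane
        inside = (A * A + B * B) <= r2
        z1 = np.clip(min(p0[2], p1[2]), 0.0, zmax)
        z2 = np.clip(max(p0[2], p1[2]), 0.0, zmax)
        raw[r0:r1, c0:c1] += np.where(inside, wcdf(np.array(z2)) - wcdf(np.array(z1)), 0.0)
        return
    beta = -2.0 * s0 * uz
    gamma = A * A + B * B - s0 * s0 - r2
    disc = beta * beta - 4.0 * alpha * gamma
    ok = disc > 0
    sq = np.sqrt(np.maximum(disc, 0.0))
    z1 = (-beta - sq) / (2.0 * alpha) + p0[2]
    z2 = (-beta + sq) / (2.0 * alpha) + p0[2]
    if abs(uz) > 1e-9:
        # clip to the finite axis range t in [0, length]
        ca = (0.0 - s0) / uz + p0[2]
        cb = (length - s0) / uz + p0[2]
        z1 = np.maximum(z1, np.minimum(ca, cb))
        z2 = np.minimum(z2, np.maximum(ca, cb))
    else:
        ok &= (s0 >= 0.0) & (s0 <= length)
    z1 = np.clip(z1, 0.0, zmax)
    z2 = np.clip(z2, 0.0, zmax)
    valid = ok & (z2 > z1)
    contrib = np.zeros_like(z1)
    contrib[valid] = wcdf(z2[valid]) - wcdf(z1[valid])
    raw[r0:r1, c0:c1] += contrib


def _subtract_sphere(raw: np.ndarray, xs: np.ndarray, ys: np.ndarray,
                     center: np.ndarray, rho: float, wcdf: _WeightCdf,
                     zmax: float, pixel_size: float) -> None:
    """Remove the weighted z-chord of a dye-excluding sphere from ``raw``."""
    c0 = max(int((center[0] - rho) / pixel_size), 0)
    c1 = min(int((center[0] + rho) / pixel_size) + 2, raw.shape[1])
    r0 = max(int((center[1] - rho) / pixel_size), 0)
    r1 = min(int((center[1] + rho) / pixel_size) + 2, raw.shape[0])
    if c0 >= c1 or r0 >= r1:
        return
    X = xs[c0:c1][None, :]
    Y = ys[r0:r1][:, None]
    h2 = rho * rho - (X - center[0]) ** 2 - (Y - center[1]) ** 2
    inside = h2 > 0
    h = np.sqrt(np.maximum(h2, 0.0))
    z1 = np.clip(center[2] - h, 0.0, zmax)
    z2 = np.clip(center[2] + h, 0.0, zmax)
    chord = np.where(inside, wcdf(z2) - wcdf(z1), 0.0)
    raw[r0:r1, c0:c1] -= chord


def _render_movie(network: VesselNetwork, truth: GroundTruth, wcdf: _WeightCdf,
                  config: SceneConfig, noise_stream: str) -> Movie:
    T = config.n_frames
    rows, cols = config.frame_shape
    px = config.pixel_size
    zmax = config.volume_size[2]
    xs = (np.arange(cols) + 0.5) * px
    ys = (np.arange(rows) + 0.5) * px
    margin = 2.0 * config.lateral_blur_fwhm + px
    sigma_px = config.lateral_blur_fwhm * _FWHM_TO_SIGMA / px
    noise_rng = config.rng(noise_stream)
    dt = config.frame_interval

    static = all(np.ptp(seg.radius_t) == 0 for seg in network)

    def vessel_image(frame: int) -> np.ndarray:
        raw = np.zeros((rows, cols))
        for seg in network:
            radius = float(seg.radius_t[frame])
            pts = seg.centerline
            for i in range(len(pts) - 1):
                _add_capsule(raw, xs, ys, pts[i], pts[i + 1], radius,
                             wcdf, zmax, px, margin)
        return raw

    base = vessel_image(0) if static else None
    frames = np.empty((T, rows, cols), dtype=np.float32)
    for f in range(T):
        raw = base.copy() if static else vessel_image(f)
        for seg in network:
            rho = min(config.rbc_radius, 0.8 * float(seg.radius_t[f]))
            if rho <= 0:
                continue
            for center in truth.rbc_positions(seg, f, dt):
                _subtract_sphere(raw, xs, ys, center, rho, wcdf, zmax, px)
        np.clip(raw, 0.0, None, out=raw)
        raw += config.background
        if sigma_px > 0.05:
            raw = gaussian_filter(raw, sigma_px, mode="nearest")
        if config.noise_photons > 0:
            raw = noise_rng.poisson(config.noise_photons * raw).astype(np.float32)
        frames[f] = raw
    return Movie(frames, pixel_size=px, frame_interval=dt)


def render_bessel_projection(network: VesselNetwork, truth: GroundTruth,
                             axial_profile: AxialProfile, config: SceneConfig) -> Movie:
    """Render the movie seen by an axially extended (Bessel) focus.

    The two-photon axial weight (profile squared, centered at mid-depth)
    integrates dye over the whole volume, so lumen brightness grows with
    vessel axial extent.
    """
    wcdf = _bessel_weight_cdf(axial_profile, config.volume_size[2])
    return _render_movie(network, truth, wcdf, config, "bessel-noise")


def render_gaussian_plane(network: VesselNetwork, truth: GroundTruth,
                          z_plane: float, config: SceneConfig,
                          axial_fwhm: float = 3.1) -> Movie:
    """Render a single thin-focus plane at depth ``z_plane`` (µm)."""
    if not 0 <= z_plane <= config.volume_size[2]:
        raise ValueError(f"z_plane {z_plane} outside volume depth {config.volume_size[2]}")
    wcdf = _gaussian_weight_cdf(z_plane, axial_fwhm, config.volume_size[2])
    return _render_movie(network, truth, wcdf, config, "gaussian-noise")


def render_gaussian_stack(network: VesselNetwork, truth: GroundTruth,
                          config: SceneConfig, z_step: float = 1.0,
                          axial_fwhm: float = 3.1, rbcs: bool = False) -> Stack:
    """Structural z-stack: one thin-focus plane per z position.

    By default RBC shadows are omitted, emulating the time-averaged
    structural stacks in which moving shadows wash out.
    """
    depth = config.volume_size[2]
    planes = np.arange(0.0, depth + 1e-9, z_step)
    rows, cols = config.frame_shape
    data = np.empty((planes.size, rows, cols), dtype=np.float32)
    one_frame = SceneConfig(**{**config.__dict__, "duration": config.frame_interval})
    offsets = truth.rbc_offsets if rbcs else [np.empty(0) for _ in truth.rbc_offsets]
    sub_truth = GroundTruth(times=truth.times[:1], arousal=truth.arousal[:1],
                            diameters=truth.diameters[:, :1], speeds=truth.speeds,
                            signs=truth.signs, rbc_offsets=offsets)
    for i, zp in enumerate(planes):
        wcdf = _gaussian_weight_cdf(zp, axial_fwhm, depth)
        plane = _render_movie(network, sub_truth, wcdf, one_frame, f"stack-noise-{i}")
        data[i] = plane.data[0]
    return Stack(data, pixel_size=config.pixel_size, z_step=z_step)


def _translate(frame: np.ndarray, dy: int, dx: int, fill: float) -> np.ndarray:
    out = np.full_like(frame, fill)
    h, w = frame.shape
    ys_dst = slice(max(dy, 0), min(h + dy, h))
    xs_dst = slice(max(dx, 0), min(w + dx, w))
    ys_src = slice(max(-dy, 0), min(h - dy, h))
    xs_src = slice(max(-dx, 0), min(w - dx, w))
    out[ys_dst, xs_dst] = frame[ys_src, xs_src]
    return out


def apply_motion(movie: Movie, amplitude: float, seed: int = 0) -> tuple[Movie, np.ndarray]:
    """Apply an integer-pixel random-walk lateral drift to every frame.

    Returns the shifted movie and the (T, 2) array of applied (dy, dx)
    pixel shifts.  ``amplitude`` (µm) bounds the walk; it must stay below
    10% of the field size.
    """
    T, h, w = movie.data.shape
    amp_px = int(round(amplitude / movie.pixel_size))
    if amp_px == 0:
        return movie.with_data(movie.data.copy()), np.zeros((T, 2), dtype=int)
    if amp_px > 0.1 * min(h, w):
        raise ValueError(f"motion amplitude {amplitude} µm exceeds 10% of the field")
    rng = np.random.default_rng(seed)
    steps = rng.integers(-1, 2, size=(T, 2))
    steps[0] = 0
    shifts = np.clip(np.cumsum(steps, axis=0), -amp_px, amp_px)
    out = np.empty_like(movie.data)
    for f in range(T):
        fill = float(np.median(movie.data[f]))
        out[f] = _translate(movie.data[f], int(shifts[f, 0]), int(shifts[f, 1]), fill)
    return movie.with_data(out), shifts
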