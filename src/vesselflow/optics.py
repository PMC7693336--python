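"""Axial excitation profiles of Gaussian and annular (Bessel) foci.

An annular aperture transmitting a thin ring of light between inner and
outer numerical apertures produces an axially elongated focus.  The
on-axis one-photon intensity of such an annulus is, in the scalar
paraxial-annulus model,

    I(z) = sinc^2( k z (cos(theta_in) - cos(theta_out)) / 2 ),

with k = 2 pi n / lambda and sin(theta) = NA / n.  The full scalar Debye
integral over the annular pupil is provided as an independent numerical
cross-check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "AnnulusSpec",
    "AxialProfile",
    "annulus_axial_profile",
    "debye_axial_profile",
    "axial_fwhm",
    "fwhm_of_profile",
    "design_annulus",
    "measure_bead_fwhm",
    "closed_form_fwhm",
]

#: positive root of sin(x)^2 / x^2 = 1/2
_SINC_SQ_HALF_ARG = 1.3915573782515102


class NoCrossingError(ValueError):
    """Profile never falls below half maximum on one or both sides."""


@dataclass(frozen=True)
class AnnulusSpec:
    """Annular-aperture illumination parameters.

    Parameters
    ----------
    na_outer : float
        Numerical aperture of the outer edge of the annulus.
    ratio : float
        Inner/outer radius ratio of the annular mask, in (0, 1).
    wavelength : float
        Excitation wavelength in µm.
    refractive_index : float
        Refractive index of the immersion/sample medium.
    """

    na_outer: float
    ratio: float
    wavelength: float
    refractive_index: float = 1.33

    def __post_init__(self) -> None:
        if not 0 < self.na_outer < self.refractive_index:
            raise ValueError(
                f"na_outer must lie in (0, n={self.refractive_index}), got {self.na_outer}"
            )
        if not 0 < self.ratio < 1:
            raise ValueError(f"ratio must lie in (0, 1), got {self.ratio}")
        if self.wavelength <= 0:
            raise ValueError(f"wavelength must be positive, got {self.wavelength}")

    @property
    def na_inner(self) -> float:
        return self.ratio * self.na_outer

    @property
    def wavenumber(self) -> float:
        """k = 2 pi n / lambda in rad/µm."""
        return 2.0 * math.pi * self.refractive_index / self.wavelength

    @property
    def cos_span(self) -> float:
        """cos(theta_inner) - cos(theta_outer), the annulus 'thickness' on the z axis."""
        n = self.refractive_index
        cos_out = math.sqrt(1.0 - (self.na_outer / n) ** 2)
        cos_in = math.sqrt(1.0 - (self.na_inner / n) ** 2)
        return cos_in - cos_out


@dataclass
class AxialProfile:
    """On-axis intensity versus axial position.

    ``z`` is a monotone increasing µm grid (symmetric about 0 for the
    closed-form profiles); ``intensity`` is normalized to peak 1.
    ``kind`` is ``"one_photon"`` or ``"two_photon"``.
    """

    z: np.ndarray
    intensity: np.ndarray
    kind: str = "one_photon"

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.z.shape != self.intensity.shape or self.z.ndim != 1:
            raise ValueError("z and intensity must be 1D arrays of equal length")
        if np.any(np.diff(self.z) <= 0):
            raise ValueError("z grid must be strictly increasing")
        if self.kind not in ("one_photon", "two_photon"):
            raise ValueError(f"unknown profile kind {self.kind!r}")

    def two_photon(self) -> "AxialProfile":
        """Squared-intensity profile (two-photon excitation weight)."""
        if self.kind == "two_photon":
            return self
        return AxialProfile(self.z, self.intensity**2, kind="two_photon")


def closed_form_fwhm(spec: AnnulusSpec) -> float:
    """Axial FWHM (µm) of the sinc^2 one-photon profile, from the half-max root."""
    return 4.0 * _SINC_SQ_HALF_ARG / (spec.wavenumber * spec.cos_span)


def _default_grid(spec: AnnulusSpec) -> np.ndarray:
    fwhm = closed_form_fwhm(spec)
    half = 2.5 * fwhm
    step = fwhm / 400.0  # keep grid step well under FWHM/200
    n = int(math.ceil(half / step))
    return np.arange(-n, n + 1) * step


def annulus_axial_profile(
    spec: AnnulusSpec, z: np.ndarray | None = None, kind: str = "one_photon"
) -> AxialProfile:
    """On-axis axial intensity profile of an annular-aperture focus.

    Parameters
    ----------
    spec : AnnulusSpec
    z : array, optional
        µm grid; defaults to a symmetric grid spanning ±2.5 expected FWHM.
    kind : {"one_photon", "two_photon"}
        Return the illumination intensity or its square.
    """
    if z is None:
        z = _default_grid(spec)
    z = np.asarray(z, dtype=float)
    arg = spec.wavenumber * z * spec.cos_span / 2.0
    intensity = np.sinc(arg / math.pi) ** 2  # np.sinc(x) = sin(pi x)/(pi x)
    profile = AxialProfile(z, intensity, kind="one_photon")
    if kind == "two_photon":
        return profile.two_photon()
    return profile


def debye_axial_profile(spec: AnnulusSpec, z: np.ndarray) -> AxialProfile:
    """On-axis intensity from the scalar Debye integral over the annular pupil.

    U(z) = int_{theta_in}^{theta_out} sqrt(cos t) sin t exp(i k z cos t) dt,
    evaluated by fixed-order Gauss-Legendre quadrature; independent
    numerical route used to cross-check the closed form.
    """
    z = np.asarray(z, dtype=float)
    n = spec.refractive_index
    t_out = math.asin(spec.na_outer / n)
    t_in = math.asin(spec.na_inner / n)
    nodes, weights = np.polynomial.legendre.leggauss(512)
    theta = 0.5 * (t_out - t_in) * nodes + 0.5 * (t_out + t_in)
    w = 0.5 * (t_out - t_in) * weights
    apod = np.sqrt(np.cos(theta)) * np.sin(theta)
    phase = np.exp(1j * spec.wavenumber * np.outer(z, np.cos(theta)))
    field = phase @ (apod * w)
    intensity = np.abs(field) ** 2
    intensity /= intensity.max()
    return AxialProfile(z, intensity, kind="one_photon")


def fwhm_of_profile(x: np.ndarray, y: np.ndarray) -> float:
    """Full width at half maximum of a sampled profile.

    Half-max crossings are located by linear interpolation on either side
    of the global maximum.  Raises :class:`NoCrossingError` if the profile
    never falls below half max on one side.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or x.shape != y.shape or x.size < 3:
        raise ValueError("profile must be 1D with at least 3 samples")
    i_max = int(np.argmax(y))
    half = y[i_max] / 2.0

    def _cross(indices: np.ndarray, side: str) -> float:
        below = np.nonzero(y[indices] < half)[0]
        if below.size == 0:
            raise NoCrossingError(f"profile never falls below half max on the {side} side")
        j = indices[below[0]]  # first sample below half, moving away from peak
        k = j + 1 if side == "left" else j - 1  # neighbor toward the peak
        y0, y1 = y[j], y[k]
        frac = (half - y0) / (y1 - y0)
        return x[j] + frac * (x[k] - x[j])

    left = _cross(np.arange(i_max, -1, -1), "left")
    right = _cross(np.arange(i_max, x.size), "right")
    return float(right - left)


def axial_fwhm(profile: AxialProfile) -> float:
    """FWHM (µm) of an :class:`AxialProfile` by linear interpolation at half max."""
    return fwhm_of_profile(profile.z, profile.intensity)


def design_annulus(
    target_fwhm: float,
    na_outer: float,
    wavelength: float,
    refractive_index: float = 1.33,
) -> float:
    """Inner/outer mask radius ratio giving a requested axial FWHM.

    FWHM grows monotonically with the ratio (thinner annulus), so the
    design is a 1D root search on the closed-form FWHM.  Raises
    ``ValueError`` when the target is below the full-aperture limit.
    """
    lo, hi = 1e-6, 1.0 - 1e-9

    def f(ratio: float) -> float:
        spec = AnnulusSpec(na_outer, ratio, wavelength, refractive_index)
        return closed_form_fwhm(spec) - target_fwhm

    if f(lo) > 0:
        raise ValueError(
            f"target FWHM {target_fwhm} µm is below the full-aperture limit "
            f"{f(lo) + target_fwhm:.3g} µm at NA {na_outer}"
        )
    ratio = brentq(f, lo, hi, xtol=1e-12)
    return float(ratio)


def measure_bead_fwhm(stack, axis: str = "axial") -> float:
    """FWHM (µm) of a 1D profile through the brightest voxel of a bead stack.

    ``axis="axial"`` takes the profile along z at the maximum's (y, x);
    ``axis="lateral"`` takes the row profile through the maximum in its
    brightest plane.
    """
    data = np.asarray(stack.data, dtype=float)
    if data.size == 0 or np.ptp(data) == 0:
        raise ValueError("stack is empty or constant; cannot measure a bead profile")
    zc, yc, xc = np.unravel_index(int(np.argmax(data)), data.shape)
    if axis == "axial":
        profile = data[:, yc, xc]
        coords = np.arange(data.shape[0]) * stack.z_step
    elif axis == "lateral":
        profile = data[zc, yc, :]
        coords = np.arange(data.shape[2]) * stack.pixel_size
    else:
        raise ValueError(f"axis must be 'axial' or 'lateral', got {axis!r}")
    return fwhm_of_profile(coords, profile)
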