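"""STED effective point-spread-function (E-PSF) optics model.

In a STED microscope the fluorescence ability surviving depletion is well
described by a Gaussian E-PSF whose full width at half maximum shrinks with
the doughnut peak intensity ``I`` as

    d(I) = lambda / (2 NA sqrt(1 + I / I_s))

where ``lambda`` is the STED wavelength, ``NA`` the numerical aperture and
``I_s`` the saturation intensity (the intensity that halves the fluorescence
ability).  All intensities in this package are dimensionless multiples of
``I_s``; lengths are nanometres.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "EPSFModel",
    "FWHM_TO_SIGMA",
    "epsf_fwhm",
    "intensity_for_fwhm",
    "epsf_value",
    "fwhm_to_sigma",
    "sigma_to_fwhm",
    "doughnut_intensity",
]

#: sigma = FWHM / (2 sqrt(2 ln 2)); approximately 0.4247
FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))

_4LN2 = 4.0 * math.log(2.0)


@dataclass(frozen=True)
class EPSFModel:
    """Optics parameters of the STED E-PSF.

    Parameters
    ----------
    lambda_sted : float
        STED-beam wavelength in nm.  The diffraction-limited width at
        ``I = 0`` is computed from this wavelength; pass an explicit
        ``d0_override`` to use a different zero-intensity width.
    numerical_aperture : float
        Objective numerical aperture (dimensionless).
    I_s : float
        Saturation intensity in arbitrary units; defaults to 1 so that all
        intensities are expressed as multiples of I_s.
    d0_override : float or None
        Optional replacement for the I=0 FWHM in nm.
    """

    lambda_sted: float = 775.0
    numerical_aperture: float = 1.4
    I_s: float = 1.0
    d0_override: float | None = None

    def __post_init__(self) -> None:
        if self.lambda_sted <= 0:
            raise ValueError("lambda_sted must be positive")
        if not (0.0 < self.numerical_aperture <= 1.7):
            raise ValueError("numerical_aperture must be in (0, 1.7]")
        if self.I_s <= 0:
            raise ValueError("I_s must be positive")
        if self.d0_override is not None and self.d0_override <= 0:
            raise ValueError("d0_override must be positive")

    @property
    def d0(self) -> float:
        """Zero-STED (diffraction-limited) E-PSF FWHM in nm."""
        if self.d0_override is not None:
            return self.d0_override
        return self.lambda_sted / (2.0 * self.numerical_aperture)


def epsf_fwhm(model: EPSFModel, I) -> np.ndarray | float:
    """E-PSF FWHM ``d = d0 / sqrt(1 + I/I_s)`` at doughnut peak intensity ``I``.

    ``I`` may be a scalar or array; negative intensities raise ``ValueError``.
    """
    I = np.asarray(I, dtype=float)
    if np.any(I < 0):
        raise ValueError("STED intensity must be non-negative")
    out = model.d0 / np.sqrt(1.0 + I / model.I_s)
    return float(out) if out.ndim == 0 else out


def intensity_for_fwhm(model: EPSFModel, d) -> np.ndarray | float:
    """Doughnut peak intensity required for E-PSF FWHM ``d`` (inverse of
    :func:`epsf_fwhm`): ``I = I_s ((d0/d)^2 - 1)``."""
    d = np.asarray(d, dtype=float)
    d0 = model.d0
    if np.any(d <= 0) or np.any(d > d0 * (1 + 1e-12)):
        raise ValueError(f"FWHM must lie in (0, d0={d0:.4g}] nm")
    out = model.I_s * ((d0 / d) ** 2 - 1.0)
    out = np.maximum(out, 0.0)  # clip rounding at d = d0
    return float(out) if out.ndim == 0 else out


def epsf_value(d, rho) -> np.ndarray | float:
    """Relative emission probability at distance ``rho`` from the doughnut
    minimum for a Gaussian E-PSF of FWHM ``d``: ``exp(-4 ln2 rho^2 / d^2)``.

    Equals 1 at rho=0 and exactly 0.5 at rho=d/2.
    """
    d = np.asarray(d, dtype=float)
    rho = np.asarray(rho, dtype=float)
    if np.any(d <= 0):
        raise ValueError("FWHM d must be positive")
    if np.any(rho < 0):
        raise ValueError("radial distance must be non-negative")
    out = np.exp(-_4LN2 * (rho / d) ** 2)
    return float(out) if out.ndim == 0 else out


def fwhm_to_sigma(x) -> np.ndarray | float:
    """Convert a Gaussian FWHM to its standard deviation (factor ~0.4247)."""
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("length must be positive")
    out = x * FWHM_TO_SIGMA
    return float(out) if out.ndim == 0 else out


def sigma_to_fwhm(x) -> np.ndarray | float:
    """Convert a Gaussian standard deviation to its FWHM (exact inverse of
    :func:`fwhm_to_sigma`)."""
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("length must be positive")
    out = x / FWHM_TO_SIGMA
    return float(out) if out.ndim == 0 else out


def doughnut_intensity(model: EPSFModel, I_peak, rho) -> np.ndarray | float:
    """Radial doughnut intensity profile (diagnostic only).

    First-order vortex-beam approximation
    ``I(rho) = I_peak * (2 e rho^2 / w^2) * exp(-2 rho^2 / w^2)`` with waist
    ``w = lambda / (pi NA)``; zero on the axis and maximal (= ``I_peak``) on
    the crest at ``rho = w / sqrt(2)``.  The localization math never uses this
    profile — the Gaussian E-PSF is authoritative; it exists to inspect the
    intensity the fluorophore experiences during a scan.
    """
    I_peak = np.asarray(I_peak, dtype=float)
    rho = np.asarray(rho, dtype=float)
    if np.any(I_peak < 0):
        raise ValueError("I_peak must be non-negative")
    if np.any(rho < 0):
        raise ValueError("radial distance must be non-negative")
    w = model.lambda_sted / (math.pi * model.numerical_aperture)
    u = (rho / w) ** 2
    out = I_peak * 2.0 * math.e * u * np.exp(-2.0 * u)
    return float(out) if out.ndim == 0 else out
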