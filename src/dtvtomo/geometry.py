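"""Imaging-system geometry for free-space-propagation phase contrast.

A point-projection microscope with source-to-object distance ``R1`` and
object-to-detector (propagation) distance ``R2`` magnifies the object by
``M = (R1 + R2) / R1``.  Finite source size and detector point-spread
function blur the image; modelling both as Gaussians of widths ``sigma_s``
and ``sigma_d`` gives the total system PSF width

    sigma = sqrt((1 - 1/M)^2 sigma_s^2 + sigma_d^2 / M^2)

expressed at the object (effective-pixel) plane.  For a fixed system
length ``R1 + R2`` the phase-fringe contrast is maximised at

    M_opt = 1 + sigma_d / sigma_s,

which balances the growth of the propagation term against the source-blur
penalty.  All blur widths here are the Gaussian width parameter of the
formula above; full-width-at-half-maximum conversion (x 2.3548) is applied
only where resolution is *measured*, in :mod:`dtvtomo.metrics`.

Units at construction: distances in mm, blur widths and pixel pitch in
micrometres, wavelength in metres.  Internally everything is converted to
micrometres.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "SystemGeometry",
    "optimal_magnification",
    "system_psf_width",
    "effective_pixel_size",
]

_MM = 1.0e3  # mm -> um
_M = 1.0e6  # m -> um


@dataclass(frozen=True)
class SystemGeometry:
    """Cone/parallel imaging geometry and optical constants.

    Parameters
    ----------
    R1 : float
        Source-to-object distance in mm.  Must be positive.
    R2 : float
        Object-to-detector propagation distance in mm.  ``0`` is the
        contact configuration.
    sigma_s : float
        Gaussian width of the source spot, micrometres.
    sigma_d : float
        Gaussian width of the detector PSF, micrometres.
    pixel_pitch : float
        Physical detector pixel size, micrometres.
    lambda_eff : float
        Effective (mean polychromatic) wavelength in metres.
    delta_beta : float
        Ratio delta/beta of the homogeneous-object complex refractive
        index ``n = 1 - delta + i beta``; used by phase retrieval.
    """

    R1: float
    R2: float
    sigma_s: float
    sigma_d: float
    pixel_pitch: float
    lambda_eff: float
    delta_beta: float

    def __post_init__(self) -> None:
        if self.R1 <= 0:
            raise ValueError(f"R1 must be > 0 mm, got {self.R1}")
        if self.R2 < 0:
            raise ValueError(f"R2 must be >= 0 mm, got {self.R2}")
        if self.sigma_s < 0 or self.sigma_d < 0:
            raise ValueError("blur widths must be non-negative")
        if self.pixel_pitch <= 0:
            raise ValueError("pixel_pitch must be > 0 um")
        if self.lambda_eff <= 0:
            raise ValueError("lambda_eff must be > 0 m")
        if self.delta_beta <= 0:
            raise ValueError("delta_beta must be > 0")

    # -- derived quantities, all in micrometres ------------------------------

    @property
    def magnification(self) -> float:
        """Geometric magnification ``M = (R1 + R2) / R1`` (>= 1)."""
        return (self.R1 + self.R2) / self.R1

    @property
    def r1_um(self) -> float:
        return self.R1 * _MM

    @property
    def r2_um(self) -> float:
        return self.R2 * _MM

    @property
    def wavelength_um(self) -> float:
        return self.lambda_eff * _M

    @property
    def effective_pixel_um(self) -> float:
        """Detector pixel size demagnified to the sample plane."""
        return self.pixel_pitch / self.magnification

    @property
    def system_sigma_um(self) -> float:
        """Total system PSF Gaussian width at the sample plane."""
        return system_psf_width(self.magnification, self.sigma_s, self.sigma_d)

    @property
    def mu_per_beta(self) -> float:
        """Conversion ``mu = 4 pi beta / lambda`` in um^-1 per unit beta."""
        return 4.0 * math.pi / self.wavelength_um


def optimal_magnification(sigma_s: float, sigma_d: float) -> float:
    """Contrast-optimal magnification ``1 + sigma_d / sigma_s``.

    Valid for a fixed source-to-detector length; depends only on the ratio
    of detector PSF width to source width.

    Raises
    ------
    ValueError
        If ``sigma_s`` is zero (point source: the optimum is unbounded).
    """
    if sigma_s <= 0:
        raise ValueError("optimal magnification undefined for a point source (sigma_s = 0)")
    if sigma_d < 0:
        raise ValueError("sigma_d must be non-negative")
    return 1.0 + sigma_d / sigma_s


def system_psf_width(M: float, sigma_s: float, sigma_d: float) -> float:
    """Total system PSF width at magnification ``M`` (micrometres).

    ``sqrt((1 - 1/M)^2 sigma_s^2 + sigma_d^2 / M^2)``; reduces to
    ``sigma_d`` at contact (M = 1) and approaches ``sigma_s`` as M grows.
    """
    if M < 1.0:
        raise ValueError(f"magnification must be >= 1, got {M}")
    return math.hypot((1.0 - 1.0 / M) * sigma_s, sigma_d / M)


def effective_pixel_size(geom: SystemGeometry) -> float:
    """Detector pixel pitch referred to the sample plane, micrometres."""
    return geom.effective_pixel_um
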