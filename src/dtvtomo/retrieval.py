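"""Single-distance TIE-based (Paganin-type) phase retrieval.

For a homogeneous object with known delta/beta, the projected phase can be
recovered from one flat/dark-corrected near-field image by a Fourier
filter:

    phi = -(1/2) (delta/beta) log | F^-1 [ F(I / I0) / D(u, v) ] |
    D(u, v) = (lambda R2 / 4 pi M) (delta/beta) (u^2 + v^2) + 1

with (u, v) the *angular* spatial frequencies (rad per micrometre) on the
effective-pixel grid and R2/M the effective propagation distance.  This
convention makes the filter the exact inverse of the linearised TIE
forward model: at R2 = 0 the filter is unity and the formula reduces to
Beer-Lambert inversion, and for a weak homogeneous object the retrieval
inverts :func:`dtvtomo.simulate.tie_intensity` up to linearisation error.
The low-pass character of the filter is what converts phase contrast into
a large CNR gain on noisy data.

Images are symmetrically padded to twice their size before the transform
to suppress wrap-around; intensities are clamped at a small positive floor
before the logarithm.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .geometry import SystemGeometry

__all__ = ["FrequencyGrid", "retrieval_filter", "retrieve_phase", "retrieve_stack"]

log = logging.getLogger(__name__)

#: default floor for I/I0 before the logarithm
CLAMP_FLOOR = 1.0e-6


@dataclass(frozen=True)
class FrequencyGrid:
    """Angular spatial-frequency coordinates matching an image grid.

    ``u``/``v`` are in rad/um, DC at index (0, 0), shapes equal to the
    image shape (FFT layout).
    """

    u: np.ndarray
    v: np.ndarray

    @classmethod
    def for_shape(cls, shape: tuple[int, int], spacing: float) -> "FrequencyGrid":
        fy = 2.0 * np.pi * np.fft.fftfreq(shape[0], d=spacing)
        fx = 2.0 * np.pi * np.fft.fftfreq(shape[1], d=spacing)
        v, u = np.meshgrid(fy, fx, indexing="ij")
        return cls(u=u, v=v)


def retrieval_filter(grid: FrequencyGrid, geom: SystemGeometry,
                     delta_beta: float | None = None) -> np.ndarray:
    """Paganin denominator ``1 / (c (u^2+v^2) + 1)``; 1 at DC, in (0, 1]."""
    db = geom.delta_beta if delta_beta is None else float(delta_beta)
    if db <= 0:
        raise ValueError("delta/beta must be positive")
    c = (geom.wavelength_um * geom.r2_um / (4.0 * np.pi * geom.magnification)) * db
    return 1.0 / (c * (grid.u ** 2 + grid.v ** 2) + 1.0)


def retrieve_phase(
    projection: np.ndarray,
    geom: SystemGeometry,
    delta_beta: float | None = None,
    spacing: float | None = None,
    pad: bool = True,
    clamp: float = CLAMP_FLOOR,
) -> np.ndarray:
    """Retrieve the projected phase from one corrected projection I/I0.

    ``projection`` may be 1D (single-slice detector row) or 2D.  Returns a
    real phase image of the same shape; the sign convention is positive
    for phase-delaying material (the negative of the physical phase shift
    ``-(2 pi / lambda) int delta dz``).
    """
    db = geom.delta_beta if delta_beta is None else float(delta_beta)
    h = geom.effective_pixel_um if spacing is None else float(spacing)
    img = np.atleast_2d(np.asarray(projection, dtype=float))
    squeeze = np.asarray(projection).ndim == 1
    n_clamped = int(np.count_nonzero(img < clamp))
    if n_clamped:
        log.warning("clamping %d non-positive/low pixels to %.1e before retrieval",
                    n_clamped, clamp)
        img = np.clip(img, clamp, None)

    if pad:
        py, px = img.shape[0], img.shape[1]
        # symmetric padding keeps boundary values continuous across the wrap
        work = np.pad(img, ((0, py), (0, px)), mode="symmetric")
    else:
        work = img
    grid = FrequencyGrid.for_shape(work.shape, h)
    filt = retrieval_filter(grid, geom, db)
    rec = np.fft.ifft2(np.fft.fft2(work) * filt)
    rec = np.abs(rec)[: img.shape[0], : img.shape[1]]
    phi = -0.5 * db * np.log(np.clip(rec, clamp, None))
    return phi[0] if squeeze else phi


def retrieve_stack(projections: np.ndarray, geom: SystemGeometry, **kwargs) -> np.ndarray:
    """Apply :func:`retrieve_phase` to every projection in a stack."""
    stack = np.asarray(projections, dtype=float)
    return np.stack([retrieve_phase(p, geom, **kwargs) for p in stack])
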