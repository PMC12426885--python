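"""Forward simulator for free-space-propagation phase-contrast scans.

Pipeline per projection: Beer-Lambert contact image and projected phase
from the (delta, beta) maps -> near-field transport-of-intensity (TIE)
propagation -> Gaussian system blur -> Poisson photon noise, with flat and
dark frames included.  Static protocols freeze the phantom; continuous
protocols rotate at constant angular velocity, evaluating the evolving
phantom at each exposure midpoint (no intra-exposure integration).

The detector image of the TIE model is

    I(z_d) = (contact / M^2) * (1 - (R2 lambda / 2 pi M) Lap phi)

with the transverse Laplacian taken on the effective-pixel grid.  A single
effective wavelength is used throughout (no polychromatic weighting).

Simulation and reconstruction share the same discrete projector; a
``supersample`` factor rasterises the phantom on a finer grid and bins the
detector to avoid the inverse crime when desired.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
from scipy import ndimage

from .geometry import SystemGeometry
from .phantom import VesselPhantom, optics_maps
from .projector import ParallelProjector

__all__ = [
    "ScanProtocol",
    "ProjectionSet",
    "contact_image",
    "tie_intensity",
    "apply_system_blur",
    "simulate_scan",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScanProtocol:
    """Acquisition protocol for a reference or dynamic scan.

    ``static`` mode distributes ``n_projections`` over ``angular_range``
    with the sample frozen; ``continuous`` mode rotates at
    ``angular_velocity`` (deg/s) while frames of length ``exposure`` are
    read out back to back.  ``photons_per_pixel`` is the expected
    flat-field count per frame; ``None`` disables noise.

    ``angle_offset_deg``, ``step_scale``, ``skip_at``/``skip_frames`` model
    acquisition imperfections: an unknown start angle, detector dead-time
    dilation of the angular step, and a mid-scan burst of dropped frames.
    The *recorded* angles are always the nominal ones; the true angles are
    kept in the projection metadata for validation.
    """

    mode: str = "static"
    n_projections: int = 360
    angular_range: float = 180.0
    exposure: float = 1.0
    angular_velocity: float = 0.0
    photons_per_pixel: float | None = None
    seed: int = 0
    angle_offset_deg: float = 0.0
    step_scale: float = 1.0
    skip_at: int | None = None
    skip_frames: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("static", "continuous"):
            raise ValueError(f"unknown scan mode {self.mode!r}")
        if self.n_projections < 1:
            raise ValueError("n_projections must be >= 1")
        if self.exposure <= 0:
            raise ValueError("exposure must be > 0 s")
        if self.mode == "continuous" and self.angular_velocity <= 0:
            raise ValueError("continuous mode requires angular_velocity > 0")

    @property
    def duration(self) -> float:
        """Total scan time in seconds."""
        return self.n_projections * self.exposure

    def nominal_angles(self) -> np.ndarray:
        if self.mode == "static":
            return np.arange(self.n_projections) * self.angular_range / self.n_projections
        return self.angular_velocity * self.exposure * np.arange(self.n_projections)

    def true_angles(self) -> np.ndarray:
        """Actual sample angles per recorded frame, imperfections applied."""
        idx = np.arange(self.n_projections, dtype=float)
        if self.skip_at is not None and self.skip_frames > 0:
            idx = idx + self.skip_frames * (np.arange(self.n_projections) >= self.skip_at)
        if self.mode == "static":
            step = self.angular_range / self.n_projections
        else:
            step = self.angular_velocity * self.exposure
        return self.angle_offset_deg + step * self.step_scale * idx

    def frame_times(self) -> np.ndarray:
        """True frame start times (s), accounting for skipped frames."""
        idx = np.arange(self.n_projections, dtype=float)
        if self.skip_at is not None and self.skip_frames > 0:
            idx = idx + self.skip_frames * (np.arange(self.n_projections) >= self.skip_at)
        return idx * self.exposure


@dataclass
class ProjectionSet:
    """Measured/simulated detector frames with references and bookkeeping.

    ``intensity`` has shape (n_projections, nz, n_det); a single-slice
    phantom gives nz = 1.  ``angles_deg`` are the nominal (recorded)
    angles; true angles, when known, live in ``meta["true_angles_deg"]``.
    """

    intensity: np.ndarray
    flat: np.ndarray
    dark: np.ndarray
    angles_deg: np.ndarray
    timestamps: np.ndarray
    pixel_size: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 3:
            raise ValueError("intensity must be (n_proj, nz, n_det)")
        n = self.intensity.shape[0]
        if not (len(self.angles_deg) == len(self.timestamps) == n):
            raise ValueError("angles/timestamps length mismatch")

    @property
    def n_projections(self) -> int:
        return self.intensity.shape[0]

    def corrected(self) -> np.ndarray:
        """Dark- and flat-field corrected projections (I - d) / (f - d)."""
        denom = self.flat - self.dark
        if np.any(denom <= 0):
            raise ValueError("flat - dark must be positive everywhere")
        return (self.intensity - self.dark[None]) / denom[None]


def contact_image(
    delta_map: np.ndarray,
    beta_map: np.ndarray,
    angle_deg: float,
    geom: SystemGeometry,
    voxel_size: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Attenuation contact image and projected phase at one angle.

    ``mu = 4 pi beta / lambda`` is integrated along rays to give
    ``exp(-int mu dz)`` in (0, 1]; the phase is ``-(2 pi / lambda) int
    delta dz``.  Maps may be 2D (one slice) or 3D (slice stack); output
    shape is (nz, n_det).
    """
    delta_map = np.asarray(delta_map, dtype=float)
    beta_map = np.asarray(beta_map, dtype=float)
    if delta_map.shape != beta_map.shape:
        raise ValueError("delta and beta maps must be co-registered")
    if np.any(beta_map < 0):
        raise ValueError("beta must be non-negative")
    if delta_map.ndim == 2:
        delta_map = delta_map[None]
        beta_map = beta_map[None]
    nz, ny, nx = delta_map.shape
    if ny != nx:
        raise ValueError("slices must be square")
    proj = ParallelProjector(nx, voxel_size)
    lam = geom.wavelength_um
    mu_int = np.empty((nz, proj.n_det))
    delta_int = np.empty((nz, proj.n_det))
    for z in range(nz):
        mu_int[z] = proj.forward(beta_map[z] * geom.mu_per_beta, [angle_deg])[0]
        delta_int[z] = proj.forward(delta_map[z], [angle_deg])[0]
    attenuation = np.exp(-mu_int)
    phase = -(2.0 * np.pi / lam) * delta_int
    return attenuation, phase


def tie_intensity(
    attenuation_image: np.ndarray,
    phase_image: np.ndarray,
    geom: SystemGeometry,
    spacing: float | None = None,
) -> np.ndarray:
    """Near-field detector intensity from the TIE model.

    ``spacing`` is the transverse grid step in micrometres (defaults to
    the geometry's effective pixel).  Negative intensities (weak-object
    violation at strong edges) are clipped to zero with a logged warning.
    """
    att = np.atleast_2d(np.asarray(attenuation_image, dtype=float))
    phi = np.atleast_2d(np.asarray(phase_image, dtype=float))
    if att.shape != phi.shape:
        raise ValueError("attenuation and phase images must match")
    h = geom.effective_pixel_um if spacing is None else float(spacing)
    M = geom.magnification
    coeff = geom.r2_um * geom.wavelength_um / (2.0 * np.pi * M)
    lap = ndimage.laplace(phi, mode="reflect") / h ** 2
    out = (att / M ** 2) * (1.0 - coeff * lap)
    n_neg = int(np.count_nonzero(out < 0))
    if n_neg:
        log.warning("TIE intensity negative at %d pixels; clipping to 0", n_neg)
        out = np.clip(out, 0.0, None)
    return out


def apply_system_blur(detector_image: np.ndarray, geom: SystemGeometry,
                      spacing: float | None = None) -> np.ndarray:
    """Convolve with the Gaussian system PSF (flux-conserving, reflective)."""
    img = np.asarray(detector_image, dtype=float)
    h = geom.effective_pixel_um if spacing is None else float(spacing)
    sigma_px = geom.system_sigma_um / h
    if sigma_px == 0:
        return img.copy()
    return ndimage.gaussian_filter(img, sigma_px, mode="reflect")


def simulate_scan(
    phantom_timeline: Callable[[float], VesselPhantom] | VesselPhantom,
    protocol: ScanProtocol,
    geom: SystemGeometry,
    supersample: int = 1,
    n_flats: int = 16,
) -> ProjectionSet:
    """Simulate a full scan of an evolving phantom.

    ``phantom_timeline`` maps time (s) to a phantom state; a bare phantom
    is treated as static.  In continuous mode frame ``i`` starts at
    ``t_i = i * exposure`` and the phantom is evaluated at the exposure
    midpoint.  Poisson noise is applied to expected counts
    ``photons_per_pixel * M^2 * I`` (so an empty beam averages
    ``photons_per_pixel``); flats are the average of ``n_flats`` noisy
    flat frames, darks are zero.
    """
    if isinstance(phantom_timeline, VesselPhantom):
        frozen = phantom_timeline
        timeline = lambda t: frozen  # noqa: E731
    else:
        timeline = phantom_timeline
    if supersample < 1:
        raise ValueError("supersample must be >= 1")

    nominal = protocol.nominal_angles()
    true_angles = protocol.true_angles()
    t_start = protocol.frame_times()
    timestamps = np.arange(protocol.n_projections) * protocol.exposure
    rng = np.random.default_rng(protocol.seed)
    M = geom.magnification

    _cache: dict[float, tuple] = {}

    def maps_at(t: float):
        if t in _cache:
            return _cache[t]
        ph = timeline(t)
        if ph is None:
            raise ValueError(f"phantom timeline undefined at t = {t} s")
        if supersample > 1:
            nz, ny, nx = ph.grid_shape
            ph = replace(ph, grid_shape=(nz, ny * supersample, nx * supersample),
                         voxel_size=ph.voxel_size / supersample, labels=None)
        out = ph, optics_maps(ph)
        if len(_cache) < 4:  # static scans reuse one state; dynamic ones never hit
            _cache[t] = out
        return out

    first_ph = timeline(0.0)
    vox = first_ph.voxel_size
    spacing = vox / supersample
    frames = []
    for i in range(protocol.n_projections):
        if protocol.mode == "static":
            t_mid = 0.0
        else:
            t_mid = t_start[i] + protocol.exposure / 2.0
        ph, (dmap, bmap) = maps_at(t_mid)
        att, phi = contact_image(dmap, bmap, true_angles[i], geom, spacing)
        det = tie_intensity(att, phi, geom, spacing)
        det = apply_system_blur(det, geom, spacing)
        if supersample > 1:
            det = det.reshape(det.shape[0], -1, supersample).mean(axis=2)
        frames.append(det)
    ideal = np.stack(frames)  # includes the 1/M^2 factor

    flat_ideal = np.full(ideal.shape[1:], 1.0 / M ** 2)
    if protocol.photons_per_pixel is None:
        intensity = ideal
        flat = flat_ideal
    else:
        scale = protocol.photons_per_pixel * M ** 2
        intensity = rng.poisson(scale * ideal).astype(float)
        flat = rng.poisson(scale * flat_ideal, size=(n_flats,) + flat_ideal.shape)
        flat = flat.mean(axis=0)
    dark = np.zeros_like(flat)

    return ProjectionSet(
        intensity=intensity,
        flat=flat,
        dark=dark,
        angles_deg=nominal,
        timestamps=timestamps,
        pixel_size=vox,
        meta={
            "true_angles_deg": true_angles,
            "mode": protocol.mode,
            "exposure_s": protocol.exposure,
            "angular_velocity_deg_s": protocol.angular_velocity,
            "magnification": M,
        },
    )
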