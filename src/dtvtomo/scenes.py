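"""Reference study scenes: end-to-end synthetic experiments.

These functions wire the phantom, simulator, retrieval, reconstruction
and analysis modules into the canonical desk-scale experiments the
package is validated on:

- :func:`dynamic_slice_scene` -- one axial slice of the wood skewer
  imaged twice: a long well-sampled reference scan of the dry state, and
  a fast undersampled continuous scan of a partially water-filled state.
  The three processing chains (conventional attenuation FBP, analytical
  phase-retrieved FBP, dTV-regularised phase-retrieved) are reconstructed
  from the *same* dynamic data.
- :func:`filling_timeline_scene` -- a 3D phantom filling by capillary
  action over many time points, producing classified volumes for the
  waterfront tracker.

Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .dtv import PriorField, ReconConfig, pdhg_reconstruct
from .geometry import SystemGeometry
from .phantom import (WATER, FillSchedule, VesselFill, VesselPhantom,
                      build_phantom, default_schedule, fill_state, optics_maps)
from .projector import Sinogram, VolumeImage, fbp_reconstruct
from .retrieval import retrieve_phase
from .simulate import ProjectionSet, ScanProtocol, simulate_scan

__all__ = [
    "study_geometry",
    "DynamicSliceScene",
    "dynamic_slice_scene",
    "phase_sinogram",
    "attenuation_sinogram",
    "filling_timeline_scene",
]


def study_geometry() -> SystemGeometry:
    """The laboratory propagation geometry used throughout the package."""
    return SystemGeometry(R1=320.0, R2=140.0, sigma_s=70.0, sigma_d=30.0,
                          pixel_pitch=15.0, lambda_eff=6.53e-11, delta_beta=1000.0)


def phase_sinogram(pset: ProjectionSet, geom: SystemGeometry) -> Sinogram:
    """Retrieve phase per projection and convert to delta line integrals.

    The retrieved phase of a delta-decrement ``delta`` over path T is
    ``2 pi delta T / lambda``, so dividing by ``2 pi / lambda`` yields the
    delta line integral that the projector models.
    """
    corr = pset.corrected()[:, 0, :]
    phis = np.stack([retrieve_phase(row, geom, spacing=pset.pixel_size)
                     for row in corr])
    return Sinogram(phis * geom.wavelength_um / (2.0 * np.pi),
                    pset.angles_deg, pset.pixel_size, timestamps=pset.timestamps)


def attenuation_sinogram(pset: ProjectionSet, floor: float = 1.0e-6) -> Sinogram:
    """Log-normalised attenuation line integrals (conventional chain)."""
    corr = np.clip(pset.corrected()[:, 0, :], floor, None)
    return Sinogram(-np.log(corr), pset.angles_deg, pset.pixel_size,
                    timestamps=pset.timestamps)


@dataclass
class DynamicSliceScene:
    """All artefacts of the single-slice dynamic experiment."""

    geom: SystemGeometry
    phantom_dry: VesselPhantom
    phantom_dyn: VesselPhantom
    reference_scan: ProjectionSet
    dynamic_scan: ProjectionSet
    v: VolumeImage                      # high-quality dry reference (delta)
    recon_conventional: VolumeImage     # FBP of attenuation data (mu)
    recon_analytical: VolumeImage       # FBP of phase-retrieved data (delta)
    recon_regularised: VolumeImage      # dTV-PDHG of phase-retrieved data
    prior: PriorField
    masks: dict = field(default_factory=dict)

    def cnr_samples(self, volume: VolumeImage) -> tuple[np.ndarray, np.ndarray]:
        """(water, air) grey-value samples from the eroded vessel masks."""
        return volume.values[self.masks["water"]], volume.values[self.masks["air"]]

    def static_edge_profile(self, volume: VolumeImage, span_um: float = 160.0):
        """Edge profile across the outer wood-air boundary (prior-aligned).

        Sampled along the central row on the side opposite the cavity, so
        no dynamic feature contaminates the plateaus.
        """
        from .metrics import EdgeProfile

        n = volume.values.shape[0]
        vox = volume.voxel_size
        c = (n - 1) / 2.0
        cav = self.phantom_dry.vessels[0]
        side = -1 if cav.x_um > 0 else 1  # away from the cavity
        edge_x = c + side * self.phantom_dry.wood_radius_um / vox
        half = int(round(span_um / vox))
        xs = np.arange(int(round(edge_x)) - half, int(round(edge_x)) + half + 1)
        xs = xs[(xs >= 0) & (xs < n)]
        row = int(round(c))
        vals = volume.values[row, xs]
        if side == -1:  # make the profile run wood -> air consistently
            vals = vals[::-1]
        return EdgeProfile((np.arange(vals.size)) * vox, vals)

    def waterline_profile(self, volume: VolumeImage, inset_voxels: int = 2):
        """Vertical profile through the cavity crossing the water level.

        This edge does not exist in the dry reference, so the prior offers
        the solver no gradient direction here.
        """
        from .metrics import EdgeProfile

        n = volume.values.shape[0]
        vox = volume.voxel_size
        c = (n - 1) / 2.0
        cav = self.phantom_dry.vessels[0]
        cx = int(round(c + cav.x_um / vox))
        cy = int(round(c + cav.y_um / vox))
        rr = int(round(cav.radius_um / vox))
        ys = np.arange(cy - rr + inset_voxels, cy + rr - inset_voxels + 1)
        return EdgeProfile((ys - ys[0]) * vox, volume.values[ys, cx])


def _lumen_mask(ph: VesselPhantom, ids, erode: int = 1) -> np.ndarray:
    m = np.zeros(ph.grid_shape[1:], bool)
    for v in ph.vessels:
        if v.vessel_id in ids:
            m |= ph.vessel_cross_section(v)
    return ndimage.binary_erosion(m, iterations=erode) if erode else m


def dynamic_slice_scene(
    seed: int,
    n: int = 128,
    n_vessels: int = 10,
    cavity_radius_um: float = 160.0,
    reference_projections: int = 360,
    dynamic_projections: int = 180,
    reference_photons: float = 20000.0,
    dynamic_photons: float = 1000.0,
    alpha: float = 1.0e4,
    eta_rel: float = 0.2,
    n_iterations: int = 100,
    geom: SystemGeometry | None = None,
) -> DynamicSliceScene:
    """Build, scan and reconstruct the single-slice dynamic experiment.

    The dry phantom carries ``n_vessels`` small vessels plus one large
    cavity.  In the dynamic state every other small vessel is filled with
    water and the cavity holds a horizontal water level at its midline --
    an edge the dry reference knows nothing about.  The reference scan is
    static and well sampled; the dynamic scan is a 9 s continuous rotation
    (180 x 50 ms at 20 deg/s) with 20x fewer photons per frame.
    """
    geom = geom or study_geometry()
    vox = geom.effective_pixel_um
    ph = build_phantom(n_vessels, (n, n), vox, seed=seed,
                       radius_range_um=(32.0, 52.0),
                       large_cavity_radius_um=cavity_radius_um)
    cavity = ph.vessels[0]
    small = ph.vessels[1:]
    water_ids = [v.vessel_id for i, v in enumerate(small) if i % 2 == 0]
    air_ids = [v.vessel_id for v in small if v.vessel_id not in water_ids]

    labels_dyn = ph.labels.copy()
    yy, xx = ph._inplane_coords()
    for v in small:
        if v.vessel_id in water_ids:
            labels_dyn[0][ph.vessel_cross_section(v)] = WATER
    lumen_cavity = ph.vessel_cross_section(cavity)
    labels_dyn[0][lumen_cavity & (yy < cavity.y_um)] = WATER
    ph_dyn = replace(ph, labels=labels_dyn)

    ref_scan = simulate_scan(
        ph, ScanProtocol(mode="static", n_projections=reference_projections,
                         angular_range=180.0, exposure=1.0,
                         photons_per_pixel=reference_photons, seed=seed), geom)
    dyn_scan = simulate_scan(
        ph_dyn, ScanProtocol(mode="continuous", n_projections=dynamic_projections,
                             exposure=0.05, angular_velocity=20.0,
                             photons_per_pixel=dynamic_photons, seed=seed + 1), geom)

    v_ref = fbp_reconstruct(phase_sinogram(ref_scan, geom), "hann", semantics="delta")
    b_delta = phase_sinogram(dyn_scan, geom)
    b_mu = attenuation_sinogram(dyn_scan)

    recon_conv = fbp_reconstruct(b_mu, "hann", semantics="mu")
    recon_pr = fbp_reconstruct(b_delta, "hann", semantics="delta")
    prior = PriorField.from_reference(v_ref, eta_rel=eta_rel)
    cfg = ReconConfig(alpha=alpha, n_iterations=n_iterations, init="fbp",
                      objective_every=10, seed=seed)
    recon_dtv = pdhg_reconstruct(b_delta, prior, cfg)

    masks = {
        "water": _lumen_mask(ph, water_ids),
        "air": _lumen_mask(ph, air_ids),
        "cavity": lumen_cavity,
        "wood": ndimage.binary_erosion(
            (xx ** 2 + yy ** 2 <= ph.wood_radius_um ** 2), iterations=3)
        & (ph.labels[0] == 1),
        "water_ids": water_ids,
        "air_ids": air_ids,
    }
    return DynamicSliceScene(
        geom=geom, phantom_dry=ph, phantom_dyn=ph_dyn,
        reference_scan=ref_scan, dynamic_scan=dyn_scan, v=v_ref,
        recon_conventional=recon_conv, recon_analytical=recon_pr,
        recon_regularised=recon_dtv, prior=prior, masks=masks)


def filling_timeline_scene(
    seed: int,
    grid: tuple[int, int, int] = (64, 64, 64),
    n_vessels: int = 6,
    k_ref: float = 1600.0,
    t_max: float = 180.0,
    dt: float = 9.0,
    noise_sd_frac: float = 1.0 / 6.0,
    jump_vessel_rank: int = 0,
    jump_factor: float = 3.0,
    jump_time: float | None = None,
) -> dict:
    """Capillary-filling timeline as classified-volume inputs for tracking.

    Generates a 3D phantom whose vessels fill as ``h_i = k_i sqrt(t)``
    with ``k_i`` inversely proportional to the radius; one vessel gets a
    rate-jump event (vessel separation) at ``jump_time``.  Returns the dry
    delta volume, per-time-point noisy delta volumes (Gaussian noise with
    sd a fraction of the water-air class gap, standing in for reconstruct-
    ion noise), the vessel label volume and the ground-truth schedule.
    """
    ph = build_phantom(n_vessels, grid, 10.5, seed=seed,
                       radius_range_um=(28.0, 50.0))
    schedule = default_schedule(ph, k_ref=k_ref)
    if jump_time is None:
        jump_time = 0.55 * t_max
    jumped = ph.vessels[jump_vessel_rank].vessel_id
    base = schedule.fills[jumped]
    schedule.fills[jumped] = VesselFill(
        t0=base.t0, k=base.k, events=((jump_time, jump_factor * base.k),))

    delta_dry, _ = optics_maps(ph)
    d_air = ph.optics["air"][0]
    d_water = ph.optics["water"][0]
    gap = d_water - d_air
    rng = np.random.default_rng(seed + 17)

    vessel_labels = np.zeros(ph.grid_shape, dtype=np.int32)
    for v in ph.vessels:
        vessel_labels[ph.vessel_mask(v.vessel_id)] = v.vessel_id + 1

    times = np.arange(0.0, t_max + dt / 2, dt)
    timeline = []
    for t in times:
        state = fill_state(ph, schedule, t)
        delta_t, _ = optics_maps(state)
        noisy = delta_t + noise_sd_frac * gap * rng.standard_normal(delta_t.shape)
        timeline.append((float(t), noisy))
    v_noisy = delta_dry + noise_sd_frac * gap * rng.standard_normal(delta_dry.shape)
    return {
        "phantom": ph,
        "schedule": schedule,
        "times": times,
        "timeline": timeline,
        "reference": v_noisy,
        "reference_clean": delta_dry,
        "vessel_labels": vessel_labels,
        "threshold": 0.5 * gap,
        "class_gap": gap,
        "jumped_vessel_label": jumped + 1,
        "jump_time": jump_time,
    }
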