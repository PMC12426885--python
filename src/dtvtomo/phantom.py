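"""Synthetic wood-skewer phantom with vessels filling by capillary action.

The test object is a cylinder of wood-like material standing in air, pierced
by axial vessels (initially air-filled tubes).  Over time water rises in
each vessel; the default dynamics follow a Lucas-Washburn-type law
``h_i(t) = k_i * sqrt(t - t0_i)`` with the rate constant inversely
proportional to the vessel radius, since capillary rise is faster in
narrower channels.  Optional rate-jump events emulate a joined vessel pair
separating mid-rise, which produces a sharp advance of the waterfront.

Crucially for structure-prior reconstruction, filling only relabels voxels
*inside* vessels from air to water: every material boundary of the dry
state is preserved, so the gradient directions of the dry reference and any
filled state coincide wherever both have gradients.

Vessel geometry is drawn in physical (micrometre) coordinates from the
seed, then rasterised onto the requested grid -- so the same seed yields
the same physical object at any resolution, which allows inverse-crime-free
simulation on a supersampled grid.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "AIR", "WOOD", "WATER", "MATERIAL_NAMES", "DEFAULT_OPTICS",
    "Vessel", "VesselPhantom", "VesselFill", "FillSchedule",
    "build_phantom", "fill_state", "optics_maps", "figure1_pair",
    "default_schedule",
]

AIR, WOOD, WATER = 0, 1, 2
MATERIAL_NAMES = {AIR: "air", WOOD: "wood", WATER: "water"}

#: Default (delta, beta) per material at an effective energy of ~19 keV.
#: The ordering delta_air < delta_wood < delta_water mirrors the grey-value
#: ordering observed in phase-retrieved birch reconstructions; values are
#: synthetic conventions, not instrument calibrations.
DEFAULT_OPTICS: dict[str, tuple[float, float]] = {
    "air": (1.0e-10, 1.0e-13),
    "wood": (4.0e-7, 4.0e-10),
    "water": (5.2e-7, 5.2e-10),
}


@dataclass(frozen=True)
class Vessel:
    """One axial vessel: in-plane centre and radius in micrometres.

    ``pair_id``/``separation_z_um`` describe a joined vessel pair: below the
    separation height the two tubes are connected through a shared membrane
    opening (a capsule-shaped cross-section), above it they are separate.
    """

    vessel_id: int
    x_um: float
    y_um: float
    radius_um: float
    pair_id: int | None = None
    separation_z_um: float | None = None


@dataclass
class VesselPhantom:
    """Labelled three-material volume plus the generating vessel table."""

    grid_shape: tuple[int, int, int]  # (nz, ny, nx)
    voxel_size: float  # um
    wood_radius_um: float
    vessels: list[Vessel]
    optics: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_OPTICS))
    labels: np.ndarray | None = None
    fill_heights_um: dict[int, float] = field(default_factory=dict)
    texture_amplitude: float = 0.0
    texture_seed: int = 0

    def __post_init__(self) -> None:
        if self.labels is None:
            self.labels = self._rasterize()

    # -- physical coordinate grids ------------------------------------------

    def _inplane_coords(self) -> tuple[np.ndarray, np.ndarray]:
        _, ny, nx = self.grid_shape
        y = (np.arange(ny) - (ny - 1) / 2.0) * self.voxel_size
        x = (np.arange(nx) - (nx - 1) / 2.0) * self.voxel_size
        return np.meshgrid(y, x, indexing="ij")

    def z_centers_um(self) -> np.ndarray:
        """Height of each slice centre above the volume base."""
        nz = self.grid_shape[0]
        return (np.arange(nz) + 0.5) * self.voxel_size

    def vessel_cross_section(self, vessel: Vessel, joined: bool = False) -> np.ndarray:
        """Boolean in-plane mask of one vessel (or of a joined pair capsule)."""
        yy, xx = self._inplane_coords()
        mask = (xx - vessel.x_um) ** 2 + (yy - vessel.y_um) ** 2 <= vessel.radius_um ** 2
        if joined and vessel.pair_id is not None:
            partner = next(v for v in self.vessels if v.vessel_id == vessel.pair_id)
            mask |= _capsule_mask(yy, xx, vessel, partner)
        return mask

    def vessel_mask(self, vessel_id: int) -> np.ndarray:
        """3D mask of one vessel's air/water lumen (joined sections included)."""
        v = next(ves for ves in self.vessels if ves.vessel_id == vessel_id)
        sep = self.vessel_cross_section(v, joined=False)
        if v.pair_id is None or v.separation_z_um is None:
            return np.broadcast_to(sep, self.grid_shape).copy()
        joined = self.vessel_cross_section(v, joined=True)
        z = self.z_centers_um()
        out = np.empty(self.grid_shape, dtype=bool)
        below = z < v.separation_z_um
        out[below] = joined
        out[~below] = sep
        return out

    def _rasterize(self) -> np.ndarray:
        nz, ny, nx = self.grid_shape
        yy, xx = self._inplane_coords()
        wood2d = (xx ** 2 + yy ** 2 <= self.wood_radius_um ** 2)
        labels = np.where(wood2d, WOOD, AIR).astype(np.uint8)
        labels = np.broadcast_to(labels, self.grid_shape).copy()
        z = self.z_centers_um()
        for v in self.vessels:
            lumen = self.vessel_cross_section(v, joined=False)
            if v.pair_id is not None and v.separation_z_um is not None:
                joined = self.vessel_cross_section(v, joined=True)
                below = z < v.separation_z_um
                labels[below] = np.where(joined, AIR, labels[below])
                labels[~below] = np.where(lumen, AIR, labels[~below])
            else:
                labels[:] = np.where(lumen, AIR, labels)
            h = self.fill_heights_um.get(v.vessel_id, 0.0)
            if h > 0:
                filled = z < h
                lum3 = self.vessel_mask(v.vessel_id)
                water = lum3 & filled[:, None, None]
                labels[water] = WATER
        return labels

    def to_vessel_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["id", "x_um", "y_um", "radius_um", "pair_id", "separation_z_um"])
            for v in self.vessels:
                w.writerow([v.vessel_id, v.x_um, v.y_um, v.radius_um,
                            v.pair_id if v.pair_id is not None else "",
                            v.separation_z_um if v.separation_z_um is not None else ""])


def _capsule_mask(yy: np.ndarray, xx: np.ndarray, a: Vessel, b: Vessel) -> np.ndarray:
    """Stadium-shaped connection between two vessel centres."""
    ax, ay, bx, by = a.x_um, a.y_um, b.x_um, b.y_um
    dx, dy = bx - ax, by - ay
    L2 = dx * dx + dy * dy
    if L2 == 0:
        return np.zeros_like(xx, dtype=bool)
    t = ((xx - ax) * dx + (yy - ay) * dy) / L2
    t = np.clip(t, 0.0, 1.0)
    px, py = ax + t * dx, ay + t * dy
    r = min(a.radius_um, b.radius_um)
    return (xx - px) ** 2 + (yy - py) ** 2 <= r ** 2


class PackingError(RuntimeError):
    """Vessel placement failed; carries the count that could not be packed."""

    def __init__(self, placed: int, requested: int):
        self.placed = placed
        self.requested = requested
        super().__init__(
            f"could not pack {requested} vessels (placed {placed}); "
            "enlarge the grid or reduce count/radii")


def build_phantom(
    n_vessels: int,
    grid_shape: Sequence[int],
    voxel_size: float,
    seed: int,
    radius_range_um: tuple[float, float] = (30.0, 55.0),
    wood_radius_frac: float = 0.42,
    n_pairs: int = 0,
    large_cavity_radius_um: float | None = None,
    optics: dict[str, tuple[float, float]] | None = None,
    texture_amplitude: float = 0.0,
    min_gap_um: float | None = None,
    max_tries: int = 5000,
) -> VesselPhantom:
    """Build a dry phantom: wood cylinder with non-overlapping air vessels.

    ``grid_shape`` may be ``(ny, nx)`` for a single axial slice or
    ``(nz, ny, nx)``.  ``n_pairs`` of the vessels are laid out as joined
    pairs with a membrane that opens below a separation height drawn from
    the middle of the volume.  ``large_cavity_radius_um`` optionally adds
    one oversized vessel (useful as a water reservoir whose interior is
    featureless in the dry reference).  Deterministic for a fixed seed.
    """
    if n_vessels < 0:
        raise ValueError("n_vessels must be >= 0")
    grid_shape = tuple(int(s) for s in grid_shape)
    if len(grid_shape) == 2:
        grid_shape = (1,) + grid_shape
    nz, ny, nx = grid_shape
    rng = np.random.default_rng(seed)
    half_extent = min(ny, nx) / 2.0 * voxel_size
    wood_r = wood_radius_frac * min(ny, nx) * voxel_size
    if wood_r >= half_extent:
        raise ValueError("wood cylinder does not fit inside the grid")
    height = nz * voxel_size
    gap = 2.0 * voxel_size if min_gap_um is None else float(min_gap_um)

    placed: list[Vessel] = []

    def fits(x, y, r) -> bool:
        if math.hypot(x, y) + r > wood_r - gap:
            return False
        for v in placed:
            if math.hypot(x - v.x_um, y - v.y_um) < r + v.radius_um + gap:
                return False
        return True

    def place(r: float) -> tuple[float, float]:
        for _ in range(max_tries):
            rad = (wood_r - r - gap) * math.sqrt(rng.uniform())
            ang = rng.uniform(0, 2 * math.pi)
            x, y = rad * math.cos(ang), rad * math.sin(ang)
            if fits(x, y, r):
                return x, y
        raise PackingError(len(placed), n_vessels)

    next_id = 0
    if large_cavity_radius_um is not None:
        x, y = place(large_cavity_radius_um)
        placed.append(Vessel(next_id, x, y, large_cavity_radius_um))
        next_id += 1

    n_singles = n_vessels - 2 * n_pairs
    if n_singles < 0:
        raise ValueError("n_pairs exceeds n_vessels / 2")
    for _ in range(n_pairs):
        r = rng.uniform(*radius_range_um)
        x, y = place(r)
        a = Vessel(next_id, x, y, r, pair_id=next_id + 1,
                   separation_z_um=float(rng.uniform(0.4, 0.6) * height))
        placed.append(a)
        # partner sits one membrane-width away, same radius
        for _ in range(max_tries):
            ang = rng.uniform(0, 2 * math.pi)
            d = 2 * r + 1.5 * voxel_size
            bx, by = x + d * math.cos(ang), y + d * math.sin(ang)
            if fits(bx, by, r):
                break
        else:
            raise PackingError(len(placed), n_vessels)
        placed.append(Vessel(next_id + 1, bx, by, r, pair_id=next_id,
                             separation_z_um=a.separation_z_um))
        next_id += 2
    for _ in range(n_singles):
        r = rng.uniform(*radius_range_um)
        x, y = place(r)
        placed.append(Vessel(next_id, x, y, r))
        next_id += 1

    return VesselPhantom(
        grid_shape=grid_shape,
        voxel_size=float(voxel_size),
        wood_radius_um=wood_r,
        vessels=placed,
        optics=dict(optics) if optics is not None else dict(DEFAULT_OPTICS),
        texture_amplitude=texture_amplitude,
        texture_seed=seed + 1,
    )


# ---------------------------------------------------------------------------
# filling dynamics


@dataclass(frozen=True)
class VesselFill:
    """Capillary-rise parameters for one vessel.

    ``h(t) = k * sqrt(t - t0)`` for ``t > t0``; each ``(t_e, k_new)`` event
    switches the rate constant from that time onward (height continuous).
    """

    t0: float = 0.0
    k: float = 40.0  # um / sqrt(s)
    events: tuple[tuple[float, float], ...] = ()

    def height(self, t: float) -> float:
        if t <= self.t0:
            return 0.0
        h = 0.0
        k = self.k
        t_prev = self.t0
        for t_e, k_new in sorted(self.events):
            if t_e <= self.t0:
                k = k_new
                continue
            if t <= t_e:
                break
            h += k * (math.sqrt(t_e - self.t0) - math.sqrt(t_prev - self.t0))
            k, t_prev = k_new, t_e
        h += k * (math.sqrt(t - self.t0) - math.sqrt(t_prev - self.t0))
        return h


@dataclass
class FillSchedule:
    """Per-vessel filling parameters; vessels absent from the map stay dry."""

    fills: dict[int, VesselFill]

    def height(self, vessel_id: int, t: float) -> float:
        fill = self.fills.get(vessel_id)
        return 0.0 if fill is None else fill.height(t)


def default_schedule(phantom: VesselPhantom, k_ref: float = 400.0,
                     t0_spread: float = 0.0, seed: int = 0) -> FillSchedule:
    """Rate constants inversely proportional to radius: ``k_i = k_ref / r_i``.

    ``k_ref`` has units um^(3/2)/s^(1/2) wrapped into um/sqrt(s) after the
    division; a 40 um vessel with the default fills ~10 um/sqrt(s).
    Optional start-time jitter emulates staggered water entry.
    """
    rng = np.random.default_rng(seed)
    fills = {}
    for v in phantom.vessels:
        t0 = float(rng.uniform(0, t0_spread)) if t0_spread > 0 else 0.0
        fills[v.vessel_id] = VesselFill(t0=t0, k=k_ref / v.radius_um)
    return FillSchedule(fills)


def fill_state(phantom: VesselPhantom, schedule: FillSchedule, t: float) -> VesselPhantom:
    """Phantom at time ``t``: vessel voxels below each front are water.

    Water appears only inside vessels and the water set is non-decreasing in
    ``t`` (the fill law is monotone); all other labels are untouched, so the
    material boundaries of the dry phantom are preserved.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    heights = {v.vessel_id: schedule.height(v.vessel_id, t) for v in phantom.vessels}
    return replace(phantom, fill_heights_um=heights, labels=None)


# ---------------------------------------------------------------------------
# optics


def optics_maps(phantom: VesselPhantom) -> tuple[np.ndarray, np.ndarray]:
    """Voxelwise (delta, beta) maps from the material table.

    With ``texture_amplitude > 0`` the wood voxels get a smooth
    multiplicative texture emulating sub-resolution porosity.
    """
    labels = phantom.labels
    present = np.unique(labels)
    delta = np.zeros(labels.shape)
    beta = np.zeros(labels.shape)
    for lab in present:
        name = MATERIAL_NAMES.get(int(lab))
        if name is None or name not in phantom.optics:
            raise KeyError(f"no optics declared for material {name or int(lab)!r}")
        d, b = phantom.optics[name]
        if b < 0:
            raise ValueError(f"beta must be >= 0 for material {name!r}")
        delta[labels == lab] = d
        beta[labels == lab] = b
    if phantom.texture_amplitude > 0:
        rng = np.random.default_rng(phantom.texture_seed)
        noise = ndimage.gaussian_filter(rng.standard_normal(labels.shape), 1.0)
        noise /= max(noise.std(), 1e-12)
        factor = np.clip(1.0 + phantom.texture_amplitude * noise, 0.1, None)
        wood = labels == WOOD
        delta[wood] *= factor[wood]
        beta[wood] *= factor[wood]
    return delta, beta


# ---------------------------------------------------------------------------
# shape-preserving image pair


def figure1_pair(
    seed: int,
    shape: tuple[int, int] = (128, 128),
    n_vessels: int = 8,
    changed_fraction: float = 0.5,
    blur_sigma: float = 1.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Two images with identical structure boundaries, different intensities.

    Emulates a slice before/after a dynamic process that changes what is
    *inside* structures without moving any edge: a fraction of the vessel
    interiors brightens between image ``a`` and image ``b``.  Interior
    levels are chosen strictly between background and matrix so no edge
    contrast changes sign, making the normalised gradient directions of the
    pair identical while the raw images decorrelate.
    """
    # wide placement gap so blur tails of neighbouring structures do not mix
    ph = build_phantom(n_vessels, shape, voxel_size=1.0, seed=seed,
                       radius_range_um=(4.0, 6.0), wood_radius_frac=0.44,
                       min_gap_um=6.0 * blur_sigma)
    yy, xx = ph._inplane_coords()
    inside_wood = xx ** 2 + yy ** 2 <= ph.wood_radius_um ** 2
    base = np.where(inside_wood, 1.0, 0.0)
    img_a = base.copy()
    img_b = base.copy()
    rng = np.random.default_rng(seed + 7)
    for v in ph.vessels:
        lum = ph.vessel_cross_section(v)
        img_a[lum] = 0.35
        img_b[lum] = 0.70 if rng.uniform() < changed_fraction else 0.35
    img_a = ndimage.gaussian_filter(img_a, blur_sigma)
    img_b = ndimage.gaussian_filter(img_b, blur_sigma)
    return img_a, img_b
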