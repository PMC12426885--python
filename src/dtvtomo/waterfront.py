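"""Per-vessel water classification and waterfront-height tracking.

Voxels inside a vessel are classified as water when the grey-value
difference between the dynamic reconstruction ``u(t)`` and the dry
reference ``v`` exceeds a threshold (by default the halfway point between
the water and air class means).  For each vessel the thickness ratio

    R(z) = (water voxels at height z) / (vessel voxels at height z)

is computed, and the waterfront height is the lowest height at which R
drops below a ratio threshold (default 0.1) and *stays* below it for a
persistence distance (default 20 voxels); the persistence rule suppresses
spurious front jumps from isolated droplets or air inclusions.  Error
bounds come from repeating the extraction at ratio thresholds 0.05 and
0.15.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .projector import VolumeImage

__all__ = [
    "VesselTrack",
    "classify_water",
    "thickness_ratio",
    "vessel_ratio_profile",
    "front_height",
    "front_uncertainty",
    "segment_vessels",
    "track_vessels",
    "halfway_threshold",
]

log = logging.getLogger(__name__)

RATIO_THRESHOLD = 0.1
RATIO_THRESHOLD_BOUNDS = (0.05, 0.15)
PERSISTENCE_VOXELS = 20


def halfway_threshold(mean_water: float, mean_air: float) -> float:
    """Halfway classification threshold ``(mean_water - mean_air) / 2``."""
    return 0.5 * (mean_water - mean_air)


def classify_water(u_t: VolumeImage | np.ndarray, v: VolumeImage | np.ndarray,
                   vessel_mask: np.ndarray, threshold: float) -> np.ndarray:
    """Water mask: vessel voxels whose grey value rose above ``threshold``.

    ``u_t`` and ``v`` must be co-registered; the comparison is
    ``u_t - v > threshold`` restricted to ``vessel_mask``.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    ut = u_t.values if isinstance(u_t, VolumeImage) else np.asarray(u_t)
    vv = v.values if isinstance(v, VolumeImage) else np.asarray(v)
    if ut.shape != vv.shape or ut.shape != vessel_mask.shape:
        raise ValueError("volumes and vessel mask must share one grid")
    return vessel_mask & ((ut - vv) > threshold)


def thickness_ratio(water_mask: np.ndarray, vessel_mask: np.ndarray,
                    axis: int = 1) -> np.ndarray:
    """Projected-thickness ratio R along one in-plane axis.

    Counts water and vessel voxels along ``axis`` (the coronal projection
    direction); R is NaN where the vessel has zero thickness.
    """
    if water_mask.shape != vessel_mask.shape:
        raise ValueError("mask shapes differ")
    water = water_mask.sum(axis=axis).astype(float)
    vessel = vessel_mask.sum(axis=axis).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(vessel > 0, water / vessel, np.nan)


def vessel_ratio_profile(water_mask: np.ndarray, vessel_mask: np.ndarray) -> np.ndarray:
    """Total per-height ratio R(z) over a vessel's full cross-section."""
    water = water_mask.reshape(water_mask.shape[0], -1).sum(axis=1).astype(float)
    vessel = vessel_mask.reshape(vessel_mask.shape[0], -1).sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(vessel > 0, water / vessel, np.nan)


def front_height(R_profile: np.ndarray, ratio_threshold: float = RATIO_THRESHOLD,
                 persistence: int = PERSISTENCE_VOXELS,
                 voxel_size: float = 1.0, base_index: int = 0) -> float:
    """Lowest height where R drops and stays below the threshold.

    Scans upward from the vessel base and returns the first index ``z*``
    (converted to micrometres via ``voxel_size``) such that R < threshold
    throughout ``[z*, z* + persistence)``; windows truncated by the vessel
    top count if all their existing samples are below threshold.  Returns
    the vessel top if the condition is never met.  Heights are measured
    from ``base_index`` (the lowest defined sample).
    """
    if persistence < 1:
        raise ValueError("persistence must be >= 1")
    R = np.asarray(R_profile, dtype=float)
    defined = np.flatnonzero(~np.isnan(R))
    if defined.size == 0:
        raise ValueError("R profile undefined everywhere")
    lo, hi = defined[0], defined[-1] + 1
    below = R[lo:hi] < ratio_threshold
    n = below.size
    for z in range(n):
        if np.all(below[z: z + persistence]):
            return (lo + z - base_index) * voxel_size
    return (hi - base_index) * voxel_size


def front_uncertainty(R_profile: np.ndarray,
                      thresholds: tuple[float, float] = RATIO_THRESHOLD_BOUNDS,
                      persistence: int = PERSISTENCE_VOXELS,
                      voxel_size: float = 1.0, base_index: int = 0) -> tuple[float, float]:
    """Front heights at the low/high ratio thresholds, as ordered bounds.

    A lower ratio threshold can only move the detected front down, so the
    pair brackets the default-threshold height.
    """
    lo_t, hi_t = thresholds
    if not (0 < lo_t < 1 and 0 < hi_t < 1):
        raise ValueError("thresholds must lie in (0, 1)")
    h = [front_height(R_profile, t, persistence, voxel_size, base_index)
         for t in (lo_t, hi_t)]
    return (min(h), max(h))


@dataclass
class VesselTrack:
    """Waterfront trajectory of one vessel across the scan timeline."""

    vessel_id: int
    times: np.ndarray
    heights_um: np.ndarray
    bounds_um: np.ndarray  # (n_times, 2) low/high from the threshold sweep
    threshold: float
    monotone: bool = True
    R_profiles: list[np.ndarray] = field(default_factory=list)

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["t_s", "h_um", "h_low_um", "h_high_um"])
            for t, h, (blo, bhi) in zip(self.times, self.heights_um, self.bounds_um):
                w.writerow([t, h, blo, bhi])


def segment_vessels(v: VolumeImage, wood_mask: np.ndarray | None = None,
                    threshold: float | None = None,
                    min_voxels: int = 8) -> np.ndarray:
    """Label vessels in the high-quality dry reference volume.

    Vessels are connected components of below-threshold (air) voxels
    inside the wood region; the grey-value threshold defaults to Otsu on
    the wood region.  Returns an integer label volume (0 = background).
    """
    vals = v.values
    region = wood_mask if wood_mask is not None else np.ones(vals.shape, bool)
    thr = threshold_otsu(vals[region]) if threshold is None else threshold
    air = (vals < thr) & region
    labels, n = ndimage.label(air)
    if n == 0:
        return labels
    counts = np.bincount(labels.ravel())
    small = np.flatnonzero(counts < min_voxels)
    if small.size:
        labels[np.isin(labels, small)] = 0
    return labels


def track_vessels(
    timeline: list[tuple[float, VolumeImage | np.ndarray]],
    v: VolumeImage | np.ndarray,
    vessel_labels: np.ndarray,
    threshold: float,
    ratio_threshold: float = RATIO_THRESHOLD,
    threshold_bounds: tuple[float, float] = RATIO_THRESHOLD_BOUNDS,
    persistence: int = PERSISTENCE_VOXELS,
    voxel_size: float = 1.0,
) -> tuple[list[VesselTrack], dict]:
    """Track every vessel's waterfront across a reconstruction timeline.

    ``timeline`` is a list of ``(t, u_t)`` pairs on the same grid as the
    reference ``v`` and the integer ``vessel_labels`` volume.  Heights are
    measured from each vessel's own base (its lowest segmented voxel).
    Returns the per-vessel tracks plus a cohort summary with the median
    and standard deviation of the height across vessels per time point.
    """
    ids = [int(i) for i in np.unique(vessel_labels) if i != 0]
    if not ids:
        raise ValueError("no vessels in segmentation")
    times = np.array([t for t, _ in timeline], dtype=float)
    masks = {i: vessel_labels == i for i in ids}
    bases = {}
    for i in ids:
        zs = np.flatnonzero(masks[i].reshape(masks[i].shape[0], -1).any(axis=1))
        bases[i] = int(zs[0])
    heights = {i: [] for i in ids}
    bounds = {i: [] for i in ids}
    profiles = {i: [] for i in ids}
    for t, u_t in timeline:
        ut = u_t.values if isinstance(u_t, VolumeImage) else np.asarray(u_t)
        for i in ids:
            mask = masks[i]
            water = classify_water(ut, v, mask, threshold)
            R = vessel_ratio_profile(water, mask)
            h = front_height(R, ratio_threshold, persistence, voxel_size, bases[i])
            b = front_uncertainty(R, threshold_bounds, persistence, voxel_size, bases[i])
            heights[i].append(h)
            bounds[i].append(b)
            profiles[i].append(R)
    tracks = []
    for i in ids:
        h = np.array(heights[i])
        b = np.array(bounds[i])
        # non-decreasing within the error bounds of consecutive points
        mono = bool(np.all(h[1:] >= np.minimum.accumulate(np.array(
            [lo for lo, _ in bounds[i]]))[:-1] - voxel_size))
        tracks.append(VesselTrack(vessel_id=i, times=times, heights_um=h,
                                  bounds_um=b, threshold=threshold,
                                  monotone=mono, R_profiles=profiles[i]))
    mat = np.stack([tr.heights_um for tr in tracks])  # (n_vessels, n_times)
    summary = {
        "times": times,
        "median_um": np.median(mat, axis=0),
        "std_um": mat.std(axis=0),
        "n_vessels": len(ids),
        "height_matrix_um": mat,
    }
    return tracks, summary


def plot_cohort(tracks: list[VesselTrack], summary: dict, path=None):
    """Waterfront-vs-time chart: single-vessel markers over cohort band."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    t = summary["times"]
    med, sd = summary["median_um"], summary["std_um"]
    ax.fill_between(t, med - sd, med + sd, color="0.8", label="cohort +/- sd")
    ax.plot(t, med, color="0.3", label="cohort median")
    tr = tracks[0]
    err = np.abs(tr.bounds_um.T - tr.heights_um[None])
    ax.errorbar(tr.times, tr.heights_um, yerr=err, fmt="r.", label=f"vessel {tr.vessel_id}")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("waterfront height (um)")
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
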