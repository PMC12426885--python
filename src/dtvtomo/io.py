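"""Volume and projection I/O: HDF5 datasets and TIFF stacks.

Volumes round-trip losslessly (float data plus voxel size and value
semantics); projection sets are stored as HDF5 with ``intensity``,
``flat``, ``dark``, ``angles`` and ``timestamps`` datasets, or as a TIFF
stack with a CSV sidecar of angles/timestamps.  Missing metadata raises
instead of being silently defaulted.
"""

from __future__ import annotations

import csv
from pathlib import Path

import h5py
import numpy as np
import tifffile

from .projector import VolumeImage
from .simulate import ProjectionSet

__all__ = [
    "write_volume", "read_volume",
    "write_projections", "read_projections",
    "export_projections_tiff",
]


def _ext(path) -> str:
    return Path(path).suffix.lower()


def write_volume(path, volume: VolumeImage) -> None:
    """Write a volume as HDF5 (.h5/.hdf5) or multi-page TIFF (.tif)."""
    ext = _ext(path)
    if ext in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            d = f.create_dataset("volume", data=volume.values.astype(np.float32), track_times=False)
            d.attrs["voxel_size_um"] = volume.voxel_size
            d.attrs["semantics"] = volume.semantics
    elif ext in (".tif", ".tiff"):
        data = volume.values.astype(np.float32)
        if data.ndim == 2:
            data = data[None]
        tifffile.imwrite(path, data,
                         metadata={"voxel_size_um": volume.voxel_size,
                                   "semantics": volume.semantics})
    else:
        raise ValueError(f"unsupported volume format {ext!r}")


def read_volume(path) -> VolumeImage:
    ext = _ext(path)
    if ext in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            if "volume" not in f:
                raise KeyError("HDF5 file has no 'volume' dataset")
            d = f["volume"]
            if "voxel_size_um" not in d.attrs or "semantics" not in d.attrs:
                raise KeyError("volume dataset is missing voxel_size_um/semantics attrs")
            return VolumeImage(values=d[()].astype(float),
                               voxel_size=float(d.attrs["voxel_size_um"]),
                               semantics=str(d.attrs["semantics"]))
    if ext in (".tif", ".tiff"):
        with tifffile.TiffFile(path) as tf:
            data = tf.asarray().astype(float)
            meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
        if "voxel_size_um" not in meta or "semantics" not in meta:
            raise KeyError("TIFF stack is missing voxel_size_um/semantics metadata")
        if data.ndim == 3 and data.shape[0] == 1:
            data = data[0]
        return VolumeImage(values=data, voxel_size=float(meta["voxel_size_um"]),
                           semantics=str(meta["semantics"]))
    raise ValueError(f"unsupported volume format {ext!r}")


def write_projections(path, pset: ProjectionSet) -> None:
    """Write a projection set to HDF5."""
    with h5py.File(path, "w") as f:
        f.create_dataset("intensity", data=pset.intensity.astype(np.float32), track_times=False)
        f.create_dataset("flat", data=pset.flat.astype(np.float32), track_times=False)
        f.create_dataset("dark", data=pset.dark.astype(np.float32), track_times=False)
        f.create_dataset("angles", data=pset.angles_deg, track_times=False)
        f.create_dataset("timestamps", data=pset.timestamps, track_times=False)
        f.attrs["pixel_size_um"] = pset.pixel_size
        if "true_angles_deg" in pset.meta:
            f.create_dataset("true_angles", data=np.asarray(pset.meta["true_angles_deg"]), track_times=False)


def read_projections(path) -> ProjectionSet:
    with h5py.File(path, "r") as f:
        for name in ("intensity", "flat", "dark", "angles", "timestamps"):
            if name not in f:
                raise KeyError(f"projection file is missing the {name!r} dataset")
        meta = {}
        if "true_angles" in f:
            meta["true_angles_deg"] = f["true_angles"][()]
        return ProjectionSet(
            intensity=f["intensity"][()].astype(float),
            flat=f["flat"][()].astype(float),
            dark=f["dark"][()].astype(float),
            angles_deg=f["angles"][()],
            timestamps=f["timestamps"][()],
            pixel_size=float(f.attrs["pixel_size_um"]),
            meta=meta,
        )


def export_projections_tiff(tiff_path, csv_path, pset: ProjectionSet) -> None:
    """TIFF stack (one page per projection) plus CSV sidecar of angles."""
    tifffile.imwrite(tiff_path, pset.intensity.astype(np.float32),
                     metadata={"pixel_size_um": pset.pixel_size})
    with open(csv_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["index", "angle_deg", "timestamp_s"])
        for i, (a, t) in enumerate(zip(pset.angles_deg, pset.timestamps)):
            w.writerow([i, a, t])
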