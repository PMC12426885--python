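"""End-to-end pipeline runner with artefact manifest.

Executes the stages simulate -> retrieve -> align -> reconstruct ->
analyse from a :class:`~dtvtomo.config.RunConfig`, writing every artefact
under the configured output directory and a ``manifest.json`` listing
each output file with its SHA-256 hash and the effective configuration,
so any number in the outputs is traceable to config plus data.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, replace
from pathlib import Path

import numpy as np

from . import io as dio
from .align import refine_alignment
from .config import RunConfig
from .dtv import PriorField, ReconConfig, pdhg_reconstruct
from .metrics import cnr, material_histograms
from .phantom import WATER, build_phantom
from .projector import Sinogram, fbp_reconstruct
from .scenes import attenuation_sinogram, phase_sinogram
from .simulate import ScanProtocol, simulate_scan

__all__ = ["run_pipeline", "STAGES", "PipelineError"]

log = logging.getLogger(__name__)

STAGES = ("simulate", "retrieve", "align", "reconstruct", "analyse")


class PipelineError(RuntimeError):
    """A stage could not run (bad config or missing upstream artefact)."""


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig, stages: list[str] | None = None) -> dict:
    """Run the requested stages in order; returns the manifest dict.

    Stages depend on their predecessors' artefacts on disk; requesting a
    later stage without its inputs raises :class:`PipelineError` naming
    the stage.
    """
    config.validate()
    stages = list(STAGES) if stages is None else [s for s in STAGES if s in set(stages)]
    unknown = set(stages or []) - set(STAGES)
    if unknown:
        raise PipelineError(f"unknown stages: {sorted(unknown)}")
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    geom = config.geometry.build()
    manifest: dict = {"config": asdict(config), "stages": {}, "outputs": {}}

    def record(name: str, path: Path):
        manifest["outputs"][name] = {"path": str(path), "sha256": _sha256(path)}

    paths = {
        "reference": out / "reference_projections.h5",
        "dynamic": out / "dynamic_projections.h5",
        "sino_delta_ref": out / "sino_delta_reference.h5",
        "sino_delta_dyn": out / "sino_delta_dynamic.h5",
        "sino_mu_dyn": out / "sino_mu_dynamic.h5",
        "v": out / "reference_volume.h5",
        "recon": out / "reconstruction.h5",
        "align": out / "alignment.json",
        "analysis": out / "analysis.json",
        "convergence": out / "convergence.json",
    }

    for stage in stages:
        t0 = time.time()
        log.info("stage %s starting", stage)
        if stage == "simulate":
            _stage_simulate(config, geom, paths)
            record("reference_projections", paths["reference"])
            record("dynamic_projections", paths["dynamic"])
        elif stage == "retrieve":
            _require(paths["reference"], paths["dynamic"], stage=stage)
            _stage_retrieve(config, geom, paths)
            for k in ("sino_delta_ref", "sino_delta_dyn", "sino_mu_dyn", "v"):
                record(k, paths[k])
        elif stage == "align":
            _require(paths["sino_delta_dyn"], paths["v"], stage=stage)
            _stage_align(config, paths)
            record("alignment", paths["align"])
        elif stage == "reconstruct":
            _require(paths["sino_delta_dyn"], paths["v"], stage=stage)
            _stage_reconstruct(config, paths)
            record("reconstruction", paths["recon"])
            record("convergence", paths["convergence"])
        elif stage == "analyse":
            _require(paths["recon"], paths["v"], stage=stage)
            _stage_analyse(config, paths)
            record("analysis", paths["analysis"])
        manifest["stages"][stage] = {"seconds": round(time.time() - t0, 3)}
        log.info("stage %s done in %.1fs", stage, time.time() - t0)

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _require(*paths: Path, stage: str) -> None:
    missing = [str(p) for p in paths if not p.exists()]
    if missing:
        raise PipelineError(f"stage {stage!r} is missing upstream artefacts: {missing}")


def _build_phantoms(config: RunConfig):
    p = config.phantom
    ph = build_phantom(p.n_vessels, (p.grid, p.grid), p.voxel_size,
                       seed=config.seed,
                       radius_range_um=(p.radius_min_um, p.radius_max_um),
                       large_cavity_radius_um=p.large_cavity_radius_um,
                       n_pairs=p.n_pairs, texture_amplitude=p.texture_amplitude)
    labels_dyn = ph.labels.copy()
    small = ph.vessels[1:] if p.large_cavity_radius_um else ph.vessels
    for i, v in enumerate(small):
        if i % 2 == 0:
            labels_dyn[0][ph.vessel_cross_section(v)] = WATER
    if p.large_cavity_radius_um:
        cav = ph.vessels[0]
        yy, xx = ph._inplane_coords()
        labels_dyn[0][ph.vessel_cross_section(cav) & (yy < cav.y_um)] = WATER
    return ph, replace(ph, labels=labels_dyn)


def _stage_simulate(config: RunConfig, geom, paths) -> None:
    ph, ph_dyn = _build_phantoms(config)
    s = config.scan
    ref = simulate_scan(ph, ScanProtocol(
        mode="static", n_projections=s.reference_projections,
        angular_range=s.reference_range, exposure=s.reference_exposure,
        photons_per_pixel=s.reference_photons, seed=config.seed),
        geom, supersample=s.supersample)
    dyn = simulate_scan(ph_dyn, ScanProtocol(
        mode="continuous", n_projections=s.dynamic_projections,
        exposure=s.dynamic_exposure, angular_velocity=s.angular_velocity,
        photons_per_pixel=s.dynamic_photons, seed=config.seed + 1),
        geom, supersample=s.supersample)
    dio.write_projections(paths["reference"], ref)
    dio.write_projections(paths["dynamic"], dyn)


def _stage_retrieve(config: RunConfig, geom, paths) -> None:
    ref = dio.read_projections(paths["reference"])
    dyn = dio.read_projections(paths["dynamic"])
    db = config.retrieval.delta_beta
    if db is not None:
        from dataclasses import replace as dr
        geom = dr(geom, delta_beta=db)
    b_ref = phase_sinogram(ref, geom)
    b_dyn = phase_sinogram(dyn, geom)
    b_mu = attenuation_sinogram(dyn, floor=config.retrieval.clamp)
    v = fbp_reconstruct(b_ref, config.recon.fbp_filter, semantics="delta")
    _write_sino(paths["sino_delta_ref"], b_ref)
    _write_sino(paths["sino_delta_dyn"], b_dyn)
    _write_sino(paths["sino_mu_dyn"], b_mu)
    dio.write_volume(paths["v"], v)


def _write_sino(path, sino: Sinogram) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=sino.data, track_times=False)
        f.create_dataset("angles", data=sino.angles_deg, track_times=False)
        if sino.timestamps is not None:
            f.create_dataset("timestamps", data=sino.timestamps, track_times=False)
        f.attrs["pixel_size_um"] = sino.pixel_size


def _read_sino(path) -> Sinogram:
    import h5py

    with h5py.File(path, "r") as f:
        ts = f["timestamps"][()] if "timestamps" in f else None
        return Sinogram(f["data"][()], f["angles"][()],
                        float(f.attrs["pixel_size_um"]), timestamps=ts)


def _stage_align(config: RunConfig, paths) -> None:
    sino = _read_sino(paths["sino_delta_dyn"])
    v = dio.read_volume(paths["v"])
    step = float(np.median(np.diff(sino.angles_deg)))
    res = refine_alignment(sino, v, nominal_step_deg=step)
    paths["align"].write_text(json.dumps({
        "offset_deg": res.offset_deg,
        "step_deg": res.step_deg,
        "objective_curve": res.objective_curve,
        "notes": res.notes,
    }, indent=2))


def _stage_reconstruct(config: RunConfig, paths) -> None:
    sino = _read_sino(paths["sino_delta_dyn"])
    v = dio.read_volume(paths["v"])
    r = config.recon
    if r.method == "fbp":
        rec = fbp_reconstruct(sino, r.fbp_filter, semantics="delta")
        history = []
    else:
        prior = PriorField.from_reference(v, eta_rel=r.eta_rel)
        cfg = ReconConfig(alpha=r.alpha, n_iterations=r.n_iterations,
                          init=r.init, fbp_filter=r.fbp_filter, seed=config.seed)
        rec = pdhg_reconstruct(sino, prior, cfg)
        history = rec.meta["objective"]
    dio.write_volume(paths["recon"], rec)
    paths["convergence"].write_text(json.dumps(
        {"objective": history, "method": r.method}, indent=2))


def _stage_analyse(config: RunConfig, paths) -> None:
    rec = dio.read_volume(paths["recon"])
    ph, ph_dyn = _build_phantoms(config)
    from scipy import ndimage

    labels = ph_dyn.labels[0]
    water = ndimage.binary_erosion(labels == WATER, iterations=1)
    air = ndimage.binary_erosion(
        (labels == 0)
        & (ph.labels[0] == 0)
        & np.broadcast_to(
            (np.sum(np.stack(ph._inplane_coords()) ** 2, axis=0)
             <= ph.wood_radius_um ** 2), labels.shape), iterations=1)
    regions = {"water": water, "air": air}
    hist = material_histograms(rec, regions, bins=config.analysis.histogram_bins)
    result = {
        "cnr_water_air": cnr(rec.values[water], rec.values[air]),
        "categories": {k: {kk: (vv.tolist() if isinstance(vv, np.ndarray) else vv)
                           for kk, vv in d.items()} for k, d in hist.items()},
    }
    paths["analysis"].write_text(json.dumps(result, indent=2))
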