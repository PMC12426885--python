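"""Run configuration: a schema-validated YAML file driving the pipeline.

Sections mirror the pipeline stages -- geometry, phantom, scans,
retrieval, reconstruction, analysis -- with every parameter defaulted to
the laboratory study settings (1001 x 1 s reference scan, 180 x 50 ms
dynamic frames at 20 deg/s, delta/beta = 1000, alpha/eta solver defaults,
10.5 um voxels).  Configs round-trip exactly through write/read.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .geometry import SystemGeometry

__all__ = ["RunConfig", "load_config", "save_config", "ConfigError"]


class ConfigError(ValueError):
    """A configuration value failed validation; names the offending field."""


@dataclass
class GeometrySection:
    R1: float = 320.0
    R2: float = 140.0
    sigma_s: float = 70.0
    sigma_d: float = 30.0
    pixel_pitch: float = 15.0
    lambda_eff: float = 6.53e-11
    delta_beta: float = 1000.0

    def build(self) -> SystemGeometry:
        return SystemGeometry(**asdict(self))


@dataclass
class PhantomSection:
    n_vessels: int = 10
    grid: int = 128
    voxel_size: float = 10.5
    radius_min_um: float = 32.0
    radius_max_um: float = 52.0
    large_cavity_radius_um: float | None = 130.0
    n_pairs: int = 0
    texture_amplitude: float = 0.0


@dataclass
class ScanSection:
    reference_projections: int = 360
    reference_range: float = 180.0
    reference_exposure: float = 1.0
    reference_photons: float = 20000.0
    dynamic_projections: int = 180
    dynamic_exposure: float = 0.05
    angular_velocity: float = 20.0
    dynamic_photons: float = 1000.0
    supersample: int = 1


@dataclass
class RetrievalSection:
    delta_beta: float | None = None  # fall back to geometry's value
    pad: bool = True
    clamp: float = 1.0e-6


@dataclass
class ReconSection:
    method: str = "dtv"
    alpha: float = 1.0e4
    eta_rel: float = 0.2
    n_iterations: int = 100
    init: str = "fbp"
    fbp_filter: str = "hann"


@dataclass
class AnalysisSection:
    ratio_threshold: float = 0.1
    ratio_threshold_low: float = 0.05
    ratio_threshold_high: float = 0.15
    persistence_voxels: int = 20
    histogram_bins: int = 64


@dataclass
class RunConfig:
    geometry: GeometrySection = field(default_factory=GeometrySection)
    phantom: PhantomSection = field(default_factory=PhantomSection)
    scan: ScanSection = field(default_factory=ScanSection)
    retrieval: RetrievalSection = field(default_factory=RetrievalSection)
    recon: ReconSection = field(default_factory=ReconSection)
    analysis: AnalysisSection = field(default_factory=AnalysisSection)
    seed: int = 0
    output_dir: str = "dtvtomo_out"
    log_level: str = "INFO"

    def validate(self) -> None:
        g = self.geometry
        checks = [
            ("geometry.R1", g.R1 > 0),
            ("geometry.R2", g.R2 >= 0),
            ("geometry.pixel_pitch", g.pixel_pitch > 0),
            ("geometry.lambda_eff", g.lambda_eff > 0),
            ("geometry.delta_beta", g.delta_beta > 0),
            ("phantom.n_vessels", self.phantom.n_vessels >= 0),
            ("phantom.grid", self.phantom.grid >= 16),
            ("phantom.voxel_size", self.phantom.voxel_size > 0),
            ("scan.reference_projections", self.scan.reference_projections >= 1),
            ("scan.dynamic_projections", self.scan.dynamic_projections >= 1),
            ("scan.reference_exposure", self.scan.reference_exposure > 0),
            ("scan.dynamic_exposure", self.scan.dynamic_exposure > 0),
            ("scan.angular_velocity", self.scan.angular_velocity > 0),
            ("scan.supersample", self.scan.supersample >= 1),
            ("retrieval.clamp", self.retrieval.clamp > 0),
            ("recon.alpha", self.recon.alpha >= 0),
            ("recon.eta_rel", self.recon.eta_rel > 0),
            ("recon.n_iterations", self.recon.n_iterations >= 0),
            ("recon.method", self.recon.method in ("fbp", "dtv")),
            ("recon.init", self.recon.init in ("fbp", "zeros")),
            ("analysis.persistence_voxels", self.analysis.persistence_voxels >= 1),
            ("analysis.ratio_threshold",
             0 < self.analysis.ratio_threshold < 1),
        ]
        for name, ok in checks:
            if not ok:
                raise ConfigError(f"invalid value for {name}")


_SECTIONS = {f.name: f for f in fields(RunConfig)}


def load_config(path) -> RunConfig:
    """Read and validate a YAML run configuration; unknown keys raise."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    cfg = RunConfig()
    for key, val in raw.items():
        if key not in _SECTIONS:
            raise ConfigError(f"unknown config section/key {key!r}")
        f = _SECTIONS[key]
        if isinstance(val, dict):
            section = getattr(cfg, key)
            known = {sf.name for sf in fields(section)}
            for k, v in val.items():
                if k not in known:
                    raise ConfigError(f"unknown key {key}.{k}")
                setattr(section, k, v)
        else:
            setattr(cfg, key, val)
    cfg.validate()
    return cfg


def save_config(path, cfg: RunConfig) -> None:
    cfg.validate()
    Path(path).write_text(yaml.safe_dump(asdict(cfg), sort_keys=False))
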