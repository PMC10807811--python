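"""Pipeline configuration: a validated schema with traceable defaults.

Every default is either a printed instrument/sample parameter (densities,
depth, pixel sizes, the 391–795 us working range and the 410 us reference)
or a documented modelling choice (tau schedule, contrast, fit bounds); see
docs/methods.md. Configs load from YAML or JSON, validate via pydantic, and
hash canonically so every output file can embed the configuration that
produced it.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, Field, model_validator

from .spin_bath import MonteCarloConfig
from .wlc import PolymerParams

__all__ = [
    "SensorSection",
    "PolymerSection",
    "AnchorsSection",
    "AcquisitionSection",
    "ThresholdsSection",
    "SynthSection",
    "PipelineConfig",
    "load_config",
    "config_hash",
]


class SensorSection(BaseModel):
    nv_density_per_um2: float = Field(1000.0, gt=0)
    nv_depth_nm: float = Field(5.0, gt=0)
    depth_model: str = "fixed"
    depth_sd_nm: float = Field(2.0, gt=0)
    gd_density_per_um2: float = Field(9000.0, gt=0)
    cutoff_radius_nm: float = Field(50.0, gt=0)
    pixel_nm: float = Field(600.0, gt=0)
    angular_model: str = "isotropic"
    # Calibrated if omitted:
    coupling: float | None = None
    gamma_int: float | None = None


class PolymerSection(BaseModel):
    contour_length_nm: float = Field(7.98, gt=0)
    persistence_length_nm: float = Field(0.38, gt=0)
    temperature_k: float = Field(298.0, gt=0)
    stretch_modulus_pn: float | None = None

    def to_params(self) -> PolymerParams:
        return PolymerParams(
            contour_length=self.contour_length_nm,
            persistence_length=self.persistence_length_nm,
            temperature=self.temperature_k,
            stretch_modulus=self.stretch_modulus_pn,
        )


class AnchorsSection(BaseModel):
    h_low_nm: float = 0.3
    t1_low_us: float = 391.0
    h_high_nm: float = 6.0
    t1_high_us: float = 795.0

    @model_validator(mode="after")
    def _ordered(self):
        if not (0 < self.t1_low_us < self.t1_high_us and self.h_low_nm < self.h_high_nm):
            raise ValueError("anchors must be positive with T1 increasing in h")
        return self


class AcquisitionSection(BaseModel):
    tau_min_us: float = Field(1.0, gt=0)
    tau_max_us: float = Field(3000.0, gt=0)
    n_tau: int = Field(24, ge=5)
    contrast_a: float = Field(0.1, gt=0)
    contrast_c: float = Field(1.0, gt=0)
    photons_per_pixel: float = Field(1e5, gt=0)
    camera_pixel_nm: float = Field(96.0, gt=0)

    @model_validator(mode="after")
    def _span(self):
        if self.tau_max_us / self.tau_min_us < 10:
            raise ValueError("tau schedule must span at least one decade")
        return self


class ThresholdsSection(BaseModel):
    reference_t1_us: float = Field(410.0, gt=0)
    t1_range_us: tuple[float, float] = (391.0, 795.0)

    @model_validator(mode="after")
    def _ordered(self):
        if not self.t1_range_us[0] <= self.t1_range_us[1]:
            raise ValueError("t1_range_us must be ordered")
        return self


class SynthSection(BaseModel):
    shape: tuple[int, int] = (64, 64)
    footprint: str = "ellipse"
    edge_band_nm: float = Field(480.0, gt=0)
    interior_force_pn: float = Field(8.0, ge=0)
    edge_force_pn: float = Field(25.0, ge=0)
    noise_sd_pn: float = Field(0.0, ge=0)


class PipelineConfig(BaseModel):
    sensor: SensorSection = SensorSection()
    polymer: PolymerSection = PolymerSection()
    anchors: AnchorsSection = AnchorsSection()
    acquisition: AcquisitionSection = AcquisitionSection()
    thresholds: ThresholdsSection = ThresholdsSection()
    synth: SynthSection = SynthSection()
    calibration_h_min_nm: float = 0.3
    calibration_h_max_nm: float = 6.0
    calibration_n_points: int = Field(20, ge=1)
    calibration_method: str = "analytic"
    calibration_replicates: int = Field(24, ge=2)
    binning: int = Field(1, ge=1)
    fix_b: float | None = None
    fix_c: float | None = None
    seed: int = 0

    def mc_config(self) -> MonteCarloConfig:
        return MonteCarloConfig(
            pixel_nm=self.sensor.pixel_nm,
            nv_density_per_um2=self.sensor.nv_density_per_um2,
            nv_depth_nm=self.sensor.nv_depth_nm,
            depth_model=self.sensor.depth_model,
            depth_sd_nm=self.sensor.depth_sd_nm,
            gd_density_per_um2=self.sensor.gd_density_per_um2,
            cutoff_radius_nm=self.sensor.cutoff_radius_nm,
            tau_min_us=self.acquisition.tau_min_us,
            tau_max_us=self.acquisition.tau_max_us,
            n_tau=self.acquisition.n_tau,
            contrast_a=self.acquisition.contrast_a,
            contrast_c=self.acquisition.contrast_c,
        )


def load_config(path=None) -> PipelineConfig:
    """Load a YAML/JSON config file; ``None`` returns the defaults."""
    if path is None:
        return PipelineConfig()
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    return PipelineConfig.model_validate(data)


def config_hash(config: PipelineConfig) -> str:
    """Short stable hash of the canonical JSON form of a config."""
    blob = json.dumps(config.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]
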