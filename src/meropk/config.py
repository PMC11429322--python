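"""Validated run configuration for the simulation campaigns.

A :class:`RunConfig` bundles the population constants, covariate
distribution, regimen grid, targets and Monte Carlo settings; it loads
from a YAML file and hashes canonically for provenance logging.
"""

from __future__ import annotations

import hashlib
import json
from typing import List, Literal

import yaml
from pydantic import BaseModel, Field, model_validator

from .model_core import Regimen
from .population import CovariateDistribution, PopulationModel
from .pta import MIC_LADDER, PDTarget

__all__ = [
    "PopulationSettings",
    "CovariateSettings",
    "RegimenSettings",
    "TargetSettings",
    "RunConfig",
    "load_config",
]


class PopulationSettings(BaseModel):
    theta1: float = 12.4
    theta2: float = -0.392
    tv_V1: float = 8.26
    tv_Q: float = 5.22
    tv_V2: float = 4.06
    omega_CL: float = Field(0.262, ge=0)
    shared_exponent: float = 1.53
    omega_Q: float = Field(0.144, ge=0)
    omega_V2: float = Field(0.179, ge=0)
    sigma_prop: float = Field(0.109, ge=0)
    cr_ref: float = Field(0.86, gt=0)

    def build(self) -> PopulationModel:
        return PopulationModel(**self.model_dump())


class CovariateSettings(BaseModel):
    cr_mean: float = Field(0.863, gt=0)
    cr_cv: float = Field(0.190, ge=0)
    weight_mean: float = Field(65.7, gt=0)
    weight_cv: float = Field(0.208, ge=0)
    age_mean: float = Field(36.8, gt=0)
    age_cv: float = Field(0.199, ge=0)
    height_mean: float = Field(168.0, gt=0)
    height_cv: float = Field(0.0429, ge=0)
    cystatin_mean: float = Field(0.790, gt=0)
    cystatin_cv: float = Field(0.159, ge=0)
    male_fraction: float = Field(8.0 / 12.0, ge=0, le=1)

    def build(self) -> CovariateDistribution:
        return CovariateDistribution(**self.model_dump())


class RegimenSettings(BaseModel):
    dose: float = Field(gt=0)
    infusion_duration: float = 0.5
    interval: float = 8.0
    mode: Literal["intermittent", "continuous"] = "intermittent"

    @model_validator(mode="after")
    def _check(self):
        if self.mode == "intermittent" and not 0 < self.infusion_duration <= self.interval:
            raise ValueError("need 0 < infusion_duration <= interval")
        return self

    def build(self) -> Regimen:
        return Regimen(**self.model_dump())


class TargetSettings(BaseModel):
    fraction_threshold: float = Field(gt=0, le=1)
    mic_multiplier: float = Field(1.0, gt=0)
    unbound_fraction: float = Field(0.98, gt=0, le=1)

    def build(self) -> PDTarget:
        return PDTarget(**self.model_dump())


_DEFAULT_TARGETS = [
    {"fraction_threshold": 0.40, "mic_multiplier": 1},
    {"fraction_threshold": 0.40, "mic_multiplier": 4},
    {"fraction_threshold": 1.00, "mic_multiplier": 1},
    {"fraction_threshold": 1.00, "mic_multiplier": 4},
]


def _intermittent_grid() -> List[dict]:
    grid = []
    for interval in (6.0, 8.0, 12.0):
        for t_inf in (0.5, 3.0):
            for dose in (500.0, 1000.0, 1500.0, 2000.0):
                grid.append(
                    {"dose": dose, "infusion_duration": t_inf, "interval": interval}
                )
    return grid


class RunConfig(BaseModel):
    """Everything needed to reproduce a PTA campaign."""

    population: PopulationSettings = PopulationSettings()
    covariates: CovariateSettings = CovariateSettings()
    regimens: List[RegimenSettings] = Field(
        default_factory=lambda: [RegimenSettings(**r) for r in _intermittent_grid()]
    )
    targets: List[TargetSettings] = Field(
        default_factory=lambda: [TargetSettings(**t) for t in _DEFAULT_TARGETS]
    )
    mic_ladder: List[float] = Field(default_factory=lambda: list(MIC_LADDER))
    n_subjects: int = Field(10_000, ge=1)
    seed: int = 2024
    grid_step: float = Field(0.005, gt=0)
    include_fixed_iiv: bool = True

    def content_hash(self) -> str:
        blob = json.dumps(self.model_dump(), sort_keys=True, default=float)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(data)
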