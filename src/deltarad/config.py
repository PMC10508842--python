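"""Strict YAML-backed pipeline configuration.

One base seed flows into cohort generation and cross-validation; unknown keys
are rejected so typos fail loudly. The schema round-trips through YAML/JSON.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Tuple

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .model import CvConfig
from .synthetic import CohortConfig


class FeatureOptions(BaseModel):
    model_config = ConfigDict(extra="forbid")

    n_levels: int = 16
    haralick_windows: Tuple[int, ...] = (3, 5, 7)
    gabor_wavelength: float = 4.0
    collage_window: int = 5
    collage_bins: int = 8


class CohortSection(BaseModel):
    model_config = ConfigDict(extra="forbid")

    n_patients: int = 30
    prevalence_pos: float = 19 / 30
    grid_shape: Tuple[int, int, int] = (48, 48, 16)
    voxel_spacing_mm: Tuple[float, float, float] = (1.0, 1.0, 3.0)
    lesion_radius_mm: float = 6.0
    texture_corr_len_mm: float = 2.0
    texture_sd: float = 12.0
    delta_corr_len_effect: float = 1.3
    delta_sd_effect: float = 1.3
    lesion_growth_factor: float = 1.15
    psa_baseline_mean: float = 5.5
    psa_baseline_sd: float = 2.0
    delta_psa_effect_d: float = 0.8
    volume_effect_d: float = 0.8
    noise_sd: float = 3.0

    def build(self, seed: int) -> CohortConfig:
        return CohortConfig(seed=seed, **self.model_dump())


class CvSection(BaseModel):
    model_config = ConfigDict(extra="forbid")

    n_runs: int = 100
    n_folds: int = 3
    rf_trees: int = 500
    stage2_trees: int = 200
    mrmr_k: int = 5
    prune_threshold: float = 0.90
    select_within_folds: bool = True

    def build(self, seed: int) -> CvConfig:
        return CvConfig(seed=seed, **self.model_dump())


class PathsSection(BaseModel):
    model_config = ConfigDict(extra="forbid")

    cohort_dir: str = "cohort"
    features_dir: str = "features"
    report_dir: str = "report"


class PipelineConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    cohort: CohortSection = Field(default_factory=CohortSection)
    cv: CvSection = Field(default_factory=CvSection)
    features: FeatureOptions = Field(default_factory=FeatureOptions)
    paths: PathsSection = Field(default_factory=PathsSection)
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.model_validate(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(json.loads(self.model_dump_json()), fh,
                           sort_keys=True)

    def hash(self) -> str:
        payload = self.model_dump_json()
        return hashlib.sha256(payload.encode()).hexdigest()[:16]
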