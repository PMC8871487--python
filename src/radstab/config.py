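"""Structured, schema-validated run configuration.

One document holds every stage's parameters; unknown keys are rejected so
typos fail fast.  ``stage_seed`` derives per-stage seeds from the master seed
by a fixed affine counter scheme, letting individual stages be rerun in
isolation while staying reproducible.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field

SCHEMA_VERSION = 1

STAGES = ("simulate", "extract", "reliability", "survival", "stats")


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PerturbationConfig(_Strict):
    n_variants: int = 100
    amplitude_mm: float = 1.5
    noise_corr_mm: float = 5.0
    gradient_modulation: bool = True
    min_dice: float = 0.6


class SurvivalGenConfig(_Strict):
    beta: dict[str, float] = Field(default_factory=lambda: {
        "original.firstorder.Mean": 0.8,
        "original.shape2D.PixelSurface": 0.6,
        "original.shape2D.MajorAxisLength": 0.4,
    })
    baseline_rate: float = 0.25
    censor_rate: float = 0.05
    admin_censor_time: float = 5.0


class CohortConfig(_Strict):
    n_patients: int = 50
    modality: str = "CT-like"
    image_size: int = 64
    pixel_spacing: float = 1.0
    semi_axis_range_mm: tuple[float, float] = (4.0, 14.0)
    irregularity_range: tuple[float, float] = (0.05, 0.25)
    texture_corr_range_mm: tuple[float, float] = (2.0, 5.0)
    sharpness_range_mm: tuple[float, float] = (0.5, 3.0)
    k_manual: int = 4
    manual_amplitude_mm: float = 0.5


class CropConfig(_Strict):
    box_size: int | None = None  # None -> sized from the cohort's diameters
    min_volume_mm3: float = 30.0
    slice_thickness_mm: float = 1.0


class FeatureExtractionConfig(_Strict):
    n_bins: int = 32
    discretization: str = "fixed_bin_count"
    bin_width: float | None = None
    wavelets: bool = False
    wavelet: str = "coif1"


class SignatureConfig(_Strict):
    high_threshold: float = 0.99
    low_threshold: float = 0.75


class SurvivalEvalConfig(_Strict):
    n_folds: int = 5
    max_k: int = 5
    min_improvement: float = 0.005
    penalty: float = 1e-6
    refit_per_variant: bool = False


class StatsConfig(_Strict):
    alpha: float = 0.05
    n_comparisons: int = 2


class RunConfig(_Strict):
    """Top-level configuration for the end-to-end pipeline."""

    schema_version: int = SCHEMA_VERSION
    master_seed: int = 0
    cohort: CohortConfig = Field(default_factory=CohortConfig)
    perturbation: PerturbationConfig = Field(default_factory=PerturbationConfig)
    survival_gen: SurvivalGenConfig = Field(default_factory=SurvivalGenConfig)
    crop: CropConfig = Field(default_factory=CropConfig)
    features: FeatureExtractionConfig = Field(default_factory=FeatureExtractionConfig)
    signatures: SignatureConfig = Field(default_factory=SignatureConfig)
    survival_eval: SurvivalEvalConfig = Field(default_factory=SurvivalEvalConfig)
    stats: StatsConfig = Field(default_factory=StatsConfig)

    # -- helpers -----------------------------------------------------------
    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def stage_seed(self, stage: str) -> int:
        idx = STAGES.index(stage)
        return (self.master_seed * 100_003 + idx) % 2**31

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls.model_validate(data)
        if cfg.schema_version != SCHEMA_VERSION:
            raise ValueError(f"unsupported schema_version {cfg.schema_version}")
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(mode="json"),
                                             sort_keys=False))
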