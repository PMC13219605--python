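"""Schema-validated pipeline configuration (YAML-backed, unknown keys
rejected)."""

from __future__ import annotations

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .classifier import ForestHyperparams
from .sampling import ResampleSpec
from .synthetic_data import LethalityMechanism, WeatherGenParams

__all__ = [
    "GeneratorConfig",
    "MechanismConfig",
    "ExtractionConfig",
    "SplitConfig",
    "ResampleConfig",
    "ClassifierConfig",
    "PipelineConfig",
    "load_config",
]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GeneratorConfig(_Strict):
    n_cities: int = 8
    years: int = 15
    mean_tmax_range: tuple[float, float] = (8.0, 24.0)
    seasonal_amplitude: float = 10.0
    amplitude_jitter: tuple[float, float] = (0.5, 1.4)
    seasonal_phase: float = 110.0
    ar1_coefficient: float = Field(0.7, ge=0.0, lt=1.0)
    noise_sd: float = 2.5
    rh_mean: float = 60.0
    rh_amplitude: float = 10.0
    rh_temp_coupling: float = -2.0
    rh_noise_sd: float = 5.0
    wind_mean: float = 3.5
    wind_sd: float = 1.5
    cities_per_country: int = 4
    start_year: int = 1980

    def weather_params(self, seed: int) -> WeatherGenParams:
        return WeatherGenParams(
            n_cities=self.n_cities,
            years=self.years,
            mean_tmax_range=self.mean_tmax_range,
            seasonal_amplitude=self.seasonal_amplitude,
            amplitude_jitter=self.amplitude_jitter,
            seasonal_phase=self.seasonal_phase,
            ar1_coefficient=self.ar1_coefficient,
            noise_sd=self.noise_sd,
            rh_mean=self.rh_mean,
            rh_amplitude=self.rh_amplitude,
            rh_temp_coupling=self.rh_temp_coupling,
            rh_noise_sd=self.rh_noise_sd,
            wind_mean=self.wind_mean,
            wind_sd=self.wind_sd,
            seed=seed,
        )


class MechanismConfig(_Strict):
    shock_weights: tuple[float, float, float, float, float] = (10.0, 0.8, 16.0, 0.8, -0.8)
    threshold_wbt: float = Field(35.0, gt=25.0)
    target_prevalence: float = Field(0.0078, gt=0.0, lt=0.5)

    def mechanism(self, seed: int) -> LethalityMechanism:
        return LethalityMechanism(
            shock_weights=self.shock_weights,
            threshold_wbt=self.threshold_wbt,
            target_prevalence=self.target_prevalence,
            seed=seed,
        )


class ExtractionConfig(_Strict):
    percentile: float = Field(0.90, gt=0.0, lt=1.0)
    min_duration: int = Field(2, ge=1)
    adaptive_n: int = Field(30, ge=1)
    m: int = Field(10, ge=1)
    min_history_years: int = Field(10, ge=1)


class SplitConfig(_Strict):
    test_frac: float = Field(0.10, gt=0.0, lt=1.0)
    val_frac: float = Field(0.10, gt=0.0, lt=1.0)
    region_key: str = "city_id"


class ResampleConfig(_Strict):
    strategy: str = "smote"
    downsample_keep_fraction: float = 0.25
    smote_k: int = 5
    target_ratio: float = 1.0

    def spec(self, seed: int) -> ResampleSpec:
        return ResampleSpec(
            strategy=self.strategy,
            downsample_keep_fraction=self.downsample_keep_fraction,
            smote_k=self.smote_k,
            target_ratio=self.target_ratio,
            seed=seed,
        )


class ClassifierConfig(_Strict):
    n_trees: int = Field(500, ge=1)
    max_depth: int | None = None
    max_features: str | int | float = "sqrt"
    min_samples_leaf: int = Field(1, ge=1)
    decision_threshold: float = Field(0.6, gt=0.0, lt=1.0)

    def hyperparams(self) -> ForestHyperparams:
        return ForestHyperparams(
            n_trees=self.n_trees,
            max_depth=self.max_depth,
            max_features=self.max_features,
            min_samples_leaf=self.min_samples_leaf,
        )


class PipelineConfig(_Strict):
    generator: GeneratorConfig = Field(default_factory=GeneratorConfig)
    mechanism: MechanismConfig = Field(default_factory=MechanismConfig)
    extraction: ExtractionConfig = Field(default_factory=ExtractionConfig)
    split: SplitConfig = Field(default_factory=SplitConfig)
    resample: ResampleConfig = Field(default_factory=ResampleConfig)
    classifier: ClassifierConfig = Field(default_factory=ClassifierConfig)
    wbt_baseline_thresholds: tuple[float, ...] = (20.0, 25.0, 30.0, 35.0)
    shock_cutoff: float = 25.0
    importance_repeats: int = Field(10, ge=1)
    run_selection: bool = False
    selection_max_steps: int | None = None
    seed: int = 0


def load_config(path) -> PipelineConfig:
    """Read and validate a YAML pipeline configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return PipelineConfig.model_validate(raw)
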