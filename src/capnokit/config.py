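"""Tunable pipeline parameters, YAML round-trippable.

Every threshold used by denoising, breath detection, phase segmentation,
breath QC, featurization and model evaluation lives here, so that no rule
is buried in code. Defaults are defensible engineering choices for 50 Hz
mouthpiece capnography, not claims about any particular device.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml


@dataclass
class DenoiseConfig:
    window_s: float = 0.3  # Savitzky-Golay window (rounded to odd samples)
    polyorder: int = 3


@dataclass
class DetectConfig:
    onset_kpa: float = 0.5  # rise above running baseline starting an excursion
    offset_kpa: float = 0.25  # fall below running baseline ending it
    baseline_window_s: float = 4.0  # rolling-minimum window for the baseline
    baseline_smooth_s: float = 1.0
    refine_eps_kpa: float = 0.05  # edge refinement level above baseline
    min_breath_s: float = 1.0  # excursions closer than this are merged


@dataclass
class SegmentConfig:
    slope_frac: float = 0.1  # phase boundary at this fraction of peak slope
    min_phase_samples: int = 3


@dataclass
class QCConfig:
    min_amplitude_kpa: float = 2.0  # below: nose_breathing
    baseline_mismatch_kpa: float = 0.15  # Phase-1 vs Phase-4b level gap: condensation
    max_fall_time_s: float = 0.55  # smeared downstroke: condensation
    spike_residual_kpa: float = 0.35  # median-filter residual: cough_swallow
    cardio_min_crossings: int = 4  # ripple must complete several half-cycles
    spike_window_s: float = 0.22
    cardio_band_hz: tuple = (0.8, 2.5)  # cardiogenic ripple frequency band
    cardio_sd_kpa: float = 0.045  # detrended Phase-3 residual SD threshold


@dataclass
class FeatureConfig:
    axis_scale: float = 1.0  # kPa per second: canonical aspect for angles
    min_breaths: int = 5  # valid breaths needed for a reportable capnogram
    min_phase_samples: int = 3


@dataclass
class ModelConfig:
    holdout_frac: float = 0.2
    n_folds: int = 5
    n_iterations: int = 100
    lr_C: float = 1.0
    xgb_n_estimators: int = 100
    xgb_max_depth: int = 3
    xgb_learning_rate: float = 0.1
    svm_C: float = 1.0
    svm_calibration_folds: int = 3
    decision_boundary: float = 0.5


@dataclass
class PipelineConfig:
    denoise: DenoiseConfig = field(default_factory=DenoiseConfig)
    detect: DetectConfig = field(default_factory=DetectConfig)
    segment: SegmentConfig = field(default_factory=SegmentConfig)
    qc: QCConfig = field(default_factory=QCConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    model: ModelConfig = field(default_factory=ModelConfig)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        cfg = cls()
        for section_name, section_val in (d or {}).items():
            section = getattr(cfg, section_name)
            for k, v in (section_val or {}).items():
                if not hasattr(section, k):
                    raise KeyError(f"unknown config key {section_name}.{k}")
                if isinstance(getattr(section, k), tuple) and isinstance(v, list):
                    v = tuple(v)
                setattr(section, k, v)
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})
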