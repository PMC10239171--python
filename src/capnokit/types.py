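"""Core domain containers.

Conventions used throughout the package:

* pressures in kPa, times in seconds, sample indices 0-based,
  intervals half-open ``[start, end)``;
* a *capnogram* is one uniformly sampled recording of respired pCO2;
* one respiratory cycle (Phase 1 baseline, Phase 2 upstroke, Phase 3
  plateau, Phase 4a downstroke, Phase 4b baseline) is one *breath*.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .errors import ParameterError

#: the five artefact classes recognised by breath QC
ARTEFACT_KINDS = (
    "nose_breathing",
    "condensation",
    "incomplete_breath",
    "cough_swallow",
    "cardiogenic_oscillation",
)

#: QC precedence: the first matching reason is the primary one
EXCLUSION_PRECEDENCE = (
    "incomplete_breath",
    "condensation",
    "nose_breathing",
    "cough_swallow",
    "cardiogenic_oscillation",
    "feature_incomputable",
)


@dataclass
class CapnogramTrace:
    """A uniformly sampled pCO2 time series with recording metadata."""

    samples: np.ndarray  # kPa
    sample_rate: float  # Hz
    recording_id: str = ""
    patient_id: str = ""
    collected_at: Optional[str] = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sample_rate <= 0:
            raise ParameterError("sample_rate must be positive")
        if self.samples.ndim != 1 or self.samples.size < 2:
            raise ParameterError("trace needs at least 2 samples")
        if not np.all(np.isfinite(self.samples)):
            raise ParameterError("trace contains non-finite samples")

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sample_rate

    def copy_with(self, **kw) -> "CapnogramTrace":
        return replace(self, **kw)


@dataclass
class BreathBoundaries:
    """Per-breath phase boundaries, half-open sample intervals.

    ``start <= p1_end <= p2_end <= p3_end <= p4a_end <= end``;
    Phase 1 is ``[start, p1_end)``, Phase 2 ``[p1_end, p2_end)``,
    Phase 3 ``[p2_end, p3_end)``, Phase 4a ``[p3_end, p4a_end)`` and
    Phase 4b ``[p4a_end, end)``.
    """

    start: int
    p1_end: int
    p2_end: int
    p3_end: int
    p4a_end: int
    end: int

    def as_tuple(self) -> tuple:
        return (self.start, self.p1_end, self.p2_end, self.p3_end, self.p4a_end, self.end)

    def validate(self) -> None:
        s, a, b, c, d, e = self.as_tuple()
        if not (s < a <= b <= c <= d <= e):
            raise ParameterError(f"phase boundaries out of order: {self.as_tuple()}")


@dataclass
class BreathRecord:
    """One detected breath: interval, optional phase boundaries, QC status."""

    start: int
    end: int
    boundaries: Optional[BreathBoundaries] = None
    qc_status: str = "valid"  # "valid" | "excluded"
    exclusion_reason: Optional[str] = None
    incomplete: bool = False

    def __post_init__(self) -> None:
        if self.qc_status == "excluded" and self.exclusion_reason is None:
            raise ParameterError("excluded breath needs an exclusion_reason")


@dataclass
class BreathSegmentation:
    """All breaths of one recording, ordered and non-overlapping."""

    breaths: list = field(default_factory=list)  # list[BreathRecord]

    @property
    def n_breaths(self) -> int:
        return len(self.breaths)

    @property
    def valid_breaths(self) -> list:
        return [b for b in self.breaths if b.qc_status == "valid"]

    def validate(self) -> None:
        prev_end = -1
        for b in self.breaths:
            if b.start < prev_end:
                raise ParameterError("breaths overlap or are unordered")
            prev_end = b.end
            if b.boundaries is not None:
                b.boundaries.validate()


@dataclass
class QCReport:
    """Summary of breath detection and exclusion for one recording."""

    n_breaths_detected: int
    n_valid: int
    exclusion_counts: dict
    snr_per_breath: list
    denoise_correlation: float

    def validate(self) -> None:
        if self.n_valid > self.n_breaths_detected:
            raise ParameterError("n_valid exceeds n_breaths_detected")
        if sum(self.exclusion_counts.values()) != self.n_breaths_detected - self.n_valid:
            raise ParameterError("exclusion counts do not sum to exclusions")


@dataclass
class BreathMorphology:
    """Parameters of one idealised respiratory cycle.

    ``obstruction_index`` runs from 0 (square, healthy waveform) to 1
    (maximal "shark-fin" obstruction); it controls the upstroke time
    constant, the plateau fraction and the plateau curvature.
    """

    etco2: float = 5.0  # kPa, pCO2 at close of expiratory plateau
    baseline: float = 0.0  # kPa, inspiratory baseline
    respiratory_period: float = 4.0  # s
    ei_ratio: float = 1.4  # expiratory / inspiratory duration
    obstruction_index: float = 0.0
    plateau_slope: float = 0.03  # kPa/s, linear term of the plateau
    noise_sd: float = 0.0  # kPa, additive white noise

    def validate(self) -> None:
        if not (self.etco2 > self.baseline >= 0):
            raise ParameterError("need etco2 > baseline >= 0")
        if not (0.0 <= self.obstruction_index <= 1.0):
            raise ParameterError("obstruction_index must lie in [0, 1]")
        if self.respiratory_period <= 0 or self.ei_ratio <= 0:
            raise ParameterError("respiratory_period and ei_ratio must be positive")
        if self.noise_sd < 0 or self.plateau_slope < 0:
            raise ParameterError("noise_sd and plateau_slope must be non-negative")


@dataclass
class ArtefactSpec:
    """A rendered artefact window within a recording."""

    kind: str
    onset: float  # s
    duration: float  # s
    magnitude: float = 1.0

    def validate(self, recording_duration: Optional[float] = None) -> None:
        if self.kind not in ARTEFACT_KINDS:
            raise ParameterError(f"unknown artefact kind {self.kind!r}")
        if self.onset < 0 or self.duration <= 0:
            raise ParameterError("artefact onset/duration invalid")
        if recording_duration is not None and self.onset + self.duration > recording_duration + 1e-9:
            raise ParameterError("artefact extends past end of recording")


@dataclass
class SyntheticPatient:
    """Latent description of one simulated participant."""

    patient_id: str
    label: str  # "COPD" | "non_COPD"
    condition: str  # healthy, asthma, heart_failure, ...
    age: float
    sex: str  # "F" | "M"
    bmi: float
    fev1_pct_pred: float
    morphology_mean: BreathMorphology
    within_patient_sd: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.label not in ("COPD", "non_COPD"):
            raise ParameterError("label must be COPD or non_COPD")
        if self.fev1_pct_pred <= 0:
            raise ParameterError("fev1_pct_pred must be positive")
        self.morphology_mean.validate()
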