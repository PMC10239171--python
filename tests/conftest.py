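"""Shared fixtures: synthetic patients and cohorts generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

from capnokit.synthetic import BASE_WITHIN_SD, CohortConfig, generate_cohort
from capnokit.types import BreathMorphology, SyntheticPatient


def make_patient(obstruction: float = 0.0, noise_sd: float = 0.0,
                 jitter_scale: float = 0.0, period: float = 4.0,
                 ei_ratio: float = 1.4, etco2: float = 5.0,
                 plateau_slope: float | None = None,
                 patient_id: str = "P0", label: str = "non_COPD") -> SyntheticPatient:
    """A patient with fully controlled morphology for deterministic tests."""
    morph = BreathMorphology(
        etco2=etco2, baseline=0.0, respiratory_period=period, ei_ratio=ei_ratio,
        obstruction_index=obstruction,
        plateau_slope=0.03 + 0.45 * obstruction if plateau_slope is None else plateau_slope,
        noise_sd=noise_sd,
    )
    sd = {k: v * jitter_scale for k, v in BASE_WITHIN_SD.items()}
    return SyntheticPatient(
        patient_id=patient_id, label=label,
        condition="COPD" if label == "COPD" else "healthy",
        age=55.0, sex="F", bmi=26.0, fev1_pct_pred=max(100.0 - 70.0 * obstruction, 15.0),
        morphology_mean=morph, within_patient_sd=sd,
    )


@pytest.fixture(scope="session")
def table1_cohort():
    """Cohort mirroring the study's class proportions (80 COPD / 215 non-COPD),
    3 recordings per patient, default separated preset, no artefacts."""
    cfg = CohortConfig(artefact_rate=0.0, noise_sd=0.04)
    return generate_cohort(80, 215, recordings_per_patient=3, config=cfg, rng_seed=101)


@pytest.fixture(scope="session")
def table1_features(table1_cohort):
    from capnokit.features import featurize_cohort

    return featurize_cohort(table1_cohort)


@pytest.fixture(scope="session")
def plateau_signal_cohort():
    """Class signal injected only through plateau-generator parameters.

    240 patients: with 82 features, the coefficient noise on
    signal-free regions shrinks enough at ~400 balanced rows for the
    importance map to be a stable readout."""
    cfg = CohortConfig(artefact_rate=0.0, noise_sd=0.04, plateau_signal_only=True)
    return generate_cohort(80, 160, recordings_per_patient=3, config=cfg, rng_seed=202)


@pytest.fixture(scope="session")
def plateau_signal_features(plateau_signal_cohort):
    from capnokit.features import featurize_cohort

    return featurize_cohort(plateau_signal_cohort)


@pytest.fixture(scope="session")
def noise_free_cohort():
    """100 noise-free, artefact-free recordings with ground truth."""
    cfg = CohortConfig(artefact_rate=0.0, noise_sd=0.0)
    return generate_cohort(17, 33, recordings_per_patient=2, config=cfg, rng_seed=303)
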