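"""Seeded generator of labelled synthetic capnograms and cohorts.

The generator emulates the structure the downstream pipeline assumes:
50 Hz tidal-breathing pCO2 recordings of ~75 s, square-wave-like healthy
breaths versus concave "shark-fin" obstructed breaths, within-patient
repeat recordings, class-conditional morphology distributions, % predicted
FEV1 negatively linked to obstruction, and five artefact classes.

Breath model (one respiratory cycle of period ``T``)
----------------------------------------------------
The cycle is piecewise analytic so every geometric feature has a closed
(or densely computable) form for oracle testing:

* Phase 1  — flat inspiratory baseline ``B``;
* Phase 2  — expiratory upstroke: saturating exponential from ``B`` to the
  plateau onset, time constant ``t2 / ln 10`` so the upstroke derivative
  decays to exactly 10% of its peak at the constructed Phase-2/3 boundary
  (this is the generator's shape convention; it gives every boundary a
  well-defined derivative signature);
* Phase 3  — expiratory plateau: linear + quadratic, ending exactly at
  ``etco2``; slope and curvature grow with ``obstruction_index``;
* Phase 4a — inspiratory downstroke: truncated exponential decay back to
  ``B`` with the symmetric time constant ``t4a / ln 10``;
* Phase 4b — flat inspiratory baseline.

The expiratory fraction of the cycle is ``ei_ratio / (1 + ei_ratio)``;
within expiration the upstroke takes ``0.10 + 0.35 * obstruction_index``
of the time, within inspiration the downstroke takes 40%, and the
remaining baseline time is split evenly between Phase 4b and the next
cycle's Phase 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParameterError
from .types import (
    ArtefactSpec,
    BreathBoundaries,
    BreathMorphology,
    CapnogramTrace,
    SyntheticPatient,
)

LN10 = math.log(10.0)

#: plateau quadratic coefficient (kPa/s^2) at obstruction_index = 1
PLATEAU_CURVATURE_GAIN = 0.12
#: fraction of expiration taken by the upstroke: UPSTROKE_FRAC_MIN + gain * obstruction
UPSTROKE_FRAC_MIN = 0.10
UPSTROKE_FRAC_GAIN = 0.35
#: fraction of inspiration taken by the downstroke
DOWNSTROKE_FRAC = 0.40

#: a breath counts as overlapping a window-type artefact when at least this
#: fraction of its duration lies inside the window
ARTEFACT_OVERLAP_FRAC = 0.3


# --------------------------------------------------------------------------
# single-breath continuous model
# --------------------------------------------------------------------------

def phase_durations(m: BreathMorphology) -> dict:
    """Continuous-time durations of the five phases of one cycle."""
    m.validate()
    T = m.respiratory_period
    te = T * m.ei_ratio / (1.0 + m.ei_ratio)
    ti = T - te
    t2 = te * (UPSTROKE_FRAC_MIN + UPSTROKE_FRAC_GAIN * m.obstruction_index)
    t3 = te - t2
    t4a = DOWNSTROKE_FRAC * ti
    t1 = t4b = 0.5 * (ti - t4a)
    return {"t1": t1, "t2": t2, "t3": t3, "t4a": t4a, "t4b": t4b}


def _plateau_coeffs(m: BreathMorphology, t3: float) -> tuple:
    """(c0, s, q): plateau p(u) = c0 + s u + q u^2 ending at etco2."""
    q = PLATEAU_CURVATURE_GAIN * m.obstruction_index
    s = m.plateau_slope
    c0 = m.etco2 - s * t3 - q * t3 * t3
    if c0 <= m.baseline:
        raise ParameterError(
            "plateau rise exceeds excursion height; reduce plateau_slope or period"
        )
    return c0, s, q


def breath_waveform(m: BreathMorphology, t: np.ndarray) -> np.ndarray:
    """Noise-free pCO2 of one cycle at times ``t`` in [0, T) (vectorised)."""
    d = phase_durations(m)
    t1, t2, t3, t4a = d["t1"], d["t2"], d["t3"], d["t4a"]
    B, E = m.baseline, m.etco2
    c0, s, q = _plateau_coeffs(m, t3)

    t = np.asarray(t, dtype=float)
    out = np.full(t.shape, B)

    # Phase 2: normalised saturating exponential from B to c0
    u = t - t1
    in2 = (u >= 0) & (u < t2)
    tau2 = t2 / LN10
    out[in2] = B + (c0 - B) * (1.0 - np.exp(-u[in2] / tau2)) / (1.0 - 0.1)

    # Phase 3: quadratic plateau
    u = t - (t1 + t2)
    in3 = (u >= 0) & (u < t3)
    out[in3] = c0 + s * u[in3] + q * u[in3] ** 2

    # Phase 4a: truncated exponential decay from E to B
    u = t - (t1 + t2 + t3)
    in4 = (u >= 0) & (u < t4a)
    tau4 = t4a / LN10
    out[in4] = B + (E - B) * (np.exp(-u[in4] / tau4) - 0.1) / (1.0 - 0.1)

    return out


def boundary_times(m: BreathMorphology) -> tuple:
    """(p1_end, p2_end, p3_end, p4a_end, end) in seconds from cycle start."""
    d = phase_durations(m)
    a = d["t1"]
    b = a + d["t2"]
    c = b + d["t3"]
    e = c + d["t4a"]
    return (a, b, c, e, e + d["t4b"])


def generate_breath(
    morphology: BreathMorphology,
    sample_rate: float = 50.0,
    rng_seed: int = 0,
) -> tuple:
    """One full respiratory cycle as a trace, plus ground-truth boundaries."""
    morphology.validate()
    if sample_rate <= 0:
        raise ParameterError("sample_rate must be positive")
    n = int(round(morphology.respiratory_period * sample_rate))
    t = np.arange(n) / sample_rate
    x = breath_waveform(morphology, t)
    if morphology.noise_sd > 0:
        rng = np.random.default_rng(rng_seed)
        x = x + rng.normal(0.0, morphology.noise_sd, size=n)
    bt = boundary_times(morphology)
    idx = [int(round(b * sample_rate)) for b in bt]
    bounds = BreathBoundaries(0, idx[0], idx[1], idx[2], idx[3], n)
    trace = CapnogramTrace(samples=x, sample_rate=sample_rate, recording_id="breath")
    return trace, bounds


def analytic_breath_features(m: BreathMorphology, axis_scale: float = 1.0,
                             n_dense: int = 4000) -> dict:
    """Closed-form / dense-grid geometric features of the noise-free cycle.

    Slopes are least-squares line fits of the continuous model over each
    phase, evaluated on a dense grid (independent of the discrete feature
    pipeline); angles follow the two-slope arctan construction with the
    canonical ``axis_scale`` (kPa per second treated as 1:1 by default).
    """
    d = phase_durations(m)
    t1, t2, t3, t4a, t4b = d["t1"], d["t2"], d["t3"], d["t4a"], d["t4b"]
    c0, s, q = _plateau_coeffs(m, t3)
    B, E = m.baseline, m.etco2

    def dense_ls_slope(t_lo, t_hi):
        tt = np.linspace(t_lo, t_hi, n_dense)
        xx = breath_waveform(m, tt)
        return np.polyfit(tt, xx, 1)[0]

    m2 = dense_ls_slope(t1, t1 + t2)
    m3 = s + q * t3  # LS slope of a quadratic == derivative at midpoint
    m4 = dense_ls_slope(t1 + t2 + t3, t1 + t2 + t3 + t4a)
    m_base = 0.0

    def angle(m_in, m_out):
        a = math.atan(m_in / axis_scale) - math.atan(m_out / axis_scale)
        return 180.0 - math.degrees(abs(a))

    alpha = angle(m2, m3)
    beta = angle(m3, m4)
    gamma = angle(m4, m_base)
    delta = angle(m2, m_base)

    # areas above baseline (exact integrals)
    tau2 = t2 / LN10
    auc2 = (c0 - B) / 0.9 * (t2 - tau2 * (1.0 - 0.1))
    auc3 = (c0 - B) * t3 + s * t3**2 / 2.0 + q * t3**3 / 3.0
    tau4 = t4a / LN10
    auc4 = (E - B) / 0.9 * (tau4 * (1.0 - 0.1) - 0.1 * t4a)
    auc_total = auc2 + auc3 + auc4

    exp_dur = t2 + t3
    insp_dur = t1 + t4a + t4b
    return {
        "alpha_deg": alpha,
        "beta_deg": beta,
        "gamma_deg": gamma,
        "delta_deg": delta,
        "phase2_slope": m2,
        "phase3_slope": m3,
        "phase4a_slope": m4,
        "phase3_quad_coeff": q,
        "phase3_concavity": q * t3 * t3 / 4.0,
        "baseline_pco2": B,
        "etco2": E,
        "plateau_mean": c0 + s * t3 / 2.0 + q * t3 * t3 / 3.0,
        "pco2_range": E - B,
        "auc_total": auc_total,
        "auc_phase2": auc2,
        "auc_phase3": auc3,
        "auc_per_second": auc_total / m.respiratory_period,
        "breath_duration": m.respiratory_period,
        "exp_duration": exp_dur,
        "insp_duration": insp_dur,
        "ei_ratio": exp_dur / insp_dur,
        "phase2_duration": t2,
        "phase3_duration": t3,
        "phase4a_duration": t4a,
        "phase2_frac_of_exp": t2 / exp_dur,
        "phase3_frac_of_exp": t3 / exp_dur,
        "max_upslope": (c0 - B) / 0.9 / tau2,
        "min_downslope": -(E - B) / 0.9 / tau4,
    }


# --------------------------------------------------------------------------
# whole-recording assembly
# --------------------------------------------------------------------------

@dataclass
class RecordingGroundTruth:
    """What the generator knows about one synthetic recording."""

    boundaries: list  # list[BreathBoundaries], clipped to trace length
    morphologies: list  # list[BreathMorphology], one per breath
    artefact_breaths: dict  # kind -> sorted list of breath indices
    incomplete_final: bool

    @property
    def n_breaths(self) -> int:
        return len(self.boundaries)


def _jittered(m: BreathMorphology, sd: dict, rng) -> BreathMorphology:
    def draw(value, key, lo, hi):
        s = sd.get(key, 0.0)
        return float(np.clip(value + (rng.normal(0.0, s) if s > 0 else 0.0), lo, hi))

    return BreathMorphology(
        etco2=draw(m.etco2, "etco2", m.baseline + 1.0, 10.0),
        baseline=m.baseline,
        respiratory_period=draw(m.respiratory_period, "respiratory_period", 1.5, 10.0),
        ei_ratio=draw(m.ei_ratio, "ei_ratio", 0.6, 3.0),
        obstruction_index=draw(m.obstruction_index, "obstruction_index", 0.0, 1.0),
        plateau_slope=draw(m.plateau_slope, "plateau_slope", 0.0, 0.8),
        noise_sd=m.noise_sd,
    )


def generate_capnogram(
    patient: SyntheticPatient,
    duration: float = 75.0,
    sample_rate: float = 50.0,
    artefacts: list | None = None,
    rng_seed: int = 0,
) -> tuple:
    """Render one recording: (CapnogramTrace, RecordingGroundTruth).

    Breath-to-breath morphology jitter is drawn from
    ``patient.within_patient_sd``; the trace has exactly
    ``round(duration * sample_rate)`` samples. An ``incomplete_breath``
    artefact rescales the breath train so the recording is cut in the
    middle of the final breath's expiratory plateau; a trailing cycle cut
    before the end of its downstroke is always ground-truth incomplete.
    """
    patient.validate()
    if duration <= 0 or sample_rate <= 0:
        raise ParameterError("duration and sample_rate must be positive")
    artefacts = list(artefacts or [])
    for a in artefacts:
        a.validate(recording_duration=duration)

    rng = np.random.default_rng(np.random.SeedSequence([int(rng_seed) % (2**31), 17]))
    n_samples = int(round(duration * sample_rate))

    # draw breath morphologies until the train covers the recording
    morphs, starts, total = [], [], 0.0
    while total < duration + 1e-9:
        bm = _jittered(patient.morphology_mean, patient.within_patient_sd, rng)
        morphs.append(bm)
        starts.append(total)
        total += bm.respiratory_period

    incomplete_specs = [a for a in artefacts if a.kind == "incomplete_breath"]
    if incomplete_specs:
        # scale all periods by the lambda closest to 1 that lands the cut
        # at the centre of some breath's plateau
        best = None
        for bm, t0 in zip(morphs, starts):
            bt = boundary_times(bm)
            mid = t0 + 0.5 * (bt[1] + bt[2])
            lam = duration / mid
            if best is None or abs(lam - 1.0) < abs(best - 1.0):
                best = lam
        lam = float(np.clip(best, 0.85, 1.15))
        for bm in morphs:
            bm.respiratory_period *= lam
        starts = list(np.asarray(starts) * lam)
        while starts[-1] + morphs[-1].respiratory_period < duration:
            bm = _jittered(patient.morphology_mean, patient.within_patient_sd, rng)
            starts.append(starts[-1] + morphs[-1].respiratory_period)
            morphs.append(bm)

    t_global = np.arange(n_samples) / sample_rate
    x = np.full(n_samples, patient.morphology_mean.baseline)
    boundaries, kept_morphs = [], []
    for bm, t0 in zip(morphs, starts):
        i0 = int(np.ceil(t0 * sample_rate - 1e-9))
        if i0 >= n_samples:
            break
        i1 = min(int(np.ceil((t0 + bm.respiratory_period) * sample_rate - 1e-9)), n_samples)
        x[i0:i1] = breath_waveform(bm, t_global[i0:i1] - t0)
        bt = boundary_times(bm)
        idx = [min(int(round((t0 + b) * sample_rate)), n_samples) for b in bt]
        # drop a trailing fragment in which expiration never started
        if idx[0] >= n_samples:
            break
        boundaries.append(BreathBoundaries(i0, *idx[:4], i1))
        kept_morphs.append(bm)

    incomplete_final = bool(boundaries) and boundaries[-1].end >= n_samples \
        and n_samples < boundaries[-1].p4a_end + 1

    # ---- artefact rendering on the clean assembled signal -----------------
    artefact_breaths: dict = {}
    B = patient.morphology_mean.baseline

    def breaths_overlapping(w0, w1, min_frac=ARTEFACT_OVERLAP_FRAC):
        hits = []
        for j, bb in enumerate(boundaries):
            s0, s1 = bb.start / sample_rate, bb.end / sample_rate
            ov = min(s1, w1) - max(s0, w0)
            if ov > min_frac * (s1 - s0):
                hits.append(j)
        return hits

    for a in artefacts:
        w0, w1 = a.onset, a.onset + a.duration
        win = (t_global >= w0) & (t_global < w1)
        if a.kind == "nose_breathing":
            # nose breathing affects whole breaths: attenuate every
            # substantially overlapped cycle end to end
            hits = breaths_overlapping(w0, w1)
            mask = np.zeros(n_samples, dtype=bool)
            for j in hits:
                mask[boundaries[j].start:boundaries[j].end] = True
            if not hits:
                mask = win
            x[mask] = B + 0.3 * (x[mask] - B) + rng.normal(0.0, 0.05 * a.magnitude, int(mask.sum()))
        elif a.kind == "condensation":
            # smooth drift bump plus a causal smear of fast transitions
            drift = 0.5 * a.magnitude * np.sin(np.pi * (t_global[win] - w0) / a.duration) ** 2
            seg = x[win].copy()
            tau = 0.4 * a.magnitude
            alpha_f = 1.0 - math.exp(-1.0 / (tau * sample_rate))
            for i in range(1, seg.size):
                seg[i] = seg[i - 1] + alpha_f * (seg[i] - seg[i - 1])
            x[win] = seg + drift
            hits = breaths_overlapping(w0, w1)
        elif a.kind == "cough_swallow":
            centres = np.arange(w0 + 0.5 * min(a.duration, 1.2), w1, 1.2)
            if centres.size == 0:
                centres = np.array([0.5 * (w0 + w1)])
            for c in centres:
                x += 1.4 * a.magnitude * np.exp(-0.5 * ((t_global - c) / 0.05) ** 2)
            hits = [j for j, bb in enumerate(boundaries)
                    if any(bb.start <= c * sample_rate < bb.end for c in centres)]
        elif a.kind == "cardiogenic_oscillation":
            ripple = 0.12 * a.magnitude * np.sin(2 * np.pi * 1.4 * (t_global - w0))
            hits = []
            for j, bb in enumerate(boundaries):
                p3 = np.zeros(n_samples, dtype=bool)
                p3[bb.p2_end:bb.p3_end] = True
                mask = p3 & win
                if mask.sum() > 0.5 * max(bb.p3_end - bb.p2_end, 1):
                    x[mask] += ripple[mask]
                    hits.append(j)
        elif a.kind == "incomplete_breath":
            hits = [len(boundaries) - 1] if incomplete_final else []
        else:  # pragma: no cover - validated upstream
            raise ParameterError(a.kind)
        if hits:
            artefact_breaths.setdefault(a.kind, set()).update(hits)

    if incomplete_final:
        artefact_breaths.setdefault("incomplete_breath", set()).add(len(boundaries) - 1)
    artefact_breaths = {k: sorted(v) for k, v in artefact_breaths.items()}

    noise_sd = patient.morphology_mean.noise_sd
    if noise_sd > 0:
        x = x + rng.normal(0.0, noise_sd, n_samples)

    trace = CapnogramTrace(
        samples=x, sample_rate=sample_rate,
        recording_id=f"{patient.patient_id}_r{rng_seed}",
        patient_id=patient.patient_id,
    )
    gt = RecordingGroundTruth(
        boundaries=boundaries,
        morphologies=kept_morphs,
        artefact_breaths=artefact_breaths,
        incomplete_final=incomplete_final,
    )
    return trace, gt


# --------------------------------------------------------------------------
# cohort generation
# --------------------------------------------------------------------------

#: non-COPD condition mix (proportions follow the study's condition table)
NON_COPD_CONDITIONS = {
    "healthy": 0.16,
    "asthma": 0.655,
    "heart_failure": 0.047,
    "breathing_pattern_disorder": 0.047,
    "pneumonia": 0.077,
    "motor_neuron_disease": 0.014,
}

#: class-conditional obstruction_index (mean, sd, lo, hi) per condition
OBSTRUCTION_PRESETS = {
    "separated": {
        "COPD": (0.72, 0.09, 0.50, 0.95),
        "healthy": (0.06, 0.04, 0.00, 0.18),
        "asthma": (0.22, 0.10, 0.02, 0.45),
        "heart_failure": (0.18, 0.08, 0.00, 0.40),
        "breathing_pattern_disorder": (0.10, 0.05, 0.00, 0.30),
        "pneumonia": (0.15, 0.07, 0.00, 0.35),
        "motor_neuron_disease": (0.12, 0.06, 0.00, 0.30),
    },
    "hard": {
        "COPD": (0.55, 0.15, 0.15, 0.95),
        "healthy": (0.12, 0.08, 0.00, 0.35),
        "asthma": (0.35, 0.15, 0.00, 0.75),
        "heart_failure": (0.30, 0.12, 0.00, 0.60),
        "breathing_pattern_disorder": (0.20, 0.10, 0.00, 0.50),
        "pneumonia": (0.25, 0.12, 0.00, 0.55),
        "motor_neuron_disease": (0.22, 0.10, 0.00, 0.50),
    },
}


@dataclass
class CohortConfig:
    """Study-condition knobs for synthetic cohorts."""

    duration: float = 75.0
    sample_rate: float = 50.0
    noise_sd: float = 0.04  # kPa additive sensor noise
    artefact_rate: float = 0.2  # expected artefact windows per recording
    preset: str = "separated"  # class-conditional obstruction separation
    fev1_noise_sd: float = 8.0  # % predicted FEV1 scatter around the link
    within_patient_scale: float = 1.0  # multiplies breath/recording jitter
    plateau_signal_only: bool = False  # class signal only via plateau_slope

    def obstruction_params(self, condition: str) -> tuple:
        return OBSTRUCTION_PRESETS[self.preset][condition]


#: breath-to-breath jitter SDs at within_patient_scale = 1
BASE_WITHIN_SD = {
    "etco2": 0.08,
    "respiratory_period": 0.06,
    "ei_ratio": 0.03,
    "obstruction_index": 0.015,
    "plateau_slope": 0.010,
}


@dataclass
class Cohort:
    """Manifest + traces + per-recording ground truth for one cohort."""

    manifest: pd.DataFrame  # one row per recording
    traces: dict  # recording_id -> CapnogramTrace
    ground_truth: dict  # recording_id -> RecordingGroundTruth
    patients: list = field(default_factory=list)  # list[SyntheticPatient]


def _truncnorm(rng, mean, sd, lo, hi):
    return float(np.clip(rng.normal(mean, sd), lo, hi))


def generate_patient(label: str, condition: str, config: CohortConfig,
                     patient_id: str, rng) -> SyntheticPatient:
    obs_mean, obs_sd, obs_lo, obs_hi = config.obstruction_params(condition)
    obstruction = _truncnorm(rng, obs_mean, obs_sd, obs_lo, obs_hi)

    if label == "COPD":
        age = _truncnorm(rng, 67, 8, 40, 90)
        bmi = _truncnorm(rng, 26, 4, 16, 45)
        sex = "F" if rng.random() < 0.49 else "M"
    else:
        age = _truncnorm(rng, 52, 14, 18, 90)
        bmi = _truncnorm(rng, 29.5, 5.5, 16, 50)
        sex = "F" if rng.random() < 0.62 else "M"

    fev1 = float(np.clip(100.0 - 70.0 * obstruction
                         + rng.normal(0.0, config.fev1_noise_sd), 15.0, 130.0))

    if config.plateau_signal_only:
        # class signal injected only through plateau-generator parameters:
        # shape (upstroke, timing) parameters are drawn label-blind
        shape_obstruction = _truncnorm(rng, 0.15, 0.05, 0.0, 0.3)
        plateau_slope = float(np.clip(0.03 + 0.45 * obstruction + rng.normal(0, 0.02), 0.0, 0.6))
        ei = _truncnorm(rng, 1.3, 0.12, 1.05, 1.8)
    else:
        shape_obstruction = obstruction
        plateau_slope = float(np.clip(0.03 + 0.45 * obstruction + rng.normal(0, 0.02), 0.0, 0.6))
        ei = float(np.clip(_truncnorm(rng, 1.3, 0.12, 1.05, 1.8) + 0.5 * obstruction, 0.8, 2.3))

    morph = BreathMorphology(
        etco2=_truncnorm(rng, 5.0, 0.45, 3.9, 6.3),
        baseline=0.0,
        respiratory_period=_truncnorm(rng, 4.0, 0.5, 3.0, 5.5),
        ei_ratio=ei,
        obstruction_index=shape_obstruction,
        plateau_slope=plateau_slope,
        noise_sd=config.noise_sd,
    )
    sd = {k: v * config.within_patient_scale for k, v in BASE_WITHIN_SD.items()}
    return SyntheticPatient(
        patient_id=patient_id, label=label, condition=condition,
        age=age, sex=sex, bmi=bmi, fev1_pct_pred=fev1,
        morphology_mean=morph, within_patient_sd=sd,
    )


def _sample_artefacts(rng, config: CohortConfig, duration: float) -> list:
    kinds = ["nose_breathing", "condensation", "incomplete_breath",
             "cough_swallow", "cardiogenic_oscillation"]
    n = rng.poisson(config.artefact_rate)
    out = []
    for _ in range(int(n)):
        kind = kinds[int(rng.integers(len(kinds)))]
        dur = float(rng.uniform(4.0, 10.0))
        onset = float(rng.uniform(0.0, max(duration - dur, 0.1)))
        out.append(ArtefactSpec(kind=kind, onset=onset, duration=min(dur, duration - onset),
                                magnitude=float(rng.uniform(0.8, 1.2))))
    return out


def generate_cohort(
    n_copd: int,
    n_non_copd: int,
    recordings_per_patient: int = 3,
    config: CohortConfig | None = None,
    rng_seed: int = 0,
) -> Cohort:
    """Generate a labelled cohort of capnogram recordings.

    Each patient receives ``recordings_per_patient`` traces; % predicted
    FEV1 decreases (noisily, monotonically) with obstruction_index; COPD
    obstruction is stochastically larger than non-COPD under every preset.
    """
    if n_copd < 0 or n_non_copd < 0 or recordings_per_patient < 0:
        raise ParameterError("counts must be non-negative")
    config = config or CohortConfig()
    root = np.random.SeedSequence(int(rng_seed) % (2**31))
    rng = np.random.default_rng(root.spawn(1)[0])

    conditions = list(NON_COPD_CONDITIONS)
    probs = np.array([NON_COPD_CONDITIONS[c] for c in conditions])
    probs = probs / probs.sum()

    patients = []
    for i in range(n_copd):
        patients.append(generate_patient("COPD", "COPD", config, f"P{i:04d}", rng))
    for i in range(n_non_copd):
        cond = conditions[int(rng.choice(len(conditions), p=probs))]
        patients.append(generate_patient("non_COPD", cond, config, f"P{n_copd + i:04d}", rng))

    rows, traces, gts = [], {}, {}
    for p_idx, pat in enumerate(patients):
        for r in range(recordings_per_patient):
            seed_r = int((rng_seed * 100003 + p_idx * 131 + r * 7 + 1) % (2**31))
            artefacts = _sample_artefacts(rng, config, config.duration)
            trace, gt = generate_capnogram(
                pat, duration=config.duration, sample_rate=config.sample_rate,
                artefacts=artefacts, rng_seed=seed_r,
            )
            rec_id = f"{pat.patient_id}_rec{r}"
            trace.recording_id = rec_id
            traces[rec_id] = trace
            gts[rec_id] = gt
            rows.append({
                "recording_id": rec_id, "patient_id": pat.patient_id,
                "label": pat.label, "condition": pat.condition,
                "age": pat.age, "sex": pat.sex, "bmi": pat.bmi,
                "fev1_pct_pred": pat.fev1_pct_pred, "order": r,
                "obstruction_index": pat.morphology_mean.obstruction_index,
            })
    manifest = pd.DataFrame(rows, columns=[
        "recording_id", "patient_id", "label", "condition", "age", "sex",
        "bmi", "fev1_pct_pred", "order", "obstruction_index",
    ])
    return Cohort(manifest=manifest, traces=traces, ground_truth=gts, patients=patients)
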