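"""Per-breath geometric features and per-capnogram aggregation.

Each valid breath yields 39 named scalars: the four transition angles
(alpha at the upstroke/plateau junction — enlarged in the "shark-fin"
waveform of airway obstruction — beta, gamma, delta at the other phase
junctions), phase curve fits (slopes, curvature, residuals, plateau
concavity), levels (baseline, plateau, end-tidal pCO2), timing (phase
durations, expiratory:inspiratory ratio, rise/fall times), areas under
the curve above the breath's own baseline, and derivative summaries.

Angles use a canonical axis scaling (1 kPa per 1 s by default): an angle
between two fitted slopes is otherwise aspect-ratio dependent. The angle
at a junction between fitted slopes ``m_in`` and ``m_out`` is::

    180 deg - |arctan(m_in / scale) - arctan(m_out / scale)|

so an ideal square breath (vertical upstroke meeting a horizontal
plateau) has alpha = 90 deg, and a sloped, concave plateau pushes alpha
well above 90 deg.

Per capnogram the per-breath scalars are aggregated as median + SD over
valid breaths (the SD of the within-breath-normalised plateau central
time is omitted), giving 77 aggregates; with 5 whole-capnogram features
(respiratory rate, maximum end-tidal CO2, short-term ETCO2 variability,
absolute pCO2 variability, valid-breath fraction) the capnogram feature
vector has exactly 82 entries. The manifest YAML shipped with the
package is the single source of truth for names, order and the waveform
region assigned to every feature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .config import FeatureConfig, PipelineConfig
from .errors import ConfigurationError
from .types import BreathBoundaries, BreathSegmentation, CapnogramTrace
from .waveform import process_trace


class FeatureIncomputable(Exception):
    """The full per-breath feature set cannot be computed for this breath."""


# --------------------------------------------------------------------------
# manifest
# --------------------------------------------------------------------------

def _load_manifest() -> dict:
    with resources.files("capnokit.data").joinpath("feature_manifest.yaml").open() as fh:
        return yaml.safe_load(fh)


_MANIFEST = _load_manifest()
PER_BREATH_FEATURES: tuple = tuple(_MANIFEST["per_breath"])
SD_OMITTED: frozenset = frozenset(_MANIFEST["sd_omitted"])
WHOLE_CAPNOGRAM_FEATURES: tuple = tuple(_MANIFEST["whole_capnogram"])

#: the 77 per-breath aggregate names, manifest order: medians then SDs
AGGREGATE_FEATURES: tuple = tuple(
    [f"{name}_median" for name in PER_BREATH_FEATURES]
    + [f"{name}_sd" for name in PER_BREATH_FEATURES if name not in SD_OMITTED]
)
#: all 82 capnogram feature names in canonical order
ALL_FEATURES: tuple = AGGREGATE_FEATURES + WHOLE_CAPNOGRAM_FEATURES


def feature_region_map() -> dict:
    """Waveform region for every one of the 82 feature-vector entries."""
    base = {**_MANIFEST["per_breath"], **_MANIFEST["whole_capnogram"]}
    out = {}
    for name in ALL_FEATURES:
        stem = name
        for suffix in ("_median", "_sd"):
            if stem.endswith(suffix) and stem[: -len(suffix)] in base:
                stem = stem[: -len(suffix)]
                break
        if stem not in base:
            raise ConfigurationError(f"feature {name} missing from region map")
        out[name] = base[stem]
    return out


# --------------------------------------------------------------------------
# phase fits and angles
# --------------------------------------------------------------------------

def fit_phase(trace: CapnogramTrace, interval: tuple, model: str = "line") -> tuple:
    """Least-squares fit over a half-open sample interval, in (s, kPa).

    Returns ``(slope, rmse)`` for ``model='line'`` and
    ``(slope_at_midpoint, quad_coeff, rmse)`` for ``model='quadratic'``.
    """
    i0, i1 = int(interval[0]), int(interval[1])
    if i1 - i0 < 3:
        raise FeatureIncomputable(f"phase [{i0},{i1}) has fewer than 3 samples")
    t = np.arange(i0, i1) / trace.sample_rate
    y = trace.samples[i0:i1]
    # trapezoid-rule endpoint weights make the discrete fit a quadrature-
    # consistent estimate of the continuous least-squares line/parabola
    w = np.ones(t.size)
    w[0] = w[-1] = math.sqrt(0.5)
    if model == "line":
        coef = np.polyfit(t, y, 1, w=w)
        rmse = float(np.sqrt(np.mean((np.polyval(coef, t) - y) ** 2)))
        return float(coef[0]), rmse
    if model == "quadratic":
        coef = np.polyfit(t, y, 2, w=w)
        rmse = float(np.sqrt(np.mean((np.polyval(coef, t) - y) ** 2)))
        t_mid = 0.5 * (t[0] + t[-1])
        slope_mid = float(2 * coef[0] * t_mid + coef[1])
        return slope_mid, float(coef[0]), rmse
    raise ValueError(f"unknown model {model!r}")


def _junction_angle(m_in: float, m_out: float, axis_scale: float) -> float:
    a = math.atan(m_in / axis_scale) - math.atan(m_out / axis_scale)
    return 180.0 - math.degrees(abs(a))


def compute_angles(trace: CapnogramTrace, phases: BreathBoundaries,
                   axis_scale: float = 1.0) -> tuple:
    """(alpha, beta, gamma, delta) in degrees from fitted phase slopes.

    Baseline phases shorter than 3 samples contribute slope 0 (a flat
    baseline); upstroke/plateau/downstroke fits shorter than 3 samples
    raise :class:`FeatureIncomputable`.
    """
    b = phases

    def line_slope(i0, i1, required, inclusive=True):
        if inclusive:
            i1 = min(i1 + 1, b.end)
        if i1 - i0 < 3:
            if required:
                raise FeatureIncomputable("degenerate phase for angle fit")
            return 0.0
        return fit_phase(trace, (i0, i1), "line")[0]

    # baseline-phase fits are trimmed away from the corners, where an
    # edge-preserving smoother leaves a few samples of under/overshoot
    g1 = min(5, max(0, (b.p1_end - b.start) // 3))
    g4 = min(5, max(0, (b.end - b.p4a_end) // 3))
    m1 = line_slope(b.start, b.p1_end - g1, required=False, inclusive=False)
    m2 = line_slope(b.p1_end, b.p2_end, required=True)
    m3 = line_slope(b.p2_end, b.p3_end, required=True)
    m4 = line_slope(b.p3_end, b.p4a_end, required=True)
    m4b = line_slope(b.p4a_end + g4, b.end, required=False, inclusive=False)
    alpha = _junction_angle(m2, m3, axis_scale)
    beta = _junction_angle(m3, m4, axis_scale)
    gamma = _junction_angle(m4, m4b, axis_scale)
    delta = _junction_angle(m1, m2, axis_scale)
    return alpha, beta, gamma, delta


# --------------------------------------------------------------------------
# per-breath feature set
# --------------------------------------------------------------------------

def _crossing_time(t: np.ndarray, y: np.ndarray, level: float, rising: bool) -> float | None:
    """First time ``y`` crosses ``level`` (linear interpolation)."""
    above = y >= level
    idx = np.nonzero(above if rising else ~above)[0]
    if idx.size == 0 or idx[0] == 0:
        return t[0] if idx.size else None
    i = idx[0]
    y0, y1 = y[i - 1], y[i]
    if y1 == y0:
        return float(t[i])
    frac = (level - y0) / (y1 - y0)
    return float(t[i - 1] + frac * (t[i] - t[i - 1]))


def compute_breath_features(trace: CapnogramTrace, phases: BreathBoundaries,
                            config=None) -> dict:
    """All 39 per-breath scalars, or raise :class:`FeatureIncomputable`."""
    cfg = (config.features if isinstance(config, PipelineConfig) else config) \
        or PipelineConfig().features
    b = phases
    b.validate()
    fs = trace.sample_rate
    dt = 1.0 / fs
    x = trace.samples
    seg = x[b.start:b.end]
    t_seg = np.arange(b.start, b.end) * dt

    for lo, hi in ((b.p1_end, b.p2_end), (b.p2_end, b.p3_end), (b.p3_end, b.p4a_end)):
        if hi - lo < cfg.min_phase_samples:
            raise FeatureIncomputable("phase shorter than min_phase_samples")

    p1 = x[b.start:b.p1_end]
    p3 = x[b.p2_end:b.p3_end]
    p4b = x[b.p4a_end:b.end]
    base_samples = np.concatenate([p1, p4b]) if p4b.size else p1
    baseline = float(np.median(base_samples))

    # phase fits include the right boundary sample: the continuous phase
    # segment is closed at its junction point
    m2, rmse2 = fit_phase(trace, (b.p1_end, b.p2_end + 1), "line")
    m3_mid, quad3, rmse3 = fit_phase(trace, (b.p2_end, b.p3_end + 1), "quadratic")
    m4, rmse4 = fit_phase(trace, (b.p3_end, min(b.p4a_end + 1, b.end)), "line")
    try:
        _, quad2, _ = fit_phase(trace, (b.p1_end, b.p2_end + 1), "quadratic")
    except FeatureIncomputable:
        quad2 = 0.0

    alpha, beta, gamma, delta = compute_angles(trace, b, cfg.axis_scale)

    # plateau concavity: deviation of the Phase-3 midpoint below its chord
    p3c = x[b.p2_end: b.p3_end + 1]
    t3 = np.arange(b.p2_end, b.p3_end + 1) * dt
    t3_mid = 0.5 * (t3[0] + t3[-1])
    chord_mid = 0.5 * (p3c[0] + p3c[-1])
    sig_mid = float(np.interp(t3_mid, t3, p3c))
    concavity = chord_mid - sig_mid

    etco2 = float(x[min(b.p3_end, b.end - 1)])
    plateau_mean = float(np.mean(p3))
    pco2_range = float(np.max(seg) - np.min(seg))

    breath_dur = (b.end - b.start) * dt
    exp_dur = (b.p3_end - b.p1_end) * dt
    insp_dur = breath_dur - exp_dur
    t2_dur = (b.p2_end - b.p1_end) * dt
    t3_dur = (b.p3_end - b.p2_end) * dt
    t4a_dur = (b.p4a_end - b.p3_end) * dt

    height = float(np.max(seg)) - baseline
    if height <= 0:
        raise FeatureIncomputable("non-positive excursion height")
    i_peak = int(np.argmax(seg))
    up = seg[: i_peak + 1]
    t_up = t_seg[: i_peak + 1]
    t25 = _crossing_time(t_up, up, baseline + 0.25 * height, rising=True)
    t75 = _crossing_time(t_up, up, baseline + 0.75 * height, rising=True)
    rise_25_75 = (t75 - t25) if (t25 is not None and t75 is not None) else float("nan")
    down = seg[i_peak:]
    t_down = t_seg[i_peak:]
    f75 = _crossing_time(t_down, down, baseline + 0.75 * height, rising=False)
    f25 = _crossing_time(t_down, down, baseline + 0.25 * height, rising=False)
    fall_75_25 = (f25 - f75) if (f25 is not None and f75 is not None) else float("nan")

    rel = seg - baseline
    auc_total = float(np.trapezoid(rel, dx=dt))
    auc_p2 = float(np.trapezoid(x[b.p1_end: b.p2_end + 1] - baseline, dx=dt))
    auc_p3 = float(np.trapezoid(x[b.p2_end: b.p3_end + 1] - baseline, dx=dt))

    deriv = np.gradient(seg) * fs

    feats = {
        "alpha_deg": alpha,
        "beta_deg": beta,
        "gamma_deg": gamma,
        "delta_deg": delta,
        "phase2_slope": m2,
        "phase3_slope": m3_mid,
        "phase4a_slope": m4,
        "phase2_fit_rmse": rmse2,
        "phase3_fit_rmse": rmse3,
        "phase4a_fit_rmse": rmse4,
        "phase3_quad_coeff": quad3,
        "phase3_concavity": concavity,
        "baseline_pco2": baseline,
        "plateau_mean": plateau_mean,
        "etco2": etco2,
        "pco2_range": pco2_range,
        "plateau_central_time_frac": ((0.5 * (b.p2_end + b.p3_end)) - b.start) / (b.end - b.start),
        "breath_duration": breath_dur,
        "exp_duration": exp_dur,
        "insp_duration": insp_dur,
        "phase2_duration": t2_dur,
        "phase3_duration": t3_dur,
        "phase4a_duration": t4a_dur,
        "ei_ratio": exp_dur / insp_dur,
        "rise_time_25_75": rise_25_75,
        "fall_time_75_25": fall_75_25,
        "time_to_peak_frac": i_peak / (b.end - b.start),
        "phase2_frac_of_exp": t2_dur / exp_dur,
        "phase3_frac_of_exp": t3_dur / exp_dur,
        "auc_total": auc_total,
        "auc_phase2": auc_p2,
        "auc_phase3": auc_p3,
        "auc_per_second": auc_total / breath_dur,
        "max_upslope": float(np.max(deriv)),
        "min_downslope": float(np.min(deriv)),
        "phase2_curvature": quad2,
        "alpha_beta_ratio": alpha / beta,
        "plateau_slope_over_height": m3_mid / (etco2 - baseline) if etco2 > baseline else float("nan"),
        "within_breath_pco2_sd": float(np.std(seg)),
    }
    assert tuple(feats) == PER_BREATH_FEATURES or set(feats) == set(PER_BREATH_FEATURES)
    if not all(np.isfinite(v) for v in feats.values()):
        raise FeatureIncomputable("non-finite feature value")
    return feats


# --------------------------------------------------------------------------
# per-capnogram aggregation
# --------------------------------------------------------------------------

@dataclass
class CapnogramFeatureVector:
    """The 82-element capnogram feature vector plus validity metadata."""

    values: dict = field(default_factory=dict)
    n_valid_breaths: int = 0
    valid: bool = False

    def to_series(self) -> pd.Series:
        s = pd.Series({k: self.values.get(k, np.nan) for k in ALL_FEATURES}, dtype=float)
        s["n_valid_breaths"] = self.n_valid_breaths
        s["valid"] = bool(self.valid)
        return s


def aggregate_capnogram(breath_features: list, segmentation: BreathSegmentation,
                        trace: CapnogramTrace, config=None) -> CapnogramFeatureVector:
    """Aggregate per-breath features + whole-capnogram features.

    Median and SD (over valid breaths; SD with ``n-1`` divisor, 0 for a
    single breath) for the per-breath set; the capnogram is marked
    invalid — not an error — when fewer than ``min_breaths`` valid
    breaths remain.
    """
    cfg = (config.features if isinstance(config, PipelineConfig) else config) \
        or PipelineConfig().features
    n_valid = len(breath_features)
    n_detected = segmentation.n_breaths
    out: dict = {}
    if n_valid:
        mat = {k: np.array([bf[k] for bf in breath_features]) for k in PER_BREATH_FEATURES}
        for k in PER_BREATH_FEATURES:
            out[f"{k}_median"] = float(np.median(mat[k]))
        for k in PER_BREATH_FEATURES:
            if k in SD_OMITTED:
                continue
            out[f"{k}_sd"] = float(np.std(mat[k], ddof=1)) if n_valid > 1 else 0.0

        out["respiratory_rate"] = n_valid / trace.duration * 60.0
        etco2s = mat["etco2"]
        out["max_etco2"] = float(np.max(etco2s))
        out["etco2_short_term_variability"] = (
            float(np.mean(np.abs(np.diff(etco2s)))) if n_valid > 1 else 0.0
        )
        valid_samples = np.concatenate([
            trace.samples[b.start:b.end]
            for b, bf in zip(segmentation.valid_breaths, breath_features)
        ])
        out["pco2_absolute_variability"] = float(np.std(valid_samples))
        out["valid_breath_fraction"] = n_valid / n_detected if n_detected else 0.0

    return CapnogramFeatureVector(
        values=out, n_valid_breaths=n_valid, valid=n_valid >= cfg.min_breaths,
    )


# --------------------------------------------------------------------------
# recording- and cohort-level drivers
# --------------------------------------------------------------------------

def extract_features(trace: CapnogramTrace, config: PipelineConfig | None = None):
    """Full single-recording pipeline: process + featurize + aggregate.

    Breaths whose full feature set cannot be computed are excluded with
    reason ``feature_incomputable``. Returns
    ``(CapnogramFeatureVector, BreathSegmentation, QCReport)``.
    """
    cfg = config or PipelineConfig()
    clean, seg, report = process_trace(trace, cfg)
    feats = []
    for rec in seg.breaths:
        if rec.qc_status != "valid":
            continue
        try:
            feats.append(compute_breath_features(clean, rec.boundaries, cfg))
        except FeatureIncomputable:
            rec.qc_status = "excluded"
            rec.exclusion_reason = "feature_incomputable"
            report.exclusion_counts["feature_incomputable"] = \
                report.exclusion_counts.get("feature_incomputable", 0) + 1
            report.n_valid -= 1
    vec = aggregate_capnogram(feats, seg, clean, cfg)
    return vec, seg, report


def featurize_cohort(cohort, config: PipelineConfig | None = None) -> pd.DataFrame:
    """Feature table: one row per recording, manifest column order."""
    rows = []
    for rec_id, trace in cohort.traces.items():
        vec, _, _ = extract_features(trace, config)
        s = vec.to_series()
        s["recording_id"] = rec_id
        s["patient_id"] = trace.patient_id
        rows.append(s)
    table = pd.DataFrame(rows).reset_index(drop=True)
    meta = ["recording_id", "patient_id", "n_valid_breaths", "valid"]
    return table[meta + list(ALL_FEATURES)]
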