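"""Denoising, breath separation, phase segmentation and breath QC.

The processing chain mirrors how cloud capnography platforms treat a
complete recording:

1. :func:`denoise` — Savitzky-Golay polynomial smoothing (edge-preserving
   on the fast upstroke/downstroke transitions), reporting the input/output
   correlation as a diagnostic;
2. :func:`detect_breaths` — hysteresis double-threshold on the signal
   relative to a running baseline, robust to plateau ripple; breath
   boundaries fall at the midpoints of inter-excursion baseline gaps;
3. :func:`segment_phases` — phase boundaries where the derivative crosses
   a configured fraction (default 10%) of the breath's peak up/down slope;
4. :func:`qc_breath` — deterministic one-reason-per-breath artefact rules
   with fixed precedence: incomplete > condensation > nose_breathing >
   cough_swallow > cardiogenic_oscillation.

Indices are 0-based, intervals half-open, everywhere.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import median_filter, percentile_filter, uniform_filter1d
from scipy.signal import savgol_filter

from .config import DetectConfig, PipelineConfig, QCConfig, SegmentConfig
from .errors import DegenerateInputError
from .types import (
    BreathBoundaries,
    BreathRecord,
    BreathSegmentation,
    CapnogramTrace,
    QCReport,
)


def _odd(n: int) -> int:
    n = max(int(n), 3)
    return n if n % 2 == 1 else n + 1


# --------------------------------------------------------------------------
# denoising
# --------------------------------------------------------------------------

def denoise(trace: CapnogramTrace, config=None) -> tuple:
    """Smooth a raw trace; returns (denoised trace, in/out correlation).

    The correlation between raw and denoised series is the standard
    diagnostic for how much structure denoising removed; it is reported
    as 1.0 by convention when either series is constant.
    """
    cfg = (config.denoise if isinstance(config, PipelineConfig) else config) \
        or PipelineConfig().denoise
    window = _odd(round(cfg.window_s * trace.sample_rate))
    if trace.n_samples <= window:
        raise DegenerateInputError(
            f"trace ({trace.n_samples} samples) shorter than filter window ({window})"
        )
    order = min(cfg.polyorder, window - 1)
    smoothed = savgol_filter(trace.samples, window_length=window, polyorder=order)
    if np.ptp(trace.samples) == 0 or np.ptp(smoothed) == 0:
        corr = 1.0
    else:
        corr = float(np.corrcoef(trace.samples, smoothed)[0, 1])
    return trace.copy_with(samples=smoothed), corr


# --------------------------------------------------------------------------
# breath separation
# --------------------------------------------------------------------------

def running_baseline(x: np.ndarray, sample_rate: float, cfg: DetectConfig) -> np.ndarray:
    """Slowly varying baseline: smoothed rolling low percentile.

    A rolling 10th percentile over a window spanning at least one
    respiratory cycle tracks slow drift while staying insensitive both to
    the expiratory excursions and to the few-sample undershoot a
    polynomial smoother leaves at sharp corners (which a rolling minimum
    would latch onto).
    """
    w = _odd(round(cfg.baseline_window_s * sample_rate))
    base = percentile_filter(x, percentile=10, size=w, mode="nearest")
    # hold the estimate flat where the window runs off either edge: there the
    # percentile is dominated by padding and can chase an unfinished excursion
    half = w // 2
    if x.size > 2 * half:
        base[:half] = base[half]
        base[x.size - half:] = base[x.size - half - 1]
    return uniform_filter1d(base, size=_odd(round(cfg.baseline_smooth_s * sample_rate)),
                            mode="nearest")


def detect_breaths(trace: CapnogramTrace, config=None) -> list:
    """Separate a denoised trace into breath intervals.

    Returns a list of :class:`BreathRecord` (boundaries not yet set) whose
    intervals tile ``[0, n)``; each contains exactly one expiratory
    excursion. A trailing excursion still above the offset threshold at
    the end of the trace is flagged ``incomplete``. No excursions -> ``[]``.
    """
    cfg = (config.detect if isinstance(config, PipelineConfig) else config) \
        or PipelineConfig().detect
    x = trace.samples
    fs = trace.sample_rate
    n = x.size
    r = x - running_baseline(x, fs, cfg)

    # hysteresis state machine
    excursions = []
    in_exc = False
    on_idx = 0
    for i in range(n):
        if not in_exc and r[i] >= cfg.onset_kpa:
            in_exc, on_idx = True, i
        elif in_exc and r[i] < cfg.offset_kpa:
            excursions.append([on_idx, i, False])
            in_exc = False
    if in_exc:
        excursions.append([on_idx, n, True])  # open at end of trace

    # drop too-short excursions (e.g. isolated cough spikes over baseline)
    min_len = 0.4 * fs
    excursions = [e for e in excursions if (e[1] - e[0]) >= min_len or e[2]]
    if not excursions:
        return []

    # refine each excursion's edges down to near-baseline level
    eps = cfg.refine_eps_kpa
    for e in excursions:
        i = e[0]
        while i > 0 and r[i - 1] > eps:
            i -= 1
        e[0] = i
        j = e[1]
        while j < n and r[j - 1] > eps:
            j += 1
        e[1] = min(j, n)

    # breath boundaries at midpoints of the inter-excursion baseline gaps
    records = []
    for k, e in enumerate(excursions):
        start = 0 if k == 0 else (excursions[k - 1][1] + e[0]) // 2
        end = n if k == len(excursions) - 1 else (e[1] + excursions[k + 1][0]) // 2
        records.append(BreathRecord(start=start, end=end, incomplete=bool(e[2])))
    return records


# --------------------------------------------------------------------------
# phase segmentation
# --------------------------------------------------------------------------

def segment_phases(trace: CapnogramTrace, breath: tuple, config=None):
    """Phase boundaries of one breath, or ``None`` on segmentation failure.

    The Phase-1/2 and Phase-2/3 boundaries bracket the region where the
    derivative exceeds ``slope_frac`` of the breath's peak upslope; the
    Phase-3/4a and Phase-4a/4b boundaries do the same on the downslope.
    """
    cfg = (config.segment if isinstance(config, PipelineConfig) else config) \
        or PipelineConfig().segment
    start, end = int(breath[0]), int(breath[1])
    seg = trace.samples[start:end]
    if seg.size < 5 * cfg.min_phase_samples:
        return None
    deriv = np.gradient(seg) * trace.sample_rate

    imax = int(np.argmax(deriv))
    vmax = deriv[imax]
    if vmax < 1.0:  # kPa/s: no credible expiratory upstroke
        return None
    imin = imax + int(np.argmin(deriv[imax:]))
    vmin = deriv[imin]
    if vmin > -1.0:
        return None

    thr_up = cfg.slope_frac * vmax
    i = imax
    while i > 0 and deriv[i - 1] >= thr_up:
        i -= 1
    p1_end = i
    i = imax
    while i < imin and deriv[i] >= thr_up:
        i += 1
    p2_end = i

    thr_dn = cfg.slope_frac * vmin  # negative
    i = imin
    while i > p2_end and deriv[i - 1] <= thr_dn:
        i -= 1
    p3_end = i
    i = imin
    while i < seg.size - 1 and deriv[i] <= thr_dn:
        i += 1
    p4a_end = min(i, seg.size)

    b = BreathBoundaries(start, start + p1_end, start + p2_end,
                         start + p3_end, start + p4a_end, end)
    s, a, bb, c, d, e = b.as_tuple()
    if not (s < a <= bb <= c <= d <= e):
        return None
    if min(a - s, bb - a, c - bb) < cfg.min_phase_samples:
        return None
    return b


# --------------------------------------------------------------------------
# breath QC
# --------------------------------------------------------------------------

def _local_baseline(seg: np.ndarray, b: BreathBoundaries) -> float:
    base = np.concatenate([seg[: b.p1_end - b.start], seg[b.p4a_end - b.start:]])
    return float(np.median(base)) if base.size else float(np.min(seg))

def _fall_time_75_25(seg: np.ndarray, b: BreathBoundaries, fs: float) -> float:
    base = _local_baseline(seg, b)
    height = float(np.max(seg)) - base
    if height <= 0:
        return 0.0
    i0 = int(np.argmax(seg))
    below75 = np.nonzero(seg[i0:] < base + 0.75 * height)[0]
    if below75.size == 0:
        return 0.0
    i75 = i0 + below75[0]
    below25 = np.nonzero(seg[i75:] < base + 0.25 * height)[0]
    if below25.size == 0:
        return float(seg.size - i75) / fs
    return float(below25[0]) / fs


def qc_breath(trace: CapnogramTrace, breath: BreathRecord, config=None,
              raw_trace: CapnogramTrace | None = None) -> tuple:
    """Classify one segmented breath: ('valid', None) or ('excluded', reason).

    Deterministic rules, one primary reason by fixed precedence:
    incomplete_breath > feature_incomputable > condensation >
    nose_breathing > cough_swallow > cardiogenic_oscillation.
    The transient-spike (cough/swallow) check runs on the raw trace when
    available, since denoising suppresses exactly the discontinuity it
    looks for; baseline-level comparisons use low percentiles so an
    overlapping spike cannot masquerade as drift.
    """
    cfg = (config.qc if isinstance(config, PipelineConfig) else config) \
        or PipelineConfig().qc
    fs = trace.sample_rate
    seg = trace.samples[breath.start:breath.end]

    if breath.incomplete:
        return "excluded", "incomplete_breath"

    def spike_hit() -> bool:
        src = raw_trace.samples[breath.start:breath.end] if raw_trace is not None else seg
        k = _odd(round(cfg.spike_window_s * fs))
        resid = src - median_filter(src, size=k, mode="nearest")
        return float(np.max(np.abs(resid))) > cfg.spike_residual_kpa

    b = breath.boundaries
    if b is None:
        # a transient spike can itself wreck segmentation; attribute the
        # failure to the spike when one is present
        if spike_hit():
            return "excluded", "cough_swallow"
        return "excluded", "feature_incomputable"

    # baseline levels from low percentiles of corner-trimmed windows:
    # robust both to smoother under/overshoot at the phase corners and to
    # an overlapping transient spike
    p1 = seg[: b.p1_end - b.start]
    p4b = seg[b.p4a_end - b.start:]
    if p1.size > 4:
        p1 = p1[:-3]
    if p4b.size > 4:
        p4b = p4b[3:]
    if p1.size and p4b.size:
        mismatch = abs(float(np.percentile(p4b, 10)) - float(np.percentile(p1, 10)))
        if mismatch > cfg.baseline_mismatch_kpa:
            return "excluded", "condensation"
    k = _odd(round(cfg.spike_window_s * fs))
    despiked = median_filter(seg, size=k, mode="nearest")
    if _fall_time_75_25(despiked, b, fs) > cfg.max_fall_time_s:
        return "excluded", "condensation"

    amplitude = float(np.max(seg)) - _local_baseline(seg, b)
    if amplitude < cfg.min_amplitude_kpa:
        return "excluded", "nose_breathing"

    if spike_hit():
        return "excluded", "cough_swallow"

    p3 = seg[b.p2_end - b.start: b.p3_end - b.start]
    if p3.size >= 8:
        t = np.arange(p3.size) / fs
        r3 = p3 - np.polyval(np.polyfit(t, p3, 2), t)
        sd = float(np.std(r3))
        if sd > cfg.cardio_sd_kpa:
            crossings = int(np.sum(np.diff(np.signbit(r3 - np.mean(r3)))))
            freq = crossings / (2.0 * p3.size / fs)
            lo, hi = cfg.cardio_band_hz
            if crossings >= cfg.cardio_min_crossings and lo <= freq <= hi:
                return "excluded", "cardiogenic_oscillation"
    return "valid", None


def breath_snr(trace: CapnogramTrace, breath: BreathRecord) -> float:
    """Excursion amplitude over baseline-residual noise (dimensionless)."""
    seg = trace.samples[breath.start:breath.end]
    b = breath.boundaries
    if b is None:
        return float("nan")
    base = np.concatenate([seg[: b.p1_end - b.start], seg[b.p4a_end - b.start:]])
    noise = float(np.std(base)) if base.size > 2 else 0.0
    amplitude = float(np.max(seg)) - _local_baseline(seg, b)
    return amplitude / max(noise, 1e-6)


# --------------------------------------------------------------------------
# whole-recording pipeline
# --------------------------------------------------------------------------

def process_trace(trace: CapnogramTrace, config: PipelineConfig | None = None) -> tuple:
    """Denoise + detect + segment + QC one recording.

    Returns ``(denoised_trace, BreathSegmentation, QCReport)``.
    """
    cfg = config or PipelineConfig()
    clean, corr = denoise(trace, cfg)
    records = detect_breaths(clean, cfg)
    counts: dict = {}
    snrs = []
    for rec in records:
        rec.boundaries = segment_phases(clean, (rec.start, rec.end), cfg)
        status, reason = qc_breath(clean, rec, cfg, raw_trace=trace)
        rec.qc_status, rec.exclusion_reason = status, reason
        if status == "excluded":
            counts[reason] = counts.get(reason, 0) + 1
        snrs.append(breath_snr(clean, rec))
    seg = BreathSegmentation(breaths=records)
    seg.validate()
    report = QCReport(
        n_breaths_detected=len(records),
        n_valid=sum(1 for r in records if r.qc_status == "valid"),
        exclusion_counts=counts,
        snr_per_breath=snrs,
        denoise_correlation=corr,
    )
    report.validate()
    return clean, seg, report
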