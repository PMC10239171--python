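# Methods and design notes

## The breath model

One respiratory cycle of period `T` (s) is built from five analytic
pieces. With baseline `B`, end-tidal pressure `E` (kPa), expiratory
fraction `T_e/T = ei/(1+ei)` for expiratory:inspiratory ratio `ei`, and
obstruction index `q ∈ [0,1]`:

* **Phase 1** (inspiratory baseline): constant `B`, duration
  `t1 = (T_i − t4a)/2`;
* **Phase 2** (upstroke): duration `t2 = T_e (0.10 + 0.35 q)`; a
  saturating exponential from `B` to the plateau onset `c0`, normalised
  to reach `c0` exactly at `t2`, with time constant `τ2 = t2 / ln 10`;
* **Phase 3** (plateau): duration `t3 = T_e − t2`; quadratic
  `c0 + s u + c u²` with linear slope `s` (the `plateau_slope`
  morphology field) and curvature `c = 0.12 q` kPa/s², anchored so the
  phase ends exactly at `E`;
* **Phase 4a** (downstroke): duration `0.4 T_i`; truncated exponential
  decay back to `B` with `τ4 = t4a / ln 10`;
* **Phase 4b**: constant `B`, mirror of Phase 1.

Two consequences drive testability. First, every geometric feature has
a closed or densely computable form (`analytic_breath_features`), fully
independent of the discrete pipeline, so feature extraction can be
checked against an oracle. Second, the `1/ln 10` time constants mean
the phase derivative decays to exactly 10% of its peak at each
constructed boundary — the same criterion the segmenter uses — so phase
boundaries are genuinely recoverable from the waveform rather than
being hidden latent variables. This is the generator's shape
convention, chosen at design time; the segmentation fraction is still a
free config parameter.

The obstruction index raises the α angle three ways that mirror
obstructive physiology: a longer, shallower upstroke, a steeper
plateau, and more plateau curvature. An ideal square breath (`q = 0`,
zero plateau slope) has α = δ = 90° in the arctan construction; at
50 Hz the finite sampled upstroke slope keeps the realised α a few
degrees above that limit.

## Synthetic cohorts

Cohort defaults mirror the modelled study population: 80 COPD / 215
non-COPD patients, the non-COPD mix dominated by asthma with healthy,
heart-failure, breathing-pattern-disorder, pneumonia and
motor-neuron-disease minorities, three recordings per patient, 75 s at
50 Hz. Per-patient % predicted FEV1 is `100 − 70·q` plus Gaussian noise
(SD 8, clipped to [15, 130]) — a monotone noisy link chosen so that
feature-vs-spirometry correlations land in the strong (|ρ| ≈ 0.7–0.9)
regime. Class-conditional obstruction distributions come in two
presets: `separated` (default; COPD ~ N(0.72, 0.09) clipped to
[0.50, 0.95], all non-COPD conditions below ~0.45) and `hard`
(overlapping). COPD obstruction is stochastically larger under both.
The `plateau_signal_only` switch draws upstroke/timing shape parameters
label-blind and routes the class signal exclusively through the plateau
slope, which is how importance localization is tested.

Breath-to-breath jitter SDs (ETCO2 0.08 kPa, period 0.06 s, E:I ratio
0.03, obstruction 0.015, plateau slope 0.01, scaled by
`within_patient_scale`) are small enough that a noise-free cohort still
satisfies the 3-sample boundary-recovery contract, and large enough
that SD-aggregate features are non-degenerate.

Artefact renderings (the five QC classes): nose breathing attenuates
whole overlapped breaths to 30% amplitude and adds a noise floor;
condensation adds a slow sin² baseline bump (0.5 kPa peak) and a causal
exponential smear (τ ≈ 0.4 s) of fast transitions; cough/swallow adds
1.4 kPa Gaussian spikes of ~0.1 s; cardiogenic oscillation adds a
1.4 Hz, 0.12 kPa ripple to Phase-3 samples; incomplete-breath rescales
the breath train (≤ 15%) so the recording ends mid-plateau. Severities
were fixed once, at design time, to be unambiguous instances of their
class; real prevalences are unknown, so the per-recording artefact rate
(default 0.2) is an arbitrary, documented knob. A breath is
ground-truth-labelled by an artefact window when ≥ 30% of its duration
overlaps it (spikes: when it contains a spike centre) — a breath
grazing a window is not meaningfully corrupted.

## Waveform processing

* **Denoising**: Savitzky–Golay, 0.3 s window, order 3 — polynomial
  smoothing preserves the fast upstroke/downstroke transitions far
  better than moving averages. The raw/denoised correlation is reported
  per recording (1.0 by convention for constant input).
* **Breath detection**: the running baseline is a smoothed rolling 10th
  percentile over a 4 s window (a rolling minimum would latch onto the
  few-sample undershoot the smoother leaves at sharp corners, and the
  estimate is held flat where the window runs off the trace edges).
  Hysteresis thresholds on the baseline-subtracted signal (onset
  +0.5 kPa, offset +0.25 kPa) find expiratory excursions; excursions
  shorter than 0.4 s (isolated spikes) are discarded; excursion edges
  are refined to the +0.05 kPa level, and breath boundaries are placed
  at the midpoints of inter-excursion baseline gaps. The first breath
  starts at sample 0; the last ends at the trace end, so a completed
  final cycle owns the trailing baseline — its `end` index is a
  convention rather than a measured boundary. A trailing excursion
  still above the offset threshold at the trace end is pre-flagged
  incomplete.
* **Phase segmentation**: boundaries bracket the region where the
  derivative exceeds 10% of the breath's peak upslope (downslope for
  Phases 3→4a→4b). On noise-free cohorts ≥ 99% of boundaries land
  within 3 samples of ground truth; the residual tail (≤ 4 samples,
  ~0.3% of boundaries) comes from smoothing blur on the steepest
  near-square upstrokes.
* **Breath QC**: deterministic rules with one primary reason per breath,
  fixed precedence (incomplete > condensation > nose breathing >
  cough/swallow > cardiogenic oscillation; an unsegmentable breath is
  `feature_incomputable` unless a spike explains the failure).
  Condensation: Phase-1 vs Phase-4b baseline mismatch > 0.15 kPa
  (corner-trimmed 10th percentiles, robust to smoother overshoot and
  spikes) or a despiked 75→25% fall time > 0.55 s. Nose breathing:
  excursion amplitude < 2 kPa. Cough/swallow: median-filter residual
  (0.22 s window) > 0.35 kPa, computed on the *raw* trace — denoising
  suppresses exactly the discontinuity this rule detects (clean raw
  traces stay below ~0.22 kPa). Cardiogenic: quadratic-detrended
  Phase-3 residual SD > 0.045 kPa with ≥ 4 zero crossings at an
  estimated frequency inside 0.8–2.5 Hz. All thresholds live in the
  YAML-serialisable config; they are defensible defaults for these
  synthetic signatures, not claims about any device.

## Features

39 per-breath scalars (see `data/feature_manifest.yaml` for the full
list and waveform-region map). Conventions that needed fixing:

* angles use a canonical 1 kPa ≡ 1 s axis scale (angles between fitted
  slopes are otherwise aspect-dependent); β, γ, δ reuse the two-slope
  construction at the plateau→downstroke, downstroke→baseline and
  baseline→upstroke junctions;
* phase fits include the right boundary sample (the continuous phase is
  closed at its junction) and use trapezoid-rule endpoint weights, making
  the discrete fit a quadrature-consistent estimate of the continuous
  least-squares line/parabola — without this the steepest upstroke
  slope is biased ~2% at 50 Hz. Baseline-phase slope fits are trimmed
  a few samples away from corners (smoother under/overshoot);
* ETCO2 is the sample at the Phase-3/4a boundary; AUCs are trapezoidal,
  measured above the breath's own baseline (median of Phases 1 and 4b),
  making them insensitive to baseline drift;
* the inspiratory-baseline split into Phase 1 vs Phase 4b is a
  cycle-cutting convention, so there is no separate `phase1_duration`
  feature (`insp_duration` carries the information); this keeps the
  per-breath set at 39;
* aggregation: median + SD (sample SD, n−1; 0 for a single breath) over
  valid breaths for all 39, except that the SD of the per-breath
  normalised plateau central time is omitted — 77 aggregates, plus 5
  whole-capnogram features = 82. A capnogram with fewer than 5 valid
  breaths (config `min_breaths`) is marked invalid, not an error.
  Respiratory rate is the valid-breath count scaled to breaths/min over
  the recording duration, and the valid-breath fraction counts
  detections in its denominator — these two, plus the pooled-sample
  variability, are the only entries that can respond to an excluded
  breath; all median/SD aggregates ignore excluded breaths entirely.

Whether "absolute and short-term variability" are per-breath or
whole-recording quantities is genuinely ambiguous; both exist here
(`within_breath_pco2_sd` per breath; `pco2_absolute_variability` and
`etco2_short_term_variability` — mean |successive ETCO2 difference| —
per capnogram), with the whole-recording pair counted among the 5.

## Modelling protocol

Balancing keeps the earliest 1 recording per non-COPD patient and 3 per
COPD patient (fewer if fewer exist; invalid capnograms are dropped
before selection). Standardisation (zero mean, unit *population* SD;
zero-variance columns pass through centred) is fitted on training rows
only — a global fit would leak test information and inflate metrics.
The 20% hold-out is taken at patient level per class; each CV iteration
shuffles the remaining patients per class and deals them round-robin
into 5 folds with a fold pointer continuing across classes, so class
proportions *and* total fold sizes are as even as possible (a
289-patient pool yields the 231/58 train/test patient split). An audit
function recounts overlap violations from scratch; sklearn's
`StratifiedGroupKFold` serves as an independent balance cross-check in
tests, never as the implementation.

Hyperparameters (unknowable from outside): logistic regression with L2
penalty, C = 1; gradient boosted trees with 100 trees, depth 3,
learning rate 0.1; linear SVM with C = 1 and sigmoid (Platt-style)
calibration on 3 internal training-fold splits. "Micro-averaged AUROC"
for a binary task is taken as the standard single-curve AUROC.
Confusion metrics use a 0.5 probability boundary. Build time is
recorded but hardware-dependent, so nothing asserts on it.

Weighted importance: per feature, the mean over rows of |normalised
value × |LR coefficient||; per region, the mean over that region's
features. Single-feature regions (Phase 1's baseline level, Phase 4b's
γ angle) make the map noisy on small cohorts — with 82 features the
coefficient noise on signal-free features only falls below the signal
reliably from a few hundred balanced rows, which is why importance
tests use ~240-patient cohorts.

The misclassification audit defines a patient as correct within an
iteration when more than half of their test-fold rows classify to the
true label (a 1-of-2 tie counts as incorrect), and as misclassified
overall when wrong in a strict majority of iterations; rates stratify
by birth sex × COPD status, and two-sided Mann–Whitney tests compare
age and BMI between misclassified and correctly classified patients.

## Post-hoc analyses

Per-patient feature values are medians over the patient's recordings;
Spearman's ρ is primary (relationships need not be linear), Pearson's r
is reported only when |ρ − r| < 0.05, and |ρ| > 0.5 flags a strong
correlation with no multiple-testing correction — a documented
limitation of the magnitude-threshold convention. Average waveforms
resample every valid breath onto a normalised [0, 1] time grid (linear
interpolation) before pointwise averaging per group; breath-time
normalisation is the alignment convention chosen here.

## What the synthetic data does and does not show

The generator reproduces the *structure* the pipeline assumes —
morphology that varies monotonically with obstruction, within-patient
repeatability, FEV1 coupling, artefact signatures — but its breaths are
far cleaner than real tidal breathing: no breath-to-breath shape
changes beyond parameter jitter, no baseline wander outside the
condensation artefact, no sensor drift, white rather than structured
noise, and artefact renderings matched to the QC rules' assumptions
rather than learned from device data. Passing tests therefore validate
the pipeline's internal consistency, its contracts, and its behaviour
under the stated generative model; they say nothing about clinical
performance on real recordings, and the near-perfect AUROCs on the
default separated cohort reflect the cohort's deliberate separability.

## Problem sizes

Tests and the acceptance script run at desk scale: 100-recording
noise-free cohorts for segmentation recovery; 25 single-artefact
recordings per class for exclusion recall; a 295-patient,
885-recording cohort (balanced to 455 rows) for protocol and
discrimination checks with 10 cross-validation iterations; a
240-patient cohort for importance localization; 100 iterations for the
split-integrity audit, which needs no waveforms. These sizes keep full
runs in the minutes range while leaving every measured rate well away
from its threshold.
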