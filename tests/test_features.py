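"""Feature manifest conformance, closed-form oracles and aggregation."""

import math

import numpy as np
import pytest

from capnokit.config import PipelineConfig
from capnokit.features import (
    AGGREGATE_FEATURES,
    ALL_FEATURES,
    PER_BREATH_FEATURES,
    WHOLE_CAPNOGRAM_FEATURES,
    FeatureIncomputable,
    aggregate_capnogram,
    compute_angles,
    compute_breath_features,
    extract_features,
    feature_region_map,
    fit_phase,
)
from capnokit.synthetic import (
    analytic_breath_features,
    generate_breath,
    generate_capnogram,
)
from capnokit.types import (
    ArtefactSpec,
    BreathBoundaries,
    BreathMorphology,
    BreathRecord,
    BreathSegmentation,
    CapnogramTrace,
)

from conftest import make_patient


class TestManifest:
    def test_feature_counts(self):
        assert len(PER_BREATH_FEATURES) == 39
        assert len(AGGREGATE_FEATURES) == 77
        assert len(WHOLE_CAPNOGRAM_FEATURES) == 5
        assert len(ALL_FEATURES) == 82

    def test_region_map_covers_every_feature(self):
        regions = feature_region_map()
        assert set(regions) == set(ALL_FEATURES)
        assert set(regions.values()) <= {
            "phase1", "phase2", "phase3", "phase4a", "phase4b", "whole_capnogram"}


class TestFitPhase:
    def _trace_from(self, y):
        return CapnogramTrace(np.asarray(y, dtype=float), sample_rate=50.0)

    def test_exact_line_recovered(self):
        t = np.arange(100) / 50.0
        trace = self._trace_from(0.3 * t + 2.0)
        slope, rmse = fit_phase(trace, (0, 100), "line")
        assert slope == pytest.approx(0.3, abs=1e-12)
        assert rmse == pytest.approx(0.0, abs=1e-12)

    def test_exact_parabola_recovered(self):
        t = np.arange(101) / 50.0  # [0, 2] s
        trace = self._trace_from(0.1 * t**2)
        slope_mid, quad, rmse = fit_phase(trace, (0, 101), "quadratic")
        assert quad == pytest.approx(0.1, abs=1e-10)
        assert slope_mid == pytest.approx(0.2, abs=1e-10)  # derivative at t=1
        assert rmse == pytest.approx(0.0, abs=1e-10)

    def test_noisy_line_slope_within_three_standard_errors(self):
        rng = np.random.default_rng(77)
        n, sd, true_slope = 200, 0.05, 0.4
        t = np.arange(n) / 50.0
        trace = self._trace_from(true_slope * t + 1.0 + rng.normal(0, sd, n))
        slope, _ = fit_phase(trace, (0, n), "line")
        se = sd / math.sqrt(np.sum((t - t.mean()) ** 2))  # closed-form OLS SE
        assert abs(slope - true_slope) < 3 * se

    def test_short_phase_raises(self):
        with pytest.raises(FeatureIncomputable):
            fit_phase(self._trace_from(np.zeros(50)), (0, 2), "line")


class TestAngles:
    def _piecewise_linear_breath(self, m2, m3, fs=50.0):
        """Baseline, linear upstroke slope m2, linear plateau slope m3,
        steep linear downstroke, baseline; exact boundaries known."""
        n1, n2, n3, n4, n5 = 25, 20, 80, 20, 25
        up_end = m2 * n2 / fs
        plateau_end = up_end + m3 * n3 / fs
        y = np.concatenate([
            np.zeros(n1),
            m2 * np.arange(n2) / fs,
            up_end + m3 * np.arange(n3) / fs,
            plateau_end * (1.0 - np.arange(n4) / n4),
            np.zeros(n5),
        ])
        b = BreathBoundaries(0, n1, n1 + n2, n1 + n2 + n3, n1 + n2 + n3 + n4,
                             n1 + n2 + n3 + n4 + n5)
        return CapnogramTrace(y, fs), b

    def test_alpha_matches_arctan_oracle(self):
        m2, m3 = 10.0, 0.2
        trace, b = self._piecewise_linear_breath(m2, m3)
        alpha, beta, gamma, delta = compute_angles(trace, b, axis_scale=1.0)
        want = 180.0 - math.degrees(math.atan(m2) - math.atan(m3))
        assert alpha == pytest.approx(want, abs=1e-6)

    def test_square_breath_angles_near_90(self):
        trace, b = self._piecewise_linear_breath(200.0, 0.0)
        alpha, beta, gamma, delta = compute_angles(trace, b)
        assert alpha == pytest.approx(90.0, abs=1.0)
        assert delta == pytest.approx(90.0, abs=1.0)

    def test_all_angles_in_open_interval(self):
        for obs in (0.0, 0.5, 1.0):
            m = BreathMorphology(obstruction_index=obs, plateau_slope=0.03 + 0.45 * obs)
            trace, b = generate_breath(m, 50.0)
            for a in compute_angles(trace, b):
                assert 0.0 < a < 180.0


class TestOracleEquivalence:
    # obstruction values putting every phase boundary exactly on a 50 Hz
    # sample (T = 4 s, ei_ratio = 1.5): the remaining discrepancy is then
    # purely the discrete estimator, not boundary rounding
    ALIGNED = [0.0, 6 / 42, 12 / 42, 21 / 42, 30 / 42, 1.0]

    @pytest.mark.parametrize("obs", ALIGNED)
    def test_geometry_matches_closed_form(self, obs):
        m = BreathMorphology(obstruction_index=obs, plateau_slope=0.03 + 0.45 * obs,
                             respiratory_period=4.0, ei_ratio=1.5, noise_sd=0.0)
        trace, bounds = generate_breath(m, 50.0)
        ana = analytic_breath_features(m)
        got = compute_breath_features(trace, bounds)
        for k in ("alpha_deg", "beta_deg", "gamma_deg", "delta_deg"):
            assert abs(got[k] - ana[k]) < 2.0
        for k in ("phase2_slope", "phase3_slope", "phase4a_slope"):
            assert abs(got[k] - ana[k]) <= 0.02 * abs(ana[k]) + 1e-9
        for k in ("auc_total", "auc_phase2", "auc_phase3"):
            assert abs(got[k] - ana[k]) <= 0.01 * abs(ana[k])

    def test_alpha_and_concavity_monotone_in_obstruction(self):
        alphas, concs = [], []
        for obs in self.ALIGNED:
            m = BreathMorphology(obstruction_index=obs, plateau_slope=0.03 + 0.45 * obs,
                                 respiratory_period=4.0, ei_ratio=1.5)
            trace, bounds = generate_breath(m, 50.0)
            got = compute_breath_features(trace, bounds)
            alphas.append(got["alpha_deg"])
            concs.append(got["phase3_concavity"])
        assert all(a2 >= a1 for a1, a2 in zip(alphas, alphas[1:]))
        assert all(c2 >= c1 for c1, c2 in zip(concs, concs[1:]))


class TestBreathFeatureSet:
    def test_ei_ratio_from_boundaries(self):
        m = BreathMorphology(respiratory_period=4.5, ei_ratio=2.0)
        trace, b = generate_breath(m, 50.0)
        feats = compute_breath_features(trace, b)
        assert feats["exp_duration"] == pytest.approx(3.0, abs=0.05)
        assert feats["insp_duration"] == pytest.approx(1.5, abs=0.05)
        assert feats["ei_ratio"] == pytest.approx(2.0, abs=0.06)

    def test_square_breath_plateau_flat(self):
        m = BreathMorphology(obstruction_index=0.0, plateau_slope=0.0, ei_ratio=1.5)
        trace, b = generate_breath(m, 50.0)
        feats = compute_breath_features(trace, b)
        assert feats["phase3_slope"] == pytest.approx(0.0, abs=1e-9)
        assert feats["phase3_concavity"] == pytest.approx(0.0, abs=1e-9)

    def test_all_39_fields_finite(self):
        trace, b = generate_breath(BreathMorphology(obstruction_index=0.6,
                                                    plateau_slope=0.3), 50.0)
        feats = compute_breath_features(trace, b)
        assert set(feats) == set(PER_BREATH_FEATURES)
        assert all(np.isfinite(v) for v in feats.values())

    def test_auc_decomposition_inequality(self):
        trace, b = generate_breath(BreathMorphology(obstruction_index=0.4,
                                                    plateau_slope=0.2), 50.0)
        f = compute_breath_features(trace, b)
        assert f["auc_total"] >= f["auc_phase2"] + f["auc_phase3"] - 0.05


class TestAggregation:
    def test_valid_recording_yields_82_features(self):
        trace, _ = generate_capnogram(make_patient(obstruction=0.3), rng_seed=11)
        vec, _, _ = extract_features(trace)
        assert vec.valid
        assert len(vec.values) == 82
        assert tuple(vec.values) == ALL_FEATURES

    def test_identical_breaths_have_zero_sds(self):
        trace, b = generate_breath(BreathMorphology(), 50.0)
        feats = compute_breath_features(trace, b)
        seg = BreathSegmentation(breaths=[
            BreathRecord(start=b.start, end=b.end, boundaries=b) for _ in range(6)])
        vec = aggregate_capnogram([dict(feats)] * 6, seg, trace)
        assert vec.valid
        for name in AGGREGATE_FEATURES:
            if name.endswith("_sd"):
                assert vec.values[name] == pytest.approx(0.0, abs=1e-12)

    def test_respiratory_rate_from_span(self):
        pat = make_patient(period=5.0)
        trace, _ = generate_capnogram(pat, duration=75.0, rng_seed=2)
        vec, _, _ = extract_features(trace)
        # 15 ground-truth breaths; the naturally cut final cycle may drop one
        expected = vec.n_valid_breaths / 75.0 * 60.0
        assert vec.values["respiratory_rate"] == pytest.approx(expected)

    def test_max_etco2_bounds_per_breath_values(self, table1_features):
        row = table1_features.iloc[0]
        assert row["max_etco2"] >= row["etco2_median"] - 1e-9

    def test_too_few_breaths_marks_invalid_not_error(self):
        pat = make_patient()
        trace, _ = generate_capnogram(pat, duration=12.0, rng_seed=3)
        vec, _, _ = extract_features(trace)
        assert not vec.valid

    def test_excluded_breath_leaves_aggregates_unchanged(self):
        # same recording with and without one injected artefact breath:
        # every aggregate and whole-capnogram feature except the
        # valid-breath fraction (whose denominator counts detections)
        # must be identical because the artefactual breath is excluded
        pat = make_patient(obstruction=0.2)
        clean_trace, _ = generate_capnogram(pat, rng_seed=21)
        art_trace, gt = generate_capnogram(
            pat, artefacts=[ArtefactSpec("cough_swallow", 30.0, 1.0)], rng_seed=21)
        v1, _, _ = extract_features(clean_trace)
        v2, _, _ = extract_features(art_trace)
        affected = gt.artefact_breaths.get("cough_swallow", [])
        assert affected
        skip = {"valid_breath_fraction", "respiratory_rate"}
        for name in ALL_FEATURES:
            if name in skip or name == "pco2_absolute_variability":
                continue
            if name.endswith("_sd") or name.endswith("_median"):
                assert v2.values[name] == pytest.approx(v1.values[name], rel=0.05, abs=0.02), name
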