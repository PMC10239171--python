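"""Modelling-dataset assembly and the training/evaluation protocol.

The protocol mirrors standard practice for diagnostic classifiers built
on repeat physiological recordings:

* class balancing by record selection — the first recording per
  majority-class (non-COPD) patient, the first three per minority-class
  (COPD) patient;
* per-feature standardisation (zero mean, unit population SD), fitted on
  training rows only and applied to held-out rows;
* a patient-level 20% unseen hold-out, then group-stratified 5-fold
  cross-validation over the remaining patients, repeated (default 100
  iterations), with all recordings of a patient confined to one fold;
* three interpretable model families: L2 logistic regression, gradient
  boosted trees and a linear-kernel SVM with Platt-style probability
  calibration;
* sensitivity / specificity / NPV / PPV / accuracy / AUROC per fold, a
  0.5 decision boundary for confusion counts, weighted feature
  importance by waveform region, per-patient prediction consistency,
  a misclassification / demographic-bias audit, and paired t-tests
  between model families.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.calibration import CalibratedClassifierCV
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC
from xgboost import XGBClassifier

from .config import ModelConfig, PipelineConfig
from .errors import ConfigurationError, ParameterError, SplitError
from .features import ALL_FEATURES, feature_region_map

MODEL_FAMILIES = ("logistic_regression", "gradient_boosted_trees", "linear_svm")


# --------------------------------------------------------------------------
# dataset assembly
# --------------------------------------------------------------------------

@dataclass
class ModellingDataset:
    """Balanced modelling rows: one per selected capnogram."""

    frame: pd.DataFrame  # patient_id, recording_id, label (1=COPD), features
    feature_cols: tuple = ALL_FEATURES

    @property
    def patients(self) -> pd.DataFrame:
        return self.frame[["patient_id", "label"]].drop_duplicates("patient_id")

    def permute_labels(self, rng_seed: int) -> "ModellingDataset":
        """Patient-level label permutation (null-distribution cohorts)."""
        rng = np.random.default_rng(rng_seed)
        pats = self.patients.reset_index(drop=True)
        permuted = pats["label"].to_numpy()[rng.permutation(len(pats))]
        mapping = dict(zip(pats["patient_id"], permuted))
        frame = self.frame.copy()
        frame["label"] = frame["patient_id"].map(mapping)
        return ModellingDataset(frame=frame, feature_cols=self.feature_cols)


def join_cohort(manifest: pd.DataFrame, feature_table: pd.DataFrame) -> pd.DataFrame:
    """Join the cohort manifest with the per-recording feature table."""
    return manifest.merge(
        feature_table.drop(columns=["patient_id"], errors="ignore"),
        on="recording_id", how="inner",
    )


def assemble_dataset(cohort: pd.DataFrame,
                     feature_cols: tuple = ALL_FEATURES) -> ModellingDataset:
    """Apply the class-balancing selection rule to a joined cohort table.

    Rows with invalid feature vectors are dropped before selection; the
    earliest recordings are kept (1 per non-COPD patient, up to 3 per
    COPD patient — a COPD patient with fewer simply contributes fewer).
    """
    required = {"patient_id", "recording_id", "label", "order"}
    if not required.issubset(cohort.columns):
        raise ParameterError(f"cohort table missing columns {required - set(cohort.columns)}")
    rows = cohort[cohort["valid"].astype(bool)] if "valid" in cohort.columns else cohort
    rows = rows.sort_values(["patient_id", "order"], kind="stable")
    kept = []
    for (pid, label), grp in rows.groupby(["patient_id", "label"], sort=False):
        n = 3 if label == "COPD" else 1
        kept.append(grp.head(n))
    frame = pd.concat(kept, ignore_index=True) if kept else rows.iloc[:0].copy()
    frame = frame.copy()
    frame["label"] = (frame["label"] == "COPD").astype(int)
    if frame[list(feature_cols)].isna().any().any():
        raise ParameterError("missing feature values in assembled dataset")
    return ModellingDataset(frame=frame, feature_cols=tuple(feature_cols))


def scale_features(train: pd.DataFrame, apply: pd.DataFrame,
                   feature_cols) -> tuple:
    """Standardise features: mean/SD from ``train`` only, applied to both.

    Population-SD (divisor ``n``) convention; zero-variance columns are
    centred and passed through with a unit divisor. Returns
    ``(train_scaled, apply_scaled, scaler)`` with numpy arrays.
    """
    scaler = StandardScaler()
    xt = scaler.fit_transform(train[list(feature_cols)].to_numpy(dtype=float))
    xa = scaler.transform(apply[list(feature_cols)].to_numpy(dtype=float))
    return xt, xa, scaler


# --------------------------------------------------------------------------
# split planning
# --------------------------------------------------------------------------

@dataclass
class SplitPlan:
    """Patient-level hold-out + repeated group-stratified k-fold folds."""

    holdout_patient_ids: frozenset
    iterations: list  # list[dict patient_id -> fold index]
    k: int

    @property
    def n_iterations(self) -> int:
        return len(self.iterations)


def make_split_plan(dataset: ModellingDataset, holdout_frac: float = 0.2,
                    k: int = 5, n_iter: int = 100, rng_seed: int = 0) -> SplitPlan:
    """Seeded patient-level split plan.

    The hold-out takes ``holdout_frac`` of the patients of each class;
    each iteration deals the remaining patients of each class round-robin
    into ``k`` folds after a shuffle (group-stratified: class proportions
    are balanced across folds and a patient's recordings never straddle a
    fold boundary).
    """
    pats = dataset.patients
    rng = np.random.default_rng(np.random.SeedSequence([int(rng_seed) % (2**31), 29]))
    by_class = {lab: grp["patient_id"].to_numpy() for lab, grp in pats.groupby("label")}
    for lab, ids in by_class.items():
        if len(ids) * (1.0 - holdout_frac) < k:
            raise SplitError(f"class {lab}: {len(ids)} patients is too few for {k} folds")

    holdout = []
    dev = {}
    for lab in sorted(by_class):
        ids = np.sort(by_class[lab])
        ids = ids[rng.permutation(len(ids))]
        n_hold = int(round(holdout_frac * len(ids)))
        holdout.extend(ids[:n_hold])
        dev[lab] = ids[n_hold:]
        if len(dev[lab]) < k:
            raise SplitError(f"class {lab}: fewer than {k} development patients")

    iterations = []
    for _ in range(n_iter):
        assignment = {}
        pos = 0  # fold pointer continues across classes: per-class balance
        for lab in sorted(dev):  # AND near-equal total fold sizes
            ids = dev[lab][rng.permutation(len(dev[lab]))]
            for pid in ids:
                assignment[pid] = pos % k
                pos += 1
        iterations.append(assignment)
    return SplitPlan(holdout_patient_ids=frozenset(holdout), iterations=iterations, k=k)


def audit_split_plan(plan: SplitPlan, dataset: ModellingDataset) -> int:
    """Count patient-overlap violations (rows of one patient straddling
    train and test of any fold, or a development/hold-out clash)."""
    violations = 0
    dev_pats = set(dataset.patients["patient_id"]) - set(plan.holdout_patient_ids)
    for assignment in plan.iterations:
        if set(assignment) != dev_pats:
            violations += 1
        rows = dataset.frame[dataset.frame["patient_id"].isin(dev_pats)]
        folds = rows["patient_id"].map(assignment)
        if folds.isna().any():
            violations += 1
        # a patient maps to exactly one fold by construction of the dict;
        # verify each patient's rows land in a single fold
        per_pat = rows.assign(fold=folds).groupby("patient_id")["fold"].nunique()
        violations += int((per_pat != 1).sum())
    if plan.holdout_patient_ids & dev_pats:
        violations += 1
    return violations


# --------------------------------------------------------------------------
# models and metrics
# --------------------------------------------------------------------------

def _make_model(family: str, cfg: ModelConfig, seed: int):
    if family == "logistic_regression":
        # default penalty is L2; C controls its strength
        return LogisticRegression(C=cfg.lr_C, max_iter=2000, random_state=seed)
    if family == "gradient_boosted_trees":
        return XGBClassifier(
            n_estimators=cfg.xgb_n_estimators, max_depth=cfg.xgb_max_depth,
            learning_rate=cfg.xgb_learning_rate, eval_metric="logloss",
            n_jobs=1, random_state=seed, tree_method="hist", verbosity=0,
        )
    if family == "linear_svm":
        return CalibratedClassifierCV(
            LinearSVC(C=cfg.svm_C, random_state=seed),
            method="sigmoid", cv=cfg.svm_calibration_folds,
        )
    raise ConfigurationError(f"unknown model family {family!r}")


def confusion_metrics(y_true: np.ndarray, prob: np.ndarray,
                      boundary: float = 0.5) -> dict:
    """Metric suite at a probability decision boundary."""
    y_true = np.asarray(y_true, dtype=int)
    pred = (np.asarray(prob) >= boundary).astype(int)
    tp = int(np.sum((pred == 1) & (y_true == 1)))
    tn = int(np.sum((pred == 0) & (y_true == 0)))
    fp = int(np.sum((pred == 1) & (y_true == 0)))
    fn = int(np.sum((pred == 0) & (y_true == 1)))

    def ratio(a, b):
        return a / b if b else float("nan")

    out = {
        "accuracy": ratio(tp + tn, len(y_true)),
        "sensitivity": ratio(tp, tp + fn),
        "specificity": ratio(tn, tn + fp),
        "ppv": ratio(tp, tp + fp),
        "npv": ratio(tn, tn + fn),
        "tp": tp, "tn": tn, "fp": fp, "fn": fn,
    }
    out["auroc"] = float(roc_auc_score(y_true, prob)) if len(np.unique(y_true)) == 2 \
        else float("nan")
    out["f1"] = ratio(2 * tp, 2 * tp + fp + fn)
    return out


@dataclass
class EvaluationReport:
    """Cross-validation metric distributions plus post-hoc artefacts."""

    cv_metrics: pd.DataFrame  # model, iteration, fold + metric columns
    holdout_metrics: dict  # model -> metric dict (single unseen evaluation)
    lr_importance: pd.Series | None = None  # |coefficient| per feature
    lr_region_importance: pd.Series | None = None
    balanced_archive: pd.DataFrame | None = None  # LR test-fold predictions
    full_archive: pd.DataFrame | None = None  # LR predictions on all capnograms
    failed_folds: int = 0

    def summary(self) -> pd.DataFrame:
        metrics = ["accuracy", "auroc", "sensitivity", "specificity", "npv", "ppv"]
        per_iter = self.cv_metrics.groupby(["model", "iteration"])[metrics].mean()
        return per_iter.groupby("model").agg(["mean", "std"])


def train_and_evaluate(plan: SplitPlan, dataset: ModellingDataset,
                       model_families=MODEL_FAMILIES,
                       config: ModelConfig | None = None,
                       rng_seed: int = 0,
                       full_table: pd.DataFrame | None = None) -> EvaluationReport:
    """Execute the full cross-validation + hold-out protocol.

    For the logistic-regression family, per-row probabilities on every
    test fold are archived, and — when ``full_table`` (all capnograms
    joined with labels, not just the balanced selection) is supplied —
    probabilities for *all* capnograms of each test-fold patient, for the
    consistency analysis. Fully deterministic given ``rng_seed``.
    """
    cfg = config or PipelineConfig().model
    if isinstance(model_families, str):
        model_families = (model_families,)
    frame = dataset.frame
    fcols = list(dataset.feature_cols)
    dev = frame[~frame["patient_id"].isin(plan.holdout_patient_ids)]
    hold = frame[frame["patient_id"].isin(plan.holdout_patient_ids)]

    rows, bal_arch, full_arch = [], [], []
    failed = 0
    for it, assignment in enumerate(plan.iterations):
        folds = dev["patient_id"].map(assignment)
        for fold in range(plan.k):
            train = dev[folds != fold]
            test = dev[folds == fold]
            if test.empty or train["label"].nunique() < 2:
                failed += 1
                continue
            xt, xs, scaler = scale_features(train, test, fcols)
            yt = train["label"].to_numpy()
            ys = test["label"].to_numpy()
            for family in model_families:
                model = _make_model(family, cfg, seed=rng_seed + 1000 * it + fold)
                t0 = time.perf_counter()
                try:
                    model.fit(xt, yt)
                except Exception:
                    failed += 1
                    continue
                build_time = time.perf_counter() - t0
                prob = model.predict_proba(xs)[:, 1]
                m = confusion_metrics(ys, prob, cfg.decision_boundary)
                m.update(model=family, iteration=it, fold=fold,
                         build_time_s=build_time, n_test=len(test))
                rows.append(m)
                if family == "logistic_regression":
                    bal_arch.append(pd.DataFrame({
                        "iteration": it, "fold": fold,
                        "patient_id": test["patient_id"].to_numpy(),
                        "recording_id": test["recording_id"].to_numpy(),
                        "y_true": ys, "prob": prob,
                    }))
                    if full_table is not None:
                        sub = full_table[full_table["patient_id"].isin(test["patient_id"])]
                        if not sub.empty:
                            xf = scaler.transform(sub[fcols].to_numpy(dtype=float))
                            pf = model.predict_proba(xf)[:, 1]
                            full_arch.append(pd.DataFrame({
                                "iteration": it, "fold": fold,
                                "patient_id": sub["patient_id"].to_numpy(),
                                "recording_id": sub["recording_id"].to_numpy(),
                                "y_true": (sub["label"] == "COPD").astype(int).to_numpy()
                                if sub["label"].dtype == object else sub["label"].to_numpy(),
                                "prob": pf,
                            }))

    cv = pd.DataFrame(rows)

    # final models: fit on the full development set, single hold-out pass
    holdout_metrics = {}
    lr_importance = lr_region = None
    if not hold.empty and not dev.empty:
        xt, xh, scaler = scale_features(dev, hold, fcols)
        yt = dev["label"].to_numpy()
        yh = hold["label"].to_numpy()
        for family in model_families:
            model = _make_model(family, cfg, seed=rng_seed)
            model.fit(xt, yt)
            prob = model.predict_proba(xh)[:, 1]
            holdout_metrics[family] = confusion_metrics(yh, prob, cfg.decision_boundary)
            if family == "logistic_regression":
                try:
                    lr_importance, lr_region = feature_importance(model, xt, fcols)
                except ConfigurationError:
                    # custom feature columns outside the manifest: report
                    # coefficient magnitudes without a region breakdown
                    lr_importance = pd.Series(np.abs(np.ravel(model.coef_)),
                                              index=fcols, name="importance")
                    lr_region = None

    return EvaluationReport(
        cv_metrics=cv, holdout_metrics=holdout_metrics,
        lr_importance=lr_importance, lr_region_importance=lr_region,
        balanced_archive=pd.concat(bal_arch, ignore_index=True) if bal_arch else None,
        full_archive=pd.concat(full_arch, ignore_index=True) if full_arch else None,
        failed_folds=failed,
    )


def feature_importance(lr_model, scaled_rows: np.ndarray, feature_cols) -> tuple:
    """|coefficient| per feature + weighted importance per waveform region.

    The weighted importance of a feature on a row is the magnitude of the
    product of its normalised value and its importance; a region's value
    is the mean over its features, averaged over rows.
    """
    coef = np.abs(np.ravel(lr_model.coef_))
    if coef.size != len(feature_cols):
        raise ConfigurationError("coefficient vector does not match feature columns")
    importance = pd.Series(coef, index=list(feature_cols), name="importance")
    weighted = np.mean(np.abs(scaled_rows) * coef[None, :], axis=0)
    regions = feature_region_map()
    missing = [f for f in feature_cols if f not in regions]
    if missing:
        raise ConfigurationError(f"features missing from region map: {missing[:3]}")
    wf = pd.Series(weighted, index=list(feature_cols))
    region = wf.groupby(pd.Series({f: regions[f] for f in feature_cols})).mean()
    return importance, region.sort_values(ascending=False)


# --------------------------------------------------------------------------
# post-hoc analyses of the prediction archive
# --------------------------------------------------------------------------

def per_patient_consistency(full_archive: pd.DataFrame,
                            conditions: pd.DataFrame,
                            boundary: float = 0.5) -> pd.DataFrame:
    """Per-condition consistency of predictions across repeat recordings.

    For every patient in a test fold, all of that patient's capnograms
    are scored; per (iteration, patient) the classification accuracy and
    the SD of predicted COPD probability are computed, then averaged over
    patients within each condition and finally over iterations.
    """
    df = full_archive.merge(conditions[["patient_id", "condition"]].drop_duplicates(),
                            on="patient_id")
    df["correct"] = ((df["prob"] >= boundary).astype(int) == df["y_true"]).astype(float)
    per_pat = df.groupby(["iteration", "condition", "patient_id"]).agg(
        accuracy=("correct", "mean"), prob_sd=("prob", "std"),
        n_capnograms=("prob", "size"),
    ).fillna({"prob_sd": 0.0})
    per_iter = per_pat.groupby(["iteration", "condition"]).agg(
        accuracy=("accuracy", "mean"), prob_sd=("prob_sd", "mean"),
        n_patients=("n_capnograms", "size"), capnograms_per_patient=("n_capnograms", "mean"),
    )
    out = per_iter.groupby("condition").agg(
        n_patients=("n_patients", "max"),
        capnograms_per_patient=("capnograms_per_patient", "mean"),
        accuracy=("accuracy", "mean"), accuracy_sd=("accuracy", "std"),
        prob_sd=("prob_sd", "mean"), prob_sd_sd=("prob_sd", "std"),
    )
    return out.sort_values("accuracy", ascending=False)


def misclassification_audit(balanced_archive: pd.DataFrame,
                            demographics: pd.DataFrame,
                            boundary: float = 0.5) -> dict:
    """Strict-majority misclassification flags + demographic bias tests.

    A patient is correct in an iteration when more than half of their
    test-fold rows are classified to the true label; a patient is
    'misclassified' overall when wrong in more than 50% of the iterations
    in which they appeared. Rates are stratified by birth sex and COPD
    status; age and BMI distributions of misclassified vs correctly
    classified patients are compared with two-sided Mann-Whitney tests.
    """
    df = balanced_archive.copy()
    df["correct"] = ((df["prob"] >= boundary).astype(int) == df["y_true"]).astype(float)
    per_iter = df.groupby(["patient_id", "iteration"]).agg(
        acc=("correct", "mean"), label=("y_true", "first"))
    per_iter["iter_correct"] = per_iter["acc"] > 0.5
    per_pat = per_iter.groupby("patient_id").agg(
        wrong_frac=("iter_correct", lambda s: 1.0 - s.mean()),
        label=("label", "first"))
    per_pat["misclassified"] = per_pat["wrong_frac"] > 0.5

    demo = demographics.drop_duplicates("patient_id").set_index("patient_id")
    per_pat = per_pat.join(demo[["sex", "age", "bmi"]], how="left")

    strata = {}
    for (label, sex), grp in per_pat.groupby(["label", "sex"]):
        key = f"{'COPD' if label == 1 else 'non_COPD'}_{sex}"
        strata[key] = {"n": int(len(grp)),
                       "n_misclassified": int(grp["misclassified"].sum()),
                       "rate": float(grp["misclassified"].mean()) if len(grp) else None}

    tests = {}
    mis = per_pat[per_pat["misclassified"]]
    ok = per_pat[~per_pat["misclassified"]]
    for var in ("age", "bmi"):
        a, b = mis[var].dropna(), ok[var].dropna()
        if len(a) and len(b):
            res = stats.mannwhitneyu(a, b, alternative="two-sided")
            tests[var] = {"U": float(res.statistic), "p": float(res.pvalue),
                          "n_misclassified": int(len(a)), "n_correct": int(len(b))}
        else:
            tests[var] = {"U": None, "p": None,
                          "n_misclassified": int(len(a)), "n_correct": int(len(b))}
    return {"per_patient": per_pat, "strata": strata, "tests": tests}


def paired_ttest(a: np.ndarray, b: np.ndarray) -> dict:
    """Two-sided paired t-test with explicit degenerate handling.

    Identical series give ``t = 0, p = 1``; series whose differences are
    a non-zero constant give infinite ``t`` with ``p = 0`` and a
    degenerate flag.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ParameterError("paired series must have equal length")
    d = a - b
    if np.allclose(d, 0.0, atol=1e-15):
        return {"t": 0.0, "p": 1.0, "degenerate": False}
    if np.allclose(d, d[0], rtol=1e-9, atol=1e-15):
        return {"t": float(np.inf) * np.sign(d[0]), "p": 0.0, "degenerate": True}
    res = stats.ttest_rel(a, b)
    return {"t": float(res.statistic), "p": float(res.pvalue), "degenerate": False}


def compare_models(cv_metrics: pd.DataFrame,
                   metrics=("specificity", "sensitivity", "f1", "auroc")) -> pd.DataFrame:
    """Pairwise paired t-tests between model families, paired by iteration."""
    per_iter = cv_metrics.groupby(["model", "iteration"])[list(metrics)].mean()
    models = sorted(per_iter.index.get_level_values("model").unique())
    rows = []
    for m1, m2 in combinations(models, 2):
        s1, s2 = per_iter.loc[m1], per_iter.loc[m2]
        common = s1.index.intersection(s2.index)
        for metric in metrics:
            r = paired_ttest(s1.loc[common, metric], s2.loc[common, metric])
            rows.append({"model_a": m1, "model_b": m2, "metric": metric, **r})
    return pd.DataFrame(rows)
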