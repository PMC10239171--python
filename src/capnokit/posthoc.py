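"""Post-hoc physiological analyses.

Two analyses connect the classifier back to respiratory physiology:

* correlation of the most important capnogram features with paired
  spirometry (% predicted FEV1), using Spearman's rank correlation since
  the relationships need not be linear; Pearson's r is additionally
  reported when a simple linearity check passes; |rho| > 0.5 flags a
  strong correlation;
* group-average waveforms: every valid breath is resampled onto a common
  normalised time grid (fraction of breath duration) and averaged
  pointwise per group, exposing where — typically the alpha-angle
  region between upstroke and plateau — obstructed waveforms diverge
  from healthy ones.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParameterError


def correlate_features_with_fev1(feature_table: pd.DataFrame,
                                 manifest: pd.DataFrame,
                                 top_features: list,
                                 strong_threshold: float = 0.5,
                                 linearity_gap: float = 0.05) -> pd.DataFrame:
    """Spearman correlation of per-patient feature medians with FEV1.

    ``feature_table`` has one row per recording; the per-patient value of
    each feature is the median over that patient's capnograms. Features
    with fewer than 3 paired patients are skipped. Pearson's r is
    reported when |rho - r| < ``linearity_gap``.
    """
    fev1 = manifest.drop_duplicates("patient_id").set_index("patient_id")["fev1_pct_pred"]
    table = feature_table[feature_table["valid"].astype(bool)] \
        if "valid" in feature_table.columns else feature_table
    per_pat = table.groupby("patient_id")[list(top_features)].median()
    per_pat = per_pat.join(fev1, how="inner").dropna(subset=["fev1_pct_pred"])

    rows = []
    for feat in top_features:
        pairs = per_pat[[feat, "fev1_pct_pred"]].dropna()
        if len(pairs) < 3:
            continue
        rho = float(stats.spearmanr(pairs[feat], pairs["fev1_pct_pred"]).statistic)
        r = float(stats.pearsonr(pairs[feat], pairs["fev1_pct_pred"]).statistic)
        linear = abs(rho - r) < linearity_gap
        rows.append({
            "feature": feat, "spearman_rho": rho,
            "pearson_r": r if linear else float("nan"),
            "n_patients": int(len(pairs)),
            "strong": abs(rho) > strong_threshold,
        })
    return pd.DataFrame(rows)


def average_waveform(traces: dict, segmentations: dict,
                     groups: pd.DataFrame, grid_size: int = 101) -> pd.DataFrame:
    """Pointwise mean waveform per group on a normalised [0, 1] time grid.

    ``groups`` maps recording_id -> group label. Every valid breath of
    every recording in a group is linearly interpolated onto the grid;
    empty groups are omitted. Returns a long-format frame with columns
    group, time_frac, mean_pco2, n_breaths.
    """
    if grid_size < 2:
        raise ParameterError("grid_size must be at least 2")
    grid = np.linspace(0.0, 1.0, grid_size)
    sums: dict = {}
    counts: dict = {}
    lookup = groups.set_index("recording_id")["group"] if isinstance(groups, pd.DataFrame) \
        else pd.Series(groups)
    for rec_id, seg in segmentations.items():
        if rec_id not in lookup.index or rec_id not in traces:
            continue
        g = lookup.loc[rec_id]
        x = traces[rec_id].samples
        for breath in seg.valid_breaths:
            y = x[breath.start:breath.end]
            if y.size < 2:
                continue
            t = np.linspace(0.0, 1.0, y.size)
            yi = np.interp(grid, t, y)
            sums[g] = sums.get(g, 0.0) + yi
            counts[g] = counts.get(g, 0) + 1
    rows = []
    for g in sorted(sums):
        mean = sums[g] / counts[g]
        for tf, v in zip(grid, mean):
            rows.append({"group": g, "time_frac": float(tf),
                         "mean_pco2": float(v), "n_breaths": counts[g]})
    return pd.DataFrame(rows)


def waveform_divergence(avg: pd.DataFrame, group_a: str, group_b: str) -> dict:
    """Where two group-average waveforms diverge most (normalised time)."""
    a = avg[avg["group"] == group_a].set_index("time_frac")["mean_pco2"]
    b = avg[avg["group"] == group_b].set_index("time_frac")["mean_pco2"]
    diff = (a - b).abs().dropna()
    if diff.empty:
        raise ParameterError("groups do not share a grid")
    t_star = float(diff.idxmax())
    return {"time_frac": t_star, "gap_kpa": float(diff.max())}
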