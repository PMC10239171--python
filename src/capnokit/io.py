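"""Plain-text interchange formats.

Traces travel as a two-column CSV (``time_s, pco2_kpa``) with a JSON
sidecar for metadata and optional generator ground truth, or as a
single-file JSON dialect embedding both. Cohort manifests, feature
tables and QC reports are CSV/JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParameterError
from .types import BreathBoundaries, BreathSegmentation, CapnogramTrace, QCReport


# --------------------------------------------------------------------------
# traces
# --------------------------------------------------------------------------

def write_trace_csv(trace: CapnogramTrace, path, ground_truth=None) -> None:
    """CSV (time_s, pco2_kpa) + ``<stem>.meta.json`` sidecar."""
    path = Path(path)
    df = pd.DataFrame({"time_s": trace.times, "pco2_kpa": trace.samples})
    df.to_csv(path, index=False, float_format="%.6f")
    meta = {
        "recording_id": trace.recording_id,
        "patient_id": trace.patient_id,
        "sample_rate": trace.sample_rate,
        "collected_at": trace.collected_at,
    }
    if ground_truth is not None:
        meta["ground_truth"] = _ground_truth_dict(ground_truth)
    path.with_suffix(".meta.json").write_text(json.dumps(meta, indent=1))


def read_trace_csv(path) -> CapnogramTrace:
    path = Path(path)
    df = pd.read_csv(path)
    if not {"time_s", "pco2_kpa"}.issubset(df.columns):
        raise ParameterError(f"{path} lacks time_s/pco2_kpa columns")
    t = df["time_s"].to_numpy()
    dt = np.diff(t)
    if dt.size and (dt.max() - dt.min()) > 1e-6:
        raise ParameterError(f"{path}: samples not uniformly spaced")
    meta_path = path.with_suffix(".meta.json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    rate = meta.get("sample_rate") or (1.0 / dt.mean() if dt.size else 1.0)
    return CapnogramTrace(
        samples=df["pco2_kpa"].to_numpy(), sample_rate=float(rate),
        recording_id=meta.get("recording_id", path.stem),
        patient_id=meta.get("patient_id", ""),
        collected_at=meta.get("collected_at"),
    )


def write_trace_json(trace: CapnogramTrace, path, ground_truth=None) -> None:
    """Single-file JSON dialect embedding samples, metadata and truth."""
    doc = {
        "recording_id": trace.recording_id,
        "patient_id": trace.patient_id,
        "sample_rate": trace.sample_rate,
        "collected_at": trace.collected_at,
        "pco2_kpa": [round(float(v), 6) for v in trace.samples],
    }
    if ground_truth is not None:
        doc["ground_truth"] = _ground_truth_dict(ground_truth)
    Path(path).write_text(json.dumps(doc))


def read_trace_json(path) -> CapnogramTrace:
    doc = json.loads(Path(path).read_text())
    return CapnogramTrace(
        samples=np.asarray(doc["pco2_kpa"], dtype=float),
        sample_rate=float(doc["sample_rate"]),
        recording_id=doc.get("recording_id", ""),
        patient_id=doc.get("patient_id", ""),
        collected_at=doc.get("collected_at"),
    )


def _ground_truth_dict(gt) -> dict:
    return {
        "boundaries": [list(b.as_tuple()) for b in gt.boundaries],
        "artefact_breaths": {k: list(v) for k, v in gt.artefact_breaths.items()},
        "incomplete_final": bool(gt.incomplete_final),
    }


# --------------------------------------------------------------------------
# segmentation and QC
# --------------------------------------------------------------------------

def write_segmentation_json(seg: BreathSegmentation, report: QCReport, path) -> None:
    doc = {
        "breaths": [
            {
                "start": b.start, "end": b.end,
                "boundaries": list(b.boundaries.as_tuple()) if b.boundaries else None,
                "qc_status": b.qc_status,
                "exclusion_reason": b.exclusion_reason,
                "incomplete": bool(b.incomplete),
            }
            for b in seg.breaths
        ],
        "qc_report": {
            "n_breaths_detected": report.n_breaths_detected,
            "n_valid": report.n_valid,
            "exclusion_counts": report.exclusion_counts,
            "denoise_correlation": report.denoise_correlation,
            "snr_per_breath": [None if not np.isfinite(s) else round(float(s), 3)
                               for s in report.snr_per_breath],
        },
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_segmentation_json(path) -> tuple:
    from .types import BreathRecord

    doc = json.loads(Path(path).read_text())
    breaths = []
    for b in doc["breaths"]:
        rec = BreathRecord(start=b["start"], end=b["end"],
                           qc_status=b["qc_status"],
                           exclusion_reason=b["exclusion_reason"],
                           incomplete=b["incomplete"])
        if b["boundaries"]:
            rec.boundaries = BreathBoundaries(*b["boundaries"])
        breaths.append(rec)
    q = doc["qc_report"]
    report = QCReport(
        n_breaths_detected=q["n_breaths_detected"], n_valid=q["n_valid"],
        exclusion_counts=q["exclusion_counts"],
        snr_per_breath=[float("nan") if s is None else s for s in q["snr_per_breath"]],
        denoise_correlation=q["denoise_correlation"],
    )
    return BreathSegmentation(breaths=breaths), report


# --------------------------------------------------------------------------
# cohort directories
# --------------------------------------------------------------------------

def write_cohort(cohort, out_dir, fmt: str = "csv") -> Path:
    """Write a generated cohort: manifest CSV + one trace file per recording."""
    out = Path(out_dir)
    traces_dir = out / "traces"
    traces_dir.mkdir(parents=True, exist_ok=True)
    manifest = cohort.manifest.copy()
    paths = []
    for rec_id in manifest["recording_id"]:
        trace = cohort.traces[rec_id]
        gt = cohort.ground_truth.get(rec_id)
        if fmt == "csv":
            p = traces_dir / f"{rec_id}.csv"
            write_trace_csv(trace, p, ground_truth=gt)
        else:
            p = traces_dir / f"{rec_id}.json"
            write_trace_json(trace, p, ground_truth=gt)
        paths.append(str(p.relative_to(out)))
    manifest["trace_path"] = paths
    manifest.to_csv(out / "manifest.csv", index=False)
    return out / "manifest.csv"


def read_manifest(path) -> pd.DataFrame:
    return pd.read_csv(path)


def load_trace(path) -> CapnogramTrace:
    path = Path(path)
    if path.suffix == ".json":
        return read_trace_json(path)
    return read_trace_csv(path)
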