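"""Plain-text readers and writers for cohort data and pipeline outputs.

Layout written by :func:`write_cohort`::

    DIR/
      manifest.csv                      subject_id,label,files...
      <subject>_<modality>_<role>.csv   t_seconds,value
      <subject>_truth.csv               kind,time_seconds,extra
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .types import FeatureMatrix, EvaluationReport, RawSignal, SubjectRecording

__all__ = [
    "write_signal_csv",
    "read_signal_csv",
    "write_cohort",
    "read_cohort_signals",
    "write_feature_matrix",
    "read_feature_matrix",
    "write_report",
]

_SEGMENTS = (("ecg", "baseline"), ("ecg", "task"), ("gsr", "baseline"), ("gsr", "task"))


def write_signal_csv(sig: RawSignal, path: Path) -> None:
    df = pd.DataFrame({"t_seconds": sig.times, "value": sig.samples})
    df.to_csv(path, index=False, float_format="%.6f")


def read_signal_csv(path: Path, fs: float | None = None, role: str = "task",
                    modality: str = "ecg") -> RawSignal:
    df = pd.read_csv(path)
    t = df["t_seconds"].to_numpy()
    if fs is None:
        fs = 1.0 / float(np.median(np.diff(t)))
    return RawSignal(df["value"].to_numpy(), float(round(fs, 6)), role, modality)


def write_cohort(cohort: Sequence[SubjectRecording], out_dir: Path) -> Path:
    """Write per-segment signal CSVs, ground-truth CSVs, and a manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest_rows = []
    for rec in cohort:
        row: dict = {"subject_id": rec.subject_id, "label": rec.label}
        for modality, role in _SEGMENTS:
            name = f"{rec.subject_id}_{modality}_{role}.csv"
            write_signal_csv(rec.signal(modality, role), out_dir / name)  # type: ignore[arg-type]
            row[f"{modality}_{role}"] = name
        truth_rows = []
        for role, times in rec.truth.r_peak_times.items():
            truth_rows += [{"kind": "r_peak", "time_seconds": t, "extra": role} for t in times]
        for role, times in rec.truth.scr_event_times.items():
            truth_rows += [{"kind": "scr", "time_seconds": t, "extra": role} for t in times]
        truth_name = f"{rec.subject_id}_truth.csv"
        pd.DataFrame(truth_rows, columns=["kind", "time_seconds", "extra"]).to_csv(
            out_dir / truth_name, index=False, float_format="%.6f"
        )
        row["truth"] = truth_name
        manifest_rows.append(row)
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(manifest_rows).to_csv(manifest, index=False)
    return manifest


def read_cohort_signals(manifest_path: Path, fs: float = 500.0) -> list[dict]:
    """Load cohort signals listed in a manifest (no ground truth needed).

    Returns one dict per subject with keys subject_id, label and the
    four RawSignal segments.
    """
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    manifest = pd.read_csv(manifest_path)
    subjects = []
    for _, row in manifest.iterrows():
        entry = {"subject_id": row["subject_id"], "label": row["label"]}
        for modality, role in _SEGMENTS:
            entry[f"{modality}_{role}"] = read_signal_csv(
                base / row[f"{modality}_{role}"], fs=fs, role=role, modality=modality
            )
        subjects.append(entry)
    return subjects


def write_feature_matrix(matrix: FeatureMatrix, path: Path) -> None:
    matrix.data.to_csv(path, index=False)


def read_feature_matrix(path: Path, modality: str = "multimodal",
                        normalized: bool = True) -> FeatureMatrix:
    return FeatureMatrix(data=pd.read_csv(path), modality=modality, normalized=normalized)


def write_report(report: EvaluationReport, path: Path) -> None:
    Path(path).write_text(json.dumps(report.to_dict(), indent=2, default=float) + "\n")
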