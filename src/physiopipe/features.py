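"""Windowing, HRV and electrodermal features, baseline normalization,
and feature-matrix assembly.

ECG features are computed on 10 s windows with 5 s step; GSR features on
30 s windows with 20 s step. Task-segment features are normalized by the
subject's aggregated baseline features (elementwise ratio). Missing
values are marked NaN and handled at assembly (drop columns that are
mostly missing, then drop rows with any remaining missing value).
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

from .ecg import PanTompkinsDetector
from .eda import preprocess_gsr
from .types import (
    FeatureMatrix,
    InvalidParameterError,
    RawSignal,
    RRSeries,
    SCREvent,
    SubjectRecording,
)

logger = logging.getLogger(__name__)

__all__ = [
    "segment",
    "ecg_time_features",
    "lomb_band_powers",
    "ecg_freq_features",
    "ecg_window_features",
    "gsr_window_features",
    "baseline_normalize",
    "extract_ecg_features",
    "extract_gsr_features",
    "process_subject",
    "assemble_matrix",
    "cohort_feature_matrices",
    "ECG_FEATURES",
    "GSR_FEATURES",
]

# windowing defaults (s)
ECG_WINDOW, ECG_OVERLAP = 10.0, 5.0
GSR_WINDOW, GSR_OVERLAP = 30.0, 10.0

# HRV spectral bands (Hz)
BANDS = {
    "ULF": (0.0, 0.003),
    "VLF": (0.003, 0.04),
    "LF": (0.04, 0.15),
    "HF": (0.15, 0.4),
    "TP": (0.0, 0.4),
}
MF_BAND = (0.08, 0.15)
FREQ_GRID = np.arange(0.001, 0.4005, 0.001)

ECG_TIME_FEATURES = [
    "RR_min", "RR_max", "RR_diff", "RR_mean", "RR_SD", "RR_CV",
    "SDSD", "NN50", "PNN50",
]
ECG_FREQ_FEATURES = ["ULF", "VLF", "LF", "HF", "TP", "LF_norm", "HF_norm", "LF_HF", "LMHF"]
ECG_FEATURES = ECG_TIME_FEATURES + ECG_FREQ_FEATURES

_EVENT_FIELDS = ["RT", "HRT", "Amp", "Area", "Prom"]
_AGGS = ["mean", "min", "max", "SD"]
GSR_EVENT_FEATURES = [f"{f}_{a}" for f in _EVENT_FIELDS for a in _AGGS]
GSR_SCALAR_FEATURES = ["SCL", "MAV1Diff_SCL", "MAV2Diff_SCL", "BP", "PSD"]
GSR_FEATURES = GSR_EVENT_FEATURES + GSR_SCALAR_FEATURES

#: baseline features smaller than this in magnitude make the ratio undefined
NORMALIZE_EPS = 1e-9
#: columns missing in more than this fraction of rows are dropped at assembly
COLUMN_DROP_FRACTION = 0.4


def segment(duration: float, window: float, overlap: float) -> list[tuple[float, float]]:
    """Sliding-window starts/ends fully inside [0, duration].

    Count = floor((duration − window) / (window − overlap)) + 1.
    """
    if overlap >= window:
        raise InvalidParameterError("overlap must be smaller than the window")
    if overlap < 0 or window <= 0:
        raise InvalidParameterError("window must be positive and overlap nonnegative")
    if window > duration:
        return []
    step = window - overlap
    n = int(np.floor((duration - window) / step + 1e-9)) + 1
    return [(k * step, k * step + window) for k in range(n)]


# ---------------------------------------------------------------------------
# ECG features
# ---------------------------------------------------------------------------

def ecg_time_features(intervals: Sequence[float]) -> dict[str, float] | None:
    """Time-domain HRV statistics for one window; None if < 3 intervals.

    NN50 counts successive-difference magnitudes above 50 ms; PNN50 is
    its percentage of the n−1 successive differences.
    """
    rr = np.asarray(intervals, dtype=float)
    if rr.size < 3:
        return None
    diffs = np.diff(rr)
    nn50 = int(np.sum(np.abs(diffs) > 0.050))
    mean = float(rr.mean())
    # exact zeros for exactly-constant windows (float round-off in the
    # mean otherwise leaks ~1e-16 into the spread statistics)
    sd = 0.0 if np.ptp(rr) == 0.0 else float(rr.std(ddof=0))
    return {
        "RR_min": float(rr.min()),
        "RR_max": float(rr.max()),
        "RR_diff": float(rr.max() - rr.min()),
        "RR_mean": mean,
        "RR_SD": sd,
        "RR_CV": sd / mean if mean else np.nan,
        "SDSD": 0.0 if np.ptp(diffs) == 0.0 else float(diffs.std(ddof=0)),
        "NN50": float(nn50),
        "PNN50": 100.0 * nn50 / diffs.size,
    }


def lomb_band_powers(
    rr_times: np.ndarray,
    rr_values: np.ndarray,
    freqs: np.ndarray = FREQ_GRID,
) -> dict[str, float] | None:
    """HRV band powers from a Lomb–Scargle periodogram of the tachogram.

    The periodogram is evaluated on a fixed grid (default 0.001–0.4 Hz,
    step 0.001) and scaled to a one-sided power spectral density
    (s²/Hz) so that band powers are trapezoidal integrals of the PSD;
    on evenly sampled data this matches an FFT periodogram.
    Returns None for fewer than 4 points.
    """
    t = np.asarray(rr_times, dtype=float)
    y = np.asarray(rr_values, dtype=float)
    if t.size < 4:
        return None
    if np.any(np.diff(t) <= 0):
        raise InvalidParameterError("rr_times must be strictly increasing")
    yc = y - y.mean()
    if np.allclose(yc, 0.0):
        psd = np.zeros_like(freqs)
    else:
        p = sps.lombscargle(t, yc, 2.0 * np.pi * freqs)
        dt_mean = float(np.mean(np.diff(t)))
        psd = 2.0 * dt_mean * p
    out: dict[str, float] = {}
    for name, (lo, hi) in BANDS.items():
        out[name] = _integrate_band(freqs, psd, lo, hi)
    out["_MF"] = _integrate_band(freqs, psd, *MF_BAND)
    return out


def _integrate_band(freqs: np.ndarray, psd: np.ndarray, lo: float, hi: float) -> float:
    mask = (freqs >= lo - 1e-12) & (freqs <= hi + 1e-12)
    if mask.sum() < 2:
        return 0.0
    return float(np.trapezoid(psd[mask], freqs[mask]))


def ecg_freq_features(bands: dict[str, float]) -> dict[str, float]:
    """Derived spectral ratios from band powers (incl. the MF band).

    LF_norm/HF_norm use LF+HF as denominator; LMHF = (LF+MF)/HF. When
    HF = 0 the ratio features are marked missing (NaN).
    """
    lf, hf, mf = bands["LF"], bands["HF"], bands.get("_MF", 0.0)
    out = {k: bands[k] for k in ("ULF", "VLF", "LF", "HF", "TP")}
    denom = lf + hf
    out["LF_norm"] = 100.0 * lf / denom if denom > 0 else np.nan
    out["HF_norm"] = 100.0 * hf / denom if denom > 0 else np.nan
    out["LF_HF"] = lf / hf if hf > 0 else np.nan
    out["LMHF"] = (lf + mf) / hf if hf > 0 else np.nan
    return out


def ecg_window_features(rr: RRSeries, start: float, end: float) -> dict[str, float]:
    """All 18 ECG features for one window; NaN-filled when missing."""
    times = rr.interval_times
    in_win = (times >= start) & (times < end) & ~rr.flags
    intervals = rr.intervals[in_win]
    tfeat = ecg_time_features(intervals)
    if tfeat is None:
        return {k: np.nan for k in ECG_FEATURES}
    bands = lomb_band_powers(times[in_win], intervals)
    if bands is None:
        ffeat = {k: np.nan for k in ECG_FREQ_FEATURES}
    else:
        ffeat = ecg_freq_features(bands)
    return {**tfeat, **ffeat}


# ---------------------------------------------------------------------------
# GSR features
# ---------------------------------------------------------------------------

def _aggregate_events(values: np.ndarray, prefix: str) -> dict[str, float]:
    out = {}
    if values.size == 0:
        return {f"{prefix}_{a}": np.nan for a in _AGGS}
    out[f"{prefix}_mean"] = float(values.mean())
    out[f"{prefix}_min"] = float(values.min())
    out[f"{prefix}_max"] = float(values.max())
    out[f"{prefix}_SD"] = float(values.std(ddof=0))
    return out


def scr_event_aggregates(
    events: Iterable[SCREvent], scl: float
) -> dict[str, float]:
    """Mean/min/max/SD of RT, HRT, Amp, Area, Prom across events.

    Censored half-recoveries are excluded from the HRT aggregates;
    prominence is recomputed against the supplied skin-conductance level.
    """
    events = list(events)
    rt = np.array([e.rise_time for e in events])
    hrt = np.array([e.half_recovery_duration for e in events if not e.censored])
    amp = np.array([e.amplitude for e in events])
    area = np.array([e.area for e in events])
    prom = np.array([e.peak_value - scl for e in events])
    out: dict[str, float] = {}
    out.update(_aggregate_events(rt, "RT"))
    out.update(_aggregate_events(hrt, "HRT"))
    out.update(_aggregate_events(amp, "Amp"))
    out.update(_aggregate_events(area, "Area"))
    out.update(_aggregate_events(prom, "Prom"))
    return out


def gsr_window_features(
    samples: np.ndarray,
    fs: float,
    events: Iterable[SCREvent],
) -> dict[str, float]:
    """Electrodermal features for one window of filtered GSR.

    Event statistics aggregate SCRs whose peak lies in the window;
    SCL is the window mean; MAV1Diff/MAV2Diff are the mean absolute
    first/second sample differences; BP is Welch band power over
    0.01–1 Hz; PSD is total periodogram power over 0–1 Hz.
    """
    x = np.asarray(samples, dtype=float)
    scl = float(x.mean())
    out = scr_event_aggregates(events, scl)
    out["SCL"] = scl
    out["MAV1Diff_SCL"] = float(np.mean(np.abs(np.diff(x)))) if x.size > 1 else 0.0
    out["MAV2Diff_SCL"] = float(np.mean(np.abs(np.diff(x, 2)))) if x.size > 2 else 0.0
    nper = int(min(x.size, 16 * fs))
    f_w, p_w = sps.welch(x, fs=fs, nperseg=nper)
    out["BP"] = _integrate_band(f_w, p_w, 0.01, 1.0)
    f_p, p_p = sps.periodogram(x, fs=fs)
    out["PSD"] = _integrate_band(f_p, p_p, 0.0, 1.0)
    return out


# ---------------------------------------------------------------------------
# Per-segment extraction
# ---------------------------------------------------------------------------

def extract_ecg_features(
    rr: RRSeries,
    duration: float,
    window: float = ECG_WINDOW,
    overlap: float = ECG_OVERLAP,
) -> pd.DataFrame:
    """Windowed ECG feature table; one row per window, NaN = missing."""
    rows = []
    for start, end in segment(duration, window, overlap):
        feats = ecg_window_features(rr, start, end)
        rows.append({"w_start": start, "w_end": end, **feats})
    return pd.DataFrame(rows, columns=["w_start", "w_end", *ECG_FEATURES])


def extract_gsr_features(
    filtered: RawSignal,
    events: Sequence[SCREvent],
    window: float = GSR_WINDOW,
    overlap: float = GSR_OVERLAP,
) -> pd.DataFrame:
    """Windowed GSR feature table; one row per window, NaN = missing."""
    fs = filtered.fs
    rows = []
    for start, end in segment(filtered.duration, window, overlap):
        in_win = [e for e in events if start <= e.peak_time < end]
        x = filtered.samples[int(start * fs): int(end * fs)]
        feats = gsr_window_features(x, fs, in_win)
        rows.append({"w_start": start, "w_end": end, **feats})
    return pd.DataFrame(rows, columns=["w_start", "w_end", *GSR_FEATURES])


# ---------------------------------------------------------------------------
# Baseline normalization
# ---------------------------------------------------------------------------

def baseline_normalize(
    task: pd.DataFrame | pd.Series | dict,
    baseline: pd.Series | dict,
    eps: float = NORMALIZE_EPS,
) -> pd.DataFrame | pd.Series:
    """Elementwise ratio task/baseline over shared feature names.

    Baseline entries with magnitude below ``eps`` yield NaN ratios
    rather than infinities. Raises on feature-name mismatch.
    """
    base = pd.Series(baseline, dtype=float)
    if isinstance(task, dict):
        task = pd.Series(task, dtype=float)
    names = [c for c in (task.columns if isinstance(task, pd.DataFrame) else task.index)
             if c not in ("w_start", "w_end")]
    if set(names) - set(base.index):
        raise InvalidParameterError(
            f"feature-name mismatch: {sorted(set(names) - set(base.index))}"
        )
    base = base[names]
    denom = base.where(base.abs() >= eps)
    if isinstance(task, pd.DataFrame):
        out = task.copy()
        out[names] = task[names] / denom
        return out
    return task[names] / denom


def baseline_vector_ecg(baseline_df: pd.DataFrame) -> pd.Series:
    """Per-subject ECG baseline: mean over baseline windows (NaN-skipping)."""
    return baseline_df[ECG_FEATURES].mean(skipna=True)


def baseline_vector_gsr(
    baseline_df: pd.DataFrame,
    filtered_baseline: RawSignal,
    baseline_events: Sequence[SCREvent],
) -> pd.Series:
    """Per-subject GSR baseline vector.

    Scalar window features (SCL, MAV diffs, BP, PSD) are averaged over
    baseline windows; the SCR event statistics are computed from events
    pooled over the whole baseline segment, which stabilizes them when
    individual 30 s baseline windows hold 0–1 events.
    """
    scalars = baseline_df[GSR_SCALAR_FEATURES].mean(skipna=True)
    scl = float(filtered_baseline.samples.mean())
    pooled = pd.Series(scr_event_aggregates(baseline_events, scl), dtype=float)
    return pd.concat([pooled, scalars])[GSR_FEATURES]


# ---------------------------------------------------------------------------
# Subject processing and matrix assembly
# ---------------------------------------------------------------------------

def process_subject(
    rec: SubjectRecording,
    detector: PanTompkinsDetector | None = None,
) -> dict:
    """Run preprocessing + feature extraction for one subject.

    Returns normalized task-window feature tables per modality along
    with the raw (unnormalized) tables and baseline vectors.
    """
    detector = detector or PanTompkinsDetector()
    out: dict = {"subject_id": rec.subject_id, "label": rec.label}

    rr_base = detector.rr_series(rec.ecg_baseline)
    rr_task = detector.rr_series(rec.ecg_task)
    ecg_base = extract_ecg_features(rr_base, rec.ecg_baseline.duration)
    ecg_task = extract_ecg_features(rr_task, rec.ecg_task.duration)
    ecg_baseline_vec = baseline_vector_ecg(ecg_base)
    out["ecg_raw"] = ecg_task
    out["ecg_baseline_vec"] = ecg_baseline_vec
    out["ecg"] = baseline_normalize(ecg_task, ecg_baseline_vec)

    filt_base, ev_base = preprocess_gsr(rec.gsr_baseline)
    filt_task, ev_task = preprocess_gsr(rec.gsr_task)
    gsr_base = extract_gsr_features(filt_base, ev_base)
    gsr_task = extract_gsr_features(filt_task, ev_task)
    gsr_baseline_vec = baseline_vector_gsr(gsr_base, filt_base, ev_base)
    out["gsr_raw"] = gsr_task
    out["gsr_baseline_vec"] = gsr_baseline_vec
    out["gsr"] = baseline_normalize(gsr_task, gsr_baseline_vec)
    return out


def _multimodal_rows(sub: dict) -> pd.DataFrame:
    """Pair each GSR window with the mean of overlapping ECG windows."""
    gsr = sub["gsr"]
    ecg = sub["ecg"]
    ecg_raw = sub["ecg_raw"]  # carries w_start/w_end aligned with sub["ecg"]
    rows = []
    for i in range(len(gsr)):
        gs = float(sub["gsr_raw"].iloc[i]["w_start"])
        ge = float(sub["gsr_raw"].iloc[i]["w_end"])
        overlap = (ecg_raw["w_start"] < ge) & (ecg_raw["w_end"] > gs)
        ecg_mean = ecg.loc[overlap.to_numpy(), ECG_FEATURES].mean(skipna=True)
        rows.append(pd.concat([gsr.iloc[i][GSR_FEATURES], ecg_mean]))
    return pd.DataFrame(rows).reset_index(drop=True)


def assemble_matrix(
    subjects: Sequence[dict],
    modality: str = "multimodal",
    column_drop_fraction: float = COLUMN_DROP_FRACTION,
) -> FeatureMatrix:
    """Stack per-subject normalized window features into one matrix.

    ``modality`` selects ECG windows, GSR windows, or the multimodal
    pairing (each GSR 30 s window joined with the mean of the ECG
    feature vectors whose windows overlap it). Columns missing in more
    than ``column_drop_fraction`` of rows are dropped (logged), then
    rows with any remaining missing value are dropped (logged).
    """
    frames = []
    for sub in subjects:
        if modality == "ecg":
            df = sub["ecg"][ECG_FEATURES].copy()
        elif modality == "gsr":
            df = sub["gsr"][GSR_FEATURES].copy()
        elif modality == "multimodal":
            df = _multimodal_rows(sub)
        else:
            raise InvalidParameterError(f"unknown modality {modality!r}")
        df.insert(0, "window_id", np.arange(len(df)))
        df.insert(0, "label", sub["label"])
        df.insert(0, "subject_id", sub["subject_id"])
        frames.append(df)
    data = pd.concat(frames, ignore_index=True)

    feat_cols = [c for c in data.columns if c not in ("subject_id", "label", "window_id")]
    miss_frac = data[feat_cols].isna().mean()
    dropped_cols = miss_frac[miss_frac > column_drop_fraction].index.tolist()
    if dropped_cols:
        logger.info("dropping %d mostly-missing columns: %s", len(dropped_cols), dropped_cols)
        data = data.drop(columns=dropped_cols)
    n_before = len(data)
    data = data.dropna().reset_index(drop=True)
    if n_before - len(data):
        logger.info("dropped %d/%d rows with missing values", n_before - len(data), n_before)
    if data.empty:
        raise InvalidParameterError("feature matrix is empty after dropping missing rows")
    return FeatureMatrix(data=data, modality=modality, normalized=True)


def cohort_feature_matrices(
    cohort: Sequence[SubjectRecording],
    modalities: Sequence[str] = ("ecg", "gsr", "multimodal"),
) -> dict[str, FeatureMatrix]:
    """Process every subject and assemble one matrix per modality."""
    subjects = [process_subject(rec) for rec in cohort]
    return {m: assemble_matrix(subjects, m) for m in modalities}
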