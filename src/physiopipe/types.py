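"""Core domain containers shared across the pipeline.

All time quantities are in seconds, conductance in microsiemens (µS),
ECG amplitude in millivolts (mV), sampling rates in Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import pandas as pd

Role = Literal["baseline", "task"]
Modality = Literal["ecg", "gsr"]
Label = Literal["expert", "novice"]

#: RR intervals outside this range (s) are flagged physiologically implausible.
RR_PLAUSIBLE = (0.3, 2.0)


class InvalidParameterError(ValueError):
    """Raised when an operation receives out-of-contract parameters."""


class TooShortError(ValueError):
    """Raised when a signal is too short for the requested filter chain."""


class InsufficientPeaksError(ValueError):
    """Raised when fewer than two R-peaks are available for RR computation."""


@dataclass(frozen=True)
class RawSignal:
    """One uniformly sampled channel of a wearable recording."""

    samples: np.ndarray
    fs: float
    role: Role = "task"
    modality: Modality = "ecg"

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if self.fs <= 0:
            raise InvalidParameterError(f"sampling rate must be positive, got {self.fs}")
        if samples.ndim != 1:
            raise InvalidParameterError("signal must be one-dimensional")
        if samples.size and not np.all(np.isfinite(samples)):
            raise InvalidParameterError("signal contains non-finite samples")

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.fs


@dataclass(frozen=True)
class RRSeries:
    """R-peak times and the inter-beat (RR) intervals they define.

    ``flags`` marks intervals outside the physiologically plausible
    0.3–2.0 s range; flagged intervals are retained but excluded from
    feature computation downstream.
    """

    peak_times: np.ndarray          # sorted, s
    intervals: np.ndarray           # successive differences, s
    flags: np.ndarray               # bool, True = implausible

    @classmethod
    def from_peaks(cls, peak_times: np.ndarray) -> "RRSeries":
        peak_times = np.asarray(peak_times, dtype=float)
        if peak_times.size < 2:
            raise InsufficientPeaksError(
                f"need at least 2 R-peaks, got {peak_times.size}"
            )
        if np.any(np.diff(peak_times) <= 0):
            raise InvalidParameterError("peak times must be strictly increasing")
        intervals = np.diff(peak_times)
        lo, hi = RR_PLAUSIBLE
        flags = (intervals < lo) | (intervals > hi)
        return cls(peak_times=peak_times, intervals=intervals, flags=flags)

    @property
    def interval_times(self) -> np.ndarray:
        """Time stamp of each interval: the time of its closing R-peak."""
        return self.peak_times[1:]


@dataclass(frozen=True)
class SCREvent:
    """One detected skin-conductance response.

    ``half_recovery_time`` is NaN when the recovery to half amplitude is
    censored by the next response's onset or the end of the segment.
    """

    onset_time: float
    peak_time: float
    half_recovery_time: float       # NaN if censored
    censored: bool
    rise_time: float                # RT = peak_time - onset_time
    half_recovery_duration: float   # HRT = half_recovery_time - peak_time, NaN if censored
    amplitude: float                # Amp = value(peak) - value(onset), µS
    area: float                     # µS·s, onset → half-recovery (or censoring point)
    prominence: float               # peak value above segment-level SCL, µS
    peak_value: float
    onset_value: float

    def __post_init__(self) -> None:
        if not self.onset_time < self.peak_time:
            raise InvalidParameterError("SCR onset must precede its peak")
        if self.amplitude < 0:
            raise InvalidParameterError("SCR amplitude must be nonnegative")
        if not self.censored and not self.half_recovery_time > self.peak_time:
            raise InvalidParameterError(
                "uncensored half-recovery must follow the peak"
            )


@dataclass(frozen=True)
class ClassParams:
    """Generator parameters describing one expertise class.

    ``task_shift`` is a dimensionless multiplier applied when deriving
    task-segment parameters from the baseline parameters: heart rate,
    sympathovagal balance, SCR rate/amplitude and tonic level all scale
    with it (mean RR scales by 1/task_shift).
    """

    mean_rr: float = 0.8            # s
    sdnn: float = 0.05              # s, RR standard deviation
    lf_hf_ratio: float = 1.5        # target LF/HF spectral balance
    scr_rate: float = 4.0           # events / minute
    scr_amp_mean: float = 0.4       # µS
    scl_level: float = 5.0          # µS
    task_shift: float = 1.2

    def __post_init__(self) -> None:
        if self.mean_rr <= 0:
            raise InvalidParameterError("mean_rr must be positive")
        if self.sdnn < 0 or self.scr_rate < 0 or self.scr_amp_mean < 0:
            raise InvalidParameterError("sdnn, scr_rate and scr_amp_mean must be >= 0")
        if self.task_shift <= 0:
            raise InvalidParameterError("task_shift must be positive")

    def for_task(self) -> "ClassParams":
        """Parameters governing the task segment."""
        s = self.task_shift
        return replace(
            self,
            mean_rr=self.mean_rr / s,
            lf_hf_ratio=self.lf_hf_ratio * s,
            scr_rate=self.scr_rate * s,
            scr_amp_mean=self.scr_amp_mean * s,
            scl_level=self.scl_level * s,
            task_shift=1.0,
        )


@dataclass(frozen=True)
class GroundTruth:
    """Generator-side truth for one subject: event times and realized params."""

    r_peak_times: dict[str, np.ndarray]      # role -> sorted times (s)
    scr_event_times: dict[str, np.ndarray]   # role -> sorted times (s)
    params: ClassParams                      # realized baseline params for the subject


@dataclass(frozen=True)
class SubjectRecording:
    subject_id: str
    label: Label
    ecg_baseline: RawSignal
    ecg_task: RawSignal
    gsr_baseline: RawSignal
    gsr_task: RawSignal
    truth: GroundTruth

    def __post_init__(self) -> None:
        rates = {s.fs for s in (self.ecg_baseline, self.ecg_task,
                                self.gsr_baseline, self.gsr_task)}
        if len(rates) != 1:
            raise InvalidParameterError("all four signals must share one sampling rate")

    def signal(self, modality: Modality, role: Role) -> RawSignal:
        return getattr(self, f"{modality}_{role}")


ID_COLUMNS = ["subject_id", "label", "window_id"]


@dataclass
class FeatureMatrix:
    """Windowed feature vectors with subject IDs and class labels.

    ``data`` holds one row per window with columns
    ``subject_id, label, window_id, <feature...>``.
    """

    data: pd.DataFrame
    modality: str                    # ecg | gsr | multimodal
    normalized: bool = False

    @property
    def feature_names(self) -> list[str]:
        return [c for c in self.data.columns if c not in ID_COLUMNS]

    @property
    def X(self) -> np.ndarray:
        return self.data[self.feature_names].to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        return self.data["label"].to_numpy()

    @property
    def groups(self) -> np.ndarray:
        return self.data["subject_id"].to_numpy()

    @property
    def n_subjects(self) -> int:
        return self.data["subject_id"].nunique()

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class EvaluationReport:
    """Per-fold and aggregate LOSO metrics for one classifier run."""

    folds: pd.DataFrame              # held_out_subject, TP, TN, FP, FN, accuracy, ...
    aggregate: dict[str, float]
    aggregation: str                 # mean-over-folds | pooled-windows
    classifier: dict
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "aggregation": self.aggregation,
            "classifier": self.classifier,
            "seed": self.seed,
            "aggregate": self.aggregate,
            "folds": self.folds.to_dict(orient="records"),
        }
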