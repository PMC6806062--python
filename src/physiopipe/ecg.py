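"""Pan–Tompkins-style QRS detection and RR-interval extraction.

The chain is: zero-phase Butterworth bandpass (5–15 Hz) → 5-point
derivative → rectification (absolute value) → 150 ms moving-window
integration → adaptive dual-threshold peak picking with search-back.
Rectification uses the absolute value rather than the classic squaring;
a ``rectify="square"`` switch restores the original behaviour.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps
from scipy.ndimage import uniform_filter1d

from .types import InvalidParameterError, RawSignal, RRSeries, TooShortError

__all__ = ["pt_filter_chain", "detect_r_peaks", "compute_rr", "PanTompkinsDetector"]

BANDPASS = (5.0, 15.0)          # Hz
BUTTER_ORDER = 3                # effective order 6 after forward-backward pass
INTEGRATION_WINDOW = 0.150      # s
REFRACTORY = 0.200              # s
SEARCHBACK_TIMEOUT = 2.0        # s without an accepted peak
RELOCALIZE_WINDOW = 0.075       # s, re-localization to the bandpassed signal


def bandpass_ecg(x: np.ndarray, fs: float) -> np.ndarray:
    sos = sps.butter(BUTTER_ORDER, BANDPASS, btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x)


def pt_filter_chain(sig: RawSignal, rectify: str = "abs") -> np.ndarray:
    """Bandpass → derivative → rectify → integrate; returns the integrated
    waveform (same length and rate as the input, nonnegative)."""
    if sig.modality != "ecg":
        raise InvalidParameterError("pt_filter_chain expects an ECG signal")
    if sig.fs < 100:
        raise InvalidParameterError("QRS detection requires fs >= 100 Hz")
    if sig.duration < 1.0:
        raise TooShortError("ECG segment shorter than the 1 s filter warm-up")
    bp = bandpass_ecg(sig.samples, sig.fs)
    deriv = derivative_5pt(bp, sig.fs)
    if rectify == "abs":
        rect = np.abs(deriv)
    elif rectify == "square":
        rect = deriv * deriv
    else:
        raise InvalidParameterError(f"unknown rectification {rectify!r}")
    win = max(int(round(INTEGRATION_WINDOW * sig.fs)), 1)
    return uniform_filter1d(rect, size=win, mode="nearest")


def derivative_5pt(x: np.ndarray, fs: float) -> np.ndarray:
    """Classic 5-point derivative y(n) = fs/8·[2x(n)+x(n−1)−x(n−3)−2x(n−4)]."""
    kernel = np.array([2.0, 1.0, 0.0, -1.0, -2.0]) * fs / 8.0
    y = np.convolve(x, kernel)[: x.size]
    y[:4] = 0.0  # filter warm-up
    return y


def _candidate_peaks(integrated: np.ndarray, fs: float) -> np.ndarray:
    dist = max(int(round(REFRACTORY * fs)), 1)
    peaks, _ = sps.find_peaks(integrated, distance=dist)
    return peaks


def detect_r_peaks(
    integrated: np.ndarray,
    bandpassed: np.ndarray,
    fs: float,
) -> np.ndarray:
    """Adaptive dual-threshold QRS detection; returns R-peak times (s).

    As in the classic formulation, running signal/noise level estimates
    are kept for *both* the integrated and the bandpassed waveforms
    (SPK ← 0.125·peak + 0.875·SPK on signal peaks, NPK analogously;
    0.25 weight after a search-back acceptance), with
    THRESHOLD1 = NPK + 0.25·(SPK−NPK) and THRESHOLD2 = 0.5·THRESHOLD1
    in each domain; a candidate is accepted only when it exceeds
    THRESHOLD1 in both. If no peak is accepted for 2 s the candidates
    since the last acceptance are re-scanned against THRESHOLD2.
    Accepted peaks are re-localized to the nearest local maximum of the
    bandpassed signal within ±75 ms.
    """
    integrated = np.asarray(integrated, dtype=float)
    bandpassed = np.asarray(bandpassed, dtype=float)
    candidates = _candidate_peaks(integrated, fs)
    if candidates.size == 0:
        return np.array([])

    half = int(round(RELOCALIZE_WINDOW * fs))

    def bp_peak(idx: int) -> float:
        lo, hi = max(idx - half, 0), min(idx + half + 1, bandpassed.size)
        return float(bandpassed[lo:hi].max())

    # initialize level estimates from the first two seconds
    init_i = integrated[: max(int(2 * fs), 1)]
    init_f = bandpassed[: max(int(2 * fs), 1)]
    spk_i = 0.7 * float(init_i.max())
    npk_i = 0.5 * float(init_i.mean())
    spk_f = 0.7 * float(init_f.max())
    npk_f = 0.5 * float(np.abs(init_f).mean())
    if spk_i <= 0:
        return np.array([])

    refractory = int(round(REFRACTORY * fs))
    timeout = int(round(SEARCHBACK_TIMEOUT * fs))
    accepted: list[int] = []
    pending: list[int] = []     # unaccepted candidates since last acceptance

    def t1_i() -> float:
        return npk_i + 0.25 * (spk_i - npk_i)

    def t1_f() -> float:
        return npk_f + 0.25 * (spk_f - npk_f)

    for idx in candidates:
        val = integrated[idx]
        valf = bp_peak(idx)
        if (val > t1_i() and valf > t1_f()
                and (not accepted or idx - accepted[-1] > refractory)):
            accepted.append(int(idx))
            spk_i = 0.125 * val + 0.875 * spk_i
            spk_f = 0.125 * valf + 0.875 * spk_f
            pending.clear()
            continue
        npk_i = 0.125 * val + 0.875 * npk_i
        npk_f = 0.125 * valf + 0.875 * npk_f
        pending.append(int(idx))
        # search-back: no acceptance within the timeout window
        last = accepted[-1] if accepted else 0
        if idx - last > timeout and pending:
            t2_i, t2_f = 0.5 * t1_i(), 0.5 * t1_f()
            back = [p for p in pending
                    if integrated[p] > t2_i and bp_peak(p) > t2_f
                    and (not accepted or p - accepted[-1] > refractory)]
            if back:
                best = max(back, key=lambda p: integrated[p])
                accepted.append(best)
                accepted.sort()
                spk_i = 0.25 * integrated[best] + 0.75 * spk_i
                spk_f = 0.25 * bp_peak(best) + 0.75 * spk_f
                pending = [p for p in pending if p > best]

    if not accepted:
        return np.array([])

    # re-localize to the bandpassed waveform to remove integration lag
    half = int(round(RELOCALIZE_WINDOW * fs))
    located = []
    for idx in accepted:
        lo = max(idx - half, 0)
        hi = min(idx + half + 1, bandpassed.size)
        located.append(lo + int(np.argmax(bandpassed[lo:hi])))
    located = np.unique(located)
    # enforce refractory after re-localization
    keep = [located[0]]
    for idx in located[1:]:
        if idx - keep[-1] > refractory:
            keep.append(idx)
    return np.asarray(keep) / fs


def compute_rr(r_peak_times: np.ndarray) -> RRSeries:
    """Successive R-peak differences with plausibility flags (0.3–2.0 s)."""
    return RRSeries.from_peaks(np.asarray(r_peak_times, dtype=float))


class PanTompkinsDetector:
    """Convenience wrapper running the full chain on a RawSignal.

    Parameters
    ----------
    rectify : {"abs", "square"}
        Rectification applied after the derivative stage. The default
        follows the absolute-value variant; "square" restores the
        original energy-based form.
    """

    def __init__(self, rectify: str = "abs"):
        self.rectify = rectify

    def detect(self, sig: RawSignal) -> np.ndarray:
        integrated = pt_filter_chain(sig, rectify=self.rectify)
        bp = bandpass_ecg(sig.samples, sig.fs)
        return detect_r_peaks(integrated, bp, sig.fs)

    def rr_series(self, sig: RawSignal) -> RRSeries:
        return compute_rr(self.detect(sig))
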