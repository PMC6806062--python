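"""Synthetic two-class ECG + GSR cohort generator with full ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes: ECG with a PQRST morphology and class-dependent RR statistics,
GSR with a drifting tonic level plus discrete skin-conductance responses,
and a per-subject baseline → task parameter shift that encodes the
cognitive-load response the classification targets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .types import ClassParams, GroundTruth, InvalidParameterError, RawSignal, SubjectRecording

__all__ = [
    "EcgNoise",
    "GsrTonic",
    "EXPERT_DEFAULT",
    "NOVICE_DEFAULT",
    "generate_rr_series",
    "synthesize_ecg",
    "generate_scr_train",
    "synthesize_gsr",
    "generate_subject",
    "generate_cohort",
    "bateman",
    "bateman_peak_time",
]

# Default class parameter presets. Experts are modeled as showing a mild
# task response (small shift from baseline), novices a strong one; the
# baseline-normalized features the pipeline uses discriminate on the
# *shift*, not on absolute baseline levels.
EXPERT_DEFAULT = ClassParams(
    mean_rr=0.85, sdnn=0.05, lf_hf_ratio=1.5, scr_rate=4.0,
    scr_amp_mean=0.3, scl_level=4.0, task_shift=1.08,
)
NOVICE_DEFAULT = ClassParams(
    mean_rr=0.75, sdnn=0.05, lf_hf_ratio=2.0, scr_rate=4.0,
    scr_amp_mean=0.4, scl_level=6.0, task_shift=1.35,
)


@dataclass(frozen=True)
class EcgNoise:
    """Additive ECG noise model (amplitudes in mV)."""

    baseline_wander_amp: float = 0.1    # <0.5 Hz sinusoidal wander
    baseline_wander_freq: float = 0.25
    powerline_amp: float = 0.05
    powerline_freq: float = 60.0        # 50 or 60 Hz
    broadband_sd: float = 0.05

    @classmethod
    def none(cls) -> "EcgNoise":
        return cls(baseline_wander_amp=0.0, powerline_amp=0.0, broadband_sd=0.0)


@dataclass(frozen=True)
class GsrTonic:
    """Tonic skin-conductance model: a level plus a slow sinusoidal drift."""

    scl_level: float = 5.0              # µS
    drift_amp: float = 0.2              # µS
    drift_freq: float = 0.01            # Hz


# ---------------------------------------------------------------------------
# RR-interval process
# ---------------------------------------------------------------------------

#: LF/HF modulation frequencies (Hz), centered in the canonical HRV bands.
_LF_FREQ = 0.095
_HF_FREQ = 0.275
#: Fraction of total RR variance carried by the two sinusoidal modulators;
#: the remainder is a mean-reverting AR(1) broadband component.
_OSC_FRACTION = 0.9
_AR_PHI = 0.3


def generate_rr_series(
    params: ClassParams,
    duration: float,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Draw a beat-to-beat RR-interval series (seconds).

    The marginal mean is ``params.mean_rr`` and the marginal SD is
    ``params.sdnn``. Variability is the sum of two sinusoidal modulators —
    one in the LF band (0.04–0.15 Hz), one in the HF band (0.15–0.4 Hz),
    with power ratio ``params.lf_hf_ratio`` — and a mean-reverting AR(1)
    residual. The cumulative sum of the returned intervals never exceeds
    ``duration``.
    """
    if duration <= 0 or params.mean_rr <= 0:
        raise InvalidParameterError("duration and mean_rr must be positive")
    if duration <= 2 * params.mean_rr:
        raise InvalidParameterError("duration must exceed two mean RR intervals")

    mu, sd = params.mean_rr, params.sdnn
    if sd == 0:
        n = int(math.floor(duration / mu + 1e-9))
        return np.full(n, mu)

    rng = np.random.default_rng(seed)
    r = params.lf_hf_ratio
    var = sd * sd
    # length-bias compensation: sampling the modulation at beat times
    # oversamples short intervals, depressing the beat-domain mean by
    # ~var/mu; raise the base level so the realized mean hits mean_rr
    mu = mu + var / mu
    var_lf = _OSC_FRACTION * var * r / (1.0 + r)
    var_hf = _OSC_FRACTION * var / (1.0 + r)
    var_ar = (1.0 - _OSC_FRACTION) * var
    a_lf = math.sqrt(2.0 * var_lf)
    a_hf = math.sqrt(2.0 * var_hf)
    phase_lf, phase_hf = rng.uniform(0.0, 2.0 * math.pi, size=2)
    eps_sd = math.sqrt(var_ar * (1.0 - _AR_PHI**2))

    intervals: list[float] = []
    t = 0.0
    x = rng.normal(0.0, math.sqrt(var_ar)) if var_ar > 0 else 0.0
    while True:
        rr = (
            mu
            + a_lf * math.sin(2.0 * math.pi * _LF_FREQ * t + phase_lf)
            + a_hf * math.sin(2.0 * math.pi * _HF_FREQ * t + phase_hf)
            + x
        )
        rr = max(rr, 0.25 * mu)  # guard against nonphysical nonpositive beats
        if t + rr > duration:
            break
        intervals.append(rr)
        t += rr
        x = _AR_PHI * x + rng.normal(0.0, eps_sd) if var_ar > 0 else 0.0
    return np.asarray(intervals)


# ---------------------------------------------------------------------------
# ECG synthesis
# ---------------------------------------------------------------------------

# PQRST template: sum of Gaussians, (amplitude mV, center offset s, width s)
# relative to the R apex. R amplitude 1 mV by convention.
_PQRST = (
    (0.12, -0.20, 0.025),   # P
    (-0.10, -0.035, 0.010),  # Q
    (1.00, 0.0, 0.012),      # R
    (-0.18, 0.035, 0.012),   # S
    (0.30, 0.22, 0.045),     # T
)
_TEMPLATE_SPAN = (-0.30, 0.42)  # s around the R apex where the template is nonzero


def synthesize_ecg(
    rr: np.ndarray,
    fs: float = 500.0,
    noise: EcgNoise | None = None,
    seed: int | np.random.Generator = 0,
    role: str = "task",
) -> tuple[RawSignal, np.ndarray]:
    """Render an ECG trace from an RR-interval series.

    A sum-of-Gaussians PQRST template is placed at each cumulative RR time
    (R apexes snapped to the sample grid, so the returned ``r_peak_times``
    coincide with exact sample maxima in the noiseless limit). Additive
    noise is sinusoidal baseline wander, a powerline sinusoid, and white
    broadband noise.
    """
    rr = np.asarray(rr, dtype=float)
    if rr.size == 0:
        raise InvalidParameterError("RR series must be non-empty")
    if fs < 100:
        raise InvalidParameterError("ECG synthesis requires fs >= 100 Hz")
    noise = noise or EcgNoise()

    n = int(round(rr.sum() * fs))
    peak_idx = np.round(np.cumsum(rr) * fs).astype(int)
    peak_idx = peak_idx[peak_idx < n]          # last beat may truncate
    peak_times = peak_idx / fs

    signal = np.zeros(n)
    lo_off = int(_TEMPLATE_SPAN[0] * fs)
    hi_off = int(_TEMPLATE_SPAN[1] * fs)
    rel_t = np.arange(lo_off, hi_off + 1) / fs
    template = np.zeros_like(rel_t)
    for amp, center, width in _PQRST:
        template += amp * np.exp(-0.5 * ((rel_t - center) / width) ** 2)
    for idx in peak_idx:
        lo = idx + lo_off
        hi = idx + hi_off + 1
        s_lo, s_hi = max(lo, 0), min(hi, n)
        signal[s_lo:s_hi] += template[s_lo - lo: (s_hi - lo)]

    t = np.arange(n) / fs
    rng = np.random.default_rng(seed)
    if noise.baseline_wander_amp:
        signal += noise.baseline_wander_amp * np.sin(
            2 * np.pi * noise.baseline_wander_freq * t + rng.uniform(0, 2 * np.pi)
        )
    if noise.powerline_amp:
        signal += noise.powerline_amp * np.sin(
            2 * np.pi * noise.powerline_freq * t + rng.uniform(0, 2 * np.pi)
        )
    if noise.broadband_sd:
        signal += rng.normal(0.0, noise.broadband_sd, size=n)

    return RawSignal(signal, fs, role=role, modality="ecg"), peak_times


# ---------------------------------------------------------------------------
# SCR event train and GSR synthesis
# ---------------------------------------------------------------------------

#: Minimum inter-event gap (s); keeps responses resolvable after the 1 Hz
#: low-pass / 2 s moving-average preprocessing chain.
MIN_SCR_GAP = 5.0


def generate_scr_train(
    rate: float,
    amp_mean: float,
    duration: float,
    seed: int | np.random.Generator,
    min_gap: float = MIN_SCR_GAP,
) -> list[tuple[float, float]]:
    """Draw SCR event times and amplitudes.

    Events follow a homogeneous Poisson process (``rate`` per minute)
    thinned to enforce a minimum inter-event gap; amplitudes are
    log-normal with mean ``amp_mean`` µS (shape σ = 0.4).
    """
    if rate < 0:
        raise InvalidParameterError("rate must be >= 0")
    if rate == 0 or duration <= 0:
        return []
    rng = np.random.default_rng(seed)
    rate_per_s = rate / 60.0
    # compensate the driving intensity for gap-thinning losses so the
    # *realized* event rate matches the requested one (a renewal process
    # with dead time `gap` and exponential intensity λ has mean rate
    # λ/(1+λ·gap); invert when feasible)
    if rate_per_s * min_gap < 0.9:
        rate_per_s = rate_per_s / (1.0 - rate_per_s * min_gap)
    n_draw = rng.poisson(rate_per_s * duration)
    times = np.sort(rng.uniform(0.0, duration, size=n_draw))
    kept: list[float] = []
    for ti in times:
        if not kept or ti - kept[-1] >= min_gap:
            kept.append(float(ti))
    sigma = 0.4
    mu_log = math.log(amp_mean) - 0.5 * sigma**2 if amp_mean > 0 else -np.inf
    amps = (
        rng.lognormal(mu_log, sigma, size=len(kept))
        if amp_mean > 0
        else np.zeros(len(kept))
    )
    return [(t, float(a)) for t, a in zip(kept, amps)]


def bateman_peak_time(tau_r: float, tau_d: float) -> float:
    """Time from onset to peak of the biexponential SCR kernel."""
    return tau_r * tau_d / (tau_d - tau_r) * math.log(tau_d / tau_r)


def bateman(t: np.ndarray, tau_r: float, tau_d: float) -> np.ndarray:
    """Amplitude-normalized biexponential SCR kernel (peak value 1)."""
    tstar = bateman_peak_time(tau_r, tau_d)
    peak = math.exp(-tstar / tau_d) - math.exp(-tstar / tau_r)
    out = np.where(t >= 0, np.exp(-t / tau_d) - np.exp(-t / tau_r), 0.0) / peak
    return out


def synthesize_gsr(
    events: list[tuple[float, float]],
    tonic: GsrTonic,
    duration: float,
    fs: float = 500.0,
    noise_sd: float = 0.02,
    seed: int | np.random.Generator = 0,
    tau_r: float = 0.75,
    tau_d: float = 2.0,
    role: str = "task",
) -> tuple[RawSignal, np.ndarray]:
    """Render a GSR trace: tonic drift + Bateman-shaped SCRs + white noise.

    Each event ``(time, A)`` contributes an amplitude-normalized
    biexponential response whose peak above the tonic level equals ``A``.
    """
    if fs < 10:
        raise InvalidParameterError("GSR synthesis requires fs >= 10 Hz")
    if tau_r >= tau_d:
        raise InvalidParameterError("rise constant tau_r must be < decay tau_d")
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    signal = np.full(n, tonic.scl_level)
    if tonic.drift_amp:
        signal += tonic.drift_amp * np.sin(
            2 * np.pi * tonic.drift_freq * t + rng.uniform(0, 2 * np.pi)
        )
    event_times = []
    for et, amp in sorted(events):
        if et >= duration:
            continue
        start = int(math.ceil(et * fs))
        rel = t[start:] - et
        signal[start:] += amp * bateman(rel, tau_r, tau_d)
        event_times.append(et)
    if noise_sd:
        signal += rng.normal(0.0, noise_sd, size=n)
    return RawSignal(signal, fs, role=role, modality="gsr"), np.asarray(event_times)


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

#: Relative SD of per-subject log-normal jitter around class parameters.
SUBJECT_JITTER = 0.04


def _jitter_params(params: ClassParams, rng: np.random.Generator,
                   jitter: float) -> ClassParams:
    def j(v: float, scale: float = jitter) -> float:
        return float(v * rng.lognormal(0.0, scale)) if v > 0 else v

    return replace(
        params,
        mean_rr=j(params.mean_rr),
        sdnn=j(params.sdnn),
        lf_hf_ratio=j(params.lf_hf_ratio),
        scr_rate=j(params.scr_rate),
        scr_amp_mean=j(params.scr_amp_mean),
        scl_level=j(params.scl_level),
        task_shift=j(params.task_shift, jitter / 2),
    )


def generate_subject(
    subject_id: str,
    label: str,
    params: ClassParams,
    seed: int | np.random.SeedSequence,
    fs: float = 500.0,
    baseline_duration: float = 120.0,
    task_duration: float = 600.0,
    ecg_noise: EcgNoise | None = None,
    gsr_noise_sd: float = 0.02,
    jitter: float = SUBJECT_JITTER,
) -> SubjectRecording:
    """Simulate one subject: baseline + task segments of ECG and GSR."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rngs = [np.random.default_rng(s) for s in ss.spawn(9)]
    subject_params = _jitter_params(params, rngs[0], jitter)
    ecg_noise = ecg_noise or EcgNoise()

    segments: dict[str, dict] = {}
    for role, dur, p, k in (
        ("baseline", baseline_duration, subject_params, 1),
        ("task", task_duration, subject_params.for_task(), 5),
    ):
        rr = generate_rr_series(p, dur, rngs[k])
        ecg, r_peaks = synthesize_ecg(rr, fs=fs, noise=ecg_noise, seed=rngs[k + 1], role=role)
        events = generate_scr_train(p.scr_rate, p.scr_amp_mean, dur, rngs[k + 2])
        tonic = GsrTonic(scl_level=p.scl_level)
        gsr, scr_times = synthesize_gsr(
            events, tonic, dur, fs=fs, noise_sd=gsr_noise_sd, seed=rngs[k + 3], role=role
        )
        segments[role] = {"ecg": ecg, "gsr": gsr, "r_peaks": r_peaks, "scrs": scr_times}

    truth = GroundTruth(
        r_peak_times={r: segments[r]["r_peaks"] for r in segments},
        scr_event_times={r: segments[r]["scrs"] for r in segments},
        params=subject_params,
    )
    return SubjectRecording(
        subject_id=subject_id,
        label=label,  # type: ignore[arg-type]
        ecg_baseline=segments["baseline"]["ecg"],
        ecg_task=segments["task"]["ecg"],
        gsr_baseline=segments["baseline"]["gsr"],
        gsr_task=segments["task"]["gsr"],
        truth=truth,
    )


def generate_cohort(
    n_expert: int = 5,
    n_novice: int = 5,
    expert_params: ClassParams = EXPERT_DEFAULT,
    novice_params: ClassParams = NOVICE_DEFAULT,
    seed: int = 0,
    **subject_kwargs,
) -> list[SubjectRecording]:
    """Simulate a two-class cohort; deterministic given ``seed``."""
    if n_expert < 1 or n_novice < 1:
        raise InvalidParameterError("need at least one subject per class")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_expert + n_novice)
    cohort = []
    for i in range(n_expert):
        cohort.append(
            generate_subject(f"E{i+1:02d}", "expert", expert_params, children[i],
                             **subject_kwargs)
        )
    for i in range(n_novice):
        cohort.append(
            generate_subject(f"N{i+1:02d}", "novice", novice_params,
                             children[n_expert + i], **subject_kwargs)
        )
    return cohort
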