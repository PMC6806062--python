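# Methods

`physiopipe` implements a complete analysis chain for two-channel
wearable recordings — single-lead ECG and single-channel skin
conductance (GSR/EDA), both sampled at 500 Hz — whose goal is to
classify a binary subject-level trait (expert vs. novice operator)
from the physiological response to a demanding task. Each subject
contributes a ~2 min resting baseline and a ~10 min task segment.
Because no public recordings exist for this protocol, the package
includes a first-class synthetic cohort generator with complete ground
truth; every quantitative guarantee the test suite makes is a statement
about recovery of that known ground truth.

## Synthetic cohort model

**RR-interval process.** Beat-to-beat intervals follow
`rr(t) = µ + a_LF·sin(2π·0.095·t + φ1) + a_HF·sin(2π·0.275·t + φ2) + x(t)`,
where `x` is a mean-reverting AR(1) residual (φ = 0.3). The two
sinusoids sit mid-band in the canonical LF (0.04–0.15 Hz) and HF
(0.15–0.4 Hz) ranges and carry 90% of the programmed variance, split so
that their power ratio equals the target LF/HF; the AR(1) carries the
remaining 10% as broadband floor. This is deliberately the simplest
process with independently controllable mean, SD, and LF/HF balance —
the only three properties the downstream features depend on; it is not
an integral-pulse-frequency-modulation cardiac model. Two numerical
details matter:

- *Length-bias compensation.* Sampling the modulation at beat times
  oversamples short intervals, depressing the beat-domain mean by
  ≈ σ²/µ (about 3 ms at µ = 0.8 s, σ = 50 ms); the base level is raised
  by σ²/µ so the realized mean matches the requested one.
- Intervals are floored at 0.25·µ to exclude nonphysical beats; with
  default parameters the floor is never hit in practice.

**ECG morphology.** A fixed sum-of-Gaussians PQRST template (R apex
1 mV; P 0.12 mV at −200 ms; Q −0.10 mV at −35 ms; S −0.18 mV at
+35 ms; T 0.30 mV at +220 ms) is placed at each cumulative RR time,
with R apexes snapped to the sample grid so ground-truth peak times are
exact sample maxima in the noiseless limit. Additive noise comprises
sinusoidal baseline wander (default 0.1 mV at 0.25 Hz), a powerline
sinusoid (default 0.05 mV at 60 Hz; 50 Hz configurable), and white
broadband noise (default 0.05 mV; 0.316 mV ≈ 10 dB SNR at the R peak).

**Skin conductance.** The tonic level is a constant plus a slow
sinusoidal drift (0.2 µS at 0.01 Hz). Phasic events follow a Poisson
process thinned to a 5 s minimum gap — kept resolvable by the 1 Hz /
2 s smoothing chain — with the driving intensity raised by
λ′ = λ/(1 − λ·gap) so the *realized* rate matches the requested one.
Each event adds an amplitude-normalized biexponential (Bateman)
response `A·(e^(−t/τ_d) − e^(−t/τ_r))/b_max` with τ_r = 0.75 s,
τ_d = 2.0 s by default, so the peak above tonic equals the drawn
amplitude `A` exactly (log-normal, σ = 0.4, mean = the class
`scr_amp_mean`). White measurement noise (default 0.02 µS) is added.

**Classes and the task shift.** Each class is described by baseline
parameters (mean RR, SDNN, LF/HF, SCR rate, SCR amplitude, tonic level)
and a single dimensionless `task_shift` applied when deriving
task-segment parameters (heart rate, LF/HF, SCR rate/amplitude and
tonic level scale with it; mean RR scales by its inverse). Because
features are baseline-normalized ratios, class separability is carried
by the *shift*, not by absolute baseline levels: experts default to a
mild task response (shift 1.08), novices to a strong one (1.35),
encoding the premise that task load — and hence the autonomic response
— varies inversely with expertise. Per-subject parameters are
log-normally jittered (4% relative SD; 2% on the shift). A null cohort
is obtained by giving both classes identical parameters. No public
distributional statistics exist for the target population, so these
defaults are documented choices, not claims of fidelity; the generator
also omits motion artifacts, ectopy, sensor dropout, and
non-stationarity beyond the single baseline→task shift, so passing
tests demonstrate correct *recovery machinery*, not field performance.

## ECG processing

The QRS detector follows the Pan–Tompkins design: zero-phase 3rd-order
Butterworth bandpass 5–15 Hz (effective order 6 forward–backward; zero
phase avoids R-latency shift), the classic 5-point derivative
`y(n) = fs/8·[2x(n)+x(n−1)−x(n−3)−2x(n−4)]`, rectification, and a
150 ms moving-window integration. Rectification is the **absolute
value** by default, with the original squaring available behind
`rectify="square"`; the two differ in noise contrast (squaring
suppresses the noise floor quadratically), which is why detection keeps
the full dual-domain threshold scheme below.

Peak decisions use parallel adaptive threshold pairs on *both* the
integrated and the bandpassed waveforms: running signal/noise levels
updated as `SPK ← 0.125·peak + 0.875·SPK` (noise analogously),
`T1 = NPK + 0.25·(SPK − NPK)`, `T2 = 0.5·T1`, a 200 ms refractory
period, and a search-back pass against `T2` whenever no beat is
accepted for 2 s (search-back acceptances update `SPK` with weight
0.25). Accepted peaks are re-localized to the bandpassed signal's local
maximum within ±75 ms so RR intervals are not biased by integration
lag. Thresholds are level-derived, making detection exactly invariant
to global amplitude scaling. RR intervals outside 0.3–2.0 s are flagged
and excluded from feature computation but retained in output.

Measured on synthetic ground truth (±50 ms match): sensitivity and
positive predictivity are 1.0 noiseless and ≈ 0.99 / 0.96 at 10 dB
broadband SNR, pooled over 20 independent 60 s records.

## GSR processing

The filter chain is a zero-phase 4th-order Butterworth low-pass at
1 Hz followed by a centered 2 s moving average (1000 samples at the
nominal 500 Hz; the size is rate-relative so other rates behave
equivalently), reflect-padded at the edges. SCR *detection* finds local
maxima with prominence ≥ 0.01 µS (a ripple guard) on the fully
filtered trace; event *values* are read from the low-pass-only trace,
because the 2 s average — an artifact-suppression step — attenuates a
default-morphology SCR peak by ~13% and would bias every amplitude
feature. Onset is the preceding local minimum refined to the foot of
the rise (last sample within 5% of the amplitude above the minimum;
the raw minimum sits ~0.3 s early on filtered traces due to filter
pre-ringing). Amplitude is peak minus onset value; half-recovery is the
first post-peak crossing of onset + Amp/2, *censored* (flagged, NaN)
when the next event's onset or the segment end intervenes; area is the
trapezoidal integral of the signal above onset value from onset to the
half-recovery or censoring point, floored at 0; prominence is the peak
value above the skin-conductance level. Censoring rather than dropping
keeps event counts honest; censored half-recoveries are excluded from
window aggregates. No tonic/phasic deconvolution is attempted — the
pipeline is peak-based by design.

## Features

ECG features are computed on 10 s windows stepped by 5 s; GSR features
on 30 s windows stepped by 20 s. Windows with fewer than 3 plausible
RR intervals (or fewer than 4 tachogram points for spectra, or zero
SCRs for event aggregates) are marked missing rather than raising.

*ECG time domain* (per window): RR min/max/range/mean/SD, coefficient
of variation, SDSD, NN50 and pNN50. NN50 counts successive-difference
magnitudes above 50 ms — the standard HRV definition — and
pNN50 = 100·NN50/(n−1). Exactly-constant windows return exact zeros
for the spread statistics (float round-off in the mean otherwise leaks
~1e−16).

*ECG frequency domain*: the unevenly sampled tachogram's Lomb–Scargle
periodogram, evaluated on a fixed 0.001–0.4 Hz grid (step 0.001 Hz)
and scaled to a one-sided PSD (s²/Hz) so that band powers are
trapezoidal integrals over ULF (<0.003 Hz), VLF (0.003–0.04), LF
(0.04–0.15), HF (0.15–0.4) and TP (0–0.4); on evenly sampled data this
normalization reproduces an FFT periodogram's band powers (verified to
<0.1%). Derived ratios: LF_norm = 100·LF/(LF+HF), HF_norm analogously,
LF/HF, and LMHF = (LF+MF)/HF with MF = 0.08–0.15 Hz. HF = 0 marks the
ratios missing. Caveat stated plainly: ULF and VLF are not physically
resolvable inside a 10 s window; they are integrals of spectral
leakage, retained because the downstream workflow expects the full
18-feature set, and they carry little stable information.

*GSR* (per window): mean/min/max/SD of rise time, half-recovery time,
amplitude, area and prominence across events peaking in the window
(20 values); the skin-conductance level (window mean); mean absolute
first and second sample differences of the window; Welch band power
over 0.01–1 Hz; and total periodogram power over 0–1 Hz.

*Baseline normalization*: task windows are divided elementwise by a
per-subject baseline vector. For ECG and the scalar GSR features the
baseline vector is the mean over baseline windows (same windowing);
the GSR *event* statistics instead pool all events of the 2 min
baseline segment, because 30 s baseline windows hold 0–2 events and
their per-window SDs are frequently exactly 0, which would make the
ratio undefined and silently delete whole subjects. Baseline entries
with magnitude below 1e−9 mark the ratio missing (never ±∞).

*Assembly*: ECG and GSR matrices use their own windows as rows; the
multimodal matrix anchors on GSR windows and joins each with the mean
of the ECG feature vectors whose windows overlap it. Feature columns
missing in more than 40% of rows are dropped (logged), then rows with
any remaining missing value are dropped (logged); nothing is imputed.

## Feature selection

`LassoFeatureRanker` standardizes features internally and fits an
L1-penalized linear regression of the 0/1 label (a logistic variant is
available). The penalty is chosen by 5-fold cross-validation with the
one-standard-error rule — the largest penalty whose CV error is within
one SE of the minimum — which is markedly more stable than the raw CV
minimum and is the calibration under which a fixed |coefficient| > 0.01
cutoff behaves sensibly (pure-noise coefficients stay below it).
CV folds are assigned by content-hash of each row, making the fit
exactly invariant to row duplication and row order. Selection keeps
features with |coefficient| strictly above the cutoff, ordered by
magnitude (ties by name); an empty selection warns and falls back to
the full feature set. Coefficients are reported on the standardized
scale, so their magnitudes depend on that convention and are not
comparable across scalings. By default selection sees all subjects
(matching the workflow this package reproduces); note this leaks label
information across LOSO folds — fit the ranker inside each training
fold for a leakage-safe protocol.

## Classification and evaluation

Four classifiers are wrapped behind one estimator: SVM with the
inhomogeneous quadratic kernel (x·yᵀ+1)², C = 1 (the homogeneous
coef0 = 0 variant is sign-blind after standardization and was measurably
broken on symmetric clusters); a Gini decision tree (unbounded depth);
a 100-tree random forest; and 5-nearest-neighbours with uniform
Euclidean weighting. Standardization is fit on training rows only.

Evaluation is leave-one-subject-out: each fold tests all windows of one
subject. Confusion counts take "expert" as positive; accuracy,
precision, recall and F1 follow the standard confusion-matrix formulas
with undefined divisions returning 0 plus a flag. Because every LOSO
test set is single-class, precision and recall are undefined on
negative-class folds; the default `mean-over-folds` aggregate therefore
averages each metric over the folds where it is defined, and a
`pooled-windows` mode (metrics from summed counts) is provided and is
the better-behaved summary for F1. A caution this package's null
simulations make visible: subject-level holdout on null data often
lands *below* 0.5 (mean ≈ 0.42 over 10 null cohorts) — the familiar
anti-learning effect of leave-one-group-out with few groups — so
"chance" under LOSO is a band, not a point.

t-SNE projects a standardized matrix to 2-D (perplexity 30, reduced
with a warning when rows < 3·perplexity; 10,000 iterations; learning
rate 10; PCA initialization; fixed seed) and reports the class
silhouette on the embedding as a scalar separability summary —
visualization plumbing, not an inferential statistic.

## Problem sizes used in validation

Detector oracles use 20 independent 60 s (ECG) or 300 s (GSR) records
per condition; moment-recovery checks use 30 seeds of 600 s; the
planted-LASSO design uses n = 500 with 1 informative + 17 noise
features over 50 seeds; discrimination uses one separated 5+5 cohort
(2 min baseline, 10 min task per subject) and ten 5+5 null cohorts.
These sizes were chosen so each check is decisively powered while the
whole validation remains desk-scale.

## Known limitations

- Generator realism is limited as described above; absolute feature
  values (especially ULF/VLF and the GSR spectral scalars) should not
  be interpreted physiologically.
- The default selection protocol leaks labels (by design, for
  fidelity to the reproduced workflow); use in-fold selection for
  honest generalization estimates.
- Multimodal window pairing (GSR-anchored, overlapping-ECG averaging)
  is one of several defensible alignments; results can differ under
  others.
- Fold-mean F1 under LOSO reflects only positive-class folds; prefer
  the pooled mode when comparing F1 across configurations.
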