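import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.signal import periodogram

from physiopipe.features import (
    BANDS,
    ECG_FEATURES,
    GSR_FEATURES,
    assemble_matrix,
    baseline_normalize,
    ecg_freq_features,
    ecg_time_features,
    ecg_window_features,
    gsr_window_features,
    lomb_band_powers,
    segment,
)
from physiopipe.types import InvalidParameterError, RRSeries, SCREvent


class TestSegment:
    @pytest.mark.parametrize("duration,window,overlap,expected", [
        (600, 10, 5, 119),
        (600, 30, 10, 29),
        (10, 10, 5, 1),
        (120, 10, 5, 23),
        (120, 30, 10, 5),
    ])
    def test_window_counts(self, duration, window, overlap, expected):
        wins = segment(duration, window, overlap)
        assert len(wins) == expected
        assert wins[0] == (0, window)
        assert all(end <= duration for _, end in wins)

    def test_overlap_must_be_smaller_than_window(self):
        with pytest.raises(InvalidParameterError):
            segment(100, 10, 10)

    @settings(max_examples=100, deadline=None)
    @given(
        duration=st.integers(10, 2000),
        window=st.integers(1, 100),
        overlap=st.integers(0, 99),
    )
    def test_count_matches_brute_force(self, duration, window, overlap):
        if overlap >= window or window > duration:
            return
        wins = segment(duration, window, overlap)
        step = window - overlap
        brute = [
            (k * step, k * step + window)
            for k in range(duration + 1)
            if k * step + window <= duration
        ]
        assert wins == brute


class TestEcgTimeFeatures:
    def test_constant_intervals(self):
        f = ecg_time_features([0.8, 0.8, 0.8])
        assert f["RR_mean"] == pytest.approx(0.8)
        for k in ("RR_SD", "RR_CV", "SDSD", "NN50", "PNN50"):
            assert f[k] == 0.0

    def test_hand_computed_case(self):
        f = ecg_time_features([0.80, 0.86, 0.90, 0.91])
        assert f["NN50"] == 1
        assert f["PNN50"] == pytest.approx(100 / 3)
        assert f["RR_diff"] == pytest.approx(0.11)

    def test_too_few_intervals_marked_missing(self):
        assert ecg_time_features([0.8, 0.8]) is None

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(0.3, 2.0), min_size=3, max_size=40))
    def test_order_statistics(self, intervals):
        f = ecg_time_features(intervals)
        tol = 1e-12
        assert f["RR_min"] - tol <= f["RR_mean"] <= f["RR_max"] + tol
        assert f["RR_diff"] == pytest.approx(f["RR_max"] - f["RR_min"])
        assert f["RR_SD"] >= 0 and f["SDSD"] >= 0


class TestLombBandPowers:
    def test_constant_series_zero_power(self):
        t = np.cumsum(np.full(20, 0.8))
        bands = lomb_band_powers(t, np.full(20, 0.8))
        for k in BANDS:
            assert bands[k] < 1e-10

    def test_lf_modulation_dominates(self):
        t = np.cumsum(np.full(120, 0.8))
        y = 0.8 + 0.05 * np.sin(2 * np.pi * 0.1 * t)
        bands = lomb_band_powers(t, y)
        assert bands["LF"] > 10 * bands["HF"]

    def test_matches_fft_on_even_sampling(self):
        """Even tachogram whose Fourier grid matches the Lomb grid:
        every band power within 5% of the FFT periodogram oracle."""
        rng = np.random.default_rng(3)
        dt, n = 0.8, 1250       # 1000 s -> Fourier step 0.001 Hz
        t = np.arange(1, n + 1) * dt
        y = (
            0.8
            + 0.02 * np.sin(2 * np.pi * 0.002 * t)
            + 0.02 * np.sin(2 * np.pi * 0.02 * t)
            + 0.03 * np.sin(2 * np.pi * 0.10 * t)
            + 0.02 * np.sin(2 * np.pi * 0.25 * t)
            + rng.normal(0, 0.01, n)
        )
        bands = lomb_band_powers(t, y)
        f, p = periodogram(y, fs=1 / dt, detrend="constant")
        for name, (lo, hi) in BANDS.items():
            m = (f >= lo - 1e-12) & (f <= hi + 1e-12)
            oracle = np.trapezoid(p[m], f[m])
            assert bands[name] == pytest.approx(oracle, rel=0.05)

    def test_band_additivity(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            rr = 0.8 + rng.normal(0, 0.05, 60)
            t = np.cumsum(rr)
            b = lomb_band_powers(t, rr)
            assert b["ULF"] + b["VLF"] + b["LF"] + b["HF"] <= b["TP"] * 1.01

    def test_too_few_points_missing(self):
        assert lomb_band_powers(np.array([1, 2, 3.0]), np.ones(3)) is None


class TestEcgFreqFeatures:
    def test_equal_lf_hf_symmetry(self):
        bands = {"ULF": 0, "VLF": 0, "LF": 2.0, "HF": 2.0, "TP": 4.0, "_MF": 0.0}
        f = ecg_freq_features(bands)
        assert f["LF_norm"] == f["HF_norm"] == 50.0
        assert f["LF_HF"] == 1.0
        assert f["LMHF"] == f["LF_HF"]      # MF = 0 degenerates to LF/HF

    def test_lmhf_at_least_lf_hf(self):
        bands = {"ULF": 0, "VLF": 0, "LF": 3.0, "HF": 1.5, "TP": 4.5, "_MF": 0.7}
        f = ecg_freq_features(bands)
        assert f["LMHF"] >= f["LF_HF"]

    def test_zero_hf_marked_missing(self):
        bands = {"ULF": 0, "VLF": 0, "LF": 1.0, "HF": 0.0, "TP": 1.0, "_MF": 0.0}
        f = ecg_freq_features(bands)
        assert np.isnan(f["LF_HF"]) and np.isnan(f["LMHF"])


def make_event(onset, peak_t, amp, peak_value, censored=False, hrt=2.0):
    return SCREvent(
        onset_time=onset,
        peak_time=peak_t,
        half_recovery_time=float("nan") if censored else peak_t + hrt,
        censored=censored,
        rise_time=peak_t - onset,
        half_recovery_duration=float("nan") if censored else hrt,
        amplitude=amp,
        area=amp * 2.0,
        prominence=amp,
        peak_value=peak_value,
        onset_value=peak_value - amp,
    )


class TestGsrWindowFeatures:
    def test_constant_signal_without_events(self):
        f = gsr_window_features(np.full(15_000, 4.2), 500, [])
        assert f["SCL"] == pytest.approx(4.2)
        assert f["MAV1Diff_SCL"] == 0 and f["MAV2Diff_SCL"] == 0
        assert f["BP"] < 1e-12
        assert np.isnan(f["RT_mean"]) and np.isnan(f["Amp_SD"])

    def test_two_identical_events_zero_spread(self):
        ev = [make_event(1.0, 2.5, 0.5, 5.5), make_event(10.0, 11.5, 0.5, 5.5)]
        f = gsr_window_features(np.full(15_000, 5.0), 500, ev)
        for field in ("RT", "HRT", "Amp", "Area", "Prom"):
            assert f[f"{field}_SD"] == 0.0
            assert f[f"{field}_min"] == f[f"{field}_max"]

    def test_censored_hrt_excluded(self):
        ev = [make_event(1.0, 2.5, 0.5, 5.5), make_event(10.0, 11.5, 0.4, 5.4, censored=True)]
        f = gsr_window_features(np.full(15_000, 5.0), 500, ev)
        assert f["HRT_SD"] == 0.0           # only the uncensored event counts
        assert f["Amp_SD"] > 0              # both events count for Amp


class TestBaselineNormalize:
    def test_identity(self):
        row = pd.Series({"RR_mean": 0.8, "SCL": 5.0})
        out = baseline_normalize(row, row)
        assert np.allclose(out.values, 1.0)

    def test_simple_ratio(self):
        out = baseline_normalize({"RR_mean": 0.9}, {"RR_mean": 0.75})
        assert out["RR_mean"] == pytest.approx(1.2)

    def test_zero_baseline_marked_missing(self):
        out = baseline_normalize({"NN50": 3.0}, {"NN50": 0.0})
        assert np.isnan(out["NN50"])

    def test_name_mismatch_rejected(self):
        with pytest.raises(InvalidParameterError):
            baseline_normalize({"a": 1.0}, {"b": 1.0})

    def test_baseline_equals_task_gives_all_ones(self):
        """A window normalized against itself is exactly 1 everywhere."""
        rng = np.random.default_rng(0)
        peaks = np.cumsum(rng.uniform(0.7, 0.9, 20))
        rr = RRSeries.from_peaks(peaks)
        feats = pd.Series(ecg_window_features(rr, 0.0, peaks[-1] + 1))
        out = baseline_normalize(feats, feats)
        defined = out.dropna()
        assert len(defined) >= 15
        assert np.allclose(defined.values, 1.0)


class TestAssembleMatrix:
    def _toy_subject(self, sid, label, seed, nan_at=None):
        rng = np.random.default_rng(seed)
        ecg = pd.DataFrame(rng.uniform(0.5, 1.5, (23, len(ECG_FEATURES))),
                           columns=ECG_FEATURES)
        ecg.insert(0, "w_start", np.arange(23) * 5.0)
        ecg.insert(1, "w_end", np.arange(23) * 5.0 + 10.0)
        gsr = pd.DataFrame(rng.uniform(0.5, 1.5, (5, len(GSR_FEATURES))),
                           columns=GSR_FEATURES)
        gsr.insert(0, "w_start", np.arange(5) * 20.0)
        gsr.insert(1, "w_end", np.arange(5) * 20.0 + 30.0)
        if nan_at is not None:
            gsr.loc[nan_at, "SCL"] = np.nan
        return {"subject_id": sid, "label": label, "ecg": ecg, "gsr": gsr,
                "ecg_raw": ecg, "gsr_raw": gsr}

    def test_row_counts_per_modality(self):
        subs = [self._toy_subject("a", "expert", 0), self._toy_subject("b", "novice", 1)]
        assert len(assemble_matrix(subs, "ecg")) == 46
        assert len(assemble_matrix(subs, "gsr")) == 10
        m = assemble_matrix(subs, "multimodal")
        assert len(m) == 10
        assert set(m.feature_names) == set(ECG_FEATURES) | set(GSR_FEATURES)

    def test_single_missing_cell_drops_one_row(self):
        subs = [self._toy_subject("a", "expert", 0, nan_at=2),
                self._toy_subject("b", "novice", 1)]
        assert len(assemble_matrix(subs, "gsr")) == 9

    def test_mostly_missing_column_dropped_not_rows(self):
        subs = [self._toy_subject("a", "expert", 0), self._toy_subject("b", "novice", 1)]
        for s in subs:
            s["gsr"]["PSD"] = np.nan
        m = assemble_matrix(subs, "gsr")
        assert "PSD" not in m.feature_names
        assert len(m) == 10


class TestPipelineRecovery:
    def test_task_shift_reflected_in_rr_mean(self, separated_cohort, separated_tables):
        """Normalized RR_mean tracks 1/task_shift within 5% per subject."""
        for rec, sub in zip(separated_cohort, separated_tables):
            expected = 1.0 / rec.truth.params.task_shift
            observed = sub["ecg"]["RR_mean"].mean()
            assert observed == pytest.approx(expected, rel=0.05)
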