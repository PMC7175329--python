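"""R-peak detection against generator ground truth; HRV indices and
sample entropy against brute-force reference implementations."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mrrecg.hrv import (
    HRVFeatures,
    InsufficientBeatsError,
    RRSeries,
    detect_rpeaks,
    hrv_features,
    hrv_features_for_record,
    sample_entropy,
)
from mrrecg.synth import RHYTHM_LIBRARY, RhythmSpec, generate_record, ground_truth_rpeaks


def rr_series(rr_ms, fs=500.0, duration_s=None):
    rr_ms = np.asarray(rr_ms, dtype=float)
    idx = np.concatenate([[0.0], np.cumsum(rr_ms)]) / 1000.0 * fs
    duration = duration_s or (idx[-1] / fs + 1.0)
    return RRSeries(rr_ms, idx.astype(np.int64), fs, duration)


def sample_entropy_oracle(series, m, r):
    """Independent double-loop template counter."""
    series = np.asarray(series, dtype=float)
    n = len(series)
    n_templates = n - m

    def count(length):
        c = 0
        for i in range(n_templates):
            for j in range(n_templates):
                if i == j:
                    continue
                if max(abs(series[i + k] - series[j + k]) for k in range(length)) <= r:
                    c += 1
        return c

    b = count(m)
    a = count(m + 1)
    if a == 0 or b == 0:
        return np.inf
    return -np.log(a / b)


class TestDetector:
    def test_recovers_10_peaks_at_60bpm(self):
        spec = RhythmSpec("Normal sinus rhythm", 60.0, rr_jitter_sd=0.0)
        rec = generate_record(spec, fs=500.0, duration_s=10.0, seed=21)
        rr = detect_rpeaks(rec.lead("II"), rec.fs)
        assert rr.n_peaks == 10
        # all RR intervals 1000 ms to within one sample (2 ms at 500 Hz)
        np.testing.assert_allclose(rr.rr_ms, 1000.0, atol=2.0)

    def test_flat_signal_raises(self):
        with pytest.raises(InsufficientBeatsError):
            detect_rpeaks(np.zeros(5000), 500.0)

    @pytest.mark.parametrize("class_name", ["Sinus bradycardia", "Sinus tachycardia",
                                            "Normal sinus rhythm"])
    def test_recall_at_least_95_percent_at_20db(self, class_name):
        hits = total = 0
        for seed in range(5):
            rec = generate_record(
                RHYTHM_LIBRARY[class_name], fs=500.0, duration_s=10.0,
                seed=seed, snr_db=20.0,
            )
            truth = ground_truth_rpeaks(rec)
            rr = detect_rpeaks(rec.lead("II"), rec.fs)
            det_times = rr.r_peak_indices / rec.fs
            for t in truth:
                if np.min(np.abs(det_times - t)) <= 0.05:  # +-50 ms
                    hits += 1
            total += len(truth)
        assert hits / total >= 0.95

    def test_refractory_period_enforced(self):
        rec = generate_record(
            RHYTHM_LIBRARY["Sinus tachycardia"], fs=500.0, duration_s=10.0,
            seed=2, snr_db=20.0,
        )
        rr = detect_rpeaks(rec.lead("II"), rec.fs)
        assert (np.diff(rr.r_peak_indices) >= 0.2 * rec.fs).all()


class TestHRVFeatures:
    def test_hand_arithmetic_example(self):
        feats = hrv_features(rr_series([800, 850, 900]))
        assert feats.rr_mean == 850
        assert feats.rr_max == 900
        assert feats.rr_min == 800
        # population SD of {800, 850, 900} = sqrt(5000/3)
        assert feats.sdnn == pytest.approx(40.8248, abs=1e-3)
        assert feats.rmssd == pytest.approx(50.0)
        assert feats.pnn50 == 0.0  # differences of exactly 50 are not counted

    def test_constant_series_all_zero_variability(self):
        feats = hrv_features(rr_series([1000] * 9))
        assert feats.sdnn == 0 and feats.rmssd == 0 and feats.pnn50 == 0
        assert feats.sampen_m1 == 0 and feats.sampen_m2 == 0

    def test_pnn50_strict_inequality(self):
        feats = hrv_features(rr_series([800, 860, 805]))
        assert feats.pnn50 == 1.0  # |+60| and |-55| both exceed 50

    def test_r_density_is_peaks_per_second(self):
        s = rr_series([1000] * 9, duration_s=10.0)
        assert hrv_features(s).r_density == pytest.approx(1.0)

    def test_matches_naive_formulas_on_random_series(self, rng):
        for _ in range(1000):
            n = int(rng.integers(3, 30))
            rr = rng.uniform(400, 1400, size=n)
            feats = hrv_features(rr_series(rr))
            d = np.diff(rr)
            assert feats.rr_mean == pytest.approx(sum(rr) / n)
            assert feats.rr_max == max(rr) and feats.rr_min == min(rr)
            assert feats.sdnn == pytest.approx(
                (sum((x - sum(rr) / n) ** 2 for x in rr) / n) ** 0.5
            )
            assert feats.rmssd == pytest.approx(
                (sum(x**2 for x in d) / len(d)) ** 0.5
            )
            assert feats.pnn50 == pytest.approx(
                sum(1 for x in d if abs(x) > 50) / len(d)
            )

    def test_invariant_order_and_exactly_nine(self):
        feats = hrv_features(rr_series([800, 850, 900, 870, 910]))
        assert len(feats.to_array()) == 9
        assert feats.rr_min <= feats.rr_mean <= feats.rr_max
        assert feats.rmssd >= 0 and 0 <= feats.pnn50 <= 1

    def test_neutral_sentinel_for_undetectable_record(self):
        from mrrecg.io import ECGRecord, LabelVector, CANONICAL_LEADS

        rec = ECGRecord(
            "flat", np.zeros((8, 2000)), 200.0, CANONICAL_LEADS, 50, "male",
            LabelVector.from_names((), ("A",)),
        )
        feats = hrv_features_for_record(rec)
        assert not feats.valid
        np.testing.assert_array_equal(feats.to_array(), 0.0)


class TestSampleEntropy:
    def test_constant_series_is_zero(self):
        assert sample_entropy(np.full(12, 5.0), 1, 0.5) == 0.0
        assert sample_entropy(np.full(12, 5.0), 2, 0.1) == 0.0

    def test_alternating_series_matches_brute_force(self):
        series = np.array([1, 2, 1, 2, 1, 2, 1, 2], dtype=float)
        got = sample_entropy(series, 1, 0.1)
        expected = sample_entropy_oracle(series, 1, 0.1)
        assert got == pytest.approx(expected)

    def test_ramp_with_tiny_tolerance_hits_sentinel(self):
        series = np.arange(10, dtype=float)
        assert sample_entropy(series, 1, 0.1) == np.inf

    def test_matches_brute_force_on_random_series(self, rng):
        for _ in range(300):
            n = int(rng.integers(6, 14))
            series = rng.normal(size=n)
            r = float(rng.uniform(0.1, 1.0))
            for m in (1, 2):
                got = sample_entropy(series, m, r)
                expected = sample_entropy_oracle(series, m, r)
                if np.isinf(expected):
                    assert np.isinf(got)
                else:
                    assert got == pytest.approx(expected)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        offset=st.floats(-50, 50),
        scale=st.floats(0.1, 10),
    )
    def test_shift_invariance_and_coscaling(self, offset, scale):
        rng = np.random.default_rng(7)
        series = rng.normal(size=12)
        base = sample_entropy(series, 1, 0.4)
        assert sample_entropy(series + offset, 1, 0.4) == pytest.approx(base)
        assert sample_entropy(series * scale, 1, 0.4 * scale) == pytest.approx(base)

    def test_degenerate_length_rejected(self):
        with pytest.raises(ValueError):
            sample_entropy(np.array([1.0, 2.0]), 2, 0.5)
        with pytest.raises(ValueError):
            sample_entropy(np.arange(5.0), 1, 0.0)
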