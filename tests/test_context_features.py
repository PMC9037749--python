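"""RR-context feature maps: beat regions, relative RR, sample entropy."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from weakbeat import context_features as cf
from weakbeat.synthetic_ecg import SynthSpec, generate_record


def brute_force_sampen(x, m, r, cap=None):
    """Independent O(n^2) pair-enumeration oracle."""
    x = np.asarray(x, dtype=float)
    n = len(x)

    def count(length):
        # standard convention: n - m templates at both lengths m and m+1
        total = 0
        for i in range(n - m):
            for j in range(i + 1, n - m):
                if max(abs(x[i + k] - x[j + k]) for k in range(length)) <= r:
                    total += 1
        return total

    b = count(m)
    a = count(m + 1)
    n_pairs = (n - m) * (n - m - 1) // 2
    cap_val = cap if cap is not None else np.log(n_pairs + 1)
    if b == 0:
        return cap_val
    if a == 0:
        return min(cap_val, np.log(b + 1))
    return -np.log(a / b)


class TestBeatRegions:
    @pytest.mark.parametrize("peaks,n,expected", [
        ([100, 200, 300], 400, [(0, 150), (150, 250), (250, 400)]),
        ([200], 400, [(0, 400)]),
        ([0, 10], 20, [(0, 5), (5, 20)]),
    ])
    def test_midpoint_partition(self, peaks, n, expected):
        regions = cf.beat_regions(cf.RPeakSet(np.array(peaks), 125.0), n)
        assert regions == expected

    def test_regions_partition_signal(self, rng):
        peaks = np.sort(rng.choice(5000, size=40, replace=False))
        regions = cf.beat_regions(cf.RPeakSet(peaks, 125.0), 5000)
        assert regions[0][0] == 0 and regions[-1][1] == 5000
        for (a, b), (c, d) in zip(regions[:-1], regions[1:]):
            assert b == c and a < b

    def test_no_peaks_single_region(self):
        assert cf.beat_regions(cf.RPeakSet(np.array([], dtype=int), 125.0), 100) == [(0, 100)]


class TestRelativeRR:
    def test_regular_rhythm_all_zero(self):
        peaks = np.arange(0, 2500, 100)
        fmap = cf.relative_rr_map(cf.RPeakSet(peaks, 125.0), 2500)
        np.testing.assert_allclose(fmap.values, 0.0, atol=1e-12)

    def test_direct_substitution(self):
        # context mean 0.8 s, current RR 0.4 s, s=10 -> 10*(0.8-0.4)/0.8 = 5
        # RRs (samples at 125 Hz): six of 100 then one of 50; context window
        # covers all intervals
        peaks = np.array([0, 100, 200, 300, 400, 500, 550])
        cfg = cf.FeatureConfig(context_len=6)
        fmap = cf.relative_rr_map(cf.RPeakSet(peaks, 125.0), 600, cfg)
        rr = np.diff(peaks)
        i_n = rr.mean()
        expected = 10 * (i_n - 50) / i_n
        assert fmap.values[560] == pytest.approx(expected)

    def test_windowed_mean_matches_brute_force_oracle(self):
        # 61 equal RRs of 0.8 s with one long RR of 1.2 s in the middle
        rr = np.full(62, 100)
        rr[31] = 150
        peaks = np.concatenate([[0], np.cumsum(rr)])
        rpeaks = cf.RPeakSet(peaks, 125.0)
        cfg = cf.FeatureConfig(context_len=60, scale_s=10.0)
        fmap = cf.relative_rr_map(rpeaks, int(peaks[-1]) + 50, cfg)
        regions = cf.beat_regions(rpeaks, int(peaks[-1]) + 50)
        # oracle: explicit clamped-window enumeration per beat
        for beat in range(1, len(peaks)):
            j = beat - 1
            width = min(60, len(rr))
            start = min(max(j - 60 // 2, 0), len(rr) - width)
            i_n = rr[start : start + width].mean()
            expected = 10.0 * (i_n - rr[j]) / i_n
            lo, hi = regions[beat]
            np.testing.assert_allclose(fmap.values[lo:hi], expected, atol=1e-12)

    def test_first_beat_inherits_second(self):
        peaks = np.array([100, 200, 250, 350])
        fmap = cf.relative_rr_map(cf.RPeakSet(peaks, 125.0), 400)
        assert fmap.values[0] == fmap.values[160]

    def test_time_rescaling_invariance(self):
        peaks = np.array([0, 90, 200, 280, 400, 520])
        a = cf.relative_rr_map(cf.RPeakSet(peaks, 125.0), 600)
        b = cf.relative_rr_map(cf.RPeakSet(peaks * 2, 125.0), 1200)
        regions_a = cf.beat_regions(cf.RPeakSet(peaks, 125.0), 600)
        regions_b = cf.beat_regions(cf.RPeakSet(peaks * 2, 125.0), 1200)
        for (la, _), (lb, _) in zip(regions_a, regions_b):
            assert a.values[la] == pytest.approx(b.values[lb])

    def test_single_peak_warns_zero_map(self):
        with pytest.warns(UserWarning):
            fmap = cf.relative_rr_map(cf.RPeakSet(np.array([50]), 125.0), 100)
        np.testing.assert_array_equal(fmap.values, 0.0)

    def test_shortened_rr_gives_positive_value(self):
        peaks = np.array([0, 100, 200, 250, 350, 450])  # one premature beat
        fmap = cf.relative_rr_map(cf.RPeakSet(peaks, 125.0), 500)
        assert fmap.values[230] > 0  # region of the premature beat


class TestSampEn:
    def test_constant_sequence_zero(self):
        assert cf.sampen(np.full(50, 0.8), m=1, r=0.05) == 0.0

    def test_alternating_sequence_matches_enumeration(self):
        x = np.array([1.0, 1.1, 1.0, 1.1, 1.0, 1.1])
        assert cf.sampen(x, 1, 0.05) == pytest.approx(brute_force_sampen(x, 1, 0.05))

    def test_monotone_sequence_hits_cap(self):
        x = np.arange(10) * 1.0  # steps 1 >> r
        n_pairs = 9 * 8 // 2
        assert cf.sampen(x, 1, 0.05) == pytest.approx(np.log(n_pairs + 1))

    def test_too_short_returns_nan(self):
        assert np.isnan(cf.sampen(np.array([1.0, 2.0]), m=1, r=0.05))

    def test_matches_brute_force_on_random_sequences(self, rng):
        for _ in range(25):
            n = int(rng.integers(5, 60))
            x = rng.normal(1.0, 0.05, size=n)
            assert cf.sampen(x, 1, 0.05) == pytest.approx(
                brute_force_sampen(x, 1, 0.05), abs=0)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.5, 1.5), min_size=4, max_size=40),
           st.integers(1, 2))
    def test_property_matches_oracle(self, seq, m):
        x = np.asarray(seq)
        assert cf.sampen(x, m, 0.05) == pytest.approx(
            brute_force_sampen(x, m, 0.05), abs=1e-12)


class TestRREntropyMap:
    def test_regular_rhythm_zero_everywhere(self):
        peaks = np.arange(0, 2500, 100)
        fmap = cf.rr_entropy_map(cf.RPeakSet(peaks, 125.0), 2500)
        np.testing.assert_allclose(fmap.values, 0.0, atol=1e-12)

    def test_short_record_single_window_painted_everywhere(self):
        # 10 beats -> 9 RRs < 60: one SampEn value over all RRs
        rr = np.array([100, 50, 100, 55, 100, 45, 100, 60, 100])
        peaks = np.concatenate([[0], np.cumsum(rr)])
        fmap = cf.rr_entropy_map(cf.RPeakSet(peaks, 125.0), int(peaks[-1]) + 10)
        expected = brute_force_sampen(rr / np.median(rr), 1, 0.05)
        np.testing.assert_allclose(fmap.values, expected)

    def test_long_bigeminy_matches_windowed_oracle(self):
        # alternating short/long RRs with physiological jitter (an exactly
        # periodic alternation would be predictable and score entropy 0)
        rng = np.random.default_rng(7)
        rr = np.empty(80, dtype=int)
        rr[0::2] = 70 + rng.integers(-8, 9, 40)
        rr[1::2] = 130 + rng.integers(-8, 9, 40)
        peaks = np.concatenate([[0], np.cumsum(rr)])
        n = int(peaks[-1]) + 10
        rpeaks = cf.RPeakSet(peaks, 125.0)
        fmap = cf.rr_entropy_map(rpeaks, n)
        assert (fmap.values > 0).all()
        # oracle at an interior painted beat
        rr_norm = rr / np.median(rr)
        start = 5
        expected = brute_force_sampen(rr_norm[start : start + 60], 1, 0.05)
        central = start + 30
        regions = cf.beat_regions(rpeaks, n)
        lo, hi = regions[central]
        np.testing.assert_allclose(fmap.values[lo:hi], expected)

    def test_piecewise_constant_on_regions(self):
        spec = SynthSpec(seed=11, rhythm="af_like")
        rec = generate_record(spec)
        rpeaks = cf.RPeakSet(rec.beats.positions, rec.sampling_rate)
        fmap = cf.rr_entropy_map(rpeaks, len(rec.samples))
        for lo, hi in cf.beat_regions(rpeaks, len(rec.samples)):
            assert np.unique(fmap.values[lo:hi]).size == 1


class TestDetectRPeaks:
    def test_regular_train_recovered(self):
        spec = SynthSpec(seed=2, rhythm="sinus", noise_sd=0.02)
        rec = generate_record(spec)
        det = cf.detect_rpeaks(rec.samples, rec.sampling_rate)
        truth = rec.beats.positions
        assert len(det) == len(truth)
        assert np.max(np.abs(det.indices - truth)) <= 3

    def test_flat_signal_no_peaks(self):
        det = cf.detect_rpeaks(np.zeros(1000), 125.0)
        assert len(det) == 0

    def test_too_short_warns(self):
        with pytest.warns(UserWarning):
            det = cf.detect_rpeaks(np.zeros(100), 125.0)
        assert len(det) == 0


def test_knowledge_feature_stack_shape_and_ablation():
    spec = SynthSpec(seed=4, rhythm="bigeminy_V")
    rec = generate_record(spec)
    rpeaks = cf.RPeakSet(rec.beats.positions, rec.sampling_rate)
    full = cf.knowledge_features(rpeaks, len(rec.samples))
    assert full.shape == (len(rec.samples), 2)
    only_rr = cf.knowledge_features(rpeaks, len(rec.samples), channels=("relative_rr",))
    np.testing.assert_array_equal(only_rr[:, 1], 0.0)
    np.testing.assert_array_equal(only_rr[:, 0], full[:, 0])
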