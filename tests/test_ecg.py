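import math

import numpy as np
import pytest
from scipy.stats import t as t_dist

from emophysio import ecg as E
from emophysio.synthetic import generate_ecg
from emophysio.types import RRSeries, SegmentAnnotation, SignalRecord


class TestDownsample:
    def test_30s_at_1024_gives_7680(self):
        rec = generate_ecg(30.0, 800.0, 20.0, seed=0)
        out = E.downsample(rec, 256.0)
        assert out.values.size == 7680
        assert out.fs == 256.0

    def test_5hz_sine_amplitude_preserved(self):
        fs = 1024.0
        t = np.arange(int(10 * fs)) / fs
        rec = SignalRecord(np.sin(2 * np.pi * 5.0 * t), fs)
        out = E.downsample(rec, 256.0)
        # ignore filter edge transients
        core = out.values[256:-256]
        assert np.max(np.abs(core)) == pytest.approx(1.0, rel=0.01)

    def test_identity_when_equal_fs(self):
        rec = generate_ecg(5.0, 800.0, 10.0, seed=1)
        out = E.downsample(rec, rec.fs)
        assert np.array_equal(out.values, rec.values)

    def test_non_integer_factor_rejected(self):
        rec = generate_ecg(5.0, 800.0, 10.0, seed=1)
        with pytest.raises(ValueError):
            E.downsample(rec, 300.0)


class TestSegmentSession:
    def test_full_protocol_yields_29_snippets(self, protocol, strong_cohort):
        _, cohort = strong_cohort
        session = cohort[0]
        ecg256 = E.downsample(session.ecg, 256.0)
        pairs = E.segment_session(ecg256, session.annotations)
        assert len(pairs) == 29
        stages = [ann.stage for ann, _ in pairs]
        assert stages.count("stimulus") + stages.count("recall") == 14
        assert stages.count("rest") == 14
        assert stages.count("baseline") == 1

    def test_30s_snippet_sample_count(self):
        rec = generate_ecg(40.0, 800.0, 10.0, fs=256.0, seed=2)
        ann = SegmentAnnotation(5.0, 35.0, "stimulus", category="fear", method="image")
        ((_, snip),) = E.segment_session(rec, [ann])
        assert snip.values.size == 7680

    def test_overlapping_annotations_rejected(self):
        rec = generate_ecg(40.0, 800.0, 10.0, fs=256.0, seed=2)
        anns = [
            SegmentAnnotation(0.0, 20.0, "rest"),
            SegmentAnnotation(10.0, 30.0, "rest"),
        ]
        with pytest.raises(ValueError):
            E.segment_session(rec, anns)

    def test_out_of_span_rejected(self):
        rec = generate_ecg(10.0, 800.0, 10.0, fs=256.0, seed=2)
        with pytest.raises(ValueError):
            E.segment_session(rec, [SegmentAnnotation(5.0, 20.0, "rest")])


class TestRemoveRawOutliers:
    def test_clean_signal_untouched(self, clean_snippet_256):
        out = E.remove_raw_outliers(clean_snippet_256)
        assert out.meta["tagged_windows"].size == 0
        assert np.array_equal(out.values, clean_snippet_256.values)

    def test_interior_spike_replaced_by_predecessor(self, clean_snippet_256):
        w = 256
        x = clean_snippet_256.values.copy()
        x[int(5.4 * 256)] = 10.0
        out = E.remove_raw_outliers(clean_snippet_256.copy_with(x))
        assert list(out.meta["tagged_windows"]) == [5]
        assert np.array_equal(out.values[5 * w : 6 * w], x[4 * w : 5 * w])

    def test_first_window_replaced_by_successor(self, clean_snippet_256):
        w = 256
        x = clean_snippet_256.values.copy()
        x[128] = 10.0
        out = E.remove_raw_outliers(clean_snippet_256.copy_with(x))
        assert list(out.meta["tagged_windows"]) == [0]
        assert np.array_equal(out.values[:w], x[w : 2 * w])

    def test_negative_spike_tagged(self, clean_snippet_256):
        w = 256
        x = clean_snippet_256.values.copy()
        x[int(7.5 * 256)] = -10.0
        out = E.remove_raw_outliers(clean_snippet_256.copy_with(x))
        assert 7 in out.meta["tagged_windows"]

    def test_length_and_untagged_windows_preserved(self, clean_snippet_256, rng):
        x = clean_snippet_256.values.copy()
        for t in rng.uniform(1, 29, size=3):
            x[int(t * 256)] = rng.uniform(8, 15)
        out = E.remove_raw_outliers(clean_snippet_256.copy_with(x))
        assert out.values.size == x.size
        w = 256
        for i in range(x.size // w):
            if i not in out.meta["tagged_windows"]:
                assert np.array_equal(out.values[i * w : (i + 1) * w], x[i * w : (i + 1) * w])

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            E.remove_raw_outliers(SignalRecord(np.zeros(100), 256.0))


class TestDetectRPeaks:
    def test_zero_variance_intervals_exact(self):
        rec = generate_ecg(20.0, 1000.0, 0.0, seed=0)
        rr = E.detect_r_peaks(E.downsample(rec, 256.0))
        assert np.all(np.abs(rr.intervals - 1000.0) <= 1000.0 / 256.0 + 1e-9)

    def test_flat_signal_rejected(self):
        with pytest.raises(E.UnusableSegmentError):
            E.detect_r_peaks(SignalRecord(np.zeros(7680), 256.0))

    def test_hr_recovered_within_1_bpm(self):
        rec = generate_ecg(60.0, 600.0, 10.0, seed=4)
        rr = E.detect_r_peaks(E.downsample(rec, 256.0))
        hr = 60000.0 / rr.intervals.mean()
        true_hr = 60000.0 / (np.diff(rec.meta["beat_times"]).mean() * 1000.0)
        assert abs(hr - true_hr) < 1.0
        assert abs(hr - 100.0) < 2.0

    def test_refractory_constraint(self, clean_snippet_256):
        rr = E.detect_r_peaks(clean_snippet_256)
        assert np.all(np.diff(rr.peak_times) >= 0.2)


def _gesd_oracle(x, alpha=0.05, max_outliers=None):
    """Independent GESD reference built directly from t-distribution quantiles."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if max_outliers is None:
        max_outliers = max(int(math.ceil(0.1 * n)), 1)
    max_outliers = min(max_outliers, n - 2)
    working = list(range(n))
    removed, n_out = [], 0
    for i in range(1, max_outliers + 1):
        sub = x[working]
        mu = sub.mean()
        sd = sub.std(ddof=1)
        if sd == 0:
            break
        j = int(np.argmax(np.abs(sub - mu)))
        r = abs(sub[j] - mu) / sd
        m = len(working)
        tc = t_dist.ppf(1 - alpha / (2 * m), m - 2)
        lam = (m - 1) * tc / math.sqrt((m - 2 + tc**2) * m)
        removed.append(working.pop(j))
        if r > lam:
            n_out = i
    return sorted(removed[:n_out])


class TestCleanRr:
    def test_constant_series_identity(self):
        rr = RRSeries.from_peak_times(np.arange(20) * 0.8)
        out = E.clean_rr(rr)
        assert np.array_equal(out.intervals, rr.intervals)

    def test_planted_outlier_flagged_and_replaced(self, rng):
        iv = rng.normal(800, 10, size=50)
        iv[20] = 2000.0
        rr = RRSeries(np.concatenate([[0], np.cumsum(iv) / 1000]), iv)
        out = E.clean_rr(rr)
        assert 700.0 <= out.intervals[20] <= 900.0
        assert np.allclose(np.delete(out.intervals, 20), np.delete(iv, 20))

    def test_gesd_matches_independent_oracle(self, rng):
        for _ in range(50):
            x = rng.normal(800, 10, size=rng.integers(20, 60))
            n_plant = rng.integers(0, 3)
            for j in rng.choice(x.size, size=n_plant, replace=False):
                x[j] = rng.choice([300.0, 2000.0])
            assert sorted(E.gesd_outliers(x).tolist()) == _gesd_oracle(x)

    def test_clean_series_unchanged(self, rng):
        iv = rng.normal(800, 10, size=40)
        rr = RRSeries(np.concatenate([[0], np.cumsum(iv) / 1000]), iv)
        out = E.clean_rr(rr)
        assert np.allclose(out.intervals, iv)

    def test_fixed_point_under_second_pass(self, rng):
        iv = rng.normal(800, 15, size=60)
        iv[[10, 30]] = [2000.0, 300.0]
        rr = RRSeries(np.concatenate([[0], np.cumsum(iv) / 1000]), iv)
        out = E.clean_rr(rr)
        assert E.gesd_outliers(out.intervals).size == 0

    def test_short_series_returned_unchanged(self):
        rr = RRSeries.from_peak_times([0.0, 0.8, 1.6, 2.4])
        assert np.array_equal(E.clean_rr(rr).intervals, rr.intervals)


class TestEndToEndRrRecovery:
    def test_pipeline_rr_mean_within_1pct(self):
        rec = generate_ecg(60.0, 750.0, 30.0, seed=8)
        truth = np.diff(rec.meta["beat_times"]).mean() * 1000.0
        snip = E.downsample(rec, 256.0)
        rr = E.clean_rr(E.detect_r_peaks(E.remove_raw_outliers(snip)))
        assert abs(rr.intervals.mean() - truth) / truth < 0.01

    def test_pipeline_rr_mean_within_2pct_with_spikes(self):
        rec = generate_ecg(60.0, 750.0, 30.0, spike_rate=2.0, seed=9)
        truth = np.diff(rec.meta["beat_times"]).mean() * 1000.0
        snip = E.downsample(rec, 256.0)
        rr = E.clean_rr(E.detect_r_peaks(E.remove_raw_outliers(snip)))
        assert abs(rr.intervals.mean() - truth) / truth < 0.02


class TestSessionUsable:
    def test_discard_rule(self):
        assert E.session_usable([True] * 25 + [False] * 4)  # 13.8% bad
        assert not E.session_usable([True] * 22 + [False] * 7)  # 24% bad
        assert not E.session_usable([])
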