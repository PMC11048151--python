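import numpy as np
import pytest
from scipy import signal as sps

import ppg2ecg as p
from ppg2ecg.preprocess import (
    ECG_BAND_HZ,
    PPG_BAND_HZ,
    cheby2_bandpass,
    detect_r_peaks,
    detect_systolic_peaks,
)

from conftest import recall

FS = 125.0


def sinusoid_ratio(f_hz, band, fs=FS, seconds=30.0):
    t = np.arange(0, seconds, 1 / fs)
    x = np.sin(2 * np.pi * f_hz * t)
    y = cheby2_bandpass(x, fs, *band)
    mid = slice(int(5 * fs), int((seconds - 5) * fs))  # trim transients
    return y[mid].std() / x[mid].std()


class TestBandpass:
    def test_zero_in_zero_out(self):
        out = cheby2_bandpass(np.zeros(1000), FS, *PPG_BAND_HZ)
        np.testing.assert_allclose(out, 0.0)

    def test_passband_tone_preserved(self):
        assert sinusoid_ratio(5.0, PPG_BAND_HZ) >= 0.9

    def test_stopband_tone_suppressed(self):
        assert sinusoid_ratio(40.0, PPG_BAND_HZ) <= 0.1

    def test_ecg_band_wider(self):
        assert sinusoid_ratio(15.0, ECG_BAND_HZ) >= 0.9
        assert sinusoid_ratio(15.0, PPG_BAND_HZ) <= 0.6

    def test_zero_phase(self):
        t = np.arange(0, 10, 1 / FS)
        x = np.sin(2 * np.pi * 2.0 * t)
        y = cheby2_bandpass(x, FS, *PPG_BAND_HZ)
        c = sps.correlate(y, x, mode="full")
        assert int(np.argmax(c)) - (len(x) - 1) == 0

    def test_band_outside_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            cheby2_bandpass(np.zeros(1000), FS, 0.5, 80.0)

    def test_length_preserved(self):
        x = np.random.default_rng(0).normal(size=777)
        assert len(cheby2_bandpass(x, FS, *ECG_BAND_HZ)) == 777


class TestRPeakDetection:
    def test_flat_signal_empty(self):
        assert len(detect_r_peaks(np.zeros(1000), FS)) == 0

    def test_clean_synthetic_recovery(self):
        params = p.SynthParams(duration_s=60, hr_bpm=60, hrv_sd_s=0.0, noise_sd=0.0, seed=2)
        rec = p.gen_record(params)
        peaks = detect_r_peaks(rec.ecg, FS)
        assert abs(len(peaks) - 60) <= 1
        assert recall(peaks, rec.annotations, 3) >= 0.99

    def test_noisy_recovery(self):
        params = p.SynthParams(duration_s=60, hr_bpm=70, noise_sd=0.05, seed=4)
        rec = p.gen_record(params)
        peaks = detect_r_peaks(cheby2_bandpass(rec.ecg, FS, *ECG_BAND_HZ), FS)
        assert recall(peaks, rec.annotations, 5) >= 0.95

    def test_refractory_separation(self, noisy_record):
        peaks = detect_r_peaks(noisy_record.ecg, FS)
        assert np.all(np.diff(peaks) >= 0.2 * FS)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="2 s"):
            detect_r_peaks(np.zeros(100), FS)


class TestSystolicDetection:
    def test_flat_signal_empty(self):
        assert len(detect_systolic_peaks(np.zeros(1000), FS)) == 0

    def test_clean_synthetic_recovery(self):
        params = p.SynthParams(duration_s=60, hr_bpm=60, hrv_sd_s=0.0, pat_s=0.24,
                               noise_sd=0.0, seed=2)
        rec = p.gen_record(params)
        peaks = detect_systolic_peaks(rec.ppg, FS)
        assert abs(len(peaks) - 60) <= 1
        assert recall(peaks, rec.annotations + 30, 3) >= 0.99

    def test_prominent_dicrotic_not_double_counted(self):
        pp = (1.0, 0.09, 0.4, 0.30, 0.09)
        params = p.SynthParams(duration_s=60, hr_bpm=70, noise_sd=0.0, ppg_params=pp, seed=5)
        rec = p.gen_record(params)
        peaks = detect_systolic_peaks(rec.ppg, FS)
        assert abs(len(peaks) - len(rec.annotations)) <= 1
        assert recall(peaks, rec.annotations + 30, 3) >= 0.99

    def test_minimum_separation(self, noisy_record):
        peaks = detect_systolic_peaks(noisy_record.ppg, FS)
        assert np.all(np.diff(peaks) >= 0.3 * FS)


class TestAlignment:
    def _align(self, record):
        ecg_f = cheby2_bandpass(record.ecg, record.fs, *ECG_BAND_HZ)
        ppg_f = cheby2_bandpass(record.ppg, record.fs, *PPG_BAND_HZ)
        filtered = p.Record(ecg=ecg_f, ppg=ppg_f, fs=record.fs, record_id=record.record_id)
        return p.align_pair(
            filtered, detect_r_peaks(ecg_f, record.fs), detect_systolic_peaks(ppg_f, record.fs)
        )

    def test_lag_matches_pat(self, clean_record):
        aligned = self._align(clean_record)
        assert abs(aligned.lag_samples - 30) <= 1
        assert len(aligned) == len(clean_record) - aligned.lag_samples

    def test_zero_pat_near_zero_lag(self):
        params = p.SynthParams(duration_s=60, hr_bpm=70, pat_s=0.0, noise_sd=0.0, seed=6)
        aligned = self._align(p.gen_record(params))
        assert aligned.lag_samples in (0, 1)

    @pytest.mark.parametrize("pat_s", [0.0, 0.12, 0.24, 0.4])
    def test_residual_offset_small(self, pat_s):
        params = p.SynthParams(duration_s=120, hr_bpm=75, pat_s=pat_s, noise_sd=0.02, seed=3)
        aligned = self._align(p.gen_record(params))
        r2 = detect_r_peaks(aligned.ecg, FS)
        s2 = detect_systolic_peaks(aligned.ppg, FS)
        offsets = []
        for t in r2:
            d = s2 - t
            d = d[np.abs(d) < 40]
            if len(d):
                offsets.append(d[np.argmin(np.abs(d))])
        assert abs(np.median(offsets)) <= 2

    def test_too_few_peaks_rejected(self):
        rec = p.Record(ecg=np.zeros(1000), ppg=np.zeros(1000), fs=FS)
        with pytest.raises(ValueError, match="3 systolic"):
            p.align_pair(rec, np.array([10]), np.array([15, 120]))

    def test_no_preceding_r_peak_rejected(self):
        rec = p.Record(ecg=np.zeros(1000), ppg=np.zeros(1000), fs=FS)
        with pytest.raises(ValueError, match="R peak"):
            p.align_pair(rec, np.array([500]), np.array([15, 120, 240]))


class TestNormalize:
    def test_affine_map_by_hand(self):
        np.testing.assert_allclose(p.normalize_minmax(np.array([2.0, 4.0, 3.0])), [0, 1, 0.5])

    def test_idempotent(self):
        x = np.random.default_rng(0).normal(size=100)
        once = p.normalize_minmax(x)
        np.testing.assert_allclose(p.normalize_minmax(once), once, atol=1e-15)

    def test_constant_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            p.normalize_minmax(np.full(10, 5.0))


class TestSegmentation:
    def _aligned(self, n, fs=FS):
        rng = np.random.default_rng(0)
        return p.AlignedRecord(ecg=rng.normal(size=n), ppg=rng.normal(size=n),
                               lag_samples=0, fs=fs)

    def test_protocol_segment_count(self, cfg):
        segs = p.segment_record(self._aligned(int(294 * FS) + 100), cfg)
        assert len(segs) == 98
        assert all(len(s.ppg_in) == 375 for s in segs)
        assert all(s.ppg_in.min() >= 0 and s.ppg_in.max() <= 1 for s in segs)

    def test_single_segment(self):
        cfg = p.RunConfig(record_seconds_used=3.0)
        segs = p.segment_record(self._aligned(375), cfg)
        assert len(segs) == 1

    def test_too_short_rejected(self):
        cfg = p.RunConfig(record_seconds_used=3.0)
        with pytest.raises(ValueError, match="required"):
            p.segment_record(self._aligned(374), cfg)

    def test_pipeline_conservation(self, noisy_record, cfg):
        segs, _, _, _ = p.preprocess_record(noisy_record, cfg)
        assert len(segs) * 375 == int(cfg.record_seconds_used * cfg.fs)


class TestSplit:
    @pytest.mark.parametrize("n, expected", [(98, (58, 20, 20)), (10, (6, 2, 2)), (5, (3, 1, 1))])
    def test_floor_arithmetic(self, n, expected):
        segs = [None] * n
        tr, va, te = p.split_segments(segs)
        assert (len(tr), len(va), len(te)) == expected
        assert list(tr) + list(va) + list(te) == list(range(n))

    def test_too_few_rejected(self):
        with pytest.raises(ValueError, match="at least 5"):
            p.split_segments([None] * 4)


class TestGapInjection:
    def _segments(self, cfg, n_records_seconds=294):
        rng = np.random.default_rng(1)
        n = int(n_records_seconds * cfg.fs)
        aligned = p.AlignedRecord(ecg=rng.normal(size=n), ppg=rng.normal(size=n),
                                  lag_samples=0, fs=cfg.fs)
        return p.segment_record(aligned, cfg)

    @pytest.mark.parametrize("gap_s, expected", [(1.0, 125), (2.0, 250), (3.0, 375), (4.0, 500)])
    def test_mask_counts_exact(self, gap_s, expected):
        cfg = p.RunConfig(seed=2, gap_seconds=gap_s)
        segs = self._segments(cfg)
        out, spec = p.inject_gap(segs, cfg, np.random.default_rng(9))
        n_masked = sum(int((~s.mask).sum()) for s in out)
        assert n_masked == expected
        # contiguity in record coordinates
        flat = np.concatenate([~s.mask for s in out])
        idx = np.flatnonzero(flat)
        assert idx[-1] - idx[0] + 1 == expected
        assert idx[0] == spec.start_sample

    def test_gap_confined_to_training_portion(self):
        cfg = p.RunConfig(seed=2, gap_seconds=4.0)
        segs = self._segments(cfg)
        tr, _, _ = p.split_segments(segs, cfg.split_fractions)
        for trial in range(20):
            out, spec = p.inject_gap(segs, cfg, np.random.default_rng(trial))
            assert spec.start_sample + 500 <= len(tr) * 375

    def test_long_gap_spans_segments(self):
        cfg = p.RunConfig(seed=2, gap_seconds=4.0)
        out, _ = p.inject_gap(self._segments(cfg), cfg, np.random.default_rng(3))
        touched = [s.segment_index for s in out if not s.mask.all()]
        assert len(touched) >= 2

    def test_zeroed_where_masked_ppg_untouched(self):
        cfg = p.RunConfig(seed=2, gap_seconds=2.0)
        segs = self._segments(cfg)
        out, _ = p.inject_gap(segs, cfg, np.random.default_rng(4))
        for before, after in zip(segs, out):
            np.testing.assert_array_equal(before.ppg_in, after.ppg_in)
            assert np.all(after.ecg_target[~after.mask] == 0.0)
            np.testing.assert_array_equal(
                after.ecg_target[after.mask], before.ecg_target[after.mask]
            )

    def test_seeded_determinism(self):
        cfg = p.RunConfig(seed=2, gap_seconds=1.0)
        segs = self._segments(cfg)
        _, s1 = p.inject_gap(segs, cfg, np.random.default_rng(7))
        _, s2 = p.inject_gap(segs, cfg, np.random.default_rng(7))
        assert s1 == s2
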