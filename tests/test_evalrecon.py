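import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ppg2ecg as p
from ppg2ecg.evalrecon import (
    frechet_distance,
    pearson_r,
    prd,
    rmse,
    stitch,
    summarize,
    xcorr_align,
)
from ppg2ecg.trainer import mse_loss


def brute_force_frechet(a, b):
    """Exhaustive minimum over monotone couplings of the max pointwise distance.

    Enumerates every lattice path from (0, 0) to (n-1, m-1) with steps
    (1,0), (0,1), (1,1) — independent of the dynamic programme under test.
    """

    best = [np.inf]

    def walk(i, j, cur):
        cur = max(cur, abs(a[i] - b[j]))
        if cur >= best[0]:
            return
        if i == len(a) - 1 and j == len(b) - 1:
            best[0] = cur
            return
        for di, dj in ((1, 0), (0, 1), (1, 1)):
            ni, nj = i + di, j + dj
            if ni < len(a) and nj < len(b):
                walk(ni, nj, cur)

    walk(0, 0, -np.inf)
    return best[0]


def synthetic_ecg(seconds=16.0, seed=0, noise=0.01):
    params = p.SynthParams(duration_s=seconds, hr_bpm=72, hrv_sd_s=0.05,
                           noise_sd=noise, seed=seed)
    return p.gen_ecg(p.gen_beat_times(params), params)


class TestStitch:
    def test_concatenation(self):
        a, b = np.arange(375.0), np.arange(375.0) + 10
        out = stitch([a, b])
        assert len(out) == 750
        np.testing.assert_array_equal(out[:375], a)
        np.testing.assert_array_equal(out[375:], b)

    def test_identity_single(self):
        a = np.arange(10.0)
        np.testing.assert_array_equal(stitch([a]), a)

    def test_no_smoothing_at_boundary(self):
        a, b = np.full(5, 1.0), np.full(5, -1.0)
        out = stitch([a, b])
        assert out[4] == 1.0 and out[5] == -1.0

    def test_errors(self):
        with pytest.raises(ValueError, match="empty"):
            stitch([])
        with pytest.raises(ValueError, match="unequal"):
            stitch([np.zeros(3), np.zeros(4)])


class TestXcorrAlign:
    def test_recovers_constructed_delay(self):
        base = synthetic_ecg(20.0, seed=1)
        n, k, m = 1500, 13, 130
        a = base[m : m + n]
        b = base[m - k : m - k + n]  # b delayed by k samples
        shifted, lag = xcorr_align(a, b, m)
        assert lag == -k
        core = slice(m, n - m)
        assert pearson_r(a[core], shifted[core]) == pytest.approx(1.0, abs=1e-12)

    def test_zero_lag_for_identical(self):
        a = synthetic_ecg(8.0, seed=2)
        shifted, lag = xcorr_align(a, a, 100)
        assert lag == 0
        np.testing.assert_array_equal(shifted, a)

    @given(st.integers(min_value=-125, max_value=125))
    @settings(max_examples=40)
    def test_exact_recovery_property(self, k):
        base = synthetic_ecg(26.0, seed=3)
        m, n = 126, 2500
        a = base[m : m + n]
        b = base[m + k : m + k + n]
        _, lag = xcorr_align(a, b, 125)
        assert lag == k

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            xcorr_align(np.ones(100), np.zeros(100), 10)

    def test_alignment_never_hurts(self):
        rng = np.random.default_rng(0)
        a = synthetic_ecg(10.0, seed=4)
        b = a + rng.normal(0, 0.3, size=a.shape)
        shifted, lag = xcorr_align(a, b, 50)
        assert pearson_r(a, shifted) >= pearson_r(a, b) - 1e-12


class TestMetricExamples:
    def test_pearson_limits(self):
        a = np.array([1.0, 2.0, 3.0, 1.0])
        assert pearson_r(a, a) == pytest.approx(1.0)
        assert pearson_r(a, -a) == pytest.approx(-1.0)

    def test_pearson_hand_value(self):
        assert pearson_r(np.array([1.0, 2, 3]), np.array([1.0, 2, 4])) == pytest.approx(
            0.9820, abs=1e-4
        )

    def test_pearson_invariance(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(size=40), rng.normal(size=40)
        assert pearson_r(a, b) == pytest.approx(pearson_r(b, a))
        assert pearson_r(2 * a + 5, b) == pytest.approx(pearson_r(a, b))

    def test_rmse_examples(self):
        assert rmse(np.zeros(4), np.zeros(4)) == 0.0
        assert rmse(np.zeros(4), np.ones(4)) == 1.0
        assert rmse(np.array([1.0, 2]), np.array([3.0, 4])) == pytest.approx(2.0)

    def test_prd_examples(self):
        a = np.array([3.0, 4.0])
        assert prd(a, a) == 0.0
        assert prd(a, np.zeros(2)) == pytest.approx(100.0)
        assert prd(np.array([2.0, 0]), np.array([1.0, 0])) == pytest.approx(50.0)

    def test_prd_zero_reference_rejected(self):
        with pytest.raises(ValueError, match="zero-energy"):
            prd(np.zeros(5), np.ones(5))

    def test_frechet_examples(self):
        a = np.array([0.0, 1.0, 0.0])
        assert frechet_distance(a, a) == 0.0
        assert frechet_distance(np.array([0.0]), np.array([3.0])) == 3.0
        assert frechet_distance(a, np.zeros(3)) == 1.0


class TestMetricIdentities:
    def test_rmse_squared_is_mse(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(size=100), rng.normal(size=100)
        assert rmse(a, b) ** 2 == pytest.approx(mse_loss(a, b), abs=1e-10)

    def test_prd_identity(self):
        rng = np.random.default_rng(6)
        a, b = rng.normal(size=123), rng.normal(size=123)
        lhs = prd(a, b)
        rhs = 100.0 * rmse(a, b) * np.sqrt(len(a)) / np.sqrt(np.sum(a**2))
        assert lhs == pytest.approx(rhs, abs=1e-10)

    @given(
        st.lists(st.floats(-10, 10), min_size=1, max_size=6),
        st.lists(st.floats(-10, 10), min_size=1, max_size=6),
    )
    @settings(max_examples=250)
    def test_frechet_matches_brute_force(self, a, b):
        a, b = np.asarray(a), np.asarray(b)
        assert frechet_distance(a, b) == pytest.approx(brute_force_frechet(a, b), abs=1e-12)

    @given(st.integers(0, 1000))
    @settings(max_examples=30)
    def test_frechet_bounded_by_pointwise_max(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 50))
        a, b = rng.normal(size=n), rng.normal(size=n)
        assert frechet_distance(a, b) <= np.max(np.abs(a - b)) + 1e-12


class TestEvaluateRecord:
    def test_perfect_reconstruction(self, cfg):
        a = synthetic_ecg(12.0, seed=7)
        before, after = p.evaluate_record(a, a.copy(), cfg)
        for rep in (before, after):
            assert rep.r == pytest.approx(1.0)
            assert rep.rmse == 0.0
            assert rep.prd == 0.0
            assert rep.fd == 0.0
        assert after.lag_samples == 0

    def test_shift_improves_alignment(self, cfg):
        base = synthetic_ecg(20.0, seed=8)
        a = base[130 : 130 + 1500]
        b = base[120 : 120 + 1500]
        before, after = p.evaluate_record(a, b, cfg)
        assert after.r > before.r
        assert after.r == pytest.approx(1.0, abs=1e-3)
        assert after.lag_samples == -10

    def test_noise_rmse_matches_sigma(self, cfg):
        rng = np.random.default_rng(9)
        a = synthetic_ecg(20.0, seed=9)
        sigma = 0.1
        b = a + rng.normal(0, sigma, size=a.shape)
        before, _ = p.evaluate_record(a, b, cfg)
        assert before.rmse == pytest.approx(sigma, rel=0.1)


class TestSummarize:
    def _report(self, r, aligned):
        return p.MetricsReport(r=r, rmse=0.1, prd=5.0, fd=0.2, aligned=aligned)

    def test_mean_and_sample_sd(self):
        pairs = [
            (self._report(0.8, False), self._report(0.8, True)),
            (self._report(0.9, False), self._report(0.9, True)),
        ]
        summ = summarize(pairs, "I")
        mean, sd = summ.stats[(True, "r")]
        assert mean == pytest.approx(0.85)
        assert sd == pytest.approx(np.std([0.8, 0.9], ddof=1))
        frame = summ.to_frame()
        assert "0.850 ± 0.071" in frame.to_string()

    def test_identical_reports_zero_sd(self):
        pairs = [(self._report(0.7, False), self._report(0.7, True))] * 3
        summ = summarize(pairs, "II")
        for key, (mean, sd) in summ.stats.items():
            assert sd == pytest.approx(0.0, abs=1e-12)
        assert summ.n_records == 3

    def test_too_few_reports_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            summarize([(self._report(0.5, False), self._report(0.5, True))], "I")
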