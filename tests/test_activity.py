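"""Adaptive thresholds, transients, sparseness, correlations, covariance."""

import numpy as np
import pytest

import runwheel as rw
from runwheel.behaviour import LOCOMOTION

FR = 30.0


def _gcamp_kernel(rise=0.03, decay=0.4, fr=FR):
    t = np.arange(0, 3, 1 / fr)
    k = np.exp(-t / decay) - np.exp(-t / rise)
    return k / k.max()


class TestAdaptiveThreshold:
    def test_symmetric_gaussian_exits_immediately_with_sd_threshold(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 5000)
        thr, on, n_removed = rw.adaptive_threshold(x)
        assert n_removed < 0.05 * len(x)
        assert thr == pytest.approx(1.0, rel=0.1)
        assert np.array_equal(on, x > thr)

    @pytest.mark.parametrize("contamination", [0.05, 0.1, 0.2])
    def test_recovers_noise_sigma_of_contaminated_gaussian(self, contamination):
        rng = np.random.default_rng(1)
        n = 4000
        x = rng.normal(0, 1, n)
        k = int(contamination * n)
        x[:k] = rng.normal(10, 1, k)
        thr, on, _ = rw.adaptive_threshold(x)
        assert thr == pytest.approx(1.0, rel=0.15)
        assert on[:k].all()  # the outliers are labelled "on"

    def test_mirrored_symmetric_data_give_identical_threshold(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 2, 3000)
        x = np.concatenate([x, -x])  # exactly symmetric
        thr_pos, _, _ = rw.adaptive_threshold(x)
        thr_neg, _, _ = rw.adaptive_threshold(-x)
        assert thr_pos == pytest.approx(thr_neg, rel=1e-12)

    def test_fallback_when_skewness_never_crosses_zero(self):
        # exponential data stay right-skewed under any truncation from above
        rng = np.random.default_rng(3)
        x = rng.exponential(1.0, 2000)
        with pytest.warns(UserWarning, match="falling back"):
            thr, _, _ = rw.adaptive_threshold(x)
        mad = 1.4826 * np.median(np.abs(x - np.median(x)))
        assert thr == pytest.approx(np.median(x) + 2 * mad)

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError, match="50"):
            rw.adaptive_threshold(np.zeros(10))


class TestDetectTransients:
    def test_noise_only_false_positive_rate(self):
        n = int(300 * FR)
        rates = [
            rw.detect_transients(np.random.default_rng(s).normal(0, 0.02, n), FR).rate_hz
            for s in range(10)
        ]
        assert max(rates) < 0.02

    def test_injected_transients_recovered_with_rise_time(self):
        rng = np.random.default_rng(0)
        n = int(300 * FR)
        tr = rng.normal(0, 0.02, n)
        k = _gcamp_kernel()
        t_peak_ms = np.argmax(k) / FR * 1000
        starts = (np.arange(20, 280, 20) * FR).astype(int)
        for s in starts:
            tr[s : s + len(k)] += 0.5 * k[: n - s]
        ts = rw.detect_transients(tr, FR)
        assert ts.n_events == len(starts)
        assert ts.rate_hz == pytest.approx(len(starts) / 300.0, rel=0.2)
        # onset-to-peak within two frames of the kernel's time to peak
        assert abs(np.median(ts.rise_times_ms) - t_peak_ms) <= 2000 / FR
        # one-to-one pairing with injections (20 s apart): every detected
        # onset lies within a second of some injected event
        err = np.abs(ts.onset_times[:, None] - starts[None, :] / FR).min(axis=1)
        assert err.max() < 1.0

    def test_symmetric_oscillation_rejected(self):
        n = int(60 * FR)
        tr = 0.5 * np.sin(2 * np.pi * 0.5 * np.arange(n) / FR)
        assert rw.detect_transients(tr, FR).n_events == 0

    def test_flat_trace_yields_empty_set(self):
        ts = rw.detect_transients(np.zeros(int(20 * FR)), FR)
        assert ts.n_events == 0

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError, match="10 s"):
            rw.detect_transients(np.zeros(10), FR)


class TestPopulationSparseness:
    def test_silent_cells_are_fully_off(self):
        rng = np.random.default_rng(0)
        traces = rng.normal(0, 0.01, (4, int(30 * FR)))
        thresholds = np.full(4, 1.0)  # far above noise
        s = rw.population_sparseness(traces, FR, thresholds=thresholds)
        assert np.all(s.fractions == 1.0)

    def test_hand_counted_on_off_matrix(self):
        # 10 cells; exactly 2 exceed threshold in the second bin
        n_bins, w = 6, int(0.5 * FR)
        traces = np.zeros((10, n_bins * w))
        traces[3, w + 2] = 5.0
        traces[7, 2 * w - 1] = 5.0
        s = rw.population_sparseness(traces, FR, thresholds=np.full(10, 1.0))
        expected = np.ones(n_bins)
        expected[1] = 0.8
        np.testing.assert_allclose(s.fractions, expected)

    def test_invariant_to_cell_relabelling_and_affine_rescaling(self):
        rng = np.random.default_rng(1)
        k = _gcamp_kernel()
        traces = rng.normal(0, 0.02, (6, int(60 * FR)))
        for i in range(6):
            for s in rng.integers(0, traces.shape[1] - len(k), 3):
                traces[i, s : s + len(k)] += k
        base = rw.population_sparseness(traces, FR)
        perm = rw.population_sparseness(traces[::-1], FR)
        np.testing.assert_allclose(base.fractions, perm.fractions)
        scaled = rw.population_sparseness(3.0 * traces, FR)
        np.testing.assert_allclose(base.fractions, scaled.fractions)

    def test_duplicating_cells_leaves_fractions_unchanged(self):
        rng = np.random.default_rng(2)
        traces = rng.normal(0, 1, (5, int(20 * FR)))
        thr = np.full(5, 2.0)
        a = rw.population_sparseness(traces, FR, thresholds=thr)
        b = rw.population_sparseness(
            np.vstack([traces, traces]), FR, thresholds=np.concatenate([thr, thr])
        )
        np.testing.assert_allclose(a.fractions, b.fractions)


class TestPairwiseCorrelations:
    def test_identical_and_antiphase_traces(self):
        t = np.arange(600) / FR
        a = np.sin(2 * np.pi * 0.5 * t)
        corr, _ = rw.pairwise_correlations(np.stack([a, a, -a]))
        assert corr[0, 1] == pytest.approx(1.0)
        assert corr[0, 2] == pytest.approx(-1.0)

    def test_independent_noise_has_near_zero_correlation(self):
        rng = np.random.default_rng(0)
        traces = rng.normal(0, 1, (8, 4000))
        corr, p75 = rw.pairwise_correlations(traces)
        iu = np.triu_indices(8, k=1)
        assert np.max(np.abs(corr[iu])) < 3 / np.sqrt(4000)
        assert abs(p75) < 3 / np.sqrt(4000)

    def test_zero_variance_trace_excluded_with_warning(self):
        rng = np.random.default_rng(1)
        traces = np.vstack([rng.normal(0, 1, (2, 500)), np.zeros(500)])
        with pytest.warns(UserWarning, match="zero-variance"):
            corr, p75 = rw.pairwise_correlations(traces)
        assert np.isnan(corr[2, 0]) and np.isfinite(corr[0, 1])


class TestSpeedCovariance:
    @staticmethod
    def _speed(n, seed=0):
        rng = np.random.default_rng(seed)
        v = np.clip(np.cumsum(rng.normal(0, 0.5, n)), 0, None) % 20
        return v

    def test_scaled_speed_is_significant_at_zero_lag(self):
        n = int(600 * FR)
        speed = self._speed(n)
        rng = np.random.default_rng(1)
        res = rw.speed_covariance(
            0.1 * speed + rng.normal(0, 0.02, n), speed, FR, n_surrogates=2000, seed=2
        )
        assert res.significant
        assert res.peak_covariance > 0.9
        assert abs(res.peak_lag_s) < 0.5

    def test_independent_noise_rarely_significant(self):
        n = int(400 * FR)
        speed = self._speed(n)
        hits = 0
        for s in range(30):
            trace = np.random.default_rng(100 + s).normal(0, 1, n)
            res = rw.speed_covariance(trace, speed, FR, n_surrogates=1000, seed=s)
            hits += res.significant
        assert hits <= 3  # 1% nominal with max-statistic correction

    def test_covariance_bounded_and_locomotion_values_returned(self):
        n = int(200 * FR)
        speed = self._speed(n)
        labels = np.where(speed > 2.0, LOCOMOTION, 0).astype(np.int8)
        rng = np.random.default_rng(3)
        res = rw.speed_covariance(
            rng.normal(0, 1, n), speed, FR, n_surrogates=500, seed=4, labels=labels
        )
        assert np.all(np.abs(res.covariance) <= 1.0)
        assert len(res.locomotion_dff) == np.count_nonzero(labels == LOCOMOTION)

    def test_short_recording_rejected(self):
        with pytest.raises(ValueError, match="3"):
            rw.speed_covariance(np.zeros(100), np.zeros(100), FR)


class TestStereotypyComparison:
    def test_narrow_activity_beats_broad_behaviour(self):
        # activity metrics narrower than behaviour metrics: the direction
        # of the session-stability comparison is reproduced
        rng = np.random.default_rng(0)
        behaviour = rng.lognormal(np.log(10), 0.8, 500)   # broad, log-normal
        activity = rng.normal(0.05, 0.005, 500)            # narrow
        assert rw.stereotypy(activity).phi < rw.stereotypy(behaviour).phi
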