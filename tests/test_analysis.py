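"""Spike/burst detection, rates, peak statistics, filtering, regression."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dopanet.analysis import (SpikeTrain, current_voltage_correlation,
                              detect_bursts, detect_spikes, firing_rate,
                              iqr_filter, mean_membrane_potential,
                              mean_peak_potential, peak_stats,
                              rate_da_regression)
from dopanet.errors import RangeError
from dopanet.fixtures import constructed_spike_train

DT = 0.1  # ms


def spike_trace(times_ms, duration_ms=500.0, base=-70.0, peak=30.0, dt=DT):
    """Triangular spikes (~1 ms wide) injected at the given times."""
    n = int(round(duration_ms / dt))
    v = np.full(n, base)
    half = int(round(0.5 / dt))
    for t in times_ms:
        i = int(round(t / dt))
        for j in range(-half, half + 1):
            if 0 <= i + j < n:
                v[i + j] = max(v[i + j], peak - abs(j) * (peak - base) / half)
    return v


def train(times):
    return SpikeTrain(neuron_id=0, times=np.asarray(times, dtype=float),
                      threshold=0.0)


class TestDetectSpikes:
    def test_flat_trace_yields_empty_train(self):
        assert len(detect_spikes(np.full(1000, -70.0), DT)) == 0

    def test_injected_spikes_found_at_known_times(self):
        times = [50.0, 120.0, 300.0]
        got = detect_spikes(spike_trace(times), DT)
        assert len(got) == 3
        np.testing.assert_allclose(got.times, times, atol=2 * DT + 0.5)

    def test_amplitude_above_threshold_does_not_change_count(self):
        v = spike_trace([50.0, 120.0, 300.0])
        base = detect_spikes(v, DT)
        doubled = detect_spikes(np.where(v > 0, v * 2, v), DT)
        assert len(doubled) == len(base)

    def test_refractory_lockout_merges_near_crossings(self):
        v = spike_trace([100.0, 101.0])  # closer than the 2 ms lockout
        assert len(detect_spikes(v, DT)) == 1


class TestDetectBursts:
    def test_hand_computed_two_burst_example(self):
        t = train(constructed_spike_train())  # [0, 30, 60, 200, 230, 400]
        b = detect_bursts(t)
        assert b.count == 2
        assert b.bursts == [(0, 2), (3, 4)]
        assert b.spike_counts() == [3, 2]

    def test_no_bursts_when_all_isis_exceed_onset(self):
        assert detect_bursts(train([0, 50, 120, 200])).count == 0

    def test_single_burst_when_all_isis_small(self):
        b = detect_bursts(train(np.arange(0, 300, 30.0)))
        assert b.count == 1
        assert b.spike_counts() == [10]

    def test_continuation_allows_isis_up_to_100ms(self):
        # opens with 40, continues at 90, closes at 150
        b = detect_bursts(train([0, 40, 130, 280]))
        assert b.bursts == [(0, 2)]

    @settings(derandomize=True, max_examples=30)
    @given(st.floats(0.1, 500.0))
    def test_time_translation_invariance(self, shift):
        t0 = constructed_spike_train()
        b0 = detect_bursts(train(t0))
        b1 = detect_bursts(train(t0 + shift))
        assert b0.bursts == b1.bursts

    def test_idempotence_on_detected_structure(self):
        t = train(constructed_spike_train())
        assert detect_bursts(t).bursts == detect_bursts(t).bursts


class TestRatesAndPotentials:
    def test_firing_rate_basics(self):
        assert firing_rate(train([]), (0.0, 1000.0)) == 0.0
        assert firing_rate(train(np.linspace(0, 2999, 30)), (0.0, 3000.0)) == \
            pytest.approx(10.0)
        # spikes outside the window are ignored
        assert firing_rate(train([100.0, 5000.0]), (0.0, 1000.0)) == \
            pytest.approx(1.0)
        with pytest.raises(RangeError):
            firing_rate(train([1.0]), (100.0, 100.0))

    def test_mean_membrane_potential(self):
        assert mean_membrane_potential(np.full(100, -70.0)) == pytest.approx(-70.0)
        rng = np.random.default_rng(0)
        v = rng.normal(-65, 5, 10_001)
        # two-pass oracle vs single pass
        stream = 0.0
        for i, x in enumerate(v, start=1):
            stream += (x - stream) / i
        assert mean_membrane_potential(v) == pytest.approx(stream, rel=1e-12)

    def test_mean_peak_potential_fixture_and_sentinel(self):
        v = spike_trace([100.0], peak=32.0)
        t = detect_spikes(v, DT)
        assert mean_peak_potential(v, t, DT) == pytest.approx(32.0, abs=0.1)
        assert math.isnan(mean_peak_potential(v, train([]), DT))

    def test_mean_peak_potential_translation_equivariance(self):
        v = spike_trace([100.0, 200.0], peak=30.0)
        t = detect_spikes(v, DT)
        base = mean_peak_potential(v, t, DT)
        shifted = mean_peak_potential(v + 7.5, detect_spikes(v + 7.5, DT, 7.5), DT)
        assert shifted == pytest.approx(base + 7.5, abs=1e-9)


class TestPeakStats:
    def test_zero_current_and_empty_train(self):
        stats = peak_stats(np.zeros(1000), train([]), DT)
        assert stats.peak_frequency == 0.0
        assert math.isnan(stats.mean_peak_amplitude)

    def test_constructed_transients(self):
        times = [50.0, 150.0, 250.0, 350.0, 450.0]
        amps = [1.0, 2.0, 3.0, 4.0, 5.0]
        n = int(round(500.0 / DT))
        i_trace = np.zeros(n)
        for t, a in zip(times, amps):
            i_trace[int(round(t / DT))] = -a  # inward transients
        stats = peak_stats(i_trace, train(times), DT, duration_ms=500.0)
        assert stats.peak_frequency == pytest.approx(5 / 0.5)
        assert stats.mean_peak_amplitude == pytest.approx(np.mean(amps))

    def test_scaling_doubles_amplitude_not_frequency(self):
        times = [50.0, 150.0]
        n = int(round(300.0 / DT))
        i_trace = np.zeros(n)
        for t in times:
            i_trace[int(round(t / DT))] = 2.0
        s1 = peak_stats(i_trace, train(times), DT)
        s2 = peak_stats(2.0 * i_trace, train(times), DT)
        assert s2.peak_frequency == s1.peak_frequency
        assert s2.mean_peak_amplitude == pytest.approx(2 * s1.mean_peak_amplitude)


class TestIQRFilter:
    def test_hand_computed_example(self):
        np.testing.assert_array_equal(iqr_filter([1, 2, 3, 4, 5, 6, 7, 8]),
                                      [3, 4, 5, 6])

    def test_all_equal_unchanged(self):
        np.testing.assert_array_equal(iqr_filter([5.0] * 6), [5.0] * 6)

    def test_subset_and_order_stability(self):
        vals = [9.0, 1.0, 5.0, 7.0, 3.0, 8.0, 2.0, 6.0]
        out = iqr_filter(vals)
        assert set(out).issubset(set(vals))
        positions = [vals.index(v) for v in out]
        assert positions == sorted(positions)

    def test_too_few_values_rejected(self):
        with pytest.raises(RangeError):
            iqr_filter([1.0, 2.0, 3.0])


class TestRegressionAndCorrelation:
    def test_perfect_line(self):
        x = np.array([0.0, 25.0, 50.0, 75.0, 100.0])
        y = 0.2 * x + 3.0
        slope, intercept, r = rate_da_regression(x, y)
        assert slope == pytest.approx(0.2)
        assert intercept == pytest.approx(3.0)
        assert r == pytest.approx(1.0)

    def test_permutation_invariance_and_oracle(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(0, 100, 40)
        y = 0.15 * x + rng.normal(0, 1.0, 40)
        slope, intercept, r = rate_da_regression(x, y)
        order = rng.permutation(40)
        s2, i2, r2 = rate_da_regression(x[order], y[order])
        assert (s2, i2, r2) == pytest.approx((slope, intercept, r))
        # normal-equations oracle
        xm, ym = x - x.mean(), y - y.mean()
        slope_ne = (xm @ ym) / (xm @ xm)
        r_ne = (xm @ ym) / math.sqrt((xm @ xm) * (ym @ ym))
        assert slope == pytest.approx(slope_ne)
        assert intercept == pytest.approx(y.mean() - slope_ne * x.mean())
        assert r == pytest.approx(r_ne)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(RangeError):
            rate_da_regression([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        with pytest.raises(RangeError):
            rate_da_regression([1.0, 2.0], [1.0, 2.0])

    def test_correlation_identities_and_oracle(self):
        rng = np.random.default_rng(5)
        v = rng.normal(-60, 8, 5000)
        assert current_voltage_correlation(v, v) == pytest.approx(1.0)
        assert current_voltage_correlation(-v, v) == pytest.approx(-1.0)
        i = 0.5 * v + rng.normal(0, 2, 5000)
        got = current_voltage_correlation(i, v)
        cov = np.mean((i - i.mean()) * (v - v.mean()))
        want = cov / (i.std() * v.std())
        assert got == pytest.approx(want, rel=1e-10)

    def test_zero_variance_gives_nan(self):
        assert math.isnan(current_voltage_correlation(np.zeros(100),
                                                      np.arange(100.0)))
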