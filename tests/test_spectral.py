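"""LFP construction, resampling, PSD/STFT and the spectral group statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dopanet.errors import AlignmentError, RangeError
from dopanet.fixtures import sinusoid_trace, white_noise_traces
from dopanet.spectral import (LFP_RATE_HZ, N_FREQ, FieldPotential, PSDResult,
                              band_power, compute_psd, delta_p, diff_ratio,
                              make_lfp, resample_500hz, stft, to_dbm)

SIM_DT = 0.02  # ms -> 50 kHz


def fp_from(values, label=""):
    time = np.arange(len(values)) * (1000.0 / LFP_RATE_HZ)
    return FieldPotential(time=time, values=np.asarray(values, float), label=label)


def noise_psds(n, seed, n_samples=2000, scale=1.0):
    traces = white_noise_traces(n, n_samples, seed, scale=scale)
    return [compute_psd(fp_from(t)) for t in traces]


class TestLFP:
    def test_mean_of_constant_traces(self):
        v = np.full((28, 50_001), -63.5)
        lfp = make_lfp(v, SIM_DT)
        np.testing.assert_allclose(lfp.values, -63.5, atol=1e-9)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(0)
        v = rng.normal(-65, 5, (6, 25_000))
        a = make_lfp(v, SIM_DT).values
        b = make_lfp(v[::-1], SIM_DT).values
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_mean_of_two_sinusoids_matches_analytic_average(self):
        n = 100_000
        t = np.arange(n) * SIM_DT / 1000.0
        v1 = np.sin(2 * np.pi * 10.0 * t)
        v2 = 3.0 * np.sin(2 * np.pi * 10.0 * t)
        lfp = make_lfp(np.vstack([v1, v2]), SIM_DT)
        t500 = np.arange(lfp.values.size) / LFP_RATE_HZ
        expected = 2.0 * np.sin(2 * np.pi * 10.0 * t500)
        # ignore filter edges
        sl = slice(50, -50)
        np.testing.assert_allclose(lfp.values[sl], expected[sl], atol=0.02)

    def test_incomplete_traces_rejected(self):
        v = np.full((3, 1000), -60.0)
        v[1, 10] = np.nan
        with pytest.raises(AlignmentError):
            make_lfp(v, SIM_DT)


class TestResample:
    def test_dc_preserved(self):
        x = np.full(50_000, -70.0)
        y = resample_500hz(x, SIM_DT)
        assert y.size == 500
        np.testing.assert_allclose(y, -70.0, atol=1e-9)

    def test_inband_tone_amplitude_preserved_within_1pct(self):
        x = sinusoid_trace(10.0, 4000.0, 50_000.0)
        y = resample_500hz(x, SIM_DT)
        assert abs(np.std(y[100:-100]) - np.std(x)) / np.std(x) < 0.01

    def test_above_nyquist_tone_attenuated_below_1pct(self):
        x = sinusoid_trace(400.0, 4000.0, 50_000.0)  # Nyquist after decimation: 250 Hz
        y = resample_500hz(x, SIM_DT)
        assert np.std(y[100:-100]) < 0.01 * np.std(x)

    def test_non_integer_factor_rejected(self):
        with pytest.raises(RangeError):
            resample_500hz(np.zeros(1000), 0.003)


class TestPSD:
    def test_grid_shape_and_range(self):
        psd = noise_psds(1, 0)[0]
        assert psd.frequencies.size == N_FREQ == 1024
        assert psd.frequencies[0] == 0.0
        assert psd.frequencies.max() < 250.0
        assert np.all(np.diff(psd.frequencies) > 0)

    def test_white_noise_spectrum_is_flat(self):
        traces = white_noise_traces(40, 8000, 7)
        mean_power = np.mean([compute_psd(fp_from(t)).power for t in traces],
                             axis=0)
        low = mean_power[(np.arange(N_FREQ) > 4) & (np.arange(N_FREQ) < 512)].mean()
        high = mean_power[512:].mean()
        assert low == pytest.approx(high, rel=0.05)

    def test_pure_tone_peaks_at_nearest_bin(self):
        psd = compute_psd(fp_from(sinusoid_trace(40.0, 4000.0, 500.0)))
        got = psd.frequencies[np.argmax(psd.power)]
        nearest = psd.frequencies[np.argmin(np.abs(psd.frequencies - 40.0))]
        assert got == nearest

    def test_parseval_total_power_matches_variance(self):
        rng = np.random.default_rng(11)
        x = rng.standard_normal(2 ** 17)  # ~127 averaged segments
        psd = compute_psd(fp_from(x))
        df = psd.frequencies[1] - psd.frequencies[0]
        # one-sided integral over the kept grid (the dropped 250 Hz bin is
        # a ~1/1024 correction)
        total = np.sum(psd.power) * df
        assert total == pytest.approx(np.var(x), rel=0.01)

    def test_short_input_rejected(self):
        with pytest.raises(RangeError):
            compute_psd(fp_from(np.zeros(100)))


class TestSTFT:
    def test_window_count_formula(self):
        x = np.zeros(2000)
        _, times, spec = stft(fp_from(x))
        assert spec.shape[1] == (2000 - 50) // 25 + 1

    def test_stationary_tone_constant_columns(self):
        f, times, spec = stft(fp_from(sinusoid_trace(40.0, 4000.0, 500.0)))
        peak_rows = spec.argmax(axis=0)
        assert np.all(peak_rows == peak_rows[0])
        col_power = spec.sum(axis=0)
        assert col_power.std() / col_power.mean() < 0.05

    def test_tone_switch_detected_at_junction(self):
        a = sinusoid_trace(20.0, 2000.0, 500.0)
        b = sinusoid_trace(80.0, 2000.0, 500.0)
        f, times, spec = stft(fp_from(np.concatenate([a, b])))
        peak_freqs = f[spec.argmax(axis=0)]
        switch_idx = np.argmax(peak_freqs > 50.0)
        # the switch happens within one window of the 2000 ms junction
        assert abs(times[switch_idx] - 2000.0) <= 100.0

    def test_too_short_input_rejected(self):
        with pytest.raises(RangeError):
            stft(fp_from(np.zeros(30)))


class TestDbm:
    def test_reference_values(self):
        assert to_dbm(1.0) == pytest.approx(0.0)
        assert to_dbm(10.0) == pytest.approx(10.0)
        assert to_dbm(0.5) == pytest.approx(-3.0103, abs=1e-4)

    def test_nonpositive_floored_with_warning(self):
        with pytest.warns(UserWarning, match="floored"):
            out = to_dbm(np.array([1.0, 0.0]))
        assert np.isfinite(out).all()


class TestDiffRatio:
    def test_self_comparison_yields_zero(self):
        psds = noise_psds(3, 21)
        summary = diff_ratio(psds, list(psds))
        assert summary.diff_ratio == 0.0
        assert summary.n_diff == 0

    def test_large_separation_saturates_to_one(self):
        quiet = noise_psds(4, 31, scale=1.0)
        loud = noise_psds(4, 32, scale=100.0)  # +40 dBm at every frequency
        summary = diff_ratio(quiet, loud)
        assert summary.diff_ratio > 0.95

    def test_monotone_nonincreasing_in_alpha(self):
        a = noise_psds(4, 41)
        b = noise_psds(4, 42)
        ratios = [diff_ratio(a, b, alpha=al).diff_ratio
                  for al in (0.2, 0.1, 0.05, 0.01)]
        assert all(x >= y for x, y in zip(ratios, ratios[1:]))

    def test_grid_mismatch_rejected(self):
        a = noise_psds(2, 51)
        bad = PSDResult(frequencies=a[0].frequencies + 0.5,
                        power=a[0].power.copy())
        with pytest.raises(AlignmentError):
            diff_ratio(a, [bad, bad])

    def test_needs_two_spectra_per_group(self):
        a = noise_psds(2, 61)
        with pytest.raises(RangeError):
            diff_ratio(a[:1], a)


class TestDeltaPAndBands:
    def test_identical_inputs_give_zero_map(self):
        psd = noise_psds(1, 71)[0]
        np.testing.assert_allclose(delta_p(psd, psd), 0.0, atol=1e-12)

    def test_tenfold_power_is_plus_ten_dbm(self):
        psd = noise_psds(1, 72)[0]
        scaled = PSDResult(frequencies=psd.frequencies, power=10.0 * psd.power)
        np.testing.assert_allclose(delta_p(scaled, psd), 10.0, atol=1e-9)

    def test_antisymmetry(self):
        a, b = noise_psds(2, 73)
        np.testing.assert_allclose(delta_p(a, b), -delta_p(b, a), atol=1e-12)

    def test_band_power_identities(self):
        flat = PSDResult(frequencies=np.linspace(0, 250, N_FREQ, endpoint=False),
                         power=np.full(N_FREQ, 2.5))
        assert band_power(flat, (30.0, 50.0)) == pytest.approx(2.5)
        assert band_power(flat, (0.0, 250.0)) == pytest.approx(np.mean(flat.power))

    def test_tone_energy_localised_in_band(self):
        psd = compute_psd(fp_from(sinusoid_trace(40.0, 4000.0, 500.0)))
        assert band_power(psd, (30.0, 50.0)) > 50 * band_power(psd, (50.0, 100.0))

    def test_invalid_band_rejected(self):
        psd = noise_psds(1, 74)[0]
        with pytest.raises(RangeError):
            band_power(psd, (260.0, 280.0))


class TestPipelineLinearity:
    def test_common_scaling_shifts_dbm_but_not_group_statistics(self):
        traces = white_noise_traces(4, 2000, 81, scale=1.0)
        base = [compute_psd(fp_from(t)) for t in traces]
        scaled = [compute_psd(fp_from(3.0 * t)) for t in traces]
        # PSD scales by c^2 -> dBm shifts by 20*log10(c)
        np.testing.assert_allclose(
            scaled[0].dbm - base[0].dbm, 20.0 * np.log10(3.0), atol=1e-8)
        other = [compute_psd(fp_from(t))
                 for t in white_noise_traces(4, 2000, 82)]
        other_scaled = [compute_psd(fp_from(3.0 * t))
                        for t in white_noise_traces(4, 2000, 82)]
        r1 = diff_ratio(base, other).diff_ratio
        r2 = diff_ratio(scaled, other_scaled).diff_ratio
        assert r1 == pytest.approx(r2, abs=1e-12)
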