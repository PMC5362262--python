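"""Density profiles, autocorrelation, Fourier spectra, and period recovery."""

import numpy as np
import pytest

from flagstorm import (
    AnalysisError,
    FlagellumModel,
    ParameterError,
    acf,
    analyze_periodicity,
    angular_distribution,
    assign_stripes,
    average_acfs,
    find_angular_peaks,
    first_peak,
    fundamental_period,
    longitudinal_density,
    spectrum,
)
from flagstorm.periodicity import AutocorrelationFunction, DensityProfile1D, modulation_depth
from tests.conftest import surface_cylindrical


def acf_oracle(counts, max_lag_bins):
    """Direct O(n^2) summation of the constant-denominator ACF."""
    x = np.asarray(counts, float) - np.mean(counts)
    denom = np.sum(x * x)
    out = np.empty(max_lag_bins + 1)
    for k in range(max_lag_bins + 1):
        total = 0.0
        for i in range(len(x) - k):
            total += x[i] * x[i + k]
        out[k] = total / denom
    return out


def dft_power_oracle(x, n_fft):
    """Direct DFT summation, one-sided power without DC."""
    n = np.arange(len(x))
    ks = np.arange(1, n_fft // 2 + 1)
    power = np.empty(len(ks))
    for j, k in enumerate(ks):
        c = np.sum(x * np.exp(-2j * np.pi * k * n / n_fft))
        power[j] = np.abs(c) ** 2
    return power


def square_wave_profile(period_nm=800.0, bin_nm=20.0, n_periods=10, amplitude=50.0):
    nbins = int(period_nm / bin_nm) * n_periods
    s = (np.arange(nbins) + 0.5) * bin_nm
    counts = amplitude * (np.mod(s, period_nm) >= period_nm / 2)
    return DensityProfile1D(bin_nm, counts.astype(float))


class TestLongitudinalDensity:
    def test_single_bin_point_mass(self):
        prof = longitudinal_density(np.full(100, 130.0), 20.0, length_nm=400.0)
        assert prof.counts[6] == 100
        assert prof.counts.sum() == 100

    def test_uniform_sample_multinomial_dispersion(self):
        rng = np.random.default_rng(4)
        s = rng.uniform(0, 10_000, 50_000)
        prof = longitudinal_density(s, 20.0, length_nm=10_000.0)
        mean = 50_000 / len(prof.counts)
        cv = prof.counts.std() / prof.counts.mean()
        # Poisson-multinomial CV ~ 1/sqrt(mean)
        assert cv == pytest.approx(1 / np.sqrt(mean), rel=0.15)

    def test_gapped_domain_alternating_runs(self):
        m = FlagellumModel(gap_period_nm=800.0, sigma_xy_nm=0.0, sigma_z_nm=0.0,
                           background_density_per_um3=0.0, seed=2)
        cyl, truth = surface_cylindrical(m)
        prof = longitudinal_density(cyl["s_nm"], 20.0, length_nm=m.length_nm)
        phase_bins = np.mod((np.arange(len(prof.counts)) + 0.5) * 20.0, 800.0)
        assert prof.counts[phase_bins < 400.0].sum() == 0
        assert prof.counts[phase_bins > 400.0].sum() == prof.n

    def test_empty_domain_rejected(self):
        with pytest.raises(ParameterError):
            longitudinal_density(np.empty(0), 20.0)


class TestAcf:
    def test_lag_zero_is_exactly_one(self):
        prof = square_wave_profile()
        assert acf(prof).values[0] == 1.0

    def test_matches_direct_summation_oracle(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(20.0, 300).astype(float)
        prof = DensityProfile1D(20.0, counts)
        fast = acf(prof, max_lag_nm=2000.0)
        oracle = acf_oracle(counts, len(fast.values) - 1)
        np.testing.assert_allclose(fast.values, oracle, rtol=1e-10, atol=1e-12)

    def test_square_wave_global_max_at_period(self):
        # the per-lag (unbiased) convention makes rho(period) = 1 exactly;
        # under the default biased convention the period must still be the
        # largest local maximum away from the origin
        prof = square_wave_profile(period_nm=800.0, bin_nm=20.0)
        unbiased = acf(prof, max_lag_nm=2000.0, denominator="per-lag")
        assert unbiased.lags_nm[1:][np.argmax(unbiased.values[1:])] == 800.0
        biased = acf(prof, max_lag_nm=2000.0)
        away = biased.lags_nm >= 100.0
        assert biased.lags_nm[away][np.argmax(biased.values[away])] == 800.0

    def test_constant_profile_rejected(self):
        with pytest.raises(AnalysisError):
            acf(DensityProfile1D(20.0, np.full(100, 5.0)))

    def test_values_bounded_by_one(self):
        rng = np.random.default_rng(1)
        prof = DensityProfile1D(20.0, rng.poisson(8.0, 500).astype(float))
        a = acf(prof)
        assert np.all(np.abs(a.values) <= 1.0 + 1e-6)


class TestAverageAcfs:
    def test_identical_inputs_idempotent(self):
        a = acf(square_wave_profile())
        avg = average_acfs([a, a, a])
        np.testing.assert_allclose(avg.values, a.values, rtol=0, atol=1e-15)
        assert avg.n_averaged == 3

    def test_single_input_identity(self):
        a = acf(square_wave_profile())
        np.testing.assert_array_equal(average_acfs([a]).values, a.values)

    def test_averaging_reduces_variance(self):
        # the averaged ACF of 8 noisy domains fluctuates less than singles
        singles, averaged = [], []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            acfs = [
                acf(DensityProfile1D(20.0, rng.poisson(10.0, 400).astype(float)))
                for _ in range(8)
            ]
            tail = slice(20, None)
            singles.append(np.var(acfs[0].values[tail]))
            averaged.append(np.var(average_acfs(acfs).values[tail]))
        assert np.mean(averaged) < np.mean(singles) / 4

    def test_mixed_bin_widths_rejected(self):
        a = acf(square_wave_profile(bin_nm=20.0))
        b = acf(square_wave_profile(bin_nm=40.0))
        with pytest.raises(ParameterError):
            average_acfs([a, b])


class TestFirstPeak:
    def test_square_wave_first_peak_at_period(self):
        a = acf(square_wave_profile(period_nm=800.0), max_lag_nm=4000.0)
        assert first_peak(a) == pytest.approx(800.0, abs=20.0)

    def test_decaying_acf_has_no_peak(self):
        lags = np.arange(0, 2000.0, 20.0)
        a = AutocorrelationFunction(lags, np.exp(-lags / 400.0))
        assert first_peak(a) is None

    def test_returns_smaller_of_two_periods(self):
        lags = np.arange(0, 4010.0, 20.0)
        vals = 0.5 * np.cos(2 * np.pi * lags / 800.0) + 0.3 * np.cos(2 * np.pi * lags / 1600.0)
        vals[0] = 1.0
        a = AutocorrelationFunction(lags, vals)
        peak = first_peak(a)
        assert peak == pytest.approx(800.0, abs=40.0)

    def test_min_lag_guard(self):
        a = acf(square_wave_profile())
        with pytest.raises(ParameterError):
            first_peak(a, min_lag_nm=20.0)


class TestSpectrum:
    def test_aligned_cosine_peaks_exactly_at_reciprocal_period(self):
        bin_nm = 20.0
        nbins = 512
        s = np.arange(nbins) * bin_nm
        period = nbins * bin_nm / 16  # 640 nm, on the unpadded grid
        prof = DensityProfile1D(bin_nm, 10 + 5 * np.cos(2 * np.pi * s / period))
        spec = spectrum(prof, zero_pad_factor=1)
        f_at_max = spec.frequencies_per_nm[np.argmax(spec.power)]
        assert f_at_max == pytest.approx(1.0 / period, rel=1e-12)

    def test_matches_direct_dft_oracle(self):
        rng = np.random.default_rng(7)
        counts = rng.poisson(15.0, 128).astype(float)
        prof = DensityProfile1D(20.0, counts)
        spec = spectrum(prof, zero_pad_factor=1)
        oracle = dft_power_oracle(counts - counts.mean(), 128)
        np.testing.assert_allclose(spec.power, oracle, rtol=1e-8)

    def test_square_wave_fundamental_beats_harmonics(self):
        prof = square_wave_profile(period_nm=800.0)
        spec = spectrum(prof)
        f = spec.frequencies_per_nm

        def power_at(freq):
            return spec.power[np.argmin(np.abs(f - freq))]

        assert power_at(1 / 800.0) > power_at(2 / 800.0)
        assert power_at(1 / 800.0) > power_at(3 / 800.0)

    def test_parseval_consistency(self):
        rng = np.random.default_rng(9)
        counts = rng.poisson(12.0, 200).astype(float)
        prof = DensityProfile1D(20.0, counts)
        spec = spectrum(prof, zero_pad_factor=4)
        x = counts - counts.mean()
        n_fft = 800
        # one-sided power with DC excluded (DC is zero after detrending);
        # Nyquist term appears once, interior terms twice
        total = 2 * spec.power[:-1].sum() + spec.power[-1]
        np.testing.assert_allclose(total / n_fft, np.sum(x**2), rtol=1e-6)

    def test_white_noise_has_no_significant_fundamental(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            prof = DensityProfile1D(20.0, rng.poisson(10.0, 500).astype(float))
            spec = spectrum(prof)
            if fundamental_period(spec, profile=prof) is not None:
                hits += 1
        assert hits <= 1


class TestFundamentalPeriod:
    @pytest.mark.parametrize("period", [600.0, 800.0, 1000.0])
    def test_square_wave_period_recovered(self, period):
        prof = square_wave_profile(period_nm=period, n_periods=12)
        spec = spectrum(prof)
        est = fundamental_period(spec, profile=prof)
        assert est == pytest.approx(period, abs=20.0)

    def test_period_ordering_preserved(self):
        est = []
        for period in (600.0, 1000.0):
            prof = square_wave_profile(period_nm=period, n_periods=10)
            est.append(fundamental_period(spectrum(prof), profile=prof))
        assert est[0] < est[1]

    def test_band_outside_support_rejected(self):
        spec = spectrum(square_wave_profile())
        with pytest.raises(ParameterError):
            fundamental_period(spec, search_band_nm=(1.0, 2.0))


class TestAnalyzePeriodicity:
    @staticmethod
    def labeled(model):
        cyl, _ = surface_cylindrical(model)
        peaks = find_angular_peaks(angular_distribution(cyl))
        return cyl, assign_stripes(cyl, peaks)

    def test_gapped_dataset_concordant_near_truth(self, null_model):
        cyl, labels = self.labeled(null_model)
        res = analyze_periodicity(cyl, labels, length_nm=null_model.length_nm)
        assert res.concordant
        assert res.acf_first_peak_nm == pytest.approx(800.0, abs=20.0)
        assert res.fft_fundamental_period_nm == pytest.approx(800.0, abs=20.0)
        assert res.n_domains_averaged == 4

    def test_continuous_dataset_flags_no_periodicity(self, wt_model):
        cyl, labels = self.labeled(wt_model)
        res = analyze_periodicity(cyl, labels, length_nm=wt_model.length_nm)
        assert res.acf_first_peak_nm is None
        assert res.fft_fundamental_period_nm is None
        assert res.no_periodicity
        assert res.concordant

    def test_modulation_depth_discriminates_regimes(self, wt_model, null_model):
        cyl_w, lab_w = self.labeled(wt_model)
        cyl_n, lab_n = self.labeled(null_model)
        res_w = analyze_periodicity(cyl_w, lab_w, length_nm=wt_model.length_nm)
        res_n = analyze_periodicity(cyl_n, lab_n, length_nm=null_model.length_nm)
        assert res_n.acf_modulation_depth > res_w.acf_modulation_depth

    def test_degenerate_domains_raise(self):
        import pandas as pd

        cyl = pd.DataFrame({"s_nm": np.full(50, 10.0), "r_nm": np.full(50, 300.0),
                            "theta_rad": np.zeros(50)})
        with pytest.raises((AnalysisError, ParameterError)):
            analyze_periodicity(cyl, np.zeros(50, int), length_nm=20.0)
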