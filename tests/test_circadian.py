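"""Period spectra, two-harmonic sinusoid fitting, and cohort rhythm
variability summaries."""

import numpy as np
import pandas as pd
import pytest

from circastress import circadian, synth
from circastress.circadian import (
    OMEGA_24H,
    RhythmFit,
    fit_second_order_sine,
    period_spectrum,
    rhythm_variability,
    summarize_cohort_spectra,
)

TABLE_AMPLITUDES = (77.6, -61.04, 2.28, -37.29)


def two_harmonic(x, a0, amps, omega=OMEGA_24H):
    a1, b1, a2, b2 = amps
    return (a0 + a1 * np.sin(omega * x) + b1 * np.cos(omega * x)
            + a2 * np.sin(2 * omega * x) + b2 * np.cos(2 * omega * x))


class TestPeriodSpectrum:
    def test_24h_sine_peaks_at_720_samples(self):
        x = np.arange(2160.0)
        spec = period_spectrum(np.sin(2 * np.pi * x / 720.0))
        assert spec.peak_period() == pytest.approx(720.0)

    def test_constant_series_has_zero_amplitude(self):
        spec = period_spectrum(np.full(720, 5.0))
        assert np.allclose(spec.amplitude, 0.0)

    def test_amplitude_calibration(self):
        x = np.arange(2160.0)
        spec = period_spectrum(3.0 * np.sin(2 * np.pi * x / 720.0))
        assert spec.amplitude.max() == pytest.approx(3.0, rel=0.05)

    def test_parseval_total_power_equals_variance(self):
        rng = np.random.default_rng(0)
        y = rng.normal(0, 2, 2160)
        spec = period_spectrum(y)
        # amplitude 2|X_k|/n -> per-component power amp^2/2 (Nyquist: amp^2)
        power = np.sum(spec.amplitude[:-1] ** 2) / 2 + spec.amplitude[-1] ** 2
        assert power == pytest.approx(np.var(y), rel=1e-8)

    def test_missing_values_interpolated_up_to_limit(self):
        x = np.arange(2160.0)
        y = np.sin(2 * np.pi * x / 720.0)
        y[::10] = np.nan
        assert period_spectrum(y).peak_period() == pytest.approx(720.0)
        y[: int(0.4 * len(y))] = np.nan
        with pytest.raises(ValueError, match="missing"):
            period_spectrum(y)


class TestCohortSummary:
    def test_identical_spectra_zero_width_ci(self):
        spec = period_spectrum(np.sin(2 * np.pi * np.arange(720.0) / 720.0))
        summ = summarize_cohort_spectra([spec, spec, spec])
        assert np.allclose(summ.ci95_low, summ.ci95_high)

    def test_ci_width_shrinks_as_sqrt_m(self):
        rng = np.random.default_rng(1)
        x = np.arange(720.0)

        def spectra(m):
            return [
                period_spectrum(np.sin(2 * np.pi * x / 720.0) + rng.normal(0, 0.5, 720))
                for _ in range(m)
            ]

        w10 = np.mean(
            summarize_cohort_spectra(spectra(10)).ci95_high
            - summarize_cohort_spectra(spectra(10)).ci95_low
        )
        w40 = np.mean(
            summarize_cohort_spectra(spectra(40)).ci95_high
            - summarize_cohort_spectra(spectra(40)).ci95_low
        )
        assert w40 == pytest.approx(w10 / 2.0, rel=0.35)

    def test_shared_24h_component_is_cohort_significant(self):
        rng = np.random.default_rng(2)
        x = np.arange(2160.0)
        specs = [
            period_spectrum(
                two_harmonic(x, 900.0, TABLE_AMPLITUDES) + rng.normal(0, 20, 2160)
            )
            for _ in range(20)
        ]
        summ = summarize_cohort_spectra(specs)
        at_720 = np.isclose(summ.period_axis, 720.0)
        short = summ.period_axis < 100.0
        assert summ.ci95_low[at_720][0] > np.median(summ.ci95_high[short])

    def test_single_spectrum_rejected(self):
        spec = period_spectrum(np.sin(np.arange(720.0)))
        with pytest.raises(ValueError):
            summarize_cohort_spectra([spec])


class TestSecondOrderSineFit:
    def test_exact_recovery_from_noise_free_curve(self):
        x = np.arange(2160.0)
        y = two_harmonic(x, 1000.0, TABLE_AMPLITUDES)
        fit = fit_second_order_sine(y)
        assert fit.A0 == pytest.approx(1000.0, rel=1e-6)
        assert np.allclose(fit.amplitudes, TABLE_AMPLITUDES, rtol=1e-6, atol=1e-4)
        assert fit.omega == pytest.approx(OMEGA_24H, rel=1e-6)

    def test_noisy_recovery_within_three_standard_errors(self):
        rng = np.random.default_rng(3)
        x = np.arange(2160.0)
        sigma = 10.0
        errs = []
        for _ in range(30):
            y = two_harmonic(x, 1000.0, TABLE_AMPLITUDES) + rng.normal(0, sigma, 2160)
            fit = fit_second_order_sine(y)
            errs.append(fit.amplitudes - np.asarray(TABLE_AMPLITUDES))
        # per-amplitude SE for a sinusoidal regressor: sigma * sqrt(2/n)
        se = sigma * np.sqrt(2.0 / 2160)
        assert np.all(np.abs(np.mean(errs, axis=0)) < 3 * se / np.sqrt(30))

    def test_constant_input_gives_null_amplitudes(self):
        fit = fit_second_order_sine(np.full(2160, 7.0))
        assert np.allclose(fit.amplitudes, 0.0, atol=1e-8)
        assert fit.A0 == pytest.approx(7.0)

    def test_residuals_orthogonal_to_fitted_basis(self):
        rng = np.random.default_rng(4)
        x = np.arange(2160.0)
        y = two_harmonic(x, 900.0, TABLE_AMPLITUDES) + rng.normal(0, 5, 2160)
        fit = fit_second_order_sine(y)
        resid = y - fit.predict(x)
        basis = np.column_stack(
            [np.ones_like(x), np.sin(fit.omega * x), np.cos(fit.omega * x),
             np.sin(2 * fit.omega * x), np.cos(2 * fit.omega * x)]
        )
        grad = basis.T @ resid / len(x)
        assert np.max(np.abs(grad)) < 1e-6 * np.std(y)

    def test_monte_carlo_median_amplitude_error_under_5pct(self):
        """At generator-default amplitudes and noise, the fundamental
        amplitudes are recovered with small median relative error."""
        rng = np.random.default_rng(5)
        x = np.arange(2160.0)
        rel_errs = []
        for _ in range(100):
            y = two_harmonic(x, 900.0, TABLE_AMPLITUDES) + rng.normal(0, 10.0, 2160)
            fit = fit_second_order_sine(y)
            rel_errs.append(
                np.abs(fit.amplitudes[:2] - np.asarray(TABLE_AMPLITUDES[:2]))
                / np.abs(TABLE_AMPLITUDES[:2])
            )
        assert np.median(rel_errs, axis=0).max() < 0.05


class TestRhythmVariability:
    @staticmethod
    def _fit(params):
        return RhythmFit(900.0, *params, omega=OMEGA_24H, rss=0.0, converged=True)

    def test_identical_subjects_and_days_give_zero_spread(self):
        f = self._fit((77.6, -61.0, 2.3, -37.3))
        day = {"a": {1: f, 2: f}, "b": {1: f, 2: f}}
        pooled = {"a": f, "b": f}
        summary = rhythm_variability(day, pooled)
        assert np.allclose(summary["std1"], 0.0)
        assert np.allclose(summary["std2"], 0.0)

    def test_hand_built_two_subject_table(self):
        day = {
            "a": {1: self._fit((10.0, 0, 0, 0)), 2: self._fit((14.0, 0, 0, 0))},
            "b": {1: self._fit((30.0, 0, 0, 0)), 2: self._fit((30.0, 0, 0, 0))},
        }
        pooled = {"a": self._fit((12.0, 0, 0, 0)), "b": self._fit((30.0, 0, 0, 0))}
        s = rhythm_variability(day, pooled)
        assert s.loc["A1", "mean"] == pytest.approx(21.0)
        # std1: mean of sample SDs (sd(10,14)=2*sqrt2, sd(30,30)=0)
        assert s.loc["A1", "std1"] == pytest.approx((np.std([10, 14], ddof=1) + 0) / 2)
        assert s.loc["A1", "std2"] == pytest.approx(np.std([12, 30], ddof=1))

    def test_sampled_cohort_refit_shows_std1_below_std2(self):
        """Day-wise vs pooled refits on curves generated from sampled
        profiles reproduce the within < between spread ordering."""
        profiles = synth.sample_profiles(12, seed=6)
        x_day = np.arange(720.0)
        day_fits, pooled_fits = {}, {}
        rng = np.random.default_rng(7)
        for p in profiles:
            per_day = {}
            segments = []
            for d, amps in enumerate(p.day_params):
                y = two_harmonic(x_day + d * 720.0, p.baseline_rr, amps)
                y = y + rng.normal(0, 3, 720)
                per_day[d + 1] = fit_second_order_sine(y, x=x_day + d * 720.0)
                segments.append(y)
            day_fits[p.subject_id] = per_day
            pooled_fits[p.subject_id] = fit_second_order_sine(np.concatenate(segments))
        summary = rhythm_variability(day_fits, pooled_fits)
        assert (summary["std1"] < summary["std2"]).all()

    def test_fewer_than_two_subjects_rejected(self):
        f = self._fit((1, 1, 1, 1))
        with pytest.raises(ValueError):
            rhythm_variability({"a": {1: f, 2: f}}, {"a": f})
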