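"""Circadian rhythm characterization of HRV feature series.

A 3-day feature series sampled every 2 min (2160 samples) is examined two
ways: an FFT amplitude spectrum plotted against period (in samples, n/k for
bin k), where 24-h and 12-h rhythms appear as peaks at 720 and 360; and a
second-order sinusoid fit

    y = A0 + A1 sin(wx) + B1 cos(wx) + A2 sin(2wx) + B2 cos(2wx),

estimated by variable projection: for fixed angular frequency w the
amplitudes solve a linear least-squares problem, and w itself is optimized
within +/-20% of the 24-h frequency (2*pi/720 rad/sample) to prevent the
fundamental from locking onto a harmonic.

Cohort-level rhythm stability is summarized as in chronobiology practice:
``std1`` (mean over subjects of the SD of day-wise fitted amplitudes) versus
``std2`` (SD over subjects of the pooled multi-day fits); std1 < std2 means
rhythms are stable within a person relative to the population spread.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

OMEGA_24H = 2.0 * np.pi / 720.0
AMPLITUDE_NAMES = ("A1", "B1", "A2", "B2")


@dataclass(frozen=True)
class PeriodSpectrum:
    period_axis: np.ndarray     # samples, n/k for k = 1..n//2
    amplitude: np.ndarray       # feature units, 2|X_k|/n

    def period_hours(self, sample_minutes: float = 2.0) -> np.ndarray:
        return self.period_axis * sample_minutes / 60.0

    def peak_period(self, exclude: float | None = None) -> float:
        """Period-axis location of the largest amplitude, optionally after
        excluding the bin at period ``exclude`` (for secondary peaks)."""
        amp = self.amplitude.copy()
        if exclude is not None:
            amp[np.isclose(self.period_axis, exclude)] = -np.inf
        return float(self.period_axis[np.argmax(amp)])


@dataclass(frozen=True)
class CohortSpectrumSummary:
    period_axis: np.ndarray
    mean_amplitude: np.ndarray
    ci95_low: np.ndarray
    ci95_high: np.ndarray


@dataclass(frozen=True)
class RhythmFit:
    A0: float
    A1: float
    B1: float
    A2: float
    B2: float
    omega: float            # rad/sample
    rss: float
    converged: bool

    @property
    def amplitudes(self) -> np.ndarray:
        return np.array([self.A1, self.B1, self.A2, self.B2])

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return (
            self.A0
            + self.A1 * np.sin(self.omega * x)
            + self.B1 * np.cos(self.omega * x)
            + self.A2 * np.sin(2 * self.omega * x)
            + self.B2 * np.cos(2 * self.omega * x)
        )


def _interpolate_missing(y: np.ndarray, max_missing: float = 0.3) -> np.ndarray:
    y = np.asarray(y, dtype=float).copy()
    bad = ~np.isfinite(y)
    if bad.mean() > max_missing:
        raise ValueError(f"{bad.mean():.0%} of samples missing (> {max_missing:.0%})")
    if bad.any():
        idx = np.arange(len(y))
        y[bad] = np.interp(idx[bad], idx[~bad], y[~bad])
    return y


def period_spectrum(series: np.ndarray) -> PeriodSpectrum:
    """Mean-removed FFT amplitude spectrum on a period axis (samples).

    Missing values are linearly interpolated first (error if > 30% missing);
    amplitude for bin k is 2|X_k|/n.
    """
    y = _interpolate_missing(series)
    n = len(y)
    if n < 4:
        raise ValueError("series too short")
    y = y - y.mean()
    spec = np.fft.rfft(y)
    k = np.arange(1, n // 2 + 1)
    amp = 2.0 * np.abs(spec[1: n // 2 + 1]) / n
    if n % 2 == 0:
        amp[-1] /= 2.0          # Nyquist bin is not doubled
    return PeriodSpectrum(period_axis=n / k, amplitude=amp)


def summarize_cohort_spectra(spectra: list[PeriodSpectrum]) -> CohortSpectrumSummary:
    """Per-period mean amplitude with a normal-theory 95% CI across subjects."""
    if len(spectra) < 2:
        raise ValueError("need at least 2 spectra")
    axis = spectra[0].period_axis
    for s in spectra[1:]:
        if len(s.period_axis) != len(axis) or not np.allclose(s.period_axis, axis):
            raise ValueError("spectra must share a common period axis")
    amps = np.vstack([s.amplitude for s in spectra])
    mean = amps.mean(axis=0)
    half = 1.96 * amps.std(axis=0, ddof=1) / np.sqrt(len(spectra))
    return CohortSpectrumSummary(axis, mean, mean - half, mean + half)


def fit_second_order_sine(
    series: np.ndarray,
    x: np.ndarray | None = None,
    init_omega: float = OMEGA_24H,
    omega_bounds: tuple[float, float] | None = None,
) -> RhythmFit:
    """Variable-projection least squares for the two-harmonic sinusoid.

    For each candidate w the linear amplitudes are solved exactly; w is then
    optimized by bounded scalar minimization of the profiled RSS.
    """
    y = _interpolate_missing(series)
    x = np.arange(len(y), dtype=float) if x is None else np.asarray(x, dtype=float)
    if len(y) < 6:
        raise ValueError("too few samples for a 5-parameter fit")
    if omega_bounds is None:
        omega_bounds = (0.8 * init_omega, 1.2 * init_omega)

    def design(w: float) -> np.ndarray:
        return np.column_stack(
            [np.ones_like(x), np.sin(w * x), np.cos(w * x),
             np.sin(2 * w * x), np.cos(2 * w * x)]
        )

    def profile_rss(w: float) -> float:
        _, res, rank, _ = np.linalg.lstsq(design(w), y)
        if rank < 5 or len(res) == 0:
            return float(np.sum((y - design(w) @ np.linalg.lstsq(design(w), y)[0]) ** 2))
        return float(res[0])

    opt = minimize_scalar(
        profile_rss, bounds=omega_bounds, method="bounded",
        options={"xatol": init_omega * 1e-7},
    )
    w = float(opt.x)
    beta, _, _, _ = np.linalg.lstsq(design(w), y)
    resid = y - design(w) @ beta
    return RhythmFit(
        A0=float(beta[0]), A1=float(beta[1]), B1=float(beta[2]),
        A2=float(beta[3]), B2=float(beta[4]), omega=w,
        rss=float(np.sum(resid**2)), converged=bool(opt.success),
    )


def rhythm_variability(
    fits_by_subject_day: dict[str, dict[int, RhythmFit]],
    fits_by_subject_pooled: dict[str, RhythmFit],
) -> pd.DataFrame:
    """Cohort rhythm-stability table: per amplitude parameter, the cohort
    mean of pooled fits, std1 (within-subject day-to-day SD, averaged), and
    std2 (between-subject SD of pooled fits)."""
    subjects = [s for s in fits_by_subject_pooled if s in fits_by_subject_day]
    if len(subjects) < 2:
        raise ValueError("need at least 2 subjects")
    pooled = np.vstack([fits_by_subject_pooled[s].amplitudes for s in subjects])
    day_sds = []
    for s in subjects:
        day_fits = fits_by_subject_day[s]
        if len(day_fits) < 2:
            raise ValueError(f"subject {s} has fewer than 2 day-wise fits")
        day_params = np.vstack([f.amplitudes for f in day_fits.values()])
        day_sds.append(day_params.std(axis=0, ddof=1))
    day_sds = np.vstack(day_sds)
    return pd.DataFrame(
        {
            "mean": pooled.mean(axis=0),
            "std1": day_sds.mean(axis=0),
            "std2": pooled.std(axis=0, ddof=1),
        },
        index=list(AMPLITUDE_NAMES),
    )


def fit_subject_rhythms(
    feature_series: pd.DataFrame,
    column: str,
    samples_per_day: int = 720,
) -> tuple[dict[int, RhythmFit], RhythmFit]:
    """Day-wise and pooled Eq.-style fits for one subject's feature column."""
    y = feature_series[column].to_numpy(dtype=float)
    n_days = int(np.ceil(len(y) / samples_per_day))
    day_fits = {}
    for d in range(n_days):
        seg = y[d * samples_per_day: (d + 1) * samples_per_day]
        x = np.arange(d * samples_per_day, d * samples_per_day + len(seg), dtype=float)
        day_fits[d + 1] = fit_second_order_sine(seg, x)
    pooled = fit_second_order_sine(y)
    return day_fits, pooled
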