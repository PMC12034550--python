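"""Short-term HRV features on 2-min windows.

Ten features per window, matching the formulas used throughout the package:

time domain
    meanNN    mean RR interval (ms)
    HR        average heart rate (beats/min): the per-minute means of
              60000/RR_i over the window's two minutes, averaged
    SDNN      population SD of the window's intervals (1/N normalization)
    RMSSD     root-mean-square of successive differences (1/(N-1))
    PNN50     fraction of successive differences strictly greater than
              50 ms, relative to the window beat count N

frequency domain (AR spectrum of the resampled tachogram)
    vlf, lf, hf   band powers (ms^2) over [0.0033, 0.04], [0.04, 0.15] and
                  [0.15, 0.5] Hz, integrated from a Burg autoregressive PSD
                  (cubic-spline resampling at 4 Hz, model order 16)

nonlinear (Poincare plot axes, as-printed normalization)
    ST1 = sqrt( 1/(N-1) * sum_i (RR_i + RR_{i-1} - 2*meanNN)^2 )
    ST2 = sqrt( 1/(N-1) * sum_i (RR_i - RR_{i-1})^2 )

Note ST1/ST2 deliberately keep this exact convention (sum-based minor axis,
difference-based major axis, no 1/sqrt(2)) rather than the textbook Poincare
SD1/SD2; the classifier and F-statistics consume them as defined here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from statsmodels.regression.linear_model import burg

FEATURE_COLUMNS = [
    "meanNN", "HR", "SDNN", "RMSSD", "PNN50", "vlf", "lf", "hf", "ST1", "ST2",
]

BANDS = {"vlf": (0.0033, 0.04), "lf": (0.04, 0.15), "hf": (0.15, 0.5)}

WINDOW_MS = 120_000.0
MIN_BEATS = 20


@dataclass(frozen=True)
class SpectralEstimate:
    freqs: np.ndarray       # Hz
    psd: np.ndarray         # ms^2/Hz
    model_order: int
    resample_rate: float    # Hz


def time_domain(rr: np.ndarray, minute_split: int) -> tuple[float, float, float, float, float]:
    """(meanNN, HR, SDNN, RMSSD, PNN50) for one window.

    ``minute_split`` is the number of beats falling in the window's first
    minute; HR averages the two per-minute means of the instantaneous rate.
    """
    rr = np.asarray(rr, dtype=float)
    n = len(rr)
    if n < 2:
        raise ValueError("window too short")
    mean_nn = float(rr.mean())
    first, second = rr[:minute_split], rr[minute_split:]
    rates = [60_000.0 * np.mean(1.0 / part) for part in (first, second) if len(part)]
    hr = float(np.mean(rates))
    sdnn = float(rr.std())                       # population SD (1/N)
    diffs = np.diff(rr)
    rmssd = float(np.sqrt(np.mean(diffs**2)))
    pnn50 = float(np.sum(np.abs(diffs) > 50.0) / n)
    return mean_nn, hr, sdnn, rmssd, pnn50


def poincare_axes(rr: np.ndarray) -> tuple[float, float]:
    """Poincare-plot axis lengths (ST1, ST2) with the package's as-printed
    1/(N-1) normalization over consecutive-pair sums and differences."""
    rr = np.asarray(rr, dtype=float)
    n = len(rr)
    if n < 2:
        raise ValueError("need at least 2 intervals")
    mean_nn = rr.mean()
    sums = rr[1:] + rr[:-1] - 2.0 * mean_nn
    diffs = rr[1:] - rr[:-1]
    st1 = float(np.sqrt(np.sum(sums**2) / (n - 1)))
    st2 = float(np.sqrt(np.sum(diffs**2) / (n - 1)))
    return st1, st2


def ar_psd(
    rr: np.ndarray,
    timestamps: np.ndarray,
    resample_rate: float = 4.0,
    order: int = 16,
    n_freqs: int = 513,
) -> SpectralEstimate:
    """Burg AR power spectral density of one window's tachogram.

    The irregular beat series is cubic-spline interpolated onto a uniform
    grid at ``resample_rate``, mean-removed, and the AR(order) spectrum is
    evaluated on ``n_freqs`` points over [0, resample_rate/2].
    """
    rr = np.asarray(rr, dtype=float)
    t = np.asarray(timestamps, dtype=float) / 1000.0      # s
    if len(rr) < order + 2 or t[-1] - t[0] < 60.0:
        raise ValueError("window too short for spectral estimation")
    grid = np.arange(t[0], t[-1], 1.0 / resample_rate)
    x = CubicSpline(t, rr)(grid)
    x = x - x.mean()
    freqs = np.linspace(0.0, resample_rate / 2.0, n_freqs)
    if np.allclose(x, 0.0):
        return SpectralEstimate(freqs, np.zeros_like(freqs), order, resample_rate)
    rho, sigma2 = burg(x, order=order, demean=False)
    # PSD(f) = sigma2 * dt / |1 - sum_k rho_k e^{-2 pi i f k dt}|^2
    dt = 1.0 / resample_rate
    k = np.arange(1, order + 1)
    h = 1.0 - np.exp(-2j * np.pi * freqs[:, None] * k[None, :] * dt) @ rho
    psd = sigma2 * dt / np.abs(h) ** 2
    return SpectralEstimate(freqs, psd, order, resample_rate)


def band_power(spec: SpectralEstimate, lo: float, hi: float) -> float:
    """Trapezoidal integral of the PSD over [lo, hi] Hz (ms^2)."""
    if not lo < hi <= spec.resample_rate / 2.0 + 1e-12:
        raise ValueError(f"band [{lo}, {hi}] outside the spectral grid")
    grid = np.linspace(lo, hi, 201)
    vals = np.interp(grid, spec.freqs, spec.psd)
    return float(np.trapezoid(vals, grid))


def _phase_of_window(w0: float, w1: float, annotations: pd.DataFrame) -> str:
    inside = annotations[(annotations.start_ms <= w0) & (annotations.end_ms >= w1)]
    if len(inside):
        return str(inside.iloc[0].phase)
    return "free-living"


def _session_of_window(w0: float, w1: float, annotations: pd.DataFrame):
    inside = annotations[(annotations.start_ms <= w0) & (annotations.end_ms >= w1)]
    if len(inside):
        row = inside.iloc[0]
        return int(row.day), str(row.session)
    day = int(w0 // (24 * 3_600_000)) + 1
    return day, ""


def extract_features(
    t: np.ndarray,
    rr: np.ndarray,
    annotations: pd.DataFrame | None = None,
    window_ms: float = WINDOW_MS,
    stride_ms: float = WINDOW_MS,
    min_beats: int = MIN_BEATS,
    total_ms: float | None = None,
    resample_rate: float = 4.0,
    ar_order: int = 16,
) -> pd.DataFrame:
    """Per-window feature table over a cleaned, timestamped recording.

    Windows are anchored to the recording start on a ``stride_ms`` grid.  A
    window is labeled rest/stress only when it lies fully inside a single
    annotated phase; otherwise it is free-living.  Windows with fewer than
    ``min_beats`` surviving beats are flagged missing (never dropped).
    """
    t = np.asarray(t, dtype=float)
    rr = np.asarray(rr, dtype=float)
    end = total_ms if total_ms is not None else t[-1]
    n_windows = int(np.ceil(end / stride_ms))
    rows = []
    for w in range(n_windows):
        w0 = w * stride_ms
        w1 = w0 + window_ms
        lo, hi = np.searchsorted(t, [w0, w1])
        beats_t = t[lo:hi]
        beats_rr = rr[lo:hi]
        phase = (
            _phase_of_window(w0, w1, annotations) if annotations is not None else "free-living"
        )
        day, session = (
            _session_of_window(w0, w1, annotations)
            if annotations is not None
            else (int(w0 // (24 * 3_600_000)) + 1, "")
        )
        row = {
            "window_start_ms": w0,
            "window_end_ms": w1,
            "phase": phase,
            "day": day,
            "session": session,
            "n_beats": len(beats_rr),
            "missing": False,
        }
        if len(beats_rr) < min_beats:
            row["missing"] = True
            row.update({c: np.nan for c in FEATURE_COLUMNS})
        else:
            split = int(np.searchsorted(beats_t, w0 + 60_000.0))
            mean_nn, hr, sdnn, rmssd, pnn50 = time_domain(beats_rr, split)
            st1, st2 = poincare_axes(beats_rr)
            try:
                spec = ar_psd(beats_rr, beats_t, resample_rate, ar_order)
                vlf, lf, hf = (band_power(spec, *BANDS[b]) for b in ("vlf", "lf", "hf"))
            except ValueError:
                row["missing"] = True
                vlf = lf = hf = np.nan
            row.update(
                meanNN=mean_nn, HR=hr, SDNN=sdnn, RMSSD=rmssd, PNN50=pnn50,
                vlf=vlf, lf=lf, hf=hf, ST1=st1, ST2=st2,
            )
        rows.append(row)
    return pd.DataFrame(rows)


def write_feature_csv(features: pd.DataFrame, path) -> None:
    meta = [c for c in features.columns if c not in FEATURE_COLUMNS]
    features[meta + FEATURE_COLUMNS].to_csv(path, index=False)


def read_feature_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, keep_default_na=True).fillna({"session": ""})
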