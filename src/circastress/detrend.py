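"""Smoothness-priors detrending of feature series.

The series X is modelled as a stationary part plus a smooth trend.  The
trend is the penalized least-squares solution

    trend = argmin_z ||z - X||^2 + lambda^2 ||D_d z||^2
          = (I + lambda^2 D_d' D_d)^{-1} X,

with D_d the d-th order finite-difference operator (d = 2 by default, rows
[1, -2, 1]); the residual X - trend is the detrended series.  The residual
operator acts as a high-pass filter whose interior-point gain at angular
frequency w (rad/sample) is

    g(w) = lambda^2 (2 sin(w/2))^(2d) / (1 + lambda^2 (2 sin(w/2))^(2d)),

so lambda sets the cutoff: at lambda = 10000, d = 2 the half-power point is
w = lambda^{-1/2} = 0.01 rad/sample (about 0.0016 cycles/sample), which for
2-min samples suppresses the 24-h band while passing session-scale changes.

The linear system is symmetric positive definite and banded (bandwidth d);
it is solved with a banded Cholesky solve in O(n) time and memory — the
dense inverse is never formed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.linalg import solveh_banded

DEFAULT_LAMBDA = 10_000.0


@dataclass(frozen=True)
class SPAConfig:
    lam: float = DEFAULT_LAMBDA
    order: int = 2

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("lambda must be non-negative")
        if self.order not in (1, 2, 3):
            raise ValueError("difference order must be 1, 2 or 3")


@dataclass
class DetrendResult:
    trend: np.ndarray
    residual: np.ndarray
    config: SPAConfig


def difference_matrix(n: int, d: int = 2) -> sparse.csr_matrix:
    """(n-d) x n sparse d-th order finite-difference operator."""
    if n <= d:
        raise ValueError(f"need n > d (got n={n}, d={d})")
    coeffs = np.array([(-1) ** (d - j) * _binom(d, j) for j in range(d + 1)], dtype=float)
    diags = [np.full(n - d, c) for c in coeffs]
    return sparse.diags(diags, offsets=list(range(d + 1)), shape=(n - d, n)).tocsr()


def _binom(n: int, k: int) -> int:
    from math import comb

    return comb(n, k)


def spa_detrend(x: np.ndarray, config: SPAConfig | None = None) -> DetrendResult:
    """Split a series into smooth trend and detrended residual.

    Solves (I + lambda^2 D'D) trend = x via a symmetric banded solve; the
    residual is x - trend, so trend + residual reconstructs x exactly.
    """
    config = config or SPAConfig()
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n <= config.order:
        raise ValueError("series shorter than the difference order")
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains missing values; interpolate first")
    if config.lam == 0.0:
        return DetrendResult(trend=x.copy(), residual=np.zeros_like(x), config=config)
    d_mat = difference_matrix(n, config.order)
    # Woodbury/dual form: residual = D' (lambda^-2 I + D D')^-1 D x.
    # Unlike the primal system I + lambda^2 D'D (condition ~ lambda^2), this
    # stays well-posed for arbitrarily large lambda, and anything in the
    # null space of D (e.g. a linear ramp for d = 2) is trend exactly.
    m = n - config.order
    a = (d_mat @ d_mat.T).todia()
    ab = np.zeros((config.order + 1, m))
    for off in range(config.order + 1):
        ab[config.order - off, off:] = a.diagonal(off)
    ab[config.order] += 1.0 / config.lam**2
    y = solveh_banded(ab, d_mat @ x)
    residual = d_mat.T @ y
    return DetrendResult(trend=x - residual, residual=residual, config=config)


def frequency_response(config: SPAConfig, omega: np.ndarray | float) -> np.ndarray | float:
    """Interior-point high-pass gain of the residual filter at ``omega``
    (rad/sample), in [0, 1]."""
    w = np.asarray(omega, dtype=float)
    s = (2.0 * np.sin(w / 2.0)) ** (2 * config.order)
    g = config.lam**2 * s / (1.0 + config.lam**2 * s)
    return float(g) if np.isscalar(omega) else g


def half_power_cutoff(config: SPAConfig) -> float:
    """Angular frequency (rad/sample) where the residual gain crosses 1/2."""
    from scipy.optimize import brentq

    return float(brentq(lambda w: frequency_response(config, w) - 0.5, 1e-9, np.pi))


def detrend_feature_table(
    features: pd.DataFrame,
    config: SPAConfig | None = None,
    columns: list[str] | None = None,
) -> pd.DataFrame:
    """Detrend each feature column of a per-subject 2-min feature table.

    Missing windows are linearly interpolated before the solve and re-flagged
    as missing afterwards.  Returns a copy with feature columns replaced by
    residuals and ``<feature>_trend`` columns appended.
    """
    from .features import FEATURE_COLUMNS

    config = config or SPAConfig()
    columns = columns or [c for c in FEATURE_COLUMNS if c in features.columns]
    out = features.copy()
    missing = features["missing"].to_numpy(dtype=bool) if "missing" in features else None
    for col in columns:
        y = features[col].to_numpy(dtype=float)
        bad = ~np.isfinite(y)
        if bad.all():
            raise ValueError(f"column {col} has no valid samples")
        if bad.any():
            idx = np.arange(len(y))
            y = y.copy()
            y[bad] = np.interp(idx[bad], idx[~bad], y[~bad])
        res = spa_detrend(y, config)
        resid = res.residual.copy()
        trend = res.trend.copy()
        remask = bad if missing is None else (bad | missing)
        resid[remask] = np.nan
        trend[remask] = np.nan
        out[col] = resid
        out[col + "_trend"] = trend
    return out
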