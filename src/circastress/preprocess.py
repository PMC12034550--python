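"""RR-interval outlier removal with sliding-window confidence ellipses.

Consecutive intervals are embedded as 2-D points (RR_i, RR_{i+1}).  Within
each window a 95% confidence ellipse is fitted from the sample covariance of
the point cloud (scale s = 5.991, the chi-square 2-df 95% quantile), and a
point is an outlier when its squared Mahalanobis distance from the window
mean exceeds s.  In the eigenbasis of the covariance this is exactly the
ellipse inequality

    (R1' - c1)^2 / lambda1 + (R2' - c2)^2 / lambda2 <= s,

with axis half-lengths sqrt(s*lambda_k) and major-axis angle
alpha = arctan(v1_y / v1_x).  Windows of 50 intervals advance by 25 so each
interior interval is examined in two windows; the final window is anchored
to the last 50 intervals.  Of a flagged pair, the member farther from the
window median RR is removed (ties remove the later interval).  Data quality
is summarized by the coefficient of variation CV = sigma/mu of the interval
series before and after cleaning.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

#: chi-square(2 df) 95% quantile defining the 95% confidence ellipse
ELLIPSE_SCALE_95: float = float(np.round(stats.chi2.ppf(0.95, df=2), 3))

DEGENERATE_EIGVAL = 1e-6  # ms^2; below this the window is treated as clean


@dataclass(frozen=True)
class BeatPairSeries:
    """Overlapping 2-D embedding of an interval series.

    ``pairs[k] = (rr[k], rr[k+1])``; ``index_map[k] = (k, k+1)`` locates the
    two source intervals of pair k.
    """

    pairs: np.ndarray          # (N-1, 2)
    index_map: np.ndarray      # (N-1, 2) int

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass(frozen=True)
class ConfidenceEllipse:
    center: tuple[float, float]
    eigvals: tuple[float, float]        # (lambda1 >= lambda2), ms^2
    angle: float                        # rad, major axis vs +x, in (-pi/2, pi/2]
    scale: float = ELLIPSE_SCALE_95
    cov: np.ndarray | None = None       # sample covariance (kept for flagging)

    @property
    def degenerate(self) -> bool:
        return self.eigvals[1] < DEGENERATE_EIGVAL

    @property
    def axis_half_lengths(self) -> tuple[float, float]:
        return (
            float(np.sqrt(self.scale * self.eigvals[0])),
            float(np.sqrt(self.scale * max(self.eigvals[1], 0.0))),
        )


@dataclass(frozen=True)
class QualityReport:
    cv_before: float
    cv_after: float
    n_removed: int
    per_window_removals: np.ndarray


def embed_pairs(rr: np.ndarray) -> BeatPairSeries:
    """Embed N intervals as N-1 consecutive (RR_i, RR_{i+1}) points."""
    rr = np.asarray(rr, dtype=float)
    if len(rr) < 2:
        raise ValueError("need at least 2 intervals to form pairs")
    pairs = np.column_stack([rr[:-1], rr[1:]])
    idx = np.column_stack([np.arange(len(rr) - 1), np.arange(1, len(rr))])
    return BeatPairSeries(pairs=pairs, index_map=idx)


def fit_ellipse(pairs: BeatPairSeries | np.ndarray, s: float = ELLIPSE_SCALE_95) -> ConfidenceEllipse:
    """Confidence ellipse of a pair cloud: mean center, covariance eigenstructure."""
    pts = pairs.pairs if isinstance(pairs, BeatPairSeries) else np.asarray(pairs, dtype=float)
    if len(pts) < 3:
        raise ValueError("need at least 3 pairs to fit an ellipse")
    center = pts.mean(axis=0)
    cov = np.cov(pts, rowvar=False)
    if not np.all(np.isfinite(cov)):
        raise ValueError("covariance is not finite")
    eigvals, eigvecs = np.linalg.eigh(cov)          # ascending
    lam1, lam2 = float(eigvals[1]), float(eigvals[0])
    v1 = eigvecs[:, 1]
    angle = float(np.arctan2(v1[1], v1[0]))
    if angle <= -np.pi / 2:
        angle += np.pi
    elif angle > np.pi / 2:
        angle -= np.pi
    return ConfidenceEllipse(
        center=(float(center[0]), float(center[1])),
        eigvals=(lam1, lam2),
        angle=angle,
        scale=s,
        cov=cov,
    )


def flag_outliers(pairs: BeatPairSeries | np.ndarray, ellipse: ConfidenceEllipse) -> np.ndarray:
    """Boolean mask over pairs: True where the squared Mahalanobis distance to
    the ellipse center exceeds the scale s (the rotated ellipse inequality)."""
    pts = pairs.pairs if isinstance(pairs, BeatPairSeries) else np.asarray(pairs, dtype=float)
    if ellipse.degenerate:
        return np.zeros(len(pts), dtype=bool)
    d = pts - np.asarray(ellipse.center)
    c = ellipse.cov
    if c is None:  # rebuild covariance from the eigenstructure
        r = np.array(
            [[np.cos(ellipse.angle), -np.sin(ellipse.angle)],
             [np.sin(ellipse.angle), np.cos(ellipse.angle)]]
        )
        c = r @ np.diag(ellipse.eigvals) @ r.T
    det = c[0, 0] * c[1, 1] - c[0, 1] * c[1, 0]
    d2 = (
        c[1, 1] * d[:, 0] ** 2
        - 2.0 * c[0, 1] * d[:, 0] * d[:, 1]
        + c[0, 0] * d[:, 1] ** 2
    ) / det
    return d2 > ellipse.scale


def coefficient_of_variation(rr: np.ndarray) -> float:
    """CV = sigma/mu (population SD) of an interval series."""
    rr = np.asarray(rr, dtype=float)
    if len(rr) == 0:
        raise ValueError("empty series")
    mu = rr.mean()
    if mu == 0:
        raise ValueError("zero-mean series")
    return float(rr.std() / mu)


def _window_starts(n: int, window: int, step: int) -> np.ndarray:
    starts = list(range(0, max(n - window, 0) + 1, step))
    if starts[-1] != n - window:
        starts.append(n - window)      # final window anchored to series end
    return np.asarray(starts, dtype=int)


def sliding_clean(
    rr: np.ndarray,
    window: int = 50,
    step: int = 25,
    s: float = ELLIPSE_SCALE_95,
    return_mask: bool = False,
):
    """Remove RR outliers window by window and report CV before/after.

    An interval is removed iff some window flags a pair containing it and it
    is the pair member farther from that window's median RR.  Returns the
    cleaned series and a :class:`QualityReport` (plus the keep-mask if
    ``return_mask``).
    """
    rr = np.asarray(rr, dtype=float)
    n = len(rr)
    if n < 2:
        raise ValueError("need at least 2 intervals")
    window = min(window, n)
    starts = _window_starts(n, window, step)

    # vectorized per-window statistics over the pair clouds
    w_idx = starts[:, None] + np.arange(window)[None, :]     # (W, window)
    wdata = rr[w_idx]
    x = wdata[:, :-1]
    y = wdata[:, 1:]
    m = window - 1
    mx = x.mean(axis=1, keepdims=True)
    my = y.mean(axis=1, keepdims=True)
    dx = x - mx
    dy = y - my
    cxx = (dx * dx).sum(axis=1) / (m - 1)
    cyy = (dy * dy).sum(axis=1) / (m - 1)
    cxy = (dx * dy).sum(axis=1) / (m - 1)
    tr = cxx + cyy
    disc = np.sqrt(np.maximum((cxx - cyy) ** 2 + 4 * cxy**2, 0.0))
    lam2 = (tr - disc) / 2.0
    det = cxx * cyy - cxy**2
    ok = lam2 >= DEGENERATE_EIGVAL
    d2 = np.zeros_like(x)
    with np.errstate(divide="ignore", invalid="ignore"):
        d2[ok] = (
            cyy[ok, None] * dx[ok] ** 2
            - 2 * cxy[ok, None] * dx[ok] * dy[ok]
            + cxx[ok, None] * dy[ok] ** 2
        ) / det[ok, None]
    flagged = d2 > s

    medians = np.median(wdata, axis=1)
    remove = np.zeros(n, dtype=bool)
    per_window = np.zeros(len(starts), dtype=int)
    wi, pj = np.nonzero(flagged)
    for w, j in zip(wi, pj):
        i1 = starts[w] + j
        i2 = i1 + 1
        dev1 = abs(rr[i1] - medians[w])
        dev2 = abs(rr[i2] - medians[w])
        victim = i2 if dev2 >= dev1 else i1    # ties remove the later interval
        if not remove[victim]:
            per_window[w] += 1
        remove[victim] = True

    clean = rr[~remove]
    report = QualityReport(
        cv_before=coefficient_of_variation(rr),
        cv_after=coefficient_of_variation(clean) if len(clean) else float("nan"),
        n_removed=int(remove.sum()),
        per_window_removals=per_window,
    )
    if return_mask:
        return clean, report, ~remove
    return clean, report


def clean_recording(rec, window: int = 50, step: int = 25, s: float = ELLIPSE_SCALE_95):
    """Clean a synthetic recording, keeping timestamps and truth labels of the
    surviving beats.  Returns (t, rr, phase, artifact, QualityReport)."""
    _, report, keep = sliding_clean(rec.rr, window, step, s, return_mask=True)
    return (
        rec.t[keep],
        rec.rr[keep],
        rec.truth_phase[keep],
        rec.truth_artifact[keep],
        report,
    )
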