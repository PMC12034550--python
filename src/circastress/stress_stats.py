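"""Rest-vs-stress separability of HRV features via a two-group F statistic.

For one feature with rest samples x1 (n1 of them) and stress samples x2
(n2), the between- and within-group sums of squares are

    SSA = n1 (mean1 - grand)^2 + n2 (mean2 - grand)^2        (df = 1)
    SSE = sum (x1 - mean1)^2 + sum (x2 - mean2)^2            (df = n1+n2-2)

and F = SSA / (SSE / (n1+n2-2)), referred to the F(1, n1+n2-2) upper tail
(identical to one-way two-group ANOVA, i.e. the squared pooled t statistic).
The headline comparison computes F for each of the 10 features before and
after smoothness-priors detrending: removing the circadian confound should
raise F because rest/stress distributions from different times of day stop
overlapping.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .features import FEATURE_COLUMNS


@dataclass(frozen=True)
class GroupedFeatureSamples:
    rest: np.ndarray
    stress: np.ndarray

    def __post_init__(self) -> None:
        if len(self.rest) < 2 or len(self.stress) < 2:
            raise ValueError("both groups need at least 2 samples")


@dataclass(frozen=True)
class FStatResult:
    ssa: float
    sse: float
    df: tuple[int, int]
    f: float
    p: float


def f_statistic(groups: GroupedFeatureSamples) -> FStatResult:
    """Two-group F statistic with its F(1, n1+n2-2) upper-tail p-value."""
    x1 = np.asarray(groups.rest, dtype=float)
    x2 = np.asarray(groups.stress, dtype=float)
    n1, n2 = len(x1), len(x2)
    m1, m2 = x1.mean(), x2.mean()
    grand = np.concatenate([x1, x2]).mean()
    ssa = n1 * (m1 - grand) ** 2 + n2 * (m2 - grand) ** 2
    sse = np.sum((x1 - m1) ** 2) + np.sum((x2 - m2) ** 2)
    df2 = n1 + n2 - 2
    if sse == 0.0:
        if ssa == 0.0:
            raise ValueError("degenerate groups: SSA = SSE = 0")
        return FStatResult(float(ssa), 0.0, (1, df2), float("inf"), 0.0)
    f = float(ssa / (sse / df2))
    return FStatResult(float(ssa), float(sse), (1, df2), f, float(stats.f.sf(f, 1, df2)))


def grouped_samples(features: pd.DataFrame, column: str) -> GroupedFeatureSamples:
    """Pool a feature's rest- and stress-phase windows across the table."""
    ok = features["missing"] == False if "missing" in features else np.ones(len(features), bool)  # noqa: E712
    vals = features.loc[ok]
    rest = vals.loc[vals.phase == "rest", column].dropna().to_numpy()
    stress = vals.loc[vals.phase == "stress", column].dropna().to_numpy()
    return GroupedFeatureSamples(rest=rest, stress=stress)


def compare_detrending(
    raw: pd.DataFrame,
    detrended: pd.DataFrame,
    columns: list[str] | None = None,
) -> pd.DataFrame:
    """Per-feature table of (F_raw, F_detrended) over pooled session windows.

    ``raw`` and ``detrended`` are feature tables (possibly concatenated over
    subjects) carrying phase labels; rows must align.
    """
    columns = columns or FEATURE_COLUMNS
    if len(raw) != len(detrended):
        raise ValueError("raw and detrended tables must align row-wise")
    for tbl in (raw, detrended):
        if "phase" not in tbl or not {"rest", "stress"} <= set(tbl.phase.unique()):
            raise ValueError("both phases must be present")
    rows = []
    for col in columns:
        fr = f_statistic(grouped_samples(raw, col))
        fd = f_statistic(grouped_samples(detrended, col))
        rows.append(
            {
                "feature": col,
                "F_raw": fr.f,
                "p_raw": fr.p,
                "F_detrended": fd.f,
                "p_detrended": fd.p,
                "improved": fd.f > fr.f,
            }
        )
    return pd.DataFrame(rows).set_index("feature")
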