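"""Shared fixtures: synthetic recordings and cohort feature tables.

The expensive cohort (20 subjects x 3 days, full clean/feature/detrend
pipeline) is session-scoped and shared by the stress-statistics and
classification tests.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from circastress import classify, synth
from circastress.pipeline import cohort_feature_tables


@pytest.fixture(scope="session")
def default_subject() -> synth.RRRecording:
    """One default-profile 3-day recording."""
    return synth.simulate_subject(synth.SubjectProfile(subject_id="S_fix", seed=11))


@pytest.fixture(scope="session")
def quiet_subject() -> synth.RRRecording:
    """A noise-free, artifact-free subject: circadian law only."""
    profile = synth.SubjectProfile(
        subject_id="S_quiet", seed=12, hf_amp=0.0, lf_amp=0.0,
        noise_sd=0.0, artifact_rate=0.0, wander_sd=0.0, osc_gain_sd=0.0,
        stress_effect=synth.StressEffect(1e-9, 1e-9),
    )
    return synth.simulate_subject(profile)


@pytest.fixture(scope="session")
def cohort_tables():
    """Full-pipeline feature tables for a 20-subject, 3-day cohort.

    Returns (raw tables, detrended tables, ages, quality reports) keyed by
    subject id; built once per test session.
    """
    recs = synth.make_cohort(20, seed=0)
    raw, det, ages, quality = cohort_feature_tables(recs)
    return raw, det, ages, quality


@pytest.fixture(scope="session")
def cohort_datasets(cohort_tables):
    """Labeled session-window tables (raw, detrended) for the shared cohort."""
    raw, det, ages, _ = cohort_tables
    raw_data = classify.build_dataset(raw, detrended=False, ages=ages)
    det_data = classify.build_dataset(det, detrended=True, ages=ages)
    return raw_data, det_data


def mean_nn_series(rec: synth.RRRecording, stride_ms: float = 120_000.0) -> np.ndarray:
    """Plain per-window mean RR of a recording (no spectral features)."""
    total = rec.schedule.n_days * synth.MS_PER_DAY
    edges = np.arange(0.0, total + stride_ms, stride_ms)
    idx = np.searchsorted(rec.t, edges)
    out = np.full(len(edges) - 1, np.nan)
    for w in range(len(out)):
        seg = rec.rr[idx[w]: idx[w + 1]]
        if len(seg):
            out[w] = seg.mean()
    return out
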