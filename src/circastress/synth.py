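"""Synthetic multi-day RR-interval cohorts with known circadian structure.

Every downstream stage of the pipeline (cleaning, feature extraction,
rhythm fitting, detrending, stress classification) is validated against
recordings produced here, where the circadian law, the stress episodes and
the sensor artifacts are all known exactly.

The generator emulates a wearable study protocol: each subject is recorded
continuously for several days, with three stress-induction sessions per day
(default 08:30, 14:00, 22:30), each consisting of a pre-task rest phase, a
timed cognitive stress task, and a post-task rest phase.

Model
-----
The instantaneous mean RR interval (ms) follows a second-order sinusoid in
clock time,

    RR(x) = A0 + A1 sin(wx) + B1 cos(wx) + A2 sin(2wx) + B2 cos(2wx),

with x in 2-min samples and w = 2*pi/720 (a 24-h fundamental plus a 12-h
harmonic).  Beat-to-beat variability is added as two deterministic
oscillations — a vasomotor component near 0.1 Hz (LF) and a respiratory
component near 0.25 Hz (HF) — plus Gaussian beat-timing jitter.  The
oscillation amplitudes are coupled to the circadian cycle (high vagal tone
at night raises mean RR and short-term variability together), so every
derived HRV statistic, not just the mean, carries the circadian rhythm.
Slow Ornstein-Uhlenbeck wander of the mean RR and of the oscillation gain
adds the non-rhythmic low-frequency variability of real recordings, which
makes rest windows from different times of day overlap in feature space.
During stress phases the mean RR is multiplied by (1 - mean_drop) and the
oscillation amplitudes by (1 - var_shrink).

Beats are generated by integrate-to-threshold over the instantaneous rate
1/RR(t): the integral of the rate is accumulated on a fine time grid and a
beat is emitted at every unit crossing.  This guarantees that the sum of the
emitted intervals equals the elapsed recording time exactly.  Measurement
noise is modelled as jitter on the beat *times* (not the intervals), which
conserves elapsed time and matches how wearable beat detectors actually err.

Missed-beat artifacts merge two adjacent intervals into their sum; extra-beat
artifacts split one interval at a uniform random fraction in [0.3, 0.7].
Both conserve total elapsed time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

MS_PER_MIN = 60_000.0
MS_PER_DAY = 24 * 60 * MS_PER_MIN
SAMPLE_MS = 2 * MS_PER_MIN          # one circadian "sample" = 2 min
OMEGA_24H = 2.0 * np.pi / 720.0     # rad per 2-min sample

#: Cohort-level population means and spreads of the circadian amplitudes
#: (ms), in the order (A1, B1, A2, B2).  ``std1`` is the day-to-day spread
#: within a subject, ``std2`` the spread across subjects (std1 < std2).
POPULATION_AMPLITUDE_MEAN = np.array([77.60, -61.04, 2.28, -37.29])
POPULATION_AMPLITUDE_STD1 = np.array([11.08, 10.80, 1.16, 11.17])
POPULATION_AMPLITUDE_STD2 = np.array([41.98, 35.18, 27.12, 22.41])

PHASE_REST = "rest"
PHASE_STRESS = "stress"
PHASE_FREE = "free-living"

SESSION_NAMES = ("morning", "afternoon", "evening")


@dataclass(frozen=True)
class StressEffect:
    """Multiplicative stress response: fractional drop of the mean RR and
    fractional shrink of the beat-to-beat oscillation amplitudes."""

    mean_drop: float = 0.08
    var_shrink: float = 0.30

    def validate(self) -> None:
        for v in (self.mean_drop, self.var_shrink):
            if not 0.0 < v < 1.0:
                raise ValueError(f"stress effect components must lie in (0,1), got {v}")


@dataclass(frozen=True)
class SubjectProfile:
    """Everything needed to generate one subject's multi-day recording."""

    subject_id: str = "S00"
    baseline_rr: float = 900.0                  # A0, ms
    circadian_params: tuple[float, float, float, float] = tuple(POPULATION_AMPLITUDE_MEAN)
    omega: float = OMEGA_24H                    # rad per 2-min sample
    hf_amp: float = 25.0                        # ms, ~0.25 Hz respiratory
    lf_amp: float = 20.0                        # ms, ~0.1 Hz vasomotor
    noise_sd: float = 8.0                       # ms, beat-timing jitter SD
    #: coupling of the oscillation amplitudes to the normalized circadian
    #: mean-RR deviation, so short-term variability is itself rhythmic
    #: (high vagal tone at night raises both mean RR and HF/LF amplitude)
    circ_var_gain: float = 3.0
    #: slow non-rhythmic wander of the mean RR (OU process, ms) and of the
    #: oscillation gain (OU process, dimensionless), correlation time tau
    wander_sd: float = 25.0
    osc_gain_sd: float = 0.3
    wander_tau_s: float = 300.0
    stress_effect: StressEffect = field(default_factory=StressEffect)
    artifact_rate: float = 0.01                 # per-beat event probability
    age: int = 30
    seed: int = 0
    #: optional per-day circadian amplitudes (n_days x 4); overrides
    #: ``circadian_params`` day by day and models day-to-day drift
    day_params: tuple[tuple[float, float, float, float], ...] | None = None

    def validate(self) -> None:
        if self.baseline_rr <= 0:
            raise ValueError("baseline_rr must be positive")
        if not 0.0 <= self.artifact_rate < 0.05:
            raise ValueError("artifact_rate must lie in [0, 0.05)")
        self.stress_effect.validate()
        if self.omega <= 0:
            raise ValueError("omega must be positive")


@dataclass(frozen=True)
class SessionSchedule:
    """Daily stress-session layout: clock times and phase durations."""

    session_clock_times: tuple[str, ...] = ("08:30", "14:00", "22:30")
    pre_rest_min: float = 5.0
    stress_min: float = 4.0
    post_rest_min: float = 5.0
    n_days: int = 3

    def validate(self) -> None:
        if min(self.pre_rest_min, self.stress_min, self.post_rest_min) <= 0:
            raise ValueError("phase durations must be positive")
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")
        starts = sorted(_clock_to_ms(c) for c in self.session_clock_times)
        total = (self.pre_rest_min + self.stress_min + self.post_rest_min) * MS_PER_MIN
        for a, b in zip(starts, starts[1:]):
            if a + total > b:
                raise ValueError("sessions overlap within a day")
        if starts and starts[-1] + total > MS_PER_DAY:
            raise ValueError("last session runs past midnight")

    def windows(self) -> pd.DataFrame:
        """All phase windows over ``n_days`` as a table with columns
        subject-agnostic: day (1-based), session, phase, start_ms, end_ms."""
        rows = []
        order = np.argsort([_clock_to_ms(c) for c in self.session_clock_times])
        for day in range(self.n_days):
            base = day * MS_PER_DAY
            for k, idx in enumerate(order):
                name = SESSION_NAMES[k] if k < len(SESSION_NAMES) else f"session{k}"
                t0 = base + _clock_to_ms(self.session_clock_times[idx])
                t1 = t0 + self.pre_rest_min * MS_PER_MIN
                t2 = t1 + self.stress_min * MS_PER_MIN
                t3 = t2 + self.post_rest_min * MS_PER_MIN
                rows.append((day + 1, name, PHASE_REST, t0, t1))
                rows.append((day + 1, name, PHASE_STRESS, t1, t2))
                rows.append((day + 1, name, PHASE_REST, t2, t3))
        return pd.DataFrame(rows, columns=["day", "session", "phase", "start_ms", "end_ms"])


@dataclass
class RRRecording:
    """Timestamped beat-to-beat intervals for one subject.

    ``t`` holds cumulative time since recording start (ms) with
    ``t[i] - t[i-1] == rr[i]`` exactly; phase and artifact ground truth is
    carried per beat.
    """

    t: np.ndarray
    rr: np.ndarray
    truth_phase: np.ndarray
    truth_artifact: np.ndarray
    profile: SubjectProfile
    schedule: SessionSchedule

    def __post_init__(self) -> None:
        if np.any(self.rr <= 0):
            raise ValueError("RR intervals must be positive")
        if not np.allclose(np.diff(self.t, prepend=0.0), self.rr, rtol=0, atol=1e-6):
            raise ValueError("t must be the cumulative sum of rr")

    def __len__(self) -> int:
        return len(self.rr)

    @property
    def annotations(self) -> pd.DataFrame:
        return self.schedule.windows()


def _clock_to_ms(clock: str) -> float:
    h, m = clock.split(":")
    return (int(h) * 60 + int(m)) * MS_PER_MIN


def circadian_mean_rr(
    t_ms: np.ndarray,
    baseline: float,
    amplitudes: tuple[float, float, float, float],
    omega: float = OMEGA_24H,
) -> np.ndarray:
    """Second-order sinusoidal circadian law for the mean RR, evaluated at
    absolute recording time ``t_ms`` (x is measured in 2-min samples)."""
    x = np.asarray(t_ms, dtype=float) / SAMPLE_MS
    a1, b1, a2, b2 = amplitudes
    return (
        baseline
        + a1 * np.sin(omega * x)
        + b1 * np.cos(omega * x)
        + a2 * np.sin(2 * omega * x)
        + b2 * np.cos(2 * omega * x)
    )


def _ou_process(
    rng: np.random.Generator, n: int, dt_s: float, tau_s: float, sd: float
) -> np.ndarray:
    """Stationary Ornstein-Uhlenbeck sample path (AR(1) on the grid)."""
    from scipy.signal import lfilter

    a = np.exp(-dt_s / tau_s)
    white = rng.normal(0.0, 1.0, n)
    x = lfilter([sd * np.sqrt(1.0 - a**2)], [1.0, -a], white)
    x[0] = sd * white[0]
    return x


def _phase_of_times(t_ms: np.ndarray, windows: pd.DataFrame) -> np.ndarray:
    """Label each time with the phase window containing it (else free-living)."""
    phase = np.full(len(t_ms), PHASE_FREE, dtype=object)
    for _, w in windows.iterrows():
        inside = (t_ms >= w.start_ms) & (t_ms < w.end_ms)
        phase[inside] = w.phase
    return phase.astype(str)


def inject_artifacts(
    rr: np.ndarray, rate: float, seed: int | np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Inject missed-beat (merge) and extra-beat (split) sensor artifacts.

    Each beat independently triggers an event with probability ``rate``;
    events are missed or extra beats with equal probability.  A missed beat
    replaces two adjacent intervals by their sum; an extra beat splits one
    interval at a uniform fraction in [0.3, 0.7].  Total elapsed time is
    conserved and the returned mask marks every affected output interval.
    """
    if not 0.0 <= rate < 0.05:
        raise ValueError("artifact rate must lie in [0, 0.05)")
    rr = np.asarray(rr, dtype=float)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if rate == 0.0 or len(rr) == 0:
        return rr.copy(), np.zeros(len(rr), dtype=bool)

    hit = rng.random(len(rr)) < rate
    kind = rng.random(len(rr)) < 0.5        # True -> missed beat (merge)
    frac = rng.uniform(0.3, 0.7, len(rr))

    out: list[float] = []
    mask: list[bool] = []
    i = 0
    n = len(rr)
    while i < n:
        if hit[i] and kind[i] and i + 1 < n:
            out.append(rr[i] + rr[i + 1])
            mask.append(True)
            i += 2
        elif hit[i] and not kind[i]:
            out.append(rr[i] * frac[i])
            out.append(rr[i] * (1.0 - frac[i]))
            mask.extend((True, True))
            i += 1
        else:
            out.append(rr[i])
            mask.append(False)
            i += 1
    return np.asarray(out), np.asarray(mask, dtype=bool)


def simulate_subject(
    profile: SubjectProfile, schedule: SessionSchedule | None = None
) -> RRRecording:
    """Generate one subject's continuous multi-day RR recording.

    Deterministic given ``profile.seed``.  Raises if the parameter set would
    produce non-positive intervals (extreme amplitudes or jitter).
    """
    schedule = schedule or SessionSchedule()
    profile.validate()
    schedule.validate()
    rng = np.random.default_rng(np.random.SeedSequence([profile.seed, 0x5EED]))

    total_ms = schedule.n_days * MS_PER_DAY
    dt = 250.0                                   # integration grid step, ms
    grid = np.arange(0.0, total_ms, dt)

    # per-day circadian amplitudes (day-to-day drift if provided)
    mean_rr = np.empty_like(grid)
    for day in range(schedule.n_days):
        params = (
            profile.day_params[day]
            if profile.day_params is not None
            else profile.circadian_params
        )
        sel = slice(
            int(day * MS_PER_DAY / dt),
            int(min((day + 1) * MS_PER_DAY, total_ms) / dt) + 1,
        )
        mean_rr[sel] = circadian_mean_rr(
            grid[sel], profile.baseline_rr, tuple(params), profile.omega
        )

    windows = schedule.windows()
    stress = windows[windows.phase == PHASE_STRESS]
    mean_mult = np.ones_like(grid)
    osc_mult = np.ones_like(grid)
    for _, w in stress.iterrows():
        sel = (grid >= w.start_ms) & (grid < w.end_ms)
        mean_mult[sel] = 1.0 - profile.stress_effect.mean_drop
        osc_mult[sel] = 1.0 - profile.stress_effect.var_shrink

    t_sec = grid / 1000.0
    osc = profile.lf_amp * np.sin(2 * np.pi * 0.1 * t_sec) + profile.hf_amp * np.sin(
        2 * np.pi * 0.25 * t_sec
    )
    # circadian + stochastic modulation of the short-term variability
    z = (mean_rr - profile.baseline_rr) / profile.baseline_rr
    gain = 1.0 + profile.circ_var_gain * z
    if profile.osc_gain_sd > 0:
        gain = gain + _ou_process(rng, len(grid), dt / 1000.0,
                                  profile.wander_tau_s, profile.osc_gain_sd)
    gain = np.clip(gain, 0.15, None)
    wander = (
        _ou_process(rng, len(grid), dt / 1000.0, profile.wander_tau_s, profile.wander_sd)
        if profile.wander_sd > 0
        else 0.0
    )
    rr_inst = (mean_rr + wander) * mean_mult + osc * gain * osc_mult
    if np.any(rr_inst <= 50.0):
        raise ValueError(
            f"profile {profile.subject_id}: instantaneous RR drops to "
            f"{rr_inst.min():.1f} ms; rejecting extreme parameter set"
        )

    # integrate-to-threshold: beat at every unit crossing of int(1/RR dt)
    beats_accum = np.cumsum(dt / rr_inst)
    n_beats = int(np.floor(beats_accum[-1]))
    t_beats = np.interp(np.arange(1, n_beats + 1), beats_accum, grid + dt)

    if profile.noise_sd > 0:
        t_beats = t_beats + rng.normal(0.0, profile.noise_sd, n_beats)
    rr = np.diff(t_beats, prepend=0.0)
    if np.any(rr <= 0):
        raise ValueError(
            f"profile {profile.subject_id}: timing jitter produced a "
            "non-positive interval; rejecting extreme parameter set"
        )

    rr, artifact = inject_artifacts(rr, profile.artifact_rate, rng)
    t = np.cumsum(rr)
    midpoints = t - rr / 2.0
    phase = _phase_of_times(midpoints, windows)
    return RRRecording(
        t=t, rr=rr, truth_phase=phase, truth_artifact=artifact,
        profile=profile, schedule=schedule,
    )


@dataclass(frozen=True)
class CohortVariability:
    """Spread of circadian amplitudes: within-subject day-to-day (intra) and
    between-subject (inter), one SD per amplitude (A1, B1, A2, B2)."""

    intra_day_sd: tuple[float, float, float, float] = tuple(POPULATION_AMPLITUDE_STD1)
    inter_subject_sd: tuple[float, float, float, float] = tuple(POPULATION_AMPLITUDE_STD2)

    def validate(self) -> None:
        intra = np.asarray(self.intra_day_sd, dtype=float)
        inter = np.asarray(self.inter_subject_sd, dtype=float)
        if np.any(intra < 0) or np.any(inter < 0):
            raise ValueError("variability SDs must be non-negative")
        if np.any(intra >= inter) and np.any(inter > 0):
            raise ValueError(
                "intra-day SD must be below inter-subject SD for each amplitude"
            )


def sample_profiles(
    n_subjects: int,
    variability: CohortVariability | None = None,
    seed: int = 0,
    n_days: int = 3,
    baseline_sd: float = 60.0,
    artifact_rate: float = 0.01,
) -> list[SubjectProfile]:
    """Draw per-subject generator profiles around the population means.

    Ages are drawn so that about half the cohort is 26 or younger (matching
    the age split used by the classification scenarios).
    """
    if n_subjects < 2:
        raise ValueError("a cohort needs at least 2 subjects")
    variability = variability or CohortVariability()
    variability.validate()
    ss = np.random.SeedSequence([seed, 0xC0F0])
    rng = np.random.default_rng(ss)
    inter = np.asarray(variability.inter_subject_sd, dtype=float)
    intra = np.asarray(variability.intra_day_sd, dtype=float)

    profiles = []
    child_seeds = ss.generate_state(n_subjects)
    for i in range(n_subjects):
        amps = POPULATION_AMPLITUDE_MEAN + rng.normal(0.0, 1.0, 4) * inter
        day_amps = amps + rng.normal(0.0, 1.0, (n_days, 4)) * intra
        young = i % 2 == 0
        age = int(rng.integers(23, 27)) if young else int(rng.integers(27, 51))
        profiles.append(
            SubjectProfile(
                subject_id=f"S{i:02d}",
                baseline_rr=float(rng.normal(900.0, baseline_sd)),
                circadian_params=tuple(amps),
                day_params=tuple(tuple(row) for row in day_amps),
                age=age,
                artifact_rate=artifact_rate,
                seed=int(child_seeds[i] % (2**31)),
            )
        )
    return profiles


def make_cohort(
    n_subjects: int,
    variability: CohortVariability | None = None,
    seed: int = 0,
    schedule: SessionSchedule | None = None,
    artifact_rate: float = 0.01,
) -> list[RRRecording]:
    """Generate a seed-reproducible cohort of multi-day recordings."""
    schedule = schedule or SessionSchedule()
    profiles = sample_profiles(
        n_subjects, variability, seed, n_days=schedule.n_days,
        artifact_rate=artifact_rate,
    )
    return [simulate_subject(p, schedule) for p in profiles]


# ---------------------------------------------------------------------------
# on-disk interchange formats

def write_rr_text(rec: RRRecording, path: str | Path) -> None:
    """One RR interval in ms per line — the de-facto HRV interchange format."""
    np.savetxt(path, rec.rr, fmt="%.3f")


def read_rr_text(path: str | Path) -> np.ndarray:
    return np.loadtxt(path, ndmin=1)


def write_rr_csv(rec: RRRecording, path: str | Path) -> None:
    pd.DataFrame(
        {
            "t_ms": rec.t,
            "rr_ms": rec.rr,
            "phase": rec.truth_phase,
            "artifact": rec.truth_artifact.astype(int),
        }
    ).to_csv(path, index=False)


def read_rr_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_annotations(rec: RRRecording, path: str | Path) -> None:
    ann = rec.annotations.copy()
    ann.insert(0, "subject", rec.profile.subject_id)
    ann.to_csv(path, index=False)


def write_cohort_manifest(recs: list[RRRecording], path: str | Path) -> None:
    manifest = {
        "n_subjects": len(recs),
        "subjects": [
            {
                "subject_id": r.profile.subject_id,
                "age": r.profile.age,
                "baseline_rr": r.profile.baseline_rr,
                "circadian_params": list(r.profile.circadian_params),
                "artifact_rate": r.profile.artifact_rate,
                "seed": r.profile.seed,
                "n_beats": int(len(r)),
                "n_days": r.schedule.n_days,
            }
            for r in recs
        ],
    }
    Path(path).write_text(json.dumps(manifest, indent=2))
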