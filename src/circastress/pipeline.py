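"""End-to-end orchestration: simulate -> clean -> features -> rhythm ->
detrend -> stats -> classify, with a reproducible run manifest.

Two layers:

* in-memory helpers (:func:`cohort_feature_tables`, :func:`cohort_analysis`)
  used by the test-suite and analysis drivers — no disk round-trips;
* :func:`run_pipeline`, which executes the staged pipeline against a
  :class:`RunConfig`, writes every artifact under an output directory,
  content-hashes inputs/outputs into ``run_manifest.json`` and skips stages
  whose outputs are already up to date for the same configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import circadian, classify, detrend, features, preprocess, stress_stats, synth

STAGES = ("simulate", "clean", "features", "rhythm", "detrend", "stats", "classify")


@dataclass
class RunConfig:
    """Every tunable of the staged pipeline, echoed into the run manifest."""

    outdir: str = "results/run"
    seed: int = 0
    stages: tuple[str, ...] = STAGES
    # cohort
    n_subjects: int = 6
    n_days: int = 3
    artifact_rate: float = 0.01
    session_clock_times: tuple[str, ...] = ("08:30", "14:00", "22:30")
    stress_min: float = 4.0
    # cleaning
    window: int = 50
    step: int = 25
    scale: float = preprocess.ELLIPSE_SCALE_95
    # features
    ar_order: int = 16
    resample_rate: float = 4.0
    # detrending
    lam: float = 10_000.0
    order: int = 2
    # classification
    holdout_fraction: float = 0.2
    top_k_features: int = 7
    rhythm_feature: str = "meanNN"

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("stages", "session_clock_times"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        d["session_clock_times"] = list(self.session_clock_times)
        return d

    def schedule(self) -> synth.SessionSchedule:
        return synth.SessionSchedule(
            session_clock_times=self.session_clock_times,
            stress_min=self.stress_min,
            n_days=self.n_days,
        )


# ---------------------------------------------------------------------------
# in-memory cohort analysis

def cohort_feature_tables(
    recs: list[synth.RRRecording],
    clean: bool = True,
    lam: float = 10_000.0,
    order: int = 2,
    window: int = 50,
    step: int = 25,
    scale: float = preprocess.ELLIPSE_SCALE_95,
    ar_order: int = 16,
    resample_rate: float = 4.0,
):
    """Raw and detrended per-subject feature tables (plus ages and quality
    reports) for a generated cohort."""
    raw, det, ages, quality = {}, {}, {}, {}
    cfg = detrend.SPAConfig(lam=lam, order=order)
    for rec in recs:
        sid = rec.profile.subject_id
        if clean:
            t, rr, _, _, rep = preprocess.clean_recording(rec, window, step, scale)
            quality[sid] = rep
        else:
            t, rr = rec.t, rec.rr
        tbl = features.extract_features(
            t, rr, rec.annotations,
            total_ms=rec.schedule.n_days * synth.MS_PER_DAY,
            resample_rate=resample_rate, ar_order=ar_order,
        )
        raw[sid] = tbl
        det[sid] = detrend.detrend_feature_table(tbl, cfg)
        ages[sid] = rec.profile.age
    return raw, det, ages, quality


def cohort_rhythms(
    raw_tables: dict[str, pd.DataFrame], column: str = "meanNN"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pooled/day-wise sinusoid fits and the std1/std2 variability summary."""
    day_fits, pooled_fits, rows = {}, {}, []
    for sid, tbl in raw_tables.items():
        by_day, pooled = circadian.fit_subject_rhythms(tbl, column)
        day_fits[sid] = by_day
        pooled_fits[sid] = pooled
        rows.append(
            dict(subject=sid, day=0, A0=pooled.A0, A1=pooled.A1, B1=pooled.B1,
                 A2=pooled.A2, B2=pooled.B2, omega=pooled.omega, rss=pooled.rss)
        )
        for d, f in by_day.items():
            rows.append(
                dict(subject=sid, day=d, A0=f.A0, A1=f.A1, B1=f.B1,
                     A2=f.A2, B2=f.B2, omega=f.omega, rss=f.rss)
            )
    summary = circadian.rhythm_variability(day_fits, pooled_fits)
    return pd.DataFrame(rows), summary


def cohort_analysis(
    n_subjects: int = 6,
    seed: int = 0,
    clean: bool = True,
    schedule: synth.SessionSchedule | None = None,
    artifact_rate: float = 0.01,
    **table_kwargs,
):
    """Convenience end-to-end: cohort -> (raw table, detrended table, ages)."""
    schedule = schedule or synth.SessionSchedule()
    recs = synth.make_cohort(
        n_subjects, seed=seed, schedule=schedule, artifact_rate=artifact_rate
    )
    raw, det, ages, _ = cohort_feature_tables(recs, clean=clean, **table_kwargs)
    raw_data = classify.build_dataset(raw, detrended=False, ages=ages)
    det_data = classify.build_dataset(det, detrended=True, ages=ages)
    return raw_data, det_data, ages


# ---------------------------------------------------------------------------
# input validation

@dataclass
class ValidationReport:
    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def validate_inputs(rr_paths: list, annotation_path=None) -> ValidationReport:
    """Sanity-check on-disk RR files and a session-annotation table.

    Flags non-positive or implausible intervals (outside 200-3000 ms is a
    warning band) and overlapping annotated sessions.
    """
    report = ValidationReport()
    for path in rr_paths:
        path = Path(path)
        try:
            rr = synth.read_rr_text(path)
        except Exception as exc:  # malformed file
            report.errors.append(f"{path}: unreadable ({exc})")
            continue
        bad = np.nonzero(rr <= 0)[0]
        if len(bad):
            report.errors.append(f"{path}: non-positive RR at line {bad[0] + 1}")
        out = np.nonzero((rr < 200) | (rr > 3000))[0]
        if len(out):
            report.warnings.append(
                f"{path}: {len(out)} intervals outside the 200-3000 ms "
                f"plausibility band (first at line {out[0] + 1})"
            )
    if annotation_path is not None:
        ann = pd.read_csv(annotation_path)
        key = ["subject", "day"] if "subject" in ann else ["day"]
        for _, grp in ann.groupby(key):
            grp = grp.sort_values("start_ms")
            overlap = grp.start_ms.to_numpy()[1:] < grp.end_ms.to_numpy()[:-1]
            if overlap.any():
                report.errors.append(f"overlapping sessions for {key}={_}")
    return report


# ---------------------------------------------------------------------------
# staged on-disk pipeline

def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_hash(config: RunConfig) -> str:
    # the stage *selection* is not part of the computation's identity, so
    # running later stages on top of an earlier partial run reuses artifacts
    payload = {k: v for k, v in config.to_dict().items() if k != "stages"}
    return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()


def run_pipeline(config: RunConfig, force: bool = False) -> dict:
    """Execute the staged pipeline, returning the run manifest.

    Stage outputs live under ``config.outdir``; a stage is skipped when the
    manifest records the same configuration hash and all its outputs still
    exist.  A stage failure aborts with the failing stage named; outputs are
    written to temporaries and renamed, so no partial artifact overwrites a
    previous run.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "run_manifest.json"
    previous = json.loads(manifest_path.read_text()) if manifest_path.exists() else {}
    cfg_hash = _config_hash(config)
    reuse = previous.get("config_hash") == cfg_hash and not force
    manifest = {
        "config": config.to_dict(),
        "config_hash": cfg_hash,
        "stages": dict(previous.get("stages", {})) if reuse else {},
    }

    state: dict = {}
    for stage in STAGES:
        if stage not in config.stages:
            continue
        prev_stage = previous.get("stages", {}).get(stage, {})
        outputs = [out / p for p in prev_stage.get("outputs", [])]
        if reuse and outputs and all(p.exists() for p in outputs):
            manifest["stages"][stage] = dict(prev_stage, skipped=True)
            _load_stage_state(stage, out, config, state)
            continue
        try:
            written = _run_stage(stage, out, config, state)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc
        manifest["stages"][stage] = {
            "outputs": [str(p.relative_to(out)) for p in written],
            "sha256": {str(p.relative_to(out)): _sha256(p) for p in written},
            "skipped": False,
        }
    _atomic_write(manifest_path, json.dumps(manifest, indent=2))
    return manifest


def _atomic_write(path: Path, text: str) -> None:
    tmp = path.with_suffix(path.suffix + ".tmp")
    tmp.write_text(text)
    tmp.replace(path)


def _load_stage_state(stage: str, out: Path, config: RunConfig, state: dict) -> None:
    """Rehydrate in-memory state for a skipped stage from its artifacts."""
    if stage == "simulate":
        state["rr_frames"] = {
            p.stem: pd.read_csv(p) for p in sorted((out / "rr").glob("S*.csv"))
        }
        state["annotations"] = pd.read_csv(out / "rr" / "annotations.csv")
        state["cohort_meta"] = json.loads((out / "rr" / "manifest.json").read_text())
    elif stage == "clean":
        state["clean_frames"] = {
            p.stem: pd.read_csv(p) for p in sorted((out / "clean").glob("S*.csv"))
        }
    elif stage == "features":
        state["raw_tables"] = {
            p.stem: features.read_feature_csv(p) for p in sorted((out / "features").glob("S*.csv"))
        }
    elif stage == "detrend":
        state["det_tables"] = {
            p.stem: features.read_feature_csv(p) for p in sorted((out / "detrended").glob("S*.csv"))
        }


def _run_stage(stage: str, out: Path, config: RunConfig, state: dict) -> list[Path]:
    written: list[Path] = []
    if stage == "simulate":
        schedule = config.schedule()
        recs = synth.make_cohort(
            config.n_subjects, seed=config.seed, schedule=schedule,
            artifact_rate=config.artifact_rate,
        )
        rr_dir = out / "rr"
        rr_dir.mkdir(exist_ok=True)
        frames = {}
        for rec in recs:
            sid = rec.profile.subject_id
            synth.write_rr_text(rec, rr_dir / f"{sid}.txt")
            synth.write_rr_csv(rec, rr_dir / f"{sid}.csv")
            written += [rr_dir / f"{sid}.txt", rr_dir / f"{sid}.csv"]
            frames[sid] = pd.read_csv(rr_dir / f"{sid}.csv")
        ann = recs[0].annotations.copy()
        ann.insert(0, "subject", "all")
        ann.to_csv(rr_dir / "annotations.csv", index=False)
        synth.write_cohort_manifest(recs, rr_dir / "manifest.json")
        written += [rr_dir / "annotations.csv", rr_dir / "manifest.json"]
        state["rr_frames"] = frames
        state["annotations"] = ann
        state["cohort_meta"] = json.loads((rr_dir / "manifest.json").read_text())
        if config.lam == 0.0:
            warnings.warn(
                "lambda = 0 disables detrending: residuals are identically "
                "zero and the detrended classifier degenerates to the "
                "majority class", stacklevel=2,
            )
    elif stage == "clean":
        clean_dir = out / "clean"
        clean_dir.mkdir(exist_ok=True)
        state["clean_frames"] = {}
        quality = {}
        for sid, frame in state["rr_frames"].items():
            rr = frame.rr_ms.to_numpy()
            _, rep, keep = preprocess.sliding_clean(
                rr, config.window, config.step, config.scale, return_mask=True
            )
            kept = frame[keep]
            kept.to_csv(clean_dir / f"{sid}.csv", index=False)
            np.savetxt(clean_dir / f"{sid}.txt", kept.rr_ms.to_numpy(), fmt="%.3f")
            written += [clean_dir / f"{sid}.csv", clean_dir / f"{sid}.txt"]
            quality[sid] = dict(
                cv_before=rep.cv_before, cv_after=rep.cv_after, n_removed=rep.n_removed
            )
            state["clean_frames"][sid] = kept
        _atomic_write(clean_dir / "quality.json", json.dumps(quality, indent=2))
        written.append(clean_dir / "quality.json")
    elif stage == "features":
        feat_dir = out / "features"
        feat_dir.mkdir(exist_ok=True)
        ann = state["annotations"]
        state["raw_tables"] = {}
        for sid, frame in state["clean_frames"].items():
            tbl = features.extract_features(
                frame.t_ms.to_numpy(), frame.rr_ms.to_numpy(), ann,
                total_ms=config.n_days * synth.MS_PER_DAY,
                resample_rate=config.resample_rate, ar_order=config.ar_order,
            )
            features.write_feature_csv(tbl, feat_dir / f"{sid}.csv")
            written.append(feat_dir / f"{sid}.csv")
            state["raw_tables"][sid] = tbl
    elif stage == "rhythm":
        rhythm_dir = out / "rhythm"
        rhythm_dir.mkdir(exist_ok=True)
        fits, summary = cohort_rhythms(state["raw_tables"], config.rhythm_feature)
        fits.to_csv(rhythm_dir / "fits.csv", index=False)
        summary.to_csv(rhythm_dir / "variability.csv")
        spectra = [
            circadian.period_spectrum(t[config.rhythm_feature].to_numpy())
            for t in state["raw_tables"].values()
        ]
        summ = circadian.summarize_cohort_spectra(spectra)
        pd.DataFrame(
            {
                "period_samples": summ.period_axis,
                "mean_amplitude": summ.mean_amplitude,
                "ci95_low": summ.ci95_low,
                "ci95_high": summ.ci95_high,
            }
        ).to_csv(rhythm_dir / "cohort_spectrum.csv", index=False)
        written += [rhythm_dir / "fits.csv", rhythm_dir / "variability.csv",
                    rhythm_dir / "cohort_spectrum.csv"]
    elif stage == "detrend":
        det_dir = out / "detrended"
        det_dir.mkdir(exist_ok=True)
        cfg = detrend.SPAConfig(lam=config.lam, order=config.order)
        state["det_tables"] = {}
        for sid, tbl in state["raw_tables"].items():
            det = detrend.detrend_feature_table(tbl, cfg)
            features.write_feature_csv(det, det_dir / f"{sid}.csv")
            written.append(det_dir / f"{sid}.csv")
            state["det_tables"][sid] = det
    elif stage == "stats":
        stats_dir = out / "stats"
        stats_dir.mkdir(exist_ok=True)
        raw_all = pd.concat(state["raw_tables"].values(), ignore_index=True)
        det_all = pd.concat(
            [state["det_tables"][s] for s in state["raw_tables"]], ignore_index=True
        )
        table = stress_stats.compare_detrending(raw_all, det_all)
        table.to_csv(stats_dir / "f_table.csv")
        _atomic_write(stats_dir / "f_table.json", table.to_json(indent=2))
        written += [stats_dir / "f_table.csv", stats_dir / "f_table.json"]
    elif stage == "classify":
        cls_dir = out / "classify"
        cls_dir.mkdir(exist_ok=True)
        ages = {
            s["subject_id"]: s["age"] for s in state["cohort_meta"]["subjects"]
        }
        raw_data = classify.build_dataset(state["raw_tables"], False, ages)
        det_data = classify.build_dataset(state["det_tables"], True, ages)
        cfg = classify.TrainingConfig(
            holdout_fraction=config.holdout_fraction,
            top_k_features=config.top_k_features,
            seed=config.seed,
        )
        reports = classify.evaluate_scenarios(raw_data, det_data, config=cfg)
        classify.accuracy_matrix(reports).to_csv(cls_dir / "accuracy.csv")
        payload = [
            {
                "name": r.spec.name,
                "detrended": r.spec.detrended,
                "overall_accuracy": r.overall_accuracy,
                "accuracy": {str(k): v for k, v in r.accuracy.items()},
                "holdout_f1": r.holdout_f1,
                "selected_features": r.selected_features,
                "best_params": r.best_params,
                "importances": r.importances.to_dict(),
                "n_train": r.n_train,
            }
            for r in reports
        ]
        _atomic_write(cls_dir / "reports.json", json.dumps(payload, indent=2))
        written += [cls_dir / "accuracy.csv", cls_dir / "reports.json"]
    else:  # pragma: no cover
        raise ValueError(f"unknown stage {stage}")
    return written
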