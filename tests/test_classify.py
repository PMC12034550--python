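"""Classifier plumbing: dataset assembly, coordinate-wise grid search,
gain importances, top-k selection, scenario evaluation and split hygiene."""

import numpy as np
import pandas as pd
import pytest

from circastress import classify
from circastress.classify import (
    ScenarioSpec,
    TrainingConfig,
    build_dataset,
    feature_importance,
    grid_search_train,
    run_scenario,
    select_top_k,
)
from circastress.features import FEATURE_COLUMNS

SMALL_GRID = {"n_estimators": (25, 50), "max_depth": (2, 3), "learning_rate": (0.1, 0.3)}


def synthetic_table(n=400, informative=1.5, seed=0, sessions=("morning", "afternoon", "evening")):
    """A labeled feature table where `meanNN` carries the class signal and
    the remaining features are noise."""
    rng = np.random.default_rng(seed)
    label = rng.integers(0, 2, n)
    data = {c: rng.normal(0, 1, n) for c in FEATURE_COLUMNS}
    data["meanNN"] = data["meanNN"] - informative * label
    tbl = pd.DataFrame(data)
    tbl["label"] = label
    tbl["phase"] = np.where(label == 1, "stress", "rest")
    tbl["session"] = rng.choice(sessions, n)
    tbl["day"] = rng.integers(1, 4, n)
    tbl["subject"] = rng.choice([f"S{i}" for i in range(10)], n)
    tbl["age"] = 24 + 10 * (tbl.subject.str[1:].astype(int) % 2)
    tbl["missing"] = False
    return tbl


class TestBuildDataset:
    def test_row_count_matches_annotation_oracle(self, cohort_tables):
        raw, _, ages, _ = cohort_tables
        data = build_dataset(raw, ages=ages)
        expected = sum(
            ((t.phase.isin(["rest", "stress"])) & (~t.missing)).sum()
            for t in raw.values()
        )
        assert len(data) == expected
        assert set(data.phase) == {"rest", "stress"}

    def test_free_living_windows_never_enter(self, cohort_tables):
        raw, _, ages, _ = cohort_tables
        data = build_dataset(raw, ages=ages)
        assert (data.phase != "free-living").all()

    def test_detrended_flag_preserves_labels(self, cohort_tables):
        raw, det, ages, _ = cohort_tables
        a = build_dataset(raw, detrended=False, ages=ages)
        b = build_dataset(det, detrended=True, ages=ages)
        assert a.label.tolist() == b.label.tolist()
        assert b.detrended.all() and not a.detrended.any()

    def test_single_class_rejected(self):
        tbl = synthetic_table(50)
        tbl = tbl[tbl.phase == "rest"]
        with pytest.raises(ValueError):
            build_dataset({"s": tbl})


class TestGridSearch:
    def test_separable_data_reaches_perfect_holdout_f1(self):
        tbl = synthetic_table(300, informative=50.0)
        _, _, f1, _ = grid_search_train(tbl, TrainingConfig(seed=0, grid=SMALL_GRID))
        assert f1 == pytest.approx(1.0)

    def test_permuted_labels_score_near_chance(self):
        f1s = []
        for seed in range(3):
            tbl = synthetic_table(400, informative=0.0, seed=seed)
            _, _, f1, _ = grid_search_train(tbl, TrainingConfig(seed=seed, grid=SMALL_GRID))
            f1s.append(f1)
        assert 0.3 < np.mean(f1s) < 0.7

    def test_same_seed_selects_same_parameters(self):
        tbl = synthetic_table(300)
        cfg = TrainingConfig(seed=7, grid=SMALL_GRID)
        _, best1, _, _ = grid_search_train(tbl, cfg)
        _, best2, _, _ = grid_search_train(tbl, cfg)
        assert best1 == best2

    def test_coordinate_search_walks_grid_in_order(self):
        tbl = synthetic_table(300)
        _, _, _, trace = grid_search_train(tbl, TrainingConfig(seed=0, grid=SMALL_GRID))
        assert [t["param"] for t in trace] == list(SMALL_GRID)


class TestImportance:
    def test_informative_feature_ranks_first(self):
        tbl = synthetic_table(600, informative=3.0)
        model, _, _, _ = grid_search_train(tbl, TrainingConfig(seed=1, grid=SMALL_GRID))
        ranking = feature_importance(model)
        assert ranking.index[0] == "meanNN"

    def test_importances_normalized(self):
        tbl = synthetic_table(300)
        model, _, _, _ = grid_search_train(tbl, TrainingConfig(seed=2, grid=SMALL_GRID))
        assert feature_importance(model).sum() == pytest.approx(1.0)

    def test_duplicated_signal_column_outranks_noise(self):
        tbl = synthetic_table(600, informative=3.0, seed=3)
        tbl["SDNN"] = tbl["meanNN"] + np.random.default_rng(9).normal(0, 1e-6, len(tbl))
        model, _, _, _ = grid_search_train(tbl, TrainingConfig(seed=3, grid=SMALL_GRID))
        ranking = feature_importance(model)
        combined = ranking["meanNN"] + ranking["SDNN"]
        noise = [c for c in FEATURE_COLUMNS if c not in ("meanNN", "SDNN")]
        assert combined > ranking[noise].max()


class TestTopK:
    def test_identity_when_k_equals_length(self):
        r = pd.Series(np.linspace(1, 0, 10), index=FEATURE_COLUMNS)
        assert set(select_top_k(r, 10)) == set(FEATURE_COLUMNS)

    def test_cardinality(self):
        r = pd.Series(np.linspace(1, 0, 10), index=FEATURE_COLUMNS)
        assert len(select_top_k(r, 7)) == 7

    def test_ties_break_by_feature_name(self):
        r = pd.Series(1.0, index=["b", "a", "c"])
        assert select_top_k(r, 2) == ["a", "b"]


class TestScenarios:
    def test_split_hygiene_holdout_disjoint_from_training(self):
        data = synthetic_table(400)
        rep = run_scenario(data, ScenarioSpec(name="int"), TrainingConfig(seed=0, grid=SMALL_GRID))
        assert len(rep.train_index.intersection(rep.eval_index)) == 0

    def test_full_own_eval_scores_everything(self):
        data = synthetic_table(400)
        cfg = TrainingConfig(seed=0, grid=SMALL_GRID, own_eval="full")
        rep = run_scenario(data, ScenarioSpec(name="int"), cfg)
        assert len(rep.eval_index) == len(data)

    def test_scenario_determinism(self):
        data = synthetic_table(400)
        cfg = TrainingConfig(seed=5, grid=SMALL_GRID)
        a = run_scenario(data, ScenarioSpec(name="int"), cfg)
        b = run_scenario(data, ScenarioSpec(name="int"), cfg)
        assert a.overall_accuracy == b.overall_accuracy
        assert a.accuracy == b.accuracy
        assert a.selected_features == b.selected_features

    def test_session_scenario_trains_only_on_requested_session(self):
        data = synthetic_table(400)
        cfg = TrainingConfig(seed=0, grid=SMALL_GRID)
        rep = run_scenario(
            data, ScenarioSpec(name="m", train_sessions=("morning",)), cfg
        )
        assert (data.loc[rep.train_index].session == "morning").all()

    def test_day_group_scenario_filters_days(self):
        data = synthetic_table(400)
        cfg = TrainingConfig(seed=0, grid=SMALL_GRID)
        rep = run_scenario(
            data,
            ScenarioSpec(name="d1", group_by="day", group_value=2, eval_axis="day"),
            cfg,
        )
        assert (data.loc[rep.train_index].day == 2).all()
        assert set(rep.accuracy) <= {1, 2, 3}

    def test_age_group_scenario_filters_subjects(self):
        data = synthetic_table(400)
        cfg = TrainingConfig(seed=0, grid=SMALL_GRID)
        rep = run_scenario(
            data, ScenarioSpec(name="young", group_by="age", group_value="le26"), cfg
        )
        assert (data.loc[rep.train_index].age <= 26).all()

    def test_empty_group_rejected(self):
        data = synthetic_table(200)
        cfg = TrainingConfig(seed=0, grid=SMALL_GRID)
        with pytest.raises(ValueError):
            run_scenario(
                data, ScenarioSpec(name="d9", group_by="day", group_value=9), cfg
            )

    def test_paired_raw_detrended_share_sampling(self):
        raw = synthetic_table(400, seed=1)
        det = raw.copy()
        det[FEATURE_COLUMNS] = det[FEATURE_COLUMNS] + 0.01
        cfg = TrainingConfig(seed=3, grid=SMALL_GRID)
        reports = classify.evaluate_scenarios(
            raw, det,
            specs=[ScenarioSpec(name="a"), ScenarioSpec(name="b", detrended=True)],
            config=cfg,
        )
        assert reports[0].train_index.equals(reports[1].train_index)
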