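"""Cohort pipeline: harmonization, onset labeling, windowing, balancing."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nasga.catalog import default_catalog
from nasga.cohort import (
    CohortError,
    Episode,
    SirsAnnotation,
    TimeSeriesGrid,
    balance_classes,
    build_cohort,
    detect_onsets,
    detect_sirs,
    extract_episodes,
    filter_cohort,
    filter_episodes,
    find_sepsis_onset,
    harmonize_units,
    infection_evidence_hours,
    merge_features,
    resample_hourly,
    resolve_conflicts,
    split_dataset,
)
from oracles import brute_force_onset, brute_force_windows

CATALOG = default_catalog()


def events_frame(rows):
    return pd.DataFrame(
        rows,
        columns=["patient_id", "admission_id", "time", "feature_id", "value", "unit", "source"],
    )


def make_grid(data: np.ndarray, age: int = 50, pid: str = "P1") -> TimeSeriesGrid:
    return TimeSeriesGrid(patient_id=pid, admission_id="A1", data=data, age=age, gender="F")


def grid_with(feature_values: dict[str, np.ndarray], n_hours: int) -> TimeSeriesGrid:
    data = np.full((n_hours, CATALOG.n_features), np.nan)
    for name, values in feature_values.items():
        data[: len(values), CATALOG.column(name)] = values
    return make_grid(data)


class TestMergeFeatures:
    def test_heart_rate_ids_merge(self):
        events = events_frame(
            [
                ("P1", "A1", 0.5, "211", 80.0, "bpm", "chart"),
                ("P1", "A1", 1.5, "220045", 82.0, "bpm", "chart"),
            ]
        )
        out = merge_features(events, CATALOG)
        assert set(out["feature"]) == {"heart_rate"}

    def test_unmapped_dropped(self):
        events = events_frame(
            [
                ("P1", "A1", 0.5, "211", 80.0, "bpm", "chart"),
                ("P1", "A1", 0.5, "99999999", 1.0, "?", "chart"),
            ]
        )
        out = merge_features(events, CATALOG)
        assert len(out) == 1

    def test_temperature_ids_preserve_unit(self):
        events = events_frame(
            [
                ("P1", "A1", 0.2, "678", 98.6, "F", "chart"),
                ("P1", "A1", 1.2, "676", 37.0, "C", "chart"),
            ]
        )
        out = merge_features(events, CATALOG)
        assert set(out["feature"]) == {"temperature"}
        assert set(out["unit"]) == {"F", "C"}


class TestHarmonizeUnits:
    def test_weight_majority_milligrams(self):
        # 2 kg with two mg records: mg wins, kg converted by 1e6
        events = merge_features(
            events_frame(
                [
                    ("P1", "A1", 0.1, "763", 2.0, "kg", "chart"),
                    ("P1", "A1", 1.1, "763", 300.0, "mg", "chart"),
                    ("P1", "A1", 2.1, "763", 500.0, "mg", "chart"),
                ]
            ),
            CATALOG,
        )
        out = harmonize_units(events, CATALOG)
        assert set(out["unit"]) == {"mg"}
        assert sorted(out["value"]) == [300.0, 500.0, 2_000_000.0]

    def test_temperature_majority_celsius(self):
        events = merge_features(
            events_frame(
                [
                    ("P1", "A1", 0.1, "678", 98.6, "F", "chart"),
                    ("P1", "A1", 1.1, "676", 37.0, "C", "chart"),
                    ("P1", "A1", 2.1, "676", 36.5, "C", "chart"),
                ]
            ),
            CATALOG,
        )
        out = harmonize_units(events, CATALOG)
        assert set(out["unit"]) == {"C"}
        assert sorted(np.round(out["value"], 6)) == [36.5, 37.0, 37.0]

    def test_single_unit_unchanged(self):
        events = merge_features(
            events_frame([("P1", "A1", 0.1, "211", 80.0, "bpm", "chart")]), CATALOG
        )
        out = harmonize_units(events, CATALOG)
        assert out["value"].tolist() == [80.0]

    def test_unknown_unit_dropped(self):
        events = merge_features(
            events_frame(
                [
                    ("P1", "A1", 0.1, "211", 80.0, "bpm", "chart"),
                    ("P1", "A1", 1.1, "211", 80.0, "furlongs", "chart"),
                ]
            ),
            CATALOG,
        )
        out = harmonize_units(events, CATALOG)
        assert len(out) == 1


class TestResolveConflicts:
    def test_lab_priority(self):
        events = merge_features(
            events_frame(
                [
                    ("P1", "A1", 5.2, "51301", 12.0, "K/uL", "lab"),
                    ("P1", "A1", 5.7, "51300", 11.0, "K/uL", "chart"),
                ]
            ),
            CATALOG,
        )
        out = resolve_conflicts(events)
        assert out["value"].tolist() == [12.0]

    def test_chart_only_kept(self):
        events = merge_features(
            events_frame([("P1", "A1", 5.2, "211", 90.0, "bpm", "chart")]), CATALOG
        )
        assert len(resolve_conflicts(events)) == 1


class TestResampleHourly:
    def demo(self):
        return pd.DataFrame(
            {"patient_id": ["P1"], "admission_id": ["A1"], "age": [40], "gender": ["M"]}
        )

    def test_mean_aggregation_within_hour(self):
        events = merge_features(
            events_frame(
                [
                    ("P1", "A1", 3.1, "211", 80.0, "bpm", "chart"),
                    ("P1", "A1", 3.6, "211", 90.0, "bpm", "chart"),
                ]
            ),
            CATALOG,
        )
        grids = resample_hourly(events, self.demo(), CATALOG)
        assert grids[0].data[3, CATALOG.column("heart_rate")] == 85.0

    def test_missing_hour_is_nan(self):
        events = merge_features(
            events_frame([("P1", "A1", 3.1, "211", 80.0, "bpm", "chart")]), CATALOG
        )
        grids = resample_hourly(events, self.demo(), CATALOG)
        assert np.isnan(grids[0].data[2, CATALOG.column("temperature")])

    def test_floor_to_hour(self):
        events = merge_features(
            events_frame([("P1", "A1", 2.17, "211", 70.0, "bpm", "chart")]), CATALOG
        )
        grids = resample_hourly(events, self.demo(), CATALOG)
        assert grids[0].data[2, CATALOG.column("heart_rate")] == 70.0


class TestDetectSirs:
    def test_all_four_criteria(self):
        grid = grid_with(
            {
                "temperature": np.array([39.0]),
                "heart_rate": np.array([120.0]),
                "respiratory_rate": np.array([25.0]),
                "wbc": np.array([13.0]),
            },
            1,
        )
        sirs = detect_sirs(grid, CATALOG)
        assert sirs.counts[0] == 4 and sirs.flags[0]

    def test_normal_hour_zero(self):
        grid = grid_with(
            {
                "temperature": np.array([37.0]),
                "heart_rate": np.array([80.0]),
                "respiratory_rate": np.array([16.0]),
                "wbc": np.array([8.0]),
            },
            1,
        )
        sirs = detect_sirs(grid, CATALOG)
        assert sirs.counts[0] == 0 and not sirs.flags[0]

    def test_one_criterion_not_flagged(self):
        grid = grid_with(
            {
                "temperature": np.array([37.0]),
                "heart_rate": np.array([95.0]),
                "respiratory_rate": np.array([16.0]),
                "wbc": np.array([8.0]),
            },
            1,
        )
        sirs = detect_sirs(grid, CATALOG)
        assert sirs.counts[0] == 1 and not sirs.flags[0]

    def test_low_temperature_and_low_wbc_count(self):
        grid = grid_with(
            {"temperature": np.array([35.5]), "wbc": np.array([3.0])}, 1
        )
        sirs = detect_sirs(grid, CATALOG)
        assert sirs.counts[0] == 2 and sirs.flags[0]

    def test_missing_contributes_zero(self):
        grid = grid_with({"heart_rate": np.array([120.0])}, 1)
        sirs = detect_sirs(grid, CATALOG)
        assert sirs.counts[0] == 1


def annotation(flags):
    flags = np.asarray(flags, dtype=bool)
    return SirsAnnotation(flags=flags, counts=flags.astype(int) * 2)


class TestFindSepsisOnset:
    def test_run_with_infection(self):
        flags = np.zeros(20, dtype=bool)
        flags[10:17] = True
        assert find_sepsis_onset(annotation(flags), [12.0]) == 10

    def test_short_run_absent(self):
        flags = np.zeros(10, dtype=bool)
        flags[3:7] = True  # 4 h only
        assert find_sepsis_onset(annotation(flags), [1.0]) is None

    def test_no_infection_absent(self):
        flags = np.zeros(20, dtype=bool)
        flags[10:17] = True
        assert find_sepsis_onset(annotation(flags), []) is None

    @given(st.lists(st.booleans(), min_size=1, max_size=50))
    @settings(max_examples=200, deadline=None)
    def test_matches_brute_force(self, flags):
        got = find_sepsis_onset(annotation(flags), [0.0])
        assert got == brute_force_onset(flags, True)


class TestFilterCohort:
    def grids(self, age: int, hours: int):
        return [make_grid(np.full((hours, CATALOG.n_features), 37.0), age=age)]

    def test_minor_excluded(self):
        kept = filter_cohort(self.grids(17, 20), {"A1": None}, {"A1": False}, 3)
        assert kept == []

    def test_short_record_excluded(self):
        kept = filter_cohort(self.grids(30, 7), {"A1": None}, {"A1": False}, 3)
        assert kept == []

    def test_retained(self):
        kept = filter_cohort(self.grids(30, 9), {"A1": None}, {"A1": False}, 3)
        assert len(kept) == 1

    def test_run_without_infection_excluded(self):
        kept = filter_cohort(self.grids(30, 20), {"A1": 6}, {"A1": False}, 3)
        assert kept == []


class TestExtractEpisodes:
    def test_window_count_no_onset(self):
        grid = make_grid(np.zeros((10, CATALOG.n_features)))
        eps = extract_episodes(grid, None, 3)
        assert [e.start for e in eps] == [0, 1, 2]  # L - 5 - T + 1 = 3

    def test_short_record_no_windows(self):
        grid = make_grid(np.zeros((7, CATALOG.n_features)))
        assert extract_episodes(grid, None, 3) == []

    def test_onset_labels_positive_window(self):
        grid = make_grid(np.zeros((20, CATALOG.n_features)))
        eps = extract_episodes(grid, 8, 3)
        assert [e.start for e in eps] == [0]
        assert eps[0].label == 1  # target hour 0 + 5 + 3 == onset

    def test_windows_overlapping_or_after_onset_not_emitted(self):
        grid = make_grid(np.zeros((30, CATALOG.n_features)))
        eps = extract_episodes(grid, 12, 0)
        assert all(e.start + 5 <= 12 for e in eps)
        assert sum(e.label for e in eps) == 1

    def test_matches_brute_force_enumerator(self, rng):
        for _ in range(50):
            length = int(rng.integers(5, 40))
            onset = int(rng.integers(0, length)) if rng.random() < 0.5 else None
            horizon = int(rng.integers(0, 13))
            grid = make_grid(np.zeros((length, CATALOG.n_features)))
            eps = extract_episodes(grid, onset, horizon)
            assert [e.start for e in eps] == brute_force_windows(length, onset, horizon)
            for e in eps:
                assert e.data.shape == (5, CATALOG.n_features)
                assert e.label in (0, 1)


class TestFilterEpisodes:
    def episode(self, n_observed: int) -> Episode:
        data = np.full((5, 40), np.nan)
        data[0, :n_observed] = 1.0
        return Episode(data=data, label=0, horizon=3, patient_id="P1", start=0)

    def test_19_of_40_excluded(self):
        assert filter_episodes([self.episode(19)]) == []

    def test_20_of_40_kept(self):
        assert len(filter_episodes([self.episode(20)])) == 1

    def test_full_kept(self):
        assert len(filter_episodes([self.episode(40)])) == 1


class TestBalanceClasses:
    def episodes(self, n_pos: int, n_neg: int):
        out = []
        for i in range(n_pos):
            out.append(Episode(np.zeros((5, 2)), 1, 3, f"P{i}", 0))
        for i in range(n_neg):
            out.append(Episode(np.zeros((5, 2)), 0, 3, f"N{i}", 0))
        return out

    def test_geometric_mean_target(self):
        balanced = balance_classes(self.episodes(10, 90), seed=0)
        labels = [e.label for e in balanced]
        assert labels.count(1) == labels.count(0) == 30  # sqrt(900)

    def test_already_balanced_counts_unchanged(self):
        balanced = balance_classes(self.episodes(50, 50), seed=0)
        labels = [e.label for e in balanced]
        assert labels.count(1) == labels.count(0) == 50

    def test_originals_retained_when_oversampling(self):
        episodes = self.episodes(10, 90)
        balanced = balance_classes(episodes, seed=0)
        positive_ids = {e.patient_id for e in balanced if e.label == 1}
        assert positive_ids == {f"P{i}" for i in range(10)}

    def test_empty_class_rejected(self):
        with pytest.raises(CohortError):
            balance_classes(self.episodes(0, 10), seed=0)

    def test_deterministic(self):
        episodes = self.episodes(10, 90)
        a = balance_classes(episodes, seed=4)
        b = balance_classes(episodes, seed=4)
        assert [(e.patient_id, e.label) for e in a] == [(e.patient_id, e.label) for e in b]


class TestSplitDataset:
    def episodes(self, n: int):
        return [Episode(np.zeros((5, 2)), i % 2, 3, f"P{i}", 0) for i in range(n)]

    def test_100_splits_50_30_20(self):
        es = split_dataset(self.episodes(100), seed=0)
        counts = {s: es.splits.count(s) for s in ("train", "validation", "test")}
        assert counts == {"train": 50, "validation": 30, "test": 20}

    def test_10_splits_5_3_2(self):
        es = split_dataset(self.episodes(10), seed=0)
        counts = {s: es.splits.count(s) for s in ("train", "validation", "test")}
        assert counts == {"train": 5, "validation": 3, "test": 2}

    def test_below_10_rejected(self):
        with pytest.raises(CohortError):
            split_dataset(self.episodes(9), seed=0)

    def test_deterministic(self):
        a = split_dataset(self.episodes(40), seed=3)
        b = split_dataset(self.episodes(40), seed=3)
        assert a.splits == b.splits

    def test_splits_disjoint_and_exhaustive(self):
        es = split_dataset(self.episodes(37), seed=1)
        assert len(es.splits) == 37
        assert set(es.splits) == {"train", "validation", "test"}


class TestEndToEndCohort:
    def test_onset_recovery_on_synthetic(self, small_cohort):
        _config, tables, demo, truth = small_cohort
        _grids, onsets, _runs, _inf = detect_onsets(tables, demo)
        sepsis = truth.sepsis_patients()
        matched = sum(
            1 for pid in sepsis if onsets.get("A" + pid[1:]) == truth.onset_time[pid]
        )
        assert matched / len(sepsis) >= 0.95

    def test_infection_evidence_lookup(self, small_cohort):
        _config, tables, _demo, truth = small_cohort
        rx = tables["prescriptions"]
        pid = truth.sepsis_patients()[0]
        hours = infection_evidence_hours(rx, "A" + pid[1:])
        assert hours and min(hours) >= 0

    def test_build_cohort_shapes_and_balance(self, small_cohort):
        _config, tables, demo, _truth = small_cohort
        result = build_cohort(tables, demo, 3, seed=0)
        x, y = result.episode_set.arrays("train")
        assert x.shape[1:] == (5, 40)
        assert set(y) == {0, 1}
        assert (y == 1).sum() == (y == 0).sum()  # train split balanced
        x_test, y_test = result.episode_set.arrays("test")
        assert len(x_test) > 0

    def test_pre_split_protocol_balances_pool(self, small_cohort):
        _config, tables, demo, _truth = small_cohort
        result = build_cohort(tables, demo, 3, seed=0, balance="pre_split")
        labels = np.array([e.label for e in result.episode_set.episodes])
        assert (labels == 1).sum() == (labels == 0).sum()

    def test_label_prevalence_monotone_in_cohort_prevalence(self):
        # under exact-hour target labeling each sepsis patient contributes one
        # positive window, so episode-label prevalence tracks cohort prevalence
        from nasga.synthdata import SynthConfig, generate_cohort

        prevalences = []
        for p in (0.05, 0.2, 0.4):
            config = SynthConfig(n_patients=80, seed=11, sepsis_prevalence=p)
            tables, demo, _truth = generate_cohort(config)
            result = build_cohort(tables, demo, 3, seed=0, balance="none")
            labels = [e.label for e in result.episode_set.episodes]
            prevalences.append(sum(labels) / len(labels))
        assert prevalences[0] <= prevalences[1] <= prevalences[2]
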