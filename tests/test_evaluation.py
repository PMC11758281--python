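"""Splits, quotas, channel selection, balanced accuracy and task running."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import balanced_accuracy_score

from eegrep import (
    GeneratorConfig,
    SplitSpec,
    TaskSpec,
    apply_scores,
    balanced_accuracy,
    build_task_dataset,
    featurize_epochs,
    generate_experiment,
    make_splits,
    results_frame,
    run_task,
    select_top_channels,
    subsample_quota,
)
from eegrep.evaluation import EvaluationError


class TestBalancedAccuracy:
    def test_perfect_predictions(self):
        assert balanced_accuracy([0, 1, 0, 1], [0, 1, 0, 1]) == 1.0

    def test_mixed_recalls_example(self):
        # positives: 3 hits, 1 miss (recall 0.75); negatives: 2 hits, 2 misses (0.5)
        y_true = [1, 1, 1, 1, 0, 0, 0, 0]
        y_pred = [1, 1, 1, 0, 0, 0, 1, 1]
        assert balanced_accuracy(y_true, y_pred) == pytest.approx(0.625)

    def test_constant_predictor_scores_half(self):
        assert balanced_accuracy([0, 0, 1, 1, 1], [1, 1, 1, 1, 1]) == 0.5

    def test_equals_accuracy_for_balanced_classes(self):
        rng = np.random.default_rng(0)
        y_true = np.repeat([0, 1], 50)
        y_pred = rng.integers(0, 2, size=100)
        plain = np.mean(y_true == y_pred)
        # equal class counts: balanced accuracy == plain accuracy
        assert balanced_accuracy(y_true, y_pred) == pytest.approx(
            plain) or not np.isclose(np.bincount(y_true)[0], np.bincount(y_true)[1])

    @pytest.mark.parametrize("n_classes", [2, 3, 4])
    def test_matches_sklearn_on_random_draws(self, n_classes):
        rng = np.random.default_rng(42)
        for _ in range(20):
            y_true = rng.integers(0, n_classes, size=60)
            y_pred = rng.integers(0, n_classes, size=60)
            if len(np.unique(y_true)) < n_classes:
                continue
            assert balanced_accuracy(y_true, y_pred) == pytest.approx(
                balanced_accuracy_score(y_true, y_pred)
            )

    def test_rejects_length_mismatch(self):
        with pytest.raises(EvaluationError):
            balanced_accuracy([0, 1], [0])


def participant_frame(counts: dict[str, int]) -> pd.DataFrame:
    rows = [{"participant_id": pid} for pid, n in counts.items() for _ in range(n)]
    return pd.DataFrame(rows)


class TestMakeSplits:
    def test_new_participants_disjoint_and_exhaustive(self):
        meta = participant_frame({f"EP{i:02d}": 12 for i in range(1, 11)})
        spec = SplitSpec(scenario="new_participants", seed=3)
        for split in make_splits(meta, spec):
            train_p = set(meta["participant_id"].iloc[split.train_idx])
            test_p = set(meta["participant_id"].iloc[split.test_idx])
            assert len(train_p) == 7 and len(test_p) == 3
            assert train_p.isdisjoint(test_p)
            assert train_p | test_p == set(meta["participant_id"])

    def test_seen_participants_appear_on_both_sides(self):
        meta = participant_frame({f"EP{i}": 20 for i in range(6)})
        labels = np.tile([0, 1], 60)
        for split in make_splits(meta, SplitSpec(scenario="seen_participants", seed=1), labels):
            train_p = set(meta["participant_id"].iloc[split.train_idx])
            test_p = set(meta["participant_id"].iloc[split.test_idx])
            assert train_p == test_p == set(meta["participant_id"])

    def test_per_participant_one_split_list_per_subject(self):
        meta = participant_frame({"A": 10, "B": 10})
        splits = make_splits(meta, SplitSpec(scenario="per_participant", n_repeats=3, seed=0))
        assert sorted({s.participant for s in splits}) == ["A", "B"]
        assert len(splits) == 6
        for split in splits:
            members = meta["participant_id"].iloc[
                np.concatenate([split.train_idx, split.test_idx])]
            assert set(members) == {split.participant}

    def test_deterministic_given_seed(self):
        meta = participant_frame({f"EP{i}": 9 for i in range(5)})
        spec = SplitSpec(scenario="seen_participants", seed=11)
        a = make_splits(meta, spec)
        b = make_splits(meta, spec)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.train_idx, y.train_idx)
            np.testing.assert_array_equal(x.test_idx, y.test_idx)

    def test_new_participants_needs_two_subjects(self):
        meta = participant_frame({"A": 30})
        with pytest.raises(EvaluationError):
            make_splits(meta, SplitSpec(scenario="new_participants"))

    def test_train_and_test_never_overlap(self):
        meta = participant_frame({f"EP{i}": 15 for i in range(4)})
        for scenario in ("per_participant", "seen_participants", "new_participants"):
            for split in make_splits(meta, SplitSpec(scenario=scenario, seed=2)):
                assert not set(split.train_idx) & set(split.test_idx)


class TestSubsampleQuota:
    def test_min_rule(self):
        pids = ["A"] * 5 + ["B"] * 8 + ["C"] * 7
        keep = subsample_quota(pids, seed=0)
        kept = pd.Series(np.asarray(pids)[keep]).value_counts()
        assert kept.to_dict() == {"A": 5, "B": 5, "C": 5}

    def test_equal_counts_keep_everything(self):
        pids = ["A"] * 4 + ["B"] * 4
        assert subsample_quota(pids, seed=1).tolist() == list(range(8))

    def test_reproducible(self):
        pids = ["A"] * 9 + ["B"] * 6
        np.testing.assert_array_equal(subsample_quota(pids, 5), subsample_quota(pids, 5))

    def test_unattainable_quota_names_participant(self):
        with pytest.raises(EvaluationError, match="B"):
            subsample_quota(["A"] * 5 + ["B"] * 2, seed=0, quota=4)


class TestSelectTopChannels:
    def test_importance_ordering(self):
        coefs = np.array([3.0, -1.0, 2.0])
        chans = np.array([0, 1, 2])
        np.testing.assert_array_equal(select_top_channels(coefs, chans, 3, k=2), [0, 2])

    def test_k_equals_all(self):
        coefs = np.ones(6)
        chans = np.repeat([0, 1, 2], 2)
        np.testing.assert_array_equal(select_top_channels(coefs, chans, 3, k=3), [0, 1, 2])

    def test_ties_break_to_lower_index(self):
        coefs = np.array([1.0, 1.0, 1.0])
        chans = np.array([2, 1, 0])
        np.testing.assert_array_equal(select_top_channels(coefs, chans, 3, k=2), [0, 1])

    def test_sums_over_channel_features(self):
        coefs = np.array([[0.5, -0.5, 2.0, 0.0]])
        chans = np.array([0, 0, 1, 1])
        np.testing.assert_array_equal(select_top_channels(coefs, chans, 2, k=1), [1])

    def test_rejects_k_above_channel_count(self):
        with pytest.raises(EvaluationError):
            select_top_channels(np.ones(4), np.arange(4), 4, k=5)


@pytest.fixture(scope="module")
def epochs():
    return np.random.default_rng(8).normal(0, 10, size=(6, 16, 60))


class TestFeaturizeEpochs:
    EXPECTED_DIMS = {
        "uts": 16 * 60, "uts-rp": 16 * 60 * 60, "uts-tdf": 16 * 10,
        "uts-ph": 16 * 100, "gfp": 60, "fbn": 120, "fbn-gt": 3 + 3 * 16,
        "fbn-ph": 200,
    }

    @pytest.mark.parametrize("pipeline", list(EXPECTED_DIMS))
    def test_dimensionality_and_provenance(self, epochs, pipeline):
        matrix = featurize_epochs(epochs, pipeline)
        assert matrix.values.shape == (6, self.EXPECTED_DIMS[pipeline])
        assert matrix.channel_of_feature.shape == (self.EXPECTED_DIMS[pipeline],)
        assert np.all(np.isfinite(matrix.values))

    def test_channel_restriction(self, epochs):
        matrix = featurize_epochs(epochs, "uts-tdf", channels=[0, 3, 5])
        assert matrix.values.shape == (6, 30)
        assert set(matrix.channel_of_feature) == {0, 3, 5}

    def test_unknown_pipeline_rejected(self, epochs):
        with pytest.raises(EvaluationError, match="unknown pipeline"):
            featurize_epochs(epochs, "wavelets")


@pytest.fixture(scope="module")
def scored_experiment():
    config = GeneratorConfig(
        n_participants=3, n_sequences=6, n_channels=8,
        p300_target_boost=6.0, noise_sd=6.0, seed=19,
    )
    epochset, trials = generate_experiment(config)
    meta = apply_scores(epochset.metadata_frame(), trials)
    return epochset.values_array(), meta


class TestBuildTaskDataset:
    def test_score_task_filters_conclusive(self, scored_experiment):
        _, meta = scored_experiment
        rows, labels = build_task_dataset(meta, TaskSpec("score", "Target", seed=0))
        assert set(labels) <= {0, 1}
        assert (meta.iloc[rows]["kind"] == "Target").all()
        counts = meta.iloc[rows]["participant_id"].value_counts()
        assert counts.nunique() == 1  # equal participant contributions

    def test_stimulus_task_uses_score_zero_only(self, scored_experiment):
        _, meta = scored_experiment
        rows, labels = build_task_dataset(meta, TaskSpec("stimulus", "C1", seed=0))
        selected = meta.iloc[rows]
        assert (selected["score"] == 0.0).all()
        assert (selected["condition"] == "C1").all()
        assert set(labels) == {"Target", "Distractor"}

    def test_condition_task_has_four_classes(self, scored_experiment):
        _, meta = scored_experiment
        rows, labels = build_task_dataset(meta, TaskSpec("condition", "Target", seed=0))
        assert set(labels) == {"C1", "C2", "C3", "C4"}
        assert (meta.iloc[rows]["kind"] == "Target").all()


class TestRunTask:
    def test_planted_boost_recovered_by_uts(self, scored_experiment):
        values, meta = scored_experiment
        results = run_task(
            values, meta, "uts", TaskSpec("stimulus", "C1", seed=0),
            SplitSpec(scenario="seen_participants", n_repeats=2, seed=5),
        )
        frame = results_frame(results)
        assert len(frame) == 2
        assert frame["valid"].all()
        assert frame["balanced_accuracy"].between(0.0, 1.0).all()
        assert frame["balanced_accuracy"].mean() > 0.6  # 6 uV boost vs 6 uV noise

    def test_channel_limited_pipeline_runs_with_selection(self, scored_experiment):
        values, meta = scored_experiment
        results = run_task(
            values, meta, "uts-tdf", TaskSpec("stimulus", "C1", seed=0),
            SplitSpec(scenario="new_participants", n_repeats=1, seed=5),
            top_channels=4,
        )
        assert len(results) == 1
        assert results[0].scenario == "new_participants"

    def test_single_class_split_flagged_invalid(self):
        rng = np.random.default_rng(0)
        values = rng.normal(size=(20, 4, 60))
        meta = pd.DataFrame({
            "participant_id": ["A"] * 10 + ["B"] * 10,
            "kind": ["Target"] * 20,
            "condition": ["C1"] * 20,
            "score": [0.0] * 20,
        })
        results = run_task(
            values, meta, "gfp", TaskSpec("stimulus", "C1", seed=0),
            SplitSpec(scenario="seen_participants", n_repeats=1, seed=0),
        )
        assert not results[0].valid
        assert np.isnan(results[0].balanced_accuracy)
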