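"""Splits, the training protocol, fitness, and the evaluation metrics."""

import numpy as np
import pytest
import sklearn.metrics as skm

from sadasnet.architecture import decode, repair
from sadasnet.data import ImageDataset, SyntheticSpec, generate_synthetic
from sadasnet.evaluation import (
    Budget,
    SplitSpec,
    TrainConfig,
    cohen_kappa,
    confusion_matrix,
    evaluate_model,
    fitness,
    metrics_from_confusion,
    roc_auc_ovr,
    split_dataset,
    subsample_per_class,
    train_model,
    two_stage_search,
)
from sadasnet.pso import SwarmConfig
from sadasnet.search_space import SearchSpace, build_layout


def _dataset(n_classes, per_class, size=8, seed=0):
    return generate_synthetic(
        SyntheticSpec(
            n_classes=n_classes, image_size=size,
            per_class_counts=(per_class,) * n_classes, seed=seed,
        )
    )


class TestSplits:
    def test_published_fractions_on_balanced_two_class_set(self):
        ds = _dataset(2, 500)
        splits = split_dataset(ds, SplitSpec(seed=0))
        assert len(splits["test"]) == 200
        assert len(splits["validation"]) == 80
        assert len(splits["train"]) == 720

    def test_splits_are_disjoint_and_exhaustive(self):
        ds = _dataset(2, 5)
        splits = split_dataset(ds, SplitSpec(stratified=False, seed=1))
        sizes = {k: len(v) for k, v in splits.items()}
        assert sum(sizes.values()) == 10
        assert sizes["test"] == 2

    def test_stratification_preserves_class_proportions(self):
        ds = _dataset(7, 134)  # the balanced-majority scenario, scaled down
        splits = split_dataset(ds, SplitSpec(seed=3))
        for part in splits.values():
            counts = part.class_counts()
            assert counts.max() - counts.min() <= 1

    def test_single_sample_class_fails_with_class_name(self):
        images = np.zeros((3, 4, 4, 3), dtype=np.uint8)
        ds = ImageDataset(images, np.array([0, 0, 1]), ("a", "lonely"))
        with pytest.raises(ValueError, match="lonely"):
            split_dataset(ds, SplitSpec(seed=0))

    def test_split_deterministic_under_seed(self):
        ds = _dataset(4, 50)
        a = split_dataset(ds, SplitSpec(seed=5))
        b = split_dataset(ds, SplitSpec(seed=5))
        np.testing.assert_array_equal(a["test"].labels, b["test"].labels)


class TestSubsample:
    def test_exact_per_class_size(self):
        ds = _dataset(7, 300)
        sub = subsample_per_class(ds, 200, seed=0)
        assert len(sub) == 7 * 200
        assert (sub.class_counts() == 200).all()

    def test_small_classes_taken_whole(self):
        ds = _dataset(3, 50)
        sub = subsample_per_class(ds, 200, seed=0)
        assert len(sub) == 150

    def test_different_seeds_pick_different_equal_sized_subsets(self):
        ds = _dataset(2, 100, seed=2)
        a = subsample_per_class(ds, 40, seed=1)
        b = subsample_per_class(ds, 40, seed=2)
        assert len(a) == len(b) == 80
        assert not np.array_equal(a.images, b.images)


class TestTrainingProtocol:
    def test_piecewise_schedule_drops_twenty_percent_every_five_epochs(self):
        cfg = TrainConfig(epochs=50)
        assert all(cfg.lr_at(e) == pytest.approx(1e-4) for e in range(5))
        assert all(cfg.lr_at(e) == pytest.approx(8e-5) for e in range(5, 10))
        seq = [cfg.lr_at(e) for e in range(50)]
        assert all(b <= a for a, b in zip(seq, seq[1:]))
        assert seq[49] == pytest.approx(1e-4 * 0.8**9)

    def test_zero_epochs_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(epochs=0)


class TestConfusionMatrix:
    def test_agreement_gives_diagonal(self):
        y = np.array([0, 1, 2, 2, 1])
        cm = confusion_matrix(y, y, 3)
        assert np.trace(cm) == 5 and cm.sum() == 5

    def test_hand_counted_binary_case(self):
        cm = confusion_matrix([0, 0, 1, 1], [0, 1, 1, 1], 2)
        np.testing.assert_array_equal(cm, [[1, 1], [0, 2]])

    def test_row_sums_equal_class_counts(self):
        rng = np.random.default_rng(0)
        y_true = rng.integers(0, 5, 10_000)
        y_pred = rng.integers(0, 5, 10_000)
        cm = confusion_matrix(y_true, y_pred, 5)
        np.testing.assert_array_equal(cm.sum(axis=1), np.bincount(y_true, minlength=5))
        assert cm.sum() == 10_000

    def test_out_of_range_label_rejected(self):
        with pytest.raises(ValueError, match="y_pred"):
            confusion_matrix([0, 1], [0, 7], 2)


class TestMetrics:
    def test_perfect_diagonal_scores_one_everywhere(self):
        m = metrics_from_confusion(np.diag([5, 9, 3]))
        for vals in m["per_class"].values():
            assert vals == [1.0, 1.0, 1.0]
        assert m["overall_accuracy"] == 1.0

    def test_binary_worked_example(self):
        # TP=35, FP=10, FN=5, TN=50 for class 0
        cm = np.array([[35, 5], [10, 50]])
        m = metrics_from_confusion(cm)
        assert m["per_class"]["precision"][0] == pytest.approx(0.7778, abs=1e-4)
        assert m["per_class"]["recall"][0] == pytest.approx(0.8750, abs=1e-4)
        assert m["per_class"]["f1"][0] == pytest.approx(0.8235, abs=1e-4)
        assert m["per_class"]["specificity"][0] == pytest.approx(0.8333, abs=1e-4)
        assert m["per_class"]["accuracy"][0] == pytest.approx(0.85)

    def test_never_predicted_class_flagged_and_zero(self):
        cm = np.array([[0, 3], [0, 7]])
        m = metrics_from_confusion(cm)
        assert m["per_class"]["precision"][0] == 0.0
        assert any("precision" in f and "class 0" in f for f in m["flags"])

    def test_f1_is_harmonic_mean_of_precision_and_recall(self):
        rng = np.random.default_rng(1)
        cm = rng.integers(1, 30, (4, 4))
        m = metrics_from_confusion(cm)
        for p, r, f in zip(
            m["per_class"]["precision"], m["per_class"]["recall"], m["per_class"]["f1"]
        ):
            assert f == pytest.approx(2 * p * r / (p + r))

    def test_matches_sklearn_on_random_labels(self):
        rng = np.random.default_rng(2)
        y_true = rng.integers(0, 4, 500)
        y_pred = rng.integers(0, 4, 500)
        cm = confusion_matrix(y_true, y_pred, 4)
        m = metrics_from_confusion(cm)
        np.testing.assert_allclose(
            m["per_class"]["precision"],
            skm.precision_score(y_true, y_pred, average=None, zero_division=0),
        )
        np.testing.assert_allclose(
            m["per_class"]["recall"],
            skm.recall_score(y_true, y_pred, average=None, zero_division=0),
        )
        assert m["overall_accuracy"] == pytest.approx(skm.accuracy_score(y_true, y_pred))


class TestRocAuc:
    def test_perfect_and_inverted_separation(self):
        labels = np.array([0] * 5 + [1] * 5)
        scores = np.zeros((10, 2))
        scores[:5, 0], scores[5:, 1] = 1.0, 1.0
        res = roc_auc_ovr(scores, labels)
        assert res["per_class"] == [1.0, 1.0]
        inverted = roc_auc_ovr(scores[:, ::-1], labels)
        assert inverted["per_class"] == [0.0, 0.0]

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(0)
        labels = rng.integers(0, 3, 2000)
        scores = rng.random((2000, 3))
        scores /= scores.sum(axis=1, keepdims=True)
        res = roc_auc_ovr(scores, labels)
        for auc in res["per_class"]:
            assert abs(auc - 0.5) < 0.03

    def test_matches_sklearn_with_ties(self):
        rng = np.random.default_rng(3)
        labels = rng.integers(0, 3, 300)
        scores = np.round(rng.random((300, 3)), 1)  # heavy ties -> midrank path
        res = roc_auc_ovr(scores, labels)
        for c in range(3):
            expected = skm.roc_auc_score((labels == c).astype(int), scores[:, c])
            assert res["per_class"][c] == pytest.approx(expected)

    def test_absent_class_reported_missing(self):
        labels = np.array([0, 0, 1, 1])
        scores = np.full((4, 3), 1 / 3)
        res = roc_auc_ovr(scores, labels)
        assert res["per_class"][2] is None


class TestKappa:
    @pytest.mark.parametrize(
        "cm, expected",
        [
            (np.diag([10, 20, 5]), 1.0),
            (np.array([[25, 25], [25, 25]]), 0.0),
            (np.array([[20, 5], [10, 15]]), 0.4),
        ],
    )
    def test_hand_evaluated_cases(self, cm, expected):
        assert cohen_kappa(cm) == pytest.approx(expected)

    def test_matches_sklearn_on_random_predictions(self):
        rng = np.random.default_rng(4)
        y_true = rng.integers(0, 5, 400)
        y_pred = rng.integers(0, 5, 400)
        cm = confusion_matrix(y_true, y_pred, 5)
        assert cohen_kappa(cm) == pytest.approx(skm.cohen_kappa_score(y_true, y_pred))

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            cohen_kappa(np.zeros((3, 3)))


class TestFitness:
    def test_infeasible_candidate_scores_worst_case(self, small_layout):
        ds = _dataset(4, 20, size=12)
        splits = split_dataset(ds, SplitSpec(seed=0))
        genome = np.full(small_layout.dimension, 0.5)
        val = fitness(
            genome, small_layout, splits, (12, 12, 3), 4,
            TrainConfig(epochs=1, seed=0), budget=Budget(max_parameters=10),
        )
        assert val == 1.0

    def test_fitness_is_one_minus_report_accuracy(self, small_layout):
        ds = _dataset(2, 40, size=12, seed=5)
        splits = split_dataset(ds, SplitSpec(seed=0))
        genome = np.zeros(small_layout.dimension)  # plain conv stack
        cfg = TrainConfig(epochs=2, initial_lr=0.01, seed=0)
        val = fitness(genome, small_layout, splits, (12, 12, 3), 2, cfg)
        arch, _ = repair(decode(genome, small_layout, (12, 12, 3), 2))
        model, _ = train_model(arch, splits["train"], splits["validation"], cfg)
        report = evaluate_model(model, splits["test"])
        assert val == pytest.approx(1.0 - report.overall_accuracy)
        assert report.loss == pytest.approx(1.0 - report.overall_accuracy)
        assert 0.0 <= val <= 1.0


class TestTwoStageSearch:
    def test_evaluation_budget_and_artifact_consistency(self, small_layout):
        ds = _dataset(3, 30, size=10, seed=1)
        res = two_stage_search(
            ds,
            SwarmConfig(population_size=2, iterations=2, seed=0),
            small_layout,
            screening_config=TrainConfig(epochs=1, initial_lr=0.01, seed=0),
            final_config=TrainConfig(epochs=2, initial_lr=0.01, seed=0),
            screening_per_class=10,
        )
        assert res["evaluations"] == 4
        assert len(res["history"]) == 2
        assert res["report"].confusion.sum() == len(res["splits"]["test"])
        assert res["best_fitness"] == min(res["history"])

    def test_early_stop_still_trains_final_model(self, small_layout):
        ds = _dataset(2, 30, size=10, seed=2)
        res = two_stage_search(
            ds,
            SwarmConfig(population_size=2, iterations=5, stop_threshold=1.0, seed=0),
            small_layout,
            screening_config=TrainConfig(epochs=1, initial_lr=0.01, seed=0),
            final_config=TrainConfig(epochs=1, initial_lr=0.01, seed=0),
            screening_per_class=10,
        )
        assert len(res["history"]) == 1  # threshold met immediately
        assert res["report"] is not None
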