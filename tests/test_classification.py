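"""Classifier validation harness: folds, metrics, Y-randomization, rankings."""

import itertools

import numpy as np
import pandas as pd
import pytest

from protacsar import (
    ConfusionCounts,
    FeatureTable,
    assign_folds,
    confusion_metrics,
    crossvalidate_classifier,
    evaluate_on_test,
    rank_attributes,
    roc_auc,
    train_classifier,
    y_randomization,
)
from protacsar.descriptors import DESCRIPTOR_NAMES


def _table(X, y, subset="all"):
    n = len(y)
    frame = pd.DataFrame(X, columns=DESCRIPTOR_NAMES[: X.shape[1]])
    return FeatureTable(
        ids=tuple(f"c{i:03d}" for i in range(n)),
        X=frame,
        y=np.asarray(y, dtype=bool),
        subset=subset,
    )


def _separable_table(n=60, seed=0):
    """Labels follow a planted single-descriptor threshold rule."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, 7))
    y = X[:, 5] > 0.0  # TPSA column decides
    return _table(X, y)


class TestConfusionMetrics:
    def test_hand_case(self):
        tpr, tnr, mcc = confusion_metrics(ConfusionCounts(TP=3, FP=1, TN=3, FN=1))
        assert (tpr, tnr, mcc) == (0.75, 0.75, 0.5)

    def test_perfect(self):
        assert confusion_metrics(ConfusionCounts(5, 0, 5, 0)) == (1.0, 1.0, 1.0)

    def test_one_class_predictions_mcc_zero(self):
        _, _, mcc = confusion_metrics(ConfusionCounts(TP=5, FP=5, TN=0, FN=0))
        assert mcc == 0.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(TP=-1, FP=0, TN=1, FN=1)

    def test_inverted_predictions_flip_mcc_sign(self):
        for tp, fp, tn, fn in [(3, 1, 4, 2), (6, 2, 1, 1), (2, 3, 2, 3)]:
            _, _, mcc = confusion_metrics(ConfusionCounts(tp, fp, tn, fn))
            _, _, flipped = confusion_metrics(ConfusionCounts(TP=fn, FP=tn, TN=fp, FN=tp))
            assert flipped == pytest.approx(-mcc)

    def test_full_class_swap_preserves_mcc(self):
        for tp, fp, tn, fn in [(3, 1, 4, 2), (6, 2, 1, 1)]:
            _, _, mcc = confusion_metrics(ConfusionCounts(tp, fp, tn, fn))
            _, _, swapped = confusion_metrics(ConfusionCounts(tn, fn, tp, fp))
            assert swapped == pytest.approx(mcc)


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0.9, 0.8, 0.2, 0.1], [True, True, False, False]) == 1.0

    def test_hand_case(self):
        assert roc_auc([0.9, 0.4, 0.8, 0.3], [True, True, False, False]) == 0.75

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(1)
        scores = rng.random(2000)
        labels = rng.random(2000) < 0.5
        assert roc_auc(scores, labels) == pytest.approx(0.5, abs=0.05)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [True, True])

    def test_matches_pair_counting_oracle(self):
        """Rank-based area equals counting correctly ordered pos/neg pairs."""
        rng = np.random.default_rng(7)
        for _ in range(30):
            n = int(rng.integers(4, 13))
            scores = rng.integers(0, 5, size=n).astype(float)  # forces ties
            labels = rng.random(n) < 0.5
            if labels.all() or not labels.any():
                continue
            pos = scores[labels]
            neg = scores[~labels]
            wins = sum(
                1.0 if p > q else 0.5 if p == q else 0.0
                for p, q in itertools.product(pos, neg)
            )
            expected = wins / (len(pos) * len(neg))
            assert roc_auc(scores, labels) == pytest.approx(expected)


class TestFolds:
    @pytest.mark.parametrize("n,k", [(42, 10), (92, 10), (20, 10), (15, 4)])
    def test_fold_sizes_differ_by_at_most_one(self, n, k):
        folds = assign_folds(n, k, seed=0)
        sizes = np.bincount(folds, minlength=k)
        assert sizes.max() - sizes.min() <= 1 and sizes.sum() == n
        if n == 42 and k == 10:
            assert set(sizes) == {4, 5}

    def test_seeded_reproducible(self):
        assert np.array_equal(assign_folds(50, 10, 3), assign_folds(50, 10, 3))
        assert not np.array_equal(assign_folds(50, 10, 3), assign_folds(50, 10, 4))


class TestCrossValidation:
    def test_separable_table_high_mcc(self):
        report = crossvalidate_classifier(_separable_table(), "RF", seed=0)
        assert report.MCC >= 0.9
        assert report.phase == "cv_training"

    def test_shuffled_labels_near_zero(self):
        rng = np.random.default_rng(5)
        mccs = []
        for seed in range(20):
            table = _separable_table(seed=seed)
            shuffled = FeatureTable(
                ids=table.ids, X=table.X, y=rng.permutation(table.y), subset="all"
            )
            mccs.append(crossvalidate_classifier(shuffled, "NB", seed=seed).MCC)
        assert abs(float(np.mean(mccs))) <= 0.2

    def test_single_class_rejected(self):
        table = _table(np.random.default_rng(0).normal(size=(20, 7)), [True] * 20)
        with pytest.raises(ValueError):
            crossvalidate_classifier(table, "RF", seed=0)

    def test_deterministic_given_seed(self):
        a = crossvalidate_classifier(_separable_table(), "RF", seed=9)
        b = crossvalidate_classifier(_separable_table(), "RF", seed=9)
        assert a == b

    @pytest.mark.parametrize("algorithm", ["RF", "RT", "NB", "KNN5", "SVM_linear"])
    def test_all_algorithms_run(self, algorithm):
        report = crossvalidate_classifier(_separable_table(40), algorithm, seed=1)
        assert -1.0 <= report.MCC <= 1.0 and 0.0 <= report.roc_area <= 1.0


class TestExternalValidation:
    def test_metrics_consistent_with_confusion(self):
        train = _separable_table(60, seed=0)
        test = _separable_table(30, seed=1)
        test = FeatureTable(
            ids=tuple(f"t{i:03d}" for i in range(30)), X=test.X, y=test.y, subset="all"
        )
        model = train_classifier(train, "RF", seed=0)
        report = evaluate_on_test(model, test)
        pred = np.asarray(model.estimator.predict(test.X.to_numpy(float)), dtype=bool)
        counts = ConfusionCounts(
            TP=int((pred & test.y).sum()), FP=int((pred & ~test.y).sum()),
            TN=int((~pred & ~test.y).sum()), FN=int((~pred & test.y).sum()),
        )
        tpr, tnr, mcc = confusion_metrics(counts)
        assert (report.TPR, report.TNR, report.MCC) == (tpr, tnr, mcc)

    def test_train_test_overlap_rejected(self):
        table = _separable_table(30)
        model = train_classifier(table, "RF", seed=0)
        with pytest.raises(ValueError, match="overlap"):
            evaluate_on_test(model, table)


class TestYRandomization:
    def test_informative_table_beats_null(self):
        table = _separable_table(60, seed=2)
        true_mcc = crossvalidate_classifier(table, "RF", seed=0).MCC
        result = y_randomization(table, "RF", n_perm=10, seed=0)
        assert abs(result.mean_mcc) <= 0.15
        assert result.mean_mcc < true_mcc

    def test_same_seed_same_distribution(self):
        table = _separable_table(40, seed=3)
        a = y_randomization(table, "NB", n_perm=10, seed=5)
        b = y_randomization(table, "NB", n_perm=10, seed=5)
        assert a.mccs == b.mccs

    def test_too_few_permutations_rejected(self):
        with pytest.raises(ValueError):
            y_randomization(_separable_table(30), "NB", n_perm=5, seed=0)


class TestAttributeRanking:
    def test_attribute_identical_to_class_tops_infogain(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(40, 7))
        y = rng.random(40) < 0.5
        X[:, 0] = y.astype(float)  # MW column duplicates the class
        ranking = rank_attributes(_table(X, y), "InfoGain")
        top_name, top_score = ranking.ranking[0]
        p = y.mean()
        h_class = -(p * np.log2(p) + (1 - p) * np.log2(1 - p))
        assert top_name == "MW"
        assert top_score == pytest.approx(h_class)

    def test_constant_attribute_zero_gain(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(30, 7))
        X[:, 3] = 2.5
        y = X[:, 5] > 0
        ranking = rank_attributes(_table(X, y), "InfoGain")
        scores = dict(ranking.ranking)
        assert scores["nHAcc"] == 0.0

    @pytest.mark.parametrize("evaluator", ["InfoGain", "PearsonCorrelation", "OneR"])
    def test_scores_sorted_descending(self, evaluator):
        ranking = rank_attributes(_separable_table(50, seed=4), evaluator)
        scores = [s for _, s in ranking.ranking]
        assert scores == sorted(scores, reverse=True)
        if evaluator == "InfoGain":
            assert all(s >= 0 for s in scores)

    def test_cfs_selects_informative_attribute(self):
        table = _separable_table(60, seed=6)
        ranking = rank_attributes(table, "CFS")
        assert "TPSA" in ranking.selected
        assert ranking.merit > 0

    def test_unknown_evaluator_rejected(self):
        with pytest.raises(ValueError):
            rank_attributes(_separable_table(20), "Relief")
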