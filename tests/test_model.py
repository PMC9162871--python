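"""Splitting, feature selection, ROC/AUC engine, weak models and stacking."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from texstack import (
    AlignmentError,
    MetricError,
    ParameterError,
    WeakResult,
    auc_ci,
    operating_metrics,
    roc_and_auc,
    select_best_weak,
    select_features,
    split_cohort,
    stack_and_evaluate,
    train_weak,
    youden_threshold,
)


def pairwise_auc(scores, labels):
    """Oracle: the Mann-Whitney statistic by explicit pair enumeration."""
    scores = np.asarray(scores, float)
    pos = scores[np.asarray(labels) == 1]
    neg = scores[np.asarray(labels) == 0]
    wins = ties = 0
    for p, n in itertools.product(pos, neg):
        wins += p > n
        ties += p == n
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def _table(x, y, split, source="T1FSE"):
    x = np.atleast_2d(np.asarray(x, float))
    if x.shape[0] != len(y):
        x = x.T
    df = pd.DataFrame(x, columns=[f"f{i}" for i in range(x.shape[1])])
    df["patient_id"] = [f"P{i:03d}" for i in range(len(y))]
    df["label"] = y
    df["split"] = split
    df["source"] = source
    return df


class TestSplit:
    def test_clinical_sized_cohort_arms(self):
        labels = np.array([1] * 68 + [0] * 46)
        ids = [f"P{i}" for i in range(114)]
        assignment = split_cohort(ids, labels, test_fraction=35 / 114, seed=0)
        counts = pd.Series(assignment).value_counts()
        assert counts["train"] == 79 and counts["test"] == 35

    def test_stratified_balance_on_four_patients(self):
        assignment = split_cohort(["a", "b", "c", "d"], [0, 0, 1, 1], 0.5, seed=1)
        for arm in ("train", "test"):
            members = [p for p, a in assignment.items() if a == arm]
            assert len(members) == 2
            assert {0, 1} == {["a", "b", "c", "d"].index(m) // 2 for m in members}

    def test_deterministic_and_prevalence_preserving(self):
        rng = np.random.default_rng(0)
        labels = (rng.random(60) < 0.6).astype(int)
        ids = [f"P{i}" for i in range(60)]
        a1 = split_cohort(ids, labels, 0.3, seed=5)
        a2 = split_cohort(ids, labels, 0.3, seed=5)
        assert a1 == a2
        for arm in ("train", "test"):
            arm_labels = [labels[ids.index(p)] for p, a in a1.items() if a == arm]
            assert abs(np.mean(arm_labels) - labels.mean()) < 2 / len(arm_labels)

    def test_single_class_rejected(self):
        with pytest.raises(ParameterError):
            split_cohort(["a", "b", "c"], [1, 1, 1], 0.3)


class TestSelectFeatures:
    def test_label_copy_feature_selected(self, rng):
        y = np.repeat([0, 1], 20)
        noise = rng.normal(size=40)
        df = _table(np.column_stack([y.astype(float), noise]), y, "train")
        assert "f0" in select_features(df)

    def test_duplicate_of_selected_feature_also_selected(self, rng):
        y = np.repeat([0, 1], 20)
        strong = y + 0.1 * rng.normal(size=40)
        df = _table(np.column_stack([strong, strong.copy()]), y, "train")
        assert set(select_features(df)) == {"f0", "f1"}

    def test_fallback_returns_top_k_by_correlation(self, rng):
        y = np.repeat([0, 1], 4)  # too few samples for significance
        x = rng.normal(size=(8, 5))
        selected = select_features(_table(x, y, "train"), top_k=2)
        assert len(selected) == 2

    def test_uses_training_rows_only(self, rng):
        # One feature informative on the test rows only, one informative on
        # the training rows: selection must key on the training association.
        y = np.tile([0, 1], 30)
        split = np.tile(["train", "train", "test"], 20)
        test_only = rng.normal(size=60)
        test_only[split == "test"] += 10 * y[split == "test"]
        train_informative = y + 0.05 * rng.normal(size=60)
        df = _table(np.column_stack([test_only, train_informative]), y, split)
        assert select_features(df) == ["f1"]


class TestRocAuc:
    def test_scores_equal_labels_auc_one(self):
        _, auc = roc_and_auc([0, 0, 1, 1], [0, 0, 1, 1])
        assert auc == 1.0

    def test_all_ties_auc_half(self):
        _, auc = roc_and_auc([0.5] * 6, [0, 1, 0, 1, 0, 1])
        assert auc == 0.5

    def test_four_point_hand_enumeration(self):
        _, auc = roc_and_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])
        assert auc == 0.75

    def test_matches_pairwise_oracle(self, rng):
        for _ in range(25):
            n = rng.integers(4, 50)
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            scores = np.round(rng.random(n), 2)  # provoke ties
            _, auc = roc_and_auc(scores, labels)
            assert abs(auc - pairwise_auc(scores, labels)) < 1e-12

    def test_roc_is_monotone(self, rng):
        labels = rng.integers(0, 2, size=30)
        labels[:2] = [0, 1]
        (fpr, tpr, _), _ = roc_and_auc(rng.random(30), labels)
        assert np.all(np.diff(fpr) >= 0) and np.all(np.diff(tpr) >= 0)

    def test_single_class_rejected(self):
        with pytest.raises(MetricError):
            roc_and_auc([0.2, 0.8], [1, 1])

    @given(st.integers(0, 200))
    def test_invariant_under_strictly_increasing_transform(self, seed):
        rng = np.random.default_rng(seed)
        labels = rng.integers(0, 2, size=20)
        labels[:2] = [0, 1]
        scores = rng.normal(size=20)
        _, auc = roc_and_auc(scores, labels)
        _, auc_t = roc_and_auc(np.exp(3 * scores) + 1, labels)
        assert auc == pytest.approx(auc_t, abs=1e-12)


class TestOperatingMetrics:
    def test_perfect_scores(self):
        sens, spec, acc, _ = operating_metrics([0.1, 0.1, 0.9, 0.9], [0, 0, 1, 1], 0.5)
        assert (sens, spec, acc) == (1.0, 1.0, 1.0)

    def test_threshold_above_max_score(self):
        sens, spec, _, _ = operating_metrics([0.1, 0.9], [0, 1], 2.0)
        assert (sens, spec) == (0.0, 1.0)

    def test_clinical_arm_convention(self):
        # 35-patient arm (21 positive / 14 negative): 13 of 14 negatives
        # below threshold, 11 of 21 positives above.
        scores = np.r_[np.full(11, 0.9), np.full(10, 0.1), np.full(13, 0.2), [0.95]]
        labels = np.r_[np.ones(21, int), np.zeros(14, int)]
        sens, spec, acc, _ = operating_metrics(scores, labels, 0.5)
        assert spec == pytest.approx(0.9286, abs=1e-4)
        assert sens == pytest.approx(0.5238, abs=1e-4)
        assert acc == pytest.approx(24 / 35)

    def test_youden_threshold_separates_separable_scores(self):
        scores = [0.1, 0.2, 0.3, 0.8, 0.85, 0.9]
        labels = [0, 0, 0, 1, 1, 1]
        t = youden_threshold(scores, labels)
        sens, spec, _, _ = operating_metrics(scores, labels, t)
        assert sens == spec == 1.0


class TestAucCi:
    def test_perfect_separation_gives_degenerate_ci(self):
        lo, hi = auc_ci([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1], reps=300, seed=0)
        assert (lo, hi) == (1.0, 1.0)

    def test_deterministic_per_seed(self, rng):
        scores, labels = rng.random(40), rng.integers(0, 2, size=40)
        labels[:2] = [0, 1]
        assert auc_ci(scores, labels, reps=300, seed=3) == auc_ci(
            scores, labels, reps=300, seed=3
        )

    def test_null_scores_ci_covers_half(self, rng):
        covered = 0
        runs = 30
        for seed in range(runs):
            r = np.random.default_rng(seed)
            scores = r.random(200)
            labels = np.r_[np.ones(100, int), np.zeros(100, int)]
            lo, hi = auc_ci(scores, labels, reps=400, seed=seed)
            covered += lo <= 0.5 <= hi
        assert covered >= 0.9 * runs

    def test_too_few_reps_rejected(self):
        with pytest.raises(ParameterError):
            auc_ci([0.1, 0.9], [0, 1], reps=10)


def _weak(source, algorithm, auc_train, auc_test):
    return WeakResult(
        source=source,
        algorithm=algorithm,
        features=["f0"],
        patient_ids=["a", "b"],
        split=np.array(["train", "test"]),
        labels=np.array([0, 1]),
        scores=np.array([0.2, 0.8]),
        threshold=0.5,
        auc_train=auc_train,
        auc_test=auc_test,
    )


class TestSelectBestWeak:
    def test_clinical_triple_selects_t1fse(self):
        # The three MRI-sequence candidates are near-ties at the default
        # tolerance; the T1 FSE model both scores highest on test and shows
        # the largest train-test gap, so either rule yields it.
        results = [
            _weak("DWI", "adaboost", 0.90, 0.735),
            _weak("T1FSE", "adaboost", 0.95, 0.741),
            _weak("T2FSE", "decision_tree", 0.90, 0.726),
        ]
        assert select_best_weak(results).auc_test == 0.741

    def test_clear_winner_ignores_overfit_rule(self):
        results = [_weak("a", "svm", 0.99, 0.60), _weak("b", "svm", 0.70, 0.80)]
        assert select_best_weak(results).auc_test == 0.80

    def test_tied_test_auc_prefers_overfit_model(self):
        results = [_weak("a", "svm", 0.80, 0.75), _weak("b", "svm", 0.99, 0.75)]
        assert select_best_weak(results).auc_train == 0.99

    def test_single_candidate_returned(self):
        only = _weak("a", "svm", 0.9, 0.7)
        assert select_best_weak([only]) is only


class TestTrainWeakAndStack:
    @pytest.fixture
    def separable_table(self, rng):
        n = 40
        y = np.repeat([0, 1], n // 2)
        x = np.column_stack([y + 0.01 * rng.normal(size=n), rng.normal(size=n)])
        split = np.where(np.arange(n) % 3 == 0, "test", "train")
        return _table(x, y, split)

    @pytest.mark.parametrize("algorithm", ["adaboost", "svm", "random_forest", "decision_tree"])
    def test_separable_features_reach_auc_one(self, separable_table, algorithm):
        result = train_weak(separable_table, "T1FSE", algorithm, seed=0)
        assert result.auc_test == 1.0
        assert np.all((result.scores >= 0) & (result.scores <= 1))

    def test_training_is_deterministic(self, separable_table):
        a = train_weak(separable_table, "T1FSE", "random_forest", seed=4)
        b = train_weak(separable_table, "T1FSE", "random_forest", seed=4)
        np.testing.assert_array_equal(a.scores, b.scores)

    def test_null_features_stay_near_chance(self):
        aucs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 100
            y = rng.permutation(np.repeat([0, 1], n // 2))
            x = rng.normal(size=(n, 4))
            split = np.where(np.arange(n) % 3 == 0, "test", "train")
            res = train_weak(_table(x, y, split), "T1FSE", "decision_tree", seed=seed)
            aucs.append(res.auc_test)
        assert 0.4 <= np.mean(aucs) <= 0.6

    def test_single_class_training_rejected(self, rng):
        y = np.zeros(10, int)
        y[-1] = 1
        split = ["train"] * 9 + ["test"]
        with pytest.raises(ParameterError):
            train_weak(_table(rng.normal(size=10), y, split), "T1FSE", "svm")

    def test_stacking_perfectly_separating_inputs(self, separable_table):
        mri = train_weak(separable_table, "T1FSE", "adaboost", seed=0)
        stain_table = separable_table.copy()
        stain_table["source"] = "eosin"
        stain = train_weak(stain_table, "eosin", "random_forest", seed=0)
        stacked, report = stack_and_evaluate(mri, stain, seed=0, bootstrap_reps=300)
        assert report.auc_test == 1.0
        assert report.auc_test_ci == (1.0, 1.0)
        assert report.auc_train_ci[0] <= report.auc_train <= report.auc_train_ci[1]

    def test_misaligned_patients_rejected(self, separable_table):
        mri = train_weak(separable_table, "T1FSE", "svm", seed=0)
        other = separable_table.copy()
        other["patient_id"] = other["patient_id"].str.replace("P", "Q")
        other["source"] = "eosin"
        stain = train_weak(other, "eosin", "svm", seed=0)
        with pytest.raises(AlignmentError):
            stack_and_evaluate(mri, stain)
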