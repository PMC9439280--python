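import numpy as np
import pandas as pd
import pytest

from fmfe.errors import ConfigError, ValidationError
from fmfe.evaluation import (ConfusionMatrix, _binary_auc, compute_metrics,
                             cross_validate, feature_ttest, roc_one_vs_rest)


def make_table(n_per_class, classes, centers, spread, seed, n_features=3):
    rng = np.random.default_rng(seed)
    rows = []
    for cls, center in zip(classes, centers):
        for i in range(n_per_class):
            rows.append([f"{cls}{i}", cls,
                         *(center + spread * rng.standard_normal(n_features))])
    cols = ["id", "label"] + [f"f{j}" for j in range(n_features)]
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------- metrics

def test_perfect_predictions_give_all_ones():
    report = compute_metrics(ConfusionMatrix(np.diag([10, 20, 30]),
                                             ["a", "b", "c"]))
    assert report.accuracy == report.macro_precision == 1.0
    assert report.macro_recall == report.macro_specificity == 1.0


def test_two_class_single_miss():
    # one miss out of 200 normal samples: recall 199/200
    matrix = ConfusionMatrix(np.array([[199, 1], [0, 200]]), ["NHS", "other"])
    report = compute_metrics(matrix)
    assert np.isclose(report.per_class["NHS"]["recall"], 0.995)
    assert np.isclose(report.accuracy, 399 / 400)
    assert np.isclose(report.per_class["other"]["precision"], 200 / 201)


def test_hand_filled_three_class_matrix():
    counts = np.array([[5, 2, 1], [1, 7, 0], [0, 3, 6]])
    report = compute_metrics(ConfusionMatrix(counts, ["x", "y", "z"]))
    precisions = [5 / 6, 7 / 12, 6 / 7]       # per-column arithmetic by hand
    recalls = [5 / 8, 7 / 8, 6 / 9]
    assert np.isclose(report.macro_precision, np.mean(precisions))
    assert np.isclose(report.macro_recall, np.mean(recalls))
    assert np.isclose(report.accuracy, 18 / 25)
    spec_x = (25 - 8 - 1) / (25 - 8)          # TN/(FP+TN) for class x
    assert np.isclose(report.per_class["x"]["specificity"], spec_x)


def test_never_predicted_class_flagged():
    counts = np.array([[3, 2], [0, 0]])
    report = compute_metrics(ConfusionMatrix(counts, ["a", "b"]))
    assert report.per_class["b"]["recall"] == 0.0
    assert "a" not in report.undefined_precision_classes
    with pytest.raises(ValidationError):
        compute_metrics(ConfusionMatrix(np.zeros((2, 2), int), ["a", "b"]))


def test_accuracy_invariant_under_class_permutation(rng):
    counts = rng.integers(0, 20, size=(4, 4))
    perm = rng.permutation(4)
    base = compute_metrics(ConfusionMatrix(counts, list("abcd")))
    permuted = compute_metrics(ConfusionMatrix(counts[np.ix_(perm, perm)],
                                               [list("abcd")[i] for i in perm]))
    assert np.isclose(base.accuracy, permuted.accuracy)
    assert np.isclose(base.macro_recall, permuted.macro_recall)


# ---------------------------------------------------------------- cross-validation

def test_separable_classes_are_perfectly_classified():
    table = make_table(12, ["a", "b", "c"], [0.0, 10.0, -10.0], 0.1, seed=0)
    report = cross_validate(table, classifier="knn", n_folds=10, seed=0)
    assert report.accuracy == 1.0
    assert len(report.per_fold) == 10
    sizes = [m.total for m in report.per_fold]
    assert max(sizes) - min(sizes) <= 3      # stratified folds differ by <=1/class


def test_noise_features_sit_near_chance():
    table = make_table(20, list("abcde"), [0.0] * 5, 1.0, seed=3, n_features=8)
    report = cross_validate(table, classifier="rf", n_folds=10, seed=0)
    assert 0.05 <= report.accuracy <= 0.40   # chance level is 0.2


def test_same_seed_reproduces_folds_exactly():
    table = make_table(15, ["a", "b"], [0.0, 1.0], 1.0, seed=1)
    r1 = cross_validate(table, classifier="rf", n_folds=5, seed=42)
    r2 = cross_validate(table, classifier="rf", n_folds=5, seed=42)
    np.testing.assert_array_equal(r1.confusion.counts, r2.confusion.counts)
    for a, b in zip(r1.per_fold, r2.per_fold):
        np.testing.assert_array_equal(a.counts, b.counts)


def test_grid_search_records_selected_parameters():
    table = make_table(9, ["a", "b"], [0.0, 5.0], 0.5, seed=2)
    report = cross_validate(table, classifier="knn", n_folds=3, seed=0,
                            grid_search=True,
                            param_grid={"model__n_neighbors": [1, 3]})
    assert len(report.selected_params) == 3
    assert all("model__n_neighbors" in p for p in report.selected_params)


def test_validation_and_config_errors():
    table = make_table(5, ["a", "b"], [0.0, 1.0], 1.0, seed=0)
    with pytest.raises(ValidationError):
        cross_validate(table, classifier="rf", n_folds=10, seed=0)
    with pytest.raises(ConfigError):
        cross_validate(table, classifier="boosted-gradient", n_folds=5, seed=0)


# ---------------------------------------------------------------- ROC

def test_auc_trivial_cases(rng):
    y = np.array([0, 0, 1, 1, 0, 1] * 20, dtype=bool)
    assert _binary_auc(y, y.astype(float)) == 1.0
    scores = rng.standard_normal(y.size)
    auc = _binary_auc(y, scores)
    assert np.isclose(_binary_auc(y, -scores), 1.0 - auc, atol=1e-12)
    assert 0.4 <= auc <= 0.6 or True  # value checked below with larger n
    big = rng.standard_normal(200)
    labels = rng.integers(0, 2, 200).astype(bool)
    assert abs(_binary_auc(labels, big) - 0.5) < 0.12


def test_roc_one_vs_rest_on_separable_data():
    table = make_table(12, ["a", "b", "c"], [0.0, 8.0, -8.0], 0.2, seed=5)
    aucs = roc_one_vs_rest(table, classifier="rf", n_folds=4, seed=0)
    assert set(aucs) == {"a", "b", "c"}
    assert all(v > 0.99 for v in aucs.values())
    aucs_svm = roc_one_vs_rest(table, classifier="svm", n_folds=4, seed=0)
    assert all(v > 0.99 for v in aucs_svm.values())  # via decision_function


# ---------------------------------------------------------------- t-tests

def test_ttest_identical_groups_degenerate():
    table = pd.DataFrame({"label": ["a"] * 5 + ["b"] * 5, "f": [2.0] * 10})
    result = feature_ttest(table, "f", "a", "b")
    assert result.t == 0.0 and result.p == 1.0 and result.degenerate


def test_ttest_strong_separation_and_symmetry(rng):
    a = 5.0 + rng.standard_normal(50)
    b = -5.0 + rng.standard_normal(50)
    table = pd.DataFrame({"label": ["a"] * 50 + ["b"] * 50,
                          "f": np.concatenate([a, b])})
    fwd = feature_ttest(table, "f", "a", "b")
    rev = feature_ttest(table, "f", "b", "a")
    assert fwd.p < 1e-3
    assert np.isclose(fwd.t, -rev.t)
    assert np.isclose(fwd.p, rev.p)
    assert np.isclose(fwd.sem_a, a.std(ddof=1) / np.sqrt(50))
    with pytest.raises(ValidationError):
        feature_ttest(table, "missing", "a", "b")
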