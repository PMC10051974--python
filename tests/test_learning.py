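import numpy as np
import pandas as pd
import pytest

from tmaseg.dataio import CLASS_COLUMN
from tmaseg.learning import (
    CLASSIFIER_FAMILIES, ClassifierSpec, compare_grid, compute_metrics,
    cross_validate, select_best, train,
)


def brute_force_metrics(true, predicted):
    """Counting oracle: per-class one-vs-rest confusion and the four metrics."""
    classes = sorted(set(true) | set(predicted))
    n = len(true)
    per = {}
    for c in classes:
        tp = sum(1 for t, p in zip(true, predicted) if t == c and p == c)
        fp = sum(1 for t, p in zip(true, predicted) if t != c and p == c)
        fn = sum(1 for t, p in zip(true, predicted) if t == c and p != c)
        tn = n - tp - fp - fn
        ppv = tp / (tp + fp) if tp + fp else 0.0
        tpr = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * ppv * tpr / (ppv + tpr) if ppv + tpr else 0.0
        per[c] = dict(tp=tp, fp=fp, fn=fn, tn=tn, ppv=ppv, tpr=tpr, f1=f1)
    acc = sum(1 for t, p in zip(true, predicted) if t == p) / n
    macro = sum(per[c]["f1"] for c in classes) / len(classes)
    return per, acc, macro


def separable_table(image_id, n_per_class=30, seed=0):
    """Feature table with three well-separated Gaussian classes in 69-D."""
    from tmaseg.texture import feature_names
    rng = np.random.default_rng(seed + image_id)
    rows = []
    for idx, (code, center) in enumerate(zip((0, 2, 3), (0.0, 10.0, -10.0))):
        x = rng.normal(center, 0.5, (n_per_class, 69))
        for j in range(n_per_class):
            rows.append([image_id, idx * n_per_class + j, 0.0, 0.0, *x[j], code])
    cols = ["image_id", "superpixel_id", "row", "col", *feature_names(), CLASS_COLUMN]
    return pd.DataFrame(rows, columns=cols)


class TestTrain:
    def test_separable_classes_learned_by_random_forest(self):
        table = separable_table(0)
        model = train(table, ClassifierSpec("random_forest", seed=3))
        predicted = model.predict_table(table)
        assert (predicted == table[CLASS_COLUMN].to_numpy()).mean() >= 0.99

    @pytest.mark.parametrize("family", CLASSIFIER_FAMILIES)
    def test_all_families_fit_and_predict(self, family):
        table = separable_table(0)
        model = train(table, ClassifierSpec(family, seed=3))
        assert (model.predict_table(table) == table[CLASS_COLUMN]).mean() >= 0.9

    def test_deterministic_given_seed(self):
        table = separable_table(1)
        a = train(table, ClassifierSpec("random_forest", seed=5)).predict_table(table)
        b = train(table, ClassifierSpec("random_forest", seed=5)).predict_table(table)
        assert np.array_equal(a, b)

    def test_positional_columns_excluded_from_predictors(self):
        table = separable_table(0)
        model = train(table, ClassifierSpec("random_forest", seed=0))
        assert "image_id" not in model.feature_columns
        assert "superpixel_id" not in model.feature_columns
        assert "row" not in model.feature_columns
        assert len(model.feature_columns) == 69

    def test_single_class_rejected(self):
        table = separable_table(0)
        table[CLASS_COLUMN] = 2
        with pytest.raises(ValueError, match="2 classes"):
            train(table, ClassifierSpec("random_forest"))

    def test_nan_feature_rejected(self):
        table = separable_table(0)
        table.loc[0, "R_mean"] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            train(table, ClassifierSpec("random_forest"))

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError, match="family"):
            ClassifierSpec("deep_net")


class TestComputeMetrics:
    def test_perfect_prediction(self):
        y = [0, 2, 3, 2, 0, 3]
        cm, report = compute_metrics(y, y)
        assert report.accuracy == 1.0
        assert all(report.f1[c] == 1.0 for c in report.classes)
        assert report.macro_f1 == 1.0

    def test_binary_hand_counts(self):
        # TP=8, FP=2, FN=2 for class 1 -> PPV = TPR = F1 = 0.8
        true = [1] * 10 + [0] * 10
        pred = [1] * 8 + [0] * 2 + [1] * 2 + [0] * 8
        cm, report = compute_metrics(true, pred)
        assert (cm.tp[1], cm.fp[1], cm.fn[1]) == (8, 2, 2)
        assert report.ppv[1] == pytest.approx(0.8)
        assert report.tpr[1] == pytest.approx(0.8)
        assert report.f1[1] == pytest.approx(0.8)

    def test_no_true_positives_scores_zero(self):
        _, report = compute_metrics([2, 2, 3], [3, 3, 2])
        assert report.f1[2] == 0.0 and report.f1[3] == 0.0
        assert report.accuracy == 0.0

    def test_agrees_with_brute_force_oracle(self, rng):
        for _ in range(500):
            n = int(rng.integers(1, 30))
            true = rng.choice([0, 2, 3], n).tolist()
            pred = rng.choice([0, 2, 3], n).tolist()
            cm, report = compute_metrics(true, pred)
            per, acc, macro = brute_force_metrics(true, pred)
            assert report.accuracy == acc
            assert report.macro_f1 == pytest.approx(macro)
            for c in cm.classes:
                assert (cm.tp[c], cm.fp[c], cm.fn[c], cm.tn[c]) == \
                    (per[c]["tp"], per[c]["fp"], per[c]["fn"], per[c]["tn"])
                assert report.f1[c] == pytest.approx(per[c]["f1"])

    def test_agrees_with_sklearn(self, rng):
        from sklearn.metrics import accuracy_score, f1_score
        true = rng.choice([0, 2, 3], 200)
        pred = rng.choice([0, 2, 3], 200)
        _, report = compute_metrics(true, pred)
        assert report.accuracy == pytest.approx(accuracy_score(true, pred))
        assert report.macro_f1 == pytest.approx(f1_score(true, pred, average="macro"))

    def test_support_identities(self, rng):
        true = rng.choice([0, 2, 3], 100)
        pred = rng.choice([0, 2, 3], 100)
        cm, report = compute_metrics(true, pred)
        for c in cm.classes:
            assert cm.tp[c] + cm.fn[c] == report.support[c]
            assert cm.tp[c] + cm.fp[c] + cm.fn[c] + cm.tn[c] == cm.n
        assert sum(report.support.values()) == 100

    def test_invariant_to_class_relabeling(self, rng):
        true = rng.choice([0, 2, 3], 120)
        pred = rng.choice([0, 2, 3], 120)
        relabel = {0: 3, 2: 0, 3: 2}
        _, a = compute_metrics(true, pred)
        _, b = compute_metrics([relabel[t] for t in true], [relabel[p] for p in pred])
        assert a.accuracy == b.accuracy
        assert a.macro_f1 == pytest.approx(b.macro_f1)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics([0, 2], [0])


class TestCrossValidate:
    def test_ten_images_give_ten_folds_training_on_nine(self):
        tables = [separable_table(i, n_per_class=8) for i in range(10)]
        report = cross_validate(tables, ClassifierSpec("bayes_net"))
        assert len(report.accuracies) == 10
        assert report.image_ids == list(range(10))
        for fold in report.train_ids:
            assert len(fold) == 9
        held_out = [set(range(10)) - set(f) for f in report.train_ids]
        assert [h.pop() for h in held_out] == report.image_ids

    def test_identical_separable_images_score_high(self):
        tables = [separable_table(0), separable_table(0)]
        report = cross_validate(tables, ClassifierSpec("random_forest", seed=1))
        assert all(a >= 0.99 for a in report.accuracies)

    def test_means_are_arithmetic_means(self):
        tables = [separable_table(i, n_per_class=6) for i in range(4)]
        report = cross_validate(tables, ClassifierSpec("bayes_net"))
        assert report.mean_accuracy == pytest.approx(np.mean(report.accuracies))
        assert report.mean_macro_f1 == pytest.approx(np.mean(report.macro_f1s))

    def test_fewer_than_two_images_rejected(self):
        with pytest.raises(ValueError, match="2 images"):
            cross_validate([separable_table(0)], ClassifierSpec("bayes_net"))


class TestCompareGrid:
    def test_single_pair_is_best(self):
        tables = [separable_table(i, n_per_class=6) for i in range(3)]
        grid = compare_grid({"none": tables}, [ClassifierSpec("bayes_net")])
        assert len(grid) == 1
        assert select_best(grid) == ("none", "bayes_net")

    def test_label_shuffled_set_never_ranks_first(self, rng):
        tables = [separable_table(i, n_per_class=10) for i in range(3)]
        shuffled = [t.copy() for t in tables]
        for t in shuffled:
            t[CLASS_COLUMN] = rng.permutation(t[CLASS_COLUMN].to_numpy())
        grid = compare_grid({"none": tables, "shuffled": shuffled},
                            [ClassifierSpec("bayes_net")])
        assert grid.iloc[0]["enhancement"] == "none"

    def test_row_count_is_product(self):
        tables = [separable_table(i, n_per_class=5) for i in range(2)]
        specs = [ClassifierSpec("bayes_net"), ClassifierSpec("c45_tree")]
        grid = compare_grid({"none": tables, "equalize": tables}, specs)
        assert len(grid) == 4

    def test_tie_broken_by_macro_f1(self):
        grid = pd.DataFrame([
            {"enhancement": "match", "classifier": "svm",
             "mean_accuracy": 0.9, "mean_macro_f1": 0.7},
            {"enhancement": "normalize", "classifier": "svm",
             "mean_accuracy": 0.9, "mean_macro_f1": 0.8},
        ]).sort_values(by=["mean_accuracy", "mean_macro_f1"],
                       ascending=False).reset_index(drop=True)
        assert select_best(grid) == ("normalize", "svm")

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            select_best(pd.DataFrame())
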