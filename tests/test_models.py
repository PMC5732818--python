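import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ecrad.models import (
    CvMetrics, ModelConfig, confusion_metrics, cross_validate,
    evaluate_holdout, mcc, mcnemar_test, stratified_split, train_classifier,
    wrapper_select,
)


def make_table(rng, n=37, n_pos=11, n_features=6, effect=0.0, n_informative=1):
    """Feature table with an optional planted class effect."""
    idx = [f"case_{i:03d}" for i in range(n)]
    y = (np.arange(n) < n_pos).astype(int)
    data = rng.normal(size=(n, n_features))
    data[:, :n_informative] += np.outer(y, np.ones(n_informative)) * effect
    return pd.DataFrame(data, index=idx,
                        columns=[f"f{j}" for j in range(n_features)]), y


class TestMcc:
    @pytest.mark.parametrize("tp,tn,fp,fn,expected", [
        (5, 5, 0, 0, 1.0),
        (0, 0, 5, 5, -1.0),
        (3, 2, 1, 1, 5 / 12),
    ])
    def test_direct_formula(self, tp, tn, fp, fn, expected):
        assert mcc(tp, tn, fp, fn) == pytest.approx(expected, abs=1e-3)

    def test_zero_denominator_convention(self):
        assert mcc(5, 0, 0, 5) == 0.0

    def test_matches_sklearn_on_random_confusions(self, rng):
        from sklearn.metrics import matthews_corrcoef
        for _ in range(10):
            y = rng.integers(0, 2, 30)
            pred = rng.integers(0, 2, 30)
            tp = int(((y == 1) & (pred == 1)).sum())
            tn = int(((y == 0) & (pred == 0)).sum())
            fp = int(((y == 0) & (pred == 1)).sum())
            fn = int(((y == 1) & (pred == 0)).sum())
            assert mcc(tp, tn, fp, fn) == pytest.approx(
                matthews_corrcoef(y, pred), abs=1e-12)


class TestConfusionMetrics:
    def test_majority_predictor_on_26_11_split(self):
        y = np.array([0] * 26 + [1] * 11)
        pred = np.zeros(37, dtype=int)
        m = confusion_metrics(y, pred)
        assert m.accuracy == pytest.approx(26 / 37)
        assert m.mcc == 0.0

    def test_weighted_metrics_on_printed_confusion_fixture(self):
        # TP=20, FN=2 (class 1, support 22); TN=9, FP=3 (class 0, support 12)
        y = np.array([1] * 22 + [0] * 12)
        pred = np.array([1] * 20 + [0] * 2 + [1] * 3 + [0] * 9)
        m = confusion_metrics(y, pred)
        # hand-computed support-weighted values
        tpr1, tpr0 = 20 / 22, 9 / 12
        prec1, prec0 = 20 / 23, 9 / 11
        f1 = 2 * prec1 * tpr1 / (prec1 + tpr1)
        f0 = 2 * prec0 * tpr0 / (prec0 + tpr0)
        w1, w0 = 22 / 34, 12 / 34
        assert m.accuracy == pytest.approx(29 / 34)
        assert m.tp_rate == pytest.approx(w1 * tpr1 + w0 * tpr0)
        assert m.precision == pytest.approx(w1 * prec1 + w0 * prec0)
        assert m.f_measure == pytest.approx(w1 * f1 + w0 * f0)
        assert m.fp_rate == pytest.approx(w1 * (3 / 12) + w0 * (2 / 22))
        assert m.mcc == pytest.approx(mcc(20, 9, 3, 2))

    def test_metrics_mutually_consistent_from_one_matrix(self, rng):
        y = rng.integers(0, 2, 40)
        pred = rng.integers(0, 2, 40)
        m = confusion_metrics(y, pred)
        tp = int(((y == 1) & (pred == 1)).sum())
        tn = int(((y == 0) & (pred == 0)).sum())
        assert m.accuracy == pytest.approx((tp + tn) / 40)
        assert -1 <= m.mcc <= 1
        assert 0 <= m.tp_rate <= 1 and 0 <= m.fp_rate <= 1


class TestClassifiers:
    @pytest.mark.parametrize("algo", ["svm", "ann"])
    def test_separable_toy_set_perfect_training_accuracy(self, rng, algo):
        table, y = make_table(rng, n=24, n_pos=12, n_features=2,
                              effect=8.0, n_informative=2)
        model = train_classifier(table, y, ModelConfig(algorithm=algo, seed=0))
        assert (model.predict(table.values) == y).mean() == 1.0

    def test_ann_deterministic_under_seed(self, rng):
        table, y = make_table(rng, effect=1.0)
        cfg = ModelConfig(algorithm="ann", seed=42)
        m1 = train_classifier(table, y, cfg)
        m2 = train_classifier(table, y, cfg)
        np.testing.assert_array_equal(m1.predict(table.values),
                                      m2.predict(table.values))

    def test_too_few_cases_per_class_rejected(self, rng):
        table, _ = make_table(rng, n=5, n_pos=1)
        with pytest.raises(ValueError):
            train_classifier(table, np.array([1, 0, 0, 0, 0]),
                             ModelConfig(algorithm="svm"))


class TestCrossValidate:
    def test_perfect_planted_rule(self, rng):
        table, y = make_table(rng, n=30, n_pos=15, effect=10.0)
        m, oof = cross_validate(table, y, ModelConfig("svm", n_folds=10, seed=0))
        assert m.accuracy == 1.0
        assert m.mcc == 1.0
        assert m.auc == 1.0
        assert (oof["y_true"] == y).all()

    def test_stratified_folds_preserve_class_ratio(self, rng):
        table, y = make_table(rng, n=37, n_pos=11)
        _, oof = cross_validate(table, y, ModelConfig("svm", n_folds=10, seed=3))
        for fold in range(10):
            sub = oof[oof["fold"] == fold]
            assert 1 <= sub["y_true"].sum() <= 2  # 11 positives over 10 folds

    def test_pooled_metrics_recomputable_from_oof(self, rng):
        table, y = make_table(rng, effect=1.0)
        m, oof = cross_validate(table, y, ModelConfig("svm", n_folds=5, seed=1))
        ref = confusion_metrics(oof["y_true"].values, oof["y_pred"].values,
                                oof["score"].values)
        assert m.as_dict() == pytest.approx(ref.as_dict())


class TestWrapperSelect:
    def test_informative_feature_retained_across_seeds(self):
        kept_count = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            table, y = make_table(rng, n=37, n_pos=11, n_features=8,
                                  effect=3.0, n_informative=1)
            cfg = ModelConfig("svm", n_folds=10, seed=seed)
            selected = wrapper_select(table, y, cfg)
            kept_count += "f0" in selected
        assert kept_count >= 9

    def test_duplicated_informative_feature_one_survives(self, rng):
        table, y = make_table(rng, n=30, n_pos=12, n_features=5,
                              effect=3.0, n_informative=1)
        table["f_dup"] = table["f0"]
        selected = wrapper_select(table, y, ModelConfig("svm", n_folds=5, seed=0))
        assert ("f0" in selected) or ("f_dup" in selected)

    def test_per_algorithm_subsets_may_differ_but_are_valid(self, rng):
        table, y = make_table(rng, n=30, n_pos=12, n_features=6, effect=2.0)
        sel_svm = wrapper_select(table, y, ModelConfig("svm", n_folds=5, seed=0))
        sel_ann = wrapper_select(table, y, ModelConfig("ann", n_folds=5, seed=0))
        for sel in (sel_svm, sel_ann):
            assert 1 <= len(sel) <= 6
            assert set(sel) <= set(table.columns)


class TestMcnemar:
    def test_identical_predictions(self):
        y = np.array([0, 1, 0, 1, 1])
        pred = np.array([0, 1, 1, 1, 0])
        b, c, p = mcnemar_test(pred, pred, y)
        assert (b, c, p) == (0, 0, 1.0)

    def test_exact_binomial_worked_example(self):
        """b=1, c=5 -> two-sided exact p = 0.21875 (binomial(6, 1/2))."""
        y = np.zeros(10, dtype=int)
        # case 4: a right / b wrong; cases 5-9: a wrong / b right
        preds_a = np.array([0, 0, 0, 0, 0, 1, 1, 1, 1, 1])
        preds_b = np.array([0, 0, 0, 0, 1, 0, 0, 0, 0, 0])
        b, c, p = mcnemar_test(preds_a, preds_b, y)
        assert (b, c) == (1, 5)
        assert p == pytest.approx(0.21875, abs=1e-10)

    def test_symmetric_discordance(self):
        y = np.zeros(6, dtype=int)
        preds_a = np.array([1, 1, 1, 0, 0, 0])
        preds_b = np.array([0, 0, 0, 1, 1, 1])
        b, c, p = mcnemar_test(preds_a, preds_b, y)
        assert (b, c) == (3, 3)
        assert p == pytest.approx(1.0)

    def test_exact_p_matches_binomial_tail_for_small_counts(self):
        """Closed-form check for every (b, c) with b + c <= 10."""
        for total in range(1, 11):
            for b in range(total + 1):
                c = total - b
                y = np.zeros(b + c + 3, dtype=int)
                preds_a = np.array([0] * 3 + [0] * b + [1] * c)
                preds_b = np.array([0] * 3 + [1] * b + [0] * c)
                bb, cc, p = mcnemar_test(preds_a, preds_b, y)
                assert (bb, cc) == (b, c)
                k = min(b, c)
                ref = min(1.0, 2 * stats.binom.cdf(k, total, 0.5))
                if b == c:
                    ref = 1.0
                assert p == pytest.approx(ref, abs=1e-9), (b, c)


class TestHoldout:
    def test_perfect_separation(self, rng):
        train, y_train = make_table(rng, n=30, n_pos=15, effect=10.0)
        test, y_test = make_table(rng, n=12, n_pos=5, effect=10.0)
        model = train_classifier(train, y_train, ModelConfig("svm", seed=0))
        m, cm = evaluate_holdout(model, test, y_test)
        assert m.accuracy == 1.0
        assert cm.sum() == 12

    def test_training_isolated_from_test_labels(self, rng):
        train, y_train = make_table(rng, n=30, n_pos=15, effect=2.0)
        test, y_test = make_table(rng, n=12, n_pos=5, effect=2.0)
        model = train_classifier(train, y_train, ModelConfig("svm", seed=0))
        preds_before = model.predict(test.values).copy()
        _ = evaluate_holdout(model, test, 1 - y_test)  # shuffled labels
        np.testing.assert_array_equal(model.predict(test.values), preds_before)

    def test_stratified_split_sizes(self):
        labels = pd.Series([True] * 16 + [False] * 33,
                           index=[f"c{i}" for i in range(49)])
        train, test = stratified_split(labels, n_test=12, seed=0,
                                       n_test_positive=5)
        assert len(train) == 37 and len(test) == 12
        assert labels[test].sum() == 5
        assert labels[train].sum() == 11
        assert set(train) | set(test) == set(labels.index)
        assert not set(train) & set(test)
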