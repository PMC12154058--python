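"""Splits, confusion-matrix metrics (vs. enumeration oracle), and the
Monte Carlo harness."""

import itertools

import numpy as np
import pytest

from fritqc import (GeneratorConfig, classification_metrics, confusion,
                    evaluate_origin_models, r_squared, rmse,
                    simulate_origin_dataset, split_adulteration,
                    split_origin_mc)
from fritqc.chemometrics import PLSDAClassifier


class TestOriginSplit:
    def test_default_design_counts(self):
        ds = simulate_origin_dataset(GeneratorConfig(seed=0))
        pairs = split_origin_mc(ds, n_repeats=3, seed=1)
        for tr, te in pairs:
            assert te.size == 240 and tr.size == 480
            for c in range(4):
                assert (ds.labels[te] == c).sum() == 60
                assert (ds.labels[tr] == c).sum() == 120

    def test_partition_property(self, small_origin_set):
        for tr, te in split_origin_mc(small_origin_set, n_repeats=5, seed=2):
            assert np.intersect1d(tr, te).size == 0
            assert np.union1d(tr, te).size == small_origin_set.n

    def test_repeats_differ_and_seed_reproduces(self, small_origin_set):
        a = split_origin_mc(small_origin_set, n_repeats=20, seed=3)
        b = split_origin_mc(small_origin_set, n_repeats=20, seed=3)
        for (t1, e1), (t2, e2) in zip(a, b):
            assert np.array_equal(e1, e2)
        distinct = {tuple(e) for _, e in a}
        assert len(distinct) == 20

    def test_invalid_fraction_rejected(self, small_origin_set):
        with pytest.raises(ValueError):
            split_origin_mc(small_origin_set, test_fraction=1.5)

    def test_batch_stratified_mode_keeps_batches_whole(self, small_origin_set):
        pairs = split_origin_mc(small_origin_set, n_repeats=3, seed=0,
                                stratify_batches=True)
        for tr, te in pairs:
            tr_groups = set(zip(small_origin_set.labels[tr],
                                small_origin_set.batch_ids[tr]))
            te_groups = set(zip(small_origin_set.labels[te],
                                small_origin_set.batch_ids[te]))
            assert not tr_groups & te_groups


class TestAdulterationSplit:
    def test_13_7_per_level(self, small_adulteration_set):
        tr, te = split_adulteration(small_adulteration_set, seed=0)
        levels = np.unique(small_adulteration_set.labels)
        assert tr.size == 13 * levels.size and te.size == 7 * levels.size
        for lv in levels:
            assert (small_adulteration_set.labels[te] == lv).sum() == 7
        assert np.intersect1d(tr, te).size == 0

    def test_full_design_gives_377_203(self):
        from fritqc import simulate_adulteration_dataset
        ds = simulate_adulteration_dataset(GeneratorConfig(seed=2))
        tr, te = split_adulteration(ds, seed=0)
        assert tr.size == 377 and te.size == 203

    def test_wrong_replicate_count_rejected(self, small_adulteration_set):
        broken = small_adulteration_set.subset(
            np.arange(small_adulteration_set.n - 1))
        with pytest.raises(ValueError):
            split_adulteration(broken)


def _oracle_metrics(y_true, y_pred, c):
    """Naive per-class counting, independent of the implementation."""
    acc = sum(t == p for t, p in zip(y_true, y_pred)) / len(y_true)
    precs, recs, f1s = [], [], []
    for k in range(c):
        tp = sum(1 for t, p in zip(y_true, y_pred) if t == k and p == k)
        fp = sum(1 for t, p in zip(y_true, y_pred) if t != k and p == k)
        fn = sum(1 for t, p in zip(y_true, y_pred) if t == k and p != k)
        precs.append(tp / (tp + fp) if tp + fp else 0.0)
        recs.append(tp / (tp + fn) if tp + fn else 0.0)
        f1s.append(2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0.0)
    return acc, np.mean(precs), np.mean(recs), np.mean(f1s)


class TestClassificationMetrics:
    def test_binary_contingency_substitution(self):
        """TP=50 TN=40 FP=5 FN=5 -> acc .9, prec=rec=50/55, F1=100/110."""
        y_true = [1] * 55 + [0] * 45
        y_pred = [1] * 50 + [0] * 5 + [1] * 5 + [0] * 40
        m = classification_metrics(confusion(y_true, y_pred, 2))
        assert m["accuracy"] == pytest.approx(0.90)
        tp, tn, fp, fn = confusion(y_true, y_pred, 2).one_vs_rest(1)
        assert (tp, tn, fp, fn) == (50, 40, 5, 5)

    def test_perfect_and_diagonal_cases(self):
        m = classification_metrics(confusion([0, 1, 2] * 2, [0, 1, 2] * 2, 3))
        assert all(v == 1.0 for v in m.values())

    def test_exhaustive_agreement_with_enumeration_oracle(self):
        """All 81 x 81 (true, pred) 3-class labelings of 4 samples."""
        labelings = list(itertools.product(range(3), repeat=4))
        rng = np.random.default_rng(0)
        for y_true in labelings:
            y_pred = labelings[rng.integers(len(labelings))]
            m = classification_metrics(confusion(y_true, y_pred, 3))
            oa, op, orc, of1 = _oracle_metrics(y_true, y_pred, 3)
            assert m["accuracy"] == pytest.approx(oa)
            assert m["precision"] == pytest.approx(op)
            assert m["recall"] == pytest.approx(orc)
            assert m["f1"] == pytest.approx(of1)

    def test_counts_conserved_and_accuracy_is_trace_over_total(self, rng):
        y_true = rng.integers(0, 4, 100)
        y_pred = rng.integers(0, 4, 100)
        cm = confusion(y_true, y_pred, 4)
        assert cm.n == 100
        m = classification_metrics(cm)
        assert m["accuracy"] == pytest.approx(np.trace(cm.counts) / 100)

    def test_row_is_actual_column_is_predicted(self):
        cm = confusion([0, 0, 1], [1, 1, 1], 2)
        assert cm.counts[0, 1] == 2 and cm.counts[1, 1] == 1

    def test_out_of_range_labels_rejected(self):
        with pytest.raises(ValueError):
            confusion([0, 5], [0, 1], 4)


class TestRegressionMetrics:
    def test_exact_predictions(self):
        y = np.array([0.1, 0.2, 0.4])
        assert r_squared(y, y) == 1.0
        assert rmse(y, y) == 0.0

    def test_mean_predictor_has_zero_r2(self):
        y = np.array([0.0, 1.0, 2.0])
        assert r_squared(y, np.full(3, 1.0)) == pytest.approx(0.0)

    def test_direct_substitution(self):
        assert rmse([0, 1, 2], [0, 1, 3]) == pytest.approx(np.sqrt(1 / 3))

    def test_affine_invariance_of_r2(self, rng):
        y = rng.standard_normal(30)
        yhat = y + 0.3 * rng.standard_normal(30)
        a, b = 17.0, -3.0
        assert r_squared(a * y + b, a * yhat + b) == pytest.approx(
            r_squared(y, yhat))

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            r_squared([1.0, 1.0], [1.0, 2.0])


class TestMonteCarloHarness:
    def test_plsda_report_structure_and_determinism(self, small_origin_set):
        models = {"plsda": lambda s: PLSDAClassifier(n_components=5, seed=s)}
        preps = {"raw": lambda X: X}
        r1 = evaluate_origin_models(small_origin_set, models, preps,
                                    n_repeats=4, seed=5)
        r2 = evaluate_origin_models(small_origin_set, models, preps,
                                    n_repeats=4, seed=5)
        assert r1.records.equals(r2.records)
        agg = r1.aggregate()
        # 1 prep x 1 model x 2 splits x 4 metrics
        assert len(agg) == 8
        assert (agg["std"] >= 0).all()
        assert not r1.failures

    def test_shuffled_labels_give_chance_accuracy(self, small_origin_set):
        rng = np.random.default_rng(1)
        shuffled = small_origin_set.subset(np.arange(small_origin_set.n))
        shuffled.labels = rng.permutation(shuffled.labels)
        models = {"plsda": lambda s: PLSDAClassifier(n_components=5, seed=s)}
        rep = evaluate_origin_models(shuffled, models,
                                     {"raw": lambda X: X}, n_repeats=8, seed=2)
        agg = rep.aggregate()
        test_acc = agg[(agg.split == "test")
                       & (agg.metric == "accuracy")]["mean"].iloc[0]
        # 4 classes: chance 0.25; binomial sd over 8 repeats of 20 test rows
        assert abs(test_acc - 0.25) < 3 * np.sqrt(0.25 * 0.75 / (8 * 20))

    def test_single_model_failure_recorded_not_fatal(self, small_origin_set):
        class Broken:
            def fit(self, X, y):
                raise RuntimeError("boom")
        rep = evaluate_origin_models(
            small_origin_set, {"broken": lambda s: Broken()},
            {"raw": lambda X: X}, n_repeats=2, seed=0)
        assert len(rep.failures) == 2
        assert rep.records.empty
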