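"""Metric formulas vs independent oracles; splits; CIs; experiment harness."""

import itertools

import numpy as np
import pytest

import endofew as ef
from endofew.errors import SplitError, ValidationError
from endofew.evaluate import (_subset, compute_metrics, confidence_interval,
                              make_splits, project_2d)


def _polyp_dataset(counts, size=8, seed=0):
    """Tiny dataset with given per-class polyp counts (one image each)."""
    rng = np.random.default_rng(seed)
    samples = []
    pid = 0
    for cls, n in counts.items():
        for _ in range(n):
            samples.append(ef.ImageSample(pixels=rng.random((size, size, 3)),
                                          label=cls, polyp_id=f"p{pid:04d}"))
            pid += 1
    return ef.Dataset(samples=samples, class_vocabulary=sorted(counts))


class TestComputeMetrics:
    def test_worked_binary_example(self):
        # per-class one-vs-rest counts for "p": TP=2, TN=2, FP=1, FN=1
        y_true = ["p", "p", "p", "n", "n", "n"]
        y_pred = ["p", "p", "n", "p", "n", "n"]
        rep = compute_metrics(y_true, y_pred, ["n", "p"])
        for c in ("n", "p"):
            assert rep.per_class[c]["precision"] == pytest.approx(2 / 3)
            assert rep.per_class[c]["recall"] == pytest.approx(2 / 3)
            assert rep.per_class[c]["f1"] == pytest.approx(2 / 3)
        assert rep.accuracy == pytest.approx(2 / 3)

    def test_perfect_prediction(self):
        y = ["a", "b", "a", "b"]
        rep = compute_metrics(y, y, ["a", "b"])
        assert rep.accuracy == rep.macro_f1 == rep.macro_precision == 1.0

    def test_exhaustive_binary_vectors_vs_sklearn(self):
        """Independent cross-check on every binary labelling of length <= 6."""
        from sklearn.metrics import (accuracy_score,
                                     precision_recall_fscore_support)
        for n in range(1, 7):
            for y_true in itertools.product("ab", repeat=n):
                for y_pred in itertools.product("ab", repeat=n):
                    rep = compute_metrics(list(y_true), list(y_pred),
                                          ["a", "b"])
                    p, r, f, _ = precision_recall_fscore_support(
                        y_true, y_pred, labels=["a", "b"], average="macro",
                        zero_division=0)
                    assert rep.macro_precision == pytest.approx(p)
                    assert rep.macro_recall == pytest.approx(r)
                    assert rep.macro_f1 == pytest.approx(f)
                    assert rep.accuracy == pytest.approx(
                        accuracy_score(y_true, y_pred))

    def test_accuracy_equals_macro_recall_on_balanced_sets(self, rng):
        """On a class-balanced test set plain accuracy is macro recall."""
        for _ in range(1000):
            k = int(rng.integers(2, 4))
            per = int(rng.integers(1, 5))
            classes = [f"c{i}" for i in range(k)]
            y_true = np.repeat(classes, per)
            y_pred = rng.choice(classes, size=k * per)
            rep = compute_metrics(y_true.tolist(), y_pred.tolist(), classes)
            assert rep.accuracy == pytest.approx(rep.macro_recall, abs=1e-12)

    def test_permutation_invariance(self, rng):
        y_true = list("aabbabab")
        y_pred = list("ababbbaa")
        base = compute_metrics(y_true, y_pred, ["a", "b"])
        perm = rng.permutation(len(y_true))
        shuf = compute_metrics([y_true[i] for i in perm],
                               [y_pred[i] for i in perm], ["a", "b"])
        assert base.as_dict() == shuf.as_dict()

    def test_micro_f1_equals_accuracy_binary(self, rng):
        for _ in range(100):
            y_true = rng.choice(["a", "b"], size=12).tolist()
            y_pred = rng.choice(["a", "b"], size=12).tolist()
            rep = compute_metrics(y_true, y_pred, ["a", "b"])
            tp = sum(rep.confusion[i, i] for i in range(2))
            fp = rep.confusion.sum() * 2 - 2 * tp  # off-diagonals counted twice
            micro_f1 = 2 * tp / (2 * tp + fp) if tp + fp else 0.0
            assert micro_f1 == pytest.approx(rep.accuracy)

    def test_label_outside_vocabulary_rejected(self):
        with pytest.raises(ValidationError):
            compute_metrics(["a"], ["z"], ["a", "b"])

    def test_confusion_row_sums_equal_support(self):
        y_true = list("aaabbc")
        y_pred = list("abacbc")
        rep = compute_metrics(y_true, y_pred, ["a", "b", "c"])
        for i, c in enumerate(rep.classes):
            assert rep.confusion[i].sum() == y_true.count(c)


class TestConfidenceInterval:
    def test_constant_vector(self):
        assert confidence_interval([0.7] * 10) == (pytest.approx(0.7), 0.0)

    def test_hand_computed_half_width(self):
        values = [0.0] * 50 + [1.0] * 50
        mean, half = confidence_interval(values, level=0.90)
        sd = np.std(values, ddof=1)  # 0.502519...
        assert mean == pytest.approx(0.5)
        assert half == pytest.approx(1.6449 * sd, abs=1e-4)

    def test_half_width_scales_linearly(self, rng):
        v = rng.random(30)
        _, h1 = confidence_interval(v)
        _, h3 = confidence_interval(3 * v)
        assert h3 == pytest.approx(3 * h1)

    def test_too_few_values_rejected(self):
        with pytest.raises(ValidationError):
            confidence_interval([0.5])

    def test_percentile_method(self):
        v = list(range(101))
        mean, half = confidence_interval(v, level=0.90, method="percentile")
        assert half == pytest.approx(45.0)


class TestMakeSplits:
    def test_disjoint_and_balanced_on_paper_sized_set(self):
        ds = _polyp_dataset({"I": 34, "II": 27})
        spec = ef.SplitSpec(train_fraction=0.75, balanced_test=True,
                            n_repeats=100, seed=1)
        splits = make_splits(ds, spec)
        assert len(splits) == 100
        for train, test in splits:
            assert set(train) & set(test) == set()
            assert len(train) + len(test) == 61
            test_labels = [s.label for s in _subset(ds, test).samples]
            assert test_labels.count("I") == test_labels.count("II") == 7

    def test_default_n_repeats_is_100(self):
        assert ef.SplitSpec().n_repeats == 100

    def test_same_seed_same_splits(self):
        ds = _polyp_dataset({"a": 10, "b": 8})
        a = make_splits(ds, ef.SplitSpec(n_repeats=5, seed=3))
        b = make_splits(ds, ef.SplitSpec(n_repeats=5, seed=3))
        assert a == b

    def test_unbalanced_preserves_proportions(self):
        ds = _polyp_dataset({"a": 40, "b": 20})
        spec = ef.SplitSpec(train_fraction=0.75, balanced_test=False,
                            n_repeats=10, seed=2)
        for train, test in make_splits(ds, spec):
            test_labels = [s.label for s in _subset(ds, test).samples]
            assert abs(test_labels.count("a") - 10) <= 1
            assert abs(test_labels.count("b") - 5) <= 1

    def test_class_too_small_rejected(self):
        ds = _polyp_dataset({"a": 1, "b": 10})
        with pytest.raises(SplitError):
            make_splits(ds, ef.SplitSpec(n_repeats=2, seed=0))


class TestRunExperiment:
    def test_report_counts_and_determinism(self, tiny_encoder):
        ds = _polyp_dataset({"a": 8, "b": 8}, size=16)
        spec = ef.SplitSpec(n_repeats=4, seed=9)
        rep1 = ef.run_experiment(ds, tiny_encoder, "one_nn", spec)
        rep2 = ef.run_experiment(ds, tiny_encoder, "one_nn", spec)
        assert len(rep1.per_repeat) == 4
        assert rep1.mean == rep2.mean
        for a, b in zip(rep1.per_repeat, rep2.per_repeat):
            assert np.array_equal(a.confusion, b.confusion)

    def test_shared_splits_across_heads(self, tiny_encoder):
        ds = _polyp_dataset({"a": 8, "b": 8}, size=16)
        spec = ef.SplitSpec(n_repeats=3, seed=5)
        assert make_splits(ds, spec) == make_splits(ds, spec)

    def test_variance_report_attached(self, tiny_encoder):
        ds = _polyp_dataset({"a": 6, "b": 6}, size=16)
        rep = ef.run_experiment(ds, tiny_encoder, "centroid",
                                ef.SplitSpec(n_repeats=2, seed=1))
        assert rep.variance_report is not None
        assert rep.variance_report.inter == 1.0


class TestProjection:
    def test_shape_and_determinism(self, rng):
        X = rng.normal(size=(20, 8))
        a = project_2d(X, seed=3)
        b = project_2d(X, seed=3)
        assert a.shape == (20, 2)
        assert np.allclose(a, b)

    def test_separated_clusters_stay_separated(self, rng):
        from sklearn.metrics import silhouette_score
        X = np.vstack([rng.normal(0, 0.3, size=(15, 6)),
                       rng.normal(8, 0.3, size=(15, 6))])
        coords = project_2d(X, seed=0)
        labels = [0] * 15 + [1] * 15
        assert silhouette_score(coords, labels) > 0

    def test_too_few_points_rejected(self):
        with pytest.raises(ValidationError):
            project_2d(np.zeros((2, 3)))
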