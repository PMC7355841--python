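"""Classifier harness: training, cross-validation, grid search, metrics."""

import numpy as np
import pytest

from gazerr.classification import (
    ClassifierSpec,
    cross_validate,
    evaluate,
    grid_search,
    train_classifier,
)
from gazerr.features import LabeledDataset


def blobs(rng, n_per=60, sep=6.0, n_feat=5, n_classes=2):
    parts, labels = [], []
    for c in range(n_classes):
        centre = np.zeros(n_feat)
        centre[c % n_feat] = sep * c
        parts.append(rng.normal(centre, 1.0, size=(n_per, n_feat)))
        labels += [f"c{c}"] * n_per
    x = np.vstack(parts)
    x = (x - x.mean(axis=0)) / x.std(axis=0)
    return LabeledDataset(matrix=x, labels=np.array(labels),
                          feature_names=tuple(f"f{i}" for i in range(n_feat)))


class TestTrainClassifier:
    @pytest.mark.parametrize("kind", ["knn", "svm", "mlp"])
    def test_separable_blobs_learned_perfectly(self, kind, rng):
        ds = blobs(rng, sep=10.0)
        model = train_classifier(ds, ClassifierSpec(kind=kind, max_iter=800))
        assert model.score(ds.matrix, ds.labels) == 1.0

    def test_knn_k1_memorizes_training_set(self, rng):
        ds = blobs(rng, sep=1.0)
        model = train_classifier(ds, ClassifierSpec(kind="knn", knn_k=1))
        assert model.score(ds.matrix, ds.labels) == 1.0

    def test_single_class_rejected(self, rng):
        ds = LabeledDataset(matrix=rng.normal(size=(10, 3)),
                            labels=np.array(["a"] * 10),
                            feature_names=("x", "y", "z"))
        with pytest.raises(ValueError):
            train_classifier(ds, ClassifierSpec())

    def test_unstandardized_input_warns(self, rng):
        ds = blobs(rng)
        ds = LabeledDataset(matrix=ds.matrix * 50.0, labels=ds.labels,
                            feature_names=ds.feature_names)
        with pytest.warns(UserWarning, match="unstandardized"):
            train_classifier(ds, ClassifierSpec(kind="knn"))

    def test_knn_matches_exhaustive_nearest_neighbour(self, rng):
        train = blobs(rng, n_per=80, sep=2.0)
        probe = rng.normal(size=(40, 5))
        model = train_classifier(train, ClassifierSpec(kind="knn", knn_k=1))
        pred = model.predict(probe)
        for i, p in enumerate(probe):
            d = np.linalg.norm(train.matrix - p, axis=1)
            assert pred[i] == train.labels[d.argmin()]


class TestCrossValidate:
    def test_perfect_separation(self, rng):
        ds = blobs(rng, sep=12.0)
        mean, sd, scores = cross_validate(ds, ClassifierSpec(kind="knn"), folds=5)
        assert mean == 1.0 and len(scores) == 5

    def test_shuffled_labels_hit_chance_level(self, rng):
        ds = blobs(rng, n_per=150, sep=8.0, n_classes=4)
        shuffled = LabeledDataset(matrix=ds.matrix,
                                  labels=rng.permutation(ds.labels),
                                  feature_names=ds.feature_names)
        mean, _, _ = cross_validate(shuffled, ClassifierSpec(kind="knn"),
                                    folds=10, seed=0)
        assert mean == pytest.approx(0.25, abs=0.05)

    def test_same_seed_identical_scores(self, rng):
        ds = blobs(rng, sep=2.0)
        a = cross_validate(ds, ClassifierSpec(kind="knn"), folds=5, seed=4)[2]
        b = cross_validate(ds, ClassifierSpec(kind="knn"), folds=5, seed=4)[2]
        np.testing.assert_array_equal(a, b)

    def test_class_smaller_than_folds_rejected(self, rng):
        ds = LabeledDataset(matrix=rng.normal(size=(12, 3)),
                            labels=np.array(["a"] * 9 + ["b"] * 3),
                            feature_names=("x", "y", "z"))
        with pytest.raises(ValueError):
            cross_validate(ds, ClassifierSpec(kind="knn"), folds=5)


class TestGridSearch:
    def test_singleton_grid_returned(self, rng):
        ds = blobs(rng)
        spec = ClassifierSpec(kind="knn", knn_k=5)
        best, score = grid_search(ds, [spec], folds=4)
        assert best is spec

    def test_chosen_point_beats_all_others(self, rng):
        ds = blobs(rng, n_per=50, sep=1.5)
        grid = [ClassifierSpec(kind="knn", knn_k=k) for k in range(1, 16, 2)]
        best, best_score = grid_search(ds, grid, folds=5, seed=2)
        for spec in grid:
            score, _, _ = cross_validate(ds, spec, folds=5, seed=2)
            assert best_score >= score

    def test_empty_grid_rejected(self, rng):
        with pytest.raises(ValueError):
            grid_search(blobs(rng), [])


class TestEvaluate:
    def test_all_correct(self, rng):
        ds = blobs(rng, sep=12.0)
        model = train_classifier(ds, ClassifierSpec(kind="knn", knn_k=1))
        report = evaluate(model, ds, ClassifierSpec(kind="knn", knn_k=1))
        for rates in report.per_class.values():
            assert rates["TPR"] == 1.0 and rates["FPR"] == 0.0
            assert rates["precision"] == 1.0

    def test_two_class_hand_confusion(self):
        # build predictions realizing the confusion matrix [[8,2],[1,9]]
        y_true = np.array(["a"] * 10 + ["b"] * 10)
        y_pred = np.array(["a"] * 8 + ["b"] * 2 + ["a"] * 1 + ["b"] * 9)

        class Fixed:
            def predict(self, x):
                return y_pred

        ds = LabeledDataset(matrix=np.zeros((20, 2)), labels=y_true,
                            feature_names=("u", "v"))
        report = evaluate(Fixed(), ds)
        np.testing.assert_array_equal(report.confusion, [[8, 2], [1, 9]])
        assert report.per_class["a"]["TPR"] == pytest.approx(0.8)
        assert report.per_class["a"]["precision"] == pytest.approx(8 / 9)

    def test_metrics_match_brute_force_counting(self, rng):
        labels = np.array([f"c{i}" for i in rng.integers(0, 3, 120)])
        preds = np.array([f"c{i}" for i in rng.integers(0, 3, 120)])

        class Fixed:
            def predict(self, x):
                return preds

        ds = LabeledDataset(matrix=np.zeros((120, 2)), labels=labels,
                            feature_names=("u", "v"))
        report = evaluate(Fixed(), ds)
        assert report.confusion.sum() == 120
        for name in report.class_names:
            tp = np.sum((labels == name) & (preds == name))
            fn = np.sum((labels == name) & (preds != name))
            fp = np.sum((labels != name) & (preds == name))
            tn = np.sum((labels != name) & (preds != name))
            rates = report.per_class[name]
            assert rates["TPR"] == pytest.approx(tp / (tp + fn))
            assert rates["FPR"] == pytest.approx(fp / (fp + tn))
            assert rates["TPR"] + rates["FNR"] == pytest.approx(1.0)
            assert rates["TNR"] + rates["FPR"] == pytest.approx(1.0)

    def test_row_sums_conserve_test_counts(self, rng):
        ds = blobs(rng, n_per=40, sep=1.0, n_classes=3)
        model = train_classifier(ds, ClassifierSpec(kind="knn"))
        report = evaluate(model, ds, ClassifierSpec(kind="knn"))
        np.testing.assert_array_equal(report.confusion.sum(axis=1), [40, 40, 40])


class TestLabelNoiseDegradation:
    def test_accuracy_never_improves_with_label_noise(self, rng):
        means = {p: [] for p in (0.0, 0.2, 0.4)}
        for seed in range(5):
            r = np.random.default_rng(seed)
            ds = blobs(r, n_per=60, sep=3.0, n_classes=3)
            for p in means:
                labels = ds.labels.copy()
                flip = r.random(len(labels)) < p
                labels[flip] = r.choice(ds.class_names, flip.sum())
                noisy = LabeledDataset(matrix=ds.matrix, labels=labels,
                                       feature_names=ds.feature_names)
                m, _, _ = cross_validate(noisy, ClassifierSpec(kind="knn"),
                                         folds=5, seed=seed)
                means[p].append(m)
        avg = {p: np.mean(v) for p, v in means.items()}
        assert avg[0.0] >= avg[0.2] - 0.02 >= avg[0.4] - 0.04
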