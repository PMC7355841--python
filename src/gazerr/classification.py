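"""Classifier harness: which operating condition produced a gaze sample?

Three model families are supported — k-nearest neighbours (Euclidean
distance, default k = 3), a support vector machine with an RBF kernel
(default C = 10, gamma = 1.0), and a multilayer perceptron (ReLU, Adam,
learning rate 0.001).  KNN and SVM operate on the reduced 5-feature
statistical set by default; the MLP needs the full 20 features to avoid
underfitting.  Evaluation reports stratified cross-validation accuracy,
the confusion matrix, and one-vs-rest detection rates per class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from .features import LabeledDataset

__all__ = [
    "ClassifierSpec",
    "ClassificationReport",
    "make_estimator",
    "train_classifier",
    "cross_validate",
    "grid_search",
    "evaluate",
]


@dataclass(frozen=True)
class ClassifierSpec:
    """Hyperparameters for one classifier family.

    ``use_reduced`` controls whether the model sees the 5 statistical
    features (KNN/SVM default) or the full 20-feature set (MLP default).
    """

    kind: str = "knn"                       # knn | svm | mlp
    knn_k: int = 3
    svm_C: float = 10.0
    svm_gamma: float = 1.0
    mlp_layers: tuple[int, ...] = (50, 100, 50)
    mlp_alpha: float = 0.001
    learning_rate: float = 0.001
    max_iter: int = 400
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("knn", "svm", "mlp"):
            raise ValueError(f"unknown classifier kind {self.kind!r}")
        if self.knn_k < 1 or self.svm_C <= 0 or self.svm_gamma <= 0:
            raise ValueError("invalid hyperparameters")

    @property
    def use_reduced(self) -> bool:
        return self.kind in ("knn", "svm")


@dataclass
class ClassificationReport:
    cv_accuracy: float
    cv_sd: float
    confusion: np.ndarray
    class_names: list[str]
    per_class: dict[str, dict[str, float]]      # TPR/FPR/TNR/FNR/precision
    macro: dict[str, float]
    spec: ClassifierSpec | None = None

    def to_dict(self) -> dict:
        return {
            "cv_accuracy": self.cv_accuracy,
            "cv_sd": self.cv_sd,
            "class_names": self.class_names,
            "confusion": self.confusion.tolist(),
            "per_class": self.per_class,
            "macro": self.macro,
        }


def make_estimator(spec: ClassifierSpec):
    """Instantiate the scikit-learn estimator behind a spec."""
    if spec.kind == "knn":
        return KNeighborsClassifier(n_neighbors=spec.knn_k, metric="euclidean")
    if spec.kind == "svm":
        return SVC(kernel="rbf", C=spec.svm_C, gamma=spec.svm_gamma,
                   random_state=spec.seed)
    return MLPClassifier(
        hidden_layer_sizes=spec.mlp_layers, alpha=spec.mlp_alpha,
        activation="relu", solver="adam",
        learning_rate="constant", learning_rate_init=spec.learning_rate,
        max_iter=spec.max_iter, random_state=spec.seed,
    )


def _matrix_for(dataset: LabeledDataset, spec: ClassifierSpec) -> np.ndarray:
    if spec.use_reduced and dataset.matrix.shape[1] > 5:
        return dataset.reduced().matrix
    return dataset.matrix


def train_classifier(dataset: LabeledDataset, spec: ClassifierSpec):
    """Fit one classifier on a standardized labelled dataset."""
    if len(set(map(str, dataset.labels))) < 2:
        raise ValueError("need at least two classes")
    x = _matrix_for(dataset, spec)
    sds = x.std(axis=0)
    if np.any(np.abs(sds - 1.0) > 0.5):
        warnings.warn("features look unstandardized (column sd far from 1)")
    model = make_estimator(spec)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(x, dataset.labels)
    return model


def cross_validate(
    dataset: LabeledDataset, spec: ClassifierSpec, folds: int = 10, seed: int = 0
) -> tuple[float, float, np.ndarray]:
    """Stratified k-fold CV accuracy: (mean, sd, per-fold scores)."""
    if folds < 2:
        raise ValueError("need at least 2 folds")
    labels = dataset.labels
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < folds:
        raise ValueError("every class must have at least `folds` members")
    x = _matrix_for(dataset, spec)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    scores = []
    for tr, te in skf.split(x, labels):
        model = make_estimator(spec)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(x[tr], labels[tr])
        scores.append(model.score(x[te], labels[te]))
    scores = np.asarray(scores)
    return float(scores.mean()), float(scores.std()), scores


def grid_search(
    dataset: LabeledDataset,
    spec_grid: Sequence[ClassifierSpec],
    folds: int = 10,
    seed: int = 0,
) -> tuple[ClassifierSpec, float]:
    """Exhaustive CV over a spec grid; ties keep the earliest grid point."""
    if not spec_grid:
        raise ValueError("empty hyperparameter grid")
    best_spec, best_score = None, -np.inf
    for spec in spec_grid:
        score, _, _ = cross_validate(dataset, spec, folds=folds, seed=seed)
        if score > best_score:
            best_spec, best_score = spec, score
    return best_spec, best_score


def evaluate(
    model, test_set: LabeledDataset, spec: ClassifierSpec | None = None,
    cv_accuracy: float = float("nan"), cv_sd: float = float("nan"),
) -> ClassificationReport:
    """One-vs-rest detection rates and confusion matrix on a held-out set."""
    if test_set.n_samples == 0:
        raise ValueError("empty test set")
    x = _matrix_for(test_set, spec) if spec is not None else test_set.matrix
    pred = model.predict(x)
    classes = sorted(set(map(str, test_set.labels)) | set(map(str, pred)))
    conf = _sk_confusion(test_set.labels.astype(str), pred.astype(str),
                         labels=classes)
    per_class = {}
    for i, name in enumerate(classes):
        tp = conf[i, i]
        fn = conf[i].sum() - tp
        fp = conf[:, i].sum() - tp
        tn = conf.sum() - tp - fn - fp
        per_class[name] = {
            "TPR": tp / (tp + fn) if tp + fn else float("nan"),
            "FNR": fn / (tp + fn) if tp + fn else float("nan"),
            "FPR": fp / (fp + tn) if fp + tn else float("nan"),
            "TNR": tn / (fp + tn) if fp + tn else float("nan"),
            "precision": tp / (tp + fp) if tp + fp else float("nan"),
        }
    macro = {
        key: float(np.nanmean([d[key] for d in per_class.values()]))
        for key in ("TPR", "FPR", "TNR", "FNR", "precision")
    }
    return ClassificationReport(
        cv_accuracy=cv_accuracy, cv_sd=cv_sd, confusion=conf,
        class_names=classes, per_class=per_class, macro=macro, spec=spec,
    )
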