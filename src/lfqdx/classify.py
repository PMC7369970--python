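"""Classifier families over principal-component coordinates.

Four families are supported: k-nearest neighbors (Euclidean), L2
logistic regression, RBF-kernel support-vector machine, and a CART
decision tree. Multi-class handling for logistic and SVM is one-vs-rest.
Classifiers always consume PC-space coordinates, never raw LFQ values.

The kNN vote is implemented here rather than delegated, because the
deterministic tie rules are part of the contract: neighbors are ordered
by (distance, coordinate tuple, label) — a canonical order independent
of training-row order — and a vote tie goes to the class of the nearest
neighbor among the tied classes, so ties degrade gracefully toward 1-nn
behavior.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.multiclass import OneVsRestClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

FAMILIES = ("knn", "logistic", "svm_rbf", "tree")


@dataclass(frozen=True)
class ClassifierSpec:
    """A classifier family plus its hyperparameters.

    hyperparameters: knn -> n_neighbors; logistic -> C;
    svm_rbf -> C, gamma; tree -> max_depth.
    """

    family: str
    hyperparameters: tuple[tuple[str, float], ...] = field(default_factory=tuple)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r} (expected one of {FAMILIES})")
        hp = self.params
        if self.family == "knn":
            if int(hp.get("n_neighbors", 1)) < 1:
                raise ValueError("n_neighbors must be >= 1")
        if self.family == "logistic" and hp.get("C", 1.0) <= 0:
            raise ValueError("C must be > 0")
        if self.family == "svm_rbf":
            if hp.get("C", 1.0) <= 0 or hp.get("gamma", 0.5) <= 0:
                raise ValueError("C and gamma must be > 0")
        if self.family == "tree" and int(hp.get("max_depth", 3)) < 1:
            raise ValueError("max_depth must be >= 1")

    @staticmethod
    def make(family: str, seed: int = 0, **hyperparameters: float) -> "ClassifierSpec":
        return ClassifierSpec(
            family=family,
            hyperparameters=tuple(sorted(hyperparameters.items())),
            seed=seed,
        )

    @property
    def params(self) -> dict[str, float]:
        return dict(self.hyperparameters)

    def to_dict(self) -> dict:
        return {"family": self.family, "hyperparameters": self.params, "seed": self.seed}

    @staticmethod
    def from_dict(d: dict) -> "ClassifierSpec":
        return ClassifierSpec.make(d["family"], seed=int(d.get("seed", 0)), **d.get("hyperparameters", {}))


def _neighbor_order(train_coords: np.ndarray, train_labels: Sequence[str], query: np.ndarray) -> np.ndarray:
    """Training indices sorted by (distance, coordinate tuple, label)."""
    diffs = train_coords - query
    distances = np.sqrt(np.einsum("ij,ij->i", diffs, diffs))
    labels = np.asarray(train_labels, dtype=str)
    keys = [labels] + [train_coords[:, j] for j in range(train_coords.shape[1] - 1, -1, -1)] + [distances]
    return np.lexsort(tuple(keys))


def knn_predict(
    train_coords: np.ndarray,
    train_labels: Sequence[str],
    query: np.ndarray,
    n_neighbors: int,
) -> str:
    """Majority label among the ``n_neighbors`` closest training points.

    Deterministic: distance ties are broken by the canonical
    (coordinate, label) order, and vote ties go to the class of the
    nearest neighbor among the tied classes.
    """
    train_coords = np.asarray(train_coords, dtype=float)
    query = np.asarray(query, dtype=float).ravel()
    n = train_coords.shape[0]
    if n == 0:
        raise ValueError("empty training set")
    if n_neighbors > n:
        raise ValueError(f"n_neighbors={n_neighbors} exceeds training size {n}")
    order = _neighbor_order(train_coords, train_labels, query)
    top = order[:n_neighbors]
    votes = Counter(train_labels[i] for i in top)
    best = max(votes.values())
    tied = {label for label, c in votes.items() if c == best}
    if len(tied) == 1:
        return next(iter(tied))
    for i in top:  # nearest neighbor whose class is among the tied classes
        if train_labels[i] in tied:
            return train_labels[i]
    raise AssertionError("unreachable")


def _build_estimator(spec: ClassifierSpec):
    hp = spec.params
    if spec.family == "logistic":
        return OneVsRestClassifier(
            LogisticRegression(C=float(hp.get("C", 1.0)), max_iter=5000)
        )
    if spec.family == "svm_rbf":
        return OneVsRestClassifier(
            SVC(C=float(hp.get("C", 1.0)), kernel="rbf", gamma=float(hp.get("gamma", 0.5)))
        )
    if spec.family == "tree":
        return DecisionTreeClassifier(
            max_depth=int(hp.get("max_depth", 3)), random_state=spec.seed
        )
    raise ValueError(spec.family)


def fit_predict(
    spec: ClassifierSpec,
    train_coords: np.ndarray,
    train_labels: Sequence[str],
    queries: np.ndarray,
) -> list[str]:
    """Fit the specified classifier and predict labels for ``queries``.

    Identical inputs and seed give identical outputs for every family.
    """
    train_coords = np.asarray(train_coords, dtype=float)
    queries = np.atleast_2d(np.asarray(queries, dtype=float))
    labels = list(train_labels)
    if len(set(labels)) < 2:
        raise ValueError("training set must contain at least 2 classes")
    if spec.family == "knn":
        k = int(spec.params.get("n_neighbors", 1))
        return [knn_predict(train_coords, labels, q, k) for q in queries]
    est = _build_estimator(spec)
    est.fit(train_coords, np.asarray(labels, dtype=object))
    return [str(v) for v in est.predict(queries)]
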