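"""Quality assessment: leave-one-out cross-validation, hyperparameter
grid search, per-class error counts, and one-against-all class isolation.

With a few dozen subjects a held-out test split would be dominated by
which samples happen to land in it, so model quality is estimated by
leave-one-out cross-validation (LOOCV) over the whole dataset: n fits,
each trained on n-1 observations and scored on the held-out one. The
headline metric is plain mean accuracy (the class imbalance in the
target cohorts is mild), but per-class error counts are always reported
alongside.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .classify import ClassifierSpec, fit_predict

DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "knn": {"n_neighbors": list(range(1, 11))},
    "logistic": {"C": [0.01, 0.1, 1.0, 10.0, 100.0]},
    "svm_rbf": {"C": [0.1, 1.0, 10.0], "gamma": [0.01, 0.1, 0.5, 1.0]},
    "tree": {"max_depth": list(range(2, 9))},
}

REST_LABEL = "rest"


@dataclass
class CVReport:
    """LOOCV outcome: per-sample predictions, accuracy, per-class errors."""

    predictions: list[tuple[str, str]]
    mean_accuracy: float
    per_class_errors: dict[str, tuple[int, int]]  # class -> (errors, class size)
    chosen_spec: ClassifierSpec
    grid_results: dict[ClassifierSpec, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "predictions": [list(p) for p in self.predictions],
            "mean_accuracy": self.mean_accuracy,
            "per_class_errors": {c: list(v) for c, v in sorted(self.per_class_errors.items())},
            "chosen_spec": self.chosen_spec.to_dict(),
            "grid_results": [
                {"spec": s.to_dict(), "mean_accuracy": a}
                for s, a in sorted(self.grid_results.items(), key=lambda kv: _simplicity_key(kv[0]))
            ],
        }


@dataclass
class OneVsAllReport:
    """One-against-all isolation of a single class."""

    target_class: str
    accuracy: float
    false_positives: int
    false_negatives: int
    n: int
    spec: ClassifierSpec
    predictions: list[tuple[str, str]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "target_class": self.target_class,
            "accuracy": self.accuracy,
            "false_positives": self.false_positives,
            "false_negatives": self.false_negatives,
            "n": self.n,
            "spec": self.spec.to_dict(),
            "predictions": [list(p) for p in self.predictions],
        }


def _report_from_predictions(
    truths: Sequence[str], preds: Sequence[str], spec: ClassifierSpec
) -> CVReport:
    per_class: dict[str, tuple[int, int]] = {}
    for c in sorted(set(truths)):
        idx = [i for i, t in enumerate(truths) if t == c]
        errors = sum(1 for i in idx if preds[i] != c)
        per_class[c] = (errors, len(idx))
    total = len(truths)
    correct = sum(1 for t, p in zip(truths, preds) if t == p)
    return CVReport(
        predictions=list(zip(truths, preds)),
        mean_accuracy=correct / total,
        per_class_errors=per_class,
        chosen_spec=spec,
    )


def loocv(spec: ClassifierSpec, coords: np.ndarray, labels: Sequence[str]) -> CVReport:
    """Leave-one-out cross-validation: n fits, each on n-1 samples.

    Predictions are assembled in the input (canonical) sample order.
    """
    coords = np.asarray(coords, dtype=float)
    labels = [str(l) for l in labels]
    n = len(labels)
    if n < 2:
        raise ValueError("LOOCV requires at least 2 samples")
    if len(set(labels)) < 2:
        raise ValueError("LOOCV requires at least 2 classes")
    preds: list[str] = []
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        train_labels = [labels[j] for j in range(n) if j != i]
        classes = set(train_labels)
        if len(classes) < 2:
            if n == 2:
                raise ValueError(
                    f"holding out sample {i} leaves a single-class training set"
                )
            # a singleton class was held out: every family degenerates
            # to the constant prediction of the remaining class
            preds.append(next(iter(classes)))
            continue
        preds.append(fit_predict(spec, coords[mask], train_labels, coords[i])[0])
    return _report_from_predictions(labels, preds, spec)


def nearest_other_accuracy(coords: np.ndarray, labels: Sequence[str]) -> float:
    """Closed-form 1-nn LOOCV accuracy: the fraction of samples whose
    nearest other sample (canonical tie rules) shares their label."""
    from .classify import knn_predict

    coords = np.asarray(coords, dtype=float)
    labels = [str(l) for l in labels]
    n = len(labels)
    correct = 0
    for i in range(n):
        others = [j for j in range(n) if j != i]
        pred = knn_predict(coords[others], [labels[j] for j in others], coords[i], 1)
        correct += pred == labels[i]
    return correct / n


def _simplicity_key(spec: ClassifierSpec) -> tuple:
    """Sort key: simpler models first (fewer neighbors, smaller C,
    smaller gamma, shallower tree)."""
    hp = spec.params
    return (
        spec.family,
        hp.get("n_neighbors", 0),
        hp.get("C", 0.0),
        hp.get("gamma", 0.0),
        hp.get("max_depth", 0),
    )


def expand_grid(family: str, grid: Mapping[str, Sequence], seed: int = 0) -> list[ClassifierSpec]:
    if not grid:
        raise ValueError("grid must be non-empty")
    names = sorted(grid)
    specs = []
    for combo in itertools.product(*(grid[name] for name in names)):
        specs.append(ClassifierSpec.make(family, seed=seed, **dict(zip(names, combo))))
    return specs


def grid_search(
    family: str,
    grid: Mapping[str, Sequence] | None,
    coords: np.ndarray,
    labels: Sequence[str],
    seed: int = 0,
) -> CVReport:
    """LOOCV mean accuracy for every grid point; the returned report is
    the best point's, with ties broken toward the simpler model."""
    if grid is None:
        grid = DEFAULT_GRIDS[family]
    specs = expand_grid(family, grid, seed=seed)
    results: dict[ClassifierSpec, float] = {}
    reports: dict[ClassifierSpec, CVReport] = {}
    for spec in specs:
        report = loocv(spec, coords, labels)
        results[spec] = report.mean_accuracy
        reports[spec] = report
    best_acc = max(results.values())
    chosen = min(
        (s for s, a in results.items() if a == best_acc), key=_simplicity_key
    )
    final = reports[chosen]
    final.grid_results = results
    return final


def one_vs_all(
    target: str,
    spec: ClassifierSpec,
    coords: np.ndarray,
    labels: Sequence[str],
    method: str = "loocv",
) -> OneVsAllReport:
    """Collapse labels to {target, rest} and evaluate the binary task.

    ``method='loocv'`` (default) scores by leave-one-out; the
    ``'resubstitution'`` variant fits on the full set and scores on it.
    """
    labels = [str(l) for l in labels]
    if target not in labels:
        raise ValueError(f"target class {target!r} absent from labels")
    collapsed = [l if l == target else REST_LABEL for l in labels]
    coords = np.asarray(coords, dtype=float)
    if method == "loocv":
        preds = [p for _, p in loocv(spec, coords, collapsed).predictions]
    elif method == "resubstitution":
        preds = fit_predict(spec, coords, collapsed, coords)
    else:
        raise ValueError(f"unknown method {method!r}")
    fp = sum(1 for t, p in zip(collapsed, preds) if t == REST_LABEL and p == target)
    fn = sum(1 for t, p in zip(collapsed, preds) if t == target and p == REST_LABEL)
    n = len(collapsed)
    return OneVsAllReport(
        target_class=target,
        accuracy=1.0 - (fp + fn) / n,
        false_positives=fp,
        false_negatives=fn,
        n=n,
        spec=spec,
        predictions=list(zip(collapsed, preds)),
    )
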