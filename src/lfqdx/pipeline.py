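"""End-to-end experiment drivers and the two-stage diagnosis workflow.

An experiment binds one analysis of the study design to a single
configuration: choose a fluid and a set of disease groups, run the
preprocessing chain (quality filter -> max-normalize -> PCA truncation
-> replicate consistency check), optionally collapse groups (e.g. all
patient groups into "CKD"), and evaluate a classifier by LOOCV grid
search or a one-against-all isolation.

``diagnose_two_stage`` chains two persisted models: a urine
one-against-all model first screens for hypertensive nephropathy (H);
if the urine proteome does not look hypertensive, a plasma model
separates diabetic nephropathy (D) from glomerulonephritis (G).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .classify import ClassifierSpec, knn_predict, fit_predict
from .evaluate import CVReport, OneVsAllReport, grid_search, loocv, one_vs_all
from .io_lfq import LFQMatrix, SampleMeta, check_metadata_covers
from .preprocess import (
    ConsistencyResult,
    FilterReport,
    PCAEmbedding,
    consistency_check,
    max_normalize,
    pca_truncate,
    quality_filter,
    row_maxima,
)


@dataclass
class ExperimentConfig:
    """One experiment: subset, preprocessing thresholds, evaluation mode."""

    fluid: str = "plasma"
    groups_included: tuple[str, ...] = ("D", "G", "H", "N")
    collapse: dict[str, str] = field(default_factory=dict)
    variance_threshold: float = 0.70
    min_samples_per_protein: int = 5
    min_proteins_per_sample: int = 50
    family: str = "knn"
    grid: dict[str, list] | None = None
    classifier_spec: ClassifierSpec | None = None
    one_vs_all_target: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.groups_included:
            raise ValueError("groups_included must be non-empty")
        if not 0 < self.variance_threshold <= 1:
            raise ValueError("variance_threshold must lie in (0, 1]")
        if self.min_samples_per_protein < 0 or self.min_proteins_per_sample < 0:
            raise ValueError("filter thresholds must be >= 0")

    @staticmethod
    def from_dict(d: Mapping) -> "ExperimentConfig":
        d = dict(d)
        if "groups_included" in d:
            d["groups_included"] = tuple(d["groups_included"])
        if d.get("classifier_spec") is not None:
            d["classifier_spec"] = ClassifierSpec.from_dict(d["classifier_spec"])
        return ExperimentConfig(**d)


@dataclass
class ExperimentResult:
    filter_report: FilterReport
    embedding: PCAEmbedding
    consistency: ConsistencyResult
    report: CVReport | OneVsAllReport

    def stage_counts(self) -> dict:
        """Dataset-reduction bookkeeping across the pipeline stages."""
        return {
            "n_proteins_before": self.filter_report.n_proteins_before,
            "n_proteins_after_filter": self.filter_report.n_proteins_after,
            "n_samples_before": self.filter_report.n_samples_before,
            "n_samples_after_filter": self.filter_report.n_samples_after,
            "n_principal_components": self.embedding.k,
            "cumulative_variance": self.embedding.cumulative_variance,
            "n_samples_after_consistency": len(self.consistency.consistent_pairs),
        }

    def to_json(self) -> str:
        payload = {
            "stage_counts": self.stage_counts(),
            "filter_report": self.filter_report.to_dict(),
            "report": self.report.to_dict(),
            "rejected_samples": list(self.consistency.rejected_samples),
        }
        return json.dumps(payload, sort_keys=True, indent=2)


def _subset(
    matrix: LFQMatrix, meta: Sequence[SampleMeta], config: ExperimentConfig
) -> tuple[LFQMatrix, list[SampleMeta]]:
    lookup = check_metadata_covers(matrix, meta)
    wanted = [
        s
        for s in matrix.sample_ids
        if lookup[s].fluid == config.fluid and lookup[s].group in config.groups_included
    ]
    if not wanted:
        raise ValueError(
            f"no samples match fluid={config.fluid!r} groups={config.groups_included}"
        )
    present = {lookup[s].group for s in wanted}
    missing = set(config.groups_included) - present
    if missing:
        raise ValueError(f"requested groups absent from data: {sorted(missing)}")
    return matrix.subset_samples(wanted), [lookup[s] for s in wanted]


def run_experiment(
    config: ExperimentConfig, matrix: LFQMatrix, meta: Sequence[SampleMeta]
) -> ExperimentResult:
    """Run one experiment end to end.

    Order is fixed: subset -> quality_filter -> max_normalize ->
    pca_truncate -> consistency_check -> label collapse -> evaluation.
    """
    sub_matrix, sub_meta = _subset(matrix, meta, config)
    filtered, filter_report = quality_filter(
        sub_matrix, config.min_samples_per_protein, config.min_proteins_per_sample
    )
    # drop pairs broken by the sample filter: consistency needs both replicates
    kept = set(filtered.sample_ids)
    pair_count: dict[str, int] = {}
    for m in sub_meta:
        if m.sample_id in kept:
            pair_count[m.pair_id] = pair_count.get(m.pair_id, 0) + 1
    complete = [
        m.sample_id for m in sub_meta if m.sample_id in kept and pair_count[m.pair_id] == 2
    ]
    filtered = filtered.subset_samples(complete)
    normalized = max_normalize(filtered)
    embedding = pca_truncate(normalized, config.variance_threshold)
    consistency = consistency_check(embedding, sub_meta)

    labels = [
        config.collapse.get(m.group, m.group) for m in consistency.averaged_meta
    ]
    coords = consistency.averaged_coordinates
    if config.one_vs_all_target is not None:
        spec = config.classifier_spec or ClassifierSpec.make(
            "knn", seed=config.seed, n_neighbors=1
        )
        report: CVReport | OneVsAllReport = one_vs_all(
            config.one_vs_all_target, spec, coords, labels
        )
    elif config.classifier_spec is not None:
        report = loocv(config.classifier_spec, coords, labels)
    else:
        report = grid_search(config.family, config.grid, coords, labels, seed=config.seed)
    return ExperimentResult(filter_report, embedding, consistency, report)


@dataclass
class TrainedModel:
    """Everything needed to project and classify a new sample
    deterministically: the retained protein panel, the per-protein
    maxima of the training stage, the PCA mean and loadings, the
    training PC coordinates and labels, and the classifier spec."""

    protein_panel: list[str]
    panel_maxima: np.ndarray
    pca_mean: np.ndarray
    loadings: np.ndarray
    train_coords: np.ndarray
    train_labels: list[str]
    spec: ClassifierSpec
    one_vs_all_target: str | None = None
    min_overlap: int = 10

    def project(self, protein_ids: Sequence[str], intensities: Sequence[float]) -> np.ndarray:
        """Map a raw sample into the trained PC space.

        Panel proteins absent from the sample are treated as intensity 0
        (not detected); sample proteins outside the panel are ignored.
        Raises if the overlap falls below ``min_overlap`` proteins.
        """
        index = {p: i for i, p in enumerate(self.protein_panel)}
        vector = np.zeros(len(self.protein_panel))
        overlap = 0
        for pid, value in zip(protein_ids, intensities):
            i = index.get(str(pid))
            if i is not None:
                overlap += 1
                vector[i] = float(value)
        if overlap < self.min_overlap:
            raise ValueError(
                f"sample shares only {overlap} proteins with the trained panel "
                f"(minimum {self.min_overlap})"
            )
        normalized = vector / self.panel_maxima
        return (normalized - self.pca_mean) @ self.loadings.T

    def predict(self, protein_ids: Sequence[str], intensities: Sequence[float]) -> str:
        coords = self.project(protein_ids, intensities)
        if self.spec.family == "knn":
            k = int(self.spec.params.get("n_neighbors", 1))
            return knn_predict(self.train_coords, self.train_labels, coords, k)
        return fit_predict(self.spec, self.train_coords, self.train_labels, coords)[0]

    def to_dict(self) -> dict:
        return {
            "protein_panel": list(self.protein_panel),
            "panel_maxima": self.panel_maxima.tolist(),
            "pca_mean": self.pca_mean.tolist(),
            "loadings": self.loadings.tolist(),
            "train_coords": self.train_coords.tolist(),
            "train_labels": list(self.train_labels),
            "spec": self.spec.to_dict(),
            "one_vs_all_target": self.one_vs_all_target,
            "min_overlap": self.min_overlap,
        }

    @staticmethod
    def from_dict(d: Mapping) -> "TrainedModel":
        return TrainedModel(
            protein_panel=list(d["protein_panel"]),
            panel_maxima=np.asarray(d["panel_maxima"], dtype=float),
            pca_mean=np.asarray(d["pca_mean"], dtype=float),
            loadings=np.asarray(d["loadings"], dtype=float),
            train_coords=np.asarray(d["train_coords"], dtype=float),
            train_labels=[str(l) for l in d["train_labels"]],
            spec=ClassifierSpec.from_dict(d["spec"]),
            one_vs_all_target=d.get("one_vs_all_target"),
            min_overlap=int(d.get("min_overlap", 10)),
        )

    def save(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, sort_keys=True)

    @staticmethod
    def load(path: str) -> "TrainedModel":
        with open(path, encoding="utf-8") as fh:
            return TrainedModel.from_dict(json.load(fh))


def fit_model(
    config: ExperimentConfig,
    matrix: LFQMatrix,
    meta: Sequence[SampleMeta],
    spec: ClassifierSpec | None = None,
) -> tuple[TrainedModel, ExperimentResult]:
    """Run an experiment and persist its artifacts as a TrainedModel.

    The stored maxima and loadings come from the training stage, so a
    training sample projected as if new reproduces its training
    coordinates exactly.
    """
    result = run_experiment(config, matrix, meta)
    sub_matrix, _ = _subset(matrix, meta, config)
    filtered = sub_matrix.subset_samples(result.embedding.sample_ids)
    filtered = LFQMatrix(
        list(result.embedding.protein_ids),
        list(filtered.sample_ids),
        filtered.to_frame().loc[result.embedding.protein_ids].to_numpy(),
    )
    maxima = row_maxima(filtered)
    chosen = spec or (
        result.report.chosen_spec
        if isinstance(result.report, CVReport)
        else result.report.spec
    )
    labels = [
        config.collapse.get(m.group, m.group) for m in result.consistency.averaged_meta
    ]
    if config.one_vs_all_target is not None:
        labels = [
            l if l == config.one_vs_all_target else "rest" for l in labels
        ]
    model = TrainedModel(
        protein_panel=list(result.embedding.protein_ids),
        panel_maxima=maxima,
        pca_mean=result.embedding.mean,
        loadings=result.embedding.loadings,
        train_coords=result.consistency.averaged_coordinates,
        train_labels=labels,
        spec=chosen,
        one_vs_all_target=config.one_vs_all_target,
    )
    return model, result


def diagnose_two_stage(
    urine_model: TrainedModel,
    plasma_model: TrainedModel,
    urine_sample: tuple[Sequence[str], Sequence[float]],
    plasma_sample: tuple[Sequence[str], Sequence[float]],
) -> str:
    """Two-stage differential diagnosis of chronic kidney disease.

    Stage 1 screens the urine proteome with a one-against-all model for
    hypertensive nephropathy; a positive call short-circuits to ``H``.
    Otherwise stage 2 separates diabetic nephropathy from
    glomerulonephritis on the plasma proteome.
    """
    if urine_model.one_vs_all_target is None:
        raise ValueError("urine model must be a one-vs-all model")
    stage1 = urine_model.predict(*urine_sample)
    if stage1 == urine_model.one_vs_all_target:
        return urine_model.one_vs_all_target
    return plasma_model.predict(*plasma_sample)
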