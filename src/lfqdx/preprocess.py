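"""Preprocessing chain: quality filtration, max-normalization, PCA
truncation at a cumulative-variance threshold, and the mutual-nearest-
neighbor technical-replicate consistency check.

The chain is applied in a fixed order to each analysis subset:

1. ``quality_filter`` — drop proteins detected in too few samples, then
   samples with too few detected proteins.
2. ``max_normalize`` — divide every protein row by its maximum across
   the retained samples, mapping intensities into [0, 1].
3. ``pca_truncate`` — project samples onto the smallest number of
   principal components whose cumulative explained variance reaches a
   threshold (default 70%).
4. ``consistency_check`` — keep only A/B replicate pairs that are each
   other's nearest Euclidean neighbors in PC space, and average each
   retained pair into a single observation.

Note that the PCA and the consistency check are fitted on the full
dataset of an experiment before any cross-validation, reproducing the
original procedure; see the methods documentation for the resulting
information-leakage caveat.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.distance import squareform, pdist
from sklearn.decomposition import PCA

from .io_lfq import LFQMatrix, SampleMeta


@dataclass
class FilterReport:
    """Bookkeeping of the two-step quality filtration."""

    n_proteins_before: int
    n_proteins_after: int
    n_samples_before: int
    n_samples_after: int
    dropped_proteins: list[str] = field(default_factory=list)
    dropped_samples: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_proteins_before": self.n_proteins_before,
            "n_proteins_after": self.n_proteins_after,
            "n_samples_before": self.n_samples_before,
            "n_samples_after": self.n_samples_after,
            "dropped_proteins": list(self.dropped_proteins),
            "dropped_samples": list(self.dropped_samples),
        }


@dataclass
class PCAEmbedding:
    """Samples projected onto the leading principal components.

    ``coordinates`` is samples x k; ``loadings`` is k x proteins;
    ``mean`` is the per-protein centering vector. ``loadings`` and
    ``mean`` suffice to project new samples into the trained space.
    """

    sample_ids: list[str]
    coordinates: np.ndarray
    explained_variance_ratio: np.ndarray
    k: int
    cumulative_variance: float
    loadings: np.ndarray
    mean: np.ndarray
    protein_ids: list[str]

    def project(self, normalized_rows: np.ndarray) -> np.ndarray:
        """Project samples x proteins normalized data into PC space."""
        return (np.atleast_2d(normalized_rows) - self.mean) @ self.loadings.T


@dataclass
class ConsistencyResult:
    """Outcome of the mutual-nearest-neighbor replicate check."""

    consistent_pairs: list[str]
    rejected_samples: list[str]
    averaged_coordinates: np.ndarray
    averaged_meta: list[SampleMeta]


class EmptyResultError(ValueError):
    """All proteins or all samples were removed by filtration."""


def quality_filter(
    matrix: LFQMatrix,
    min_samples_per_protein: int = 5,
    min_proteins_per_sample: int = 50,
) -> tuple[LFQMatrix, FilterReport]:
    """Two-step quality filtration; "detected" means intensity > 0.

    Proteins detected in fewer than ``min_samples_per_protein`` samples
    are removed first; then samples in which fewer than
    ``min_proteins_per_sample`` proteins remain detected (counted on the
    protein-filtered matrix) are removed. Each step is applied once, in
    this order, without iteration.
    """
    detected = matrix.intensities > 0
    keep_proteins = detected.sum(axis=1) >= min_samples_per_protein
    dropped_proteins = [p for p, k in zip(matrix.protein_ids, keep_proteins) if not k]
    reduced = detected[keep_proteins, :]
    keep_samples = reduced.sum(axis=0) >= min_proteins_per_sample
    dropped_samples = [s for s, k in zip(matrix.sample_ids, keep_samples) if not k]

    filtered = LFQMatrix(
        [p for p, k in zip(matrix.protein_ids, keep_proteins) if k],
        [s for s, k in zip(matrix.sample_ids, keep_samples) if k],
        matrix.intensities[np.ix_(keep_proteins, keep_samples)],
    )
    report = FilterReport(
        n_proteins_before=matrix.n_proteins,
        n_proteins_after=filtered.n_proteins,
        n_samples_before=matrix.n_samples,
        n_samples_after=filtered.n_samples,
        dropped_proteins=dropped_proteins,
        dropped_samples=dropped_samples,
    )
    if filtered.n_proteins == 0 or filtered.n_samples == 0:
        raise EmptyResultError(
            f"quality filter removed everything "
            f"({report.n_proteins_after} proteins, {report.n_samples_after} samples left)"
        )
    return filtered, report


def max_normalize(matrix: LFQMatrix) -> LFQMatrix:
    """Divide each protein row by its maximum across samples.

    Maps every value into [0, 1]; zeros (not detected) stay zero and
    each row attains 1 at its maximum. Idempotent.
    """
    maxima = matrix.intensities.max(axis=1)
    if np.any(maxima <= 0):
        bad = [p for p, m in zip(matrix.protein_ids, maxima) if m <= 0]
        raise ValueError(f"all-zero protein rows (should have been filtered): {bad[:5]}")
    return LFQMatrix(
        list(matrix.protein_ids),
        list(matrix.sample_ids),
        matrix.intensities / maxima[:, None],
    )


def row_maxima(matrix: LFQMatrix) -> np.ndarray:
    """Per-protein maxima used by max_normalize (for model persistence)."""
    return matrix.intensities.max(axis=1)


def pca_truncate(matrix: LFQMatrix, variance_threshold: float = 0.70) -> PCAEmbedding:
    """PCA of samples over protein features, truncated at a cumulative
    explained-variance threshold.

    Samples are observations and proteins features; features are
    mean-centered (no variance scaling: inputs are already on [0, 1]).
    k is the smallest component count whose cumulative explained
    variance reaches ``variance_threshold``, capped at the matrix rank.
    Component signs are fixed so that each loading vector's
    largest-magnitude entry is positive.
    """
    if matrix.n_samples < 2:
        raise ValueError("PCA requires at least 2 samples")
    if not 0 < variance_threshold <= 1:
        raise ValueError("variance_threshold must lie in (0, 1]")
    X = matrix.intensities.T  # samples x proteins
    pca = PCA(n_components=None, svd_solver="full")
    scores = pca.fit_transform(X)
    ratios = pca.explained_variance_ratio_
    # numerically-zero components do not count toward the rank
    rank = int(np.sum(pca.explained_variance_ > 1e-12 * max(1.0, pca.explained_variance_[0])))
    rank = max(rank, 1)
    cumulative = np.cumsum(ratios[:rank])
    reaching = np.nonzero(cumulative >= variance_threshold)[0]
    k = int(reaching[0] + 1) if reaching.size else rank

    loadings = pca.components_[:k].copy()
    coords = scores[:, :k].copy()
    for j in range(k):
        i_max = int(np.argmax(np.abs(loadings[j])))
        if loadings[j, i_max] < 0:
            loadings[j] *= -1.0
            coords[:, j] *= -1.0
    return PCAEmbedding(
        sample_ids=list(matrix.sample_ids),
        coordinates=coords,
        explained_variance_ratio=ratios[:k].copy(),
        k=k,
        cumulative_variance=float(np.sum(ratios[:k])),
        loadings=loadings,
        mean=pca.mean_.copy(),
        protein_ids=list(matrix.protein_ids),
    )


def _nearest_neighbors(coords: np.ndarray) -> np.ndarray:
    """Index of each sample's nearest Euclidean neighbor, self excluded.

    Distance ties are broken toward the lowest sample index, so the
    result is deterministic even with duplicate coordinates.
    """
    n = coords.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples for nearest neighbors")
    dist = squareform(pdist(coords, metric="euclidean"))
    np.fill_diagonal(dist, np.inf)
    return dist.argmin(axis=1)  # argmin returns the first (lowest index) minimum


def consistency_check(
    embedding: PCAEmbedding, meta: Sequence[SampleMeta]
) -> ConsistencyResult:
    """Mutual-nearest-neighbor check of A/B technical-replicate pairs.

    A pair is consistent iff replicate A's nearest Euclidean neighbor
    among all embedded samples is its paired B and vice versa.
    Consistent pairs are averaged component-wise into one observation
    inheriting the pair's patient, group and fluid; all samples of
    inconsistent pairs are rejected.
    """
    lookup = {m.sample_id: m for m in meta}
    missing = [s for s in embedding.sample_ids if s not in lookup]
    if missing:
        raise ValueError(f"embedded samples without metadata: {missing[:5]}")
    index_of = {s: i for i, s in enumerate(embedding.sample_ids)}

    pairs: dict[str, dict[str, str]] = {}
    for s in embedding.sample_ids:
        m = lookup[s]
        pairs.setdefault(m.pair_id, {})[m.replicate_tag] = s
    for pair_id, members in pairs.items():
        if "A" not in members or "B" not in members:
            raise ValueError(f"pair {pair_id!r} is incomplete in the embedding")

    nn = _nearest_neighbors(embedding.coordinates)

    consistent: list[str] = []
    rejected: list[str] = []
    averaged_rows: list[np.ndarray] = []
    averaged_meta: list[SampleMeta] = []
    for pair_id, members in pairs.items():
        a, b = members["A"], members["B"]
        ia, ib = index_of[a], index_of[b]
        if nn[ia] == ib and nn[ib] == ia:
            consistent.append(pair_id)
            averaged_rows.append(
                (embedding.coordinates[ia] + embedding.coordinates[ib]) / 2.0
            )
            m = lookup[a]
            averaged_meta.append(
                SampleMeta(
                    sample_id=pair_id,
                    patient_id=m.patient_id,
                    group=m.group,
                    replicate_tag="A",
                    fluid=m.fluid,
                    pair_id=pair_id,
                )
            )
        else:
            rejected.extend([a, b])
    coords = (
        np.vstack(averaged_rows) if averaged_rows else np.zeros((0, embedding.k))
    )
    return ConsistencyResult(
        consistent_pairs=consistent,
        rejected_samples=rejected,
        averaged_coordinates=coords,
        averaged_meta=averaged_meta,
    )
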