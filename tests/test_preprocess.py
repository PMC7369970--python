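"""Preprocessing chain: filtration, normalization, PCA truncation,
and the mutual-nearest-neighbor replicate consistency check."""

import numpy as np
import pytest

from lfqdx import (
    LFQMatrix,
    SampleMeta,
    consistency_check,
    max_normalize,
    pca_truncate,
    quality_filter,
)
from lfqdx.preprocess import EmptyResultError, PCAEmbedding


def _matrix(values, prefix_p="r", prefix_s="c"):
    values = np.asarray(values, dtype=float)
    return LFQMatrix(
        [f"{prefix_p}{i+1}" for i in range(values.shape[0])],
        [f"{prefix_s}{j+1}" for j in range(values.shape[1])],
        values,
    )


class TestQualityFilter:
    def test_toy_matrix_filtered_in_two_ordered_steps(self):
        # r1 detected in 2 < 3 samples -> dropped; afterwards c4 retains
        # only 1 < 2 detected proteins -> dropped; result is 5 x 3.
        detected = np.array(
            [
                [1, 0, 0, 1],  # r1: 2 detections
                [1, 1, 1, 0],
                [1, 1, 1, 0],
                [1, 1, 0, 1],  # r4: keeps c4 alive until r1 is gone
                [1, 1, 1, 0],
                [1, 1, 1, 0],
            ],
            dtype=float,
        )
        filtered, report = quality_filter(
            _matrix(detected), min_samples_per_protein=3, min_proteins_per_sample=2
        )
        assert (filtered.n_proteins, filtered.n_samples) == (5, 3)
        assert report.dropped_proteins == ["r1"]
        assert report.dropped_samples == ["c4"]
        assert report.n_proteins_before == 6 and report.n_samples_before == 4

    def test_thresholds_one_one_identity_on_positive_matrix(self):
        m = _matrix(np.ones((3, 4)))
        filtered, report = quality_filter(m, 1, 1)
        assert filtered == m
        assert not report.dropped_proteins and not report.dropped_samples

    def test_filter_idempotent(self):
        rng = np.random.default_rng(0)
        values = rng.uniform(0, 1, (30, 12)) * (rng.random((30, 12)) < 0.6)
        once, _ = quality_filter(_matrix(values), 4, 5)
        twice, report = quality_filter(once, 4, 5)
        assert twice == once
        assert not report.dropped_proteins and not report.dropped_samples

    def test_all_filtered_raises(self):
        with pytest.raises(EmptyResultError):
            quality_filter(_matrix(np.eye(3)), min_samples_per_protein=2)


class TestMaxNormalize:
    def test_row_divided_by_its_maximum(self):
        out = max_normalize(_matrix([[2, 4, 8]]))
        assert np.allclose(out.intensities, [[0.25, 0.5, 1.0]])

    def test_zeros_preserved(self):
        out = max_normalize(_matrix([[0, 5]]))
        assert np.array_equal(out.intensities, [[0.0, 1.0]])

    def test_idempotent_range_and_row_max(self, rng):
        values = rng.uniform(0, 100, (20, 8))
        once = max_normalize(_matrix(values))
        twice = max_normalize(once)
        assert np.array_equal(once.intensities, twice.intensities)
        assert once.intensities.min() >= 0 and once.intensities.max() <= 1
        assert np.allclose(once.intensities.max(axis=1), 1.0)

    def test_all_zero_row_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            max_normalize(_matrix([[0, 0], [1, 2]]))


class TestPCATruncate:
    def test_collinear_data_is_rank_one(self):
        x = np.array([0.0, 0.2, 0.4, 0.9])
        m = _matrix(np.vstack([x, 2 * x]))  # 2 proteins, 4 samples, y = 2x
        emb = pca_truncate(m, variance_threshold=0.70)
        assert emb.k == 1
        assert np.allclose(emb.explained_variance_ratio, [1.0])
        assert emb.cumulative_variance == pytest.approx(1.0)

    def test_scores_reconstruct_centered_data_at_full_rank(self, rng):
        values = rng.uniform(0, 1, (6, 10))  # 6 proteins x 10 samples
        emb = pca_truncate(_matrix(values), variance_threshold=1.0)
        X = values.T
        centered = X - X.mean(axis=0)
        assert np.allclose(emb.coordinates @ emb.loadings, centered, atol=1e-9)

    def test_k_matches_brute_force_eigendecomposition(self, rng):
        # independent oracle: eigenvalues of the sample covariance matrix
        values = rng.uniform(0, 1, (50, 20))  # 50 proteins x 20 samples
        threshold = 0.70
        emb = pca_truncate(_matrix(values), variance_threshold=threshold)
        X = values.T
        centered = X - X.mean(axis=0)
        cov = centered.T @ centered / (X.shape[0] - 1)
        eigvals = np.sort(np.linalg.eigvalsh(cov))[::-1]
        eigvals = np.clip(eigvals, 0, None)
        ratios = eigvals / eigvals.sum()
        k_oracle = int(np.searchsorted(np.cumsum(ratios), threshold) + 1)
        assert emb.k == k_oracle
        assert np.allclose(emb.explained_variance_ratio, ratios[: emb.k], atol=1e-9)

    def test_ratios_non_increasing_and_threshold_minimal(self, rng):
        values = rng.uniform(0, 1, (40, 15))
        emb = pca_truncate(_matrix(values), variance_threshold=0.6)
        r = emb.explained_variance_ratio
        assert np.all(np.diff(r) <= 1e-12)
        assert emb.cumulative_variance >= 0.6
        assert emb.cumulative_variance - r[-1] < 0.6  # k is minimal

    def test_loading_signs_canonical(self, rng):
        values = rng.uniform(0, 1, (10, 12))
        emb = pca_truncate(_matrix(values), variance_threshold=0.9)
        for row in emb.loadings:
            assert row[np.argmax(np.abs(row))] > 0

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError, match="at least 2 samples"):
            pca_truncate(_matrix([[1.0], [2.0]]))


def _embedding(coords, sample_ids):
    coords = np.asarray(coords, dtype=float)
    k = coords.shape[1]
    return PCAEmbedding(
        sample_ids=list(sample_ids),
        coordinates=coords,
        explained_variance_ratio=np.full(k, 1.0 / k),
        k=k,
        cumulative_variance=1.0,
        loadings=np.zeros((k, 1)),
        mean=np.zeros(1),
        protein_ids=["p1"],
    )


def _pair_meta(pair_ids, fluid="plasma", groups=None):
    meta = []
    for i, pid in enumerate(pair_ids):
        group = (groups or {}).get(pid, "D")
        for tag in ("A", "B"):
            meta.append(
                SampleMeta(f"{pid}{tag}", f"pat{i+1}", group, tag, fluid, pid)
            )
    return meta


class TestConsistencyCheck:
    def test_well_separated_pairs_averaged_at_midpoint(self):
        coords = [(0, 0), (0.1, 0), (5, 5), (5, 5.1)]
        emb = _embedding(coords, ["pr1A", "pr1B", "pr2A", "pr2B"])
        res = consistency_check(emb, _pair_meta(["pr1", "pr2"]))
        assert res.consistent_pairs == ["pr1", "pr2"]
        assert res.rejected_samples == []
        assert np.allclose(res.averaged_coordinates, [(0.05, 0), (5, 5.05)])

    def test_pair_whose_replicate_strays_is_rejected(self):
        # hand-computed distance table: A3 lies closer to B1 (0.2) than
        # to its own partner B3 (far away); pairs 1 and 2 stay mutual.
        coords = {
            "pr1A": (0.0, 0.0),
            "pr1B": (0.1, 0.0),
            "pr2A": (5.0, 5.0),
            "pr2B": (5.0, 5.1),
            "pr3A": (0.3, 0.0),
            "pr3B": (10.0, 10.0),
        }
        emb = _embedding(list(coords.values()), list(coords))
        res = consistency_check(emb, _pair_meta(["pr1", "pr2", "pr3"]))
        assert res.consistent_pairs == ["pr1", "pr2"]
        assert sorted(res.rejected_samples) == ["pr3A", "pr3B"]
        assert res.averaged_coordinates.shape == (2, 2)

    def test_consistency_symmetric_in_replicate_orientation(self):
        coords = [(0, 0), (0.1, 0), (5, 5), (5, 5.1)]
        emb_ab = _embedding(coords, ["pr1A", "pr1B", "pr2A", "pr2B"])
        emb_ba = _embedding(
            [coords[1], coords[0], coords[3], coords[2]],
            ["pr1B", "pr1A", "pr2B", "pr2A"],
        )
        meta = _pair_meta(["pr1", "pr2"])
        res_ab = consistency_check(emb_ab, meta)
        res_ba = consistency_check(emb_ba, meta)
        assert res_ab.consistent_pairs == res_ba.consistent_pairs
        assert np.allclose(res_ab.averaged_coordinates, res_ba.averaged_coordinates)

    def test_averaged_meta_inherits_group_and_patient(self):
        emb = _embedding([(0, 0), (0.1, 0)], ["pr1A", "pr1B"])
        # lone pair: each replicate's only possible neighbor is its partner
        res = consistency_check(emb, _pair_meta(["pr1"], groups={"pr1": "G"}))
        assert len(res.averaged_meta) == 1
        avg = res.averaged_meta[0]
        assert avg.group == "G" and avg.patient_id == "pat1" and avg.pair_id == "pr1"

    def test_missing_partner_raises(self):
        emb = _embedding([(0, 0)], ["pr1A"])
        meta = [SampleMeta("pr1A", "pat1", "D", "A", "plasma", "pr1")]
        with pytest.raises(ValueError, match="incomplete"):
            consistency_check(emb, meta)

    def test_zero_noise_synthetic_pairs_all_consistent(self, small_cohort):
        from lfqdx import CohortSpec, generate_cohort

        spec, _, _ = small_cohort
        from dataclasses import replace

        m, meta = generate_cohort(replace(spec, replicate_cv=0.0, detection_rate=1.0))
        filtered, _ = quality_filter(m, 1, 1)
        emb = pca_truncate(max_normalize(filtered), 0.9)
        res = consistency_check(emb, meta)
        assert res.rejected_samples == []
        assert len(res.consistent_pairs) == len(meta) // 2
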