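"""Synthetic LFQ cohorts with the statistical structure the pipeline assumes.

The generator emulates a clinical label-free proteomics study of chronic
kidney disease: four subject groups (diabetic nephropathy D,
glomerulonephritis G, hypertensive nephropathy H, healthy N), each
patient measured in several preparations, each preparation injected
twice (technical replicates A and B), with log-normal protein
intensities, group-specific log-scale shifts on disjoint blocks of
informative proteins, and zero-inflated missingness (a protein is
independently "not detected" with probability ``1 - detection_rate``).

Hierarchy of variation, all multiplicative (log-additive):

* protein baseline: ``log mean ~ Normal(base_log_mean, base_log_sd)``
* patient biology: one true intensity per (patient, protein), shifted by
  ``effect_size`` on that group's informative block; individual
  patient-level variation beyond the group effect (``bio_log_sd``) is
  off by default so that samples are exchangeable within a group —
  see the methods documentation for why and what this omits
* preparation: each A/B pair shares a latent value = patient value times
  log-normal noise with coefficient of variation ``prep_cv``
* injection: A and B differ from the pair latent only by log-normal
  noise with coefficient of variation ``replicate_cv``
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .io_lfq import LFQMatrix, SampleMeta

_DEFAULT_GROUP_SIZES = {"D": 15, "G": 14, "H": 5, "N": 14}
_GROUP_ORDER = ("D", "G", "H", "N")
# disease groups carrying informative-protein blocks; N is the baseline
_SHIFTED_GROUPS = ("D", "G", "H")


def _cv_to_sigma(cv: float) -> float:
    """Log-scale sd of a log-normal with coefficient of variation ``cv``."""
    return float(np.sqrt(np.log1p(cv * cv)))


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic cohort.

    Defaults mirror the study design the pipeline targets: group sizes
    15/14/5/14, two A/B preparation pairs per patient (four runs each,
    192 samples total), 300 proteins of which 60 carry group effects
    (20 per disease group, disjoint blocks), a 2.0 natural-log mean
    shift on informative proteins, 5% injection-replicate CV, 30%
    preparation-to-preparation CV (independent preps vary far more than
    repeat injections of one prep), and 85% detection probability per
    (protein, sample) entry.
    """

    n_patients_per_group: dict[str, int] = field(
        default_factory=lambda: dict(_DEFAULT_GROUP_SIZES)
    )
    n_pairs_per_patient: int = 2
    n_proteins: int = 300
    n_informative: int = 60
    effect_size: float = 2.0
    replicate_cv: float = 0.05
    prep_cv: float = 0.3
    detection_rate: float = 0.85
    base_log_mean: float = 16.0
    base_log_sd: float = 1.5
    bio_log_sd: float = 0.0
    fluid: str = "plasma"
    seed: int = 0
    # protein baselines are drawn from this seed (default: ``seed``);
    # fixing it while varying ``seed`` yields new patients measured on
    # the same proteome panel — what out-of-sample diagnosis assumes
    baseline_seed: int | None = None

    def __post_init__(self) -> None:
        if not self.n_patients_per_group:
            raise ValueError("n_patients_per_group must be non-empty")
        unknown = set(self.n_patients_per_group) - set(_GROUP_ORDER)
        if unknown:
            raise ValueError(f"unknown groups: {sorted(unknown)}")
        if any(v < 0 for v in self.n_patients_per_group.values()):
            raise ValueError("patient counts must be >= 0")
        if self.n_pairs_per_patient < 0 or self.n_proteins < 0:
            raise ValueError("counts must be >= 0")
        if not 0 <= self.n_informative <= self.n_proteins:
            raise ValueError("n_informative must lie in [0, n_proteins]")
        if not 0.0 <= self.detection_rate <= 1.0:
            raise ValueError("detection_rate must lie in [0, 1]")
        if self.replicate_cv < 0 or self.prep_cv < 0:
            raise ValueError("coefficients of variation must be >= 0")

    @property
    def n_patients(self) -> int:
        return sum(self.n_patients_per_group.values())

    @property
    def n_samples(self) -> int:
        return self.n_patients * self.n_pairs_per_patient * 2


def _informative_blocks(spec: CohortSpec) -> dict[str, np.ndarray]:
    """Disjoint blocks of informative protein indices, one per disease group."""
    groups = [g for g in _SHIFTED_GROUPS if spec.n_patients_per_group.get(g, 0) > 0]
    blocks: dict[str, np.ndarray] = {}
    if not groups or spec.n_informative == 0:
        return blocks
    per_group = spec.n_informative // len(groups)
    remainder = spec.n_informative % len(groups)
    start = 0
    for i, g in enumerate(groups):
        size = per_group + (1 if i < remainder else 0)
        blocks[g] = np.arange(start, start + size)
        start += size
    return blocks


def generate_cohort(spec: CohortSpec) -> tuple[LFQMatrix, list[SampleMeta]]:
    """Draw one cohort; deterministic given ``spec.seed``.

    Returns the proteins x samples intensity matrix (0 = not detected)
    and one metadata record per sample. Sample count is
    ``sum(patients) * n_pairs_per_patient * 2``.
    """
    rng = np.random.default_rng(spec.seed)
    p = spec.n_proteins
    baseline_rng = np.random.default_rng(
        spec.seed if spec.baseline_seed is None else spec.baseline_seed
    )
    base_log = baseline_rng.normal(spec.base_log_mean, spec.base_log_sd, size=p)
    blocks = _informative_blocks(spec)
    sigma_prep = _cv_to_sigma(spec.prep_cv)
    sigma_rep = _cv_to_sigma(spec.replicate_cv)

    columns: list[np.ndarray] = []
    meta: list[SampleMeta] = []
    for group in _GROUP_ORDER:
        n_pat = spec.n_patients_per_group.get(group, 0)
        for i_pat in range(n_pat):
            patient_id = f"{group}{i_pat + 1:02d}"
            shift = np.zeros(p)
            if group in blocks:
                shift[blocks[group]] = spec.effect_size
            patient_log = base_log + shift + (
                rng.normal(0.0, spec.bio_log_sd, size=p) if spec.bio_log_sd else 0.0
            )
            for i_pair in range(spec.n_pairs_per_patient):
                pair_id = f"{patient_id}_P{i_pair + 1}"
                pair_log = patient_log + (rng.normal(0.0, sigma_prep, size=p) if sigma_prep else 0.0)
                for tag in ("A", "B"):
                    sample_log = pair_log + (rng.normal(0.0, sigma_rep, size=p) if sigma_rep else 0.0)
                    intensities = np.exp(sample_log)
                    if spec.detection_rate < 1.0:
                        detected = rng.random(p) < spec.detection_rate
                        intensities = np.where(detected, intensities, 0.0)
                    columns.append(intensities)
                    meta.append(
                        SampleMeta(
                            sample_id=f"{pair_id}{tag}",
                            patient_id=patient_id,
                            group=group,
                            replicate_tag=tag,
                            fluid=spec.fluid,
                            pair_id=pair_id,
                        )
                    )
    if columns:
        matrix = np.column_stack(columns)
    else:
        matrix = np.zeros((p, 0))
    protein_ids = [f"PROT{j + 1:04d}" for j in range(p)]
    return LFQMatrix(protein_ids, [m.sample_id for m in meta], matrix), meta


def permute_labels(meta: list[SampleMeta], seed: int) -> list[SampleMeta]:
    """Permute group labels at the patient level (null-model utility).

    All samples of one patient receive a common reassigned label; the
    multiset of patient labels is conserved. Pair structure, fluids and
    ids are untouched. Deterministic given ``seed``.
    """
    if not meta:
        raise ValueError("metadata must be non-empty")
    patients: list[str] = []
    patient_group: dict[str, str] = {}
    for m in meta:
        if m.patient_id not in patient_group:
            patients.append(m.patient_id)
            patient_group[m.patient_id] = m.group
    rng = np.random.default_rng(seed)
    labels = [patient_group[pid] for pid in patients]
    permuted = [labels[i] for i in rng.permutation(len(labels))]
    new_group = dict(zip(patients, permuted))
    return [replace(m, group=new_group[m.patient_id]) for m in meta]
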