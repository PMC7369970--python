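# Methods

## Scope and data model

The package analyses label-free quantification (LFQ) intensity
matrices: proteins × samples, non-negative, with 0 meaning "not
detected" (the MaxQuant convention for unquantified proteins). Each
prepared sample is measured twice; the two injections are technical
replicates tagged A and B and tied together by a `pair_id`. Samples are
annotated with a patient, a disease group (D = diabetic nephropathy,
G = glomerulonephritis, H = hypertensive nephropathy, N = healthy) and
a fluid (plasma or urine).

## Preprocessing chain

The chain is applied, in fixed order, to each analysis subset (fluid ×
group selection). Re-running an analysis on a different subset re-fits
everything from scratch; nothing is shared between experiments.

**Quality filtration.** Proteins detected (intensity > 0) in fewer than
`min_samples_per_protein` (default 5) samples are removed first; then
samples with fewer than `min_proteins_per_sample` (default 50) detected
proteins, counted on the protein-filtered matrix, are removed. Each
step runs exactly once — the filter is not iterated, and re-applying it
to its own output is a no-op on typical data. Replicate pairs broken by
the sample filter are removed entirely, since the consistency check
needs both members. An empty result raises instead of propagating.

**Max-normalization.** Every protein row is divided by its maximum over
the samples present in the current subset, mapping values into [0, 1]
with zeros preserved. The maximum is a subset property: normalizing the
same matrix inside a different experiment can scale rows differently.
Idempotent by construction. All-zero rows are an error (the filter
should have removed them).

**PCA truncation.** Samples are observations, proteins features.
Features are mean-centered but not variance-scaled — the inputs already
live on [0, 1], and additional scaling would re-inflate noise-dominated
proteins. The number of retained components k is the smallest count
whose cumulative explained-variance ratio reaches `variance_threshold`
(default 0.70), capped at the numerical rank (components with
eigenvalues below 1e-12 of the leading one do not count). Component
signs are fixed by requiring each loading vector's largest-magnitude
entry to be positive, so coordinates are reproducible across runs and
platforms. The decomposition itself is scikit-learn's full-SVD PCA.

**Replicate consistency check.** For every embedded sample the nearest
Euclidean neighbor among all other samples is found (self excluded;
distance ties broken toward the lowest sample index, so duplicate
coordinates resolve deterministically). A pair is *consistent* iff A's
nearest neighbor is its paired B and B's is its paired A — a mutual-
nearest-neighbor criterion that is symmetric in the A/B orientation.
Consistent pairs are averaged component-wise (the exact midpoint) into
one observation inheriting the pair's patient/group/fluid; both samples
of any inconsistent pair are excluded.

**Information-leakage caveat.** PCA and the consistency check are
fitted on the *full* dataset of an experiment before cross-validation,
so every LOOCV training fold has seen the held-out sample's coordinates
during preprocessing. This reproduces the procedure the pipeline is
modeled on and keeps the replicate-pair structure intact, but it means
LOOCV accuracies are optimistic relative to a fully nested scheme.
Out-of-sample prediction (`TrainedModel`) does not leak: new samples
are mapped with stored training-stage maxima, mean and loadings.

## Classifiers

All classifiers consume PC coordinates only, never raw LFQ values.

* **kNN** (Euclidean) is implemented in-package because its tie rules
  are part of the contract: neighbors are ordered by (distance,
  coordinate tuple, label) — a canonical order independent of
  training-row order, which makes predictions invariant under row
  permutation and under positive rescaling of all coordinates — and a
  tied vote goes to the class of the nearest neighbor among the tied
  classes, so every tie degrades gracefully toward 1-nn behavior.
* **Logistic regression** (L2, constant C) and the **RBF-kernel SVM**
  (C, gamma) are scikit-learn estimators wrapped in an explicit
  one-vs-rest scheme; the **decision tree** is CART with a depth cap
  and fixed seed. Identical inputs and seed give identical outputs.

## Evaluation

With a few dozen subjects, a held-out test split is dominated by which
samples land in it, so quality is estimated by leave-one-out
cross-validation over the whole (averaged) dataset: n fits on n−1
observations each. The headline metric is plain mean accuracy — class
imbalance in the target designs is mild (largest:smallest ratio about
3:1) — with per-class error counts always reported next to it. A fold
whose training set collapses to a single class (the held-out sample was
a singleton class) yields the constant prediction of the remaining
class; in a 2-sample problem this is an error instead.

Grid search evaluates LOOCV accuracy at every grid point and keeps the
best, breaking ties toward the simpler model (fewer neighbors, smaller
C, smaller gamma, shallower tree). Default grids: n_neighbors 1–10;
C ∈ {0.01, 0.1, 1, 10, 100}; (C, gamma) ∈ {0.1, 1, 10} × {0.01, 0.1,
0.5, 1}; max_depth 2–8.

One-against-all evaluation collapses labels to {target, rest} and
reports accuracy, false positives and false negatives. It uses LOOCV by
default; a resubstitution variant (`method="resubstitution"`) is
available because evaluating "by the entire set" is a defensible
alternative reading for this design, but note that resubstitution 1-nn
is trivially perfect and should only be used deliberately.

## Synthetic cohorts

The generator emulates the cohort design the pipeline targets:
15/14/5/14 patients in groups D/G/H/N, each with two A/B preparation
pairs (192 plasma runs; urine cohorts omit N, as healthy urine carries
too little protein to profile). The hierarchy is multiplicative
(log-additive):

| parameter | default | meaning |
| --- | --- | --- |
| `base_log_mean`, `base_log_sd` | 16.0, 1.5 | natural-log intensity distribution of protein baselines |
| `n_proteins`, `n_informative` | 300, 60 | informative proteins split into disjoint blocks, one per disease group (20 each for D/G/H; N is baseline) |
| `effect_size` | 2.0 | natural-log mean shift on a group's block |
| `prep_cv` | 0.30 | coefficient of variation between preparations of one patient |
| `replicate_cv` | 0.05 | CV between the two injections of one preparation |
| `bio_log_sd` | 0.0 | patient-level log-scale individuality beyond the group effect |
| `detection_rate` | 0.85 | probability an entry is detected; missingness is independent of intensity |
| `baseline_seed` | `seed` | fixing it while varying `seed` draws new patients on the same protein panel |

Two choices deserve justification:

* `replicate_cv < prep_cv`: repeat injections of one preparation are
  far tighter than independent preparations. This is also what makes
  the mutual-nearest-neighbor consistency check well-posed — if the two
  noise scales were equal, a replicate would be no closer to its pair
  partner than to its sibling preparation and the check would reject
  pairs by construction rather than by quality.
* `bio_log_sd = 0` by default: patients are exchangeable within a
  group. With an appreciable per-patient signature and hundreds of
  proteins, a pair's nearest neighbor is almost surely the same
  patient's other preparation, so sample-level LOOCV recognizes the
  *patient*, not the disease, and stays near 100% even with permuted
  labels. Exchangeability is the regime in which null calibration is
  meaningful. Real cohorts do have patient-level signatures — which is
  exactly why sample-level LOOCV on real multi-replicate data is
  optimistic; the generator makes that regime opt-in rather than
  baked in.

What the generator does **not** emulate: intensity-dependent
(left-censored) missingness, correlated protein modules, batch or
run-order drift, shared-peptide quantification artifacts, and
heavy-tailed contamination. Passing the synthetic acceptance checks
therefore demonstrates that the pipeline machinery is correct and
calibrated under its assumed model, not that comparable accuracies
would be reached on patient data.

A patient-level label permutation utility provides the matching null:
all samples of a patient keep one reassigned label, and the multiset of
patient labels is conserved.

## Null calibration

Two null checks are part of acceptance testing, both over 20 fixed
seeds at the study-scale defaults:

* with `effect_size = 0`, 1-nn LOOCV accuracy sits at the exact
  exchangeability chance level Σ_c n_c(n_c−1)/(n(n−1)) — the
  probability that a sample's nearest other sample shares its label
  when labels are exchangeable (≈ 0.58 for the CKD-vs-healthy split);
* with real effects but patient-permuted labels, the grid-searched kNN
  cannot beat the majority-class share (≈ 0.71), because under the null
  large-k majority voting is the best the grid contains.

Both means are required to fall inside the 95% binomial band of a
single dataset of the typical size (n ≈ 90) — deliberately conservative
for a mean over 20 runs.

## Out-of-sample projection and two-stage diagnosis

A `TrainedModel` persists the retained protein panel, per-protein
training maxima, PCA mean and loadings, training coordinates and
labels, and the classifier. A new sample is projected by zero-filling
panel proteins it lacks, ignoring proteins outside the panel, dividing
by the stored maxima (values may exceed 1 — they are not clipped),
centering with the stored mean and applying the stored loadings.
Projection of a training sample reproduces its training coordinates to
numerical precision. A configurable minimum panel overlap (default 10
proteins) guards against vacuous projections.

`diagnose_two_stage` chains a urine one-vs-all H model (stage 1) with a
plasma D-vs-G model (stage 2): a positive urine call returns H without
consulting plasma; otherwise the plasma model decides. Disagreement
handling beyond this ordering (e.g. an H-looking plasma profile after a
negative urine screen) is intentionally not invented.

## Problem sizes

All tests and the acceptance script run on synthetic cohorts at the
study-scale defaults (192 plasma runs, 136 urine runs, 300 proteins) or
smaller; the full test suite completes in well under a minute and the
acceptance script in a few seconds on one CPU.

## Known limitations

* The dataset-reduction counts printed for the original study's
  supplementary tables (e.g. 246→184 plasma proteins, 90 averaged
  samples, 17 PCs) can only be reproduced with those tables, which have
  no public accession; the experiment drivers accept them unchanged via
  `read_lfq_table` should they be available.
* Preprocessing-stage information leakage into LOOCV (see above) is
  faithful to the procedure but methodologically optimistic.
* Plain accuracy hides asymmetric error costs; per-class errors and
  false positive/negative counts are reported, but no cost-sensitive
  evaluation is offered.
* No missing-value imputation, batch correction, or protein-level
  differential testing is included — the pipeline's premise is that
  single-protein statistics are uninformative for these groups.
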