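# Methods

## Problem setting

Pulmonary fibrosis can arise through an adverse outcome pathway in which
two distinct molecular initiating events (MIEs) converge: inactivation of
the nuclear receptor PPAR-γ and activation of the innate-immunity receptor
TLR4. A chemical mixture containing one compound that hits each MIE is
therefore a plausible combination hazard even when neither compound is of
concern alone. This package implements the computational arm of that
screening idea for biocidal ingredients: two binary QSAR classifiers (one
per MIE) trained on curated bioassay pools, and a mixture screen that
flags pairs of predicted positives.

## Pipeline

1. **Compound curation** (`mieqsar.io`). Compounds enter as SMILES with an
   id, optional CAS number and optional binary activity label (1 = active
   in the MIE: PPAR-γ antagonist or TLR4 agonist). Unparseable structures
   are rejected and logged, never silently dropped. Exact structural
   duplicates are merged by canonical-SMILES equality (first occurrence
   wins); a structure observed with conflicting labels is removed
   entirely, since neither label can be trusted.

2. **Descriptors** (`mieqsar.descriptors`). The backend is RDKit-based and
   computes ~170 named descriptors: a physicochemical pool (MW, logP,
   TPSA, connectivity and shape indices, heteroatom counts, …), ring
   counts nR3–nR12, atom-pair frequencies `F0d[X-Y]` (count of X–Y
   heavy-atom pairs at shortest-path distance d ∈ {1..4}) and presences
   `B10[X-Y]`, the non-aromatic conjugated sp² carbon count `NCconj`, and
   electrotopological descriptors (`MAXDN`, `SssCH2`, Burden-matrix
   eigenvalues `SpMaxk_Bh(e)` weighted by Sanderson electronegativity).
   The named fragment/topological descriptors are implemented natively so
   the published two-descriptor TLR4 model (nR10, F02[C-O]) and
   six-descriptor PPAR-γ model are expressible; numerical parity with the
   commercial descriptor package used in the original work is not claimed,
   and its license prevents a direct comparison. Topological distance is
   the shortest path in the hydrogen-suppressed graph. Non-finite values
   are recorded as missing; variable reduction drops columns with any
   missing cell (`DROP_ANY_MISSING`) or only fully missing columns
   (`DROP_ALL_MISSING`).

3. **Applicability filtering** (`mieqsar.chemspace`). Descriptors are
   standardized (constant columns dropped with a warning) and projected
   onto a PCA basis fitted on references + candidates pooled; the default
   score space is 2-dimensional. The retention threshold is the mean
   Euclidean distance over all unordered pairs of reference compounds — a
   property of the reference (biocide) set alone. A candidate is retained
   iff its mean distance to the references is ≤ the threshold (ties kept);
   minimum-distance aggregation is available by configuration. Filtering
   is idempotent and monotone in the threshold.

4. **Class balancing** (`mieqsar.imbalance`). Tomek links — opposite-class
   mutual nearest neighbours under the Euclidean metric on standardized
   descriptors — identify boundary majority samples. Balancing removes
   majority members of links first (descending link distance, id
   tie-break), re-detecting links each round; if links are exhausted
   before the classes are equal, a seeded uniform draw from the remaining
   majority completes the 1:1 ratio. Pure link removal cannot guarantee
   exact balance, so the random top-up is the minimal completion; every
   removal is audited with its step and reason. Minority rows are never
   modified. Nearest-neighbour ties break toward the smallest id, making
   the link set deterministic.

5. **Model development** (`mieqsar.qsar`). The labeled pool splits
   stratified 80/20; a genetic algorithm searches descriptor-inclusion
   bitmasks with fitness = mean stratified 10-fold cross-validated
   balanced accuracy of an RBF-SVM (C = 5.0, γ = 1.0 throughout) on the
   masked standardized training matrix, minus a parsimony penalty of
   0.001 per selected descriptor. GA defaults: population 50, up to 100
   generations, uniform crossover p = 0.6, per-gene bit-flip mutation
   p = 1/m, tournament size 3, elitism, sparse initialisation (inclusion
   p = 0.1, reflecting that useful subsets are small), early stop after
   10 generations without improvement, memoised fitness. All randomness
   flows from one seed. The winning subset is refitted on the training
   split (scaler fitted on train only) and scored on the external split;
   the whole procedure repeats over 5 seeded splits and reports per-repeat
   and mean metrics. By default descriptor selection reruns inside every
   repeat (no selection leak); a `fixed` mode selects once and reuses the
   subset, which is appropriate once the subset is considered part of the
   model definition and is the configuration used for the large
   PPAR-γ-scale runs. Trained models serialise to JSON (scaler, support
   vectors, dual coefficients, intercept) and predict identically after a
   round trip; the decision score is the signed distance to the
   separating surface.

6. **Validation statistics** (`mieqsar.metrics`). ACC, sensitivity,
   specificity, BA = (sensitivity+specificity)/2 and MCC are computed from
   confusion counts; degenerate rates and a zero MCC denominator are
   defined as 0. AUC is the rank statistic P(score⁺ > score⁻) with ties
   counted ½. Cross-validation reports both the mean over folds and the
   pooled-prediction report; the mean-over-folds value is the headline
   number. Y-randomization retrains on label permutations (default 100)
   under the identical cross-validation scheme and reports
   z = (metric_ori − mean_perm)/sd_perm with the sample (n−1) standard
   deviation, for ACC and MCC; the model is robust when both z > 3.

7. **Mixture screening** (`mieqsar.mixtures`). Every pair of one
   PPAR-γ-positive and one TLR4-positive compound is a flagged candidate
   mixture; an optional co-exposure pair list restricts the evaluation.
   Ranking by the sum of the two decision scores is a package convention —
   joint positivity itself carries no potency ordering.

## Synthetic data

The generator (`mieqsar.synthetic`) emulates the statistical shape of the
curated bioassay pools, not their chemistry. Descriptor vectors are
class-conditional Gaussians: `n_informative` descriptors carry a symmetric
mean shift of ±`class_separation`/2 per class (so the between-class mean
distance per informative descriptor is `class_separation`), the rest are
shared noise. A fraction of majority samples is resampled tightly around
the minority centroid (`overlap_fraction`) so Tomek links exist, and
`label_noise` flips labels last. A reference cloud of 255 compounds is
drawn with a spread of 3 standard deviations; an `outlier_fraction` of
candidates is displaced by `reference_shift` = 8 on all non-informative
descriptors. The broader reference spread is deliberate: with equal
spreads the mean distance of an in-domain candidate to the references
equals the mean reference pairwise distance in expectation, so the
threshold would cut at the median of its own population; a wider reference
cloud (mirroring the observed geometry in which biocides span more of
chemical space than the curated pool) makes the threshold cover nearly all
undisplaced candidates (closed-form 2D retention ≈ 1−exp(−(1.07·s)²/2) ≈
0.99 at s = 3).

Defaults are the study conditions: 903 positives / 2181 negatives
(≈2.4:1), 30 descriptors of which 3 informative, class separation 1.1,
10% overlap, 10% out-of-domain candidates, 2% label noise. The
TLR4-shaped configuration used in the analysis scripts is 60/58 with 2
informative descriptors at separation 3.0 (a near-separable endpoint) and
13.5% out-of-domain. The toy SMILES grammar assembles ring cores (sizes
3–12 plus simple aromatics) with short C/N/O/S/halogen tails so the
descriptor paths are exercised on real molecules.

What passing on synthetic data does **not** show: real descriptor
distributions are neither Gaussian nor independent, activity labels from
bioassays carry assay-specific noise structure, and chemical space is
discrete and clumpy. The synthetic results validate the pipeline's
mechanics and statistical behaviour, not the attainable accuracy on any
real endpoint.

## Problem sizes and numerical choices

Large-scale runs (the end-to-end rehearsal and the acceptance script) use
a reduced GA budget (population 24, 30 generations, patience 8,
`GAConfig.fast`) and, for the PPAR-γ-scale pool, fixed-once descriptor
selection across the five validation repeats; these are the package's
standard large-n configurations. Y-randomization uses 100 shuffles.
Distances agree with brute-force oracles to 1e-9; PCA uses the full SVD
solver for determinism; fold assignment, splits, GA and permutations are
all seeded. Stratification is used for every split and fold so both
classes are present everywhere; folds are capped at the minority class
size when a pool is tiny.

## Known limitations

- Descriptor values are not numerically interchangeable with the
  commercial backend the original models were built on, so published
  thresholds (e.g. the 1.24/1.22 average-distance criteria) are not
  reproduced literally; the procedure that generates such thresholds is.
- The GA is a stochastic search; with correlated descriptors it may
  return a superset of the informative descriptors or swap in a
  correlated proxy.
- The mixture screen is purely qualitative (joint MIE positivity); no
  dose addition, synergy or downstream key-event modeling is attempted.
- SDF input is limited to V2000 files as read by RDKit; CSV/SMILES is the
  primary dialect.
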