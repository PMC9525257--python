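# Methods

## Problem and model

`stackpr` classifies small molecules as progesterone-receptor (PR)
antagonists (active) or inactive from SMILES alone. The model is a
stacked ensemble: a 6 × 12 grid of baseline classifiers over molecular
fingerprints produces, for each compound, a 72-dimensional vector of
predicted confidences (*probabilistic features*, PFs), and a random
forest meta-predictor (mRF) trained on a selected subset of those PFs
makes the final call. Subset selection is a genetic algorithm with a
self-assessment report (GA-SAR).

## Curation

* IC50 is the canonical bioactivity unit, internally in µM (nM inputs
  divided by 1000 at parse time, because the class thresholds are stated
  in µM). Labels: active ⇔ IC50 ≤ 1 µM, inactive ⇔ IC50 ≥ 10 µM; both
  boundaries are inclusive of their class; strictly intermediate
  compounds are excluded from modelling.
* Structures are standardized by keeping the largest organic fragment
  (salt/counter-ion stripping) and canonicalizing the tautomer (RDKit
  `FragmentParent` + `TautomerEnumerator`; tautomer step can be disabled
  when a fixed protonation/tautomer convention is supplied upstream).
  Standardization is idempotent.
* Duplicate standardized structures are merged, keeping the geometric-
  mean IC50 — standard ChEMBL-style curation, since potency errors are
  roughly log-normal.
* Train/test splitting is seeded stratified random sampling with a
  default test fraction of 0.2; per-class test counts are
  `round(n_class · fraction)`, which reproduces a 93 + 52 test set from
  463 actives + 260 inactives.

## Fingerprints

Twelve families at their conventional widths (AP2D 780, Circle 1024,
CKD/CKDExt/CKDGraph/Hybrid 1024, Estate 79, FP4/FP4C 307, KR 4860,
MACCS 166, PubChem 881). FP4C is count-valued; all others binary.

Exact native backends (RDKit): MACCS (167-bit key vector with the unused
key 0 dropped), Circle (Morgan, radius 2, 1024 bits), AP2D (hashed atom
pairs, 780 bits), Estate (79 E-state atom-type presences).

The remaining eight families are defined by the CDK/PaDEL Java
toolchain: either path-hash algorithms whose exact bit assignment is an
implementation detail of that hasher, or published SMARTS key lists
(307/881/4860 patterns) that are third-party data we do not
redistribute. They are supported two ways:

* **precomputed** — validated ingestion of PaDEL-style CSV output
  (column count must match the family width exactly; binary families
  reject values outside {0, 1});
* **hashed** (opt-in) — deterministic approximations at the exact
  conventional widths: RDKit path fingerprints with search depth 8 for
  CKD (linear paths), CKDExt (branched), CKDGraph (bond orders ignored),
  Hybrid (atom invariants carry element + hybridization); feature-typed
  radius-1 circular substructures hashed to 307 bits for FP4 (presence)
  and FP4C (counts); radius-2/radius-3 circular hashes at 881/4860 bits
  for PubChem/KR. These preserve width, value kind and determinism, not
  key identity. The stacking layer is agnostic to the backend; the
  hashed families behave as ordinary substructure descriptors.

All hashing is RDKit's fixed built-in hash — no run- or platform-
dependent seeds. One aromaticity/valence perception model (RDKit
default sanitization) is applied before every family.

Normalization is per-column min–max to [0, 1], fitted on training rows
only (scikit-learn, `clip=True`): test values outside the fitted range
are clipped, and constant columns map to 0. Clipping keeps the PF
layer's inputs bounded.

## Baseline layer

Algorithms: LR, PLS, KNN, SVM, ET, RF (scikit-learn). Grids: ET/RF
`n_estimators ∈ {20, 50, 100, 200, 500}`, LR `C ∈ {0.001, …, 100}`,
SVM `C ∈ {1, 2, 4, 8, 16, 32}`; KNN and PLS use defaults. Tuning
maximizes cross-validated MCC over the grid, evaluated on out-of-fold
class predictions with a shared stratified tenfold scheme; ties resolve
to the smaller parameter (evaluation in ascending order with strict
improvement). The chosen point is refitted on all training rows.

* scikit-learn has no PLS-DA, so PLS classifies via a thin wrapper:
  regression on the 0/1 labels with 2 components (the library default
  is also clamped to the feature count), prediction clamped to [0, 1]
  as the confidence.
* SVM confidences are Platt-calibrated (`SVC(probability=True)`, the
  calibration being fitted within each training fold by the library).

**PF protocol.** Training-set PFs are out-of-fold: each compound's PF
comes from the fold model that did not train on it, with the same fold
assignment shared by all 72 baselines — the standard stacked-
generalization guard against the meta-learner fitting optimistic
in-sample confidences. Test/prediction PFs come from the full-training
refits. An `insample` mode exists for comparison and is exactly the
leakage the permuted-label null (below) is designed to expose.

**Permuted-label leakage null.** `leakage_null_mcc` runs the real
pipeline (synthetic compounds → fingerprints → baseline PFs → meta RF)
with randomly permuted labels and reports the meta's cross-validated
MCC, which must sit near zero under the out-of-fold protocol and is
visibly inflated under the in-sample protocol. Three details keep the
null honest: the meta's CV partition is drawn independently of the PF
folds (reusing one partition lets a fold's labels reach its
meta-training rows through the baselines — a known stacking artifact
that would register as spurious "leakage"); duplicate structures are
dropped first, as curation would, because twin compounds let
memorizing baselines couple rows and inflate the null variance; and
the reduced baseline grid uses smooth learners (LR, PLS) whose
in-sample overfitting is exactly what the insample mode must expose,
rather than k-NN, whose neighbor memorization over a 16-scaffold pool
adds family-level dependence (variance, not protocol leakage) to the
null statistic.

## GA-SAR and the meta-predictor

Chromosome: 72 binary selection genes + one 3-bit parametric gene. The
3 bits (8 codes) decode to the 5 admissible mRF tree counts by value
modulo 5 — the simplest total surjection. Feasibility band 5 ≤ m ≤ 20,
clamped to the column count for reduced grids; infeasible chromosomes
are repaired by randomly flipping exactly the deficit/excess, so repair
never moves a gene unnecessarily. Fitness is the cross-validated MCC of
an mRF with the chromosome's own decoded tree count on its selected
columns; evaluations are cached by genotype.

GA numerics (defaults, all exposed in `GAConfig`): population 50,
generations 100, tournament size 3, uniform crossover at rate 0.8,
per-gene bit-flip mutation 1/75, elitism 1, 10 independent runs. These
are conventional wrapper-GA settings; the selection pressure comes from
tournament selection and elitism, and the cardinality band doubles as a
parsimony cap.

**Self-assessment report.** Each run contributes its best chromosome;
a column's SAR frequency is the fraction of runs whose best chromosome
included it. The final ranking is by frequency, ties broken by the mean
fitness of every evaluated chromosome that contained the column (a
column that only ever rode in low-fitness chromosomes ranks below one
that consistently co-occurred with signal), then by column index. The
ranking is truncated at the cardinality in [5, 20] whose refitted CV
MCC is maximal. Among cardinalities with equal CV MCC the largest is
kept: when cross-validation cannot distinguish subset sizes, we follow
the stability-selection stance — retain every consistently selected
feature up to the cap — rather than discard features on an uninformative
tie. (For hyperparameter grids, where larger values cost compute but
add no information, the opposite smaller-tie rule applies.) The mRF
tree count is taken from the overall best chromosome; whether the final
cardinality should instead be fixed by a frequency threshold is
genuinely open, and the scan over [5, 20] makes the choice explicit in
`GAResult.cardinality_scan`.

The control model skips selection: all 72 PF columns, tree count tuned
over the same five values by CV MCC. Final classification threshold is
probability ≥ 0.5 → active (ties to the positive class).

Feature importance: native backend is permutation importance (mean MCC
drop over k shuffles per selected column, seeded); a SHAP backend
delegates to the optional `shap` package.

## Synthetic data and what it shows

`make_synthetic_compounds` decorates a pool of sixteen common drug-like
scaffolds with short random heteroatom chains (built on RDKit molecules,
so every emitted SMILES is valid) and draws IC50s log-uniformly inside
each class's band (actives 10⁻³–1 µM, inactives 10–10³ µM), so labels
are recoverable exactly from the thresholds.

`make_synthetic_pf` emulates the PF layer directly: informative columns
are `clip(0.5 ± effect + N(0, noise_sd), 0, 1)` with the sign set by the
label (between-class mean difference 2·effect before clipping; clipping
rather than a logit transform keeps the PF ∈ [0, 1] invariant exact);
noise columns are Uniform(0, 1).

These fixtures test the machinery, not PR biology. Real PF columns are
correlated (72 models on 12 descriptor views of the same molecules),
unevenly informative and miscalibrated; synthetic columns are
independent with a clean planted shift. Passing the benchmark shows the
selection and stacking plumbing behaves as designed, not that the
pipeline attains any particular accuracy on real PR data.

## Planted-recovery benchmark: scale and a known limitation

The benchmark (ten seeds) generates 400 training and 200 test compounds
with 8 informative of 72 PF columns at effect 0.35, noise 0.1, runs
GA-SAR and the control, and records recovered-informative counts, test
MCCs, the subset's CV MCC and the best single-column MCC.

*Scale.* Every GA fitness evaluation is a cross-validated random-forest
fit, so the benchmark runs the GA at a reduced, fixed scale chosen once
for single-CPU execution: population 10, generations 5, 2 runs, 2-fold
fitness CV (production defaults remain 50/100/10 runs/tenfold). At this
scale the full ten-seed benchmark takes on the order of ten minutes on
one CPU.

*Limitation.* At effect 0.35 / noise 0.1 a single informative column
separates the classes at ≈ 7σ, so any chromosome containing at least
one informative column reaches CV MCC ≈ 1.0. Fitness is then flat
across most of the feasible space and the GA has no gradient toward
collecting *all* informative columns; recovery rests entirely on the
SAR aggregation (frequency + co-occurrence-fitness ranking). With few
GA runs the frequency signal is coarse, so the recovered-informative
count undercounts what a long, many-run GA-SAR would find, while the
performance comparisons (subset vs control, stacking dominance) are
unaffected because every candidate sits on the same fitness plateau.
This is a property of the strong-signal generator setting, not of the
selection machinery; weaker planted effects (where columns are
individually imperfect and complementary) give the GA a real gradient.

## Numerical conventions

* MCC returns 0 when any denominator factor is 0 (no-information
  convention); ratio metrics warn and return 0 on zero denominators.
* Threshold metrics are computed in exact rational arithmetic and
  rounded only for presentation (reports print 3 decimals).
* ROC AUC is the rank statistic (ties ½), undefined for single-class
  inputs (raises).
* All stochastic components (splits, folds, forests, GA, generators)
  consume explicit integer seeds; a fixed configuration reproduces
  `GAResult` JSON byte-identically.

## Known limitations

* The hashed fingerprint backends are approximations; models trained on
  them are not comparable bit-for-bit with PaDEL-derived models, and
  per-bit chemical interpretation (e.g. of PubChem keys) only applies to
  the precomputed backend.
* No applicability-domain analysis beyond what a user builds from the
  fingerprint matrices; no 3-D descriptors or docking.
* Flat (non-nested) cross-validation for hyperparameter choice means
  baseline CV MCCs are mildly optimistic as generalization estimates;
  the independent test split is the unbiased check.
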