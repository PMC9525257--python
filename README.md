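# stackpr

Stacked-ensemble QSAR classification of progesterone-receptor (PR)
antagonists from SMILES alone.

PR antagonists are an active strategy in breast and gynecological cancer
drug discovery, and screening large compound libraries experimentally is
expensive. `stackpr` implements a stacked-generalization pipeline that
needs nothing but a SMILES string per compound:

1. **Curation** — structures are salt-stripped and tautomer-canonicalized;
   compounds are labelled from their IC50: active when IC50 ≤ 1 µM,
   inactive when IC50 ≥ 10 µM, and excluded as intermediate in between.
2. **Baseline grid** — six classifiers (logistic regression, PLS, k-NN,
   SVM, extra trees, random forest) × twelve molecular fingerprint
   families (MACCS, circular, atom-pair, E-state, CDK path variants,
   substructure/PubChem/Klekota–Roth keys) = 72 baseline models, each
   tuned by stratified tenfold cross-validation on Matthews correlation
   (MCC) over fixed small hyperparameter grids.
3. **Stacking** — each baseline's predicted confidence becomes one
   *probabilistic feature* (PF); for compound *C* the meta-input is
   nFeat(C) = {PF₁(C), …, PF₇₂(C)}. Training-set PFs are produced
   out-of-fold to prevent leakage.
4. **GA-SAR selection** — a genetic algorithm whose chromosome carries 72
   binary selection genes plus a 3-bit gene encoding the meta random
   forest's tree count (∈ {20, 50, 100, 200, 500}) searches for an
   m-column PF subset, 5 ≤ m ≤ 20. A self-assessment report aggregates
   several GA runs into per-column selection frequencies that determine
   the final subset.
5. **Meta-predictor** — a random forest (mRF) on the selected PFs emits
   the final probability; probability ≥ 0.5 calls the compound active.

Evaluation uses MCC, F-value, sensitivity, specificity, accuracy
(exact-rational confusion-matrix arithmetic) and rank-based ROC AUC.

## Worked example

Everything below runs offline on synthetic compounds with planted
structure–activity signal:

```bash
python - <<'PY'
from stackpr.synthetic import SyntheticCompoundConfig, make_synthetic_compounds
make_synthetic_compounds(
    SyntheticCompoundConfig(n=80, active_fraction=0.5, sar_mode="scaffold", seed=4)
).to_csv("compounds.csv", index=False)
PY

stackpr curate compounds.csv --out-dir curated --seed 0
stackpr train curated/train.csv --bundle bundle \
    --algorithms LR,KNN,PLS --fingerprints MACCS,Estate \
    --cv-folds 5 --ga-cv-folds 3 --ga-population 6 --ga-generations 2 \
    --ga-runs 2 --seed 11
stackpr evaluate bundle curated/test.csv
```

The curate step reports
`curated 79 compounds (32+31 train, 8+8 test)` (one duplicate structure
was merged); training logs each baseline's cross-validated MCC and ends
with `selected 6 PF columns, meta n_estimators=50`; evaluation prints

```json
{
  "acc": 1.0, "sn": 1.0, "sp": 1.0, "mcc": 1.0,
  "f_value": 1.0, "auc": 1.0,
  "cm": {"tp": 8, "fn": 0, "tn": 8, "fp": 0}
}
```

All 16 held-out compounds are called correctly — expected here, because
`sar_mode="scaffold"` plants a deliberately easy structure–activity
rule (actives on nitrogen-containing scaffolds) that MACCS keys see
directly. The published confusion-matrix worked example is available
directly:

```bash
stackpr evaluate . --from-confusion 91,2,49,3
# -> mcc 0.925..., acc 0.966..., sn 0.978..., sp 0.942..., f_value 0.973...
```

The eight fingerprint families defined by the CDK/PaDEL Java toolchain
have no exact RDKit equivalent; they are available either from
precomputed (e.g. PaDEL) CSV tables or as deterministic hashed
approximations at the conventional widths (`--allow-approximate` /
`backend="hashed"`). See `docs/methods.md`.

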