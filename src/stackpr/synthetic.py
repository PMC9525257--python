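"""Synthetic compound sets and PF matrices with planted signal.

Every pipeline stage is testable offline: :func:`make_synthetic_compounds`
emits drug-like molecules with IC50s drawn inside each class's band, so
activity labels are recoverable exactly from the thresholds, and
:func:`make_synthetic_pf` emulates the stacking layer's input — a PF
matrix in which a known subset of columns carries a mean shift toward the
true label while the rest are pure noise. The planted-recovery benchmark
measures whether GA-SAR finds the informative columns and whether the
selected-subset meta-model keeps up with the all-columns control. These
fixtures exercise the machinery, not progesterone-receptor biology: real
PF columns are correlated, unevenly informative and miscalibrated in ways
uniform noise plus a clean mean shift is not.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import RWMol

from .baseline_models import CVScheme
from .metrics import ConfusionMatrix, mcc
from .stacking_gasar import (
    GAConfig,
    GAResult,
    PFMatrix,
    control_result,
    predict_meta,
    run_gasar,
    train_meta,
)

#: common drug-like scaffolds (valid SMILES, no download needed)
SCAFFOLD_POOL = (
    "c1ccccc1",  # benzene
    "c1ccncc1",  # pyridine
    "c1ccc2ccccc2c1",  # naphthalene
    "c1ccc2[nH]ccc2c1",  # indole
    "c1ccc2ncccc2c1",  # quinoline
    "c1cnc2[nH]ccc2c1",  # azaindole
    "C1CCNCC1",  # piperidine
    "C1CNCCN1",  # piperazine
    "C1CCOC1",  # tetrahydrofuran
    "c1ccsc1",  # thiophene
    "c1ccoc1",  # furan
    "c1cnn(c1)C",  # methylpyrazole
    "O=C1CCCCC1",  # cyclohexanone
    "c1ccc(cc1)C(=O)N",  # benzamide
    "CC12CCC3c4ccccc4CCC3C1CCC2",  # steroid-like tetracycle
    "c1ccc(cc1)S(=O)(=O)N",  # benzenesulfonamide
)


@dataclass(frozen=True)
class SyntheticPFConfig:
    """Planted-signal PF matrix: informative columns shift toward the label."""

    n_compounds: int = 400
    n_columns: int = 72
    informative_columns: tuple[int, ...] = tuple(range(8))
    effect: float = 0.35
    noise_sd: float = 0.1
    class_balance: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.effect <= 0.5:
            raise ValueError("effect must be in (0, 0.5]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not 0.0 < self.class_balance < 1.0:
            raise ValueError("class_balance must be in (0, 1)")
        if any(c < 0 or c >= self.n_columns for c in self.informative_columns):
            raise ValueError("informative_columns out of range")


def make_synthetic_pf(config: SyntheticPFConfig) -> tuple[PFMatrix, np.ndarray]:
    """Generate (PF matrix, labels) with the configured planted signal.

    Informative columns are clip(0.5 +/- effect + N(0, noise_sd), 0, 1)
    with the sign set by the label; other columns are Uniform(0, 1).
    """
    rng = np.random.default_rng(config.seed)
    n, p = config.n_compounds, config.n_columns
    n_active = int(round(n * config.class_balance))
    y = np.zeros(n, dtype=int)
    y[rng.choice(n, size=n_active, replace=False)] = 1
    values = rng.random((n, p))
    for col in config.informative_columns:
        center = np.where(y == 1, 0.5 + config.effect, 0.5 - config.effect)
        values[:, col] = np.clip(center + rng.normal(0.0, config.noise_sd, n), 0.0, 1.0)
    pf = PFMatrix(
        ids=[f"S{i:04d}" for i in range(n)],
        columns=[f"PF{j:02d}" for j in range(p)],
        values=values,
    )
    return pf, y


@dataclass(frozen=True)
class SyntheticCompoundConfig:
    """Synthetic compound table with class-respecting IC50 bands (uM)."""

    n: int = 200
    active_fraction: float = 0.5
    intermediate_fraction: float = 0.0
    scaffold_pool: tuple[str, ...] = SCAFFOLD_POOL
    active_range: tuple[float, float] = (1e-3, 1.0)
    inactive_range: tuple[float, float] = (10.0, 1e3)
    intermediate_range: tuple[float, float] = (1.5, 9.5)
    sar_mode: str = "random"  # random | scaffold
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sar_mode not in ("random", "scaffold"):
            raise ValueError("sar_mode must be 'random' or 'scaffold'")
        if not self.scaffold_pool:
            raise ValueError("scaffold pool must be non-empty")
        for smi in self.scaffold_pool:
            if Chem.MolFromSmiles(smi) is None:
                raise ValueError(f"invalid scaffold SMILES {smi!r}")
        if self.active_fraction + self.intermediate_fraction > 1.0:
            raise ValueError("class fractions exceed 1")
        if self.active_range[1] > 1.0 or self.inactive_range[0] < 10.0:
            raise ValueError("IC50 ranges must respect the class thresholds")


_CHAIN_ATOMS = ("C", "N", "O")


def _has_nitrogen(smiles: str) -> bool:
    return any(a.GetSymbol() == "N" for a in Chem.MolFromSmiles(smiles).GetAtoms())


def _decorate(
    scaffold: str, rng: np.random.Generator, chain_atoms: Sequence[str] = _CHAIN_ATOMS
) -> str:
    """Attach one to three short random chains at distinct ring positions.

    Rich enough decoration that a few hundred draws are essentially
    duplicate-free, as a curated (deduplicated) compound set would be.
    """
    mol = RWMol(Chem.MolFromSmiles(scaffold))
    carbons = [
        a.GetIdx()
        for a in mol.GetAtoms()
        if a.GetSymbol() == "C" and a.GetTotalNumHs() > 0
    ]
    if carbons:
        n_subst = min(int(rng.integers(1, 4)), len(carbons))
        anchors = rng.choice(carbons, size=n_subst, replace=False)
        for start in anchors:
            anchor = int(start)
            for _ in range(int(rng.integers(1, 4))):
                sym = str(rng.choice(list(chain_atoms)))
                new_idx = mol.AddAtom(Chem.Atom(sym))
                mol.AddBond(anchor, new_idx, Chem.BondType.SINGLE)
                anchor = new_idx
    out = mol.GetMol()
    Chem.SanitizeMol(out)
    return Chem.MolToSmiles(out)


def _loguniform(rng: np.random.Generator, lo: float, hi: float) -> float:
    return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


def make_synthetic_compounds(config: SyntheticCompoundConfig) -> pd.DataFrame:
    """Emit a compound table (id, smiles, ic50_uM) of decorated scaffolds.

    ``sar_mode='random'`` draws scaffolds independently of potency (no
    learnable structure-activity relationship — the null fixture).
    ``sar_mode='scaffold'`` plants a simple SAR: actives are built on
    nitrogen-containing scaffolds, inactives on nitrogen-free ones, and
    decoration chains avoid nitrogen, so activity is structurally
    recoverable by any fingerprint that sees the N atoms.
    """
    rng = np.random.default_rng(config.seed)
    n_active = int(round(config.n * config.active_fraction))
    n_inter = int(round(config.n * config.intermediate_fraction))
    n_inactive = config.n - n_active - n_inter
    classes = (
        [("active", config.active_range)] * n_active
        + [("inactive", config.inactive_range)] * n_inactive
        + [("intermediate", config.intermediate_range)] * n_inter
    )
    if config.sar_mode == "scaffold":
        pools = {
            "active": tuple(s for s in config.scaffold_pool if _has_nitrogen(s)),
            "inactive": tuple(s for s in config.scaffold_pool if not _has_nitrogen(s)),
        }
        pools["intermediate"] = config.scaffold_pool
        if not pools["active"] or not pools["inactive"]:
            raise ValueError(
                "scaffold SAR mode needs both N-containing and N-free scaffolds"
            )
        chain_atoms: tuple[str, ...] = ("C", "O")
    else:
        pools = {cls: config.scaffold_pool for cls in ("active", "inactive", "intermediate")}
        chain_atoms = _CHAIN_ATOMS
    rows = []
    for i, (cls, (lo, hi)) in enumerate(classes):
        scaffold = str(rng.choice(pools[cls]))
        rows.append(
            {
                "id": f"SYN{i:05d}",
                "smiles": _decorate(scaffold, rng, chain_atoms),
                "ic50_uM": _loguniform(rng, lo, hi),
            }
        )
    return pd.DataFrame(rows)


def write_synthetic_compounds(config: SyntheticCompoundConfig, path: str | Path) -> Path:
    path = Path(path)
    make_synthetic_compounds(config).to_csv(path, index=False)
    return path


@dataclass
class BenchmarkSeedResult:
    seed: int
    recovered_informative: int
    n_selected: int
    meta_test_mcc: float
    control_test_mcc: float
    meta_cv_mcc: float
    best_single_column_mcc: float


@dataclass
class BenchmarkReport:
    """Aggregated planted-recovery benchmark over a list of seeds."""

    per_seed: list[BenchmarkSeedResult]
    n_informative: int

    @property
    def median_recovered(self) -> float:
        return float(np.median([r.recovered_informative for r in self.per_seed]))

    @property
    def median_meta_test_mcc(self) -> float:
        return float(np.median([r.meta_test_mcc for r in self.per_seed]))

    @property
    def median_control_test_mcc(self) -> float:
        return float(np.median([r.control_test_mcc for r in self.per_seed]))

    @property
    def dominance_fraction(self) -> float:
        """Fraction of seeds where the meta CV MCC is within 0.02 of the
        best single PF column's MCC (the stacking-dominance check)."""
        wins = [
            r.meta_cv_mcc >= r.best_single_column_mcc - 0.02 for r in self.per_seed
        ]
        return float(np.mean(wins))

    def to_dict(self) -> dict:
        return {
            "n_informative": self.n_informative,
            "median_recovered": self.median_recovered,
            "median_meta_test_mcc": self.median_meta_test_mcc,
            "median_control_test_mcc": self.median_control_test_mcc,
            "dominance_fraction": self.dominance_fraction,
            "per_seed": [dict(r.__dict__) for r in self.per_seed],
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), sort_keys=True, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


#: benchmark GA numerics sized for a single-CPU run (see docs/methods.md)
BENCHMARK_GA = dict(
    population_size=10,
    generations=5,
    n_runs=2,
)
BENCHMARK_CV_FOLDS = 2


def _single_column_mccs(pf: PFMatrix, y: np.ndarray) -> np.ndarray:
    """MCC of thresholding each PF column at 0.5 — each column is itself a
    baseline classifier's prediction, so this is the per-baseline score."""
    out = np.zeros(pf.shape[1])
    for j in range(pf.shape[1]):
        pred = (pf.values[:, j] >= 0.5).astype(int)
        out[j] = mcc(ConfusionMatrix.from_predictions(y, pred))
    return out


def leakage_null_mcc(
    seed: int,
    n: int = 300,
    algorithms: tuple[str, ...] = ("LR", "PLS"),
    families: tuple[str, ...] = ("MACCS", "Estate"),
    cv_folds: int = 10,
    pf_mode: str = "oof",
) -> float:
    """Meta CV MCC of the stacked pipeline under permuted labels.

    Builds the real pipeline (synthetic compounds -> fingerprints ->
    baseline PFs -> meta RF) but with the activity labels randomly
    permuted. With the clean out-of-fold protocol (``pf_mode='oof'``)
    the meta learner's cross-validated MCC stays near zero; with leaky
    in-sample PFs (``pf_mode='insample'``) it is visibly inflated, which
    is exactly what this null is designed to expose.
    """
    from .baseline_models import (
        enumerate_grid,
        insample_confidences,
        oof_confidences,
        tune_baseline,
    )
    from .fingerprints import MinMaxScaler, FingerprintSpec, compute_fingerprint
    from .fingerprints import NATIVE_FAMILIES
    from .stacking_gasar import _cv_mcc_rf, assemble_pf_matrix

    rng = np.random.default_rng(seed)
    table = make_synthetic_compounds(
        SyntheticCompoundConfig(n=n, active_fraction=0.5, seed=seed)
    )
    # as in curation, drop duplicate structures: twin compounds let
    # memorizing baselines couple rows and inflate the null variance
    table = table.drop_duplicates(subset="smiles")
    y = np.array([1 if v <= 1.0 else 0 for v in table["ic50_uM"]])
    y = rng.permutation(y)  # sever any structure-activity relationship
    smiles = list(table["smiles"])
    ids = list(table["id"])
    cv = CVScheme(n_folds=cv_folds, seed=seed)
    pf_vectors = {}
    for spec in enumerate_grid(algorithms, families):
        backend = "native" if spec.fingerprint in NATIVE_FAMILIES else "hashed"
        mat = compute_fingerprint(
            smiles, FingerprintSpec(spec.fingerprint, backend=backend),
            ids=ids, allow_approximate=True,
        )
        scaled = MinMaxScaler().fit_transform(mat)
        if pf_mode == "oof":
            pf = oof_confidences(spec, scaled, y, cv, seed=seed)
        else:
            trained = tune_baseline(spec, scaled, y, cv, seed=seed)
            pf = insample_confidences(trained, scaled)
        pf_vectors[spec.name] = np.clip(pf, 0.0, 1.0)
    pf = assemble_pf_matrix(pf_vectors, ids=ids)
    # score the meta with folds independent of the PF folds: reusing the
    # same partition lets a fold's labels reach its meta-training rows
    # through the baselines (the classic stacking fold-reuse artifact)
    meta_cv = CVScheme(n_folds=cv_folds, seed=seed + 1)
    return _cv_mcc_rf(pf.values, y, 100, meta_cv, seed=seed)


def planted_recovery_benchmark(
    seed_list: Sequence[int],
    n_compounds: int = 400,
    n_test: int = 200,
    n_columns: int = 72,
    n_informative: int = 8,
    effect: float = 0.35,
    noise_sd: float = 0.1,
    ga_overrides: dict | None = None,
) -> BenchmarkReport:
    """Planted-recovery benchmark: GA-SAR vs the all-columns control.

    For each seed: generate train/test PF matrices with ``n_informative``
    planted columns, run GA-SAR, train the selected-subset meta-model and
    the control, and record the recovered-informative count, both test
    MCCs, the meta CV MCC and the best single-column MCC.
    """
    ga_kwargs = dict(BENCHMARK_GA)
    ga_kwargs.update(ga_overrides or {})
    results = []
    for seed in seed_list:
        informative = tuple(range(n_informative))
        train_cfg = SyntheticPFConfig(
            n_compounds=n_compounds,
            n_columns=n_columns,
            informative_columns=informative,
            effect=effect,
            noise_sd=noise_sd,
            seed=seed,
        )
        test_cfg = SyntheticPFConfig(
            n_compounds=n_test,
            n_columns=n_columns,
            informative_columns=informative,
            effect=effect,
            noise_sd=noise_sd,
            seed=seed + 100_000,
        )
        pf_train, y_train = make_synthetic_pf(train_cfg)
        pf_test, y_test = make_synthetic_pf(test_cfg)
        cv = CVScheme(n_folds=BENCHMARK_CV_FOLDS, seed=seed)
        config = GAConfig(seed=seed, cv=cv, **ga_kwargs)
        result = run_gasar(pf_train, y_train, config)
        control = control_result(pf_train, y_train, cv, seed=seed)

        informative_names = {pf_train.columns[i] for i in informative}
        recovered = len(informative_names & set(result.selected_columns))

        def test_mcc(res: GAResult) -> float:
            model = train_meta(pf_train, y_train, res, seed=seed)
            pred = predict_meta(model, pf_test)
            y_pred = (pred["label"] == "active").astype(int).to_numpy()
            return mcc(ConfusionMatrix.from_predictions(y_test, y_pred))

        # refit-scan CV MCC of the final subset = the meta CV MCC
        meta_cv = dict(result.cardinality_scan).get(
            len(result.selected_columns), result.best_fitness
        )
        results.append(
            BenchmarkSeedResult(
                seed=seed,
                recovered_informative=recovered,
                n_selected=len(result.selected_columns),
                meta_test_mcc=test_mcc(result),
                control_test_mcc=test_mcc(control),
                meta_cv_mcc=float(meta_cv),
                best_single_column_mcc=float(
                    _single_column_mccs(pf_train, y_train).max()
                ),
            )
        )
    return BenchmarkReport(per_seed=results, n_informative=n_informative)
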