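"""Stacked meta-learning over probabilistic features with GA-SAR selection.

The 72 baseline confidences form a per-compound probabilistic-feature
(PF) vector. A random-forest meta-predictor (mRF) is trained on either
all PF columns (control) or on an m-column subset, 5 <= m <= 20, chosen
by a genetic algorithm with a self-assessment report (GA-SAR):

* each chromosome carries one binary gene per PF column plus a 3-bit
  parametric gene decoding (modulo 5) to the mRF tree count in
  {20, 50, 100, 200, 500};
* infeasible chromosomes are repaired by randomly flipping the minimum
  number of genes back into the cardinality band;
* fitness is the cross-validated MCC of the mRF on the selected columns;
* the self-assessment report aggregates several independent GA runs:
  each column's frequency of appearing in a run's best chromosome,
  tie-broken by the mean fitness of all evaluated chromosomes that
  contained the column (a column that only ever rode in low-fitness
  chromosomes ranks below one that always co-occurred with signal);
* the final subset truncates that ranking at the cardinality whose
  refitted CV MCC is maximal; among indistinguishable cardinalities the
  largest is kept — when cross-validation cannot separate them, the
  stability-selection stance is to retain every consistently selected
  feature up to the cap rather than discard arbitrarily.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .baseline_models import CVScheme, StratificationError
from .metrics import ConfusionMatrix, mcc

N_ESTIMATORS_CHOICES = (20, 50, 100, 200, 500)
CARDINALITY_MIN = 5
CARDINALITY_MAX = 20


class ConfigurationError(ValueError):
    pass


class AlignmentError(ValueError):
    pass


@dataclass
class PFMatrix:
    """Compounds x probabilistic features, every value in [0, 1]."""

    ids: list[str]
    columns: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.ids), len(self.columns)):
            raise AlignmentError(
                f"PF matrix shape {self.values.shape} does not match "
                f"{len(self.ids)} ids x {len(self.columns)} columns"
            )
        if len(set(self.columns)) != len(self.columns):
            raise ValueError("duplicate PF column names")
        if self.values.size and (
            np.isnan(self.values).any()
            or self.values.min() < 0.0
            or self.values.max() > 1.0
        ):
            raise ValueError("PF values must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def select(self, columns: Sequence[str]) -> "PFMatrix":
        missing = [c for c in columns if c not in self.columns]
        if missing:
            raise KeyError(f"PF matrix is missing selected column(s): {missing}")
        idx = [self.columns.index(c) for c in columns]
        return PFMatrix(
            ids=list(self.ids), columns=list(columns), values=self.values[:, idx]
        )

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.values, columns=self.columns)
        frame.insert(0, "id", self.ids)
        return frame

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "PFMatrix":
        frame = pd.read_csv(path)
        ids = [str(v) for v in frame.iloc[:, 0]]
        return cls(
            ids=ids,
            columns=list(frame.columns[1:]),
            values=frame.iloc[:, 1:].to_numpy(dtype=float),
        )


def assemble_pf_matrix(
    pf_vectors: dict[str, np.ndarray], ids: Sequence[str]
) -> PFMatrix:
    """Concatenate aligned per-baseline PF vectors into one matrix.

    ``pf_vectors`` maps baseline name -> vector (one value per compound,
    same id order); column order is the mapping's (insertion) order,
    i.e. the enumeration order of the baseline grid.
    """
    ids = [str(i) for i in ids]
    columns = list(pf_vectors)
    lengths = {name: len(v) for name, v in pf_vectors.items()}
    if any(l != len(ids) for l in lengths.values()):
        raise AlignmentError(
            f"PF vector lengths {lengths} do not all match {len(ids)} compounds"
        )
    values = (
        np.column_stack([np.asarray(pf_vectors[c], dtype=float) for c in columns])
        if columns
        else np.zeros((len(ids), 0))
    )
    return PFMatrix(ids=ids, columns=columns, values=values)


def decode_param(param_bits: Sequence[int]) -> int:
    """3 bits -> mRF n_estimators; the bit value modulo 5 indexes the list."""
    if len(param_bits) != 3 or any(b not in (0, 1) for b in param_bits):
        raise ValueError(f"param_bits must be 3 bits, got {param_bits!r}")
    code = param_bits[0] * 4 + param_bits[1] * 2 + param_bits[2]
    return N_ESTIMATORS_CHOICES[code % len(N_ESTIMATORS_CHOICES)]


@dataclass
class Chromosome:
    """GA individual: one binary gene per PF column + 3 parametric bits."""

    bg: np.ndarray
    param_bits: tuple[int, int, int]
    fitness: float | None = None

    def __post_init__(self) -> None:
        self.bg = np.asarray(self.bg, dtype=np.int8)
        if not np.isin(self.bg, (0, 1)).all():
            raise ValueError("binary genes must be 0/1")

    @property
    def n_selected(self) -> int:
        return int(self.bg.sum())

    @property
    def n_estimators(self) -> int:
        return decode_param(self.param_bits)

    def key(self) -> tuple:
        return (self.bg.tobytes(), self.n_estimators)


def cardinality_bounds(n_columns: int) -> tuple[int, int]:
    """The feasible band [5, 20], clamped when fewer columns exist."""
    lo = min(CARDINALITY_MIN, n_columns)
    hi = min(CARDINALITY_MAX, n_columns)
    return lo, hi


def repair(chrom: Chromosome, rng: np.random.Generator) -> Chromosome:
    """Minimally restore the cardinality constraint.

    Below the band: randomly promote zeros; above: randomly demote ones.
    A feasible chromosome is returned unchanged, so the Hamming distance
    between input and output equals the deficit/excess exactly.
    """
    lo, hi = cardinality_bounds(len(chrom.bg))
    total = chrom.n_selected
    if lo <= total <= hi:
        return chrom
    bg = chrom.bg.copy()
    if total < lo:
        zeros = np.flatnonzero(bg == 0)
        flip = rng.choice(zeros, size=lo - total, replace=False)
        bg[flip] = 1
    else:
        ones = np.flatnonzero(bg == 1)
        flip = rng.choice(ones, size=total - hi, replace=False)
        bg[flip] = 0
    return Chromosome(bg=bg, param_bits=chrom.param_bits)


def _cv_mcc_rf(
    values: np.ndarray,
    y: np.ndarray,
    n_estimators: int,
    cv: CVScheme,
    seed: int,
) -> float:
    """Cross-validated MCC of an mRF on the given feature columns."""
    oof = np.zeros(len(y), dtype=int)
    for train_idx, test_idx in cv.splitter().split(values, y):
        if len(np.unique(y[train_idx])) < 2:
            raise StratificationError("degenerate fold: single-class training split")
        clf = RandomForestClassifier(
            n_estimators=n_estimators, random_state=seed, n_jobs=1
        )
        clf.fit(values[train_idx], y[train_idx])
        proba = clf.predict_proba(values[test_idx])[:, 1]
        oof[test_idx] = (proba >= 0.5).astype(int)
    return mcc(ConfusionMatrix.from_predictions(y, oof))


def fitness(
    chrom: Chromosome,
    pf_train: PFMatrix,
    y: np.ndarray,
    cv: CVScheme,
    seed: int = 0,
) -> float:
    """CV MCC of the mRF on the chromosome's selected columns."""
    lo, hi = cardinality_bounds(pf_train.shape[1])
    if not lo <= chrom.n_selected <= hi:
        raise ValueError("chromosome must be repaired before fitness evaluation")
    y = np.asarray(y).astype(int)
    cols = np.flatnonzero(chrom.bg == 1)
    return _cv_mcc_rf(pf_train.values[:, cols], y, chrom.n_estimators, cv, seed)


@dataclass(frozen=True)
class GAConfig:
    """GA-SAR numerics; all rates in [0, 1], population even."""

    population_size: int = 50
    generations: int = 100
    crossover_rate: float = 0.8
    mutation_rate: float = 1.0 / 75.0
    tournament_size: int = 3
    n_runs: int = 10
    seed: int = 0
    cv: CVScheme = field(default_factory=lambda: CVScheme(n_folds=10, seed=0))

    def __post_init__(self) -> None:
        if self.population_size < 4:
            raise ConfigurationError("population_size must be at least 4")
        if self.population_size % 2:
            raise ConfigurationError("population_size must be even for pairwise crossover")
        for name in ("crossover_rate", "mutation_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1]")
        if self.n_runs < 1:
            raise ConfigurationError("n_runs must be positive")


@dataclass
class GAResult:
    """Outcome of GA-SAR: the selected PF subset and its provenance."""

    selected_columns: list[str]
    n_estimators: int
    sar_frequencies: dict[str, float]
    best_fitness: float
    run_best: list[dict] = field(default_factory=list)
    fitness_trace: list[list[float]] = field(default_factory=list)
    cardinality_scan: list[tuple[int, float]] = field(default_factory=list)
    evaluated_cardinalities: list[int] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "selected_columns": self.selected_columns,
            "n_estimators": self.n_estimators,
            "sar_frequencies": self.sar_frequencies,
            "best_fitness": self.best_fitness,
            "run_best": self.run_best,
            "fitness_trace": self.fitness_trace,
            "cardinality_scan": [[k, v] for k, v in self.cardinality_scan],
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), sort_keys=True, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def _init_chromosome(n: int, rng: np.random.Generator) -> Chromosome:
    lo, hi = cardinality_bounds(n)
    m = int(rng.integers(lo, hi + 1))
    bg = np.zeros(n, dtype=np.int8)
    bg[rng.choice(n, size=m, replace=False)] = 1
    bits = tuple(int(b) for b in rng.integers(0, 2, size=3))
    return Chromosome(bg=bg, param_bits=bits)


def _tournament(pop: list[Chromosome], rng: np.random.Generator, k: int) -> Chromosome:
    idx = rng.integers(0, len(pop), size=k)
    best = max(idx, key=lambda i: pop[i].fitness)
    return pop[best]


def _uniform_crossover(
    a: Chromosome, b: Chromosome, rng: np.random.Generator
) -> tuple[Chromosome, Chromosome]:
    mask = rng.random(len(a.bg)) < 0.5
    bg1 = np.where(mask, a.bg, b.bg)
    bg2 = np.where(mask, b.bg, a.bg)
    pmask = rng.random(3) < 0.5
    p1 = tuple(int(x if m else y) for x, y, m in zip(a.param_bits, b.param_bits, pmask))
    p2 = tuple(int(y if m else x) for x, y, m in zip(a.param_bits, b.param_bits, pmask))
    return Chromosome(bg1, p1), Chromosome(bg2, p2)


def _mutate(chrom: Chromosome, rng: np.random.Generator, rate: float) -> Chromosome:
    bg = chrom.bg.copy()
    flips = rng.random(len(bg)) < rate
    bg[flips] = 1 - bg[flips]
    bits = list(chrom.param_bits)
    for i in range(3):
        if rng.random() < rate:
            bits[i] = 1 - bits[i]
    return Chromosome(bg=bg, param_bits=tuple(bits))


class _FitnessLedger:
    """Caches evaluations and accumulates per-column fitness statistics."""

    def __init__(self, pf: PFMatrix, y: np.ndarray, cv: CVScheme, seed: int):
        self.pf = pf
        self.y = y
        self.cv = cv
        self.seed = seed
        self.cache: dict[tuple, float] = {}
        self.col_fit_sum = np.zeros(pf.shape[1])
        self.col_fit_n = np.zeros(pf.shape[1])
        self.evaluated_cardinalities: list[int] = []

    def __call__(self, chrom: Chromosome) -> float:
        key = chrom.key()
        if key not in self.cache:
            self.cache[key] = fitness(chrom, self.pf, self.y, self.cv, seed=self.seed)
        fit = self.cache[key]
        # statistics count every (possibly repeated) evaluation request so
        # they reflect how often each column rode in the population
        sel = chrom.bg == 1
        self.col_fit_sum[sel] += fit
        self.col_fit_n[sel] += 1
        self.evaluated_cardinalities.append(chrom.n_selected)
        return fit

    def mean_column_fitness(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            out = self.col_fit_sum / self.col_fit_n
        return np.nan_to_num(out, nan=-np.inf)


def _run_single_ga(
    ledger: _FitnessLedger, config: GAConfig, rng: np.random.Generator
) -> tuple[Chromosome, list[float]]:
    n = ledger.pf.shape[1]
    pop = [repair(_init_chromosome(n, rng), rng) for _ in range(config.population_size)]
    for chrom in pop:
        chrom.fitness = ledger(chrom)
    best = max(pop, key=lambda c: c.fitness)
    trace = [best.fitness]
    for _ in range(config.generations):
        nxt: list[Chromosome] = []
        while len(nxt) < config.population_size:
            p1 = _tournament(pop, rng, config.tournament_size)
            p2 = _tournament(pop, rng, config.tournament_size)
            if rng.random() < config.crossover_rate:
                c1, c2 = _uniform_crossover(p1, p2, rng)
            else:
                c1 = Chromosome(p1.bg.copy(), p1.param_bits)
                c2 = Chromosome(p2.bg.copy(), p2.param_bits)
            for child in (c1, c2):
                child = repair(_mutate(child, rng, config.mutation_rate), rng)
                child.fitness = ledger(child)
                nxt.append(child)
        # elitism: best-so-far replaces the weakest child
        weakest = min(range(len(nxt)), key=lambda i: nxt[i].fitness)
        if best.fitness > nxt[weakest].fitness:
            nxt[weakest] = replace(best)
        pop = nxt[: config.population_size]
        gen_best = max(pop, key=lambda c: c.fitness)
        if gen_best.fitness > best.fitness:
            best = gen_best
        trace.append(best.fitness)
    return best, trace


def run_gasar(pf_train: PFMatrix, y: np.ndarray, config: GAConfig) -> GAResult:
    """Run GA-SAR and derive the final PF subset from the report.

    ``config.n_runs`` independent GA runs are aggregated into the
    self-assessment report (per-column selection frequency over the
    runs' best chromosomes). Columns are ranked by frequency, ties by
    mean fitness of the chromosomes that contained them, then by index;
    the ranking is truncated at the cardinality with the best refitted
    CV MCC (ties -> largest, see module docstring). The mRF tree count
    comes from the overall best chromosome.
    """
    y = np.asarray(y).astype(int)
    n = pf_train.shape[1]
    if n < 1:
        raise ConfigurationError("PF matrix has no columns")
    ledger = _FitnessLedger(pf_train, y, config.cv, seed=config.seed)
    master = np.random.default_rng(config.seed)
    run_bests: list[Chromosome] = []
    traces: list[list[float]] = []
    for _ in range(config.n_runs):
        rng = np.random.default_rng(master.integers(0, 2**31))
        best, trace = _run_single_ga(ledger, config, rng)
        run_bests.append(best)
        traces.append(trace)
    overall_best = max(run_bests, key=lambda c: c.fitness)

    freq = np.zeros(n)
    for chrom in run_bests:
        freq += chrom.bg
    freq /= config.n_runs
    tiebreak = ledger.mean_column_fitness()
    order = sorted(range(n), key=lambda i: (-freq[i], -tiebreak[i], i))

    lo, hi = cardinality_bounds(n)
    scan: list[tuple[int, float]] = []
    best_k, best_k_mcc = lo, -np.inf
    for k in range(lo, hi + 1):
        cols = np.array(sorted(order[:k]))
        score = _cv_mcc_rf(
            pf_train.values[:, cols], y, overall_best.n_estimators, config.cv,
            seed=config.seed,
        )
        scan.append((k, score))
        if score >= best_k_mcc:  # ties resolve to the larger cardinality
            best_k_mcc = score
            best_k = k
    selected_idx = sorted(order[:best_k])
    return GAResult(
        selected_columns=[pf_train.columns[i] for i in selected_idx],
        n_estimators=overall_best.n_estimators,
        sar_frequencies={pf_train.columns[i]: float(freq[i]) for i in range(n)},
        best_fitness=float(overall_best.fitness),
        run_best=[
            {
                "columns": [pf_train.columns[i] for i in np.flatnonzero(c.bg)],
                "n_estimators": c.n_estimators,
                "fitness": float(c.fitness),
            }
            for c in run_bests
        ],
        fitness_trace=[[float(v) for v in t] for t in traces],
        cardinality_scan=[(k, float(v)) for k, v in scan],
        evaluated_cardinalities=ledger.evaluated_cardinalities,
    )


def control_result(
    pf_train: PFMatrix, y: np.ndarray, cv: CVScheme, seed: int = 0
) -> GAResult:
    """The no-selection control: all PF columns, CV-tuned tree count."""
    y = np.asarray(y).astype(int)
    best_n, best_mcc = N_ESTIMATORS_CHOICES[0], -np.inf
    for n_est in N_ESTIMATORS_CHOICES:
        score = _cv_mcc_rf(pf_train.values, y, n_est, cv, seed=seed)
        if score > best_mcc:
            best_mcc = score
            best_n = n_est
    return GAResult(
        selected_columns=list(pf_train.columns),
        n_estimators=best_n,
        sar_frequencies={c: 1.0 for c in pf_train.columns},
        best_fitness=float(best_mcc),
    )


@dataclass
class MetaModel:
    """The fitted mRF restricted to the selected PF columns."""

    columns: list[str]
    n_estimators: int
    forest: RandomForestClassifier
    threshold: float = 0.5

    def predict(self, pf: PFMatrix) -> pd.DataFrame:
        sub = pf.select(self.columns)
        if sub.shape[0] == 0:
            return pd.DataFrame(columns=["id", "probability", "label"])
        proba = self.forest.predict_proba(sub.values)[:, 1]
        label = np.where(proba >= self.threshold, "active", "inactive")
        return pd.DataFrame({"id": sub.ids, "probability": proba, "label": label})


def train_meta(
    pf_train: PFMatrix, y: np.ndarray, result: GAResult, seed: int = 0
) -> MetaModel:
    """Fit the mRF on the GA-selected (or control) PF columns."""
    sub = pf_train.select(result.selected_columns)
    forest = RandomForestClassifier(
        n_estimators=result.n_estimators, random_state=seed, n_jobs=1
    )
    forest.fit(sub.values, np.asarray(y).astype(int))
    return MetaModel(
        columns=list(result.selected_columns),
        n_estimators=result.n_estimators,
        forest=forest,
    )


def predict_meta(model: MetaModel, pf_new: PFMatrix) -> pd.DataFrame:
    """Per-compound probability and class (probability >= 0.5 -> active)."""
    return model.predict(pf_new)


def feature_importance(
    model: MetaModel,
    pf: PFMatrix,
    y: np.ndarray,
    backend: str = "permutation",
    n_repeats: int = 10,
    seed: int = 0,
) -> pd.Series:
    """Per-column importance of the meta-model's inputs.

    ``permutation`` (native): mean MCC drop over ``n_repeats`` shuffles
    of each column. ``shap``: delegates to the optional shap package
    (mean |SHAP value| per column).
    """
    y = np.asarray(y).astype(int)
    sub = pf.select(model.columns)
    if backend == "permutation":
        rng = np.random.default_rng(seed)
        base_pred = (model.forest.predict_proba(sub.values)[:, 1] >= 0.5).astype(int)
        base = mcc(ConfusionMatrix.from_predictions(y, base_pred))
        drops = np.zeros(len(model.columns))
        for j in range(len(model.columns)):
            for _ in range(n_repeats):
                perm = sub.values.copy()
                perm[:, j] = rng.permutation(perm[:, j])
                pred = (model.forest.predict_proba(perm)[:, 1] >= 0.5).astype(int)
                drops[j] += base - mcc(ConfusionMatrix.from_predictions(y, pred))
        return pd.Series(drops / n_repeats, index=model.columns, name="mcc_drop")
    if backend == "shap":
        try:
            import shap
        except ImportError as exc:
            raise ConfigurationError(
                "the shap backend requires the optional 'shap' package"
            ) from exc
        explainer = shap.TreeExplainer(model.forest)
        sv = explainer.shap_values(sub.values)
        sv = sv[1] if isinstance(sv, list) else sv
        if sv.ndim == 3:
            sv = sv[:, :, 1]
        return pd.Series(
            np.abs(sv).mean(axis=0), index=model.columns, name="mean_abs_shap"
        )
    raise ConfigurationError(f"unknown importance backend {backend!r}")
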