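"""End-to-end training/prediction workflow and the model bundle format.

A *bundle* is a directory holding everything needed to reproduce a run:
fitted per-family scalers, the 72 (or fewer) tuned baseline models, the
GA-SAR result, the fitted meta-model, the PF training matrix and a JSON
manifest of configuration, seeds and package versions.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import joblib
import numpy as np
import pandas as pd

from . import __version__
from .baseline_models import (
    ALGORITHMS,
    FINGERPRINTS,
    BaselineModelSpec,
    CVScheme,
    TrainedBaseline,
    enumerate_grid,
    insample_confidences,
    oof_confidences,
    test_confidences,
    tune_baseline,
)
from .chem_io import LabeledDataset, standardize_structure
from .fingerprints import (
    NATIVE_FAMILIES,
    FingerprintMatrix,
    FingerprintSpec,
    MinMaxScaler,
    compute_fingerprint,
)
from .metrics import MetricsReport
from .stacking_gasar import (
    GAConfig,
    GAResult,
    MetaModel,
    PFMatrix,
    assemble_pf_matrix,
    control_result,
    predict_meta,
    run_gasar,
    train_meta,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrainConfig:
    """Everything that determines a training run."""

    algorithms: tuple[str, ...] = ALGORITHMS
    fingerprints: tuple[str, ...] = FINGERPRINTS
    cv_folds: int = 10
    seed: int = 0
    pf_mode: str = "oof"  # oof | insample
    use_ga: bool = True  # False -> all-columns control meta-model
    ga_population: int = 50
    ga_generations: int = 100
    ga_runs: int = 10
    ga_cv_folds: int = 10
    threshold: float = 0.5
    canonical_tautomer: bool = True

    def __post_init__(self) -> None:
        if self.pf_mode not in ("oof", "insample"):
            raise ValueError("pf_mode must be 'oof' or 'insample'")

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        text = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()[:16]


def _fingerprint_spec(name: str) -> FingerprintSpec:
    backend = "native" if name in NATIVE_FAMILIES else "hashed"
    return FingerprintSpec(name=name, backend=backend)


def _featurize(
    smiles: list[str], ids: list[str], families: tuple[str, ...]
) -> dict[str, FingerprintMatrix]:
    out = {}
    for name in families:
        spec = _fingerprint_spec(name)
        out[name] = compute_fingerprint(
            smiles, spec, ids=ids, allow_approximate=True
        )
    return out


@dataclass
class TrainedBundle:
    """In-memory handle on a trained StackPR pipeline."""

    config: TrainConfig
    scalers: dict[str, MinMaxScaler]
    baselines: dict[str, TrainedBaseline]
    ga_result: GAResult
    meta: MetaModel
    pf_train: PFMatrix
    column_order: list[str] = field(default_factory=list)

    def predict_smiles(self, smiles: list[str], ids: list[str] | None = None) -> pd.DataFrame:
        """Standardize, featurize, score through all baselines and the meta."""
        if ids is None:
            ids = [f"Q{i}" for i in range(len(smiles))]
        std = [
            standardize_structure(s, canonical_tautomer=self.config.canonical_tautomer)
            for s in smiles
        ]
        mats = _featurize(std, list(ids), self.config.fingerprints)
        pf_vectors: dict[str, np.ndarray] = {}
        for name in self.column_order:
            trained = self.baselines[name]
            family = trained.spec.fingerprint
            scaled = self.scalers[family].transform(mats[family])
            pf_vectors[name] = test_confidences(trained, scaled)
        pf = assemble_pf_matrix(pf_vectors, ids=list(ids))
        return predict_meta(self.meta, pf)

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        (path / "baselines").mkdir(parents=True, exist_ok=True)
        (path / "scalers").mkdir(exist_ok=True)
        for name, trained in self.baselines.items():
            joblib.dump(trained, path / "baselines" / f"{name}.joblib")
        for family, scaler in self.scalers.items():
            joblib.dump(scaler, path / "scalers" / f"{family}.joblib")
        joblib.dump(self.meta, path / "meta.joblib")
        self.ga_result.to_json(path / "garesult.json")
        self.pf_train.to_csv(path / "pf_train.csv")
        manifest = {
            "stackpr_version": __version__,
            "python": sys.version.split()[0],
            "config": self.config.to_dict(),
            "config_hash": self.config.config_hash(),
            "column_order": self.column_order,
            "created": time.strftime("%Y-%m-%dT%H:%M:%S"),
        }
        (path / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        return path

    @classmethod
    def load(cls, path: str | Path) -> "TrainedBundle":
        path = Path(path)
        manifest = json.loads((path / "manifest.json").read_text())
        config = TrainConfig(
            **{
                **manifest["config"],
                "algorithms": tuple(manifest["config"]["algorithms"]),
                "fingerprints": tuple(manifest["config"]["fingerprints"]),
            }
        )
        baselines = {
            p.stem: joblib.load(p) for p in sorted((path / "baselines").glob("*.joblib"))
        }
        scalers = {
            p.stem: joblib.load(p) for p in sorted((path / "scalers").glob("*.joblib"))
        }
        meta = joblib.load(path / "meta.joblib")
        ga = json.loads((path / "garesult.json").read_text())
        ga_result = GAResult(
            selected_columns=ga["selected_columns"],
            n_estimators=ga["n_estimators"],
            sar_frequencies=ga["sar_frequencies"],
            best_fitness=ga["best_fitness"],
            run_best=ga.get("run_best", []),
            fitness_trace=ga.get("fitness_trace", []),
            cardinality_scan=[tuple(kv) for kv in ga.get("cardinality_scan", [])],
        )
        pf_train = PFMatrix.from_csv(path / "pf_train.csv")
        return cls(
            config=config,
            scalers=scalers,
            baselines=baselines,
            ga_result=ga_result,
            meta=meta,
            pf_train=pf_train,
            column_order=manifest["column_order"],
        )


def train_pipeline(train: LabeledDataset, config: TrainConfig) -> TrainedBundle:
    """Featurize, tune the baseline grid, assemble PFs, select, train meta."""
    t0 = time.time()
    smiles = train.smiles
    ids = train.ids
    y = train.y
    cv = CVScheme(n_folds=config.cv_folds, seed=config.seed)

    logger.info("featurizing %d compounds x %d families", len(ids), len(config.fingerprints))
    mats = _featurize(smiles, ids, config.fingerprints)
    scalers: dict[str, MinMaxScaler] = {}
    scaled: dict[str, FingerprintMatrix] = {}
    for family, mat in mats.items():
        scaler = MinMaxScaler().fit(mat)
        scalers[family] = scaler
        scaled[family] = scaler.transform(mat)

    specs = enumerate_grid(config.algorithms, config.fingerprints)
    logger.info("tuning %d baseline models", len(specs))
    baselines: dict[str, TrainedBaseline] = {}
    pf_vectors: dict[str, np.ndarray] = {}
    for spec in specs:
        X = scaled[spec.fingerprint]
        trained = tune_baseline(spec, X, y, cv, seed=config.seed)
        baselines[spec.name] = trained
        if config.pf_mode == "oof":
            pf_vectors[spec.name] = np.clip(
                oof_confidences(trained, X, y, cv, seed=config.seed), 0.0, 1.0
            )
        else:
            pf_vectors[spec.name] = np.clip(insample_confidences(trained, X), 0.0, 1.0)
        logger.info("  %-16s cv MCC %.3f params %s", spec.name, trained.cv_mcc, trained.chosen_params)

    pf_train = assemble_pf_matrix(pf_vectors, ids=ids)
    ga_cv = CVScheme(n_folds=config.ga_cv_folds, seed=config.seed)
    if config.use_ga:
        ga_config = GAConfig(
            population_size=config.ga_population,
            generations=config.ga_generations,
            n_runs=config.ga_runs,
            seed=config.seed,
            cv=ga_cv,
        )
        logger.info("running GA-SAR on %d PF columns", pf_train.shape[1])
        ga_result = run_gasar(pf_train, y, ga_config)
    else:
        logger.info("control mode: all %d PF columns", pf_train.shape[1])
        ga_result = control_result(pf_train, y, ga_cv, seed=config.seed)
    meta = train_meta(pf_train, y, ga_result, seed=config.seed)
    meta.threshold = config.threshold
    logger.info("training complete in %.1f s", time.time() - t0)
    return TrainedBundle(
        config=config,
        scalers=scalers,
        baselines=baselines,
        ga_result=ga_result,
        meta=meta,
        pf_train=pf_train,
        column_order=[s.name for s in specs],
    )


def evaluate_bundle(bundle: TrainedBundle, data: LabeledDataset) -> MetricsReport:
    """Score a labeled dataset through the bundle and report metrics."""
    pred = bundle.predict_smiles(data.smiles, ids=data.ids)
    return MetricsReport.from_scores(
        data.y, pred["probability"].to_numpy(), threshold=bundle.meta.threshold
    )
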