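"""The 6 x 12 grid of baseline classifiers and their probabilistic features.

Six learners (LR, PLS, KNN, SVM, ET, RF) are trained on each of the
twelve fingerprint families, giving 72 baseline models. Hyperparameters
are tuned by stratified tenfold cross-validation on MCC over fixed small
grids (ET/RF n_estimators, LR and SVM C); KNN and PLS use library
defaults. Each baseline contributes one probabilistic feature (PF) per
compound — its predicted confidence of activity — via the stacked-
generalization protocol: out-of-fold predictions on the training set
(shared folds across all 72 models) and full-refit predictions on test
compounds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import ExtraTreesClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, cross_val_predict
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .fingerprints import FAMILY_WIDTHS, FingerprintMatrix
from .metrics import ConfusionMatrix, MetricsReport, mcc

ALGORITHMS = ("LR", "PLS", "KNN", "SVM", "ET", "RF")
FINGERPRINTS = tuple(sorted(FAMILY_WIDTHS))

#: hyperparameter search grids; empty = library defaults
GRIDS: dict[str, dict[str, list]] = {
    "ET": {"n_estimators": [20, 50, 100, 200, 500]},
    "KNN": {},
    "LR": {"C": [0.001, 0.01, 0.1, 1, 10, 100]},
    "PLS": {},
    "RF": {"n_estimators": [20, 50, 100, 200, 500]},
    "SVM": {"C": [1, 2, 4, 8, 16, 32]},
}


class StratificationError(ValueError):
    """A cross-validation fold would contain a single class."""


class PLSBinaryClassifier(BaseEstimator, ClassifierMixin):
    """Partial-least-squares regression used as a binary classifier.

    Regresses on the 0/1 labels with the default two components; the
    clamped regression output is the predicted confidence of the
    positive class and 0.5 is the decision threshold.
    """

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit(self, X, y):
        y = np.asarray(y, dtype=float)
        self.classes_ = np.array([0, 1])
        n_comp = min(self.n_components, np.asarray(X).shape[1], len(y) - 1)
        self.pls_ = PLSRegression(n_components=max(1, n_comp))
        self.pls_.fit(X, y)
        return self

    def predict_proba(self, X):
        raw = np.clip(self.pls_.predict(X).ravel(), 0.0, 1.0)
        return np.column_stack([1.0 - raw, raw])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


@dataclass(frozen=True)
class BaselineModelSpec:
    """One (algorithm, fingerprint) cell of the baseline grid."""

    algorithm: str
    fingerprint: str

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if self.fingerprint not in FAMILY_WIDTHS:
            raise ValueError(f"unknown fingerprint {self.fingerprint!r}")

    @property
    def name(self) -> str:
        return f"{self.algorithm}-{self.fingerprint}"

    @property
    def grid(self) -> dict[str, list]:
        return GRIDS[self.algorithm]


def enumerate_grid(
    algorithms: Sequence[str] = ALGORITHMS,
    fingerprints: Sequence[str] = FINGERPRINTS,
) -> list[BaselineModelSpec]:
    """All (algorithm, fingerprint) cells, in fixed enumeration order.

    Order is algorithm-major over the canonical tuples, so the full grid
    always enumerates the same 72 names in the same sequence.
    """
    return [
        BaselineModelSpec(algorithm=a, fingerprint=f)
        for a in algorithms
        for f in fingerprints
    ]


@dataclass(frozen=True)
class CVScheme:
    """Shared stratified k-fold scheme (default tenfold)."""

    n_folds: int = 10
    seed: int = 0
    stratified: bool = True

    def splitter(self) -> StratifiedKFold:
        if not self.stratified:
            from sklearn.model_selection import KFold

            return KFold(n_splits=self.n_folds, shuffle=True, random_state=self.seed)
        return StratifiedKFold(n_splits=self.n_folds, shuffle=True, random_state=self.seed)

    def check(self, y: np.ndarray) -> None:
        y = np.asarray(y)
        counts = np.bincount(y.astype(int), minlength=2)
        if self.stratified and counts.min() < self.n_folds:
            raise StratificationError(
                f"minority class has {counts.min()} samples, fewer than "
                f"{self.n_folds} folds"
            )


def make_estimator(algorithm: str, seed: int = 0, **params):
    """Instantiate the scikit-learn estimator for one algorithm.

    SVM uses Platt-calibrated probabilities (fitted inside each training
    fold by the library); PLS uses the clamped-regression wrapper.
    """
    if algorithm == "LR":
        return LogisticRegression(max_iter=5000, random_state=seed, **params)
    if algorithm == "PLS":
        return PLSBinaryClassifier(**params)
    if algorithm == "KNN":
        return KNeighborsClassifier(**params)
    if algorithm == "SVM":
        return SVC(probability=True, random_state=seed, **params)
    if algorithm == "ET":
        return ExtraTreesClassifier(random_state=seed, n_jobs=1, **params)
    if algorithm == "RF":
        return RandomForestClassifier(random_state=seed, n_jobs=1, **params)
    raise ValueError(f"unknown algorithm {algorithm!r}")


@dataclass
class TrainedBaseline:
    """A tuned, fully refitted baseline model."""

    spec: BaselineModelSpec
    model: object
    chosen_params: dict
    cv_mcc: float
    cv_report: MetricsReport | None = None
    grid_trace: list[tuple[dict, float]] = field(default_factory=list)

    def predict_confidence(self, X: np.ndarray | FingerprintMatrix) -> np.ndarray:
        values = X.values if isinstance(X, FingerprintMatrix) else np.asarray(X)
        n_expected = self.model.n_features_in_ if hasattr(self.model, "n_features_in_") else None
        if n_expected is not None and values.shape[1] != n_expected:
            raise ValueError(
                f"{self.spec.name}: feature width {values.shape[1]} does not "
                f"match training width {n_expected}"
            )
        if values.shape[0] == 0:
            return np.zeros(0)
        return self.model.predict_proba(values)[:, 1]


def _as_values(X) -> np.ndarray:
    return X.values if isinstance(X, FingerprintMatrix) else np.asarray(X, dtype=float)


def _cv_scores(estimator, X, y, cv: CVScheme) -> np.ndarray:
    return cross_val_predict(
        estimator, X, y, cv=cv.splitter(), method="predict_proba", n_jobs=1
    )[:, 1]


def tune_baseline(
    spec: BaselineModelSpec,
    X: np.ndarray | FingerprintMatrix,
    y: np.ndarray,
    cv: CVScheme,
    seed: int = 0,
) -> TrainedBaseline:
    """Grid-search by cross-validated MCC, then refit on all rows.

    Grid points are evaluated in ascending parameter order and selection
    is by strict improvement, so ties resolve to the smaller (simpler)
    value deterministically.
    """
    values = _as_values(X)
    y = np.asarray(y).astype(int)
    cv.check(y)
    grid = spec.grid
    trace: list[tuple[dict, float]] = []
    best_params: dict = {}
    best_mcc = -np.inf
    candidates = [{}]
    if grid:
        (pname, pvals), = grid.items()
        candidates = [{pname: v} for v in sorted(pvals)]
    for params in candidates:
        est = make_estimator(spec.algorithm, seed=seed, **params)
        scores = _cv_scores(est, values, y, cv)
        cm = ConfusionMatrix.from_predictions(y, (scores >= 0.5).astype(int))
        score = mcc(cm)
        trace.append((params, score))
        if score > best_mcc:
            best_mcc = score
            best_params = params
    final = make_estimator(spec.algorithm, seed=seed, **best_params)
    final.fit(values, y)
    return TrainedBaseline(
        spec=spec,
        model=final,
        chosen_params=best_params,
        cv_mcc=best_mcc,
        grid_trace=trace,
    )


def oof_confidences(
    trained_or_spec,
    X: np.ndarray | FingerprintMatrix,
    y: np.ndarray,
    cv: CVScheme,
    seed: int = 0,
) -> np.ndarray:
    """Out-of-fold predicted confidences, one per training compound.

    Each compound's PF comes from the fold model that did not train on
    it; the same CV scheme must be shared by all baseline models.
    """
    values = _as_values(X)
    y = np.asarray(y).astype(int)
    cv.check(y)
    if isinstance(trained_or_spec, TrainedBaseline):
        algorithm = trained_or_spec.spec.algorithm
        params = trained_or_spec.chosen_params
    else:
        algorithm = trained_or_spec.algorithm
        params = {}
    est = make_estimator(algorithm, seed=seed, **params)
    return _cv_scores(est, values, y, cv)


def insample_confidences(trained: TrainedBaseline, X) -> np.ndarray:
    """In-sample confidences from the refitted model (leaky alternative)."""
    return trained.predict_confidence(X)


def test_confidences(trained: TrainedBaseline, X_test) -> np.ndarray:
    """Confidences for new compounds from the full-training refit."""
    return trained.predict_confidence(X_test)
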