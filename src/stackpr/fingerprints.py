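"""Molecular fingerprint featurization and 0-1 normalization.

Twelve fingerprint families are supported, each at its conventional
width. Four have exact native RDKit backends:

====== ===== ==========================================================
family width backend
====== ===== ==========================================================
MACCS   166  MACCS structural keys (RDKit, key 0 unused and dropped)
Circle 1024  circular/Morgan fingerprint, radius 2, hashed to 1024 bits
AP2D    780  atom pairs at topological distances, hashed to 780 bits
Estate   79  E-state atom-type presence vector (79 types)
====== ===== ==========================================================

The remaining eight families (CKD, CKDExt, CKDGraph, Hybrid, FP4, FP4C,
PubChem, KR) are defined by the CDK/PaDEL Java toolchain (path hashes or
published SMARTS key lists). They can be supplied as precomputed CSV
tables (``backend='precomputed'``), or computed as deterministic hashed
*approximations* at the exact conventional widths
(``backend='hashed'``): path fingerprints for the CKD variants, feature-
and substructure-hashed Morgan variants for the keyed families. The
approximations preserve width, value kind (FP4C is count-valued, the
rest binary) and determinism, not bit-for-bit key identity; the stacking
layer downstream is agnostic to which backend produced a matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import MACCSkeys, rdFingerprintGenerator
from rdkit.Chem.EState import Fingerprinter as _EStateFP
from sklearn.preprocessing import MinMaxScaler as _SkMinMax

from .chem_io import SmilesParseError

FAMILY_WIDTHS: dict[str, int] = {
    "AP2D": 780,
    "Circle": 1024,
    "CKD": 1024,
    "CKDExt": 1024,
    "CKDGraph": 1024,
    "Estate": 79,
    "FP4": 307,
    "FP4C": 307,
    "Hybrid": 1024,
    "KR": 4860,
    "MACCS": 166,
    "PubChem": 881,
}

#: families with an exact native RDKit implementation
NATIVE_FAMILIES = ("AP2D", "Circle", "Estate", "MACCS")
#: families available natively only as hashed approximations
APPROXIMATE_FAMILIES = tuple(sorted(set(FAMILY_WIDTHS) - set(NATIVE_FAMILIES)))
#: count-valued families (all others are binary 0/1)
COUNT_FAMILIES = ("FP4C",)


class CapabilityError(ValueError):
    """A native exact backend is not available for the requested family."""


class SchemaError(ValueError):
    """A fingerprint table does not match its declared family."""


@dataclass(frozen=True)
class FingerprintSpec:
    """One fingerprint family and the backend that produces it."""

    name: str
    backend: str = "native"  # native | hashed | precomputed

    def __post_init__(self) -> None:
        if self.name not in FAMILY_WIDTHS:
            raise ValueError(
                f"unknown fingerprint family {self.name!r}; "
                f"known: {sorted(FAMILY_WIDTHS)}"
            )
        if self.backend not in ("native", "hashed", "precomputed"):
            raise ValueError(f"unknown backend {self.backend!r}")

    @property
    def n_features(self) -> int:
        return FAMILY_WIDTHS[self.name]

    @property
    def is_binary(self) -> bool:
        return self.name not in COUNT_FAMILIES


@dataclass
class FingerprintMatrix:
    """Compounds x features for one fingerprint family."""

    spec: FingerprintSpec
    ids: list[str]
    values: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        if self.values.shape != (len(self.ids), self.spec.n_features):
            raise SchemaError(
                f"{self.spec.name}: expected shape "
                f"({len(self.ids)}, {self.spec.n_features}), got {self.values.shape}"
            )
        if np.isnan(self.values).any():
            raise ValueError("fingerprint matrix contains NaN")
        if (self.values < 0).any():
            raise ValueError("fingerprint values must be non-negative")
        if self.spec.is_binary and not self.normalized:
            if not np.isin(self.values, (0.0, 1.0)).all():
                raise SchemaError(
                    f"{self.spec.name} is a binary family but the matrix "
                    "contains values other than 0/1"
                )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        cols = [f"{self.spec.name}_{i}" for i in range(self.spec.n_features)]
        frame = pd.DataFrame(self.values, columns=cols)
        frame.insert(0, "id", self.ids)
        return frame

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def _mols_from_smiles(smiles_list: Sequence[str]) -> list[Chem.Mol]:
    mols = []
    bad = []
    for smi in smiles_list:
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            bad.append(smi)
        else:
            mols.append(mol)
    if bad:
        raise SmilesParseError(f"unparseable SMILES: {bad[:10]}")
    return mols


def _fold_counts(pairs: dict[int, int], width: int) -> np.ndarray:
    row = np.zeros(width)
    for code, count in pairs.items():
        row[code % width] += count
    return row


def _native_row(mol: Chem.Mol, name: str) -> np.ndarray:
    if name == "MACCS":
        bv = MACCSkeys.GenMACCSKeys(mol)  # 167 bits, bit 0 never set
        arr = np.zeros(167)
        arr[list(bv.GetOnBits())] = 1.0
        return arr[1:]
    if name == "Circle":
        gen = _generators.setdefault(
            "Circle", rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=1024)
        )
        return gen.GetFingerprintAsNumPy(mol).astype(float)
    if name == "AP2D":
        gen = _generators.setdefault(
            "AP2D", rdFingerprintGenerator.GetAtomPairGenerator(fpSize=780)
        )
        return gen.GetFingerprintAsNumPy(mol).astype(float)
    if name == "Estate":
        counts, _sums = _EStateFP.FingerprintMol(mol)
        return (np.asarray(counts) > 0).astype(float)
    raise AssertionError(name)


_generators: dict[str, object] = {}


def _hashed_row(mol: Chem.Mol, name: str) -> np.ndarray:
    width = FAMILY_WIDTHS[name]
    if name in ("CKD", "CKDExt", "CKDGraph"):
        # path fingerprints, search depth 8; CKD = linear paths,
        # CKDExt additionally branched subgraphs (ring-sensitive),
        # CKDGraph ignores bond orders (connectivity only)
        bv = Chem.RDKFingerprint(
            mol,
            maxPath=8,
            fpSize=width,
            branchedPaths=(name == "CKDExt"),
            useBondOrder=(name != "CKDGraph"),
        )
        arr = np.zeros(width)
        arr[list(bv.GetOnBits())] = 1.0
        return arr
    if name == "Hybrid":
        # hybridization-sensitive paths: atom invariants carry element + hybridization
        inv = [
            int(a.GetAtomicNum()) * 16 + int(a.GetHybridization()) for a in mol.GetAtoms()
        ]
        bv = Chem.RDKFingerprint(mol, maxPath=8, fpSize=width, atomInvariants=inv)
        arr = np.zeros(width)
        arr[list(bv.GetOnBits())] = 1.0
        return arr
    if name in ("FP4", "FP4C"):
        # functional-group environments: feature-typed circular substructures
        gen = _generators.setdefault(
            "FP4",
            rdFingerprintGenerator.GetMorganGenerator(
                radius=1,
                fpSize=307,
                atomInvariantsGenerator=rdFingerprintGenerator.GetMorganFeatureAtomInvGen(),
            ),
        )
        counts = gen.GetCountFingerprintAsNumPy(mol).astype(float)
        return counts if name == "FP4C" else (counts > 0).astype(float)
    if name == "PubChem":
        gen = _generators.setdefault(
            "PubChem", rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=881)
        )
        return gen.GetFingerprintAsNumPy(mol).astype(float)
    if name == "KR":
        gen = _generators.setdefault(
            "KR", rdFingerprintGenerator.GetMorganGenerator(radius=3, fpSize=4860)
        )
        return gen.GetFingerprintAsNumPy(mol).astype(float)
    raise AssertionError(name)


def compute_fingerprint(
    smiles_list: Sequence[str],
    spec: FingerprintSpec,
    ids: Sequence[str] | None = None,
    allow_approximate: bool = False,
) -> FingerprintMatrix:
    """Compute one fingerprint family for a list of (standardized) SMILES.

    ``spec.backend='native'`` requires an exact implementation; families
    without one raise :class:`CapabilityError` unless
    ``allow_approximate=True`` (or ``backend='hashed'``), which enables
    the documented hashed approximation at the same width.
    """
    if spec.backend == "precomputed":
        raise ValueError("use load_precomputed_fingerprints for precomputed backends")
    name = spec.name
    if name in APPROXIMATE_FAMILIES and spec.backend == "native" and not allow_approximate:
        raise CapabilityError(
            f"{name} has no exact native implementation; supply a precomputed "
            "table (backend='precomputed') or opt into the hashed "
            "approximation (backend='hashed' / allow_approximate=True)"
        )
    mols = _mols_from_smiles(smiles_list)
    rower = _native_row if name in NATIVE_FAMILIES else _hashed_row
    rows = [rower(mol, name) for mol in mols]
    values = np.vstack(rows) if rows else np.zeros((0, spec.n_features))
    if ids is None:
        ids = [str(i) for i in range(len(smiles_list))]
    return FingerprintMatrix(spec=spec, ids=list(ids), values=values)


def load_precomputed_fingerprints(
    path: str | Path, spec: FingerprintSpec
) -> FingerprintMatrix:
    """Load and validate a precomputed fingerprint CSV (id column + bits).

    PaDEL-style output is accepted: the first column (named ``id`` or
    ``Name``) identifies the compound and the remaining columns are the
    family's features, which must number exactly ``spec.n_features``.
    """
    frame = pd.read_csv(path)
    id_col = frame.columns[0]
    if id_col.lower() not in ("id", "name"):
        raise SchemaError(f"first column must be the compound id, got {id_col!r}")
    feats = frame.columns[1:]
    if len(feats) != spec.n_features:
        raise SchemaError(
            f"{spec.name} expects {spec.n_features} feature columns, "
            f"file has {len(feats)}"
        )
    values = frame[feats].to_numpy(dtype=float)
    ids = [str(v) for v in frame[id_col]]
    return FingerprintMatrix(spec=spec, ids=ids, values=values)


@dataclass
class MinMaxScaler:
    """Per-column 0-1 scaling fitted on training rows only.

    Backed by scikit-learn's min-max scaler with clipping: transformed
    training values lie in [0, 1], out-of-range test values are clipped,
    and constant columns map to 0.
    """

    _scaler: _SkMinMax | None = field(default=None, repr=False)

    def fit(self, train: FingerprintMatrix) -> "MinMaxScaler":
        sk = _SkMinMax(clip=True)
        sk.fit(train.values)
        # constant columns: force (x - min) * 1 -> 0 (sklearn already uses
        # scale 1 for zero-range columns, which yields exactly 0)
        self._scaler = sk
        return self

    def transform(self, matrix: FingerprintMatrix) -> FingerprintMatrix:
        if self._scaler is None:
            raise RuntimeError("MinMaxScaler is not fitted")
        if matrix.values.shape[0] == 0:
            values = matrix.values
        else:
            values = self._scaler.transform(matrix.values)
        return FingerprintMatrix(
            spec=matrix.spec, ids=list(matrix.ids), values=values, normalized=True
        )

    def fit_transform(self, train: FingerprintMatrix) -> FingerprintMatrix:
        return self.fit(train).transform(train)
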