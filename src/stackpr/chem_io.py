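"""Compound ingestion, standardization, activity labelling and splitting.

Curation follows common ChEMBL practice for IC50-based classification:
structures are salt-stripped to the largest organic fragment and tautomer-
canonicalized, duplicate structures are merged on the geometric-mean IC50,
and compounds are labelled active (IC50 <= 1 uM), inactive (IC50 >= 10 uM)
or intermediate (strictly between, excluded from modelling).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem.MolStandardize import rdMolStandardize

logger = logging.getLogger(__name__)
RDLogger.DisableLog("rdApp.*")

ACTIVE = "active"
INACTIVE = "inactive"
INTERMEDIATE = "intermediate"

ACTIVE_MAX_UM = 1.0  # IC50 <= 1 uM  -> active
INACTIVE_MIN_UM = 10.0  # IC50 >= 10 uM -> inactive


class InputError(ValueError):
    """Malformed or empty input data."""


class ConfigurationError(ValueError):
    """Invalid configuration (missing columns, bad options...)."""


class SmilesParseError(ValueError):
    """A SMILES string could not be parsed."""


class SplitError(ValueError):
    """A requested split cannot be realized."""


@dataclass(frozen=True)
class CompoundRecord:
    """One molecule: identifier, SMILES and optional bioactivity.

    ``ic50`` is always in uM (the canonical internal unit). When both
    ``ic50`` and ``label`` are present they must agree with the
    thresholding rule.
    """

    id: str
    smiles: str
    ic50: float | None = None
    label: str | None = None

    def __post_init__(self) -> None:
        if self.ic50 is not None:
            if not math.isfinite(self.ic50) or self.ic50 <= 0:
                raise ValueError(f"ic50 must be a positive finite value, got {self.ic50!r}")
        if self.label is not None:
            if self.label not in (ACTIVE, INACTIVE, INTERMEDIATE):
                raise ValueError(f"unknown label {self.label!r}")
            if self.ic50 is not None and assign_activity_label(self.ic50) != self.label:
                raise ValueError(
                    f"label {self.label!r} disagrees with ic50={self.ic50} uM"
                )

    def with_label_from_ic50(self) -> "CompoundRecord":
        if self.ic50 is None:
            raise ValueError(f"record {self.id} has no IC50 to derive a label from")
        return replace(self, label=assign_activity_label(self.ic50))


@dataclass
class ParsedTable:
    """Records parsed from a compound table plus the drop bookkeeping.

    Iterates over the kept records, so it can be used wherever a plain
    collection of :class:`CompoundRecord` is expected.
    """

    records: list[CompoundRecord]
    n_dropped: int = 0
    dropped_ids: list[str] = field(default_factory=list)

    def __iter__(self) -> Iterator[CompoundRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, i):
        return self.records[i]


def assign_activity_label(ic50_um: float) -> str:
    """Label from IC50 in uM: <=1 active, >=10 inactive, between intermediate."""
    if not math.isfinite(ic50_um) or ic50_um <= 0:
        raise ValueError(f"IC50 must be positive and finite, got {ic50_um!r}")
    if ic50_um <= ACTIVE_MAX_UM:
        return ACTIVE
    if ic50_um >= INACTIVE_MIN_UM:
        return INACTIVE
    return INTERMEDIATE


_tautomer_enumerator: rdMolStandardize.TautomerEnumerator | None = None


def _get_tautomer_enumerator() -> rdMolStandardize.TautomerEnumerator:
    global _tautomer_enumerator
    if _tautomer_enumerator is None:
        _tautomer_enumerator = rdMolStandardize.TautomerEnumerator()
    return _tautomer_enumerator


def standardize_structure(smiles: str, canonical_tautomer: bool = True) -> str:
    """Salt-strip to the largest organic fragment and canonicalize.

    Returns the canonical SMILES of the standardized structure; the
    operation is idempotent. Set ``canonical_tautomer=False`` to skip
    tautomer canonicalization.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"cannot parse SMILES {smiles!r}")
    mol = rdMolStandardize.FragmentParent(mol)
    if canonical_tautomer:
        mol = _get_tautomer_enumerator().Canonicalize(mol)
    return Chem.MolToSmiles(mol)


def parse_compound_table(
    path: str | Path,
    unit: str = "uM",
    column_map: dict[str, str] | None = None,
    delimiter: str | None = None,
) -> ParsedTable:
    """Read a CSV/TSV compound table into records.

    ``column_map`` maps the roles ``id``, ``smiles``, ``ic50`` and/or
    ``label`` to column names in the file (defaults: same names, with
    ``ic50_uM`` also recognized for ``ic50``). IC50 values are converted
    to uM (``unit='nM'`` divides by 1000). Rows with unparseable SMILES
    are dropped and counted.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    if unit not in ("uM", "nM"):
        raise ConfigurationError(f"unit must be 'uM' or 'nM', got {unit!r}")
    if delimiter is None:
        delimiter = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    try:
        frame = pd.read_csv(path, sep=delimiter)
    except pd.errors.EmptyDataError:
        raise InputError(f"empty compound table: {path}") from None
    if frame.empty:
        raise InputError(f"compound table has no rows: {path}")

    cmap = {"id": "id", "smiles": "smiles", "ic50": "ic50", "label": "label"}
    cmap.update(column_map or {})
    if cmap["ic50"] not in frame.columns and "ic50_uM" in frame.columns:
        cmap["ic50"] = "ic50_uM"
    for role in ("id", "smiles"):
        if cmap[role] not in frame.columns:
            raise ConfigurationError(
                f"column {cmap[role]!r} (role {role!r}) missing from {path.name}; "
                f"available: {list(frame.columns)}"
            )
    has_ic50 = cmap["ic50"] in frame.columns
    has_label = cmap["label"] in frame.columns

    scale = 1e-3 if unit == "nM" else 1.0
    records: list[CompoundRecord] = []
    dropped: list[str] = []
    for _, row in frame.iterrows():
        cid = str(row[cmap["id"]])
        smi = row[cmap["smiles"]]
        if not isinstance(smi, str) or not smi.strip():
            raise InputError(f"row {cid}: empty SMILES")
        if Chem.MolFromSmiles(smi) is None:
            dropped.append(cid)
            continue
        ic50 = None
        if has_ic50 and pd.notna(row[cmap["ic50"]]):
            ic50 = float(row[cmap["ic50"]]) * scale
        label = None
        if has_label and pd.notna(row[cmap["label"]]):
            label = str(row[cmap["label"]])
        records.append(CompoundRecord(id=cid, smiles=smi, ic50=ic50, label=label))
    if dropped:
        logger.warning(
            "dropped %d row(s) with unparseable SMILES: %s",
            len(dropped), ", ".join(dropped[:10]),
        )
    return ParsedTable(records=records, n_dropped=len(dropped), dropped_ids=dropped)


def read_smi(path: str | Path) -> ParsedTable:
    """Read a .smi file: one SMILES plus optional whitespace-separated id per line."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    records: list[CompoundRecord] = []
    dropped: list[str] = []
    for i, line in enumerate(path.read_text().splitlines()):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        smi = parts[0]
        cid = parts[1] if len(parts) > 1 else f"mol{i + 1}"
        if Chem.MolFromSmiles(smi) is None:
            dropped.append(cid)
            continue
        records.append(CompoundRecord(id=cid, smiles=smi))
    if dropped:
        logger.warning("dropped %d unparseable SMILES from %s", len(dropped), path.name)
    return ParsedTable(records=records, n_dropped=len(dropped), dropped_ids=dropped)


def deduplicate(records: Iterable[CompoundRecord]) -> list[CompoundRecord]:
    """Merge records sharing a standardized structure.

    The merged IC50 is the geometric mean (mean on the log scale) of the
    duplicates' IC50s; the first id is kept. Records are assumed already
    standardized.
    """
    by_smiles: dict[str, list[CompoundRecord]] = {}
    order: list[str] = []
    for rec in records:
        if rec.smiles not in by_smiles:
            order.append(rec.smiles)
            by_smiles[rec.smiles] = []
        by_smiles[rec.smiles].append(rec)
    merged: list[CompoundRecord] = []
    for smi in order:
        group = by_smiles[smi]
        if len(group) == 1:
            merged.append(group[0])
            continue
        ic50s = [r.ic50 for r in group if r.ic50 is not None]
        ic50 = float(np.exp(np.mean(np.log(ic50s)))) if ic50s else None
        label = assign_activity_label(ic50) if ic50 is not None else group[0].label
        merged.append(CompoundRecord(id=group[0].id, smiles=smi, ic50=ic50, label=label))
    return merged


@dataclass
class LabeledDataset:
    """Ordered compounds with binary labels (active/inactive only)."""

    records: list[CompoundRecord]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.label not in (ACTIVE, INACTIVE):
                raise ValueError(
                    f"record {rec.id}: label must be active/inactive, got {rec.label!r}"
                )
            if rec.id in seen:
                raise ValueError(f"duplicate compound id {rec.id!r}")
            seen.add(rec.id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[CompoundRecord]:
        return iter(self.records)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    @property
    def smiles(self) -> list[str]:
        return [r.smiles for r in self.records]

    @property
    def y(self) -> np.ndarray:
        """Binary label vector: 1 = active, 0 = inactive."""
        return np.array([1 if r.label == ACTIVE else 0 for r in self.records])

    @property
    def class_counts(self) -> tuple[int, int]:
        y = self.y
        return int(y.sum()), int((1 - y).sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.ids,
                "smiles": self.smiles,
                "ic50_uM": [r.ic50 for r in self.records],
                "label": [r.label for r in self.records],
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "LabeledDataset":
        parsed = parse_compound_table(path, unit="uM")
        records = [
            r if r.label is not None else r.with_label_from_ic50() for r in parsed
        ]
        return cls(records=records)


@dataclass(frozen=True)
class SplitSpec:
    """How to draw the train/test partition."""

    test_fraction: float = 0.2
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test_fraction must be in (0, 1)")


def stratified_split(
    data: LabeledDataset, spec: SplitSpec
) -> tuple[LabeledDataset, LabeledDataset]:
    """Seeded (stratified) random partition into train and test sets.

    Per-class test counts are round(n_class * test_fraction), so the
    realized proportions are within one compound of the requested
    fraction in each class.
    """
    rng = np.random.default_rng(spec.seed)
    records = data.records
    if spec.stratified:
        groups = [
            [i for i, r in enumerate(records) if r.label == ACTIVE],
            [i for i, r in enumerate(records) if r.label == INACTIVE],
        ]
    else:
        groups = [list(range(len(records)))]
    test_idx: set[int] = set()
    for idx in groups:
        if not idx:
            raise SplitError("cannot split: a class has no compounds")
        n_test = int(round(len(idx) * spec.test_fraction))
        if n_test < 1 or n_test >= len(idx):
            raise SplitError(
                f"test_fraction={spec.test_fraction} leaves an empty side "
                f"for a class of size {len(idx)}"
            )
        chosen = rng.choice(len(idx), size=n_test, replace=False)
        test_idx.update(idx[i] for i in chosen)
    train = [r for i, r in enumerate(records) if i not in test_idx]
    test = [r for i, r in enumerate(records) if i in test_idx]
    return LabeledDataset(train), LabeledDataset(test)


@dataclass
class CurationReport:
    """Per-filter drop counts from :func:`curate`."""

    n_input: int = 0
    n_unparseable: int = 0
    n_duplicates_merged: int = 0
    n_intermediate: int = 0
    n_unlabeled: int = 0
    n_final: int = 0

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def curate(
    records: Sequence[CompoundRecord],
    canonical_tautomer: bool = True,
) -> tuple[LabeledDataset, CurationReport]:
    """Standardize, deduplicate, label and filter to a modelling dataset.

    Intermediate compounds (1 uM < IC50 < 10 uM) and records without any
    activity information are dropped; every filter's count is reported.
    """
    report = CurationReport(n_input=len(records))
    std: list[CompoundRecord] = []
    for rec in records:
        try:
            smi = standardize_structure(rec.smiles, canonical_tautomer=canonical_tautomer)
        except SmilesParseError:
            report.n_unparseable += 1
            continue
        std.append(replace(rec, smiles=smi))
    merged = deduplicate(std)
    report.n_duplicates_merged = len(std) - len(merged)
    kept: list[CompoundRecord] = []
    for rec in merged:
        if rec.ic50 is not None:
            rec = rec.with_label_from_ic50()
        if rec.label is None:
            report.n_unlabeled += 1
            continue
        if rec.label == INTERMEDIATE:
            report.n_intermediate += 1
            continue
        kept.append(rec)
    report.n_final = len(kept)
    return LabeledDataset(kept), report
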