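"""Compound parsing, standardization, labelling and splitting."""

import numpy as np
import pytest
from rdkit import Chem

from stackpr.chem_io import (
    ACTIVE,
    INACTIVE,
    INTERMEDIATE,
    CompoundRecord,
    ConfigurationError,
    InputError,
    LabeledDataset,
    SmilesParseError,
    SplitSpec,
    assign_activity_label,
    curate,
    deduplicate,
    parse_compound_table,
    read_smi,
    standardize_structure,
    stratified_split,
)

STANDARDIZATION_PANEL = [
    "CCO",
    "c1ccccc1",
    "CC(=O)O.[Na+]",
    "C[NH+](C)C.[Cl-]",
    "Oc1ccncc1",
    "CC(=O)Nc1ccc(O)cc1",
    "CN1CCC[C@H]1c1cccnc1",
    "CC(C)Cc1ccc(cc1)C(C)C(=O)O",
    "OC(=O)c1ccccc1O",
    "Clc1ccccc1",
    "N[C@@H](C)C(=O)O",
    "c1ccc2[nH]ccc2c1",
    "O=C(O)CC(O)(CC(=O)O)C(=O)O",
    "C1CCNCC1",
    "CC12CCC3c4ccccc4CCC3C1CCC2",
    "CC(=O)Oc1ccccc1C(=O)O",
    "O=S(=O)(N)c1ccc(cc1)Cl",
    "CCN(CC)CCNC(=O)c1ccc(N)cc1",
    "CSCC[C@H](N)C(=O)O",
    "Cn1cnc2c1c(=O)n(C)c(=O)n2C",
]


class TestLabelAssignment:
    @pytest.mark.parametrize(
        "ic50,expected",
        [(1.0, ACTIVE), (10.0, INACTIVE), (5.0, INTERMEDIATE),
         (0.001, ACTIVE), (1.0001, INTERMEDIATE), (9.999, INTERMEDIATE), (500.0, INACTIVE)],
    )
    def test_thresholds(self, ic50, expected):
        assert assign_activity_label(ic50) == expected

    @pytest.mark.parametrize("bad", [0.0, -1.0, float("nan"), float("inf")])
    def test_nonpositive_rejected(self, bad):
        with pytest.raises(ValueError):
            assign_activity_label(bad)

    def test_counts_match_brute_force_interval_counting(self):
        rng = np.random.default_rng(11)
        ic50s = np.exp(rng.uniform(np.log(1e-3), np.log(1e3), size=1000))
        labels = [assign_activity_label(v) for v in ic50s]
        assert labels.count(ACTIVE) == int(np.sum(ic50s <= 1.0))
        assert labels.count(INACTIVE) == int(np.sum(ic50s >= 10.0))
        assert labels.count(INTERMEDIATE) == int(np.sum((ic50s > 1.0) & (ic50s < 10.0)))


class TestStandardize:
    def test_identity_on_simple_molecule(self):
        assert standardize_structure("CCO") == "CCO"

    def test_salt_stripping_keeps_largest_organic_fragment(self):
        out = standardize_structure("CC(=O)O.[Na+]")
        mol = Chem.MolFromSmiles(out)
        # the acetic-acid fragment: 4 heavy atoms, no sodium
        assert mol.GetNumHeavyAtoms() == 4
        assert all(a.GetSymbol() != "Na" for a in mol.GetAtoms())

    @pytest.mark.parametrize("smiles", STANDARDIZATION_PANEL)
    def test_idempotent(self, smiles):
        once = standardize_structure(smiles)
        assert standardize_structure(once) == once

    def test_invalid_smiles_raises_with_offender(self):
        with pytest.raises(SmilesParseError, match="not_a_smiles"):
            standardize_structure("not_a_smiles")


class TestCompoundRecord:
    def test_label_must_agree_with_ic50(self):
        with pytest.raises(ValueError):
            CompoundRecord(id="x", smiles="CCO", ic50=0.5, label=INACTIVE)
        CompoundRecord(id="x", smiles="CCO", ic50=0.5, label=ACTIVE)

    def test_ic50_positive(self):
        with pytest.raises(ValueError):
            CompoundRecord(id="x", smiles="CCO", ic50=-1.0)


class TestParseTable:
    def _write(self, tmp_path, text, name="table.csv"):
        path = tmp_path / name
        path.write_text(text)
        return path

    def test_nm_converted_to_um(self, tmp_path):
        path = self._write(tmp_path, "id,smiles,ic50\nC1,CCO,500\n")
        parsed = parse_compound_table(path, unit="nM")
        assert parsed[0].ic50 == pytest.approx(0.5)

    def test_unparseable_smiles_dropped_and_counted(self, tmp_path):
        path = self._write(tmp_path, "id,smiles,ic50\nC1,CCO,1\nC2,not_a_smiles,2\n")
        parsed = parse_compound_table(path)
        assert len(parsed) == 1
        assert parsed.n_dropped == 1
        assert parsed.dropped_ids == ["C2"]

    def test_ids_preserved_in_order(self, tmp_path):
        path = self._write(tmp_path, "id,smiles\nA,CCO\nB,CCN\nC,CCC\n")
        parsed = parse_compound_table(path)
        assert [r.id for r in parsed] == ["A", "B", "C"]

    def test_missing_column_is_configuration_error(self, tmp_path):
        path = self._write(tmp_path, "name,struct\nA,CCO\n")
        with pytest.raises(ConfigurationError, match="missing"):
            parse_compound_table(path)

    def test_column_map(self, tmp_path):
        path = self._write(tmp_path, "name,struct\nA,CCO\n")
        parsed = parse_compound_table(path, column_map={"id": "name", "smiles": "struct"})
        assert parsed[0].smiles == "CCO"

    def test_empty_file_is_input_error(self, tmp_path):
        path = self._write(tmp_path, "id,smiles\n")
        with pytest.raises(InputError):
            parse_compound_table(path)

    def test_smi_roundtrip(self, tmp_path):
        path = self._write(tmp_path, "CCO mol_a\nCCN mol_b\n", name="mols.smi")
        parsed = read_smi(path)
        assert [r.id for r in parsed] == ["mol_a", "mol_b"]


class TestDeduplicate:
    def test_geometric_mean_ic50(self):
        recs = [
            CompoundRecord(id="a", smiles="CCO", ic50=0.1),
            CompoundRecord(id="b", smiles="CCO", ic50=10.0),
            CompoundRecord(id="c", smiles="CCN", ic50=2.0),
        ]
        merged = deduplicate(recs)
        assert len(merged) == 2
        assert merged[0].ic50 == pytest.approx(1.0)  # sqrt(0.1 * 10)
        assert merged[0].id == "a"


def _dataset(n_active, n_inactive):
    recs = [
        CompoundRecord(id=f"a{i}", smiles="CCO", label=ACTIVE) for i in range(n_active)
    ] + [
        CompoundRecord(id=f"i{i}", smiles="CCN", label=INACTIVE)
        for i in range(n_inactive)
    ]
    return LabeledDataset(recs)


class TestSplit:
    def test_paper_sized_split(self):
        data = _dataset(463, 260)
        train, test = stratified_split(data, SplitSpec(test_fraction=0.2, seed=1))
        assert test.class_counts == (93, 52)
        assert train.class_counts == (370, 208)

    def test_symmetric_split(self):
        train, test = stratified_split(_dataset(10, 10), SplitSpec(test_fraction=0.5, seed=0))
        assert test.class_counts == (5, 5)

    def test_partition_by_ids(self):
        data = _dataset(30, 20)
        train, test = stratified_split(data, SplitSpec(seed=3))
        assert set(train.ids) | set(test.ids) == set(data.ids)
        assert set(train.ids) & set(test.ids) == set()

    def test_deterministic_for_fixed_seed(self):
        data = _dataset(40, 25)
        s1 = stratified_split(data, SplitSpec(seed=9))
        s2 = stratified_split(data, SplitSpec(seed=9))
        assert s1[0].ids == s2[0].ids and s1[1].ids == s2[1].ids

    def test_too_small_class_raises(self):
        from stackpr.chem_io import SplitError

        with pytest.raises(SplitError):
            stratified_split(_dataset(2, 2), SplitSpec(test_fraction=0.1, seed=0))


class TestCurate:
    def test_filters_and_counts(self):
        recs = [
            CompoundRecord(id="a", smiles="CCO", ic50=0.5),
            CompoundRecord(id="b", smiles="CCN", ic50=50.0),
            CompoundRecord(id="c", smiles="CCC", ic50=5.0),  # intermediate
            CompoundRecord(id="d", smiles="OCC", ic50=0.5),  # duplicate of a
            CompoundRecord(id="e", smiles="CCCC"),  # unlabeled
        ]
        dataset, report = curate(recs)
        assert report.n_intermediate == 1
        assert report.n_duplicates_merged == 1
        assert report.n_unlabeled == 1
        assert report.n_final == 2
        assert dataset.class_counts == (1, 1)

    def test_roundtrip_csv(self, tmp_path):
        dataset, _ = curate(
            [
                CompoundRecord(id="a", smiles="CCO", ic50=0.5),
                CompoundRecord(id="b", smiles="CCN", ic50=20.0),
            ]
        )
        path = tmp_path / "data.csv"
        dataset.to_csv(path)
        loaded = LabeledDataset.from_csv(path)
        assert loaded.ids == dataset.ids
        assert (loaded.y == dataset.y).all()
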