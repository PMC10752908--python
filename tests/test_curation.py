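"""Curation: table reading, standardization, dedup, labeling, splitting."""

import numpy as np
import pandas as pd
import pytest
from rdkit import Chem

from stackqsar.curation import (
    CompoundRecord,
    ConfigurationError,
    CurationError,
    InorganicRejectionError,
    LabelThresholds,
    LabeledDataset,
    SmilesParseError,
    StratificationError,
    assign_label,
    curate,
    deduplicate,
    read_compound_table,
    standardize_structure,
    stratified_split,
)

from conftest import make_records


def _write(tmp_path, df, name="t.csv"):
    path = tmp_path / name
    df.to_csv(path, index=False)
    return path


class TestReadCompoundTable:
    def test_row_count_preserved(self, tmp_path):
        df = pd.DataFrame({"id": ["a", "b", "c"], "smiles": ["C", "CC", "CCC"],
                           "ic50_nM": [100, 200, 300]})
        recs = read_compound_table(_write(tmp_path, df))
        assert len(recs) == 3
        assert recs[0].ic50_nM == 100

    @pytest.mark.parametrize(
        "value,unit,expected",
        [("0.5", "uM", 500.0), ("0.5", "µM", 500.0), ("2", "nM", 2.0),
         ("1e-6", "M", 1000.0), ("250", "pM", 0.25)],
    )
    def test_unit_conversion(self, tmp_path, value, unit, expected):
        df = pd.DataFrame({"id": ["a"], "smiles": ["C"], "ic50": [value],
                           "units": [unit]})
        (rec,) = read_compound_table(_write(tmp_path, df))
        assert rec.ic50_nM == pytest.approx(expected)

    def test_unknown_unit_dropped_or_rejected(self, tmp_path):
        df = pd.DataFrame({"id": ["a", "b"], "smiles": ["C", "CC"],
                           "ic50": [1, 2], "units": ["furlongs", "nM"]})
        path = _write(tmp_path, df)
        recs = read_compound_table(path)
        assert [r.id for r in recs] == ["b"]
        with pytest.raises(CurationError):
            read_compound_table(path, on_unknown_unit="error")

    def test_missing_smiles_column_is_configuration_error(self, tmp_path):
        df = pd.DataFrame({"id": ["a"], "ic50_nM": [1]})
        with pytest.raises(ConfigurationError):
            read_compound_table(_write(tmp_path, df))

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("id,smiles,ic50_nM\n")
        with pytest.raises(CurationError):
            read_compound_table(path)

    def test_chembl_export_dialect(self, tmp_path):
        df = pd.DataFrame({
            "Molecule ChEMBL ID": ["CHEMBL1"],
            "Smiles": ["CCO"],
            "Standard Value": ["0.5"],
            "Standard Units": ["uM"],
        })
        (rec,) = read_compound_table(_write(tmp_path, df), dialect="chembl_export")
        assert rec.id == "CHEMBL1" and rec.ic50_nM == 500.0

    def test_unparseable_ic50_becomes_missing(self, tmp_path):
        df = pd.DataFrame({"id": ["a"], "smiles": ["C"], "ic50_nM": ["n/a"]})
        (rec,) = read_compound_table(_write(tmp_path, df))
        assert rec.ic50_nM is None


class TestStandardize:
    def test_benzene_canonical_and_idempotent(self):
        out = standardize_structure("C1=CC=CC=C1")
        assert out == Chem.CanonSmiles("c1ccccc1")
        assert standardize_structure(out) == out

    def test_salt_stripped(self):
        assert standardize_structure("CCO.Cl") == standardize_structure("CCO")

    def test_parse_error_carries_offender(self):
        with pytest.raises(SmilesParseError, match="C1CC"):
            standardize_structure("C1CC")

    def test_inorganic_rejected(self):
        with pytest.raises(InorganicRejectionError):
            standardize_structure("[Na+].[Cl-]")

    @pytest.mark.parametrize(
        "smiles",
        ["CC(=O)Oc1ccccc1C(=O)O", "CN1C=NC2=C1C(=O)N(C)C(=O)N2C",
         "FC(F)(F)c1ccc(O)cc1", "CN(C)CCCc1ccccc1.Cl", "O=C1CCCCC1"],
    )
    def test_idempotence_property(self, smiles):
        once = standardize_structure(smiles)
        assert standardize_structure(once) == once


class TestDeduplicate:
    def _rec(self, i, smi, ic50):
        return CompoundRecord(id=f"r{i}", smiles_raw=smi, smiles_canonical=smi,
                              ic50_nM=ic50)

    def test_median_of_two(self):
        out = deduplicate([self._rec(0, "CCO", 100), self._rec(1, "CCO", 300)])
        assert len(out) == 1 and out[0].ic50_nM == 200

    def test_median_of_three(self):
        out = deduplicate([self._rec(i, "CCO", v) for i, v in
                           enumerate([10, 1000, 100000])])
        assert out[0].ic50_nM == 1000

    def test_all_unique_identity_and_order(self):
        recs = [self._rec(i, s, 10) for i, s in enumerate(["C", "CC", "CCC"])]
        out = deduplicate(recs)
        assert [r.id for r in out] == ["r0", "r1", "r2"]
        assert len(out) <= len(recs)

    def test_empty(self):
        assert deduplicate([]) == []


class TestAssignLabel:
    @pytest.mark.parametrize(
        "ic50,expected",
        [(500, "active"), (1000, "active"), (1000.01, "intermediate"),
         (5000, "intermediate"), (9999.99, "intermediate"),
         (10000, "inactive"), (20000, "inactive"), (None, "unlabeled")],
    )
    def test_partition(self, ic50, expected):
        assert assign_label(ic50) == expected

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            assign_label(-1.0)

    def test_threshold_ordering_enforced(self):
        with pytest.raises(ValueError):
            LabelThresholds(active_max_nM=10000, inactive_min_nM=1000)


class TestStratifiedSplit:
    def _dataset(self, n_active, n_inactive):
        recs = make_records(n_active + n_inactive)
        for i, r in enumerate(recs):
            r.label = "active" if i < n_active else "inactive"
        return LabeledDataset(records=recs)

    def test_floor_arithmetic(self):
        train, test = stratified_split(self._dataset(10, 10), 0.8, seed=0)
        assert sum(train.y) == 8 and sum(1 - train.y) == 8
        assert sum(test.y) == 2 and sum(1 - test.y) == 2

    def test_fraction_one_puts_everything_in_train(self):
        train, test = stratified_split(self._dataset(5, 5), 1.0, seed=0)
        assert len(train) == 10 and len(test) == 0

    def test_partition_exact_and_deterministic(self):
        ds = self._dataset(23, 17)
        t1, e1 = stratified_split(ds, 0.8, seed=9)
        t2, e2 = stratified_split(ds, 0.8, seed=9)
        ids = lambda d: {r.id for r in d.records}
        assert ids(t1) == ids(t2) and ids(e1) == ids(e2)
        assert ids(t1) | ids(e1) == {r.id for r in ds.records}
        assert ids(t1) & ids(e1) == set()

    def test_different_seed_changes_membership(self):
        ds = self._dataset(23, 17)
        t1, _ = stratified_split(ds, 0.8, seed=1)
        t2, _ = stratified_split(ds, 0.8, seed=2)
        assert {r.id for r in t1.records} != {r.id for r in t2.records}

    def test_empty_class_raises(self):
        ds = self._dataset(5, 0)
        with pytest.raises(StratificationError):
            stratified_split(ds, 0.8, seed=0)


class TestCurateChain:
    def test_full_chain_drops_invalid_and_salts(self, tmp_path):
        df = pd.DataFrame({
            "id": ["a", "b", "c", "d", "e"],
            "smiles": ["CCO.Cl", "CCO", "C1CC", "c1ccccc1O", "CCCCN"],
            "ic50_nM": [100, 300, 50, 20000, 5000],
        })
        recs = read_compound_table(_write(tmp_path, df))
        ds = curate(recs)
        # a+b merge (median 200, active), c unparseable, d inactive, e intermediate (dropped)
        labels = {r.id: r.label for r in ds.records}
        assert labels == {"a": "active", "d": "inactive"}
        assert ds.records[0].ic50_nM == 200

    def test_csv_round_trip(self, tmp_path, small_dataset):
        path = tmp_path / "curated.csv"
        small_dataset.to_csv(path)
        back = LabeledDataset.from_csv(path)
        assert back.to_frame().equals(small_dataset.to_frame())
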