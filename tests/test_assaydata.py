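"""Descriptor/assay parsing, imputation, normalization and splitting."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mgoscav import assaydata
from mgoscav.assaydata import (
    AssayRecord,
    AssayTable,
    DataValidationError,
    DatasetSplit,
    DescriptorTable,
    NormalizationState,
    apply_normalization,
    fit_normalization,
    make_split,
    read_assay_table,
    read_descriptor_table,
)


def write_csv(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadDescriptorTable:
    def test_plain_parse(self, tmp_path):
        p = write_csv(
            tmp_path,
            "d.csv",
            "Name,a,b,c,d\nc1,0,1.5,2,3\nc2,1,0.5,2,4\nc3,0,2.5,2,5\n",
        )
        t = read_descriptor_table(p)
        assert t.n_compounds == 3 and t.n_features == 4
        assert not [e for e in t.qc_log if e["event"] == "imputed"]
        np.testing.assert_allclose(t.values[1], [1, 0.5, 2, 4])

    def test_missing_cell_imputed_with_column_median(self, tmp_path):
        # present values in column b are {0.2, 0.5, 0.8}; median 0.5
        p = write_csv(
            tmp_path,
            "d.csv",
            "Name,a,b\nc1,0,0.2\nc2,1,\nc3,0,0.5\nc4,1,0.8\n",
        )
        t = read_descriptor_table(p)
        imputed = [e for e in t.qc_log if e["event"] == "imputed"]
        assert len(imputed) == 1
        assert imputed[0]["compound"] == "c2" and imputed[0]["value"] == 0.5
        assert t.values[1, 1] == 0.5

    def test_constant_column_logged(self, tmp_path):
        p = write_csv(tmp_path, "d.csv", "Name,a,b\nc1,1,0.1\nc2,1,0.2\n")
        t = read_descriptor_table(p)
        assert any(e["event"] == "constant_column" and e["feature"] == "a" for e in t.qc_log)

    def test_duplicate_compound_rejected(self, tmp_path):
        p = write_csv(tmp_path, "d.csv", "Name,a\nc1,1\nc1,2\n")
        with pytest.raises(DataValidationError, match="duplicate"):
            read_descriptor_table(p)

    def test_non_numeric_cell_names_row_and_column(self, tmp_path):
        p = write_csv(tmp_path, "d.csv", "Name,a,b\nc1,1,2\nc2,x,3\n")
        with pytest.raises(DataValidationError, match="'c2'.*'a'"):
            read_descriptor_table(p)

    def test_id_column_override(self, tmp_path):
        p = write_csv(tmp_path, "d.csv", "a,cmpd,b\n1,c1,2\n3,c2,4\n")
        t = read_descriptor_table(p, dialect="plain_csv", id_column="cmpd")
        assert t.compound_ids == ["c1", "c2"]
        assert t.feature_names == ["a", "b"]


class TestReadAssayTable:
    def test_parse_and_range(self, tmp_path):
        p = write_csv(
            tmp_path,
            "a.csv",
            "compound_id,concentration_uM,activity\nc1,0.001,0.1\nc1,1000,0.9\nc2,10,0.5\n",
        )
        t = read_assay_table(p)
        assert t.n_records == 3
        assert t.concentration_range == (0.001, 1000.0)

    def test_nonpositive_concentration_rejected_with_row(self, tmp_path):
        p = write_csv(
            tmp_path, "a.csv", "compound_id,concentration_uM,activity\nc1,1,0.1\nc2,-1,0.2\n"
        )
        with pytest.raises(DataValidationError, match="row 1"):
            read_assay_table(p)

    def test_unresolvable_compound_fails_at_assembly(self, tmp_path):
        d = write_csv(tmp_path, "d.csv", "Name,a\nc1,1\n")
        a = write_csv(tmp_path, "a.csv", "compound_id,concentration_uM,activity\nghost,1,0.1\n")
        desc = read_descriptor_table(d)
        with pytest.raises(DataValidationError, match="ghost"):
            read_assay_table(a, descriptors=desc)


def toy_tables():
    desc = DescriptorTable(
        compound_ids=["c1", "c2", "c3"],
        feature_names=["f1", "f2"],
        values=np.array([[2.0, 5.0], [4.0, 5.0], [9.0, 5.0]]),
    )
    assays = AssayTable(
        records=[
            AssayRecord("c1", 10.0, 0.0),
            AssayRecord("c2", 10.0, 2.0),
            AssayRecord("c3", 400.0, 1.0),
        ]
    )
    return desc, assays


class TestNormalization:
    def test_minmax_from_training_compounds_only(self):
        desc, assays = toy_tables()
        state = fit_normalization(desc, assays, [0, 1])  # c1, c2 only
        np.testing.assert_allclose(state.feature_min, [2.0, 5.0])
        np.testing.assert_allclose(state.feature_max, [4.0, 5.0])

    def test_activity_mean_and_sample_sd(self):
        # activities {0, 2}: mean 1, sample SD sqrt(2); score of 2 = 1/sqrt(2)
        desc, assays = toy_tables()
        state = fit_normalization(desc, assays, [0, 1])
        assert state.activity_mean == 1.0
        assert state.activity_sd == pytest.approx(np.sqrt(2))
        assert state.transform_activity(2.0) == pytest.approx(0.70710678, abs=1e-8)

    def test_constant_feature_normalizes_to_zero(self):
        desc, assays = toy_tables()
        state = fit_normalization(desc, assays, [0, 1])
        arrays = apply_normalization(state, desc, assays)
        assert np.all(arrays.X[:, 1] == 0.0)

    def test_value_above_training_max_exceeds_one_unclipped(self):
        desc, assays = toy_tables()
        state = fit_normalization(desc, assays, [0, 1])
        arrays = apply_normalization(state, desc, assays)
        # c3 has f1=9 vs training range [2, 4] -> (9-2)/2 = 3.5
        assert arrays.X[2, 0] == pytest.approx(3.5)
        # value equal to training min -> 0
        assert arrays.X[0, 0] == 0.0

    def test_activity_round_trip(self):
        desc, assays = toy_tables()
        state = fit_normalization(desc, assays, [0, 1, 2])
        y = np.array([-3.2, 0.0, 0.7, 11.9])
        back = state.invert_activity(state.transform_activity(y))
        np.testing.assert_allclose(back, y, atol=1e-9)

    def test_degenerate_constant_target_raises(self):
        desc, _ = toy_tables()
        assays = AssayTable(records=[AssayRecord("c1", 1.0, 5.0), AssayRecord("c2", 1.0, 5.0)])
        with pytest.raises(DataValidationError, match="degenerate"):
            fit_normalization(desc, assays, [0, 1])

    def test_feature_name_mismatch_rejected(self):
        desc, assays = toy_tables()
        state = fit_normalization(desc, assays, [0, 1])
        other = DescriptorTable(
            compound_ids=desc.compound_ids,
            feature_names=["g1", "g2"],
            values=desc.values,
        )
        with pytest.raises(DataValidationError, match="feature names"):
            apply_normalization(state, other, assays)

    def test_leakage_guard_nontraining_rows_ignored(self):
        desc, assays = toy_tables()
        state1 = fit_normalization(desc, assays, [0, 1])
        desc2, assays2 = toy_tables()
        desc2.values[2] = [999.0, -999.0]  # non-training compound
        assays2.records[2].activity_raw = 123.0  # non-training record
        state2 = fit_normalization(desc2, assays2, [0, 1])
        np.testing.assert_array_equal(state1.feature_min, state2.feature_min)
        np.testing.assert_array_equal(state1.feature_max, state2.feature_max)
        assert state1.activity_mean == state2.activity_mean
        assert state1.activity_sd == state2.activity_sd

    def test_state_json_round_trip(self, tmp_path):
        desc, assays = toy_tables()
        state = fit_normalization(desc, assays, [0, 1])
        state.to_json(tmp_path / "s.json")
        back = NormalizationState.from_json(tmp_path / "s.json")
        np.testing.assert_array_equal(back.feature_min, state.feature_min)
        assert back.activity_sd == state.activity_sd


class TestMakeSplit:
    def test_sizes_n10(self):
        s = make_split(10, seed=0)
        assert (s.train_idx.size, s.val_idx.size, s.test_idx.size) == (8, 1, 1)

    def test_sizes_emulation_scale(self):
        s = make_split(2262, seed=0)
        assert (s.train_idx.size, s.val_idx.size, s.test_idx.size) == (1810, 226, 226)

    def test_same_seed_reproduces_membership(self):
        a, b = make_split(137, seed=42), make_split(137, seed=42)
        np.testing.assert_array_equal(a.train_idx, b.train_idx)
        np.testing.assert_array_equal(a.val_idx, b.val_idx)
        np.testing.assert_array_equal(a.test_idx, b.test_idx)

    def test_too_few_records(self):
        with pytest.raises(DataValidationError):
            make_split(9, seed=0)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(n=st.integers(10, 400), seed=st.integers(0, 2**31 - 1))
    def test_partition_property(self, n, seed):
        s = make_split(n, seed=seed)
        merged = np.concatenate([s.train_idx, s.val_idx, s.test_idx])
        assert sorted(merged.tolist()) == list(range(n))
        assert s.val_idx.size == n // 10 and s.test_idx.size == n // 10

    def test_grouped_mode_keeps_compounds_together(self):
        groups = [f"c{i//4}" for i in range(80)]  # 20 compounds x 4 records
        s = make_split(80, seed=3, groups=groups)
        for fold in (s.train_idx, s.val_idx, s.test_idx):
            fold_groups = {groups[i] for i in fold}
            for g in fold_groups:
                members = [i for i, gg in enumerate(groups) if gg == g]
                assert set(members) <= set(fold.tolist())

    def test_split_json_round_trip(self, tmp_path):
        s = make_split(57, seed=5)
        s.to_json(tmp_path / "split.json")
        back = DatasetSplit.from_json(tmp_path / "split.json")
        np.testing.assert_array_equal(back.train_idx, s.train_idx)
        assert back.seed == 5


def test_imputation_idempotent_on_complete_table(tmp_path):
    p = tmp_path / "d.csv"
    p.write_text("Name,a,b\nc1,1,0.1\nc2,0,0.2\nc3,1,0.3\n")
    t = read_descriptor_table(p)
    assert [e for e in t.qc_log if e["event"] == "imputed"] == []
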