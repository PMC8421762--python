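"""Recoding rules, algorithm-item selection, delimited I/O and splitting."""

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from itemreduce import (
    ItemDef,
    TableSchema,
    read_item_table,
    recode_item_codes,
    select_algorithm_items,
    train_validation_split,
    write_item_table,
)

from conftest import ados_items, make_table


class TestRecoding:
    def test_manual_convention_mapping(self, raw_table):
        out = recode_item_codes(raw_table)
        # 3 -> 2, 7 -> 0, 8 -> 0; 0/1/2 and missing untouched
        assert out.codes.loc["S000"].tolist() == [0, 1, 2, 2]
        assert out.codes.loc["S001", "A"] == 0
        assert out.codes.loc["S001", "B"] == 0
        assert pd.isna(out.codes.loc["S001", "D"])
        assert out.codes.loc["S002"].tolist() == [2, 2, 0, 0]

    def test_surjective_onto_recoded_vocabulary(self, raw_table):
        out = recode_item_codes(raw_table)
        observed = set(pd.unique(out.codes.to_numpy().ravel()))
        assert {v for v in observed if not pd.isna(v)} <= {0, 1, 2}

    @settings(deadline=None, max_examples=50)
    @given(
        st.lists(
            st.lists(
                st.sampled_from([0, 1, 2, 3, 7, 8, None]), min_size=3, max_size=3
            ),
            min_size=2,
            max_size=8,
        )
    )
    def test_idempotent(self, rows):
        table = make_table(
            rows, ados_items(["X", "Y", "Z"]), [i % 2 for i in range(len(rows))]
        )
        once = recode_item_codes(table)
        twice = recode_item_codes(once)
        assert once.codes.equals(twice.codes)

    def test_rejects_invalid_code_naming_cell(self):
        table = make_table([[0, 5]], ados_items(["A", "B"]), [1])
        with pytest.raises(ValueError, match=r"S000.*'B'"):
            recode_item_codes(table)


class TestAlgorithmItemSelection:
    @staticmethod
    def _adir(item_id, in_alg, domain):
        return ItemDef(item_id=item_id, instrument="ADIR",
                       in_algorithm=in_alg, domain_tag=domain)

    def test_full_instrument_filtering(self):
        """31 ADOS + 93 ADI-R items of which 37 are algorithm non-D -> 68."""
        ados = ados_items([f"ADOS{i:02d}" for i in range(31)])
        adir = [self._adir(f"ALG{i:02d}", True, "ABC"[i % 3]) for i in range(37)]
        adir += [self._adir(f"D{i:02d}", True, "D") for i in range(6)]
        adir += [self._adir(f"OFF{i:02d}", False, None) for i in range(50)]
        items = ados + adir
        assert len(items) == 31 + 93
        table = make_table([[0] * len(items), [1] * len(items)], items, [1, 0])
        out = select_algorithm_items(table)
        assert out.n_items == 68

    def test_domain_d_removed_from_algorithm_set(self):
        adir = [self._adir(f"ALG{i:02d}", True, "A") for i in range(37)]
        adir += [self._adir("D1", True, "D"), self._adir("D2", True, "D")]
        table = make_table([[0] * 39], adir, [1])
        out = select_algorithm_items(table)
        assert out.n_items == 37
        assert all(it.domain_tag != "D" for it in out.items)

    def test_ados_only_table_unchanged(self, raw_table):
        out = select_algorithm_items(raw_table)
        assert out.item_ids == raw_table.item_ids

    def test_adir_without_metadata_rejected(self):
        items = [ItemDef(item_id="Q1", instrument="ADIR")]
        table = make_table([[0]], items, [1])
        with pytest.raises(ValueError, match="algorithm membership"):
            select_algorithm_items(table)


class TestIO:
    def test_parse_small_file(self, tmp_path):
        path = tmp_path / "cohort.csv"
        path.write_text(
            "subject_id,label,A,B\n"
            "P1,1,0,3\n"
            "P2,0,NA,7\n"
            "P3,1,2,1\n"
        )
        schema = TableSchema(items=tuple(ados_items(["A", "B"])))
        table = read_item_table(path, schema)
        assert table.subjects == ["P1", "P2", "P3"]
        assert table.codes.loc["P1"].tolist() == [0, 3]
        assert pd.isna(table.codes.loc["P2", "A"])
        assert table.labels.tolist() == [1, 0, 1]

    def test_round_trip_with_missing(self, tmp_path, raw_table):
        path = tmp_path / "t.csv"
        write_item_table(raw_table, path)
        schema = TableSchema(items=raw_table.items)
        back = read_item_table(path, schema)
        assert back.codes.equals(raw_table.codes)
        assert back.labels.equals(raw_table.labels)

    def test_string_labels_mapped_per_schema(self, tmp_path, raw_table):
        path = tmp_path / "t.csv"
        schema = TableSchema(
            items=raw_table.items,
            label_map={"autism": 1, "control": 0},
            label_names=("control", "autism"),
        )
        write_item_table(raw_table, path, schema)
        assert "autism" in path.read_text()
        back = read_item_table(path, schema)
        assert back.labels.equals(raw_table.labels)

    def test_unknown_column_rejected(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text("subject_id,label,A,ROGUE\nP1,1,0,0\n")
        schema = TableSchema(items=tuple(ados_items(["A"])))
        with pytest.raises(ValueError, match="ROGUE"):
            read_item_table(path, schema)

    def test_unmapped_label_rejected(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text("subject_id,label,A\nP1,maybe,0\n")
        schema = TableSchema(items=tuple(ados_items(["A"])))
        with pytest.raises(ValueError, match="maybe"):
            read_item_table(path, schema)


class TestSplit:
    @staticmethod
    def _big_table(n=1000, prevalence=0.46):
        n_pos = round(n * prevalence)
        labels = [1] * n_pos + [0] * (n - n_pos)
        return make_table([[0]] * n, ados_items(["A"]), labels)

    def test_zero_fraction_degenerate(self, raw_table):
        split = train_validation_split(raw_table, 0.0, seed=1)
        assert split.validation.n_subjects == 0
        assert split.train.equals(raw_table)

    def test_stratified_counts(self):
        table = self._big_table()
        split = train_validation_split(table, 0.25, seed=9)
        assert split.validation.n_subjects == 250
        n_pos_val = int(split.validation.labels.sum())
        assert abs(n_pos_val - 115) <= 1

    def test_partition_disjoint_exhaustive(self):
        table = self._big_table(n=200)
        split = train_validation_split(table, 0.3, seed=5)
        tr, va = set(split.train.subjects), set(split.validation.subjects)
        assert tr.isdisjoint(va)
        assert tr | va == set(table.subjects)

    def test_prevalence_preserved_within_one_subject(self):
        table = self._big_table(n=500, prevalence=0.46)
        split = train_validation_split(table, 0.25, seed=2)
        for part, frac in ((split.train, 0.75), (split.validation, 0.25)):
            expected_pos = 230 * frac
            assert abs(int(part.labels.sum()) - expected_pos) <= 1

    def test_deterministic_given_seed(self):
        table = self._big_table(n=120)
        s1 = train_validation_split(table, 0.25, seed=7)
        s2 = train_validation_split(table, 0.25, seed=7)
        assert s1.train.subjects == s2.train.subjects
        assert s1.validation.subjects == s2.validation.subjects

    @pytest.mark.parametrize("bad", [-0.1, 1.0, 1.5])
    def test_fraction_bounds(self, raw_table, bad):
        with pytest.raises(ValueError, match="fraction"):
            train_validation_split(raw_table, bad, seed=0)

    def test_single_class_rejected(self):
        table = make_table([[0], [1], [2]], ados_items(["A"]), [1, 1, 1])
        with pytest.raises(ValueError, match="class"):
            train_validation_split(table, 0.5, seed=0)
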