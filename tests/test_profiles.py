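"""Lineage parsing, abundance-table I/O and relative-abundance conversion."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mockbench.profiles import (AbundanceTable, Lineage, LineageParseError,
                                SampleMetadata, TableFormatError,
                                format_lineage, parse_lineage,
                                read_abundance_table, to_relative,
                                validate_metadata, write_abundance_table)


class TestLineage:
    @pytest.mark.parametrize("raw, rank, attr, value", [
        ("g__Bacillus;s__", "genus", "genus", "Bacillus"),
        ("k__Bacteria;g__Listeria;s__monocytogenes", "species", "species",
         "monocytogenes"),
        ("k__Bacteria", "kingdom", "kingdom", "Bacteria"),
    ])
    def test_resolved_rank(self, raw, rank, attr, value):
        lin = parse_lineage(raw)
        assert lin.resolved_rank == rank
        assert getattr(lin, attr) == value

    def test_slashed_genus_species_label(self):
        lin = parse_lineage("g__Escherichia/Shigella;s__coli")
        assert lin.species_label == "Escherichia/Shigella coli"

    def test_empty_string_is_unassigned(self):
        lin = parse_lineage("")
        assert lin.resolved_rank is None
        assert lin.species_label == ""

    def test_bad_token_carries_offender(self):
        with pytest.raises(LineageParseError) as err:
            parse_lineage("g__Bacillus;subtilis")
        assert err.value.token == "subtilis"

    def test_case_and_whitespace_normalised(self):
        lin = parse_lineage(" G__Bacillus ; S__subtilis ")
        assert (lin.genus, lin.species) == ("Bacillus", "subtilis")

    def test_rank_skipped_flag(self):
        assert parse_lineage("f__Listeriaceae;s__monocytogenes").rank_skipped
        assert not parse_lineage("g__Listeria;s__monocytogenes").rank_skipped

    @given(st.lists(
        st.sampled_from(["", "Bacteria", "Bacillus", "sub_tilis", "A-1"]),
        min_size=7, max_size=7))
    def test_roundtrip_identity(self, labels):
        lin = Lineage(*labels)
        assert parse_lineage(format_lineage(lin)) == lin


def _toy_counts():
    df = pd.DataFrame(
        {"s1": [50.0, 30.0, 20.0], "s2": [80.0, 15.0, 5.0]},
        index=["g__A;s__a", "g__B;s__b", "g__C;s__c"])
    return AbundanceTable(df, mode="counts")


class TestTableIO:
    def test_read_counts_autodetect(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("lineage\ts1\ts2\ng__A;s__a\t3\t4\ng__B;s__b\t1\t0\n"
                     "g__C;s__c\t2\t6\n")
        t = read_abundance_table(p)
        assert t.mode == "counts" and t.data.shape == (3, 2)

    def test_negative_cell_rejected_with_location(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("lineage\ts1\ng__A;s__a\t-1\n")
        with pytest.raises(TableFormatError, match="s1"):
            read_abundance_table(p)

    def test_duplicate_lineage_rejected(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("lineage\ts1\ng__A;s__a\t1\ng__A;s__a\t2\n")
        with pytest.raises(TableFormatError, match="duplicate"):
            read_abundance_table(p)

    def test_read_write_read_roundtrip(self, tmp_path):
        t = _toy_counts()
        p = tmp_path / "t.tsv"
        write_abundance_table(t, p)
        t2 = read_abundance_table(p)
        assert list(t2.data.index) == list(t.data.index)
        assert list(t2.data.columns) == list(t.data.columns)
        assert np.array_equal(t2.data.to_numpy(), t.data.to_numpy())

    def test_percent_fixture_columns_sum_to_100(self, extraction_observed):
        assert extraction_observed.mode == "percent"
        sums = extraction_observed.data.sum(axis=0)
        assert (np.abs(sums - 100.0) <= 0.02).all()


class TestToRelative:
    def test_symmetric_column(self):
        df = pd.DataFrame({"s": [50.0, 50.0]}, index=["g__A;s__a", "g__B;s__b"])
        rel = to_relative(AbundanceTable(df))
        assert np.allclose(rel.data["s"], [0.5, 0.5])

    def test_forced_by_definition(self):
        df = pd.DataFrame({"s": [80.0, 15.0, 5.0]},
                          index=["g__A;s__a", "g__B;s__b", "g__C;s__c"])
        rel = to_relative(AbundanceTable(df))
        assert np.allclose(rel.data["s"], [0.80, 0.15, 0.05])

    def test_refuses_relative_input(self):
        rel = to_relative(_toy_counts())
        with pytest.raises(ValueError, match="already relative"):
            to_relative(rel)

    def test_zero_total_sample_named(self):
        df = pd.DataFrame({"ok": [1.0], "empty": [0.0]}, index=["g__A;s__a"])
        with pytest.raises(ValueError, match="empty"):
            to_relative(AbundanceTable(df))

    def test_preserves_within_sample_rank_order(self):
        t = _toy_counts()
        rel = to_relative(t)
        for col in t.sample_ids:
            assert (np.argsort(t.data[col].to_numpy())
                    == np.argsort(rel.data[col].to_numpy())).all()


class TestMetadata:
    def test_pair_must_have_two_members(self):
        recs = [SampleMetadata(sample_id="a", replicate_pair_id="p1")]
        with pytest.raises(ValueError, match="exactly two"):
            validate_metadata(recs)

    def test_negative_cannot_be_paired(self):
        recs = [SampleMetadata(sample_id="a", control_role="negative",
                               replicate_pair_id="p1")]
        with pytest.raises(ValueError, match="negative"):
            validate_metadata(recs)

    def test_unknown_role_rejected(self):
        with pytest.raises(ValueError, match="control_role"):
            SampleMetadata(sample_id="a", control_role="blank")
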