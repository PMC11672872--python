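"""DEG-table reading, volcano filtering and the merge-and-sort procedure."""

import logging

import pytest
from hypothesis import given, settings, strategies as st

from lengthome.deg_io import (
    ConditionList,
    DEGRecord,
    SchemaError,
    merge_and_sort,
    read_deg_table,
    volcano_filter,
    write_deg_table,
)

TABLE = (
    "seqname\tGeneSymbol\tFCAbs\tPValue\tdirection\n"
    "NM_1\tGeneA\t2.5\t0.01\tdown\n"
    "NM_2\tGeneB\t3.0\t0.002\tdown\n"
    "NM_3\tGeneC\t2.1\t0.04\tdown\n"
)


def records(*rows, condition="C10"):
    return [DEGRecord(s, g, fc, p, d, condition) for s, g, fc, p, d in rows]


class TestReadDegTable:
    def test_well_formed_rows(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text(TABLE)
        recs = read_deg_table(p, "C10")
        assert len(recs) == 3
        assert recs[0].fold_change_abs == 2.5
        assert all(r.condition == "C10" for r in recs)

    def test_blank_gene_symbol_row_dropped(self, tmp_path, caplog):
        p = tmp_path / "t.tsv"
        p.write_text(TABLE + "NM_4\t\t2.0\t0.01\tdown\n")
        with caplog.at_level(logging.INFO):
            recs = read_deg_table(p, "C10")
        assert len(recs) == 3
        assert any("dropped 1" in m for m in caplog.messages)

    def test_missing_column_is_schema_error(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("seqname\tGeneSymbol\tFCAbs\tdirection\nNM_1\tA\t2\tdown\n")
        with pytest.raises(SchemaError):
            read_deg_table(p, "C10")

    def test_non_numeric_value_names_line(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text(
            "seqname\tGeneSymbol\tFCAbs\tPValue\tdirection\nNM_1\tA\thigh\t0.01\tdown\n"
        )
        with pytest.raises(ValueError, match="line 2"):
            read_deg_table(p, "C10")

    def test_duplicate_seqname_keeps_smaller_p(self, tmp_path, caplog):
        p = tmp_path / "t.tsv"
        p.write_text(
            "seqname\tGeneSymbol\tFCAbs\tPValue\tdirection\n"
            "NM_1\tA\t2.0\t0.04\tdown\nNM_1\tA\t2.5\t0.01\tdown\n"
        )
        with caplog.at_level(logging.WARNING):
            recs = read_deg_table(p, "C10")
        assert len(recs) == 1
        assert recs[0].p_value == 0.01

    def test_round_trip_through_writer(self, tmp_path):
        recs = records(("NM_1", "A", 2.5, 0.01, "down"), ("NM_2", "B", 4.0, 0.03, "down"))
        p = tmp_path / "w.tsv"
        write_deg_table(recs, p, header_lines=["meta"])
        back = read_deg_table(p, "C10")
        assert [(r.seqname, r.fold_change_abs, r.p_value) for r in back] == [
            ("NM_1", 2.5, 0.01), ("NM_2", 4.0, 0.03),
        ]


class TestVolcanoFilter:
    def test_boundary_values_kept(self):
        # thresholds are inclusive on both axes
        kept = volcano_filter(records(("NM_1", "A", 2.0, 0.05, "down")))
        assert kept.size == 1

    def test_fc_below_threshold_removed(self):
        kept = volcano_filter(records(("NM_1", "A", 1.0, 0.001, "down")))
        assert kept.size == 0

    def test_parameter_errors(self):
        with pytest.raises(ValueError):
            volcano_filter([], fc_min=0.5)
        with pytest.raises(ValueError):
            volcano_filter([], p_max=0.0)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.tuples(
                st.integers(0, 10_000),
                st.floats(0, 8, allow_nan=False),
                st.floats(0, 1, allow_nan=False),
            ),
            max_size=120,
        )
    )
    def test_matches_brute_force_predicate_scan(self, rows):
        """The kept set equals an independent row-by-row predicate check."""
        recs = [
            DEGRecord(f"NM_{i}", f"G{i}", fc, p, "down", "C10")
            for i, (_, fc, p) in enumerate(rows)
        ]
        kept = volcano_filter(recs, fc_min=2.0, p_max=0.05)
        expected = {r.seqname for r in recs if r.fold_change_abs >= 2.0 and r.p_value <= 0.05}
        assert kept.seqnames() == expected

    def test_idempotent(self):
        recs = records(
            ("NM_1", "A", 2.0, 0.05, "down"),
            ("NM_2", "B", 5.0, 0.2, "down"),
            ("NM_3", "C", 1.5, 0.01, "down"),
        )
        once = volcano_filter(recs)
        twice = volcano_filter(once.records, condition=once.condition)
        assert [r.seqname for r in twice.records] == [r.seqname for r in once.records]


class TestMergeAndSort:
    def test_size_conserving(self):
        a = ConditionList("C10", records(("NM_1", "b", 2, 0.01, "down")))
        b = ConditionList(
            "C24", records(("NM_2", "A", 2, 0.01, "down"), ("NM_3", "c", 2, 0.01, "down"),
                           condition="C24")
        )
        merged = merge_and_sort(a, b)
        assert len(merged) == a.size + b.size
        assert [r.gene_symbol for r in merged] == ["A", "b", "c"]  # case-insensitive

    def test_empty_is_identity(self):
        a = ConditionList("C10", records(("NM_1", "Z", 2, 0.01, "down"),
                                         ("NM_2", "A", 2, 0.01, "down")))
        merged = merge_and_sort(a, ConditionList("C24", []))
        assert [r.seqname for r in merged] == ["NM_2", "NM_1"]

    def test_mixed_directions_rejected(self):
        a = ConditionList("C10", records(("NM_1", "A", 2, 0.01, "down")))
        b = ConditionList("C24", records(("NM_2", "B", 2, 0.01, "up"), condition="C24"))
        with pytest.raises(ValueError):
            merge_and_sort(a, b)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.data())
    def test_matches_independent_lexicographic_sort(self, data):
        """Ordering agrees with an independently computed stable sort."""
        syms = st.text(alphabet="abcABC", min_size=1, max_size=3)
        rows_a = data.draw(st.lists(syms, max_size=30))
        rows_b = data.draw(st.lists(syms, max_size=30))
        a = ConditionList("C10", [
            DEGRecord(f"NM_a{i}", g, 2, 0.01, "down", "C10") for i, g in enumerate(rows_a)
        ])
        b = ConditionList("C24", [
            DEGRecord(f"NM_b{i}", g, 2, 0.01, "down", "C24") for i, g in enumerate(rows_b)
        ])
        merged = merge_and_sort(a, b)
        oracle = sorted(
            a.records + b.records,
            key=lambda r: (r.gene_symbol.lower(), r.condition, r.seqname),
        )
        assert merged == oracle
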