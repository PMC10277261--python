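"""Pairwise tables, matrices, CSV I/O and missing-value detection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from divtime.divergence_data import (
    DivergenceDataError,
    DivergenceMatrix,
    DivergencePair,
    PairwiseTable,
    TableMode,
    find_missing,
    matrix_to_table,
    normalize_name,
    read_species_list,
    read_table_csv,
    table_to_matrix,
    write_table_csv,
)
from divtime import fixture_factory as ff

from conftest import FOUR_SPECIES, random_symmetric_matrix


class TestNormalizeName:
    @pytest.mark.parametrize(
        "raw, expected",
        [
            ("Passerina_amoena ", "Passerina amoena"),
            ("Passerina amoena", "Passerina amoena"),
            ("  Catharus   ustulatus", "Catharus ustulatus"),
            ("Malurus_cyaneus", "Malurus cyaneus"),
        ],
    )
    def test_normalization(self, raw, expected):
        assert normalize_name(raw) == expected

    @pytest.mark.parametrize("raw", ["", "   ", "_ _"])
    def test_empty_rejected(self, raw):
        with pytest.raises(DivergenceDataError):
            normalize_name(raw)


class TestSpeciesList:
    def test_reads_names_in_order(self, tmp_path):
        f = tmp_path / "species.txt"
        f.write_text("Passerina amoena\nCorythornis cristatus\n")
        assert read_species_list(f) == [
            "Passerina amoena",
            "Corythornis cristatus",
        ]

    def test_blank_lines_skipped(self, tmp_path):
        f = tmp_path / "species.txt"
        f.write_text("A a\nB b\n\nC c\nD d\n")
        assert len(read_species_list(f)) == 4

    def test_duplicates_warn_and_keep_first(self, tmp_path):
        f = tmp_path / "species.txt"
        f.write_text("Passerina amoena\nPasserina_amoena\n")
        with pytest.warns(UserWarning, match="duplicate"):
            names = read_species_list(f)
        assert names == ["Passerina amoena"]

    def test_empty_file_rejected(self, tmp_path):
        f = tmp_path / "species.txt"
        f.write_text("\n\n")
        with pytest.raises(DivergenceDataError):
            read_species_list(f)


class TestPairInvariants:
    def test_self_pair_nonzero_time_rejected(self):
        with pytest.raises(DivergenceDataError):
            DivergencePair("A a", "A a", 3.0)

    def test_reversed_ci_rejected(self):
        with pytest.raises(DivergenceDataError):
            DivergencePair("A a", "B b", 10.0, ci_low_mya=12.0, ci_high_mya=8.0)

    def test_median_may_sit_outside_ci(self):
        # medians and adjusted medians are reported independently of the CI
        pair = DivergencePair("A a", "B b", 50.0, ci_low_mya=10.0, ci_high_mya=20.0)
        assert pair.time_mya == 50.0

    def test_negative_time_rejected(self):
        with pytest.raises(DivergenceDataError):
            DivergencePair("A a", "B b", -1.0)


class TestTableToMatrix:
    def test_four_species_table_gives_expected_matrix(self, table1):
        m = table_to_matrix(table1)
        expected = np.array(
            [
                [0.0, 70.0, 27.6, 80.0],
                [70.0, 0.0, 70.0, 80.0],
                [27.6, 70.0, 0.0, 80.0],
                [80.0, 80.0, 80.0, 0.0],
            ]
        )
        assert m.labels == FOUR_SPECIES
        np.testing.assert_array_equal(m.values, expected)

    def test_single_species_table(self):
        t = PairwiseTable(
            species=["A a"], rows=[DivergencePair("A a", "A a", 0.0)],
            mode=TableMode.FULL,
        )
        m = table_to_matrix(t)
        assert m.values.shape == (1, 1) and m.values[0, 0] == 0.0

    def test_conflicting_orderings_raise(self):
        rows = [
            DivergencePair("A a", "A a", 0.0),
            DivergencePair("A a", "B b", 70.0),
            DivergencePair("B b", "A a", 71.0),
            DivergencePair("B b", "B b", 0.0),
        ]
        t = PairwiseTable(species=["A a", "B b"], rows=rows, mode=TableMode.FULL)
        with pytest.raises(DivergenceDataError, match="conflict"):
            table_to_matrix(t, tol=0.5)

    def test_missing_pair_raises_with_pair_named(self):
        t = PairwiseTable(
            species=["A a", "B b", "C c"],
            rows=[DivergencePair("A a", "B b", 5.0)],
            mode=TableMode.UNORDERED,
        )
        with pytest.raises(DivergenceDataError, match=r"\(A a, C c\)"):
            table_to_matrix(t)


class TestMatrixToTable:
    def test_full_mode_includes_self_pairs(self, table1):
        m = table_to_matrix(table1)
        t = matrix_to_table(m, TableMode.FULL)
        assert len(t.rows) == 16
        assert sum(r.is_self_pair for r in t.rows) == 4
        assert all(r.time_mya == 0.0 for r in t.rows if r.is_self_pair)

    def test_two_by_two_unordered(self):
        m = DivergenceMatrix(labels=["A a", "B b"], values=[[0, 35], [35, 0]])
        t = matrix_to_table(m, TableMode.UNORDERED)
        assert len(t.rows) == 1 and t.rows[0].time_mya == 35.0

    def test_single_label_unordered_is_empty(self):
        m = DivergenceMatrix(labels=["A a"], values=[[0.0]])
        assert len(matrix_to_table(m, TableMode.UNORDERED).rows) == 0

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(n=st.integers(2, 20), seed=st.integers(0, 10_000),
           mode=st.sampled_from(list(TableMode)))
    def test_round_trip_and_row_counts(self, n, seed, mode):
        """matrix -> table -> matrix is the identity; row counts are n² / nC2."""
        labels = [f"Sp {i}" for i in range(n)]
        m = DivergenceMatrix(labels=labels, values=random_symmetric_matrix(n, seed))
        t = matrix_to_table(m, mode)
        expected_rows = n * n if mode is TableMode.FULL else n * (n - 1) // 2
        assert len(t.rows) == expected_rows
        back = table_to_matrix(t)
        assert back.labels == labels
        np.testing.assert_array_equal(back.values, m.values)


class TestFindMissing:
    def test_complete_table_has_none(self, table1):
        assert find_missing(table1) == []

    def test_blanked_pair_is_reported(self, table1):
        pair = ("Passerina amoena", "Chrysococcyx cupreus")
        corrupted = ff.corrupt_table(table1, drop=[pair])
        assert find_missing(corrupted) == [pair]

    def test_absent_pair_is_reported(self):
        t = PairwiseTable(
            species=["A a", "B b", "C c"],
            rows=[
                DivergencePair("A a", "B b", 5.0),
                DivergencePair("A a", "C c", 7.0),
            ],
            mode=TableMode.UNORDERED,
        )
        assert find_missing(t) == [("B b", "C c")]

    def test_empty_iff_matrix_conversion_succeeds(self, table1):
        # the two completeness notions must agree
        assert find_missing(table1) == []
        table_to_matrix(table1)
        corrupted = ff.corrupt_table(
            table1, drop=[("Passerina amoena", "Corythornis cristatus")]
        )
        assert find_missing(corrupted) != []
        with pytest.raises(DivergenceDataError):
            table_to_matrix(corrupted)


class TestCsvRoundTrip:
    def test_four_species_round_trip(self, table1, tmp_path):
        path = tmp_path / "t.csv"
        write_table_csv(table1, path)
        back = read_table_csv(path)
        assert back.species == table1.species
        assert back.rows == table1.rows
        assert back.mode == table1.mode

    def test_missing_value_round_trip(self, table1, tmp_path):
        corrupted = ff.corrupt_table(
            table1, drop=[("Passerina amoena", "Chalcomitra amethystine")]
        )
        path = tmp_path / "t.csv"
        write_table_csv(corrupted, path)
        back = read_table_csv(path)
        assert back.rows == corrupted.rows
        # the blanked time is an empty field on disk
        blank_lines = [
            line for line in path.read_text().splitlines()
            if line.startswith("Passerina amoena,Chalcomitra amethystine")
        ]
        assert blank_lines[0].split(",")[2] == ""

    def test_na_strings_accepted(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text(
            "Taxa 1,Taxa 2,Divergence time,CI_low,CI_high,Studies\n"
            "A a,A a,0.0,n. a,n. a,n. a\n"
            "A a,B b,NA,,,\n"
            "B b,B b,NA,,,\n"
        )
        t = read_table_csv(path)
        assert t.rows[0].time_mya == 0.0 and t.rows[0].ci_low_mya is None
        assert t.rows[1].is_missing
        assert t.rows[2].time_mya == 0.0  # self-pair NA maps to 0

    def test_missing_mandatory_column(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text("Taxa 1,Divergence time\nA a,5.0\n")
        with pytest.raises(DivergenceDataError, match="Taxa 2"):
            read_table_csv(path)

    def test_non_numeric_time_names_row(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text(
            "Taxa 1,Taxa 2,Divergence time\nA a,B b,5.0\nA a,C c,oops\n"
        )
        with pytest.raises(DivergenceDataError, match="row 3"):
            read_table_csv(path)
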