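import numpy as np
import pytest
from hypothesis import given, strategies as st

from seqibd import (
    Alignment,
    AlignmentShapeError,
    FormatError,
    NoColumnsError,
    UntestableError,
    ValidationError,
    base_frequency_filter,
    p_distance_matrix,
    read_alignment,
    select_hypervariable,
    write_alignment,
)


def aln_from(*seqs, ids=None):
    ids = ids or [f"s{i}" for i in range(len(seqs))]
    return Alignment.from_strings(ids, list(seqs))


class TestReadWrite:
    def test_roundtrip_after_normalization(self, tmp_path):
        aln = aln_from("acgu.", "ACGT-")
        path = tmp_path / "a.fasta"
        write_alignment(aln, path)
        again = read_alignment(path)
        assert again.ids == aln.ids
        assert again.sequence("s0") == "ACGT-"
        assert again.sequence("s1") == "ACGT-"

    def test_case_folding_makes_rows_identical(self):
        aln = aln_from("acgt", "ACGT")
        assert aln.sequence("s0") == aln.sequence("s1") == "ACGT"

    def test_u_and_dot_normalized(self):
        aln = aln_from("augc.", "ATGC-")
        assert aln.sequence("s0") == "ATGC-"

    def test_unequal_lengths_names_offender(self):
        with pytest.raises(AlignmentShapeError, match="second"):
            aln_from("ACGT", "ACGTA", ids=["first", "second"])

    def test_empty_file_is_format_error(self, tmp_path):
        path = tmp_path / "empty.fasta"
        path.write_text("")
        with pytest.raises(FormatError):
            read_alignment(path)

    def test_single_record_rejected(self, tmp_path):
        path = tmp_path / "one.fasta"
        path.write_text(">only\nACGT\n")
        with pytest.raises(FormatError):
            read_alignment(path)

    def test_long_rows_wrapped_on_write(self, tmp_path):
        aln = aln_from("A" * 150, "C" * 150)
        path = tmp_path / "wrap.fasta"
        write_alignment(aln, path)
        lines = path.read_text().splitlines()
        assert max(len(l) for l in lines if not l.startswith(">")) == 70


class TestBaseFrequencyFilter:
    def test_unanimous_column_retained(self):
        aln = aln_from("A", "A", "A", "A")
        assert base_frequency_filter(aln).n_columns == 1

    def test_maximally_variable_column_removed(self):
        # A,C,G,T each at 25% < 30%: removed; second column keeps it alive
        aln = aln_from("AA", "CA", "GA", "TA")
        filtered = base_frequency_filter(aln)
        assert list(filtered.retained_columns) == [1]

    def test_gaps_excluded_from_denominator(self):
        # 3 A's over 3 non-gap characters = 1.0 -> retained
        rows = ["A"] * 3 + ["-"] * 7
        aln = aln_from(*rows)
        assert base_frequency_filter(aln).n_columns == 1

    def test_modal_fraction_at_point_forty(self):
        # 3 A, 3 C, 4 G: modal 4/10 = 0.40 >= 0.30 -> retained
        rows = ["A"] * 3 + ["C"] * 3 + ["G"] * 4
        aln = aln_from(*rows)
        assert base_frequency_filter(aln).n_columns == 1

    def test_gap_counting_switch(self):
        # 2 A over 8 gaps: modal 2/2=1.0 without gaps, 2/10=0.2 with
        rows = ["A"] * 2 + ["-"] * 8
        aln = aln_from(*rows)
        assert base_frequency_filter(aln, count_gaps=False).n_columns == 1
        with pytest.raises(NoColumnsError):
            base_frequency_filter(aln, count_gaps=True)

    def test_boundary_inclusive(self):
        # modal base exactly at threshold is kept ("below 30%" is excluded)
        rows = ["A", "A", "A", "C", "C", "C", "G", "G", "T", "T"]
        aln = aln_from(*rows)
        assert base_frequency_filter(aln, threshold=0.30).n_columns == 1

    def test_tiny_threshold_keeps_all_non_all_gap_columns(self):
        aln = aln_from("ACGT-", "CGTA-", "GTAC-", "TACG-")
        filtered = base_frequency_filter(aln, threshold=1e-9)
        assert list(filtered.retained_columns) == [0, 1, 2, 3]

    def test_threshold_one_keeps_exactly_unanimous(self):
        aln = aln_from("AAC", "AGC", "ATC")
        filtered = base_frequency_filter(aln, threshold=1.0)
        assert list(filtered.retained_columns) == [0, 2]

    def test_no_survivors_is_explicit_error(self):
        aln = aln_from("AC", "CG", "GT", "TA")
        with pytest.raises(NoColumnsError, match="survive"):
            base_frequency_filter(aln)

    def test_invalid_threshold(self):
        aln = aln_from("A", "A")
        with pytest.raises(ValidationError):
            base_frequency_filter(aln, threshold=0.0)


class TestPDistance:
    def test_identical_sequences_zero(self):
        dm = p_distance_matrix(aln_from("ACGTACGT", "ACGTACGT"))
        assert dm[("s0", "s1")] == 0.0

    def test_one_in_four_mismatch(self):
        dm = p_distance_matrix(aln_from("ACGT", "ACGA"))
        assert dm[("s0", "s1")] == 0.25
        assert dm.counts[0, 1] == 4

    def test_pairwise_deletion_of_gaps(self):
        dm = p_distance_matrix(aln_from("AC-T", "ACGT"))
        assert dm[("s0", "s1")] == 0.0
        assert dm.counts[0, 1] == 3

    def test_ambiguity_codes_excluded(self):
        # N never matches or mismatches; only 3 comparable columns, 1 differs
        dm = p_distance_matrix(aln_from("ANGT", "ACGA"))
        assert dm.counts[0, 1] == 3
        assert dm[("s0", "s1")] == pytest.approx(1 / 3)

    def test_no_comparable_columns_identifies_pair(self):
        with pytest.raises(ValidationError, match="left"):
            p_distance_matrix(
                aln_from("AC--", "--GT", ids=["left", "right"])
            )

    @given(
        st.lists(
            st.text(alphabet="ACGT", min_size=12, max_size=12),
            min_size=2,
            max_size=6,
        )
    )
    def test_gap_free_equals_hamming_fraction(self, seqs):
        seqs = [s for s in seqs]
        ids = [f"q{i}" for i in range(len(seqs))]
        dm = p_distance_matrix(Alignment.from_strings(ids, seqs))
        for i in range(len(seqs)):
            for j in range(i + 1, len(seqs)):
                hamming = sum(a != b for a, b in zip(seqs[i], seqs[j]))
                assert dm.values[i, j] == pytest.approx(hamming / 12)
        assert np.allclose(dm.values, dm.values.T)
        assert np.all((0 <= dm.values) & (dm.values <= 1))

    def test_filter_then_distance_equals_manual_slice(self, rng):
        letters = np.array(list("ACGT-"))
        rows = ["".join(rng.choice(letters, 40)) for _ in range(8)]
        aln = Alignment.from_strings([f"r{i}" for i in range(8)], rows)
        filtered = base_frequency_filter(aln, threshold=0.4)
        manual = aln.take_columns(
            np.searchsorted(aln.retained_columns, filtered.retained_columns)
        )
        d1 = p_distance_matrix(filtered)
        d2 = p_distance_matrix(manual)
        assert np.allclose(d1.values, d2.values)


class TestHypervariableSelection:
    def test_single_polymorphic_column_selected(self):
        # only column 2 is polymorphic
        aln = aln_from("AACA", "AAGA", "AACA", "AAGA")
        selected = select_hypervariable(aln, 0.25)
        assert list(selected.retained_columns) == [2]

    def test_idempotent_at_full_fraction(self):
        aln = aln_from("ACGT", "AGGT", "ACCT")
        once = select_hypervariable(aln, 1.0)
        twice = select_hypervariable(once, 1.0)
        assert list(twice.retained_columns) == list(aln.retained_columns)
        assert np.array_equal(twice.rows, aln.rows)

    def test_constant_alignment_is_error(self):
        aln = aln_from("ACGT", "ACGT", "ACGT")
        with pytest.raises(NoColumnsError, match="variable"):
            select_hypervariable(aln, 0.5)

    def test_entropy_ties_break_to_lower_index(self):
        # columns 0 and 1 have identical entropy; keep the earlier one
        aln = aln_from("AAG", "CCG", "AAG", "CCG")
        selected = select_hypervariable(aln, 1 / 3)
        assert list(selected.retained_columns) == [0]

    def test_invalid_fraction(self):
        aln = aln_from("AC", "AG")
        with pytest.raises(ValidationError):
            select_hypervariable(aln, 0.0)
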