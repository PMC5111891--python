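"""Substitution/indel calling, classification rules, and summaries."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plastcomp import (
    PairwiseAlignment,
    call_indels,
    call_substitutions,
    classify_substitution,
    left_normalize,
    p_distance,
    reconstruct,
    spectrum_type,
    summarize_mutations,
)
from plastcomp.errors import SequenceError


class TestTransitionRule:
    @pytest.mark.parametrize(
        "ref,alt,klass",
        [
            ("A", "G", "transition"),
            ("G", "A", "transition"),
            ("C", "T", "transition"),
            ("T", "C", "transition"),
            ("C", "A", "transversion"),
            ("G", "T", "transversion"),
            ("A", "T", "transversion"),
            ("C", "G", "transversion"),
        ],
    )
    def test_classification(self, ref, alt, klass):
        assert classify_substitution(ref, alt) == klass

    def test_identical_bases_rejected(self):
        with pytest.raises(ValueError):
            classify_substitution("A", "A")

    def test_spectrum_pools_strand_complements(self):
        assert spectrum_type("A", "C") == spectrum_type("T", "G")
        assert spectrum_type("G", "A") == spectrum_type("C", "T")
        assert len(
            {spectrum_type(r, a)
             for r in "ACGT" for a in "ACGT" if r != a}
        ) == 6


class TestCallSubstitutions:
    def test_zero_mismatch_alignment_is_empty(self):
        aln = PairwiseAlignment("r", "a", "ACGTACGT", "ACGTACGT")
        assert call_substitutions(aln) == []

    def test_each_mismatch_column_is_one_event(self):
        aln = PairwiseAlignment("r", "a", "ACGTAC", "AGGTAA")
        events = call_substitutions(aln)
        assert [(e.ref_pos, e.ref_base, e.alt_base, e.klass) for e in events] \
            == [(2, "C", "G", "transversion"), (6, "C", "A", "transversion")]

    def test_excluded_intervals_are_masked(self):
        aln = PairwiseAlignment("r", "a", "ACGTAC", "AGGTAA")
        events = call_substitutions(aln, exclude_intervals=((1, 3),))
        assert [e.ref_pos for e in events] == [6]


class TestCallIndels:
    def test_gap_free_alignment_is_empty(self):
        aln = PairwiseAlignment("r", "a", "ACGT", "ACGT")
        assert call_indels(aln) == []

    def test_homopolymer_contraction_is_insertion(self):
        # standard C AAAA C vs other C AAA C: standard carries the extra A
        aln = PairwiseAlignment("r", "a", "GCAAAACG", "GCAA-ACG")
        (event,) = call_indels(aln)
        assert (event.ref_pos, event.seq, event.direction, event.klass) \
            == (2, "A", "Insertion", "homopolymeric")

    def test_two_base_slippage_event_is_homopolymeric(self):
        aln = PairwiseAlignment("r", "a", "GCAAAAACG", "GCA--AACG")
        (event,) = call_indels(aln)
        assert (event.seq, event.length, event.klass, event.direction) \
            == ("AA", 2, "homopolymeric", "Insertion")

    def test_single_base_without_run_context_is_plain_indel(self):
        # a lone G deleted between AT and CA: no G run in the standard
        aln = PairwiseAlignment("r", "a", "AT-CA", "ATGCA")
        (event,) = call_indels(aln)
        assert (event.ref_pos, event.seq, event.direction, event.klass) \
            == (2, "G", "Deletion", "non_homopolymeric")

    def test_multibase_heterogeneous_insertion(self):
        aln = PairwiseAlignment("r", "a", "GGTACAACC", "GG-----CC")
        (event,) = call_indels(aln)
        assert (event.seq, event.length, event.klass, event.direction) \
            == ("TACAA", 5, "non_homopolymeric", "Insertion")

    def test_emitted_events_are_left_normalized(self):
        # the aligner may park the gap mid-run; the caller must not
        aln = PairwiseAlignment("r", "a", "GCTTTTACG", "GCTT-TACG")
        (event,) = call_indels(aln)
        assert event.ref_pos == 2
        pos, seq = left_normalize(aln.ref_seq, event.ref_pos, event.seq)
        assert (pos, seq) == (event.ref_pos, event.seq)


class TestLeftNormalize:
    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        st.text(alphabet="ACGT", min_size=5, max_size=40),
        st.integers(min_value=1, max_value=39),
        st.text(alphabet="ACGT", min_size=1, max_size=4),
    )
    def test_idempotent(self, ref, pos, seq):
        pos = min(pos, len(ref) - 1)
        pos1, seq1 = left_normalize(ref, pos, seq)
        assert left_normalize(ref, pos1, seq1) == (pos1, seq1)

    def test_shifts_through_repeat_context(self):
        # an AT insertion inside a TA-repeat slides to the repeat's 5' edge
        assert left_normalize("CTATATG", 6, "AT") == (1, "TA")


class TestPDistance:
    def test_identical_is_zero(self):
        aln = PairwiseAlignment("r", "a", "A" * 1000, "A" * 1000)
        assert p_distance(aln) == 0.0

    def test_one_in_four(self):
        aln = PairwiseAlignment("r", "a", "AAAA", "AAAT")
        assert p_distance(aln) == 0.25

    def test_gap_columns_excluded_pairwise(self):
        aln = PairwiseAlignment("r", "a", "AAAA--CC", "AAATGGCC")
        assert p_distance(aln) == round(1 / 6, 5)

    def test_no_comparable_columns_raises(self):
        aln = PairwiseAlignment("r", "a", "--AA", "GG--")
        with pytest.raises(SequenceError):
            p_distance(aln)

    def test_rounding_matches_report_convention(self):
        # 44 differing sites over a plastome-sized alignment
        n = 151_570
        ref = "A" * n
        alt = "C" * 44 + "A" * (n - 44)
        aln = PairwiseAlignment("r", "a", ref, alt)
        assert p_distance(aln, rounding=5) == 0.00029


class TestSummary:
    def test_counts_and_ratio(self):
        aln = PairwiseAlignment("r", "a", "ACGTACGTAA", "GCGTACATAA")
        subs = call_substitutions(aln)
        summary = summarize_mutations(subs, aln=aln)
        assert summary.n_substitutions == summary.n_ts + summary.n_tv == 2
        assert sum(summary.substitution_spectrum.values()) == 2
        assert summary.p_distance == 0.2

    def test_empty_inputs_all_zero(self):
        summary = summarize_mutations([], [], [])
        assert summary.n_total == 0
        assert summary.ts_tv_ratio is None
        assert summary.substitution_spectrum == {}


class TestReconstruction:
    def test_round_trip_on_synthetic_pair(self, small_pair):
        truth = small_pair["truth"]
        rebuilt = reconstruct(
            truth.standard.sequence,
            truth.substitutions,
            truth.indels,
            truth.inversions,
        )
        assert rebuilt == small_pair["mutated"].sequence
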