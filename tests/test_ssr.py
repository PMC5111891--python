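"""Microsatellite scanner against toy constructions and brute force."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plastcomp import CircularGenome, SSRThresholds, find_ssrs, summarize_ssrs
from plastcomp.ssr import DEFAULT_MIN_REPEATS

from .conftest import random_dna
from .oracles import brute_force_ssrs


def _linear(seq: str) -> CircularGenome:
    return CircularGenome("toy", seq, is_circular=False)


def _as_tuples(loci):
    return sorted(
        (s.motif, s.unit_length, s.n_repeats, s.start, s.end) for s in loci
    )


class TestToyConstructions:
    def test_eleven_base_mono_run(self):
        loci = find_ssrs(_linear("C" * 30 + "A" * 11 + "G" * 30))
        assert _as_tuples(loci) == [
            ("A", 1, 11, 31, 41),
            ("C", 1, 30, 1, 30),
            ("G", 1, 30, 42, 71),
        ]

    def test_nine_bases_below_mono_threshold(self):
        loci = find_ssrs(_linear("CGTCGTCG" + "A" * 9 + "GTCGTCGT"))
        assert loci == []

    def test_tetranucleotide_ttgt_times_three(self):
        loci = find_ssrs(_linear("CAGCAGCAGC" + "TTGT" * 3 + "ACGACGACGA"))
        assert _as_tuples(loci) == [("TTGT", 4, 3, 11, 22)]

    def test_mono_run_not_reported_as_dinucleotide(self):
        # the A-run appears once, under period 1 only; the flanking GC/CG
        # di-repeats are separate loci of their own motif
        loci = find_ssrs(_linear("GC" * 5 + "A" * 12 + "CG" * 5))
        assert _as_tuples(loci) == [
            ("A", 1, 12, 11, 22),
            ("CG", 2, 5, 23, 32),
            ("GC", 2, 5, 1, 10),
        ]

    def test_forward_strand_motifs_not_canonicalized(self):
        loci = find_ssrs(_linear("G" * 5 + "T" * 10 + "C" * 5))
        assert [s.motif for s in loci] == ["T"]

    def test_repeat_count_floors_partial_unit(self):
        # 3.5 AT units: locus spans only the three whole units
        loci = find_ssrs(
            _linear("CCGCCG" + "ATATATA" + "GGCGGC"),
            SSRThresholds({1: 10, 2: 3, 3: 4, 4: 3, 5: 3, 6: 3}),
        )
        assert _as_tuples(loci) == [("AT", 2, 3, 7, 12)]

    def test_origin_spanning_repeat_on_circular_genome(self):
        seq = "A" * 6 + "CGTCGATCGGTACGCTG" + "A" * 5
        loci = find_ssrs(CircularGenome("circ", seq))
        assert len(loci) == 1
        (locus,) = loci
        assert (locus.motif, locus.n_repeats, locus.wrapped) == ("A", 11, True)
        assert (locus.start, locus.end) == (24, 6)

    def test_empty_genome_classes(self):
        summary = summarize_ssrs([])
        assert summary.n_total == 0
        assert summary.at_share_percent is None


class TestOracleEquivalence:
    def test_random_sequences_match_brute_force(self):
        rng = np.random.default_rng(42)
        thresholds = SSRThresholds()
        for trial in range(220):
            n = int(rng.integers(300, 1200))
            alphabet = ("ACGT", "AT", "AAT", "ACG")[trial % 4]
            seq = random_dna(rng, n, alphabet)
            got = _as_tuples(find_ssrs(_linear(seq), thresholds))
            expected = brute_force_ssrs(seq, DEFAULT_MIN_REPEATS)
            assert got == expected, f"trial {trial} diverged"

    @settings(max_examples=80, deadline=None, derandomize=True)
    @given(st.text(alphabet="ACGT", min_size=20, max_size=400))
    def test_property_scanner_equals_oracle(self, seq):
        low = SSRThresholds({1: 4, 2: 3, 3: 2, 4: 2, 5: 2, 6: 2})
        got = _as_tuples(find_ssrs(_linear(seq), low))
        assert got == brute_force_ssrs(seq, low.min_repeats_by_unit)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.text(alphabet="AT", min_size=20, max_size=200))
    def test_property_low_complexity_equals_oracle(self, seq):
        got = _as_tuples(find_ssrs(_linear(seq)))
        assert got == brute_force_ssrs(seq, DEFAULT_MIN_REPEATS)


class TestInvariants:
    def test_maximality_and_no_same_motif_overlap(self, rng):
        for _ in range(30):
            seq = random_dna(rng, 800, "AT")
            loci = find_ssrs(_linear(seq))
            for s in loci:
                assert s.end - s.start + 1 == s.unit_length * s.n_repeats
                # flanks do not extend the perfect repeat
                if s.start > 1:
                    left = seq[s.start - 2]
                    assert left != seq[s.start - 2 + s.unit_length]
            by_motif = {}
            for s in loci:
                by_motif.setdefault(s.motif, []).append((s.start, s.end))
            for intervals in by_motif.values():
                intervals.sort()
                for (a1, b1), (a2, b2) in zip(intervals, intervals[1:]):
                    assert b1 < a2

    def test_planted_ssrs_recovered_exactly(self, small_pair):
        found = _as_tuples(find_ssrs(small_pair["genome"]))
        for s in small_pair["gen_truth"].ssrs:
            assert (s.motif, s.unit_length, s.n_repeats, s.start, s.end) in found


def test_class_summary_counts():
    loci = find_ssrs(
        _linear("A" * 10 + "GC" * 3 + "T" * 11 + "CGC" + "TA" * 5 + "GGG")
    )
    summary = summarize_ssrs(loci)
    assert summary.counts_by_unit[1] == 2
    assert summary.counts_by_unit[2] == 1
    assert summary.at_like_count == 3
    assert summary.at_share_percent == 100.0
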