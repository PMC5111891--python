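"""Quadripartite structure detection and canonical rotation."""

import numpy as np
import pytest

from plastcomp import (
    AmbiguousStructureError,
    CircularGenome,
    NoQuadripartiteStructureError,
    SequenceError,
    canonical_rotation,
    detect_inverted_repeats,
    gc_content,
    revcomp,
)

from .conftest import random_dna
from .oracles import brute_force_inverted_pairs


class TestGCContent:
    @pytest.mark.parametrize(
        "seq,expected",
        [("GGCC", 1.0), ("ATAT", 0.0), ("ATGCN", 0.5), ("ACGT", 0.5)],
    )
    def test_examples(self, seq, expected):
        assert gc_content(seq) == expected

    def test_ambiguity_codes_excluded_from_both_sides(self):
        assert gc_content("GNNNNC") == 1.0

    def test_empty_and_all_n_rejected(self):
        with pytest.raises(SequenceError):
            gc_content("")
        with pytest.raises(SequenceError):
            gc_content("NNNN")


def _planted_genome(rng, lsc=60_000, ir=10_000, ssc=8_000):
    """LSC + IRb + SSC + revcomp(IRb) with non-extendable IR flanks."""
    l = list(random_dna(rng, lsc))
    r = random_dna(rng, ir)
    s = list(random_dna(rng, ssc))
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    if l[-1] == comp[l[0]]:
        l[-1] = [b for b in "ACGT" if b != comp[l[0]]][0]
    if s[0] == comp[s[-1]]:
        s[0] = [b for b in "ACGT" if b != comp[s[-1]]][0]
    return CircularGenome("planted", "".join(l) + r + "".join(s) + revcomp(r))


class TestDetection:
    def test_planted_sixty_ten_eight_kb(self, rng):
        genome = _planted_genome(rng)
        structure = detect_inverted_repeats(genome)
        assert structure.ir_length == 10_000
        assert structure.region("LSC").length == 60_000
        assert structure.region("SSC").length == 8_000
        # boundaries at the planted junctions
        assert structure.region("LSC").start == 1
        assert structure.region("IRb").start == 60_001
        assert structure.region("SSC").start == 70_001
        assert structure.region("IRa").start == 78_001

    def test_region_lengths_tile_the_circle(self, rng):
        genome = _planted_genome(rng, 12_000, 2_000, 3_000)
        structure = detect_inverted_repeats(genome)
        lsc = structure.region("LSC").length
        ssc = structure.region("SSC").length
        assert lsc + ssc + 2 * structure.ir_length == genome.length

    def test_ira_is_exact_revcomp_of_irb(self, rng):
        genome = _planted_genome(rng, 12_000, 2_000, 3_000)
        st = detect_inverted_repeats(genome)
        ira = st.region("IRa")
        irb = st.region("IRb")
        assert genome.slice(ira.start, ira.end) == revcomp(
            genome.slice(irb.start, irb.end)
        )

    def test_random_sequence_has_no_structure(self, rng):
        genome = CircularGenome("flat", random_dna(rng, 20_000))
        with pytest.raises(NoQuadripartiteStructureError):
            detect_inverted_repeats(genome, min_ir_length=1000)

    def test_rotation_invariance(self, rng):
        genome = _planted_genome(rng, 12_000, 2_000, 3_000)
        reference = detect_inverted_repeats(genome)
        for shift in (1, 1_234, 9_999, 15_000):
            rotated = genome.rotated(shift + 1)
            st = detect_inverted_repeats(rotated)
            assert st.ir_length == reference.ir_length
            assert st.region("LSC").length == reference.region("LSC").length
            assert st.region("SSC").length == reference.region("SSC").length

    def test_tied_maximal_pairs_signal_ambiguity(self, rng):
        # two unrelated inverted pairs of identical length; 'A' bookends
        # block any flank extension ('A' never pairs with 'A')
        r1, r2 = random_dna(rng, 1_500), random_dna(rng, 1_500)
        seq = (
            random_dna(rng, 4_000) + "A" + r1 + "A"
            + random_dna(rng, 3_000) + "A" + r2 + "A"
            + random_dna(rng, 2_000) + "A" + revcomp(r1) + "A"
            + random_dna(rng, 2_500) + "A" + revcomp(r2) + "A"
            + random_dna(rng, 1_000)
        )
        genome = CircularGenome("tied", seq)
        with pytest.raises(AmbiguousStructureError):
            detect_inverted_repeats(genome, min_ir_length=1000)

    def test_matches_brute_force_on_small_genomes(self, rng):
        for seed in range(3):
            local = np.random.default_rng(seed)
            genome = _planted_genome(local, 1_200, 300, 500)
            structure = detect_inverted_repeats(genome, min_ir_length=100)
            pairs = brute_force_inverted_pairs(genome.sequence, 100)
            best = max(p[0][1] - p[0][0] + 1 for p in pairs)
            assert structure.ir_length == best
            (s1, e1), (s2, e2) = max(
                pairs, key=lambda p: p[0][1] - p[0][0] + 1
            )
            assert {structure.region("IRb").start, structure.region("IRa").start} \
                == {s1 + 1, s2 + 1}


class TestCanonicalRotation:
    def test_idempotent_on_canonical_input(self, rng):
        genome = _planted_genome(rng, 12_000, 2_000, 3_000)
        # pin orientation the way the generator does
        seq = "A" + genome.sequence[1:11_999] + "A" + genome.sequence[12_000:]
        genome = CircularGenome("pin", seq)
        st = detect_inverted_repeats(genome)
        assert canonical_rotation(st, genome).sequence == genome.sequence

    def test_rotation_and_revcomp_restore_original(self, small_pair):
        genome = small_pair["genome"]
        for variant in (genome.rotated(1_235), genome.reverse_complement()):
            st = detect_inverted_repeats(variant)
            assert canonical_rotation(st, variant).sequence == genome.sequence

    def test_redetection_on_canonical_output_starts_lsc_at_one(self, small_pair):
        genome = small_pair["genome"].rotated(4_321)
        st = detect_inverted_repeats(genome)
        canonical = canonical_rotation(st, genome)
        st2 = detect_inverted_repeats(canonical)
        assert st2.region("LSC").start == 1
        assert st2.ir_length == st.ir_length
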