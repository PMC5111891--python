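"""Micro-inversion detection and hairpin stem-arm characterisation.

A micro-inversion shows up in a collinear alignment as a short run of
mismatching columns whose other-genome segment equals the reverse complement
of the standard's segment. Such segments are typically flanked by short
inverted-repeat arms that can pair into a hairpin stem; arms are measured by
complementarity length strictly outside the inverted interval (no
free-energy folding).
"""

from __future__ import annotations

from .align import GAP, PairwiseAlignment
from .annotations import GeneFeature, classify_position
from .genome import CircularGenome, revcomp
from .mutations import InversionEvent

DEFAULT_MIN_INV = 3
DEFAULT_MAX_INV = 100
DEFAULT_MAX_ARM = 50


def find_stem_arms(
    genome: CircularGenome,
    interval: tuple[int, int],
    max_arm: int = DEFAULT_MAX_ARM,
    max_mismatches: int = 0,
) -> int:
    """Length of the inverted-repeat arms flanking an interval.

    The longest a <= max_arm such that the a bases immediately 5' of the
    interval are the reverse complement of the a bases immediately 3' of it
    (allowing up to max_mismatches mismatched pairs); 0 if none.
    """
    start, end = interval
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    best = 0
    mismatches = 0
    for a in range(1, max_arm + 1):
        left = genome.base(start - a)
        right = genome.base(end + a)
        if comp.get(left) != right:
            mismatches += 1
            if mismatches > max_mismatches:
                break
        best = a
    return best


def detect_microinversions(
    aln: PairwiseAlignment,
    min_len: int = DEFAULT_MIN_INV,
    max_len: int = DEFAULT_MAX_INV,
    genome: CircularGenome | None = None,
    features: list[GeneFeature] | None = None,
    max_arm: int = DEFAULT_MAX_ARM,
    arm_max_mismatches: int = 0,
) -> list[InversionEvent]:
    """Inverted segments between the aligned pair.

    Each maximal run of mismatching (gap-free) columns of length within
    [min_len, max_len] whose other-genome segment equals the reverse
    complement of the standard's segment is emitted as one inversion. When
    `genome` (the standard) is given, stem arms are measured around each
    interval; when `features` are given, events carry a location label.
    A palindromic segment (equal to its own reverse complement) never
    produces mismatch columns, so it is undetectable by construction.
    """
    if min_len < 2:
        raise ValueError(
            "min_len must be >= 2: a 1 bp inverted segment is "
            "indistinguishable from a substitution"
        )
    ref_len = len(aln.ref_seq)
    events = []
    col = 0
    n = aln.n_columns
    while col < n:
        cr, ca = aln.ref_aln[col], aln.alt_aln[col]
        if cr == GAP or ca == GAP or cr == ca:
            col += 1
            continue
        start = col
        while col < n:
            cr, ca = aln.ref_aln[col], aln.alt_aln[col]
            if cr == GAP or ca == GAP or cr == ca:
                break
            col += 1
        end = col  # exclusive
        run = end - start
        if not (min_len <= run <= max_len):
            continue
        ref_seg = aln.ref_aln[start:end]
        alt_seg = aln.alt_aln[start:end]
        if alt_seg != revcomp(ref_seg):
            continue  # a plain cluster of substitutions
        ref_start = aln.ref_coords[start]
        ref_end = aln.ref_coords[end - 1]
        arm = (
            find_stem_arms(genome, (ref_start, ref_end), max_arm,
                           arm_max_mismatches)
            if genome is not None
            else 0
        )
        loc = (
            classify_position(ref_start, features, ref_len)
            if features is not None
            else None
        )
        events.append(InversionEvent(ref_start, ref_end, run, arm, loc))
    return events


def write_inversions_tsv(events: list[InversionEvent], path) -> None:
    with open(path, "w") as fh:
        fh.write("ref_start\tref_end\tlength\tstem_arm_length\tlocation\n")
        for e in events:
            loc = e.location.context if e.location else "NA"
            fh.write(
                f"{e.ref_start}\t{e.ref_end}\t{e.length}\t"
                f"{e.stem_arm_length}\t{loc}\n"
            )
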