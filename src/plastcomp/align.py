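"""Anchor-based collinear alignment of two near-identical genomes.

Plastome pairs within a genus diverge by hundredths of a percent, so a full
dynamic-programming alignment is unnecessary: unique shared k-mers are
chained as anchors and only the short inter-anchor segments are resolved by
optimal global alignment (match +1, mismatch -1, gap open -5, gap extend -1,
via Bio.Align.PairwiseAligner). Both inputs must be canonically rotated; a
rotated or rearranged input fails the anchor-coverage check.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass, field

from Bio import Align

from .errors import NonCollinearError
from .genome import CircularGenome

DEFAULT_ANCHOR_K = 21
DEFAULT_MIN_COVERAGE = 0.9
DEFAULT_MAX_FILL = 20_000

GAP = "-"


@dataclass
class PairwiseAlignment:
    """A gapped pairwise alignment of the standard (ref) and other (alt).

    Invariants: removing gaps reproduces each input exactly; no column is a
    gap in both rows.
    """

    ref_id: str
    alt_id: str
    ref_aln: str
    alt_aln: str
    ref_coords: list[int | None] = field(init=False, repr=False)
    alt_coords: list[int | None] = field(init=False, repr=False)

    def __post_init__(self):
        if len(self.ref_aln) != len(self.alt_aln):
            raise ValueError("alignment rows differ in length")
        self.ref_coords = []
        self.alt_coords = []
        r = a = 0
        for cr, ca in zip(self.ref_aln, self.alt_aln):
            if cr == GAP and ca == GAP:
                raise ValueError("column gapped in both rows")
            if cr == GAP:
                self.ref_coords.append(None)
            else:
                r += 1
                self.ref_coords.append(r)
            if ca == GAP:
                self.alt_coords.append(None)
            else:
                a += 1
                self.alt_coords.append(a)

    @property
    def n_columns(self) -> int:
        return len(self.ref_aln)

    @property
    def ref_seq(self) -> str:
        return self.ref_aln.replace(GAP, "")

    @property
    def alt_seq(self) -> str:
        return self.alt_aln.replace(GAP, "")


def _unique_kmers(seq: str, k: int) -> dict[str, int]:
    pos: dict[str, int] = {}
    dup: set[str] = set()
    for i in range(len(seq) - k + 1):
        km = seq[i : i + k]
        if km in dup:
            continue
        if km in pos:
            del pos[km]
            dup.add(km)
        else:
            pos[km] = i
    return pos


def _chain(anchors: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Longest chain with both coordinates strictly increasing.

    Anchors are sorted by ref position; patience LIS on the alt positions.
    """
    if not anchors:
        return []
    tails: list[int] = []  # alt positions of chain tails
    tails_idx: list[int] = []
    parent = [-1] * len(anchors)
    for idx, (_, p2) in enumerate(anchors):
        j = bisect_left(tails, p2)
        if j == len(tails):
            tails.append(p2)
            tails_idx.append(idx)
        else:
            tails[j] = p2
            tails_idx[j] = idx
        parent[idx] = tails_idx[j - 1] if j > 0 else -1
    chain = []
    i = tails_idx[-1]
    while i != -1:
        chain.append(anchors[i])
        i = parent[i]
    chain.reverse()
    return chain


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -1
    return aligner


def _fill(aligner: Align.PairwiseAligner, s1: str, s2: str) -> tuple[str, str]:
    """Optimal global alignment of one inter-anchor segment pair."""
    if not s1 and not s2:
        return "", ""
    if not s1:
        return GAP * len(s2), s2
    if not s2:
        return s1, GAP * len(s1)
    aln = aligner.align(s1, s2)[0]
    return str(aln[0]), str(aln[1])


def align_pair(
    standard: CircularGenome,
    other: CircularGenome,
    k: int = DEFAULT_ANCHOR_K,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
    max_fill: int = DEFAULT_MAX_FILL,
) -> PairwiseAlignment:
    """Align two canonically rotated, collinear genomes.

    Raises
    ------
    NonCollinearError
        When the anchor chain covers less than `min_coverage` of either
        genome, or an inter-anchor segment exceeds `max_fill` bases.
    """
    s1, s2 = standard.sequence, other.sequence
    u1 = _unique_kmers(s1, k)
    u2 = _unique_kmers(s2, k)
    anchors = sorted(
        (p1, u2[km]) for km, p1 in u1.items() if km in u2
    )
    chain = _chain(anchors)
    if not chain:
        raise NonCollinearError(
            f"no shared unique {k}-mers between {standard.id!r} and {other.id!r}"
        )

    # merge chained anchors into maximal exact blocks on the same diagonal
    blocks: list[tuple[int, int, int]] = []  # (start1, start2, length)
    for p1, p2 in chain:
        if blocks:
            b1, b2, bl = blocks[-1]
            if p1 - b1 == p2 - b2 and p1 <= b1 + bl:
                blocks[-1] = (b1, b2, p1 + k - b1)
                continue
            if p1 < b1 + bl or p2 < b2 + bl:
                # off-diagonal overlap with the previous block: trim anchor
                delta = max(b1 + bl - p1, b2 + bl - p2)
                if delta >= k:
                    continue
                p1, p2 = p1 + delta, p2 + delta
                blocks.append((p1, p2, k - delta))
                continue
        blocks.append((p1, p2, k))

    covered = sum(bl for _, _, bl in blocks)
    if covered < min_coverage * len(s1) or covered < min_coverage * len(s2):
        raise NonCollinearError(
            f"anchor chain covers {covered} bp "
            f"({covered / len(s1):.1%} of {standard.id!r}); inputs are not "
            "collinear — check canonical rotation"
        )

    aligner = _make_aligner()
    ref_parts: list[str] = []
    alt_parts: list[str] = []
    pos1 = pos2 = 0
    for b1, b2, bl in blocks:
        g1, g2 = s1[pos1:b1], s2[pos2:b2]
        if len(g1) > max_fill or len(g2) > max_fill:
            raise NonCollinearError(
                f"inter-anchor segment of {max(len(g1), len(g2))} bp exceeds "
                f"max_fill={max_fill}"
            )
        fa, fb = _fill(aligner, g1, g2)
        ref_parts.append(fa)
        alt_parts.append(fb)
        ref_parts.append(s1[b1 : b1 + bl])
        alt_parts.append(s2[b2 : b2 + bl])
        pos1, pos2 = b1 + bl, b2 + bl
    fa, fb = _fill(aligner, s1[pos1:], s2[pos2:])
    ref_parts.append(fa)
    alt_parts.append(fb)

    aln = PairwiseAlignment(standard.id, other.id, "".join(ref_parts),
                            "".join(alt_parts))
    assert aln.ref_seq == s1 and aln.alt_seq == s2  # round-trip invariant
    return aln


def read_aligned_fasta(path) -> PairwiseAlignment:
    """Load a pre-computed two-record aligned FASTA (bypasses the aligner)."""
    from Bio import SeqIO

    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 2:
        raise NonCollinearError(f"{path}: expected exactly 2 aligned records")
    a, b = records
    return PairwiseAlignment(a.id, b.id, str(a.seq).upper(), str(b.seq).upper())
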