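"""Quadripartite plastome architecture: inverted-repeat detection.

Land-plant plastomes are organised as four regions on a circle: a large
single-copy region (LSC) and a small single-copy region (SSC) separated by
two copies of an inverted repeat (IRa, IRb), the second copy being the exact
reverse complement of the first. This module locates that architecture from
sequence alone and normalises genomes to the conventional LSC-first layout so
coordinates are comparable across genomes.

Detection is seed-and-extend: shared k-mers between the (doubled, to handle
circularity) sequence and its reverse complement seed candidate matches,
which are extended to maximal inverted pairs; a brute-force all-pairs scan is
kept in the test suite as the oracle for small genomes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

from .errors import (
    AmbiguousStructureError,
    NoQuadripartiteStructureError,
    SequenceError,
)
from .genome import CircularGenome, gc_content, revcomp

REGION_NAMES = ("LSC", "IRb", "SSC", "IRa")

DEFAULT_MIN_IR_LENGTH = 1000
DEFAULT_SEED_K = 21


@dataclass(frozen=True)
class Region:
    """One of the four plastome regions, as a 1-based circular interval."""

    name: str  # LSC | SSC | IRa | IRb
    start: int  # 1-based inclusive; may wrap (end < start)
    end: int
    length: int
    gc_fraction: float

    def __post_init__(self):
        if self.name not in REGION_NAMES:
            raise ValueError(f"bad region name {self.name!r}")
        if not (0.0 <= self.gc_fraction <= 1.0):
            raise ValueError("gc_fraction outside [0, 1]")


@dataclass(frozen=True)
class QuadripartiteStructure:
    """The four detected regions of one genome.

    Invariant: len(LSC) + len(SSC) + 2 * ir_length == total_length, and the
    regions tile the circle with no overlap or gap.
    """

    genome_id: str
    regions: dict[str, Region]
    ir_length: int
    total_length: int

    def __post_init__(self):
        lsc = self.regions["LSC"].length
        ssc = self.regions["SSC"].length
        if lsc + ssc + 2 * self.ir_length != self.total_length:
            raise ValueError("region lengths do not sum to genome length")

    def region(self, name: str) -> Region:
        return self.regions[name]

    def to_dict(self) -> dict:
        return {
            "genome_id": self.genome_id,
            "total_length": self.total_length,
            "ir_length": self.ir_length,
            "regions": [
                {
                    "region": r.name,
                    "start": r.start,
                    "end": r.end,
                    "length": r.length,
                    "gc_percent": round(100 * r.gc_fraction, 1),
                }
                for r in (self.regions[n] for n in REGION_NAMES)
            ],
        }


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------


def _maximal_inverted_matches(seq: str, min_len: int, max_mismatches: int, k: int):
    """Maximal inverted matches between the doubled sequence and its revcomp.

    Yields (i, j, m): D[i : i+m] pairs with revcomp(D[j : j+m]) where D is the
    doubled sequence and i, j are 0-based starts in D. Mismatch budget is spent
    greedily, right flank first.
    """
    L = len(seq)
    D = seq + seq
    RCD = revcomp(D)  # RCD[p] pairs with D[2L - 1 - p]
    n = len(D)
    kk = min(k, min_len)

    index: dict[str, list[int]] = {}
    for j in range(n - kk + 1):
        index.setdefault(RCD[j : j + kk], []).append(j)

    seen_diag: dict[int, list[tuple[int, int]]] = {}
    out = []
    for i in range(n - kk + 1):
        hits = index.get(D[i : i + kk])
        if not hits:
            continue
        for j in hits:
            d = i - j
            covered = False
            for a, b in seen_diag.get(d, ()):
                if a <= i and i + kk <= b:
                    covered = True
                    break
            if covered:
                continue
            # extend right then left under the mismatch budget
            budget = max_mismatches
            ri, rj = i + kk, j + kk
            while ri < n and rj < n and budget >= 0:
                if D[ri] != RCD[rj]:
                    if budget == 0:
                        break
                    budget -= 1
                ri += 1
                rj += 1
            li, lj = i - 1, j - 1
            while li >= 0 and lj >= 0 and budget >= 0:
                if D[li] != RCD[lj]:
                    if budget == 0:
                        break
                    budget -= 1
                li -= 1
                lj -= 1
            a, b = li + 1, ri  # match is D[a:b] vs RCD[...]
            m = b - a
            seen_diag.setdefault(d, []).append((a, b))
            if m >= min_len:
                out.append((a, a - d, m))
    return out, L


def _normalize_pair(i: int, j: int, m: int, L: int):
    """Convert a doubled-space match to an unordered pair of circular intervals.

    The match is D[i : i+m] == revcomp(D[j2 : j2+m]) with j2 = 2L - (j + m)
    where j indexes RCD. Returns ((s1, m), (s2, m)) with 0-based circular
    starts, ordered so the pair is canonical.
    """
    j2 = 2 * L - (j + m)
    s1, s2 = i % L, j2 % L
    if s1 > s2:
        s1, s2 = s2, s1
    return (s1, s2, m)


def _arcs_disjoint(s1: int, s2: int, m: int, L: int) -> bool:
    """True if circular arcs [s1, s1+m) and [s2, s2+m) do not overlap."""
    if 2 * m > L:
        return False
    return (s2 - s1) % L >= m and (s1 - s2) % L >= m


def detect_inverted_repeats(
    genome: CircularGenome,
    min_ir_length: int = DEFAULT_MIN_IR_LENGTH,
    max_mismatches: int = 0,
    seed_k: int = DEFAULT_SEED_K,
) -> QuadripartiteStructure:
    """Locate the quadripartite LSC-IRb-SSC-IRa architecture.

    Finds the maximal-length pair of disjoint segments such that one is the
    reverse complement of the other (allowing up to `max_mismatches`
    mismatches), and labels the longer intervening arc LSC and the shorter
    SSC. Detection is invariant under circular rotation of the input; reported
    coordinates are 1-based on the input rotation.

    Raises
    ------
    NoQuadripartiteStructureError
        If no inverted pair of at least `min_ir_length` exists.
    AmbiguousStructureError
        If two non-equivalent maximal pairs tie in length.
    """
    if min_ir_length < 1:
        raise ValueError("min_ir_length must be >= 1")
    L = genome.length
    if L < 2 * min_ir_length:
        raise NoQuadripartiteStructureError(
            f"genome {genome.id!r} ({L} bp) shorter than 2 x min_ir_length"
        )

    matches, _ = _maximal_inverted_matches(
        genome.sequence, min_ir_length, max_mismatches, seed_k
    )
    pairs = set()
    for i, j, m in matches:
        m = min(m, L)  # a match cannot exceed one full period
        s1, s2, m = _normalize_pair(i, j, m, L)
        if _arcs_disjoint(s1, s2, m, L):
            pairs.add((s1, s2, m))
    if not pairs:
        raise NoQuadripartiteStructureError(
            f"no inverted repeat pair >= {min_ir_length} bp in {genome.id!r}"
        )

    best_m = max(p[2] for p in pairs)
    best = sorted(p for p in pairs if p[2] == best_m)
    if len(best) > 1:
        raise AmbiguousStructureError(
            f"{len(best)} maximal inverted pairs of {best_m} bp tie in "
            f"{genome.id!r}; lower min_ir_length to inspect candidates"
        )
    s1, s2, m = best[0]

    # arcs between the two IR copies: from end of copy A to start of copy B
    arc1 = ((s2 - (s1 + m)) % L, (s1 + m) % L)  # (length, 0-based start)
    arc2 = ((s1 - (s2 + m)) % L, (s2 + m) % L)
    if arc1[0] == 0 or arc2[0] == 0:
        raise NoQuadripartiteStructureError(
            "IR copies are adjacent; no single-copy regions"
        )
    (lsc_len, lsc_start0), (ssc_len, ssc_start0) = sorted(
        (arc1, arc2), reverse=True
    )
    if lsc_len == ssc_len:
        raise AmbiguousStructureError("the two single-copy arcs tie in length")

    # IRb is the copy immediately following LSC in forward orientation
    irb_start0 = (lsc_start0 + lsc_len) % L
    ira_start0 = (ssc_start0 + ssc_len) % L

    def mk(name: str, start0: int, length: int) -> Region:
        start = start0 + 1
        end = (start0 + length - 1) % L + 1
        seq = genome.slice(start, end)
        return Region(name, start, end, length, gc_content(seq))

    regions = {
        "LSC": mk("LSC", lsc_start0, lsc_len),
        "IRb": mk("IRb", irb_start0, m),
        "SSC": mk("SSC", ssc_start0, ssc_len),
        "IRa": mk("IRa", ira_start0, m),
    }
    return QuadripartiteStructure(genome.id, regions, m, L)


def canonical_rotation(
    structure: QuadripartiteStructure, genome: CircularGenome
) -> CircularGenome:
    """Rotate (and, if needed, reverse-complement) to the LSC-first layout.

    The canonical layout places the first LSC base at position 1 so the
    regions read LSC, IRb, SSC, IRa in forward orientation. Both the forward
    and the reverse-complement orientation admit such a layout; the
    lexicographically smaller sequence is chosen, making the result a
    deterministic function of the circular molecule. Idempotent.
    """
    if structure.total_length != genome.length:
        raise ValueError("structure does not belong to this genome")
    L = genome.length
    fwd = genome.rotated(structure.region("LSC").start)
    # under reverse complement, position p maps to L + 1 - p; LSC start is
    # the image of the forward LSC end
    rc = genome.reverse_complement().rotated(L + 1 - structure.region("LSC").end)
    chosen = fwd if fwd.sequence <= rc.sequence else rc
    return CircularGenome(genome.id, chosen.sequence, genome.is_circular)


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------


def write_structure_tsv(structure: QuadripartiteStructure, path: str | Path) -> None:
    """Region table: region, start, end, length, gc_percent."""
    with open(path, "w") as fh:
        fh.write("region\tstart\tend\tlength\tgc_percent\n")
        for r in structure.to_dict()["regions"]:
            fh.write(
                f"{r['region']}\t{r['start']}\t{r['end']}\t"
                f"{r['length']}\t{r['gc_percent']:.1f}\n"
            )


def write_structure_json(structure: QuadripartiteStructure, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(structure.to_dict(), fh, indent=2)
        fh.write("\n")
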