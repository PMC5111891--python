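"""Simple-sequence-repeat (microsatellite) scanning.

Finds every maximal perfect tandem repeat of a 1-6 bp motif that meets a
class-specific minimum repeat count. Motifs are reported exactly as they
appear on the forward strand (A-runs and T-runs are distinct loci), a run is
reported under its primitive (smallest) period only, and repeat counts are
whole units — a trailing partial unit is not part of the locus span.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .annotations import GeneFeature, LocationLabel, classify_position
from .genome import CircularGenome

DEFAULT_MIN_REPEATS = {1: 10, 2: 5, 3: 4, 4: 3, 5: 3, 6: 3}


@dataclass(frozen=True)
class SSRThresholds:
    """Minimum repeat count per motif unit length (1..6)."""

    min_repeats_by_unit: dict[int, int] = field(
        default_factory=lambda: dict(DEFAULT_MIN_REPEATS)
    )

    def __post_init__(self):
        missing = set(range(1, 7)) - set(self.min_repeats_by_unit)
        if missing:
            raise ValueError(f"thresholds missing unit lengths {sorted(missing)}")


@dataclass(frozen=True)
class SSRLocus:
    """One microsatellite hit; 1-based inclusive coordinates.

    end - start + 1 == unit_length * n_repeats (end wraps past the origin on
    circular genomes when `wrapped` is set).
    """

    motif: str
    unit_length: int
    n_repeats: int
    start: int
    end: int
    location: LocationLabel | None = None
    wrapped: bool = False


def _is_primitive(motif: str) -> bool:
    """True if the motif is not itself a repetition of a shorter unit."""
    n = len(motif)
    for d in range(1, n):
        if n % d == 0 and motif == motif[: d] * (n // d):
            return False
    return True


def find_ssrs(
    genome: CircularGenome,
    thresholds: SSRThresholds | None = None,
    features: list[GeneFeature] | None = None,
) -> list[SSRLocus]:
    """All maximal perfect tandem repeats meeting the class thresholds.

    On circular genomes, repeats spanning the origin are detected on the
    doubled sequence and reported with wrapped coordinates. If `features` is
    given, each locus carries a location label (classified at its start).
    """
    thresholds = thresholds or SSRThresholds()
    L = genome.length
    seq = genome.sequence + genome.sequence if genome.is_circular else genome.sequence
    n = len(seq)

    loci: list[SSRLocus] = []
    for u in range(1, 7):
        min_rep = thresholds.min_repeats_by_unit[u]
        if u * 2 > n:
            continue
        i = 0
        limit = n - u
        while i < limit:
            if seq[i] != seq[i + u]:
                i += 1
                continue
            run_start = i
            while i < limit and seq[i] == seq[i + u]:
                i += 1
            # period-u region [a, b] (0-based inclusive)
            a, b = run_start, i - 1 + u
            if genome.is_circular:
                if a >= L:
                    continue  # duplicate of a region in the first copy
                if a == 0 and seq[L - 1] == seq[L - 1 + u]:
                    continue  # left-extendable across the origin; the
                    # wrapped region is reported instead
                b = min(b, a + L - 1)  # cap fully-periodic genomes
            repeats = (b - a + 1) // u
            if repeats < min_rep:
                continue
            motif = seq[a : a + u]
            if not _is_primitive(motif):
                continue  # reported under its primitive period
            start = a + 1
            end0 = a + repeats * u - 1  # 0-based inclusive
            wrapped = end0 >= L
            end = end0 % L + 1 if genome.is_circular else end0 + 1
            loci.append(SSRLocus(motif, u, repeats, start, end, wrapped=wrapped))

    loci.sort(key=lambda s: (s.start, s.unit_length))
    if features is not None:
        loci = [
            SSRLocus(
                s.motif, s.unit_length, s.n_repeats, s.start, s.end,
                classify_position(s.start, features, L), s.wrapped,
            )
            for s in loci
        ]
    return loci


@dataclass(frozen=True)
class SSRSummary:
    """Per-class locus counts and the A/T-dominance share.

    at_share_percent is the percentage (two decimals) of loci that are A or T
    mono-nucleotide runs or AT/TA di-nucleotide repeats; None when no loci.
    """

    counts_by_unit: dict[int, int]
    n_total: int
    at_like_count: int
    at_share_percent: float | None


def summarize_ssrs(loci: list[SSRLocus]) -> SSRSummary:
    counts = {u: 0 for u in range(1, 7)}
    at_like = 0
    for s in loci:
        counts[s.unit_length] += 1
        if (s.unit_length == 1 and s.motif in ("A", "T")) or (
            s.unit_length == 2 and s.motif in ("AT", "TA")
        ):
            at_like += 1
    total = len(loci)
    share = round(100.0 * at_like / total, 2) if total else None
    return SSRSummary(counts, total, at_like, share)


def write_ssr_tsv(loci: list[SSRLocus], path) -> None:
    """Locus table: No., Location, Motif, No. of repeats, SSR start, SSR end."""
    with open(path, "w") as fh:
        fh.write("no\tlocation\tmotif\tn_repeats\tssr_start\tssr_end\twrapped\n")
        for i, s in enumerate(loci, 1):
            loc = s.location.context if s.location else "NA"
            fh.write(
                f"{i}\t{loc}\t{s.motif}\t{s.n_repeats}\t{s.start}\t{s.end}\t"
                f"{'yes' if s.wrapped else 'no'}\n"
            )
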