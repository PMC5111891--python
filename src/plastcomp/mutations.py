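"""Substitution and indel calling, classification, and summary statistics.

Events are reported on the designated standard genome: an Insertion means
the standard carries bases the other genome lacks, a Deletion means the
standard has the gap. Substitutions are classed as transitions (purine to
purine, pyrimidine to pyrimidine) or transversions; indels as homopolymeric
(single-base events adjacent to a run of that base, the slippage signature)
or non-homopolymeric. Indels are left-normalized so equivalent gap
placements get one canonical representation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .align import GAP, PairwiseAlignment
from .annotations import GeneFeature, LocationLabel, classify_position
from .errors import SequenceError
from .genome import revcomp

DEFAULT_HOMOPOLYMER_MIN_RUN = 3

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")


def classify_substitution(ref_base: str, alt_base: str) -> str:
    """'transition' if both bases are purines or both pyrimidines."""
    pair = {ref_base.upper(), alt_base.upper()}
    if len(pair) != 2:
        raise ValueError("substitution requires two distinct bases")
    if pair <= _PURINES or pair <= _PYRIMIDINES:
        return "transition"
    return "transversion"


_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def spectrum_type(ref_base: str, alt_base: str) -> str:
    """Canonical label of the six non-strand-specific substitution types.

    A change and its reverse-strand counterpart (e.g. G>A and C>T) pool into
    one type, labelled by the lexicographically smaller member.
    """
    a = f"{ref_base}>{alt_base}"
    b = f"{_COMP[ref_base]}>{_COMP[alt_base]}"
    return f"{a}/{b}" if a <= b else f"{b}/{a}"


@dataclass(frozen=True)
class SubstitutionEvent:
    ref_pos: int  # 1-based on the standard genome
    ref_base: str
    alt_base: str
    klass: str  # transition | transversion
    location: LocationLabel | None = None


@dataclass(frozen=True)
class IndelEvent:
    """ref_pos is the base immediately left of the event (0 at the origin)."""

    ref_pos: int
    seq: str  # the inserted-or-deleted bases
    length: int
    klass: str  # homopolymeric | non_homopolymeric
    direction: str  # Insertion | Deletion (relative to the standard)
    location: LocationLabel | None = None


@dataclass(frozen=True)
class InversionEvent:
    """A short segment present in reverse-complement orientation in the
    other genome, with the length of the flanking inverted-repeat (hairpin
    stem) arms measured strictly outside the interval."""

    ref_start: int
    ref_end: int
    length: int
    stem_arm_length: int = 0
    location: LocationLabel | None = None


# ---------------------------------------------------------------------------
# calling
# ---------------------------------------------------------------------------


def _excluded(pos: int, intervals) -> bool:
    return any(s <= pos <= e for s, e in intervals)


def call_substitutions(
    aln: PairwiseAlignment,
    features: list[GeneFeature] | None = None,
    exclude_intervals: tuple[tuple[int, int], ...] = (),
) -> list[SubstitutionEvent]:
    """One event per mismatched non-gap column, outside excluded intervals.

    `exclude_intervals` (1-based, on the standard) masks detected
    micro-inversions so their columns do not surface as false SNPs.
    """
    ref_len = len(aln.ref_seq)
    out = []
    for col in range(aln.n_columns):
        cr, ca = aln.ref_aln[col], aln.alt_aln[col]
        if cr == GAP or ca == GAP or cr == ca:
            continue
        pos = aln.ref_coords[col]
        if _excluded(pos, exclude_intervals):
            continue
        loc = (
            classify_position(pos, features, ref_len)
            if features is not None
            else None
        )
        out.append(
            SubstitutionEvent(pos, cr, ca, classify_substitution(cr, ca), loc)
        )
    return out


def left_normalize(ref_seq: str, ref_pos: int, seq: str) -> tuple[int, str]:
    """Shift an indel to its leftmost equivalent placement.

    `ref_pos` is 1-based (base immediately left of the event); while that
    base equals the last event base the event rotates one step left.
    Idempotent once normalized.
    """
    while ref_pos >= 1 and ref_seq[ref_pos - 1] == seq[-1]:
        seq = seq[-1] + seq[:-1]
        ref_pos -= 1
    return ref_pos, seq


def _homopolymer_class(ref_seq: str, ref_pos: int, seq: str, min_run: int) -> str:
    """homopolymeric iff the event is a single-base run and the standard
    carries a run of that base of >= min_run starting right of the event."""
    base = seq[0]
    if any(c != base for c in seq):
        return "non_homopolymeric"
    run = 0
    i = ref_pos  # 0-based index of the base right of the event position
    while i < len(ref_seq) and ref_seq[i] == base:
        run += 1
        i += 1
    return "homopolymeric" if run >= min_run else "non_homopolymeric"


def call_indels(
    aln: PairwiseAlignment,
    features: list[GeneFeature] | None = None,
    homopolymer_min_run: int = DEFAULT_HOMOPOLYMER_MIN_RUN,
    exclude_intervals: tuple[tuple[int, int], ...] = (),
) -> list[IndelEvent]:
    """Maximal gap runs become left-normalized, classified indel events."""
    ref_seq = aln.ref_seq
    ref_len = len(ref_seq)
    out = []
    col = 0
    n = aln.n_columns
    while col < n:
        cr, ca = aln.ref_aln[col], aln.alt_aln[col]
        if cr != GAP and ca != GAP:
            col += 1
            continue
        gap_row = "ref" if cr == GAP else "alt"
        start = col
        while col < n and (
            (aln.ref_aln[col] == GAP) if gap_row == "ref"
            else (aln.alt_aln[col] == GAP)
        ):
            col += 1
        end = col  # exclusive
        if gap_row == "alt":
            # standard carries the bases -> Insertion
            seq = aln.ref_aln[start:end]
            ref_pos = aln.ref_coords[start] - 1
            direction = "Insertion"
        else:
            seq = aln.alt_aln[start:end]
            # base immediately left of the gap on the standard
            prev = next(
                (aln.ref_coords[c] for c in range(start - 1, -1, -1)
                 if aln.ref_coords[c] is not None),
                0,
            )
            ref_pos = prev
            direction = "Deletion"
        ref_pos, seq = left_normalize(ref_seq, ref_pos, seq)
        if _excluded(ref_pos, exclude_intervals) or _excluded(
            ref_pos + 1, exclude_intervals
        ):
            continue
        klass = _homopolymer_class(ref_seq, ref_pos, seq, homopolymer_min_run)
        loc = (
            classify_position(min(ref_pos + 1, ref_len), features, ref_len)
            if features is not None
            else None
        )
        out.append(IndelEvent(ref_pos, seq, len(seq), klass, direction, loc))
    out.sort(key=lambda e: e.ref_pos)
    return out


def p_distance(
    aln: PairwiseAlignment,
    rounding: int = 5,
    exclude_intervals: tuple[tuple[int, int], ...] = (),
) -> float:
    """Proportion of differing sites among gap-free aligned sites.

    Gap columns are excluded pairwise; `exclude_intervals` (standard
    coordinates) additionally masks micro-inversion columns.
    """
    comparable = diff = 0
    for col in range(aln.n_columns):
        cr, ca = aln.ref_aln[col], aln.alt_aln[col]
        if cr == GAP or ca == GAP:
            continue
        if exclude_intervals and _excluded(aln.ref_coords[col], exclude_intervals):
            continue
        comparable += 1
        if cr != ca:
            diff += 1
    if comparable == 0:
        raise SequenceError("no comparable (gap-free) columns")
    return round(diff / comparable, rounding)


# ---------------------------------------------------------------------------
# reconstruction (round-trip oracle used by tests and the pipeline checks)
# ---------------------------------------------------------------------------


def reconstruct(
    standard_seq: str,
    substitutions: list[SubstitutionEvent] = (),
    indels: list[IndelEvent] = (),
    inversions: list[InversionEvent] = (),
) -> str:
    """Rebuild the other genome from the standard plus the full event list."""
    seq = list(standard_seq)
    for s in substitutions:
        if seq[s.ref_pos - 1] != s.ref_base:
            raise ValueError(f"substitution at {s.ref_pos}: ref base mismatch")
        seq[s.ref_pos - 1] = s.alt_base
    for inv in inversions:
        seg = standard_seq[inv.ref_start - 1 : inv.ref_end]
        seq[inv.ref_start - 1 : inv.ref_end] = list(revcomp(seg))
    # apply right-to-left so earlier coordinates stay valid
    for ind in sorted(indels, key=lambda e: -e.ref_pos):
        if ind.direction == "Insertion":
            del seq[ind.ref_pos : ind.ref_pos + ind.length]
        else:
            seq[ind.ref_pos : ind.ref_pos] = list(ind.seq)
    return "".join(seq)


# ---------------------------------------------------------------------------
# summary
# ---------------------------------------------------------------------------


@dataclass
class MutationSummary:
    n_substitutions: int
    n_indels: int
    n_inversions: int
    n_ts: int
    n_tv: int
    ts_tv_ratio: float | None
    p_distance: float | None
    counts_by_location: dict[str, dict[str, int]]
    substitution_spectrum: dict[str, int]
    per_gene_ts_tv: dict[str, dict[str, int]] = field(default_factory=dict)

    @property
    def n_total(self) -> int:
        return self.n_substitutions + self.n_indels + self.n_inversions

    def to_dict(self) -> dict:
        return {
            "n_substitutions": self.n_substitutions,
            "n_indels": self.n_indels,
            "n_inversions": self.n_inversions,
            "n_total": self.n_total,
            "n_ts": self.n_ts,
            "n_tv": self.n_tv,
            "ts_tv_ratio": self.ts_tv_ratio,
            "p_distance": self.p_distance,
            "counts_by_location": self.counts_by_location,
            "substitution_spectrum": self.substitution_spectrum,
            "per_gene_ts_tv": self.per_gene_ts_tv,
        }


def summarize_mutations(
    substitutions: list[SubstitutionEvent],
    indels: list[IndelEvent] = (),
    inversions: list[InversionEvent] = (),
    aln: PairwiseAlignment | None = None,
    ratio_rounding: int = 2,
    p_rounding: int = 5,
) -> MutationSummary:
    """All headline statistics of one pairwise comparison.

    Ts/Tv ratio to 2 decimals (None when no transversions), p-distance to 5
    decimals with micro-inversion columns masked, six-type pooled
    substitution spectrum, per-location counts per event type, and a
    per-gene Ts/Tv tally over coding substitutions.
    """
    n_ts = sum(1 for s in substitutions if s.klass == "transition")
    n_tv = len(substitutions) - n_ts
    ratio = round(n_ts / n_tv, ratio_rounding) if n_tv else None

    spectrum: dict[str, int] = {}
    for s in substitutions:
        key = spectrum_type(s.ref_base, s.alt_base)
        spectrum[key] = spectrum.get(key, 0) + 1

    by_loc: dict[str, dict[str, int]] = {}
    for kind, events in (
        ("substitutions", substitutions),
        ("indels", indels),
        ("inversions", inversions),
    ):
        counts = {"Coding": 0, "Intron": 0, "Intergenic": 0}
        for e in events:
            if e.location is not None:
                counts[e.location.category] += 1
        by_loc[kind] = counts

    per_gene: dict[str, dict[str, int]] = {}
    for s in substitutions:
        if s.location is not None and s.location.category == "Coding":
            tally = per_gene.setdefault(s.location.context, {"ts": 0, "tv": 0})
            tally["ts" if s.klass == "transition" else "tv"] += 1

    p = None
    if aln is not None:
        mask = tuple((i.ref_start, i.ref_end) for i in inversions)
        p = p_distance(aln, p_rounding, mask)

    return MutationSummary(
        n_substitutions=len(substitutions),
        n_indels=len(indels),
        n_inversions=len(inversions),
        n_ts=n_ts,
        n_tv=n_tv,
        ts_tv_ratio=ratio,
        p_distance=p,
        counts_by_location=by_loc,
        substitution_spectrum=spectrum,
        per_gene_ts_tv=per_gene,
    )
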