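"""Synthetic plastome pairs with fully-known planted structure and mutations.

The generator emulates the architecture and mutation spectrum of a congeneric
plastome pair: a ~150 kb circle built as LSC + IRb + SSC + revcomp(IRb) with
per-region GC targets, planted gene features, planted SSR loci of every motif
class, and a mutated copy carrying substitutions at a controlled Ts fraction,
homopolymer-slippage and multi-base indels, and short inversions flanked by
inverted-repeat arms. Every planted event is recorded in a TruthSet with
exact coordinates and classifications, so pipeline recovery can be checked
event-for-event.

Design constraints that keep truth unambiguous: events are planted only in
single-copy regions (the IR mirror stays exact in both genomes), at least
100 bp from region junctions, at least 50 bp apart, and outside existing SSR
loci; homopolymer indels expand or contract existing single-base runs (the
slippage mechanism); inversion hairpin arms are embedded in the shared
background of BOTH genomes, so the standard returned in the TruthSet is the
arm-carrying genome and is the reference to compare against.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .align import _make_aligner
from .annotations import GeneFeature, classify_position
from .errors import SimulationError
from .genome import CircularGenome, revcomp
from .mutations import (
    IndelEvent,
    InversionEvent,
    SubstitutionEvent,
    classify_substitution,
    reconstruct,
)
from .ssr import DEFAULT_MIN_REPEATS, SSRLocus, SSRThresholds, find_ssrs
from .structure import detect_inverted_repeats

_BASES = np.array(list("ACGT"))
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}

JUNCTION_MARGIN = 100
EVENT_SPACING = 50


@dataclass
class GenomeSpec:
    """Architecture of one synthetic plastome.

    Defaults reproduce the published H. ammodendron genome: region lengths
    84,214 / 24,171 / 19,014 bp and per-region GC 34.4 / 43.0 / 29.7 %.
    """

    lsc_len: int = 84_214
    ir_len: int = 24_171
    ssc_len: int = 19_014
    gc_by_region: dict[str, float] = field(
        default_factory=lambda: {"LSC": 0.344, "IR": 0.430, "SSC": 0.297}
    )
    n_genes: int = 30
    intron_genes: int = 6
    n_ssrs_per_class: int = 2
    seed: int = 0

    def __post_init__(self):
        if min(self.lsc_len, self.ir_len, self.ssc_len) <= 0:
            raise SimulationError("all region lengths must be > 0")
        if any(not 0 <= f <= 1 for f in self.gc_by_region.values()):
            raise SimulationError("GC fractions must lie in [0, 1]")

    @property
    def total_len(self) -> int:
        return self.lsc_len + 2 * self.ir_len + self.ssc_len


@dataclass
class MutationSpec:
    """Planted event mix for the mutated copy.

    Defaults reproduce the published pair's counts: 44 substitutions with
    19/44 transitions, 16 homopolymer and 7 other indels, 2 inversions of
    3-14 bp with 19-27 bp hairpin arms.
    """

    n_substitutions: int = 44
    ts_fraction: float = 19 / 44
    n_homopolymer_indels: int = 16
    n_other_indels: int = 7
    indel_len_range: tuple[int, int] = (1, 6)
    n_inversions: int = 2
    inversion_len_range: tuple[int, int] = (3, 14)
    stem_arm_range: tuple[int, int] = (19, 27)
    seed: int = 0

    def __post_init__(self):
        counts = (
            self.n_substitutions,
            self.n_homopolymer_indels,
            self.n_other_indels,
            self.n_inversions,
        )
        if any(c < 0 for c in counts):
            raise SimulationError("event counts must be >= 0")
        if not 0 <= self.ts_fraction <= 1:
            raise SimulationError("ts_fraction must lie in [0, 1]")


@dataclass
class TruthSet:
    """Planted ground truth accompanying a synthetic genome (pair).

    `standard` is the reference genome the events are expressed against —
    after mutation it carries the inversion hairpin arms in its background
    and is the genome to compare the mutated copy with.
    """

    standard: CircularGenome
    region_lengths: dict[str, int]
    genes: list[GeneFeature] = field(default_factory=list)
    ssrs: list[SSRLocus] = field(default_factory=list)
    substitutions: list[SubstitutionEvent] = field(default_factory=list)
    indels: list[IndelEvent] = field(default_factory=list)
    inversions: list[InversionEvent] = field(default_factory=list)
    n_ts_planted: int = 0

    def to_dict(self) -> dict:
        def loc(e):
            return (
                {"category": e.location.category, "context": e.location.context}
                if e.location
                else None
            )

        return {
            "standard_id": self.standard.id,
            "region_lengths": self.region_lengths,
            "n_ts_planted": self.n_ts_planted,
            "genes": [
                {
                    "name": g.name,
                    "ftype": g.ftype,
                    "strand": g.strand,
                    "exons": g.exons,
                    "is_trans_spliced": g.is_trans_spliced,
                }
                for g in self.genes
            ],
            "ssrs": [
                {
                    "motif": s.motif,
                    "n_repeats": s.n_repeats,
                    "start": s.start,
                    "end": s.end,
                }
                for s in self.ssrs
            ],
            "substitutions": [
                {
                    "ref_pos": s.ref_pos,
                    "ref_base": s.ref_base,
                    "alt_base": s.alt_base,
                    "klass": s.klass,
                    "location": loc(s),
                }
                for s in self.substitutions
            ],
            "indels": [
                {
                    "ref_pos": e.ref_pos,
                    "seq": e.seq,
                    "length": e.length,
                    "klass": e.klass,
                    "direction": e.direction,
                    "location": loc(e),
                }
                for e in self.indels
            ],
            "inversions": [
                {
                    "ref_start": e.ref_start,
                    "ref_end": e.ref_end,
                    "length": e.length,
                    "stem_arm_length": e.stem_arm_length,
                    "location": loc(e),
                }
                for e in self.inversions
            ],
        }

    def write_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=n, p=p)


class _Allocator:
    """Non-overlapping placement of intervals inside eligible windows."""

    def __init__(self, rng: np.random.Generator, windows: list[tuple[int, int]]):
        # windows are 0-based half-open [a, b)
        self.rng = rng
        self.windows = [w for w in windows if w[1] > w[0]]
        if not self.windows:
            raise SimulationError("no eligible placement window")
        self.taken: list[tuple[int, int]] = []

    def block(self, start: int, end: int) -> None:
        self.taken.append((start, end))

    def _free(self, a: int, b: int, margin: int) -> bool:
        return all(b + margin <= s or e + margin <= a for s, e in self.taken)

    def _start_segments(self, length: int, margin: int) -> list[tuple[int, int]]:
        """Inclusive ranges of feasible 0-based start positions."""
        out = []
        for wa, wb in self.windows:
            lo, hi = wa, wb - length
            if hi < lo:
                continue
            # forbidden start ranges implied by taken intervals
            forbidden = sorted(
                (ta - margin - length + 1, tb + margin - 1)
                for ta, tb in self.taken
                if tb + margin - 1 >= lo and ta - margin - length + 1 <= hi
            )
            cur = lo
            for fa, fb in forbidden:
                if fa > cur:
                    out.append((cur, min(fa - 1, hi)))
                cur = max(cur, fb + 1)
                if cur > hi:
                    break
            if cur <= hi:
                out.append((cur, hi))
        return [(a, b) for a, b in out if b >= a]

    def place(self, length: int, margin: int, tries: int = 200,
              predicate=None) -> int:
        for _ in range(tries):
            segs = self._start_segments(length, margin)
            total = sum(b - a + 1 for a, b in segs)
            if total == 0:
                raise SimulationError(f"no room left for a {length} bp event")
            r = int(self.rng.integers(total))
            start = -1
            for a, b in segs:
                n = b - a + 1
                if r < n:
                    start = a + r
                    break
                r -= n
            end = start + length
            if predicate is not None and not predicate(start, end):
                continue
            self.taken.append((start, end))
            return start
        raise SimulationError(
            f"could not place a {length} bp event after {tries} tries"
        )


# ---------------------------------------------------------------------------
# genome generation
# ---------------------------------------------------------------------------


def generate_plastome(
    spec: GenomeSpec,
) -> tuple[CircularGenome, list[GeneFeature], TruthSet]:
    """Build a canonical synthetic plastome with planted genes and SSRs.

    The genome is LSC + IRb + SSC + revcomp(IRb); the first and last LSC
    bases are pinned so the sequence is its own canonical rotation, and the
    IR flanks are adjusted so the planted pair cannot be extended — detected
    junctions therefore equal planted junctions exactly. Deterministic under
    spec.seed.
    """
    rng = np.random.default_rng(spec.seed)
    gc = spec.gc_by_region
    gc_ir = gc.get("IR", gc.get("IRb", 0.43))
    lsc = _random_bases(rng, spec.lsc_len, gc["LSC"])
    irb = _random_bases(rng, spec.ir_len, gc_ir)
    ssc = _random_bases(rng, spec.ssc_len, gc["SSC"])

    # orientation pin: forward LSC-first layout is lexicographically minimal
    lsc[0], lsc[-1] = "A", "A"
    # IR maximality at the SSC flank: IRb's right neighbour must not pair
    # with IRa's left neighbour
    if ssc[0] == _COMP[ssc[-1]]:
        choices = [b for b in "ACGT" if b != _COMP[ssc[-1]]]
        ssc[0] = choices[int(rng.integers(len(choices)))]

    seq = np.concatenate([lsc, irb, ssc, np.array(list(revcomp("".join(irb))))])

    l, r, s = spec.lsc_len, spec.ir_len, spec.ssc_len
    windows = [
        (JUNCTION_MARGIN, l - JUNCTION_MARGIN),
        (l + r + JUNCTION_MARGIN, l + r + s - JUNCTION_MARGIN),
    ]
    alloc = _Allocator(rng, windows)

    # ---- plant gene features (coordinate labels; sequence untouched) -----
    features: list[GeneFeature] = []
    for i in range(spec.n_genes):
        if i < spec.intron_genes:
            n_exons = 2 + int(rng.integers(0, 2))
            exon_lens = [int(rng.integers(100, 400)) for _ in range(n_exons)]
            intron_lens = [int(rng.integers(150, 600))
                           for _ in range(n_exons - 1)]
            ftype = "CDS"
        elif i % 7 == 5:
            exon_lens, intron_lens, ftype = [int(rng.integers(70, 90))], [], "tRNA"
        elif i % 11 == 9:
            exon_lens, intron_lens, ftype = [int(rng.integers(700, 1600))], [], "rRNA"
        else:
            exon_lens, intron_lens, ftype = [int(rng.integers(300, 1200))], [], "CDS"
        span = sum(exon_lens) + sum(intron_lens)
        start0 = alloc.place(span, margin=30)
        exons = []
        pos = start0 + 1
        for j, el in enumerate(exon_lens):
            exons.append((pos, pos + el - 1))
            pos += el
            if j < len(intron_lens):
                pos += intron_lens[j]
        strand = "+" if rng.random() < 0.5 else "-"
        features.append(GeneFeature(f"gene{i + 1:03d}", ftype, strand, exons))
    features.sort(key=lambda f: f.span)

    # ---- plant SSR loci of every motif class -----------------------------
    ssrs: list[SSRLocus] = []
    for unit in range(1, 7):
        for _ in range(spec.n_ssrs_per_class):
            if unit == 1:
                motif = str(rng.choice(_BASES, p=[0.45, 0.05, 0.05, 0.45]))
            else:
                while True:
                    motif = "".join(rng.choice(_BASES, size=unit))
                    if _primitive(motif):
                        break
            repeats = DEFAULT_MIN_REPEATS[unit] + int(rng.integers(0, 3))
            length = unit * repeats
            start0 = alloc.place(length, margin=EVENT_SPACING)
            tract = np.array(list(motif * repeats))
            seq[start0 : start0 + length] = tract
            # break the repeat on both flanks so the locus is maximal
            seq[start0 - 1] = _other_base(rng, motif[-1], seq[start0 - 2])
            seq[start0 + length] = _other_base(
                rng, motif[0], seq[start0 + length + 1]
            )
            ssrs.append(
                SSRLocus(motif, unit, repeats, start0 + 1, start0 + length)
            )

    genome = CircularGenome(f"synthetic_seed{spec.seed}", "".join(seq))
    ssrs = [
        SSRLocus(x.motif, x.unit_length, x.n_repeats, x.start, x.end,
                 classify_position(x.start, features, genome.length))
        for x in ssrs
    ]
    truth = TruthSet(
        standard=genome,
        region_lengths={"LSC": l, "IR": r, "SSC": s, "total": spec.total_len},
        genes=features,
        ssrs=ssrs,
    )
    return genome, features, truth


def _primitive(motif: str) -> bool:
    n = len(motif)
    return all(
        not (n % d == 0 and motif == motif[:d] * (n // d)) for d in range(1, n)
    )


def _other_base(rng: np.random.Generator, *avoid: str) -> str:
    choices = [b for b in "ACGT" if b not in avoid]
    return choices[int(rng.integers(len(choices)))]


# ---------------------------------------------------------------------------
# mutation planting
# ---------------------------------------------------------------------------


def mutate_genome(
    genome: CircularGenome,
    features: list[GeneFeature],
    spec: MutationSpec,
    thresholds: SSRThresholds | None = None,
) -> tuple[CircularGenome, TruthSet]:
    """Plant the event mix of `spec` and return (mutated copy, truth).

    The returned TruthSet's `standard` is the reference genome to compare
    against: identical to the input except that inversion hairpin arms are
    embedded in the shared background around each planted inversion (they
    are pre-existing repeats present in both genomes). Events land only in
    single-copy regions, >= 100 bp from junctions, >= 50 bp apart, and
    outside SSR loci of the input genome. Deterministic under spec.seed.
    """
    rng = np.random.default_rng(spec.seed)
    structure = detect_inverted_repeats(genome)
    seq = list(genome.sequence)

    windows = []
    for name in ("LSC", "SSC"):
        reg = structure.region(name)
        if reg.start <= reg.end:  # skip wrapped regions
            windows.append(
                (reg.start - 1 + JUNCTION_MARGIN, reg.end - JUNCTION_MARGIN)
            )
    alloc = _Allocator(rng, windows)

    # keep existing SSR loci intact so upstream truth stays valid
    ssr_loci = find_ssrs(genome, thresholds)
    for locus in ssr_loci:
        alloc.block(locus.start - 1 - 10, locus.end + 10)

    loc_of = lambda pos: classify_position(pos, features, genome.length)

    # ---- inversions (modify the shared background: arms into standard) ----
    inversions: list[InversionEvent] = []
    lo, hi = spec.inversion_len_range
    alo, ahi = spec.stem_arm_range
    for _ in range(spec.n_inversions):
        core_len = int(rng.integers(lo, hi + 1))
        arm_len = int(rng.integers(alo, ahi + 1))
        site_len = core_len + 2 * arm_len
        start0 = alloc.place(site_len, margin=EVENT_SPACING)
        arm = rng.choice(_BASES, size=arm_len)
        core = _draw_inversion_core(rng, core_len)
        site = "".join(arm) + "".join(core) + revcomp("".join(arm))
        seq[start0 : start0 + site_len] = list(site)
        # arm maximality: the base pair just outside the arms must not pair
        outer_r = seq[start0 + site_len]
        if seq[start0 - 1] == _COMP[outer_r]:
            seq[start0 - 1] = _other_base(rng, _COMP[outer_r])
        inv_start = start0 + arm_len + 1  # 1-based
        inversions.append(
            InversionEvent(
                inv_start,
                inv_start + core_len - 1,
                core_len,
                arm_len,
                loc_of(inv_start),
            )
        )

    standard = CircularGenome(genome.id, "".join(seq), genome.is_circular)
    ref = standard.sequence

    # ---- substitutions ----------------------------------------------------
    substitutions: list[SubstitutionEvent] = []
    n_ts = int(rng.binomial(spec.n_substitutions, spec.ts_fraction))
    for i in range(spec.n_substitutions):
        p0 = alloc.place(1, margin=EVENT_SPACING)
        base = ref[p0]
        if i < n_ts:
            alt = _TRANSITION[base]
        else:
            alt = _TRANSVERSIONS[base][int(rng.integers(2))]
        substitutions.append(
            SubstitutionEvent(
                p0 + 1, base, alt, classify_substitution(base, alt),
                loc_of(p0 + 1),
            )
        )

    # ---- homopolymer (slippage) indels ------------------------------------
    indels: list[IndelEvent] = []
    runs = _short_runs(ref, windows, 3, 8)
    rng.shuffle(runs)
    placed = 0
    for r0, rlen in runs:
        if placed == spec.n_homopolymer_indels:
            break
        if not alloc._free(r0 - 1, r0 + rlen + 1, EVENT_SPACING):
            continue
        alloc.block(r0 - 1, r0 + rlen + 1)
        base = ref[r0]
        direction = "Insertion" if rng.random() < 0.5 else "Deletion"
        indels.append(
            IndelEvent(r0, base, 1, "homopolymeric", direction, loc_of(r0 + 1))
        )
        placed += 1
    if placed < spec.n_homopolymer_indels:
        raise SimulationError(
            f"only {placed}/{spec.n_homopolymer_indels} homopolymer runs "
            "available; enlarge the genome or lower the count"
        )

    # ---- other (non-slippage) indels --------------------------------------
    lo, hi = spec.indel_len_range
    for _ in range(spec.n_other_indels):
        length = int(rng.integers(lo, hi + 1))
        direction = "Insertion" if rng.random() < 0.5 else "Deletion"
        if direction == "Insertion":
            # the standard carries these bases; the mutated copy drops them
            def ok(a: int, b: int, L: int = length) -> bool:
                event = ref[a : a + L]
                if ref[a - 1] == event[-1]:
                    return False  # not left-normalized here
                if len(set(event)) == 1 and _run_len(ref, a, event[0]) >= 3:
                    return False  # would class as homopolymeric
                return True

            p0 = alloc.place(length, margin=EVENT_SPACING, predicate=ok)
            event_seq = ref[p0 : p0 + length]
            indels.append(
                IndelEvent(p0, event_seq, length, "non_homopolymeric",
                           direction, loc_of(p0 + 1))
            )
        else:
            # the mutated copy gains novel bases between p0 and p0+1
            def ok(a: int, b: int) -> bool:
                return True

            p0 = alloc.place(1, margin=EVENT_SPACING, predicate=ok)
            for _ in range(100):
                event_seq = "".join(rng.choice(_BASES, size=length))
                if ref[p0] == event_seq[-1]:
                    continue  # must already be left-normalized
                if (
                    len(set(event_seq)) == 1
                    and _run_len(ref, p0 + 1, event_seq[0]) + 1 >= 3
                ):
                    continue
                break
            else:  # pragma: no cover - bounded-retry guard
                raise SimulationError("could not draw a non-slippage indel")
            indels.append(
                IndelEvent(p0 + 1, event_seq, length, "non_homopolymeric",
                           direction, loc_of(p0 + 1))
            )

    indels.sort(key=lambda e: e.ref_pos)
    substitutions.sort(key=lambda e: e.ref_pos)
    inversions.sort(key=lambda e: e.ref_start)

    mutated_seq = reconstruct(ref, substitutions, indels, inversions)
    mutated = CircularGenome(
        f"{genome.id}_mut", mutated_seq, genome.is_circular
    )
    truth = TruthSet(
        standard=standard,
        region_lengths={
            "LSC": structure.region("LSC").length,
            "IR": structure.ir_length,
            "SSC": structure.region("SSC").length,
            "total": structure.total_length,
        },
        genes=list(features),
        substitutions=substitutions,
        indels=indels,
        inversions=inversions,
        n_ts_planted=n_ts,
    )
    return mutated, truth


def _draw_inversion_core(rng: np.random.Generator, core_len: int) -> np.ndarray:
    """Draw an invertible core whose flip is one clean mismatch run.

    Two constraints: every position must differ from its reverse complement
    (no partial palindromy), and the optimal affine-gap alignment of the
    core against its reverse complement must be the gap-free all-mismatch
    diagonal — otherwise the aligner would represent the flip as spurious
    indels plus substitutions instead of a contiguous run.
    """
    aligner = _make_aligner()
    for _ in range(200):
        core = rng.choice(_BASES, size=core_len)
        for i in range(core_len // 2):
            j = core_len - 1 - i
            if core[j] == _COMP[core[i]]:
                core[j] = _other_base(rng, _COMP[core[i]])
        core_s = "".join(core)
        flipped = revcomp(core_s)
        aln = aligner.align(core_s, flipped)[0]
        if str(aln[0]) == core_s and str(aln[1]) == flipped:
            return core
    raise SimulationError(
        f"could not draw a {core_len} bp invertible core"
    )  # pragma: no cover - bounded-retry guard


def _run_len(seq: str, start0: int, base: str) -> int:
    n = 0
    i = start0
    while i < len(seq) and seq[i] == base:
        n += 1
        i += 1
    return n


def _short_runs(
    seq: str, windows: list[tuple[int, int]], min_len: int, max_len: int
) -> list[tuple[int, int]]:
    """Maximal single-base runs of length in [min_len, max_len], as
    (0-based start, length), restricted to the given windows."""
    out = []
    for a, b in windows:
        i = a
        while i < b:
            j = i + 1
            while j < b and seq[j] == seq[i]:
                j += 1
            if (
                min_len <= j - i <= max_len
                and (i == 0 or seq[i - 1] != seq[i])
                and (j == len(seq) or seq[j] != seq[i])
            ):
                out.append((i, j - i))
            i = j
    return out
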