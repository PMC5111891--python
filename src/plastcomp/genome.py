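"""Circular genome container and elementary sequence operations.

A plastome is a circular DNA molecule; every stage of the pipeline consumes
a :class:`CircularGenome`. Coordinates are 1-based inclusive throughout the
package, and intervals may wrap around the origin.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

from .errors import SequenceError

_ALLOWED = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(sequence: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N)."""
    return sequence.translate(_COMPLEMENT)[::-1]


def gc_content(sequence: str) -> float:
    """GC proportion of a DNA string.

    Computed as (G + C) / (A + C + G + T); N and other ambiguity codes are
    excluded from both numerator and denominator.

    Raises
    ------
    SequenceError
        If the sequence is empty or contains no unambiguous base.
    """
    if not sequence:
        raise SequenceError("empty sequence")
    seq = sequence.upper()
    gc = seq.count("G") + seq.count("C")
    at = seq.count("A") + seq.count("T")
    if gc + at == 0:
        raise SequenceError("sequence contains no unambiguous (ACGT) base")
    return gc / (gc + at)


@dataclass
class CircularGenome:
    """A named circular DNA sequence.

    Parameters
    ----------
    id : str
        Text label (FASTA record id).
    sequence : str
        DNA over {A, C, G, T, N}; case-normalised to upper on construction.
    is_circular : bool
        Circular topology flag; True for plastomes.
    """

    id: str
    sequence: str
    is_circular: bool = True
    length: int = field(init=False)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise SequenceError(f"genome {self.id!r}: empty sequence")
        bad = set(self.sequence) - _ALLOWED
        if bad:
            raise SequenceError(
                f"genome {self.id!r}: disallowed characters {sorted(bad)}"
            )
        self.length = len(self.sequence)

    # -- coordinate helpers (1-based, circular) ------------------------------

    def base(self, pos: int) -> str:
        """Base at 1-based position `pos` (wraps around the origin)."""
        return self.sequence[(pos - 1) % self.length]

    def slice(self, start: int, end: int) -> str:
        """Subsequence for the 1-based inclusive interval [start, end].

        If end < start the interval wraps around the origin (circular only).
        """
        if start <= end:
            return self.sequence[start - 1 : end]
        if not self.is_circular:
            raise SequenceError("wrapped interval on a linear sequence")
        return self.sequence[start - 1 :] + self.sequence[:end]

    def rotated(self, new_start: int) -> "CircularGenome":
        """Genome rotated so that 1-based position `new_start` becomes base 1."""
        i = (new_start - 1) % self.length
        return CircularGenome(self.id, self.sequence[i:] + self.sequence[:i])

    def reverse_complement(self) -> "CircularGenome":
        return CircularGenome(self.id, revcomp(self.sequence))


def read_fasta(path: str | Path, record_id: str | None = None) -> CircularGenome:
    """Read one record from a plain or gzipped FASTA file.

    The first record is used; multi-record input is an error unless
    `record_id` selects one.
    """
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        records = list(SeqIO.parse(fh, "fasta"))
    if not records:
        raise SequenceError(f"{path}: no FASTA records")
    if record_id is not None:
        for rec in records:
            if rec.id == record_id:
                return CircularGenome(rec.id, str(rec.seq))
        raise SequenceError(f"{path}: no record with id {record_id!r}")
    if len(records) > 1:
        raise SequenceError(
            f"{path}: {len(records)} records; pass record_id to choose one"
        )
    rec = records[0]
    return CircularGenome(rec.id, str(rec.seq))


def write_fasta(genome: CircularGenome, path: str | Path, width: int = 70) -> None:
    """Write a genome as single-record FASTA (fixed line width)."""
    with open(path, "w") as fh:
        fh.write(f">{genome.id}\n")
        for i in range(0, genome.length, width):
            fh.write(genome.sequence[i : i + width] + "\n")
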