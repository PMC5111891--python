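"""Gene annotations: reading, position classification, intron inventory.

GFF3 is the native dialect (read and written); GenBank flat files are
accepted read-only. Positions on the genome are classified as Coding,
Intron, or Intergenic with a gene-context label — the categories used to
localise mutation and repeat events.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import gffutils
from Bio import SeqIO

from .errors import AnnotationError

FEATURE_TYPES = ("CDS", "tRNA", "rRNA", "pseudogene")


@dataclass
class GeneFeature:
    """One annotated gene with its exon structure.

    exons are 1-based inclusive (start, end) intervals in ascending genomic
    order; a cis-spliced gene's span is [exons[0].start, exons[-1].end].
    tRNA and rRNA exons count as coding for location labelling.
    """

    name: str
    ftype: str  # CDS | tRNA | rRNA | pseudogene
    strand: str  # '+' | '-'
    exons: list[tuple[int, int]]
    is_trans_spliced: bool = False

    def __post_init__(self):
        if self.ftype not in FEATURE_TYPES:
            raise AnnotationError(f"{self.name}: bad feature type {self.ftype!r}")
        if self.strand not in "+-":
            raise AnnotationError(f"{self.name}: bad strand {self.strand!r}")
        if not self.exons:
            raise AnnotationError(f"{self.name}: no exons")
        self.exons = sorted((int(s), int(e)) for s, e in self.exons)
        for s, e in self.exons:
            if s > e or s < 1:
                raise AnnotationError(f"{self.name}: bad exon interval ({s}, {e})")
        if not self.is_trans_spliced:
            for (_, e1), (s2, _) in zip(self.exons, self.exons[1:]):
                if s2 <= e1:
                    raise AnnotationError(f"{self.name}: overlapping exons")

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    def contains(self, pos: int) -> bool:
        s, e = self.span
        return s <= pos <= e

    def in_exon(self, pos: int) -> tuple[int, int] | None:
        for s, e in self.exons:
            if s <= pos <= e:
                return (s, e)
        return None


@dataclass(frozen=True)
class LocationLabel:
    """Category plus gene context, e.g. (Coding, "ycf1"),
    (Intron, "clpP intron"), (Intergenic, "trnK-matK")."""

    category: str  # Coding | Intron | Intergenic
    context: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.category}({self.context})"


@dataclass
class IntronRecord:
    """Exon and intron lengths of a multi-exon gene, in transcript order.

    Trans-spliced genes report exon lengths with intron slots absent (None).
    """

    gene: str
    exon_lengths: list[int]
    intron_lengths: list[int | None] = field(default_factory=list)


# ---------------------------------------------------------------------------
# readers / writer
# ---------------------------------------------------------------------------


def _from_gff3(path: Path) -> list[GeneFeature]:
    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            merge_strategy="create_unique",
            keep_order=True,
        )
    except Exception as exc:  # gffutils raises assorted parse errors
        raise AnnotationError(f"{path}: GFF3 parse failure: {exc}") from exc
    with open(path) as fh:
        if not fh.readline().startswith("##gff-version"):
            raise AnnotationError(f"{path}: missing ##gff-version pragma")

    features: list[GeneFeature] = []
    for g in db.features_of_type(("gene", "pseudogene")):
        attrs = g.attributes
        name = (attrs.get("Name") or attrs.get("ID") or [g.id])[0]
        ftype = (attrs.get("gene_type") or ["CDS"])[0]
        if g.featuretype == "pseudogene" or attrs.get("pseudo") == ["true"]:
            ftype = "pseudogene"
        trans = attrs.get("trans_spliced") == ["true"]
        exons = [
            (c.start, c.end)
            for c in db.children(g, featuretype=("exon", "CDS"), order_by="start")
        ]
        if not exons:
            exons = [(g.start, g.end)]
        features.append(
            GeneFeature(name, ftype, g.strand if g.strand in "+-" else "+",
                        exons, trans)
        )
    features.sort(key=lambda f: f.span)
    return features


def _from_genbank(path: Path) -> list[GeneFeature]:
    try:
        record = next(SeqIO.parse(str(path), "genbank"))
    except StopIteration:
        raise AnnotationError(f"{path}: no GenBank records") from None
    except Exception as exc:
        raise AnnotationError(f"{path}: GenBank parse failure: {exc}") from exc
    glen = len(record.seq)

    features: list[GeneFeature] = []
    for feat in record.features:
        if feat.type not in ("CDS", "tRNA", "rRNA"):
            continue
        name = (
            feat.qualifiers.get("gene", [None])[0]
            or feat.qualifiers.get("locus_tag", ["?"])[0]
        )
        ftype = "pseudogene" if "pseudo" in feat.qualifiers else feat.type
        # Biopython locations are 0-based half-open; convert each part
        exons = [(int(p.start) + 1, int(p.end)) for p in feat.location.parts]
        for s, e in exons:
            if e > glen:
                raise AnnotationError(
                    f"{path}: {name} exon end {e} beyond genome length {glen}"
                )
        strands = {p.strand for p in feat.location.parts}
        trans = len(strands) > 1 or "trans_splicing" in feat.qualifiers
        strand = "-" if feat.location.strand == -1 else "+"
        features.append(GeneFeature(name, ftype, strand, exons, trans))
    features.sort(key=lambda f: f.span)
    return features


def read_annotations(path: str | Path, fmt: str = "gff3") -> list[GeneFeature]:
    """Read gene features from a GFF3 or GenBank file, in genomic order."""
    path = Path(path)
    if not path.exists():
        raise AnnotationError(f"{path}: no such file")
    if fmt == "gff3":
        return _from_gff3(path)
    if fmt == "genbank":
        return _from_genbank(path)
    raise AnnotationError(f"unknown annotation format {fmt!r}")


def write_gff3(
    features: list[GeneFeature], path: str | Path, seqid: str, genome_length: int
) -> None:
    """Write features in the package's GFF3 dialect (gene + exon children)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {seqid} 1 {genome_length}\n")
        for i, f in enumerate(sorted(features, key=lambda f: f.span)):
            gid = f"gene{i:04d}"
            s, e = f.span
            attrs = f"ID={gid};Name={f.name};gene_type={f.ftype}"
            if f.is_trans_spliced:
                attrs += ";trans_spliced=true"
            gtype = "pseudogene" if f.ftype == "pseudogene" else "gene"
            fh.write(
                f"{seqid}\tplastcomp\t{gtype}\t{s}\t{e}\t.\t{f.strand}\t.\t{attrs}\n"
            )
            for es, ee in f.exons:
                fh.write(
                    f"{seqid}\tplastcomp\texon\t{es}\t{ee}\t.\t{f.strand}\t.\t"
                    f"Parent={gid}\n"
                )


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------


def classify_position(
    pos: int, features: list[GeneFeature], genome_length: int | None = None
) -> LocationLabel:
    """Label a 1-based position as Coding, Intron, or Intergenic.

    Coding if inside any exon (smallest enclosing exon wins; ties broken by
    earlier gene start); Intron if inside a cis-spliced gene's span but not an
    exon; otherwise Intergenic with an "upstream-downstream" context built
    from the nearest flanking genes in circular genomic order.
    """
    if not features:
        return LocationLabel("Intergenic", "NA-NA")

    exon_hits = []
    for f in features:
        hit = f.in_exon(pos)
        if hit is not None:
            exon_hits.append((hit[1] - hit[0], f.span[0], f))
    if exon_hits:
        exon_hits.sort(key=lambda t: (t[0], t[1]))
        return LocationLabel("Coding", exon_hits[0][2].name)

    for f in sorted(features, key=lambda f: f.span):
        if not f.is_trans_spliced and f.contains(pos):
            return LocationLabel("Intron", f"{f.name} intron")

    glen = genome_length or max(f.span[1] for f in features)
    ordered = sorted(features, key=lambda f: f.span)
    up = min(ordered, key=lambda f: (pos - f.span[1]) % glen)
    down = min(ordered, key=lambda f: (f.span[0] - pos) % glen)
    return LocationLabel("Intergenic", f"{up.name}-{down.name}")


def intron_inventory(features: list[GeneFeature]) -> list[IntronRecord]:
    """Exon/intron length table for every multi-exon gene, transcript order."""
    records = []
    for f in features:
        if len(f.exons) < 2:
            continue
        exon_lens = [e - s + 1 for s, e in f.exons]
        if f.is_trans_spliced:
            intron_lens: list[int | None] = [None] * (len(f.exons) - 1)
        else:
            intron_lens = [
                s2 - e1 - 1 for (_, e1), (s2, _) in zip(f.exons, f.exons[1:])
            ]
        if f.strand == "-":
            exon_lens.reverse()
            intron_lens.reverse()
        records.append(IntronRecord(f.name, exon_lens, intron_lens))
    return records
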