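"""IR-junction analysis: where the single-copy/IR borders fall relative to
annotated genes.

Expansion and contraction of the inverted repeat moves the four junctions
(LSC/IRb, IRb/SSC, SSC/IRa, IRa/LSC) relative to the flanking genes, which
is a classic comparative feature of plastomes. Distances count bases
strictly between a junction and the nearest gene on the single-copy side
(touching = 0, one intervening base = 1); genes whose span crosses a
junction are listed with the length of gene lying inside the IR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .annotations import GeneFeature
from .structure import QuadripartiteStructure

JUNCTION_NAMES = ("LSC/IRb", "IRb/SSC", "SSC/IRa", "IRa/LSC")


@dataclass
class JunctionReport:
    genome_id: str
    junction: str
    position: int  # last base of the upstream region, canonical rotation
    nearest_gene: str | None
    signed_distance: int | None  # 0 when the junction abuts or cuts the gene
    genes_cut: list[tuple[str, int]] = field(default_factory=list)


def junction_positions(structure: QuadripartiteStructure) -> dict[str, int]:
    """The four junction positions on the canonical (LSC-first) rotation.

    Each junction is the position of the last base of its upstream region.
    """
    lsc = structure.region("LSC").length
    ssc = structure.region("SSC").length
    ir = structure.ir_length
    if lsc <= 0 or ssc <= 0 or ir <= 0:
        raise ValueError("degenerate structure: zero-length region")
    return {
        "LSC/IRb": lsc,
        "IRb/SSC": lsc + ir,
        "SSC/IRa": lsc + ir + ssc,
        "IRa/LSC": lsc + 2 * ir + ssc,
    }


def junction_gene_distance(
    structure: QuadripartiteStructure,
    features: list[GeneFeature],
    junction: str,
) -> JunctionReport:
    """Distance from one junction to its nearest single-copy-side gene.

    Annotations must be on the same (canonical) coordinate system as the
    structure. For junctions whose single-copy region lies upstream
    (LSC/IRb, SSC/IRa) the nearest gene end is used; for those whose
    single-copy region lies downstream (IRb/SSC, IRa/LSC — the latter
    wrapping through the origin) the nearest gene start is used.
    """
    if junction not in JUNCTION_NAMES:
        raise ValueError(f"unknown junction {junction!r}")
    positions = junction_positions(structure)
    p = positions[junction]
    total = structure.total_length
    if not features:
        warnings.warn(f"{structure.genome_id}: no annotated genes", stacklevel=2)
        return JunctionReport(structure.genome_id, junction, p, None, None)

    sc_side = "left" if junction in ("LSC/IRb", "SSC/IRa") else "right"

    cut: list[tuple[str, int]] = []
    for f in features:
        s, e = f.span
        if s <= p < e:
            # overlap into the IR: the IR lies right of p for LSC/IRb and
            # SSC/IRa, left of p (i.e. ending at p) for IRb/SSC and IRa/LSC
            if junction in ("LSC/IRb", "SSC/IRa"):
                cut.append((f.name, e - p))
            else:
                cut.append((f.name, p - s + 1))
    if cut:
        cut.sort(key=lambda t: -t[1])
        return JunctionReport(
            structure.genome_id, junction, p, cut[0][0], 0, cut
        )

    best: tuple[int, str] | None = None
    for f in features:
        s, e = f.span
        if sc_side == "left":
            if e <= p:
                d = p - e
            else:
                continue
        else:
            d = (s - p - 1) % total
        if best is None or d < best[0]:
            best = (d, f.name)
    if best is None:
        return JunctionReport(structure.genome_id, junction, p, None, None)
    return JunctionReport(structure.genome_id, junction, p, best[1], best[0])


def junction_table(
    reports_by_genome: dict[str, list[JunctionReport]]
) -> list[dict]:
    """Multi-genome comparison rows, one per genome x junction."""
    rows = []
    for genome_id, reports in reports_by_genome.items():
        for r in reports:
            rows.append(
                {
                    "genome": genome_id,
                    "junction": r.junction,
                    "position": r.position,
                    "nearest_gene": r.nearest_gene or "NA",
                    "distance": r.signed_distance
                    if r.signed_distance is not None
                    else "NA",
                    "genes_cut": ";".join(
                        f"{g}:{ov}" for g, ov in r.genes_cut
                    )
                    or "NA",
                }
            )
    return rows


def write_junctions_tsv(rows: list[dict], path) -> None:
    with open(path, "w") as fh:
        fh.write("genome\tjunction\tposition\tnearest_gene\tdistance\tgenes_cut\n")
        for r in rows:
            fh.write(
                f"{r['genome']}\t{r['junction']}\t{r['position']}\t"
                f"{r['nearest_gene']}\t{r['distance']}\t{r['genes_cut']}\n"
            )
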