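"""Pipeline orchestration: structure -> SSR -> compare -> junctions.

`compare_genomes` is the library entry point for one pairwise comparison;
`run_pipeline` adds file I/O, logging, and table generation around it, and
`reference_tables_report` recomputes every headline statistic of the
published Haloxylon comparison from the packaged tables alone (no sequence
data needed).
"""

from __future__ import annotations

import json
import logging
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .align import PairwiseAlignment, align_pair
from .annotations import GeneFeature, read_annotations
from .errors import PipelineError, PlastcompError
from .genome import CircularGenome, read_fasta
from .inversions import detect_microinversions, write_inversions_tsv
from .junctions import (
    JUNCTION_NAMES,
    junction_gene_distance,
    junction_table,
    write_junctions_tsv,
)
from .mutations import (
    MutationSummary,
    classify_substitution,
    call_indels,
    call_substitutions,
    p_distance,
    summarize_mutations,
    spectrum_type,
)
from .ssr import SSRThresholds, find_ssrs, summarize_ssrs, write_ssr_tsv
from .structure import (
    QuadripartiteStructure,
    canonical_rotation,
    detect_inverted_repeats,
    write_structure_tsv,
)
from .tables import load_reference_table

logger = logging.getLogger("plastcomp")


@dataclass
class RunConfig:
    """Validated parameters of one pipeline run."""

    standard_fasta: str
    other_fasta: str | None = None
    annotations: str | None = None
    annotations_fmt: str = "gff3"
    out_dir: str = "plastcomp_out"
    min_ir_length: int = 1000
    max_mismatches: int = 0
    anchor_k: int = 21
    homopolymer_min_run: int = 3
    inversion_min_len: int = 3
    inversion_max_len: int = 100
    max_arm: int = 50
    ssr_min_repeats: dict[int, int] | None = None
    p_rounding: int = 5
    ratio_rounding: int = 2
    seed: int = 0
    verbose: bool = False

    def __post_init__(self):
        if self.min_ir_length < 1:
            raise PipelineError("config", "min_ir_length must be >= 1")
        if self.anchor_k < 4:
            raise PipelineError("config", "anchor_k must be >= 4")
        if self.homopolymer_min_run < 1:
            raise PipelineError("config", "homopolymer_min_run must be >= 1")
        if self.inversion_min_len < 2:
            raise PipelineError("config", "inversion_min_len must be >= 2")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "ssr_min_repeats" in raw and raw["ssr_min_repeats"] is not None:
            raw["ssr_min_repeats"] = {
                int(k): int(v) for k, v in raw["ssr_min_repeats"].items()
            }
        return cls(**raw)


@dataclass
class ComparisonResult:
    """Everything one pairwise comparison produces."""

    standard: CircularGenome
    other: CircularGenome
    standard_structure: QuadripartiteStructure
    other_structure: QuadripartiteStructure
    alignment: PairwiseAlignment
    substitutions: list
    indels: list
    inversions: list
    summary: MutationSummary
    ssrs: list = field(default_factory=list)
    junction_reports: list = field(default_factory=list)


def compare_genomes(
    standard: CircularGenome,
    other: CircularGenome,
    features: list[GeneFeature] | None = None,
    config: RunConfig | None = None,
) -> ComparisonResult:
    """Full pairwise comparison of two canonically rotated plastomes.

    Detects both quadripartite structures, aligns the pair, masks
    micro-inversions, then calls substitutions and indels and summarises.
    Inputs are expected on their canonical rotation (see
    `structure.canonical_rotation`); the anchor-coverage check rejects
    inputs that are not collinear.
    """
    cfg = config or RunConfig(standard_fasta="", other_fasta="")
    std_structure = detect_inverted_repeats(
        standard, cfg.min_ir_length, cfg.max_mismatches
    )
    oth_structure = detect_inverted_repeats(
        other, cfg.min_ir_length, cfg.max_mismatches
    )
    aln = align_pair(standard, other, k=cfg.anchor_k)
    inversions = detect_microinversions(
        aln,
        cfg.inversion_min_len,
        cfg.inversion_max_len,
        genome=standard,
        features=features,
        max_arm=cfg.max_arm,
    )
    mask = tuple((i.ref_start, i.ref_end) for i in inversions)
    substitutions = call_substitutions(aln, features, exclude_intervals=mask)
    indels = call_indels(
        aln, features, cfg.homopolymer_min_run, exclude_intervals=mask
    )
    summary = summarize_mutations(
        substitutions, indels, inversions, aln,
        cfg.ratio_rounding, cfg.p_rounding,
    )
    thresholds = (
        SSRThresholds(cfg.ssr_min_repeats) if cfg.ssr_min_repeats else None
    )
    ssrs = find_ssrs(standard, thresholds, features)
    junction_reports = []
    if features:
        junction_reports = [
            junction_gene_distance(std_structure, features, j)
            for j in JUNCTION_NAMES
        ]
    return ComparisonResult(
        standard, other, std_structure, oth_structure, aln,
        substitutions, indels, inversions, summary, ssrs, junction_reports,
    )


def _write_substitutions_tsv(events, path) -> None:
    with open(path, "w") as fh:
        fh.write("ref_pos\tref_base\talt_base\tclass\tlocation\tcontext\n")
        for e in events:
            cat = e.location.category if e.location else "NA"
            ctx = e.location.context if e.location else "NA"
            fh.write(
                f"{e.ref_pos}\t{e.ref_base}\t{e.alt_base}\t{e.klass}\t"
                f"{cat}\t{ctx}\n"
            )


def _write_indels_tsv(events, path) -> None:
    with open(path, "w") as fh:
        fh.write("ref_pos\tseq\tlength\tclass\tdirection\tlocation\tcontext\n")
        for e in events:
            cat = e.location.category if e.location else "NA"
            ctx = e.location.context if e.location else "NA"
            fh.write(
                f"{e.ref_pos}\t{e.seq}\t{e.length}\t{e.klass}\t"
                f"{e.direction}\t{cat}\t{ctx}\n"
            )


def _write_per_gene_tsv(per_gene: dict, path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tts\ttv\n")
        for gene in sorted(per_gene):
            t = per_gene[gene]
            fh.write(f"{gene}\t{t['ts']}\t{t['tv']}\n")


def run_pipeline(config: RunConfig) -> dict:
    """Run every applicable stage and emit the report bundle.

    Writes structure.tsv, ssr.tsv and — when a second genome is given —
    substitutions.tsv, indels.tsv, inversions.tsv, per_gene_ts_tv.tsv,
    junctions.tsv (with annotations) and summary.json into the output
    directory. Any stage failure removes partial outputs and re-raises as a
    stage-named PipelineError.
    """
    logging.basicConfig(
        level=logging.DEBUG if config.verbose else logging.INFO,
        format="%(levelname)s %(name)s: %(message)s",
    )
    for key, value in vars(config).items():
        logger.info("config %s = %r", key, value)

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(name: str, writer, *args) -> Path:
        path = out / name
        writer(*args, path)
        written.append(path)
        logger.info("wrote %s", path)
        return path

    try:
        stage = "read_inputs"
        standard = read_fasta(config.standard_fasta)
        features = None
        if config.annotations:
            features = read_annotations(config.annotations, config.annotations_fmt)

        stage = "structure"
        std_structure = detect_inverted_repeats(
            standard, config.min_ir_length, config.max_mismatches
        )
        emit("structure.tsv", write_structure_tsv, std_structure)

        stage = "ssr"
        thresholds = (
            SSRThresholds(config.ssr_min_repeats)
            if config.ssr_min_repeats
            else None
        )
        ssrs = find_ssrs(standard, thresholds, features)
        emit("ssr.tsv", write_ssr_tsv, ssrs)

        result_summary: dict = {
            "standard": standard.id,
            "structure": std_structure.to_dict(),
            "ssr_summary": summarize_ssrs(ssrs).__dict__,
        }

        if config.other_fasta:
            stage = "compare"
            other = read_fasta(config.other_fasta)
            result = compare_genomes(standard, other, features, config)
            emit("substitutions.tsv", _write_substitutions_tsv,
                 result.substitutions)
            emit("indels.tsv", _write_indels_tsv, result.indels)
            emit("inversions.tsv", write_inversions_tsv, result.inversions)
            emit("per_gene_ts_tv.tsv", _write_per_gene_tsv,
                 result.summary.per_gene_ts_tv)
            result_summary["comparison"] = result.summary.to_dict()
            if features:
                stage = "junctions"
                rows = junction_table(
                    {standard.id: result.junction_reports}
                )
                emit("junctions.tsv", write_junctions_tsv, rows)
        elif features:
            stage = "junctions"
            reports = [
                junction_gene_distance(std_structure, features, j)
                for j in JUNCTION_NAMES
            ]
            emit("junctions.tsv", write_junctions_tsv,
                 junction_table({standard.id: reports}))

        stage = "summary"
        path = out / "summary.json"
        with open(path, "w") as fh:
            json.dump(result_summary, fh, indent=2, default=str)
            fh.write("\n")
        written.append(path)
        return result_summary
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(stage, str(exc)) from exc


# ---------------------------------------------------------------------------
# fixtures-only mode: recompute headline statistics from packaged tables
# ---------------------------------------------------------------------------


def reference_tables_report() -> dict:
    """Recompute the published pair's headline statistics from the packaged
    tables using the package's own classifiers (no sequence data).

    Returns transitions/transversions and their ratio, the per-location SNP
    breakdown, the substitution spectrum, the p-distance implied by the
    substitution count over the reported genome length, region-length
    conservation, indel counts and coding share, SSR class counts and the
    A/T share, and the total mutation count.
    """
    subs = load_reference_table("substitutions")
    indels = load_reference_table("indels")
    ssr = load_reference_table("ssr_loci")
    feats = load_reference_table("genome_features")
    invs = load_reference_table("inversions")

    klass = [
        classify_substitution(r.ha_base, r.hp_base) for r in subs.itertuples()
    ]
    n_ts = klass.count("transition")
    n_tv = klass.count("transversion")
    coding = subs.location == "Coding"
    coding_ts = sum(
        1 for k, c in zip(klass, coding) if c and k == "transition"
    )
    coding_tv = int(coding.sum()) - coding_ts
    spectrum: dict[str, int] = {}
    for r in subs.itertuples():
        key = spectrum_type(r.ha_base, r.hp_base)
        spectrum[key] = spectrum.get(key, 0) + 1

    fx = feats.set_index("feature")["h_ammodendron"]
    total_len = int(fx["total_length"])
    lsc, ir, ssc = (
        int(fx["lsc_length"]), int(fx["ir_length"]), int(fx["ssc_length"])
    )

    from .ssr import SSRLocus, summarize_ssrs as _sum

    loci = [
        SSRLocus(r.motif, len(r.motif), int(r.n_repeats), int(r.start),
                 int(r.end))
        for r in ssr.itertuples()
    ]
    ssr_summary = _sum(loci)

    n_subs, n_indels, n_inversions = len(subs), len(indels), len(invs)
    return {
        "n_substitutions": n_subs,
        "n_ts": n_ts,
        "n_tv": n_tv,
        "ts_tv_ratio": round(n_ts / n_tv, 2),
        "coding_ts": coding_ts,
        "coding_tv": coding_tv,
        "snp_by_location": {
            loc: int((subs.location == loc).sum())
            for loc in ("Intergenic", "Intron", "Coding")
        },
        "substitution_spectrum": spectrum,
        "p_distance": round(n_subs / total_len, 5),
        "total_length": total_len,
        "region_length_sum": lsc + ssc + 2 * ir,
        "region_lengths_consistent": lsc + ssc + 2 * ir == total_len,
        "n_indels": n_indels,
        "indels_noncoding": int((indels.location != "Coding").sum()),
        "n_inversions": n_inversions,
        "n_mutations_total": n_subs + n_indels + n_inversions,
        "ssr_counts_by_unit": ssr_summary.counts_by_unit,
        "ssr_n_total": ssr_summary.n_total,
        "ssr_at_share_percent": ssr_summary.at_share_percent,
    }
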