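# Methods

This note documents the models, conventions and numerical choices behind
each stage of plastcomp, and what the synthetic tests do and do not show
about real data. Coordinates are 1-based inclusive everywhere; intervals may
wrap around the origin of the circular molecule.

## Quadripartite structure detection

A plastome is modelled as a circle tiled by four regions — LSC, IRb, SSC,
IRa — where IRa is the reverse complement of IRb. Detection finds the
maximal-length pair of disjoint segments such that one equals the reverse
complement of the other, allowing up to `max_mismatches` mismatches
(default 0: plastome IR copies are typically identical; the mismatch budget
is spent greedily, right flank first, and is meant for occasional near-exact
IRs, not for degenerate repeats). The search is seed-and-extend: k-mers
(k = 21) shared between the doubled sequence (doubling handles repeats that
span the origin) and its reverse complement seed diagonal runs that are
extended to maximal matches. The longer intervening arc is labelled LSC, the
shorter SSC. `min_ir_length` defaults to 1,000 bp — far above chance matches
at plastome scale, far below real plastome IRs (~10–30 kb). Genomes without
such a pair (IR-lost lineages) get a clean "no quadripartite structure"
error; two non-equivalent maximal pairs that tie in length raise an
ambiguity error rather than an arbitrary choice.

A brute-force oracle (full complementarity matrix, maximal anti-diagonal
runs) lives in the test suite and must agree with the detector on small
genomes.

**Canonical rotation.** Comparisons require a shared coordinate frame. The
canonical layout puts the first LSC base at position 1 so the regions read
LSC–IRb–SSC–IRa going forward. Both the forward and the reverse-complement
orientation of a circle admit such a layout (the molecule itself does not
distinguish them); plastcomp deterministically picks the lexicographically
smaller of the two candidate sequences. This is idempotent, undoes any
rotation and/or reverse complement, and maps near-identical genomes to
consistent frames. The synthetic generator pins the first and last LSC base
so its output is canonical by construction.

**GC content** is (G+C)/(A+C+G+T), with N and other ambiguity codes excluded
from numerator and denominator; reported as a fraction internally and as a
percentage with one decimal in tables. Whole-genome GC counts both IR copies
(i.e. it is computed over the full circle); per-region GC is computed per
region. Published per-region figures do not state which convention their
total uses — over a full plastome the difference is well under the printed
precision.

## Annotations and location labels

GFF3 is the native dialect (read via gffutils, written by the package);
GenBank flat files are accepted read-only via Biopython, with `join(...)`
locations becoming multi-exon features and `pseudo` qualifiers mapping to a
pseudogene type. Every genomic position classifies into exactly one of
Coding (inside any exon — tRNA/rRNA exons count as coding for labelling,
matching how published event tables label rRNA positions), Intron (inside a
cis-spliced gene's span but not an exon), or Intergenic (context
"upstreamGene-downstreamGene" from the nearest flanking genes in circular
order). For nested features the smallest enclosing exon wins, ties broken by
earlier gene start. Trans-spliced genes (the rps12 pattern: exons far apart,
5′ exon in the LSC) are excluded from the span-based intron rule and report
their intron slots as absent in the exon/intron inventory.

## Pairwise alignment

Congeneric plastome pairs diverge by ~0.03 %, so the aligner is built for
the near-identical collinear case: k-mers unique in both genomes (k = 21)
are matched, chained by longest increasing subsequence, merged into maximal
exact blocks, and the short inter-anchor segments are resolved by optimal
global alignment with match +1, mismatch −1, gap open −5, gap extend −1
(Biopython's PairwiseAligner). Affine gap costs keep multi-base indels as
single gap runs instead of scattered single gaps. If the anchor chain covers
less than 90 % of either genome, or an inter-anchor segment exceeds 20 kb,
the inputs are declared non-collinear — the contract is that both genomes
are canonically rotated first. A pre-computed two-record aligned FASTA can
be supplied instead (`read_aligned_fasta`) to bypass the aligner entirely.
The alignment container enforces the round-trip invariant (degapping
reproduces the inputs exactly) and forbids columns gapped in both rows.

## Event calling

**Micro-inversions first.** A maximal run of mismatching, gap-free columns
whose other-genome segment equals the reverse complement of the standard's
segment is one inversion event (length window 3–100 bp by default; the
lower bound exists because a 1 bp "inversion" is indistinguishable from a
substitution, and a 2 bp reverse-complement-matching mismatch pair is
formally ambiguous — it is reported as two substitutions). Palindromic
segments are undetectable by definition: they produce no mismatch. Inversion
intervals are masked before substitution and indel calling, so an inversion
is counted once rather than as a cluster of false SNPs. Hairpin **stem
arms** are the longest a ≤ 50 such that the a bases immediately 5′ of the
interval reverse-complement the a bases immediately 3′ (0 mismatches by
default); arms are measured strictly outside the inverted segment, and no
thermodynamic folding is attempted. Which lineage inverted is not inferred.

**Substitutions.** One event per remaining mismatched gap-free column;
adjacent mismatch columns stay separate single-base events (no MNP
merging). Transition iff both bases are purines or both pyrimidines. The
six-type spectrum pools each change with its reverse-strand counterpart
(e.g. G>A with C>T), labelled by the lexicographically smaller member.

**Indels.** Each maximal gap run is one event, expressed against the
standard genome: Insertion when the standard carries the bases, Deletion
when the standard has the gap. Events are left-normalized (shifted 5′ while
the base left of the event equals the event's last base), giving every
equivalent gap placement one canonical representation; normalization is
idempotent and aligner-placement-independent. An event is **homopolymeric**
iff its sequence is a run of one base and the standard carries a run of that
base of length ≥ `homopolymer_min_run` (default 3) immediately right of the
normalized position. Three is the smallest value that keeps classic
slippage events (including two-base expansions of an A-run) homopolymeric
while excluding a lone base deleted without any run context.

**p-distance** is the share of differing sites among gap-free aligned sites
(pairwise deletion of gap columns; either deletion convention rounds the
same at plastome divergences), with inversion columns masked in the pipeline
so p equals substitutions/comparable sites by construction. Reported to 5
decimals; Ts/Tv ratio to 2 decimals (undefined when no transversions).

## Junction analysis

The four junctions are reported as the last base of the upstream region on
the canonical rotation. The distance from a junction to its nearest gene on
the single-copy side counts bases strictly between them — touching = 0, one
intervening base = 1 — which reproduces the published 0/1/2 bp phrasing for
the trnH-type comparisons across genera. A gene whose span crosses a
junction is reported with the number of its bases inside the IR (the
ycf1-type IR-expansion case); the inside-IR and outside-IR portions always
sum to the span. Pseudogene creation by IR expansion is not modelled beyond
this report.

## Synthetic data generator

The generator emulates the published pair's study conditions; its defaults
are the reported values, not tuning knobs. A genome is LSC + IRb + SSC +
revcomp(IRb) with region lengths 84,214 / 24,171 / 19,014 bp and per-region
GC 34.4 / 43.0 / 29.7 % (bases drawn i.i.d. with G and C equally likely);
planted gene features (30 genes, 6 with introns) and two SSR loci of every
motif class (1–6 bp), each written with broken flanks so the planted locus
is maximal. The mutated copy carries 44 substitutions with transition count
drawn Binomial(44, 19/44), 16 homopolymer indels made by expanding or
contracting existing single-base runs of 3–8 bp (the slippage mechanism),
7 other indels of 1–6 bp constrained to be left-normalized and
non-homopolymeric as planted, and 2 inversions of 3–14 bp flanked by
19–27 bp hairpin arms.

Constraints that keep the truth set unambiguous, and their rationale:

- Events are planted only in single-copy regions. A single-copy change
  inside one IR copy would break the exact IR mirror of that genome;
  biologically the IR is the conserved compartment, and the published
  events fall in single-copy regions.
- Events sit ≥ 100 bp from junctions, ≥ 50 bp apart, and outside existing
  SSR loci, so no call can be ambiguous about which planted event it is.
  Stress behaviour with adjacent events is exercised only through the
  round-trip reconstruction invariant, not per-event class assertions.
- Inversion hairpin arms are pre-existing repeats, so they are embedded in
  the shared background of *both* genomes: the standard returned inside the
  TruthSet is the arm-carrying genome and is the reference to compare
  against. Inversion cores are drawn so that every position mismatches its
  reverse complement *and* the affine-gap aligner prefers the all-mismatch
  diagonal over any gapped representation — otherwise a flip could
  legitimately surface as indels plus substitutions.

Everything is deterministic under the GenomeSpec/MutationSpec seeds, down
to byte-identical FASTA/GFF3/JSON outputs.

What the generator does **not** emulate: codon structure and selection (so
synonymous/nonsynonymous classification has no synthetic truth and is out
of scope), mutation hotspots and clustering, compound or imperfect SSRs,
IR-internal events, heteroplasmy, and rearrangements beyond micro-inversions.
Passing recovery tests therefore demonstrate correctness of detection,
classification, normalization and coordinate bookkeeping under clean,
well-separated events — not robustness to every configuration real genomes
can present.

## Problem sizes used in tests and the acceptance script

Statistics derived from printed data (Ts/Tv, per-location counts, SSR class
summary, p-distance, region-length conservation) are recomputed from the
packaged reference tables at their natural sizes (44 substitutions, 23
indels, 59 SSR loci, four region lengths). Simulation-backed checks run on
compact 34 kb genomes (LSC 20 kb, IR 4 kb, SSC 6 kb) carrying the full
published event mix — the event classes, spacing rules and detection
mathematics are scale-free, so a smaller circle exercises the identical
code paths; one full-size (151.6 kb) generation is exercised for
composition targets. Recovery is checked across 20 seeds in the test suite
and 5 seeds in the acceptance script.

## Known limitations

- The aligner assumes collinearity; genomes needing rearrangement-aware
  alignment are rejected, not mis-aligned.
- SSR scanning reports perfect repeats only; a run is reported under its
  primitive period with whole-unit counts (a trailing partial unit is not
  part of the locus).
- The reference tables transcribe printed values, including three printed
  discrepancies (two indel rows whose sequence length contradicts the
  printed length, one SSR row with garbled coordinates and one with a
  garbled motif); these rows carry flags rather than silent corrections.
- The published grand total of "67 mutations" equals substitutions plus
  indels; adding the two micro-inversions gives 69. The package reports the
  substitutions-plus-indels total alongside the separate inversion count and
  leaves the arithmetic visible.
- Gene counting conventions (whether IR-duplicated genes count once or
  twice) are a bookkeeping choice exposed in reports, not fixed by the
  package.
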