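"""Packaged reference tables for the published Haloxylon plastome pair.

The tables transcribe the reported comparison of the H. ammodendron
(GenBank KF534478) and H. persicum (KF534479) chloroplast genomes: genome
features per region, the 23 indel events, the 44 substitution sites, the
per-gene coding changes, the 59 SSR loci, and the two micro-inversions.
They serve as a zero-download test surface: every derivable headline
statistic can be recomputed from them by the package's own classifiers.

Transcription discrepancies in the printed source are carried in a `flags`
column, never silently resolved: two indel rows print five-base lengths
against six-base sequences, one SSR row prints garbled coordinates and one
a garbled motif (both corrected readings are flagged).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

TABLE_NAMES = (
    "genome_features",
    "indels",
    "substitutions",
    "coding_gene_changes",
    "ssr_loci",
    "inversions",
)


def load_reference_table(name: str) -> pd.DataFrame:
    """Load one packaged reference table as a DataFrame.

    Valid names: genome_features, indels, substitutions,
    coding_gene_changes, ssr_loci, inversions.
    """
    if name not in TABLE_NAMES:
        raise KeyError(
            f"unknown reference table {name!r}; choose from {TABLE_NAMES}"
        )
    ref = resources.files("plastcomp.data") / f"{name}.tsv"
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t", dtype={"flags": "string"})
    if "flags" in df.columns:
        df["flags"] = df["flags"].fillna("")
    return df
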