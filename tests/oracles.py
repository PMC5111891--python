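"""Independent brute-force oracles used to cross-check the fast scanners.

These deliberately re-derive results from first principles (per-start
enumeration, full pair matrices) and share no code with the implementations
they check.
"""

from __future__ import annotations

import numpy as np

_COMP = str.maketrans("ACGT", "TGCA")


def _primitive(motif: str) -> bool:
    n = len(motif)
    return all(
        not (n % d == 0 and motif == motif[:d] * (n // d)) for d in range(1, n)
    )


def brute_force_ssrs(seq: str, thresholds: dict[int, int]):
    """Every maximal perfect tandem repeat of a linear sequence.

    Enumerates all (start, unit-length) pairs, extends each to its maximal
    period-u region, keeps left-maximal regions with a primitive motif and a
    whole-unit repeat count meeting the threshold. Returns sorted tuples
    (motif, unit, repeats, start, end), 1-based inclusive.
    """
    n = len(seq)
    found = set()
    for u in range(1, 7):
        for i in range(n - u):
            if i > 0 and i - 1 + u < n and seq[i - 1] == seq[i - 1 + u]:
                continue  # not left-maximal
            j = i + u
            while j < n and seq[j] == seq[j - u]:
                j += 1
            repeats = (j - i) // u
            if repeats < thresholds[u]:
                continue
            motif = seq[i : i + u]
            if not _primitive(motif):
                continue
            found.add((motif, u, repeats, i + 1, i + repeats * u))
    return sorted(found)


def brute_force_inverted_pairs(seq: str, min_len: int):
    """All maximal exact inverted pairs of a linear sequence.

    Builds the full complementarity matrix M[i, j] = (seq[i] == comp(seq[j]))
    and extracts maximal anti-diagonal runs: a run over i in [a, b] on
    anti-diagonal d pairs interval [a, b] with [d - b, d - a]. Returns
    0-based disjoint interval pairs ((s1, e1), (s2, e2)) with s1 < s2,
    both inclusive, of maximal matches >= min_len.
    """
    s = np.frombuffer(seq.encode(), dtype="S1")
    comp = np.frombuffer(seq.translate(_COMP).encode(), dtype="S1")
    m = s[:, None] == comp[None, :]
    n = len(seq)
    flipped = m[:, ::-1]  # anti-diagonal d=i+j -> diagonal offset n-1-d
    pairs = set()
    for d in range(2 * n - 1):
        v = np.diagonal(flipped, offset=n - 1 - d)
        i0 = max(0, d - n + 1)  # i of the first element of this anti-diagonal
        padded = np.concatenate(([False], v, [False]))
        edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
        for a, b in zip(edges[::2], edges[1::2]):
            run = b - a  # run over rows i in [i0+a, i0+b-1]
            if run < min_len:
                continue
            ia, ib = i0 + a, i0 + b - 1
            ja, jb = d - ib, d - ia
            first, second = sorted([(ia, ib), (ja, jb)])
            if first[1] < second[0]:  # disjoint
                pairs.add((first, second))
    return sorted(pairs)
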