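"""Pairwise sequence comparison primitives.

Identity is defined as matches divided by global-alignment length, under a
simple scoring scheme (match +1, mismatch -1, gap -2).  The small edit
distance used by denoising is computed with a banded dynamic program.
"""

from __future__ import annotations

from functools import lru_cache

from Bio import Align

_aligner = Align.PairwiseAligner(
    mode="global",
    match_score=1,
    mismatch_score=-1,
    open_gap_score=-2,
    extend_gap_score=-2,
)


@lru_cache(maxsize=200_000)
def identity(a: str, b: str) -> float:
    """Global-alignment identity: matches / alignment length."""
    if a == b:
        return 1.0
    aln = _aligner.align(a, b)[0]
    counts = aln.counts()
    return counts.identities / aln.length


def within_edit_distance(a: str, b: str, k: int) -> bool:
    """True when the Levenshtein distance of ``a`` and ``b`` is <= ``k``."""
    if a == b:
        return True
    if abs(len(a) - len(b)) > k:
        return False
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, start=1):
        cur = [i] + [0] * len(b)
        for j, cb in enumerate(b, start=1):
            cur[j] = min(prev[j - 1] + (ca != cb), prev[j] + 1, cur[j - 1] + 1)
        if min(cur) > k:  # distance can only grow from here
            return False
        prev = cur
    return prev[len(b)] <= k


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))
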