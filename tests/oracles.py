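"""Independent oracles used to check the implementation.

These deliberately avoid the library's own code paths: the alignment oracle
optimises over *all* global alignments by top-down recursion over alignment
states (with memoisation — equivalent to exhaustive enumeration), and the
tiny-string enumerator walks every alignment path explicitly.
"""

from __future__ import annotations

import sys
from functools import lru_cache

NEG_INF = float("-inf")


def oracle_align_score(
    a: str,
    b: str,
    match: float = 1.0,
    mismatch: float = -2.0,
    gap_open: float = -4.0,
    gap_extend: float = -1.0,
) -> float:
    """Best global affine-gap score over all alignments of ``a`` and ``b``.

    A gap of length k scores ``gap_open + (k - 1) * gap_extend``.
    """
    sys.setrecursionlimit(10000)

    @lru_cache(maxsize=None)
    def best(i: int, j: int, last: str) -> float:
        if i == len(a) and j == len(b):
            return 0.0
        s = NEG_INF
        if i < len(a) and j < len(b):
            sub = match if a[i] == b[j] else mismatch
            s = max(s, sub + best(i + 1, j + 1, "M"))
        if i < len(a):
            cost = gap_extend if last == "A" else gap_open
            s = max(s, cost + best(i + 1, j, "A"))
        if j < len(b):
            cost = gap_extend if last == "B" else gap_open
            s = max(s, cost + best(i, j + 1, "B"))
        return s

    return best(0, 0, "M")


def enumerate_alignment_scores(
    a: str,
    b: str,
    match: float = 1.0,
    mismatch: float = -2.0,
    gap_open: float = -4.0,
    gap_extend: float = -1.0,
) -> list[float]:
    """Scores of every global alignment of two tiny strings (no caching)."""
    out: list[float] = []

    def walk(i: int, j: int, last: str, score: float) -> None:
        if i == len(a) and j == len(b):
            out.append(score)
            return
        if i < len(a) and j < len(b):
            sub = match if a[i] == b[j] else mismatch
            walk(i + 1, j + 1, "M", score + sub)
        if i < len(a):
            cost = gap_extend if last == "A" else gap_open
            walk(i + 1, j, "A", score + cost)
        if j < len(b):
            cost = gap_extend if last == "B" else gap_open
            walk(i, j + 1, "B", score + cost)

    walk(0, 0, "M", 0.0)
    return out
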