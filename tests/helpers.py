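"""Independent oracles used by the test suite.

These deliberately re-derive expected results through different code paths
than the package: a character-table window checker for motif scanning, and
a substring-enumeration + memoized-recursion alignment scorer for local
alignment.  They are slow and simple on purpose.
"""

from __future__ import annotations

import random
from functools import lru_cache

AA = "ACDEFGHIKLMNPQRSTVWY"

# Independent expansion table (strings, not the package's frozensets).
EXPAND = {**{a: a for a in AA}, "X": AA, "B": "DN", "Z": "EQ", "J": "IL"}


def naive_window_matches(pattern: str, sequence: str,
                         max_mismatches: int = 0) -> list[tuple[int, int]]:
    """All (offset, mismatches) where the pattern fits, by direct checking."""
    out = []
    m = len(pattern)
    for off in range(len(sequence) - m + 1):
        mism = 0
        for i, pch in enumerate(pattern):
            if pch in ("x", "X"):
                continue
            allowed = EXPAND[pch]
            actual = EXPAND.get(sequence[off + i], "")
            if not any(c in allowed for c in actual):
                mism += 1
        if mism <= max_mismatches:
            out.append((off, mism))
    return out


def nw_affine_score(x: str, y: str, scheme) -> int:
    """Global affine alignment score of two (sub)strings, by memoized
    recursion over (position, previous column type)."""

    @lru_cache(maxsize=None)
    def rec(i: int, j: int, prev: str) -> int:
        if i == len(x) and j == len(y):
            return 0
        best = None
        if i < len(x) and j < len(y):
            cand = scheme.score(x[i], y[j]) + rec(i + 1, j + 1, "M")
            best = cand
        if i < len(x):
            open_cost = 0 if prev == "X" else scheme.gap_open
            cand = -(open_cost + scheme.gap_extend) + rec(i + 1, j, "X")
            best = cand if best is None else max(best, cand)
        if j < len(y):
            open_cost = 0 if prev == "Y" else scheme.gap_open
            cand = -(open_cost + scheme.gap_extend) + rec(i, j + 1, "Y")
            best = cand if best is None else max(best, cand)
        return best

    score = rec(0, 0, "M")
    rec.cache_clear()
    return score


def exhaustive_local_score(a: str, b: str, scheme) -> int:
    """Best local alignment score by enumerating every substring pair and
    globally aligning it.  Exponential in spirit, fine for lengths ≤ 8."""
    best = 0
    for i0 in range(len(a)):
        for i1 in range(i0 + 1, len(a) + 1):
            for j0 in range(len(b)):
                for j1 in range(j0 + 1, len(b) + 1):
                    best = max(best,
                               nw_affine_score(a[i0:i1], b[j0:j1], scheme))
    return best


def random_protein(rng: random.Random, length: int,
                   alphabet: str = AA) -> str:
    return "".join(rng.choice(alphabet) for _ in range(length))


def random_pattern(rng: random.Random, length: int) -> str:
    symbols = AA + "xBZJ" + "xxxx"  # bias toward wildcards
    return "".join(rng.choice(symbols) for _ in range(length))
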