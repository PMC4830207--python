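"""Smith–Waterman local protein alignment with affine gaps.

Used to localize cupin-domain homology in candidate proteins against
reference cupin sequences.  The default scoring scheme mirrors standard
protein-BLAST defaults: BLOSUM62 with gap open 11 and gap extend 1, under
the convention that a gap of length L costs ``gap_open + L * gap_extend``.

Significance is deliberately not an E-value model (database-size dependent
statistics are out of scope): a hit is accepted when its raw score per
aligned column and its aligned length clear configurable thresholds.

The traceback is fully deterministic: ties are broken diagonal > up (gap in
target) > left (gap in query), and among equal-scoring end cells the first
in row-major order wins, so repeated runs are byte-identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

import numpy as np
from Bio.Align import substitution_matrices

from .sequence_io import AMINO_ACIDS, ProteinRecord

#: Alignment alphabet: 20 amino acids followed by the ambiguity codes.
ALIGN_ALPHABET = AMINO_ACIDS + "BZJX"
_INDEX = {aa: i for i, aa in enumerate(ALIGN_ALPHABET)}

NEG_INF = -(10 ** 9)

# traceback codes
_STOP, _FROM_M, _FROM_X, _FROM_Y = 0, 1, 2, 3


class AlignmentError(ValueError):
    pass


def ambiguity_score(x: str, y: str, core: dict[tuple[str, str], int]) -> int:
    """Substitution score extended to ambiguity codes.

    For B/Z/J/X the score is the arithmetic mean of the member-pair scores,
    rounded toward zero; X averages over all 20 residues.  Symmetric by
    construction.
    """
    members = {"B": "DN", "Z": "EQ", "J": "IL", "X": AMINO_ACIDS}
    xs = members.get(x, x)
    ys = members.get(y, y)
    if any(c not in AMINO_ACIDS for c in xs) or any(
            c not in AMINO_ACIDS for c in ys):
        raise AlignmentError(f"unknown residue in pair ({x!r}, {y!r})")
    total = sum(core[(a, b)] for a in xs for b in ys)
    return math.trunc(total / (len(xs) * len(ys)))


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution matrix (extended to ambiguity codes) plus affine gaps."""

    matrix: np.ndarray  # (24, 24) ints over ALIGN_ALPHABET
    gap_open: int
    gap_extend: int
    name: str = "custom"

    def __post_init__(self) -> None:
        if self.matrix.shape != (len(ALIGN_ALPHABET), len(ALIGN_ALPHABET)):
            raise AlignmentError(
                f"matrix must be {len(ALIGN_ALPHABET)}x{len(ALIGN_ALPHABET)} "
                f"over {ALIGN_ALPHABET!r}"
            )
        if not np.array_equal(self.matrix, self.matrix.T):
            raise AlignmentError("substitution matrix must be symmetric")
        if self.gap_open < self.gap_extend or self.gap_extend <= 0:
            raise AlignmentError("require gap_open >= gap_extend > 0")

    def score(self, a: str, b: str) -> int:
        try:
            return int(self.matrix[_INDEX[a], _INDEX[b]])
        except KeyError as exc:
            raise AlignmentError(f"residue {exc} outside alignment alphabet")

    def gap_cost(self, length: int) -> int:
        """Positive cost of a gap run of ``length`` residues."""
        if length <= 0:
            return 0
        return self.gap_open + length * self.gap_extend


def _extend_core(core: dict[tuple[str, str], int]) -> np.ndarray:
    n = len(ALIGN_ALPHABET)
    mat = np.zeros((n, n), dtype=np.int64)
    for i, a in enumerate(ALIGN_ALPHABET):
        for j, b in enumerate(ALIGN_ALPHABET):
            mat[i, j] = ambiguity_score(a, b, core)
    return mat


def scheme_from_core(core: dict[tuple[str, str], int], gap_open: int = 11,
                     gap_extend: int = 1, name: str = "custom") -> ScoringScheme:
    """Build a scheme from 20x20 residue-pair scores (ambiguity rows derived)."""
    return ScoringScheme(matrix=_extend_core(core), gap_open=gap_open,
                         gap_extend=gap_extend, name=name)


def _core_from_biopython(m) -> dict[tuple[str, str], int]:
    return {(a, b): int(m[a, b]) for a in AMINO_ACIDS for b in AMINO_ACIDS}


@lru_cache(maxsize=None)
def blosum62_scheme(gap_open: int = 11, gap_extend: int = 1) -> ScoringScheme:
    """BLOSUM62 with protein-BLAST default gap penalties."""
    core = _core_from_biopython(substitution_matrices.load("BLOSUM62"))
    return scheme_from_core(core, gap_open, gap_extend, name="BLOSUM62")


def read_matrix_scheme(path: str | Path, gap_open: int = 11,
                       gap_extend: int = 1) -> ScoringScheme:
    """Load a substitution matrix in NCBI text format from a file."""
    m = substitution_matrices.read(str(path))
    missing = [aa for aa in AMINO_ACIDS if aa not in m.alphabet]
    if missing:
        raise AlignmentError(f"matrix at {path} lacks residues {missing}")
    return scheme_from_core(_core_from_biopython(m), gap_open, gap_extend,
                            name=Path(path).stem)


@dataclass(frozen=True)
class LocalAlignment:
    """Result of a local alignment; empty (score 0) when nothing aligns."""

    score: int
    query_interval: tuple[int, int]   # 0-based half-open on the query
    target_interval: tuple[int, int]  # 0-based half-open on the target
    aligned_query: str
    aligned_target: str
    identity_fraction: float

    @property
    def n_columns(self) -> int:
        return len(self.aligned_query)

    @property
    def is_empty(self) -> bool:
        return self.n_columns == 0

    def score_per_column(self) -> float:
        if self.is_empty:
            return 0.0
        return self.score / self.n_columns


def score_alignment(aligned_a: str, aligned_b: str,
                    scheme: ScoringScheme) -> int:
    """Recompute the score of a gapped alignment (consistency checks)."""
    if len(aligned_a) != len(aligned_b):
        raise AlignmentError("aligned strings differ in length")
    score = 0
    in_gap = False
    for ca, cb in zip(aligned_a, aligned_b):
        if ca == "-" or cb == "-":
            if ca == "-" and cb == "-":
                raise AlignmentError("double-gap column")
            score -= scheme.gap_extend + (0 if in_gap else scheme.gap_open)
            in_gap = True
        else:
            score += scheme.score(ca, cb)
            in_gap = False
    return score


def _encode(residues: str) -> np.ndarray:
    seq = residues[:-1] if residues.endswith("*") else residues
    try:
        return np.array([_INDEX[c] for c in seq], dtype=np.int64)
    except KeyError as exc:
        raise AlignmentError(f"residue {exc} cannot be aligned")


def _sw_fill(a: np.ndarray, b: np.ndarray, mat: np.ndarray,
             go: int, ge: int):
    """Gotoh fill: returns (M, X, Y, PM, PX, PY) DP and pointer tables.

    M ends in a substitution column, X in a gap in the target (consumes
    query), Y in a gap in the query (consumes target).
    """
    n, m = len(a), len(b)
    M = np.full((n + 1, m + 1), NEG_INF, dtype=np.int64)
    X = np.full((n + 1, m + 1), NEG_INF, dtype=np.int64)
    Y = np.full((n + 1, m + 1), NEG_INF, dtype=np.int64)
    PM = np.zeros((n + 1, m + 1), dtype=np.int8)
    PX = np.zeros((n + 1, m + 1), dtype=np.int8)
    PY = np.zeros((n + 1, m + 1), dtype=np.int8)
    open_cost = go + ge
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = mat[a[i - 1], b[j - 1]]
            # substitution: best predecessor among fresh start / M / X / Y
            best, ptr = 0, _STOP
            if M[i - 1, j - 1] > best:
                best, ptr = M[i - 1, j - 1], _FROM_M
            if X[i - 1, j - 1] > best:
                best, ptr = X[i - 1, j - 1], _FROM_X
            if Y[i - 1, j - 1] > best:
                best, ptr = Y[i - 1, j - 1], _FROM_Y
            M[i, j] = best + s
            PM[i, j] = ptr
            # gap in target (up): consume a[i-1]
            bx, px = M[i - 1, j] - open_cost, _FROM_M
            if X[i - 1, j] - ge > bx:
                bx, px = X[i - 1, j] - ge, _FROM_X
            if Y[i - 1, j] - open_cost > bx:
                bx, px = Y[i - 1, j] - open_cost, _FROM_Y
            X[i, j] = bx
            PX[i, j] = px
            # gap in query (left): consume b[j-1]
            by, py = M[i, j - 1] - open_cost, _FROM_M
            if X[i, j - 1] - open_cost > by:
                by, py = X[i, j - 1] - open_cost, _FROM_X
            if Y[i, j - 1] - ge > by:
                by, py = Y[i, j - 1] - ge, _FROM_Y
            Y[i, j] = by
            PY[i, j] = py
    return M, X, Y, PM, PX, PY


try:  # optional JIT; the pure-Python fill is the reference behaviour
    from numba import njit as _njit

    _sw_fill = _njit(cache=False)(_sw_fill)  # type: ignore[assignment]
except ImportError:  # pragma: no cover
    pass


def smith_waterman(a: ProteinRecord | str, b: ProteinRecord | str,
                   scheme: ScoringScheme | None = None) -> LocalAlignment:
    """Optimal local alignment of ``a`` (query) against ``b`` (target).

    Raises on empty input; returns an empty alignment when no positive-
    scoring pair of segments exists.
    """
    scheme = scheme or blosum62_scheme()
    res_a = a if isinstance(a, str) else a.residues
    res_b = b if isinstance(b, str) else b.residues
    ea, eb = _encode(res_a), _encode(res_b)
    if len(ea) == 0 or len(eb) == 0:
        raise AlignmentError("cannot align an empty sequence")
    M, X, Y, PM, PX, PY = _sw_fill(ea, eb, scheme.matrix,
                                   scheme.gap_open, scheme.gap_extend)
    # best end cell: local score is max over M (trailing gaps never help),
    # first occurrence in row-major order
    best = int(M.max(initial=0))
    if best <= 0:
        return LocalAlignment(score=0, query_interval=(0, 0),
                              target_interval=(0, 0), aligned_query="",
                              aligned_target="", identity_fraction=0.0)
    end = np.argwhere(M == best)[0]
    i, j = int(end[0]), int(end[1])
    end_i, end_j = i, j
    state = _FROM_M
    cols_a: list[str] = []
    cols_b: list[str] = []
    while True:
        if state == _FROM_M:
            cols_a.append(ALIGN_ALPHABET[ea[i - 1]])
            cols_b.append(ALIGN_ALPHABET[eb[j - 1]])
            prev = PM[i, j]
            i, j = i - 1, j - 1
            if prev == _STOP:
                break
            state = prev
        elif state == _FROM_X:
            cols_a.append(ALIGN_ALPHABET[ea[i - 1]])
            cols_b.append("-")
            state = PX[i, j]
            i -= 1
        else:
            cols_a.append("-")
            cols_b.append(ALIGN_ALPHABET[eb[j - 1]])
            state = PY[i, j]
            j -= 1
    aligned_a = "".join(reversed(cols_a))
    aligned_b = "".join(reversed(cols_b))
    identical = sum(1 for x, y in zip(aligned_a, aligned_b)
                    if x == y and x != "-")
    return LocalAlignment(
        score=best,
        query_interval=(i, end_i),
        target_interval=(j, end_j),
        aligned_query=aligned_a,
        aligned_target=aligned_b,
        identity_fraction=identical / len(aligned_a),
    )


@dataclass(frozen=True)
class SignificanceThresholds:
    """Score-density and length gates standing in for E-value statistics."""

    min_score_per_column: float = 2.0
    min_columns: int = 40

    def __post_init__(self) -> None:
        if self.min_score_per_column <= 0 or self.min_columns <= 0:
            raise ValueError("thresholds must be positive")

    def accepts(self, aln: LocalAlignment) -> bool:
        return (not aln.is_empty
                and aln.n_columns >= self.min_columns
                and aln.score_per_column() >= self.min_score_per_column)
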