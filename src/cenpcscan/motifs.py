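"""Degenerate protein motif parsing, consensus derivation and scanning.

The motif model is a PROSITE-like identity pattern: an ordered list of
residue sets.  ``x``/``X`` positions admit any residue ("wildcard"), ``B``
admits Asx {D, N}, ``Z`` Glx {E, Q}, ``J`` {I, L}, and a plain letter admits
exactly itself.  This is the representation behind patterns such as the
CENP-C central-region core RxxxxPxxWW or the 23-residue vertebrate CENP-C
motif NVRRTKRXRLKPLEYWRGERVBY.

Matching is by non-empty set intersection between the motif position's set
and the sequence residue's own ambiguity set, so a degenerate consensus can
be scanned against another degenerate consensus.  Wildcard positions never
count toward mismatches; only constrained positions can be violated.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources

from .sequence_io import (
    AMINO_ACIDS,
    MultipleAlignment,
    ProteinRecord,
)

FULL_SET = frozenset(AMINO_ACIDS)

#: Ambiguity expansion for residues appearing in *sequences*.
RESIDUE_SETS: dict[str, frozenset[str]] = {
    **{aa: frozenset(aa) for aa in AMINO_ACIDS},
    "X": FULL_SET,
    "B": frozenset("DN"),
    "Z": frozenset("EQ"),
    "J": frozenset("IL"),
    "*": frozenset(),  # terminal stop matches nothing
}

_AMBIGUITY_RENDER = {
    frozenset("DN"): "B",
    frozenset("EQ"): "Z",
    frozenset("IL"): "J",
}


class PatternError(ValueError):
    """Raised for malformed motif pattern strings."""


class ConsensusError(ValueError):
    """Raised when consensus derivation retains no columns."""


@dataclass(frozen=True)
class DegenerateMotif:
    """An ordered sequence of residue sets, e.g. parsed from "RxxxxPxxWW"."""

    id: str
    positions: tuple[frozenset[str], ...]
    source: str = "literal"  # "literal" | "derived"

    def __post_init__(self) -> None:
        if not self.positions:
            raise PatternError(f"motif {self.id!r} has zero positions")
        for i, pos in enumerate(self.positions):
            if not pos:
                raise PatternError(f"motif {self.id!r}: empty set at {i}")
            if not pos <= FULL_SET:
                raise PatternError(
                    f"motif {self.id!r}: non-residue symbols at {i}: {pos}"
                )
        if self.source not in ("literal", "derived"):
            raise PatternError(f"unknown motif source {self.source!r}")

    def __len__(self) -> int:
        return len(self.positions)

    def is_wildcard(self, i: int) -> bool:
        return self.positions[i] == FULL_SET

    @property
    def constrained_positions(self) -> tuple[int, ...]:
        return tuple(i for i in range(len(self)) if not self.is_wildcard(i))

    def render(self) -> str:
        """One-letter pattern string; inverse of :func:`parse_pattern`."""
        out = []
        for i, pos in enumerate(self.positions):
            if pos == FULL_SET:
                out.append("x")
            elif len(pos) == 1:
                out.append(next(iter(pos)))
            elif pos in _AMBIGUITY_RENDER:
                out.append(_AMBIGUITY_RENDER[pos])
            else:
                raise PatternError(
                    f"motif {self.id!r}: position {i} set {sorted(pos)} has "
                    "no one-letter rendering"
                )
        return "".join(out)


def parse_pattern(text: str, motif_id: str | None = None) -> DegenerateMotif:
    """Parse a one-letter degenerate pattern such as "RxxxxPxxWW".

    ``x`` and ``X`` are wildcards; B, Z, J are the IUPAC two-residue
    ambiguity codes; any other uppercase amino-acid letter constrains the
    position to that residue.
    """
    if not text:
        raise PatternError("empty pattern string")
    positions: list[frozenset[str]] = []
    for i, ch in enumerate(text):
        if ch in ("x", "X"):
            positions.append(FULL_SET)
        elif ch in ("B", "Z", "J"):
            positions.append(RESIDUE_SETS[ch])
        elif ch in FULL_SET:
            positions.append(frozenset(ch))
        else:
            raise PatternError(
                f"illegal pattern character {ch!r} at position {i}"
            )
    return DegenerateMotif(id=motif_id or text, positions=tuple(positions))


@dataclass(frozen=True)
class MotifHit:
    """A placement of a motif on a sequence.

    ``per_position`` records, per motif position, ``|`` (constrained,
    satisfied), ``.`` (wildcard) or ``x`` (constrained, violated) — the
    machine-readable form of highlighting matched identities in an
    alignment figure.
    """

    sequence_id: str
    motif_id: str
    offset: int
    length: int
    mismatches: int
    per_position: str

    def __post_init__(self) -> None:
        if self.mismatches != self.per_position.count("x"):
            raise ValueError(
                f"hit {self.motif_id}@{self.offset}: mismatch count "
                f"{self.mismatches} != per-position record "
                f"{self.per_position!r}"
            )
        if len(self.per_position) != self.length:
            raise ValueError("per_position length != motif length")

    @property
    def end(self) -> int:
        return self.offset + self.length

    @property
    def violated_positions(self) -> tuple[int, ...]:
        """0-based motif positions whose constraint was not satisfied."""
        return tuple(i for i, c in enumerate(self.per_position) if c == "x")


def _residues_of(seq: ProteinRecord | str) -> tuple[str, str]:
    if isinstance(seq, str):
        return "<string>", seq
    return seq.id, seq.residues


def scan(motif: DegenerateMotif, seq: ProteinRecord | str,
         max_mismatches: int = 0) -> list[MotifHit]:
    """All windows where ≤ ``max_mismatches`` constrained positions fail.

    A position is satisfied iff the motif set and the sequence residue's
    ambiguity set intersect (a sequence X satisfies everything; a sequence B
    satisfies any set containing D or N).  Overlapping hits are all
    reported, sorted by offset.
    """
    if max_mismatches < 0:
        raise ValueError("max_mismatches must be ≥ 0")
    seq_id, residues = _residues_of(seq)
    m = len(motif)
    hits: list[MotifHit] = []
    for off in range(len(residues) - m + 1):
        record = []
        mismatches = 0
        for i in range(m):
            if motif.is_wildcard(i):
                record.append(".")
                continue
            res_set = RESIDUE_SETS.get(residues[off + i])
            if res_set is None:
                raise ValueError(
                    f"sequence {seq_id!r}: unknown residue "
                    f"{residues[off + i]!r} at offset {off + i}"
                )
            if motif.positions[i] & res_set:
                record.append("|")
            else:
                record.append("x")
                mismatches += 1
                if mismatches > max_mismatches:
                    break
        else:
            hits.append(MotifHit(
                sequence_id=seq_id, motif_id=motif.id, offset=off,
                length=m, mismatches=mismatches,
                per_position="".join(record),
            ))
    return hits


# --- consensus derivation ---------------------------------------------------

@dataclass(frozen=True)
class ConsensusPolicy:
    """Column rules for deriving a degenerate consensus from an alignment.

    min_fraction
        A residue is retained in a column iff its frequency is at least
        ``min_fraction`` times the modal residue frequency of that column.
        1.0 keeps only the modal residue(s), ties included.
    allow_ambiguity_codes
        Collapse retained sets {D,N} / {E,Q} / {I,L} to B / Z / J; if
        False such sets degrade to a wildcard.
    max_gap_fraction
        Columns whose gap fraction exceeds this are dropped.  The default 0
        keeps only fully gap-free columns (the vertebrate CENP-C motif is
        contiguous).
    """

    min_fraction: float = 1.0
    allow_ambiguity_codes: bool = True
    max_gap_fraction: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.min_fraction <= 1.0:
            raise ValueError("min_fraction must be in (0, 1]")
        if not 0.0 <= self.max_gap_fraction <= 1.0:
            raise ValueError("max_gap_fraction must be in [0, 1]")


@dataclass(frozen=True)
class ColumnProfile:
    index: int
    frequencies: dict[str, float] = field(hash=False)
    gap_fraction: float = 0.0


def conservation_profile(aln: MultipleAlignment) -> list[ColumnProfile]:
    """Per-column residue frequencies over non-gap symbols, plus gap fraction."""
    profiles = []
    n = aln.n_rows
    for j in range(aln.n_columns):
        col = aln.column(j)
        gaps = col.count("-")
        symbols = [c for c in col if c != "-"]
        freqs: dict[str, float] = {}
        if symbols:
            for sym, count in sorted(Counter(symbols).items()):
                freqs[sym] = count / len(symbols)
        profiles.append(ColumnProfile(index=j, frequencies=freqs,
                                      gap_fraction=gaps / n))
    return profiles


def _classify_set(residues: frozenset[str],
                  policy: ConsensusPolicy) -> frozenset[str]:
    if len(residues) == 1:
        return residues
    if policy.allow_ambiguity_codes:
        for amb in (frozenset("DN"), frozenset("EQ"), frozenset("IL")):
            if residues <= amb:
                return amb
    return FULL_SET


def derive_consensus(aln: MultipleAlignment,
                     policy: ConsensusPolicy = ConsensusPolicy(),
                     motif_id: str = "derived-consensus") -> DegenerateMotif:
    """Collapse an alignment to a degenerate motif, column by column.

    Columns with too many gaps are dropped; in the remaining columns the
    residues within ``min_fraction`` of the modal frequency are pooled
    (their own ambiguity sets expanded) and the pooled set is rendered as a
    single residue, an ambiguity code, or a wildcard.
    """
    positions: list[frozenset[str]] = []
    for profile in conservation_profile(aln):
        if profile.gap_fraction > policy.max_gap_fraction:
            continue
        if not profile.frequencies:
            continue
        modal = max(profile.frequencies.values())
        kept = [sym for sym, f in profile.frequencies.items()
                if f >= policy.min_fraction * modal - 1e-12]
        pooled: frozenset[str] = frozenset().union(
            *(RESIDUE_SETS[sym] for sym in kept))
        positions.append(_classify_set(pooled, policy))
    if not positions:
        raise ConsensusError("no consensus columns survive the policy")
    return DegenerateMotif(id=motif_id, positions=tuple(positions),
                           source="derived")


# --- packaged pattern fixtures ----------------------------------------------

def load_fixture_motifs() -> dict[str, DegenerateMotif]:
    """The package's bundled identity patterns, keyed by id.

    Includes the 23-residue vertebrate CENP-C motif consensus, the identity
    pattern within it, its core, and the central-region consensus and core.
    """
    data = resources.files("cenpcscan.data").joinpath("motifs.json")
    entries = json.loads(data.read_text())
    motifs = {}
    for entry in entries:
        motifs[entry["id"]] = parse_pattern(entry["pattern"], entry["id"])
    return motifs
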