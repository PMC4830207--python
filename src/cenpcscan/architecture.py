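"""Domain-architecture classification of CENP-C ortholog candidates.

A protein is classified from two kinds of evidence: a C-terminal cupin
(dimerization) domain localized by local alignment against reference cupin
sequences, and identity-pattern hits of the CENP-C motif placed relative to
that domain.  The classes mirror the architectures seen across vertebrates:

CANONICAL_CENPC
    Cupin domain plus an exact hit of the full CENP-C motif identity
    pattern ending within ``canonical_gap_max`` (default 100) residues
    upstream of the cupin start.
PUTATIVE_FISH_CENPC
    Cupin domain plus at least one hit of the central-region core pattern
    (RxxxxPxxWW), tolerating up to ``degraded_max_mismatches`` violated
    identities, anywhere upstream of the cupin.  The shark case — both
    tryptophans of one region lost — motivates the default tolerance of 2.
MOTIF_ONLY
    CENP-C motif evidence without any cupin domain; reported as
    "M18BP1-like evidence", not as an M18BP1 identification.
CUPIN_ONLY / NONE
    Cupin without motif evidence / neither.

"Upstream" means the motif interval lies entirely before the cupin start
(N-terminal of the domain).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from . import sequence_io
from .alignment import (
    LocalAlignment,
    ScoringScheme,
    SignificanceThresholds,
    blosum62_scheme,
    smith_waterman,
)
from .motifs import DegenerateMotif, MotifHit, load_fixture_motifs, scan
from .sequence_io import ProteinRecord

logger = logging.getLogger(__name__)

CANONICAL_CENPC = "CANONICAL_CENPC"
PUTATIVE_FISH_CENPC = "PUTATIVE_FISH_CENPC"
MOTIF_ONLY = "MOTIF_ONLY"
CUPIN_ONLY = "CUPIN_ONLY"
NONE = "NONE"
ARCH_CLASSES = (CANONICAL_CENPC, PUTATIVE_FISH_CENPC, MOTIF_ONLY,
                CUPIN_ONLY, NONE)


class ClassificationError(ValueError):
    pass


@dataclass(frozen=True)
class DomainHit:
    """A localized domain interval on the query, with alignment evidence."""

    reference_id: str
    start: int  # 0-based half-open on the query
    end: int
    score: int
    identity_fraction: float

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ClassificationError(
                f"invalid domain interval [{self.start}, {self.end})")


@dataclass(frozen=True)
class ClassifierConfig:
    canonical_gap_max: int = 100
    canonical_motif_id: str = "cenpc-motif-identities"
    fish_motif_id: str = "central-region-core"
    degraded_max_mismatches: int = 2
    thresholds: SignificanceThresholds = field(
        default_factory=SignificanceThresholds)

    def __post_init__(self) -> None:
        if self.canonical_gap_max <= 0:
            raise ClassificationError("canonical_gap_max must be positive")
        if self.degraded_max_mismatches < 0:
            raise ClassificationError("degraded_max_mismatches must be ≥ 0")


@dataclass(frozen=True)
class ArchitectureCall:
    sequence_id: str
    arch_class: str
    cupin: DomainHit | None = None
    motif_hits: tuple[MotifHit, ...] = ()
    motif_to_cupin_gap: int | None = None
    conserved_region_count: int = 0
    degraded_positions: tuple[tuple[MotifHit, tuple[int, ...]], ...] = ()

    def best_motif_hit(self) -> MotifHit | None:
        """The cupin-proximal hit if a cupin exists, else the best-matching.

        Proximal = largest end coordinate among hits upstream of the cupin;
        without a cupin, fewest mismatches then leftmost.
        """
        if not self.motif_hits:
            return None
        if self.cupin is not None:
            upstream = [h for h in self.motif_hits if h.end <= self.cupin.start]
            if upstream:
                return max(upstream, key=lambda h: h.end)
        return min(self.motif_hits, key=lambda h: (h.mismatches, h.offset))


def validate_call(call: ArchitectureCall) -> None:
    """Raise unless the evidence fields are consistent with the class."""
    if call.arch_class not in ARCH_CLASSES:
        raise ClassificationError(f"unknown class {call.arch_class!r}")
    if call.motif_to_cupin_gap is not None and call.motif_to_cupin_gap < 0:
        raise ClassificationError("negative motif-to-cupin gap")
    has_cupin = call.cupin is not None
    has_motif = bool(call.motif_hits)
    expect = {
        CANONICAL_CENPC: (True, True),
        PUTATIVE_FISH_CENPC: (True, True),
        MOTIF_ONLY: (False, True),
        CUPIN_ONLY: (True, False),
        NONE: (False, False),
    }[call.arch_class]
    if (has_cupin, has_motif) != expect:
        raise ClassificationError(
            f"{call.sequence_id}: class {call.arch_class} inconsistent with "
            f"evidence (cupin={has_cupin}, motif={has_motif})")
    if call.arch_class in (CANONICAL_CENPC, PUTATIVE_FISH_CENPC):
        if call.motif_to_cupin_gap is None:
            raise ClassificationError(
                f"{call.sequence_id}: {call.arch_class} requires a gap")
        for hit in call.motif_hits:
            if hit.end > call.cupin.start:
                raise ClassificationError(
                    f"{call.sequence_id}: motif hit at {hit.offset} not "
                    "upstream of cupin")
    for hit, positions in call.degraded_positions:
        if hit.violated_positions != positions:
            raise ClassificationError(
                f"{call.sequence_id}: degraded-position record inconsistent")


def locate_cupin(seq: ProteinRecord, references: Sequence[ProteinRecord],
                 scheme: ScoringScheme | None = None,
                 thresholds: SignificanceThresholds | None = None,
                 ) -> DomainHit | None:
    """Best reference cupin alignment passing the significance thresholds.

    Ties on score are broken by higher identity, then lexicographic
    reference id, so the result is deterministic.
    """
    if not references:
        raise ClassificationError("empty cupin reference set")
    scheme = scheme or blosum62_scheme()
    thresholds = thresholds or SignificanceThresholds()
    best: tuple[int, float, str, LocalAlignment] | None = None
    for ref in references:
        aln = smith_waterman(seq, ref, scheme)
        if not thresholds.accepts(aln):
            continue
        key = (aln.score, aln.identity_fraction, ref.id)
        if best is None or (key[0], key[1], _neg_lex(key[2])) > (
                best[0], best[1], _neg_lex(best[2])):
            best = (aln.score, aln.identity_fraction, ref.id, aln)
    if best is None:
        return None
    score, identity, ref_id, aln = best
    return DomainHit(reference_id=ref_id, start=aln.query_interval[0],
                     end=aln.query_interval[1], score=score,
                     identity_fraction=identity)


class _neg_lex(str):
    """Inverts lexicographic order so earlier ids win inside a max()."""

    def __lt__(self, other):  # type: ignore[override]
        return str.__gt__(self, other)

    def __gt__(self, other):  # type: ignore[override]
        return str.__lt__(self, other)


def greedy_nonoverlapping(hits: Sequence[MotifHit]) -> list[MotifHit]:
    """Left-to-right greedy selection of non-overlapping hits."""
    chosen: list[MotifHit] = []
    last_end = -1
    for hit in sorted(hits, key=lambda h: h.offset):
        if hit.offset >= last_end:
            chosen.append(hit)
            last_end = hit.end
    return chosen


def classify(seq: ProteinRecord,
             cfg: ClassifierConfig | None = None,
             motifs: dict[str, DegenerateMotif] | None = None,
             references: Sequence[ProteinRecord] = (),
             scheme: ScoringScheme | None = None) -> ArchitectureCall:
    """Apply the architecture decision rules, in order, to one protein."""
    cfg = cfg or ClassifierConfig()
    motifs = motifs or load_fixture_motifs()
    scheme = scheme or blosum62_scheme()
    canonical = motifs[cfg.canonical_motif_id]
    fish = motifs[cfg.fish_motif_id]

    cupin = locate_cupin(seq, references, scheme, cfg.thresholds) \
        if references else None

    if cupin is not None:
        # rule 1: canonical motif (exact) ending within the gap window
        exact = scan(canonical, seq, max_mismatches=0)
        qualifying = [h for h in exact
                      if h.end <= cupin.start
                      and cupin.start - h.end <= cfg.canonical_gap_max]
        fish_up = [h for h in scan(fish, seq, cfg.degraded_max_mismatches)
                   if h.end <= cupin.start]
        # Conserved regions are counted from exact hits only: whether a
        # fully degraded region (the shark case) should count is left to
        # the report, where its violated positions are listed instead.
        regions = greedy_nonoverlapping(
            [h for h in fish_up if h.mismatches == 0])
        if qualifying:
            proximal = max(qualifying, key=lambda h: h.end)
            return ArchitectureCall(
                sequence_id=seq.id, arch_class=CANONICAL_CENPC, cupin=cupin,
                motif_hits=tuple(qualifying),
                motif_to_cupin_gap=cupin.start - proximal.end,
                conserved_region_count=len(regions),
                degraded_positions=_degraded(fish_up),
            )
        # rule 2: degraded central-region-core hits upstream of the cupin
        if fish_up:
            # the spacing is measured to the cupin-proximal exact hit when
            # one exists; degraded hits set it only when nothing is exact
            exact_up = [h for h in fish_up if h.mismatches == 0]
            proximal = max(exact_up or fish_up, key=lambda h: h.end)
            return ArchitectureCall(
                sequence_id=seq.id, arch_class=PUTATIVE_FISH_CENPC,
                cupin=cupin, motif_hits=tuple(fish_up),
                motif_to_cupin_gap=cupin.start - proximal.end,
                conserved_region_count=len(regions),
                degraded_positions=_degraded(fish_up),
            )
        return ArchitectureCall(sequence_id=seq.id, arch_class=CUPIN_ONLY,
                                cupin=cupin)
    # rule 3: no cupin; tolerant canonical-motif evidence (M18BP1-like)
    tolerant = scan(canonical, seq, cfg.degraded_max_mismatches)
    if tolerant:
        return ArchitectureCall(
            sequence_id=seq.id, arch_class=MOTIF_ONLY,
            motif_hits=tuple(tolerant),
            degraded_positions=_degraded(tolerant),
        )
    return ArchitectureCall(sequence_id=seq.id, arch_class=NONE)


def _degraded(hits: Sequence[MotifHit]
              ) -> tuple[tuple[MotifHit, tuple[int, ...]], ...]:
    return tuple((h, h.violated_positions) for h in hits if h.mismatches > 0)


def spacing_ratio(call_a: ArchitectureCall, call_b: ArchitectureCall) -> float:
    """Motif-to-cupin distance of ``a`` relative to ``b``.

    Both calls must carry a cupin and a cupin-proximal motif hit; raises on
    missing evidence or a zero denominator.  A value near 2 reproduces the
    observation that the spacing in putative teleost CENP-C is about twice
    that of other vertebrates.
    """
    for name, call in (("a", call_a), ("b", call_b)):
        if call.cupin is None or not call.motif_hits \
                or call.motif_to_cupin_gap is None:
            raise ClassificationError(
                f"call {name} ({call.sequence_id}) lacks cupin+motif evidence")
    if call_b.motif_to_cupin_gap == 0:
        raise ClassificationError("denominator gap is zero")
    return call_a.motif_to_cupin_gap / call_b.motif_to_cupin_gap


def scan_proteome(path: str | Path,
                  cfg: ClassifierConfig | None = None,
                  motifs: dict[str, DegenerateMotif] | None = None,
                  references: Sequence[ProteinRecord] = (),
                  scheme: ScoringScheme | None = None,
                  ) -> list[ArchitectureCall]:
    """Classify every record of a FASTA proteome, preserving input order."""
    try:
        records = sequence_io.read_fasta(path)
    except OSError as exc:
        raise ClassificationError(f"cannot read proteome {path}: {exc}")
    calls = [classify(rec, cfg, motifs, references, scheme)
             for rec in records]
    counts = Counter(c.arch_class for c in calls)
    logger.info("classified %d proteins: %s", len(calls),
                ", ".join(f"{k}={counts[k]}" for k in ARCH_CLASSES))
    return calls
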