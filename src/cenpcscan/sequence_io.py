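"""Protein sequence and alignment I/O with alphabet validation.

All coordinates are 0-based half-open inside the package; conversion to the
1-based inclusive convention used in human-facing reports happens only at
serialization time (:func:`to_report_coords` / :func:`from_report_coords`).

The residue alphabet is the 20 standard amino acids plus the IUPAC ambiguity
codes X (any), B (Asx = D/N), Z (Glx = E/Q) and J (I/L), because degenerate
consensus strings such as the 23-residue vertebrate CENP-C motif are
themselves legitimate sequence inputs.  A stop ``*`` is tolerated only as the
final character of a record.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AMBIGUITY_CODES = "XBZJ"
SEQUENCE_ALPHABET = frozenset(AMINO_ACIDS + AMBIGUITY_CODES)
GAP = "-"


class SequenceFormatError(ValueError):
    """Raised when a sequence or alignment file violates the format contract."""


@dataclass(frozen=True)
class ProteinRecord:
    """A validated protein sequence.

    ``residues`` is uppercase, over the 20 amino acids plus X/B/Z/J, with an
    optional single terminal ``*``.  Gap characters are never allowed.
    """

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise SequenceFormatError("protein record has an empty id")
        if not self.residues:
            raise SequenceFormatError(f"record {self.id!r}: empty sequence")
        validate_residues(self.residues, record_id=self.id)

    def __len__(self) -> int:
        return len(self.residues)


def validate_residues(residues: str, record_id: str = "<anonymous>") -> None:
    """Check a residue string against the extended amino-acid alphabet.

    Raises :class:`SequenceFormatError` naming the record and the 0-based
    offset of the first illegal character.  ``*`` is permitted only as the
    final character.
    """
    for i, ch in enumerate(residues):
        if ch in SEQUENCE_ALPHABET:
            continue
        if ch == "*" and i == len(residues) - 1:
            continue
        raise SequenceFormatError(
            f"record {record_id!r}: illegal residue {ch!r} at offset {i}"
        )


@dataclass(frozen=True)
class MultipleAlignment:
    """A validated multiple protein alignment (≥ 2 rows, uniform length)."""

    rows: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise SequenceFormatError(
                f"alignment needs at least 2 rows, got {len(self.rows)}"
            )
        width = len(self.rows[0][1])
        if width < 1:
            raise SequenceFormatError("alignment has zero columns")
        for row_id, aligned in self.rows:
            if len(aligned) != width:
                raise SequenceFormatError(
                    f"alignment row {row_id!r} has length {len(aligned)}, "
                    f"expected {width}"
                )
            for i, ch in enumerate(aligned):
                if ch != GAP and ch not in SEQUENCE_ALPHABET:
                    raise SequenceFormatError(
                        f"alignment row {row_id!r}: illegal symbol {ch!r} "
                        f"at column {i}"
                    )

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0][1])

    def column(self, j: int) -> list[str]:
        return [aligned[j] for _, aligned in self.rows]


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a protein FASTA file into validated records (order preserved)."""
    records: list[ProteinRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise SequenceFormatError(f"{path}: FASTA record with empty header")
        residues = str(rec.seq).upper()
        # Biopython folds the id into the description; keep only the remainder.
        description = rec.description[len(rec.id):].strip()
        if GAP in residues:
            raise SequenceFormatError(
                f"record {rec.id!r}: gap character in unaligned sequence "
                f"(offset {residues.index(GAP)})"
            )
        records.append(ProteinRecord(id=rec.id, residues=residues,
                                     description=description))
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path,
                width: int = 60) -> None:
    seq_records = [
        SeqRecord(Seq(r.residues), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seq_records)


def read_alignment(path: str | Path) -> MultipleAlignment:
    """Read an aligned FASTA file; rows must be equal length, ≥ 2 of them."""
    rows: list[tuple[str, str]] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        rows.append((rec.id, str(rec.seq).upper()))
    if len(rows) < 2:
        raise SequenceFormatError(
            f"{path}: alignment requires at least 2 rows, found {len(rows)}"
        )
    width = len(rows[0][1])
    for row_id, aligned in rows:
        if len(aligned) != width:
            raise SequenceFormatError(
                f"{path}: row {row_id!r} has length {len(aligned)}, "
                f"expected {width} (ragged alignment)"
            )
    return MultipleAlignment(rows=tuple(rows))


def write_alignment(aln: MultipleAlignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for row_id, aligned in aln.rows:
            fh.write(f">{row_id}\n{aligned}\n")


# --- report coordinates -----------------------------------------------------

def to_report_coords(start: int, end: int) -> tuple[int, int]:
    """0-based half-open -> 1-based inclusive (the figure convention)."""
    if not 0 <= start <= end:
        raise ValueError(f"invalid interval [{start}, {end})")
    return start + 1, end


def from_report_coords(first: int, last: int) -> tuple[int, int]:
    """1-based inclusive -> 0-based half-open."""
    if not 1 <= first <= last + 1:
        raise ValueError(f"invalid 1-based interval [{first}, {last}]")
    return first - 1, last


# --- architecture report serialization -------------------------------------

REPORT_COLUMNS = (
    "sequence_id",
    "arch_class",
    "cupin_reference",
    "cupin_start",
    "cupin_end",
    "cupin_score",
    "cupin_identity",
    "motif_hit_count",
    "conserved_region_count",
    "motif_to_cupin_gap",
    "best_motif_id",
    "best_motif_start",
    "best_motif_end",
    "best_motif_mismatches",
    "degraded_positions",
)

_NA = "."


def _call_row(call) -> dict[str, str]:
    row = {c: _NA for c in REPORT_COLUMNS}
    row["sequence_id"] = call.sequence_id
    row["arch_class"] = call.arch_class
    row["motif_hit_count"] = str(len(call.motif_hits))
    row["conserved_region_count"] = str(call.conserved_region_count)
    if call.cupin is not None:
        first, last = to_report_coords(call.cupin.start, call.cupin.end)
        row["cupin_reference"] = call.cupin.reference_id
        row["cupin_start"] = str(first)
        row["cupin_end"] = str(last)
        row["cupin_score"] = str(call.cupin.score)
        row["cupin_identity"] = f"{call.cupin.identity_fraction:.4f}"
    if call.motif_to_cupin_gap is not None:
        row["motif_to_cupin_gap"] = str(call.motif_to_cupin_gap)
    best = call.best_motif_hit()
    if best is not None:
        first, last = to_report_coords(best.offset, best.end)
        row["best_motif_id"] = best.motif_id
        row["best_motif_start"] = str(first)
        row["best_motif_end"] = str(last)
        row["best_motif_mismatches"] = str(best.mismatches)
    if call.degraded_positions:
        # 1-based positions within each degraded hit, hit anchored by offset
        parts = []
        for hit, positions in call.degraded_positions:
            pos = ",".join(str(p + 1) for p in positions)
            parts.append(f"{hit.motif_id}@{hit.offset + 1}:{pos}")
        row["degraded_positions"] = ";".join(parts)
    return row


def write_tsv_report(calls: Sequence, path: str | Path) -> None:
    """Write architecture calls as TSV, one row per protein.

    Coordinates are 1-based inclusive in the report, matching the convention
    used for protein positions in published domain diagrams.
    """
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=REPORT_COLUMNS, delimiter="\t",
                                lineterminator="\n")
        writer.writeheader()
        for call in calls:
            writer.writerow(_call_row(call))


def read_tsv_report(path: str | Path) -> list[dict[str, str]]:
    """Parse a TSV report back into per-row dicts (round-trip checks)."""
    with open(path, newline="") as fh:
        return list(csv.DictReader(fh, delimiter="\t"))


def write_json_report(calls: Sequence, path: str | Path) -> None:
    """JSON form of the TSV report (same fields, typed where natural)."""
    payload = []
    for call in calls:
        row = _call_row(call)
        typed: dict = {}
        for key, value in row.items():
            if value == _NA:
                typed[key] = None
            elif key in {"cupin_start", "cupin_end", "cupin_score",
                         "motif_hit_count", "conserved_region_count",
                         "motif_to_cupin_gap", "best_motif_start",
                         "best_motif_end", "best_motif_mismatches"}:
                typed[key] = int(value)
            elif key == "cupin_identity":
                typed[key] = float(value)
            else:
                typed[key] = value
        payload.append(typed)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")
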