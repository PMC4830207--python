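"""Seeded synthetic proteomes with planted domains and motifs, plus truth.

The generator emulates the protein architectures reported across
vertebrates so that every pipeline stage is testable without downloads:

- ``CANONICAL_CENPC`` proteins carry a C-terminal cupin copy, an instance
  of the full CENP-C motif identity pattern ending 40–100 residues upstream
  of it, and a central-region consensus instance further upstream.
- ``PUTATIVE_FISH_CENPC`` proteins carry the cupin copy and two
  central-region-core (RxxxxPxxWW) instances; the cupin-proximal one sits
  80–200 residues upstream — about twice the canonical spacing — and the
  distal one 300–450 residues upstream.
- ``MOTIF_ONLY`` proteins (M18BP1-like) carry the identity pattern at a
  random position and no cupin.
- ``NONE`` proteins are pure background.
- ``CUPIN_ONLY`` is supported via explicit plant specs but is not part of
  the default mixture: no cupin-domain protein lacking the conserved
  regions was observed in the screen this generator emulates.

Motif instances are realized by sampling uniformly within each position's
residue set; substitutions, when requested, always change the residue, so
the truth table's substitution counts are exact.  Background residues are
i.i.d. from a configurable frequency table (uniform by default, which is
unrealistic but analytically convenient; a Swiss-Prot-like preset ships
with the package).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

from . import architecture as arch
from .motifs import DegenerateMotif, load_fixture_motifs, scan
from .sequence_io import AMINO_ACIDS, MultipleAlignment, ProteinRecord

UNIFORM_BACKGROUND: dict[str, float] = {aa: 1 / 20 for aa in AMINO_ACIDS}

_REFERENCE_SEED = 271828  # fixed: the reference is a study condition
_REFERENCE_LENGTH = 110


class GenerationError(ValueError):
    pass


def load_background_preset(name: str = "uniform") -> dict[str, float]:
    """'uniform' or 'swissprot' (average Swiss-Prot composition)."""
    if name == "uniform":
        return dict(UNIFORM_BACKGROUND)
    if name == "swissprot":
        raw = resources.files("cenpcscan.data").joinpath(
            "background_freqs.json").read_text()
        freqs = json.loads(raw)["frequencies"]
        total = sum(freqs.values())
        return {aa: freqs[aa] / total for aa in AMINO_ACIDS}
    raise GenerationError(f"unknown background preset {name!r}")


def synthetic_cupin_reference(length: int = _REFERENCE_LENGTH) -> ProteinRecord:
    """A synthetic stand-in for a reference cupin-domain sequence.

    Deterministic (fixed internal seed): the reference defines the study
    conditions and must not drift with the user's simulation seed.  It is a
    random sequence, not a real cupin; what matters for the pipeline is
    that planted copies of it are recoverable by local alignment.
    """
    rng = np.random.default_rng(_REFERENCE_SEED)
    residues = "".join(rng.choice(list(AMINO_ACIDS), size=length))
    return ProteinRecord(id="synthetic-cupin-ref", residues=residues,
                         description="synthetic cupin-domain stand-in")


@dataclass(frozen=True)
class PlantSpec:
    """One element to plant: a cupin copy or a motif instance."""

    element: str  # "cupin_copy" | "motif_instance"
    source_id: str  # reference id or motif fixture id
    offset: int | str = "random"  # 0-based, or "random"
    substitution_rate: float = 0.0
    target_residues: str | None = None  # restrict substitutions, e.g. "W"

    def __post_init__(self) -> None:
        if self.element not in ("cupin_copy", "motif_instance"):
            raise GenerationError(f"unknown element {self.element!r}")
        if not 0.0 <= self.substitution_rate < 1.0001:
            raise GenerationError("substitution_rate must be in [0, 1]")
        if self.offset != "random" and (not isinstance(self.offset, int)
                                        or self.offset < 0):
            raise GenerationError(f"bad offset {self.offset!r}")


@dataclass(frozen=True)
class PlantedElement:
    element: str
    source_id: str
    start: int  # 0-based half-open, as realized
    end: int
    n_substitutions: int


@dataclass(frozen=True)
class ProteinTruth:
    protein_id: str
    intended_class: str
    elements: tuple[PlantedElement, ...]


@dataclass(frozen=True)
class SyntheticTruth:
    proteins: tuple[ProteinTruth, ...]

    def by_id(self) -> dict[str, ProteinTruth]:
        return {p.protein_id: p for p in self.proteins}

    def to_tsv(self, path: str | Path) -> None:
        """Truth table; coordinates 1-based inclusive like the reports."""
        with open(path, "w") as fh:
            fh.write("protein_id\tclass\telement\tsource_id\tstart\tend"
                     "\tsubstitutions\n")
            for prot in self.proteins:
                if not prot.elements:
                    fh.write(f"{prot.protein_id}\t{prot.intended_class}"
                             "\t.\t.\t.\t.\t.\n")
                for el in prot.elements:
                    fh.write(f"{prot.protein_id}\t{prot.intended_class}\t"
                             f"{el.element}\t{el.source_id}\t{el.start + 1}\t"
                             f"{el.end}\t{el.n_substitutions}\n")

    def to_json(self, path: str | Path) -> None:
        payload = [
            {
                "protein_id": p.protein_id,
                "class": p.intended_class,
                "elements": [
                    {"element": e.element, "source_id": e.source_id,
                     "start": e.start, "end": e.end,
                     "n_substitutions": e.n_substitutions}
                    for e in p.elements
                ],
            }
            for p in self.proteins
        ]
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
            fh.write("\n")


DEFAULT_CLASS_MIXTURE: dict[str, float] = {
    arch.CANONICAL_CENPC: 0.30,
    arch.PUTATIVE_FISH_CENPC: 0.30,
    arch.MOTIF_ONLY: 0.20,
    arch.NONE: 0.20,
}

#: Spacing conditions (residues between motif end and cupin start).
CANONICAL_GAP_RANGE = (40, 100)
FISH_PROXIMAL_GAP_RANGE = (80, 200)   # about twice the canonical spacing
FISH_DISTAL_GAP_RANGE = (300, 450)
CUPIN_C_TERMINAL_MARGIN = 30


def _realize_motif(motif: DegenerateMotif, rng: np.random.Generator) -> str:
    return "".join(rng.choice(sorted(pos)) for pos in motif.positions)


def _substitute(residues: str, rate: float, target: str | None,
                rng: np.random.Generator) -> tuple[str, int]:
    """Apply ``round(rate * n_eligible)`` substitutions; never a no-op swap."""
    if rate <= 0:
        return residues, 0
    eligible = [i for i, r in enumerate(residues)
                if target is None or r in target]
    k = int(round(rate * len(eligible)))
    if k == 0:
        return residues, 0
    chosen = rng.choice(len(eligible), size=k, replace=False)
    out = list(residues)
    for idx in sorted(int(c) for c in chosen):
        i = eligible[idx]
        alternatives = [aa for aa in AMINO_ACIDS if aa != out[i]]
        out[i] = str(rng.choice(alternatives))
    return "".join(out), k


def _default_plants(cls: str, length: int, rng: np.random.Generator,
                    ref_len: int, motif_rate: float,
                    motif_targets: str | None,
                    domain_rate: float) -> list[tuple[PlantSpec, int]]:
    """Resolve the built-in architecture template for one protein."""
    cupin_start = length - CUPIN_C_TERMINAL_MARGIN - ref_len
    plants: list[tuple[PlantSpec, int]] = []

    def motif_at(source_id: str, gap_range: tuple[int, int],
                 motif_len: int) -> tuple[PlantSpec, int]:
        gap = int(rng.integers(gap_range[0], gap_range[1] + 1))
        spec = PlantSpec("motif_instance", source_id,
                         substitution_rate=motif_rate,
                         target_residues=motif_targets)
        return spec, cupin_start - gap - motif_len

    if cls in (arch.CANONICAL_CENPC, arch.PUTATIVE_FISH_CENPC,
               arch.CUPIN_ONLY):
        plants.append((PlantSpec("cupin_copy", "synthetic-cupin-ref",
                                 substitution_rate=domain_rate), cupin_start))
    if cls == arch.CANONICAL_CENPC:
        plants.append(motif_at("cenpc-motif-identities",
                               CANONICAL_GAP_RANGE, 20))
        plants.append(motif_at("central-region-consensus", (250, 400), 10))
    elif cls == arch.PUTATIVE_FISH_CENPC:
        plants.append(motif_at("central-region-core",
                               FISH_PROXIMAL_GAP_RANGE, 10))
        plants.append(motif_at("central-region-core",
                               FISH_DISTAL_GAP_RANGE, 10))
    elif cls == arch.MOTIF_ONLY:
        offset = int(rng.integers(0, length - 20 + 1))
        plants.append((PlantSpec("motif_instance", "cenpc-motif-identities",
                                 substitution_rate=motif_rate,
                                 target_residues=motif_targets), offset))
    elif cls not in (arch.CUPIN_ONLY, arch.NONE):
        raise GenerationError(f"unknown architecture class {cls!r}")
    return plants


def _resolve_random_offsets(plants: list[tuple[PlantSpec, int | str]],
                            lengths: list[int], total: int,
                            rng: np.random.Generator
                            ) -> list[tuple[PlantSpec, int]]:
    resolved: list[tuple[PlantSpec, int]] = []
    taken: list[tuple[int, int]] = []
    for (spec, offset), span in zip(plants, lengths):
        if span > total:
            raise GenerationError(
                f"plant {spec.source_id!r} span {span} exceeds protein "
                f"length {total}")
        if offset == "random":
            for _ in range(1000):
                cand = int(rng.integers(0, total - span + 1))
                if all(cand + span <= s or cand >= e for s, e in taken):
                    offset = cand
                    break
            else:
                raise GenerationError("could not place plant without overlap")
        start = int(offset)
        if start + span > total:
            raise GenerationError(
                f"plant {spec.source_id!r} at {start} overruns length {total}")
        if any(start < e and start + span > s for s, e in taken):
            raise GenerationError(
                f"plant {spec.source_id!r} at {start} overlaps another plant")
        taken.append((start, start + span))
        resolved.append((spec, start))
    return resolved


def generate_proteome(
    n: int,
    length_range: tuple[int, int] = (650, 900),
    background: dict[str, float] | None = None,
    class_mixture: dict[str, float] | None = None,
    seed: int = 0,
    class_plants: dict[str, list[PlantSpec]] | None = None,
    motif_substitution_rate: float = 0.0,
    motif_target_residues: str | None = None,
    domain_substitution_rate: float = 0.0,
    reference: ProteinRecord | None = None,
) -> tuple[list[ProteinRecord], SyntheticTruth]:
    """Generate ``n`` proteins with planted architectures plus truth.

    Deterministic for a fixed seed.  ``class_plants`` overrides the built-in
    per-class templates with explicit :class:`PlantSpec` lists (offsets may
    be "random"); otherwise the default templates encode the spacing
    conditions in the module docstring, with the substitution parameters
    applied to motif instances (``motif_target_residues`` restricts the
    mutated positions, e.g. ``"W"`` to knock out tryptophans) and
    ``domain_substitution_rate`` to cupin copies.
    """
    if n < 0:
        raise GenerationError("n must be ≥ 0")
    background = background or UNIFORM_BACKGROUND
    mixture = class_mixture or DEFAULT_CLASS_MIXTURE
    if abs(sum(mixture.values()) - 1.0) > 1e-9:
        raise GenerationError("class mixture fractions must sum to 1")
    motifs = load_fixture_motifs()
    reference = reference or synthetic_cupin_reference()
    rng = np.random.default_rng(seed)
    alphabet = list(AMINO_ACIDS)
    probs = np.array([background[aa] for aa in AMINO_ACIDS], dtype=float)
    probs = probs / probs.sum()
    classes = sorted(mixture)
    class_probs = np.array([mixture[c] for c in classes])

    records: list[ProteinRecord] = []
    truths: list[ProteinTruth] = []
    width = max(3, len(str(max(n, 1))))
    for idx in range(n):
        cls = str(rng.choice(classes, p=class_probs))
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        if class_plants is not None:
            specs = [(s, s.offset) for s in class_plants.get(cls, [])]
            spans = [len(reference) if s.element == "cupin_copy"
                     else len(motifs[s.source_id]) for s, _ in specs]
            resolved = _resolve_random_offsets(specs, spans, length, rng)
        else:
            resolved = _default_plants(cls, length, rng, len(reference),
                                       motif_substitution_rate,
                                       motif_target_residues,
                                       domain_substitution_rate)
        residues = list("".join(rng.choice(alphabet, size=length, p=probs)))
        elements: list[PlantedElement] = []
        for spec, start in sorted(resolved, key=lambda t: t[1]):
            if spec.element == "cupin_copy":
                realized = reference.residues
            else:
                realized = _realize_motif(motifs[spec.source_id], rng)
            realized, n_subs = _substitute(realized, spec.substitution_rate,
                                           spec.target_residues, rng)
            end = start + len(realized)
            if start < 0 or end > length:
                raise GenerationError(
                    f"protein {idx}: plant {spec.source_id!r} interval "
                    f"[{start}, {end}) outside length {length}")
            residues[start:end] = realized
            elements.append(PlantedElement(
                element=spec.element, source_id=spec.source_id,
                start=start, end=end, n_substitutions=n_subs))
        pid = f"synth{idx + 1:0{width}d}"
        records.append(ProteinRecord(
            id=pid, residues="".join(residues),
            description=f"synthetic {cls.lower()}"))
        truths.append(ProteinTruth(protein_id=pid, intended_class=cls,
                                   elements=tuple(elements)))
    return records, SyntheticTruth(proteins=tuple(truths))


# --- motif specificity ------------------------------------------------------

@dataclass(frozen=True)
class FalsePositiveEstimate:
    """Monte-Carlo and closed-form specificity of an identity pattern."""

    motif_id: str
    trials: int
    sequence_length: int
    n_windows: int
    analytic_window_prob: float  # per-window hit probability
    expected_hits_per_sequence: float  # n_windows * analytic_window_prob
    fraction_with_hit: float  # MC fraction of sequences with >= 1 exact hit
    mean_hits_per_sequence: float
    sd_hits_per_sequence: float

    @property
    def se_mean_hits(self) -> float:
        return self.sd_hits_per_sequence / math.sqrt(self.trials)

    @property
    def analytic_se_mean_hits(self) -> float:
        """Binomial-approximation SE of the mean hit count; usable even
        when the Monte-Carlo sample variance is zero (very rare motifs)."""
        p = self.analytic_window_prob
        return math.sqrt(self.n_windows * p * (1 - p) / self.trials)


def analytic_window_probability(motif: DegenerateMotif,
                                background: dict[str, float] | None = None
                                ) -> float:
    """P(one window matches exactly) for i.i.d. background residues.

    Under the uniform background this is the product over positions of
    |set_i| / 20; wildcards contribute a factor of 1.
    """
    background = background or UNIFORM_BACKGROUND
    prob = 1.0
    for pos in motif.positions:
        prob *= sum(background[aa] for aa in pos)
    return prob


def estimate_false_positive_rate(motif: DegenerateMotif,
                                 background: dict[str, float] | None = None,
                                 trials: int = 2000,
                                 sequence_length: int = 200,
                                 seed: int = 0) -> FalsePositiveEstimate:
    """Monte-Carlo exact-hit statistics of a motif on random sequences."""
    if trials < 1:
        raise GenerationError("trials must be ≥ 1")
    if sequence_length < len(motif):
        raise GenerationError("sequence_length shorter than the motif")
    background = background or UNIFORM_BACKGROUND
    rng = np.random.default_rng(seed)
    alphabet = list(AMINO_ACIDS)
    probs = np.array([background[aa] for aa in AMINO_ACIDS], dtype=float)
    probs = probs / probs.sum()
    counts = np.empty(trials, dtype=np.int64)
    for t in range(trials):
        seq = "".join(rng.choice(alphabet, size=sequence_length, p=probs))
        counts[t] = len(scan(motif, seq, max_mismatches=0))
    n_windows = sequence_length - len(motif) + 1
    p = analytic_window_probability(motif, background)
    return FalsePositiveEstimate(
        motif_id=motif.id,
        trials=trials,
        sequence_length=sequence_length,
        n_windows=n_windows,
        analytic_window_prob=p,
        expected_hits_per_sequence=n_windows * p,
        fraction_with_hit=float(np.mean(counts >= 1)),
        mean_hits_per_sequence=float(counts.mean()),
        sd_hits_per_sequence=float(counts.std(ddof=1)) if trials > 1 else 0.0,
    )


def alignment_from_motif(motif: DegenerateMotif, n_rows: int = 25,
                         seed: int = 0) -> MultipleAlignment:
    """An alignment whose relaxed consensus reproduces ``motif``.

    Singleton columns are invariant; two-residue ambiguity columns are
    split as evenly as an odd row count allows (e.g. 13 Asp / 12 Asn);
    wildcard columns cycle through five chemically distinct residues.
    Deriving a consensus with ``min_fraction`` ≈ 0.8 recovers the motif.
    """
    if n_rows < 2:
        raise GenerationError("need at least 2 rows")
    rng = np.random.default_rng(seed)
    columns: list[list[str]] = []
    wildcard_pool = "AGKST"
    for pos in motif.positions:
        if pos == frozenset(AMINO_ACIDS):
            members = list(wildcard_pool)
        else:
            members = sorted(pos)
        base = [members[i % len(members)] for i in range(n_rows)]
        columns.append([base[i] for i in rng.permutation(n_rows)])
    rows = tuple(
        (f"taxon{r + 1:02d}", "".join(columns[c][r]
                                      for c in range(len(motif))))
        for r in range(n_rows)
    )
    return MultipleAlignment(rows=rows)
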