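# Methods

## Degenerate motif model

A motif is an ordered list of residue sets over the 20 amino acids.
Pattern strings map `x`/`X` to the full set, `B` to {D,N}, `Z` to {E,Q},
`J` to {I,L}, and any plain letter to a singleton. Sequences may
themselves contain X/B/Z/J (a degenerate consensus is a legitimate query
*and* a legitimate subject), so a position is *satisfied* when the motif
set and the residue's own ambiguity set intersect. This intersection rule
is the only symmetric choice once both sides may be degenerate. Wildcard
positions can never be violated; `mismatches` counts violated constrained
positions only, and the per-hit record (`|`/`.`/`x`) is the machine form
of highlighting matched identities in an alignment figure.

Scanning slides every window and reports all placements with at most
`max_mismatches` violations, overlapping hits included, sorted by offset.
The scanner is checked against a naive all-window oracle on ≥ 1000 seeded
random cases, and hits are provably monotone in the mismatch budget.

### Packaged patterns

Five identity patterns ship with the package: the 23-residue vertebrate
CENP-C motif consensus `NVRRTKRXRLKPLEYWRGERVBY`, the identity pattern
within it `RxxRxxxxPLxYWxGERxxY`, its functional core `RxxxxPxxYW`, the
central-region consensus `RxSxxPSxWW`, and the central-region core
`RxxxxPxxWW`. Their mutual consistency (core at offset 6 of the 23-mer,
identity pattern at offset 3, central core satisfied by the central
consensus at offset 0) is asserted in the test suite.

## Consensus derivation

Per column of a validated alignment: columns whose gap fraction exceeds
`max_gap_fraction` (default 0 — the vertebrate motif is contiguous) are
dropped; among the remaining residues, those with frequency at least
`min_fraction` times the **modal** frequency are pooled (their ambiguity
sets expanded), and the pooled set becomes the column's motif position: a
singleton stays itself, a subset of {D,N}/{E,Q}/{I,L} becomes B/Z/J, and
anything else becomes a wildcard. The relative-majority rule was chosen
because no derivation rule is standard for this kind of consensus: with
the strict default (`min_fraction = 1.0`) ties keep every tied residue
rather than picking one arbitrarily, and relaxing `min_fraction`
reproduces majority-style behaviour. The 25-row demonstration alignment
is derived at `min_fraction = 0.8`: with an odd row count a two-residue
Asx column (13 Asp / 12 Asn) can never tie exactly, and 0.8 retains both
residues while still rejecting sporadic variants.

## Local alignment

Smith–Waterman with affine gaps (Gotoh three-state recurrence), authored
here so that the traceback contract is explicit: ties break
diagonal > up (gap in target) > left (gap in query), and among
equal-scoring end cells the first in row-major order wins — outputs are
byte-stable. The default scheme is BLOSUM62 with gap open 11 / extend 1
(standard protein-BLAST defaults); a gap of length *L* costs
`11 + L·1`. Ambiguity codes score as the truncated mean of their member
pairs (X averages all 20), keeping the extended matrix symmetric.
Scores are validated two ways in the tests: exhaustive substring
enumeration with an independently written memoized global aligner on
short sequences, and score agreement with Biopython's `PairwiseAligner`
in local mode on longer random pairs. The inner fill loop is JIT-compiled
with numba when available; the pure-Python fill is the reference
behaviour and is what the tests exercise when numba is absent.

Significance is intentionally not an E-value model: database-size
dependent statistics are out of scope, so a hit must clear a raw-score
density (default ≥ 2.0 per aligned column) and a minimum aligned length
(default 40 columns). Both gates are configurable and monotone.

## Architecture classification

Decision rules, applied in order, given cupin references and the pattern
fixtures:

1. cupin present **and** an exact hit of the canonical identity pattern
   ending 0–100 residues upstream of the cupin start →
   `CANONICAL_CENPC`. The 100-residue window is the documented canonical
   spacing and is configurable (`canonical_gap_max`).
2. cupin present **and** ≥ 1 central-region-core hit with at most
   `degraded_max_mismatches` (default 2) violations upstream →
   `PUTATIVE_FISH_CENPC`. Two is exactly the "both tryptophans lost"
   case observed in the shark candidate.
3. no cupin **and** a canonical-pattern hit with ≤ 2 violations →
   `MOTIF_ONLY`, reported as M18BP1-like *evidence*, not as an M18BP1
   identification — ortholog assignment needs more than motif evidence.
4. otherwise `CUPIN_ONLY` (cupin, no motifs) or `NONE`.

"Upstream" means the motif interval ends at or before the cupin start
(all known placements are N-terminal of the domain).
`conserved_region_count` counts non-overlapping (greedy left-to-right)
**exact** core hits upstream; whether a fully degraded region should
count as a conserved region is genuinely open, so degraded hits are
instead recorded with their violated positions (`degraded_positions`)
and the interpretation is left to the reader of the report. The
motif-to-cupin spacing is measured to the cupin-proximal exact hit when
one exists, falling back to the proximal degraded hit; `spacing_ratio`
divides two such gaps (fish vs canonical ≈ 2).

Coordinates are 0-based half-open internally and 1-based inclusive in
TSV/JSON reports, matching the convention of protein domain diagrams.

## Synthetic data

The generator's defaults encode the study conditions: protein lengths
uniform on 650–900 residues; background residues i.i.d. uniform over the
20 amino acids (unrealistic but analytically convenient — a Swiss-Prot
composition preset is included); the cupin copy ends 30 residues from the
C-terminus; canonical identity-pattern instances end 40–100 residues
upstream of the cupin with a central-region instance 250–400 upstream;
fish-type proteins carry two central-region-core instances at 80–200
(proximal — about twice the canonical spacing) and 300–450 residues
upstream; motif-only proteins place the identity pattern uniformly. The
default class mixture is 30% canonical, 30% fish-type, 20% motif-only,
20% background: the architectures actually reported across vertebrates,
plus noise. A cupin-only class is fully supported through explicit plant
specs but is not part of the default mixture, because the screen this
emulates found no cupin-domain protein lacking the conserved regions —
and see the limitation below for why single-sequence degraded hits could
not separate such a class anyway.

Motif instances are realized by sampling uniformly within each position's
set. Substitutions are applied to a fixed count (`round(rate ×
eligible positions)`), optionally restricted to chosen residues (e.g.
`"W"` to knock out tryptophans), and always change the residue, so truth
substitution counts are exact. Planted intervals never overlap. A fixed
internal seed generates the synthetic cupin reference — it is a random
sequence standing in for a real domain, which is sufficient because the
pipeline only requires that planted (possibly mutated) copies of it be
recoverable by local alignment; it is *not* a biological cupin.

`estimate_false_positive_rate` gives both a Monte-Carlo and a closed-form
view of pattern specificity: for i.i.d. background the per-window
exact-hit probability is the product over positions of the background
mass of each residue set — `(1/20)^4 = 6.25 × 10⁻⁶` for the four-anchor
core patterns under uniform background.

## What passing tests do and do not show

The synthetic proteome has i.i.d. background, no indels within planted
elements, no compositional bias, and no homologous-but-divergent cupins
other than point-mutated copies. Perfect recovery there demonstrates the
pipeline's internal correctness — planted truth in, identical calls out —
not performance on real proteomes, where gene-model errors, low-complexity
regions and distant homology dominate the error budget.

## Known limitations

- A degraded (k ≤ 2) hit of a four-anchor pattern occurs on about 1.4% of
  random uniform windows (`analysis/05_motif_specificity.py` measures
  0.0143), so on a realistic-length protein a degraded hit upstream of a
  cupin is expected by chance alone. Degraded evidence is therefore only
  meaningful in combination with the cupin domain, and a protein whose
  only upstream "motifs" are degraded should be read with the recorded
  violated positions in hand. Cross-species conservation, not
  single-sequence scanning, is what makes degraded regions convincing.
- Significance thresholds for cupin homology are score-density gates, not
  E-values; they are calibrated for the synthetic conditions and exposed
  as configuration, not tuned to any database.
- No indel process in the generator and no profile/PSSM scoring in the
  scanner: the evidence model is identity patterns, by design.
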