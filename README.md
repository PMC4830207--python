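# cenpcscan

Motif- and domain-architecture screening for CENP-C ortholog candidates.

## The problem

CENP-C is a foundational inner-kinetochore protein: it binds CENP-A
nucleosomes and nucleates kinetochore assembly, and it is expected in
essentially every eukaryote. Yet annotated CENP-C is absent from teleost
fish sequence databases, and searches with the conserved vertebrate
"CENP-C motif" come back empty for ray-finned fish. Candidate orthologs
can still be recognized from weaker, combined evidence: homology of the
C-terminal **cupin** (dimerization) domain plus short nucleosome-binding
identity patterns placed where the CENP-C motif and the central region
ought to be. `cenpcscan` implements that screen as a reproducible,
fully tested pipeline for anyone who wants to hunt divergent CENP-C-like
(or M18BP1-like) architectures in protein FASTA collections.

## What it computes

- **Degenerate motif engine** — PROSITE-style identity patterns over
  residue sets (`x`/`X` wildcard, `B`={D,N}, `Z`={E,Q}, `J`={I,L}).
  Matching is by non-empty set intersection, so a degenerate consensus can
  be scanned against another degenerate consensus; only constrained
  positions can count as mismatches. Ships the five patterns that matter
  here, including the 23-residue vertebrate consensus
  `NVRRTKRXRLKPLEYWRGERVBY`, the identity pattern
  `RxxRxxxxPLxYWxGERxxY`, and the central-region core `RxxxxPxxWW`.
- **Consensus derivation** — collapse a protein multiple alignment to a
  degenerate motif, column by column, under a configurable
  relative-majority policy (ties keep both residues; {D,N}→B and so on).
- **Local alignment** — Smith–Waterman with affine gaps
  (BLOSUM62, gap open 11 / extend 1; a gap of length *L* costs
  11 + *L*), deterministic traceback, significance by score-per-column
  and minimum aligned length. Used to localize cupin-domain homology.
- **Architecture classifier** — per protein:
  `CANONICAL_CENPC` (cupin + exact identity-pattern hit ending ≤ 100
  residues upstream), `PUTATIVE_FISH_CENPC` (cupin + central-region-core
  hits upstream, tolerating up to 2 violated identities — the shark case
  where both tryptophans are lost), `MOTIF_ONLY` (M18BP1-like evidence),
  `CUPIN_ONLY`, `NONE`; plus the motif-to-cupin spacing and the
  fish-vs-canonical spacing ratio (≈ 2).
- **Synthetic proteomes** — seeded generator that plants cupin copies and
  motif instances (with exact, truth-tracked substitution counts) in
  random background, so recovery is measurable against ground truth.

## Worked example

```sh
cenpcscan simulate -n 200 --seed 20160120 --out-prefix results/proteome
cenpcscan classify results/proteome.fasta \
    --references results/proteome_references.fasta \
    --out-prefix results/architecture
cenpcscan report results/architecture.json
```

or, through the numbered drivers, `python analysis/01_simulate_proteome.py`
then `python analysis/04_classify_architectures.py`, which prints:

```
classified 200 proteins; accuracy vs planted truth: 100.0%
  CANONICAL_CENPC: 68
  PUTATIVE_FISH_CENPC: 62
  MOTIF_ONLY: 30
  CUPIN_ONLY: 0
  NONE: 40
mean motif-to-cupin gap: canonical 68, fish 146 residues -> spacing ratio 2.14
```

Every protein lands in its planted class; the fish-type candidates show
the motif sitting about twice as far upstream of the cupin domain as in
canonical vertebrate CENP-C, which is exactly the diagnostic spacing this
screen keys on. Scanning a single sequence works the same way:

```sh
$ printf '>vm\nNVRRTKRXRLKPLEYWRGERVBY\n' > vm.fasta
$ cenpcscan scan vm.fasta --motif-id cenpc-motif-core
sequence_id  motif_id          start  end  mismatches  per_position
vm           cenpc-motif-core  7      16   0           |....|..||
```

The core pattern hits the vertebrate consensus exactly once, at residues
7–16 (1-based), with every constrained identity satisfied.

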