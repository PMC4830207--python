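#!/usr/bin/env python
"""Classify the simulated proteome and compare against the planted truth.

Runs cupin localization plus motif placement on every protein, writes the
architecture report (TSV + JSON), and summarizes accuracy, the per-class
counts, and the fish-vs-canonical motif-to-cupin spacing ratio.
"""

import json
from pathlib import Path

from cenpcscan import (
    blosum62_scheme,
    load_fixture_motifs,
    read_fasta,
    scan_proteome,
    write_json_report,
    write_tsv_report,
)
from cenpcscan import architecture as arch

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    proteome = OUT / "proteome.fasta"
    truth_path = OUT / "proteome_truth.json"
    if not proteome.exists():
        raise SystemExit("run analysis/01_simulate_proteome.py first")
    references = read_fasta(OUT / "cupin_references.fasta")
    calls = scan_proteome(proteome, motifs=load_fixture_motifs(),
                          references=references, scheme=blosum62_scheme())
    write_tsv_report(calls, OUT / "architecture_calls.tsv")
    write_json_report(calls, OUT / "architecture_calls.json")

    truth = {p["protein_id"]: p["class"]
             for p in json.loads(truth_path.read_text())}
    correct = sum(c.arch_class == truth[c.sequence_id] for c in calls)
    print(f"classified {len(calls)} proteins; "
          f"accuracy vs planted truth: {100.0 * correct / len(calls):.1f}%")

    counts: dict[str, int] = {}
    gaps: dict[str, list[int]] = {}
    for call in calls:
        counts[call.arch_class] = counts.get(call.arch_class, 0) + 1
        if call.motif_to_cupin_gap is not None:
            gaps.setdefault(call.arch_class, []).append(call.motif_to_cupin_gap)
    for cls in arch.ARCH_CLASSES:
        print(f"  {cls}: {counts.get(cls, 0)}")
    canon = gaps.get(arch.CANONICAL_CENPC, [])
    fish = gaps.get(arch.PUTATIVE_FISH_CENPC, [])
    if canon and fish:
        mc = sum(canon) / len(canon)
        mf = sum(fish) / len(fish)
        print(f"mean motif-to-cupin gap: canonical {mc:.0f}, fish {mf:.0f} "
              f"residues -> spacing ratio {mf / mc:.2f}")
    print(f"wrote {OUT / 'architecture_calls.tsv'}")


if __name__ == "__main__":
    main()
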