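#!/usr/bin/env python
"""Simulate the study proteome: 200 proteins with planted architectures.

The mixture follows the architectures observed across vertebrates —
canonical CENP-C (cupin + full motif within 100 residues), putative fish
CENP-C (cupin + two central-region cores, doubled spacing), M18BP1-like
motif-only proteins, and unstructured background.  Writes the proteome,
the truth table and the cupin reference under results/.
"""

from pathlib import Path

from cenpcscan import generate_proteome, synthetic_cupin_reference, write_fasta

SEED = 20160120
N = 200
OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    records, truth = generate_proteome(n=N, seed=SEED)
    write_fasta(records, OUT / "proteome.fasta")
    truth.to_tsv(OUT / "proteome_truth.tsv")
    truth.to_json(OUT / "proteome_truth.json")
    write_fasta([synthetic_cupin_reference()], OUT / "cupin_references.fasta")
    classes = {}
    for prot in truth.proteins:
        classes[prot.intended_class] = classes.get(prot.intended_class, 0) + 1
    print(f"simulated {len(records)} proteins (seed {SEED}) -> "
          f"{OUT / 'proteome.fasta'}")
    for cls, count in sorted(classes.items()):
        print(f"  planted {cls}: {count}")


if __name__ == "__main__":
    main()
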