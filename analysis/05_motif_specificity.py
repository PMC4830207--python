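#!/usr/bin/env python
"""Quantify identity-pattern specificity on random background.

For each packaged pattern, compares the Monte-Carlo exact-hit rate on
uniform random sequences with the closed-form per-window probability
(product of |residue set| / 20 over positions), and reports the chance of
a degraded (k<=2) hit of the central-region core — the number that
explains why degraded single-sequence hits alone cannot separate
cupin-only proteins from fish-type candidates.  Writes
results/specificity.tsv.
"""

from pathlib import Path

from cenpcscan import estimate_false_positive_rate, load_fixture_motifs, scan
from cenpcscan.synthetic import UNIFORM_BACKGROUND
import numpy as np

from cenpcscan.sequence_io import AMINO_ACIDS

SEED = 20160120
OUT = Path(__file__).resolve().parent.parent / "results"


def degraded_window_rate(motif, k: int, trials: int, length: int,
                         seed: int) -> float:
    rng = np.random.default_rng(seed)
    windows = 0
    hits = 0
    for _ in range(trials):
        seq = "".join(rng.choice(list(AMINO_ACIDS), size=length))
        hits += len(scan(motif, seq, k))
        windows += length - len(motif) + 1
    return hits / windows


def main() -> None:
    OUT.mkdir(exist_ok=True)
    motifs = load_fixture_motifs()
    lines = ["motif_id\tanalytic_window_prob\tmc_mean_hits_per_seq"
             "\texpected_hits_per_seq\tabs_zscore"]
    for motif_id, motif in sorted(motifs.items()):
        est = estimate_false_positive_rate(motif, UNIFORM_BACKGROUND,
                                           trials=20_000,
                                           sequence_length=200, seed=SEED)
        se = max(est.analytic_se_mean_hits, 1e-300)
        z = abs(est.mean_hits_per_sequence
                - est.expected_hits_per_sequence) / se
        lines.append(f"{motif_id}\t{est.analytic_window_prob:.3e}\t"
                     f"{est.mean_hits_per_sequence:.3e}\t"
                     f"{est.expected_hits_per_sequence:.3e}\t{z:.2f}")
        print(f"{motif_id}: per-window exact-hit prob "
              f"{est.analytic_window_prob:.2e}, MC |z| = {z:.2f}")
    core = motifs["central-region-core"]
    rate = degraded_window_rate(core, k=2, trials=300, length=200, seed=SEED)
    print(f"degraded (k<=2) per-window hit rate of {core.id}: {rate:.4f} "
          f"(~1.4% expected; why degraded hits alone are weak evidence)")
    (OUT / "specificity.tsv").write_text("\n".join(lines) + "\n")
    print(f"wrote {OUT / 'specificity.tsv'}")


if __name__ == "__main__":
    main()
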