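import random

import numpy as np
import pytest

from cenpcscan import architecture as arch
from cenpcscan.architecture import (
    ArchitectureCall,
    ClassificationError,
    ClassifierConfig,
    classify,
    greedy_nonoverlapping,
    locate_cupin,
    scan_proteome,
    spacing_ratio,
    validate_call,
)
from cenpcscan.motifs import parse_pattern, scan
from cenpcscan.sequence_io import ProteinRecord, write_fasta
from cenpcscan.synthetic import generate_proteome, synthetic_cupin_reference

import helpers


def _background(rng: random.Random, length: int) -> str:
    return helpers.random_protein(rng, length)


def _instance(pattern: str, rng: random.Random) -> str:
    """A concrete realization of a degenerate pattern."""
    motif = parse_pattern(pattern)
    return "".join(sorted(pos)[rng.randrange(len(pos))]
                   for pos in motif.positions)


@pytest.fixture(scope="module")
def rng():
    return random.Random(20160120)


class TestLocateCupin:
    def test_exact_planted_copy_found_with_identity_one(
            self, scheme, cupin_reference, rng):
        flank = _background(rng, 200)
        query = ProteinRecord(
            id="q", residues=flank + cupin_reference.residues +
            _background(rng, 40))
        hit = locate_cupin(query, [cupin_reference], scheme)
        assert hit is not None
        assert (hit.start, hit.end) == (200, 200 + len(cupin_reference))
        assert hit.identity_fraction == 1.0

    def test_random_sequence_has_no_significant_hit(
            self, scheme, cupin_reference, rng):
        query = ProteinRecord(id="q", residues=_background(rng, 400))
        assert locate_cupin(query, [cupin_reference], scheme) is None

    def test_mutated_copy_recovered_with_high_interval_jaccard(
            self, scheme, cupin_reference):
        gen = np.random.default_rng(77)
        residues = list(cupin_reference.residues)
        # mutate 20% of positions, always to a different residue
        for i in gen.choice(len(residues), size=len(residues) // 5,
                            replace=False):
            choices = [aa for aa in helpers.AA if aa != residues[i]]
            residues[i] = choices[int(gen.integers(len(choices)))]
        mutated = "".join(residues)
        prefix = helpers.random_protein(random.Random(5), 150)
        query = ProteinRecord(id="q", residues=prefix + mutated +
                              helpers.random_protein(random.Random(6), 50))
        hit = locate_cupin(query, [cupin_reference], scheme)
        assert hit is not None
        planted = set(range(150, 150 + len(mutated)))
        found = set(range(hit.start, hit.end))
        jaccard = len(planted & found) / len(planted | found)
        assert jaccard >= 0.8

    def test_empty_reference_set_rejected(self, scheme, cupin_reference):
        with pytest.raises(ClassificationError):
            locate_cupin(cupin_reference, [], scheme)

    def test_tie_break_prefers_lexicographic_reference_id(
            self, scheme, cupin_reference, rng):
        ref_b = ProteinRecord(id="zz-ref", residues=cupin_reference.residues)
        query = ProteinRecord(
            id="q", residues=_background(rng, 60) + cupin_reference.residues)
        hit = locate_cupin(query, [ref_b, cupin_reference], scheme)
        assert hit.reference_id == cupin_reference.id  # 'synthetic-…' < 'zz-…'


class TestClassify:
    def test_canonical_architecture_with_gap_80(self, motifs, scheme,
                                                cupin_reference, rng):
        motif_seq = _instance("RxxRxxxxPLxYWxGERxxY", rng)
        gap = 80
        residues = (_background(rng, 300) + motif_seq + _background(rng, gap)
                    + cupin_reference.residues + _background(rng, 30))
        call = classify(ProteinRecord(id="canon", residues=residues),
                        motifs=motifs, references=[cupin_reference],
                        scheme=scheme)
        assert call.arch_class == arch.CANONICAL_CENPC
        assert call.motif_to_cupin_gap == gap
        validate_call(call)

    def test_two_core_instances_upstream_give_fish_call(
            self, motifs, scheme, cupin_reference, rng):
        inst1 = _instance("RxxxxPxxWW", rng)
        inst2 = _instance("RxxxxPxxWW", rng)
        residues = (_background(rng, 100) + inst1 + _background(rng, 200)
                    + inst2 + _background(rng, 150)
                    + cupin_reference.residues + _background(rng, 30))
        call = classify(ProteinRecord(id="fish", residues=residues),
                        motifs=motifs, references=[cupin_reference],
                        scheme=scheme)
        assert call.arch_class == arch.PUTATIVE_FISH_CENPC
        assert call.conserved_region_count == 2
        assert call.motif_to_cupin_gap == 150
        validate_call(call)

    def test_canonical_motif_without_cupin_is_motif_only(
            self, motifs, scheme, cupin_reference, rng):
        residues = (_background(rng, 200)
                    + _instance("RxxRxxxxPLxYWxGERxxY", rng)
                    + _background(rng, 100))
        call = classify(ProteinRecord(id="m18", residues=residues),
                        motifs=motifs, references=[cupin_reference],
                        scheme=scheme)
        assert call.arch_class == arch.MOTIF_ONLY
        validate_call(call)

    def test_cupin_without_motifs_is_cupin_only(self, motifs, scheme,
                                                cupin_reference, rng):
        # keep upstream short so no spurious degraded hit can arise
        residues = "P" * 20 + cupin_reference.residues + "P" * 10
        call = classify(ProteinRecord(id="cup", residues=residues),
                        motifs=motifs, references=[cupin_reference],
                        scheme=scheme)
        assert call.arch_class == arch.CUPIN_ONLY
        validate_call(call)

    def test_background_only_is_none(self, motifs, scheme, cupin_reference):
        call = classify(ProteinRecord(id="bg", residues="P" * 300),
                        motifs=motifs, references=[cupin_reference],
                        scheme=scheme)
        assert call.arch_class == arch.NONE
        validate_call(call)

    def test_degraded_tryptophans_recorded_for_shark_like_motif(
            self, motifs, scheme, cupin_reference, rng):
        inst = list(_instance("RxxxxPxxWW", rng))
        inst[8], inst[9] = "A", "A"  # both tryptophans lost
        residues = (_background(rng, 100) + "".join(inst)
                    + _background(rng, 120) + cupin_reference.residues
                    + _background(rng, 30))
        call = classify(ProteinRecord(id="shark", residues=residues),
                        motifs=motifs, references=[cupin_reference],
                        scheme=scheme)
        assert call.arch_class == arch.PUTATIVE_FISH_CENPC
        degraded = [pos for hit, pos in call.degraded_positions
                    if hit.offset == 100]
        assert degraded == [(8, 9)]

    def test_raising_gap_max_never_loses_canonical_calls(
            self, motifs, scheme, cupin_reference, rng):
        motif_seq = _instance("RxxRxxxxPLxYWxGERxxY", rng)
        counts = []
        for gap_max in (50, 100, 200, 400):
            cfg = ClassifierConfig(canonical_gap_max=gap_max)
            n_canonical = 0
            for gap in (30, 90, 150, 300):
                residues = (_background(rng, 50) + motif_seq
                            + _background(rng, gap)
                            + cupin_reference.residues + "P" * 10)
                call = classify(ProteinRecord(id=f"g{gap}", residues=residues),
                                cfg, motifs, [cupin_reference], scheme)
                n_canonical += call.arch_class == arch.CANONICAL_CENPC
            counts.append(n_canonical)
        assert counts == sorted(counts)


class TestGreedyNonoverlap:
    def test_overlapping_hits_counted_left_to_right(self):
        motif = parse_pattern("Rxx")
        hits = scan(motif, "RRRRRR", 0)  # offsets 0..3
        chosen = greedy_nonoverlapping(hits)
        assert [h.offset for h in chosen] == [0, 3]


class TestSpacingRatio:
    def _call(self, gap):
        hit = scan(parse_pattern("RxxxxPxxWW"),
                   "RAAAAPAAWW" + "A" * gap + "G" * 5, 0)[0]
        cupin = arch.DomainHit(reference_id="r", start=10 + gap,
                               end=15 + gap, score=100,
                               identity_fraction=1.0)
        return ArchitectureCall(
            sequence_id=f"gap{gap}", arch_class=arch.PUTATIVE_FISH_CENPC,
            cupin=cupin, motif_hits=(hit,), motif_to_cupin_gap=gap,
            conserved_region_count=1)

    def test_identical_calls_give_one(self):
        call = self._call(100)
        assert spacing_ratio(call, call) == 1.0

    def test_two_to_one(self):
        assert spacing_ratio(self._call(200), self._call(100)) == 2.0

    def test_zero_denominator_rejected(self):
        with pytest.raises(ClassificationError, match="zero"):
            spacing_ratio(self._call(100), self._call(0))

    def test_missing_evidence_rejected(self):
        empty = ArchitectureCall(sequence_id="x", arch_class=arch.NONE)
        with pytest.raises(ClassificationError, match="evidence"):
            spacing_ratio(empty, self._call(10))


class TestScanProteome:
    def test_empty_proteome(self, tmp_path, motifs, scheme, cupin_reference):
        path = tmp_path / "empty.fasta"
        path.write_text("")
        assert scan_proteome(path, motifs=motifs,
                             references=[cupin_reference],
                             scheme=scheme) == []

    def test_calls_match_generator_truth(self, tmp_path, motifs, scheme,
                                         cupin_reference, small_proteome):
        records, truth = small_proteome
        path = tmp_path / "synthetic.fasta"
        write_fasta(records, path)
        calls = scan_proteome(path, motifs=motifs,
                              references=[cupin_reference], scheme=scheme)
        by_id = truth.by_id()
        assert [c.sequence_id for c in calls] == [r.id for r in records]
        for call in calls:
            assert call.arch_class == by_id[call.sequence_id].intended_class
            validate_call(call)

    def test_repeated_runs_identical(self, tmp_path, motifs, scheme,
                                     cupin_reference, small_proteome):
        records, _ = small_proteome
        path = tmp_path / "synthetic.fasta"
        write_fasta(records[:10], path)
        first = scan_proteome(path, motifs=motifs,
                              references=[cupin_reference], scheme=scheme)
        second = scan_proteome(path, motifs=motifs,
                               references=[cupin_reference], scheme=scheme)
        assert first == second

    def test_missing_file_reports_context(self, motifs, cupin_reference):
        with pytest.raises(ClassificationError, match="no-such-file"):
            scan_proteome("no-such-file.fasta", motifs=motifs,
                          references=[cupin_reference])


class TestValidator:
    def test_inconsistent_class_rejected(self):
        call = ArchitectureCall(sequence_id="x",
                                arch_class=arch.CANONICAL_CENPC)
        with pytest.raises(ClassificationError, match="inconsistent"):
            validate_call(call)

    def test_validator_clean_on_classifier_output(
            self, motifs, scheme, cupin_reference):
        records, _ = generate_proteome(n=25, seed=31)
        for rec in records:
            validate_call(classify(rec, motifs=motifs,
                                   references=[cupin_reference],
                                   scheme=scheme))
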