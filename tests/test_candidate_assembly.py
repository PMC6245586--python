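"""Seed merging, TSD validation and end-to-end candidate assembly."""
import pytest

import mitescan as ms
from mitescan.candidate_assembly import (
    MiteCandidate,
    detect_tsd,
    find_candidates_in_fragment,
    merge_seed_pairs,
)
from mitescan.fasta_io import GenomeFragment, SequenceRecord
from mitescan.seed_search import SeedPair
from oracle import oracle_candidates


class TestMergeSeedPairs:
    def test_two_adjacent_perfect_seeds_merge_to_tir_11(self):
        seeds = [SeedPair(100, 200, 10), SeedPair(101, 199, 10)]
        (cand,) = merge_seed_pairs(seeds)
        assert cand.tir_length == 11
        assert (cand.start, cand.end) == (100, 210)
        assert cand.mis == 0

    def test_single_seed_passes_through(self):
        (cand,) = merge_seed_pairs([SeedPair(50, 150, 10)])
        assert (cand.start, cand.end, cand.tir_length) == (50, 160, 10)

    def test_two_distinct_mismatch_positions_are_not_merged(self):
        """Merging two imperfect repeats is refused: the chain splits."""
        seeds = [
            SeedPair(100, 200, 10, mis=1, mispos=103),
            SeedPair(101, 199, 10, mis=1, mispos=105),
        ]
        merged = merge_seed_pairs(seeds)
        assert all(c.tir_length == 10 for c in merged)

    def test_gap_two_bridge_between_perfect_and_imperfect(self):
        """A perfect seed and an imperfect one two bases on merge into
        one imperfect candidate carrying the mismatch position."""
        seeds = [
            SeedPair(3460, 3660, 10),
            SeedPair(3462, 3658, 10, mis=1, mispos=3468),
        ]
        (cand,) = merge_seed_pairs(seeds)
        assert cand.mis == 1 and cand.mispos == 3468
        assert cand.start == 3460
        assert cand.tir_length == 12

    def test_merge_is_idempotent(self):
        seeds = [
            SeedPair(100, 200, 10),
            SeedPair(101, 199, 10),
            SeedPair(400, 520, 10, mis=1, mispos=404),
        ]
        once = merge_seed_pairs(seeds)
        again = merge_seed_pairs(
            [
                SeedPair(c.start, c.end - c.tir_length, c.tir_length, c.mis, c.mispos)
                for c in once
            ]
        )
        assert [
            (c.start, c.end, c.tir_length, c.mis, c.mispos) for c in again
        ] == [(c.start, c.end, c.tir_length, c.mis, c.mispos) for c in once]


def _chrom(left, elem, right):
    return SequenceRecord("c", "", left + elem + right)


class TestDetectTsd:
    def _cand(self, start, end):
        return MiteCandidate("c", start, end, tir_length=12)

    def test_ta_tsd_retained(self):
        chrom = _chrom("G" * 47 + "CTA", "T" * 100, "TAG" + "G" * 47)
        out = detect_tsd(self._cand(50, 150), chrom)
        assert out is not None and out.tsd == "TA"

    def test_two_bp_non_ta_rejected(self):
        chrom = _chrom("G" * 48 + "AG", "T" * 100, "AG" + "G" * 48)
        assert detect_tsd(self._cand(50, 150), chrom) is None

    def test_longest_match_preferred(self):
        chrom = _chrom("G" * 45 + "TAACG", "T" * 100, "TAACG" + "G" * 45)
        out = detect_tsd(self._cand(50, 150), chrom)
        assert out.tsd == "TAACG"

    def test_chromosome_edge_rejected(self):
        chrom = SequenceRecord("c", "", "T" * 100 + "G" * 50)
        assert detect_tsd(self._cand(0, 100), chrom) is None

    def test_trim_recovers_absorbed_ta_junction(self):
        """A TA TSD is its own reverse complement, so the repeat search
        absorbs it into the TIR; the caller trims back to the true
        boundary and still calls TA."""
        genome = ms.random_genome(20000, seed=5)
        mutated, truth = ms.implant(
            genome, [ms.ImplantSpec(12, 300, "TA")], seed=6
        )
        t = truth[0]
        found = [
            c
            for c in ms.assemble_candidates(mutated)
            if (c.start, c.end) == (t.start, t.end)
        ]
        assert len(found) == 1 and found[0].tsd == "TA"
        assert found[0].tir_length == 12 and found[0].mis == 0


class TestAssembleCandidates:
    def test_recovers_all_planted_elements(self, implanted_genome):
        mutated, truth = implanted_genome
        cands = ms.assemble_candidates(mutated)
        found = {(c.start, c.end): c for c in cands}
        for t in truth:
            c = found.get((t.start, t.end))
            assert c is not None, f"implant at {t.start} not recovered"
            assert c.tir_length == t.tir_length
            assert c.tsd == t.tsd

    def test_boundary_straddling_element_found_once(self):
        genome = ms.random_genome(25000, seed=42)
        specs = [
            ms.ImplantSpec(12, 300, "TTA", positions=[9500]),   # in the overlap
            ms.ImplantSpec(12, 300, "GAT", positions=[9850]),   # across 10,000
        ]
        mutated, truth = ms.implant(genome, specs, seed=7)
        cands = ms.assemble_candidates(mutated)
        for t in truth:
            hits = [c for c in cands if (c.start, c.end) == (t.start, t.end)]
            assert len(hits) == 1

    def test_all_n_genome_yields_nothing(self):
        rec = SequenceRecord("n", "", "N" * 30000)
        assert ms.assemble_candidates(rec) == []

    def test_structural_invariants_on_random_genomes(self):
        for seed in (3, 4):
            genome = ms.random_genome(50000, seed=seed)
            specs = [
                ms.ImplantSpec(12, 250, "TA"),
                ms.ImplantSpec(10, 90, "TAA", mismatch=True),
            ]
            mutated, _ = ms.implant(genome, specs, seed=seed + 10)
            for c in ms.assemble_candidates(mutated):
                assert 50 <= c.end - c.start <= 800
                assert c.tir_length >= 10
                assert 2 <= len(c.tsd) <= 10
                assert len(c.tsd) != 2 or c.tsd == "TA"
                assert c.mis in (0, 1)
                if c.mis:
                    assert c.start + 1 <= c.mispos <= c.start + c.tir_length - 2
                seq = mutated.sequence
                assert seq[c.start - len(c.tsd) : c.start] == seq[c.end : c.end + len(c.tsd)]

    def test_agrees_with_bruteforce_oracle(self):
        """Seed search + merge equals an exhaustive inverted-repeat scan."""
        for seed in (11, 12, 13):
            genome = ms.random_genome(4000, seed=seed)
            mutated, _ = ms.implant(
                genome,
                [ms.ImplantSpec(12, 200, "TA")],
                seed=seed,
                min_separation=500,
            )
            frag = GenomeFragment("f", 0, mutated.sequence)
            got = {
                (c.start, c.end, c.tir_length, c.mis)
                for c in find_candidates_in_fragment(frag)
            }
            assert got == oracle_candidates(mutated.sequence)
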