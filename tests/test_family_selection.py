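"""Flank extraction, similarity, the flank filter and family selection."""
import random

import numpy as np
import pytest

import mitescan as ms
from mitescan.candidate_assembly import MiteCandidate
from mitescan.family_selection import (
    build_family_network,
    classify_superfamily,
    element_hits,
    extract_with_flanks,
    flank_filter,
    flanked_hits,
    pairwise_similarity,
    select_families,
)
from mitescan.fasta_io import SequenceRecord
from mitescan.scoring import filter_by_score, train_model
from mitescan.synthetic import _as_rng, _random_bases


def _rand(n, seed):
    return _random_bases(_as_rng(seed), n)


class TestExtractWithFlanks:
    def test_full_flanks(self):
        chrom = SequenceRecord("c", "", _rand(1000, 1))
        cand = MiteCandidate("c", 100, 400, 12)
        seq = extract_with_flanks(cand, chrom)
        assert len(seq) == 420
        assert seq == chrom.sequence[40:460]

    def test_truncated_at_edge(self):
        chrom = SequenceRecord("c", "", _rand(500, 2))
        cand = MiteCandidate("c", 10, 110, 12)
        seq = extract_with_flanks(cand, chrom)
        assert cand.flank_left == chrom.sequence[:10]
        assert seq == chrom.sequence[0:170]


class TestPairwiseSimilarity:
    def test_identical_sequences(self):
        seq = _rand(300, 3)
        hit = pairwise_similarity(seq, seq)
        assert hit.identity_pct == 100.0
        assert hit.align_length == 300

    def test_unrelated_sequences_give_no_hit(self):
        assert pairwise_similarity(_rand(300, 4), _rand(300, 5)) is None

    def test_shared_element_with_different_flanks(self):
        element = _rand(200, 6)
        a = _rand(60, 7) + element + _rand(60, 8)
        b = _rand(60, 9) + element + _rand(60, 10)
        hit = pairwise_similarity(a, b, element_bounds=((60, 260), (60, 260)))
        assert hit is not None and hit.covers_flank is False

    def test_segmental_duplication_covers_flank(self):
        block = _rand(320, 11)
        hit = pairwise_similarity(block, block, element_bounds=((60, 260), (60, 260)))
        assert hit is not None and hit.covers_flank is True


def _family_scenario(seed_genome=21, seed_implant=22):
    genome = ms.random_genome(40000, seed=seed_genome)
    specs = [
        ms.ImplantSpec(12, 220, "TA", n_copies=5, decay=0.015, family="A"),
        ms.ImplantSpec(13, 260, "TAA", n_copies=4, decay=0.015, family="B"),
        ms.ImplantSpec(12, 180, "GATCCA", n_copies=3, decay=0.015, family="C"),
        ms.ImplantSpec(12, 200, "GCTAA", n_copies=2, duplicate_flanks=60, family="decoy"),
        ms.ImplantSpec(14, 240, "GAT", n_copies=1, family="single"),
    ]
    mutated, truth = ms.implant(genome, specs, seed=seed_implant)
    cands = ms.assemble_candidates(mutated)
    model = train_model(
        [t.element for t in truth], [_rand(220, 99 + i) for i in range(15)]
    )
    scored = filter_by_score(cands, model)
    return mutated, truth, scored


class TestFlankFilter:
    def test_transposed_copies_kept_duplications_and_singletons_removed(self):
        mutated, truth, scored = _family_scenario()
        hits = flanked_hits(scored, {mutated.id: mutated})
        retained = flank_filter(scored, hits)
        labels = {
            (t.start, t.end): t.family for t in truth
        }
        kept = [labels.get((c.start, c.end)) for c in retained]
        assert kept.count("A") == 5
        assert kept.count("B") == 4
        assert kept.count("C") == 3
        assert "decoy" not in kept
        assert "single" not in kept

    def test_retention_requires_element_confined_partner(self):
        mutated, truth, scored = _family_scenario()
        hits = flanked_hits(scored, {mutated.id: mutated})
        retained = flank_filter(scored, hits)
        qualified = {
            cid
            for h in hits
            if h.identity_pct > 80 and not h.covers_flank
            for cid in (h.query_id, h.subject_id)
        }
        assert all(c.id in qualified for c in retained)


class TestFamilyNetwork:
    def _cands(self, n, element=None, start=0):
        out = []
        for i in range(n):
            seq = element if element is not None else _rand(200, 50 + i)
            c = MiteCandidate("c", start + i * 1000, start + i * 1000 + len(seq), 10,
                              tsd="TA", sequence=seq)
            out.append(c)
        return out

    def test_mutually_similar_copies_form_complete_graph(self):
        cands = self._cands(4, element=_rand(200, 60))
        graph = build_family_network(cands, element_hits(cands))
        assert all(graph.degree[c.id] == 3 for c in cands)

    def test_unrelated_trios_stay_separate(self):
        trio1 = self._cands(3, element=_rand(200, 61))
        trio2 = self._cands(3, element=_rand(200, 62), start=50000)
        cands = trio1 + trio2
        graph = build_family_network(cands, element_hits(cands))
        fams = select_families(graph, cands)
        assert len(fams) == 2
        assert {tuple(sorted(f.member_ids)) for f in fams} == {
            tuple(sorted(c.id for c in trio1)),
            tuple(sorted(c.id for c in trio2)),
        }

    def test_empty_candidate_list(self):
        graph = build_family_network([], [])
        assert graph.number_of_nodes() == 0
        assert select_families(graph, []) == []


class TestSelectFamilies:
    def _graph_cands(self, edges, n):
        cands = [
            MiteCandidate("c", i * 100, i * 100 + 60, 10, tsd="TA", sequence="A")
            for i in range(n)
        ]
        import networkx as nx

        graph = nx.Graph()
        for c in cands:
            graph.add_node(c.id)
        for i, j in edges:
            graph.add_edge(cands[i].id, cands[j].id)
        return graph, cands

    def test_hub_becomes_representative(self):
        graph, cands = self._graph_cands([(1, 0), (1, 2), (1, 3)], 4)
        (fam,) = select_families(graph, cands)
        assert fam.representative_id == cands[1].id

    def test_small_components_dropped(self):
        graph, cands = self._graph_cands([(0, 1)], 2)
        assert select_families(graph, cands, min_members=3) == []

    def test_tie_broken_by_smallest_coordinate(self):
        edges = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]  # K4
        graph, cands = self._graph_cands(edges, 4)
        (fam,) = select_families(graph, cands)
        assert fam.representative_id == cands[0].id

    def test_deterministic_under_input_shuffling(self):
        mutated, truth, scored = _family_scenario()
        hits = flanked_hits(scored, {mutated.id: mutated})
        retained = flank_filter(scored, hits)
        reference = None
        for shuffle_seed in range(3):
            order = list(retained)
            random.Random(shuffle_seed).shuffle(order)
            fams = select_families(
                build_family_network(order, element_hits(order)), order
            )
            signature = [
                (f.representative_id, tuple(sorted(f.member_ids))) for f in fams
            ]
            if reference is None:
                reference = signature
            assert signature == reference


class TestClassifySuperfamily:
    @pytest.mark.parametrize(
        "tsd,label",
        [
            ("TA", "Stowaway"),
            ("TAA", "Tourist"),
            ("GTCCA", "hAT"),
            ("GTCCAG", "hAT"),
            ("GATCGATC", "hAT"),
            ("GATCGATCG", "Mutator"),
            ("GATCGATCGA", "Mutator"),
            ("GGCC", "Unknown"),
            ("GGC", "Unknown"),
            ("GGCCGGC", "Unknown"),
        ],
    )
    def test_examples(self, tsd, label):
        assert classify_superfamily(tsd) == label

    def test_invalid_length(self):
        with pytest.raises(ValueError):
            classify_superfamily("A")
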