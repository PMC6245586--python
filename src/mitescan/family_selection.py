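"""False-positive removal and family building via sequence similarity.

Two similarity passes run over the candidates that survived scoring:

1.  *Flank filter.*  Each candidate is extended by 60 bp of genomic
    flank on both sides and aligned all-by-all (local alignment).  A
    real MITE has transposed copies elsewhere in the genome whose
    element sequences match but whose flanks do not; a segmental
    duplication carries its flanks along.  A candidate is retained only
    when at least one partner matches it at >80% identity *within* the
    element but not into the flanks.

2.  *Family network.*  Surviving elements (without flanks) are aligned
    all-by-all under a strict criterion (>=90% identity over >=90% of
    the shorter element, the self-contained stand-in for a BLASTN
    e-value of 1e-100).  Matches become edges of an undirected graph;
    connected components with at least ``min_members`` nodes are
    families and the member of highest degree is the family
    representative.

Alignment uses match +1, mismatch -1, gap open -2, gap extend -1;
identity is matches divided by alignment columns.  Explicit thresholds
replace e-values because e-values depend on database size and are not
reproducible inside a library.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
from Bio import Align

from .candidate_assembly import MiteCandidate
from .fasta_io import SequenceRecord

logger = logging.getLogger(__name__)

SUPERFAMILY_BY_TSD_LENGTH = {5: "hAT", 6: "hAT", 8: "hAT", 9: "Mutator", 10: "Mutator"}


@dataclass
class SimilarityHit:
    """Best local alignment between two (flanked) candidate sequences."""

    query_id: str
    subject_id: str
    identity_pct: float
    align_length: int
    covers_flank: bool


@dataclass
class MiteFamily:
    """A connected component of mutually similar elements."""

    family_id: int
    member_ids: list[str]
    representative_id: str
    superfamily: str


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -1
    return aligner

_ALIGNER = _make_aligner()


def extract_with_flanks(
    candidate: MiteCandidate, chromosome: SequenceRecord, flank: int = 60
) -> str:
    """Element sequence plus up to ``flank`` bp of genomic context per side.

    Flanks are truncated at chromosome edges and stored on the
    candidate for the flank filter.
    """
    seq = chromosome.sequence
    left = seq[max(0, candidate.start - flank) : candidate.start]
    right = seq[candidate.end : candidate.end + flank]
    candidate.flank_left = left
    candidate.flank_right = right
    if candidate.sequence is None:
        candidate.sequence = seq[candidate.start : candidate.end]
    return left + candidate.sequence + right


def _alignment_stats(alignment) -> tuple[float, int]:
    counts = alignment.counts()
    columns = counts.gaps + counts.identities + counts.mismatches
    identity = 100.0 * counts.identities / columns if columns else 0.0
    return identity, columns


def _flank_similarity(
    alignment,
    a: str,
    b: str,
    bounds_a: tuple[int, int],
    bounds_b: tuple[int, int],
) -> tuple[int, int]:
    """Aligned columns (and matches among them) that fall in a flank.

    A column counts as flank when its position on either sequence lies
    outside that sequence's element interval.  Gap columns are ignored.
    """
    blocks_a, blocks_b = alignment.aligned
    flank_cols = flank_matches = 0
    for (a_start, a_end), (b_start, b_end) in zip(blocks_a, blocks_b):
        for offset in range(a_end - a_start):
            pa, pb = a_start + offset, b_start + offset
            in_flank = not (
                bounds_a[0] <= pa < bounds_a[1] and bounds_b[0] <= pb < bounds_b[1]
            )
            if in_flank:
                flank_cols += 1
                if a[pa] == b[pb]:
                    flank_matches += 1
    return flank_cols, flank_matches


def pairwise_similarity(
    a: str,
    b: str,
    element_bounds: tuple[tuple[int, int], tuple[int, int]] | None = None,
    min_align_length: int = 30,
    min_identity: float = 80.0,
    flank_min_cols: int = 15,
    query_id: str = "a",
    subject_id: str = "b",
) -> SimilarityHit | None:
    """Best local alignment of two sequences, or None below the reporting floor.

    The floor (>= ``min_align_length`` aligned columns at >=
    ``min_identity`` % identity) stands in for the conventional BLASTN
    e-value cutoff of 1e-10.  ``element_bounds`` gives the element
    interval within each sequence; the hit ``covers_flank`` when the
    alignment holds a substantial, genuinely similar stretch inside a
    flank: at least ``flank_min_cols`` aligned flank columns at >=
    ``min_identity`` % identity.  (The raw alignment span is no test of
    flank sharing — optimal local alignments routinely wander tens of
    bases into unrelated flanks on marginally positive excursions.)
    """
    if not a or not b:
        return None
    alignments = _ALIGNER.align(a, b)
    if alignments.score <= 0:
        return None
    alignment = alignments[0]
    identity, columns = _alignment_stats(alignment)
    if columns < min_align_length or identity < min_identity:
        return None
    covers = False
    if element_bounds is not None:
        flank_cols, flank_matches = _flank_similarity(
            alignment, a, b, element_bounds[0], element_bounds[1]
        )
        covers = (
            flank_cols >= flank_min_cols
            and 100.0 * flank_matches / flank_cols >= min_identity
        )
    return SimilarityHit(
        query_id=query_id,
        subject_id=subject_id,
        identity_pct=identity,
        align_length=columns,
        covers_flank=covers,
    )


def flanked_hits(
    candidates: list[MiteCandidate],
    chromosomes: dict[str, SequenceRecord],
    flank: int = 60,
    min_align_length: int = 30,
    min_identity: float = 80.0,
    flank_min_cols: int = 15,
) -> list[SimilarityHit]:
    """All-by-all local alignment of flank-extended candidates (one hit per pair)."""
    flanked = []
    for c in candidates:
        seq = extract_with_flanks(c, chromosomes[c.record_id], flank=flank)
        # the TSD copies flanking the element are duplicated between
        # genuine transposed copies by definition, so they count as
        # element, not flank, for the covers_flank decision
        tsd_len = len(c.tsd) if c.tsd else 0
        lo = max(0, len(c.flank_left) - tsd_len)
        hi = min(len(seq), len(c.flank_left) + (c.end - c.start) + tsd_len)
        flanked.append((c, seq, (lo, hi)))
    hits: list[SimilarityHit] = []
    for i in range(len(flanked)):
        ci, seq_i, bounds_i = flanked[i]
        for j in range(i + 1, len(flanked)):
            cj, seq_j, bounds_j = flanked[j]
            hit = pairwise_similarity(
                seq_i,
                seq_j,
                element_bounds=(bounds_i, bounds_j),
                min_align_length=min_align_length,
                min_identity=min_identity,
                flank_min_cols=flank_min_cols,
                query_id=ci.id,
                subject_id=cj.id,
            )
            if hit is not None:
                hits.append(hit)
    return hits


def flank_filter(
    candidates: list[MiteCandidate],
    hits: list[SimilarityHit],
    pident_min: float = 80.0,
) -> list[MiteCandidate]:
    """Keep candidates with at least one element-confined similarity partner.

    A candidate survives when some other candidate matches it at more
    than ``pident_min`` % identity with the alignment confined to the
    elements (``covers_flank`` false).  Candidates whose only partners
    share flank sequence — segmental duplications — and candidates with
    no partner at all are removed.  Hits between candidates whose
    genomic intervals overlap are ignored: two calls on one locus are
    alternative readings of the same sequence, not evidence that it
    transposed.
    """
    by_id = {c.id: c for c in candidates}

    def same_locus(hit: SimilarityHit) -> bool:
        a, b = by_id.get(hit.query_id), by_id.get(hit.subject_id)
        if a is None or b is None:
            return False
        return a.record_id == b.record_id and a.start < b.end and b.start < a.end

    qualified: set[str] = set()
    for hit in hits:
        if (
            hit.identity_pct > pident_min
            and not hit.covers_flank
            and not same_locus(hit)
        ):
            qualified.add(hit.query_id)
            qualified.add(hit.subject_id)
    return [c for c in candidates if c.id in qualified]


def element_hits(
    candidates: list[MiteCandidate],
    min_identity: float = 90.0,
    min_coverage: float = 0.9,
) -> list[SimilarityHit]:
    """Strict all-by-all hits on element sequences without flanks.

    An alignment qualifies when it reaches ``min_identity`` % identity
    over at least ``min_coverage`` of *both* elements — the clustering
    criterion standing in for a BLASTN e-value of 1e-100.  Requiring
    mutual coverage (as CD-HIT-style family clustering does) keeps a
    sloppy long call that merely contains a short element from being
    drawn into the short element's family.
    """
    hits: list[SimilarityHit] = []
    for i in range(len(candidates)):
        ci = candidates[i]
        for j in range(i + 1, len(candidates)):
            cj = candidates[j]
            longer = max(len(ci.sequence or ""), len(cj.sequence or ""))
            if min(len(ci.sequence or ""), len(cj.sequence or "")) == 0:
                continue
            hit = pairwise_similarity(
                ci.sequence,
                cj.sequence,
                min_align_length=max(1, int(round(min_coverage * longer))),
                min_identity=min_identity,
                query_id=ci.id,
                subject_id=cj.id,
            )
            if hit is not None:
                hits.append(hit)
    return hits


def build_family_network(
    candidates: list[MiteCandidate], strict_hits: list[SimilarityHit]
) -> nx.Graph:
    """Undirected similarity graph: one node per candidate, one edge per strict hit."""
    graph = nx.Graph()
    for c in candidates:
        graph.add_node(c.id)
    for hit in strict_hits:
        if hit.query_id != hit.subject_id:
            graph.add_edge(hit.query_id, hit.subject_id)
    return graph


def classify_superfamily(tsd: str) -> str:
    """Superfamily label from the TSD: TA -> Stowaway, TAA -> Tourist,
    5/6/8 bp -> hAT, 9/10 bp -> Mutator, anything else -> Unknown."""
    if not 2 <= len(tsd) <= 10:
        raise ValueError(f"TSD length {len(tsd)} outside the 2-10 bp range")
    if tsd == "TA":
        return "Stowaway"
    if tsd == "TAA":
        return "Tourist"
    return SUPERFAMILY_BY_TSD_LENGTH.get(len(tsd), "Unknown")


def select_families(
    graph: nx.Graph,
    candidates: list[MiteCandidate],
    min_members: int = 3,
) -> list[MiteFamily]:
    """Connected components of size >= ``min_members`` become families.

    The representative is the member of maximal degree, ties broken by
    smallest (record_id, start); families are numbered in genome order
    of their first member.
    """
    by_id = {c.id: c for c in candidates}

    def sort_key(member_id: str) -> tuple:
        c = by_id[member_id]
        return (c.record_id, c.start, c.end)

    components = [
        sorted(comp, key=sort_key)
        for comp in nx.connected_components(graph)
        if len(comp) >= min_members
    ]
    components.sort(key=lambda comp: sort_key(comp[0]))

    families: list[MiteFamily] = []
    for fam_id, members in enumerate(components, start=1):
        representative = min(members, key=lambda m: (-graph.degree[m], sort_key(m)))
        rep = by_id[representative]
        superfamily = classify_superfamily(rep.tsd) if rep.tsd else "Unknown"
        families.append(
            MiteFamily(
                family_id=fam_id,
                member_ids=members,
                representative_id=representative,
                superfamily=superfamily,
            )
        )
    return families
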