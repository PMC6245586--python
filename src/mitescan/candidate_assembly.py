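"""Assembly of seed pairs into MITE candidates.

Adjacent seeds on the same anti-diagonal (constant ``left_start +
right_start``) describe one growing TIR: stepping the left word one base
right while the right word steps one base left extends the repeat by a
single base.  Maximal chains of such seeds are collapsed into one
candidate.  A single interior mismatch inside a longer TIR removes the
two seed windows in which the mismatched base would sit at a word
terminal, leaving a gap of exactly 2 between a perfect and an imperfect
seed; such gaps are bridged.  Chains that would need two distinct
mismatch positions are discarded as false positives.

After merging, each candidate must be flanked by a target site
duplication (TSD): an identical 2-10 bp word on both sides of the
element, with the special rule that a 2 bp TSD must be "TA".
Because a self-complementary TSD junction (e.g. TA, which is its own
reverse complement) is itself part of a perfect inverted repeat, the
seed search absorbs such bases into the TIR; the TSD search therefore
also probes symmetrically trimmed element boundaries (see
:func:`detect_tsd`).
"""
from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, replace

from .config import PipelineConfig
from .fasta_io import GenomeFragment, SequenceRecord, fragment_sequence
from .seed_search import SeedPair, build_kmer_index, find_seed_pairs

logger = logging.getLogger(__name__)


@dataclass
class MiteCandidate:
    """A merged MITE candidate in absolute chromosome coordinates.

    ``start``/``end`` are 0-based half-open bounds of the element (left
    TIR start through right TIR end); ``mispos`` is the absolute
    position of the single TIR mismatch on the left arm, if any.
    """

    record_id: str
    start: int
    end: int
    tir_length: int
    mis: int = 0
    mispos: int | None = None
    tsd: str | None = None
    score: float | None = None
    sequence: str | None = None
    flank_left: str | None = None
    flank_right: str | None = None

    @property
    def id(self) -> str:
        return f"{self.record_id}:{self.start + 1}-{self.end}"

    @property
    def span(self) -> int:
        return self.end - self.start


def _close_chain(chain: list[SeedPair]) -> MiteCandidate:
    """Collapse one chain of seeds into a candidate (fragment coordinates)."""
    mispositions = {s.mispos for s in chain if s.mis}
    first, last = chain[0], chain[-1]
    return MiteCandidate(
        record_id="",
        start=first.left_start,
        end=first.right_start + first.tir_length,
        tir_length=last.left_start + last.tir_length - first.left_start,
        mis=1 if mispositions else 0,
        mispos=mispositions.pop() if mispositions else None,
    )


def merge_seed_pairs(seeds: list[SeedPair]) -> list[MiteCandidate]:
    """Merge seed pairs from one fragment into maximal TIR candidates.

    Seeds are grouped by anti-diagonal (left_start + right_start) and
    chained greedily in left-to-right order.  A successor extends the
    chain when its left start is +1 from its predecessor, or +2 when
    bridging a perfect and an imperfect seed across a terminal-mismatch
    gap, and only while the chain keeps a single mismatch position: a
    merge that would combine two imperfect repeats with distinct
    mismatches is refused (the false-positive case) and the chain is
    closed instead.  Unmergeable seeds pass through as single-seed
    candidates.
    """
    by_diag: dict[int, list[SeedPair]] = defaultdict(list)
    for s in seeds:
        by_diag[s.left_start + s.right_start].append(s)

    candidates: list[MiteCandidate] = []
    for diag in sorted(by_diag):
        chain: list[SeedPair] = []
        chain_mispos: int | None = None
        for s in sorted(by_diag[diag], key=lambda s: s.left_start):
            if chain:
                gap = s.left_start - chain[-1].left_start
                linked = gap == 1 or (gap == 2 and s.mis != chain[-1].mis)
                if linked and s.mis and chain_mispos is not None:
                    linked = s.mispos == chain_mispos
            else:
                linked = False
            if linked:
                chain.append(s)
                if s.mis:
                    chain_mispos = s.mispos
            else:
                if chain:
                    candidates.append(_close_chain(chain))
                chain = [s]
                chain_mispos = s.mispos if s.mis else None
        if chain:
            candidates.append(_close_chain(chain))

    candidates = _suppress_nested(candidates)
    candidates.sort(key=lambda c: (c.start, c.end))
    return candidates


def _suppress_nested(candidates: list[MiteCandidate]) -> list[MiteCandidate]:
    """Keep only the maximal chain among candidates sharing a right TIR end."""
    best: dict[int, MiteCandidate] = {}
    for c in candidates:
        cur = best.get(c.end)
        if cur is None or (c.tir_length, -c.start) > (cur.tir_length, -cur.start):
            best[c.end] = c
    return list(best.values())


def detect_tsd(
    candidate: MiteCandidate,
    chromosome: SequenceRecord,
    min_tsd: int = 2,
    max_tsd: int = 10,
    min_tir: int = 10,
    min_length: int = 50,
) -> MiteCandidate | None:
    """Validate a candidate by its target site duplication.

    For trim offsets delta = 0, 1, ... (bounded so the TIR stays at
    least ``min_tir`` bp) the element boundary is moved symmetrically
    inward and TSD lengths L = ``max_tsd`` down to ``min_tsd`` are
    probed: the L bases immediately left of the start are compared with
    the L bases immediately right of the end, longest exact match first.
    A match is valid when L > 2 or the word is "TA".  The first trim
    offset with a valid TSD wins; with no valid TSD at any offset the
    candidate is rejected (returns None).

    The trim scan exists because a self-complementary TSD junction is
    absorbed into the TIR by the inverted-repeat search (a TA TSD
    extends every perfect TIR by two bases on each side), so the true
    element boundary can sit slightly inside the merged repeat.
    """
    seq = chromosome.sequence
    max_trim = min(max_tsd, candidate.tir_length - min_tir)
    for delta in range(0, max_trim + 1):
        s = candidate.start + delta
        e = candidate.end - delta
        if e - s < min_length:
            break
        found: str | None = None
        for L in range(max_tsd, min_tsd - 1, -1):
            if s - L < 0 or e + L > len(seq):
                continue
            left = seq[s - L : s]
            if "N" in left or left != seq[e : e + L]:
                continue
            found = left
            break
        if found is not None and (len(found) > 2 or found == "TA"):
            tir = candidate.tir_length - delta
            mis, mispos = candidate.mis, candidate.mispos
            # trimming can push the mismatched base out of the reported
            # left arm (or onto its terminal); the repeat that remains
            # is then perfect
            if mispos is not None and not (s + 1 <= mispos <= s + tir - 2):
                mis, mispos = 0, None
            return replace(
                candidate,
                start=s,
                end=e,
                tir_length=tir,
                mis=mis,
                mispos=mispos,
                tsd=found,
            )
    return None


def find_candidates_in_fragment(
    fragment: GenomeFragment, config: PipelineConfig | None = None
) -> list[MiteCandidate]:
    """Seed search + merge for one fragment (fragment-relative coordinates)."""
    cfg = config or PipelineConfig()
    index = build_kmer_index(fragment, k=cfg.k)
    seeds = find_seed_pairs(
        index,
        fragment,
        min_length=cfg.min_length,
        max_length=cfg.max_length,
        max_mismatch=cfg.max_mismatch,
        run_min=cfg.homopolymer_min,
        composition_min_pct=cfg.composition_min_pct,
    )
    return merge_seed_pairs(seeds)


def assemble_candidates(
    record: SequenceRecord, config: PipelineConfig | None = None
) -> list[MiteCandidate]:
    """Run fragmenting, seed search, merging and TSD validation for one record.

    Fragment-relative candidates are lifted to absolute chromosome
    coordinates; twins discovered in two overlapping fragments are
    deduplicated; TSD validation runs against the full chromosome so
    fragment edges never truncate a flank.  Output is sorted by
    (start, end).
    """
    cfg = config or PipelineConfig()
    seen: set[tuple[int, int, int, int, int | None]] = set()
    validated: list[MiteCandidate] = []
    for fragment in fragment_sequence(record, cfg.fragment_length, cfg.overlap):
        for cand in find_candidates_in_fragment(fragment, cfg):
            absolute = replace(
                cand,
                record_id=record.id,
                start=cand.start + fragment.offset,
                end=cand.end + fragment.offset,
                mispos=(cand.mispos + fragment.offset)
                if cand.mispos is not None
                else None,
            )
            key = (
                absolute.start,
                absolute.end,
                absolute.tir_length,
                absolute.mis,
                absolute.mispos,
            )
            if key in seen:
                continue
            seen.add(key)
            with_tsd = detect_tsd(
                absolute,
                record,
                min_tir=cfg.min_tir,
                min_length=cfg.min_length,
            )
            if with_tsd is None:
                continue
            with_tsd.sequence = record.sequence[with_tsd.start : with_tsd.end]
            validated.append(with_tsd)

    # the TSD trim can make two fragment twins converge on one locus
    unique: dict[tuple[int, int, int], MiteCandidate] = {}
    for c in validated:
        unique.setdefault((c.start, c.end, c.tir_length), c)
    out = sorted(unique.values(), key=lambda c: (c.start, c.end))
    logger.debug("%s: %d validated candidates", record.id, len(out))
    return out
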