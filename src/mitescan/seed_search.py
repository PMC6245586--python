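"""K-mer indexed search for inverted-repeat seed pairs.

A *seed* is a pair of 10-mers (left word, right word) such that the
right word equals the reverse complement of the left word either exactly
or with a single interior substitution.  Seeds are the minimal evidence
of a terminal-inverted-repeat (TIR) structure; longer TIRs are assembled
downstream by merging adjacent seeds.

The index maps every overlapping k-mer of a fragment to its start
positions, so a seed lookup is a dictionary probe instead of a scan.
Low-complexity words (homopolymer or dinucleotide runs, or heavily
skewed base composition) are rejected at this stage: they produce large
numbers of spurious inverted-repeat pairs and are unlikely to be real
TIRs.
"""
from __future__ import annotations

from dataclasses import dataclass, field

from .fasta_io import GenomeFragment

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID = frozenset("ACGTN")
_BASES = "ACGT"


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string over {A,C,G,T,N}."""
    if not set(seq) <= _VALID:
        bad = sorted(set(seq) - _VALID)
        raise ValueError(f"invalid characters in sequence: {bad}")
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class KmerIndex:
    """Positions of every (N-free) k-mer of one fragment."""

    k: int
    positions: dict[str, list[int]] = field(default_factory=dict)


@dataclass(frozen=True)
class SeedPair:
    """One matched inverted-repeat seed.

    ``left_start`` / ``right_start`` are 0-based fragment positions of
    the two words; ``mis`` is 1 when the pair carries one interior
    mismatch whose position on the left word is ``mispos`` (0-based,
    fragment coordinates).
    """

    left_start: int
    right_start: int
    tir_length: int
    mis: int = 0
    mispos: int | None = None


def build_kmer_index(fragment: GenomeFragment, k: int = 10) -> KmerIndex:
    """Index every overlapping k-mer of ``fragment``; windows with N are skipped."""
    seq = fragment.sequence
    positions: dict[str, list[int]] = {}
    # track the most recent N so windows containing it can be skipped in O(1)
    last_n = -1
    for i, base in enumerate(seq):
        if base == "N":
            last_n = i
        if i < k - 1:
            continue
        start = i - k + 1
        if last_n >= start:
            continue
        positions.setdefault(seq[start : i + 1], []).append(start)
    return KmerIndex(k=k, positions=positions)


def is_low_complexity(
    tir: str,
    run_min: int = 8,
    composition_min_pct: float = 20.0,
) -> bool:
    """True when a TIR is too simple to be trusted as a real terminal repeat.

    A TIR is low complexity when it contains a homopolymer run of at
    least ``run_min`` bp, a perfect dinucleotide (two distinct bases)
    stretch of at least ``run_min`` bp, or when its G+C or A+T content
    falls below ``composition_min_pct`` percent.
    """
    n = len(tir)
    # homopolymer run
    run = 1
    for i in range(1, n):
        run = run + 1 if tir[i] == tir[i - 1] else 1
        if run >= run_min:
            return True
    # dinucleotide stretch: period-2 repetition of two distinct bases
    run = 2
    for i in range(2, n):
        run = run + 1 if tir[i] == tir[i - 2] else 2
        if run >= run_min and tir[i] != tir[i - 1]:
            return True
    gc = sum(1 for b in tir if b in "GC")
    at = sum(1 for b in tir if b in "AT")
    if 100.0 * gc / n < composition_min_pct:
        return True
    if 100.0 * at / n < composition_min_pct:
        return True
    return False


def _interior_variants(word: str) -> list[tuple[int, str]]:
    """All single-substitution variants of ``word`` at interior positions.

    Returns (position, variant) pairs; terminal positions are excluded
    because a mismatch at the very first or last TIR base is not
    accepted.
    """
    out = []
    k = len(word)
    for j in range(1, k - 1):
        orig = word[j]
        for b in _BASES:
            if b != orig:
                out.append((j, word[:j] + b + word[j + 1 :]))
    return out


def find_seed_pairs(
    index: KmerIndex,
    fragment: GenomeFragment,
    min_length: int = 50,
    max_length: int = 800,
    max_mismatch: int = 1,
    complexity_filter: bool = True,
    run_min: int = 8,
    composition_min_pct: float = 20.0,
) -> list[SeedPair]:
    """Enumerate every inverted-repeat seed pair of one fragment.

    A pair (p, q) is reported when fragment[q:q+k] equals the reverse
    complement of fragment[p:p+k] exactly, or differs from it at exactly
    one interior position; the element span q + k - p must lie in
    [min_length, max_length] and the two words must not overlap
    (q >= p + k).  Output is sorted by (left_start, right_start).
    """
    k = index.k
    seq = fragment.sequence
    n = len(seq)
    low: dict[int, bool] = {}

    def is_low(pos: int) -> bool:
        if pos not in low:
            low[pos] = is_low_complexity(
                seq[pos : pos + k], run_min=run_min,
                composition_min_pct=composition_min_pct,
            )
        return low[pos]

    seeds: list[SeedPair] = []
    for p in range(n - k + 1):
        word = seq[p : p + k]
        if "N" in word:
            continue
        if complexity_filter and is_low(p):
            continue
        target = reverse_complement(word)
        lookups: list[tuple[str, int | None]] = [(target, None)]
        if max_mismatch >= 1:
            # a mismatch at position j of the right word sits at
            # position k-1-j of the left word
            lookups.extend(
                (variant, p + k - 1 - j) for j, variant in _interior_variants(target)
            )
        for variant, mispos in lookups:
            for q in index.positions.get(variant, ()):
                if q < p + k:
                    continue
                span = q + k - p
                if span < min_length or span > max_length:
                    continue
                if complexity_filter and is_low(q):
                    continue
                if mispos is None:
                    seeds.append(SeedPair(p, q, k))
                else:
                    seeds.append(SeedPair(p, q, k, mis=1, mispos=mispos))
    seeds.sort(key=lambda s: (s.left_start, s.right_start, s.mis))
    return seeds
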