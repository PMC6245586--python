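"""Seeded synthetic genomes with implanted MITEs and a truth table.

The generator emulates the canonical MITE structure: a target site
duplication (TSD) written identically on both sides of an element made
of a left terminal inverted repeat (TIR), an internal sequence and the
reverse complement of the left TIR, optionally with one interior TIR
mismatch and per-copy decay of the internal region.

Implanted elements are made *structurally unambiguous* so a truth table
can be compared against detections base-for-base:

* TIRs are rejection-sampled so every 10-mer window passes the
  low-complexity filter (otherwise the seed stage would drop them by
  design, not by accident);
* the bases just inside and just outside the element are adjusted so
  the inverted repeat neither extends into the internal region nor past
  the TSD by chance (a self-complementary TSD such as TA *always*
  extends the repeat by its palindromic depth; anything beyond that is
  clamped);
* the junction neighbourhood is scrubbed of coincidental words that
  would be mistaken for a TSD at a wrong trim offset.

These guarantees are what let recovery tests assert exact coordinates;
real genomes offer no such cleanliness, which is why pipeline
thresholds are exercised, not calibrated, on synthetic data.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import PlacementError
from .fasta_io import SequenceRecord
from .seed_search import is_low_complexity, reverse_complement

logger = logging.getLogger(__name__)

_BASES = "ACGT"
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass
class ImplantSpec:
    """One family of elements to implant.

    ``mismatch`` may be a single flag (applied to every copy) or one
    flag per copy.  ``decay`` is the per-base substitution rate applied
    to the internal region of each copy.  ``positions`` pins absolute
    element start coordinates; otherwise placement is random and
    non-overlapping.  ``duplicate_flanks`` > 0 writes an identical
    flanking context of that length around every copy, emulating a
    segmental duplication rather than a transposition.
    """

    tir_length: int
    total_length: int
    tsd: str
    n_copies: int = 1
    mismatch: bool | Sequence[bool] = False
    decay: float = 0.0
    positions: Sequence[int] | None = None
    family: str | None = None
    duplicate_flanks: int = 0

    @property
    def is_valid(self) -> bool:
        """Whether the spec satisfies the structural constraints of a MITE."""
        return (
            self.tir_length >= 10
            and 50 <= self.total_length <= 800
            and 2 <= len(self.tsd) <= 10
            and (len(self.tsd) != 2 or self.tsd == "TA")
        )

    def mismatch_flags(self) -> list[bool]:
        if isinstance(self.mismatch, bool):
            return [self.mismatch] * self.n_copies
        flags = list(self.mismatch)
        if len(flags) != self.n_copies:
            raise ValueError("one mismatch flag per copy is required")
        return flags


@dataclass
class ImplantTruth:
    """Truth-table row for one implanted copy (0-based half-open coordinates)."""

    record_id: str
    start: int
    end: int
    tir_length: int
    tsd: str
    family: str
    mismatch: bool
    is_valid: bool
    element: str = field(repr=False, default="")


def _as_rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _random_bases(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list(_BASES), size=length, p=probs))


def random_genome(
    length: int, gc_fraction: float = 0.5, seed: int | np.random.Generator = 0,
    record_id: str = "synthetic_1",
) -> SequenceRecord:
    """A reproducible random chromosome with the requested GC fraction."""
    if length <= 0:
        raise ValueError("genome length must be positive")
    rng = _as_rng(seed)
    return SequenceRecord(
        id=record_id,
        description="synthetic random genome",
        sequence=_random_bases(rng, length, gc_fraction),
    )


def _sample_tir(rng: np.random.Generator, length: int, k: int = 10) -> str:
    """A TIR whose every k-window (on both strands) passes the complexity filter."""
    while True:
        tir = _random_bases(rng, length)
        windows = [tir[i : i + k] for i in range(max(1, len(tir) - k + 1))]
        rc = reverse_complement(tir)
        windows += [rc[i : i + k] for i in range(max(1, len(rc) - k + 1))]
        if len(tir) >= k and any(is_low_complexity(w) for w in windows):
            continue
        return tir


def _palindromic_depth(tsd: str) -> int:
    """How far the TSD junction is self-complementary.

    Depth d means the first d bases of the right TSD copy pair with the
    last d bases of the left copy in an inverted repeat, so the seed
    search absorbs d extra bases per side into the TIR.
    """
    L = len(tsd)
    d = 0
    while d < L and tsd[L - 1 - d] == _COMP[tsd[d]]:
        d += 1
    return d


def make_mite(
    spec: ImplantSpec,
    seed: int | np.random.Generator = 0,
    mismatch: bool | None = None,
) -> tuple[str, dict]:
    """Generate one copy: TSD + left TIR + internal + revcomp(TIR) + TSD.

    Returns the full text (TSDs included) and metadata describing the
    element geometry within it.
    """
    rng = _as_rng(seed)
    internal_len = spec.total_length - 2 * spec.tir_length
    if internal_len < 0:
        raise ValueError(
            f"total_length {spec.total_length} cannot hold two TIRs of "
            f"{spec.tir_length} bp"
        )
    tir = _sample_tir(rng, spec.tir_length)
    internal = _random_bases(rng, internal_len)
    want_mismatch = spec.mismatch_flags()[0] if mismatch is None else mismatch
    seq, meta = _assemble_copy(spec, tir, internal, want_mismatch, rng)
    return seq, meta


def _clamp_internal(internal: str, rng: np.random.Generator) -> str:
    """Stop the inverted repeat from extending into the internal region.

    The two outermost internal base pairs are resampled until neither
    pairs with its opposite number, so the repeat can extend inward
    neither perfectly nor via a single bridged mismatch and the
    detected TIR length equals the implanted one.
    """
    bases = list(internal)
    n = len(bases)
    pairs = [(0, n - 1)] if n in (2, 3) else [(0, n - 1), (1, n - 2)] if n >= 4 else []
    for i, j in pairs:
        while bases[i] == _COMP[bases[j]]:
            bases[i] = rng.choice(list(_BASES))
    return "".join(bases)


def _assemble_copy(
    spec: ImplantSpec,
    tir: str,
    internal: str,
    mismatch: bool,
    rng: np.random.Generator,
) -> tuple[str, dict]:
    if spec.decay > 0 and internal:
        bases = list(internal)
        for i in range(len(bases)):
            if rng.random() < spec.decay:
                bases[i] = rng.choice([b for b in _BASES if b != bases[i]])
        internal = "".join(bases)
    internal = _clamp_internal(internal, rng)
    right = reverse_complement(tir)
    mispos_element: int | None = None
    if mismatch:
        if spec.tir_length < 3:
            raise ValueError("a TIR mismatch needs an interior position")
        # interior left-arm offsets, excluding k-1 = 9: a mismatch there
        # leaves no seed window anchored at the element start, making
        # the boundary structurally undetectable with 10-mer seeds
        offsets = [o for o in range(1, spec.tir_length - 1) if o != 9]
        mispos_element = int(rng.choice(offsets))
        j = spec.tir_length - 1 - mispos_element  # position on the right arm
        old = right[j]
        new = rng.choice([b for b in _BASES if b != old])
        right = right[:j] + new + right[j + 1 :]
    element = tir + internal + right
    meta = {
        "tir": tir,
        "element": element,
        "element_length": len(element),
        "tsd": spec.tsd,
        "mismatch": mismatch,
        "mispos_element": mispos_element,
    }
    return spec.tsd + element + spec.tsd, meta


def _junction_extension(seq: bytearray, a: int, b: int, k: int = 10) -> int:
    """How far the inverted-repeat search can push the element start
    outward of the true boundary ``a`` at this junction.

    Walks the base-pair match pattern m[t] = (seq[a-1-t] pairs with
    seq[b+t]) and replays the seed/merge reachability rules: a window
    j bases outward is a seed when its outward stretch holds no
    mismatch, or exactly one at an interior window position, and
    windows chain across single-step and bridged two-step gaps.
    """
    m: list[bool] = []
    for t in range(k + 6):
        p, q = a - 1 - t, b + t
        if p < 0 or q >= len(seq):
            break
        m.append(chr(seq[p]) == _COMP[chr(seq[q])])

    def is_seed(j: int) -> bool:
        zeros = [t for t in range(max(0, j - k), j) if not m[t]]
        if not zeros:
            return True
        return len(zeros) == 1 and 1 <= (j - 1 - zeros[0]) <= k - 2

    reach = 0
    reachable = {-1: True, 0: True}  # j=0 windows sit inside the TIR itself
    for j in range(1, len(m) + 1):
        reachable[j] = is_seed(j) and (
            reachable.get(j - 1, False) or reachable.get(j - 2, False)
        )
        if reachable[j]:
            reach = j
    return reach


def _find_junction_issue(
    seq: bytearray, a: int, b: int, tsd_len: int, reach: int
) -> tuple[int, int, int] | None:
    """Locate a junction word that would confuse the TSD caller.

    The TSD caller probes trimmed boundaries from the detected element
    start (up to ``reach`` bases outside the true one) inward; any
    valid-looking TSD word at an outward offset 1..reach, or a
    longer-than-real match at the true boundary, would make it stop at
    the wrong trim.  Returns (left window start, right window start, L)
    of the first such word, or None when the junction is clean.
    """
    n = len(seq)
    for j in range(reach + 1):
        s0, e0 = a - j, b + j
        for L in range(10, 1, -1):
            if j == 0 and L <= tsd_len:
                break  # the genuine TSD (and words it shadows) are fine
            if s0 - L < 0 or e0 + L > n:
                continue
            if seq[s0 - L : s0] == seq[e0 : e0 + L]:
                word = seq[s0 - L : s0].decode()
                if L > 2 or word == "TA":
                    return (s0 - L, e0, L)
    return None


def _sanitize_junction(
    seq: bytearray,
    a: int,
    b: int,
    tsd: str,
    rng: np.random.Generator,
    protected: tuple[int, int],
) -> None:
    """Make the TSD call at this junction unambiguous.

    Clamps chance extension of the inverted repeat past the TSD into
    the background and scrubs coincidental TSD-like words at every
    boundary offset the detector can reach, flipping only bases outside
    the ``protected`` interval.  When the TSD text itself produces an
    alternative call (e.g. CGATG, whose junction reads as a GAT
    duplication one base out), no flippable base exists and a warning
    is logged: the detected boundary will shift by a fixed amount.
    """
    tsd_len = len(tsd)
    lo, hi = protected

    def flip(pos: int) -> bool:
        if not (0 <= pos < len(seq)) or lo <= pos < hi:
            return False
        old = chr(seq[pos])
        seq[pos] = ord(rng.choice([x for x in _BASES if x != old]))
        return True

    for _ in range(100):
        # force the two base pairs just past the TSD copies to mismatch,
        # so the repeat cannot extend into plain background
        for t in (tsd_len, tsd_len + 1):
            p, q = a - 1 - t, b + t
            if 0 <= p and q < len(seq) and chr(seq[p]) == _COMP[chr(seq[q])]:
                if not flip(p):
                    flip(q)
        reach = _junction_extension(seq, a, b)
        issue = _find_junction_issue(seq, a, b, tsd_len, reach)
        if issue is None:
            return
        left_start, right_start, L = issue
        fixed = False
        for pos in range(left_start, left_start + L):
            if pos < a - tsd_len and flip(pos):
                fixed = True
                break
        if not fixed:
            for pos in range(right_start, right_start + L):
                if pos >= b + tsd_len and flip(pos):
                    fixed = True
                    break
        if not fixed:
            logger.warning(
                "TSD %r yields an intrinsically ambiguous junction at %d-%d; "
                "the detected boundary will shift", tsd, a, b
            )
            return


def implant(
    genome: SequenceRecord,
    specs: Sequence[ImplantSpec],
    seed: int | np.random.Generator = 0,
    min_separation: int = 900,
    edge_margin: int = 150,
) -> tuple[SequenceRecord, list[ImplantTruth]]:
    """Write elements into a genome and return the mutated genome plus truth.

    Copies overwrite the background sequence (coordinates are therefore
    stable), are kept at least ``min_separation`` bp apart and away from
    the chromosome edges, and have their junctions sanitized so the
    truth table is unambiguous.
    """
    rng = _as_rng(seed)
    seq = bytearray(genome.sequence, "ascii")
    n = len(seq)
    placed: list[tuple[int, int]] = []  # block intervals already used
    truth: list[ImplantTruth] = []

    def reserve(block_len: int, pinned: int | None) -> int:
        if pinned is not None:
            start = pinned
            if start < edge_margin or start + block_len > n - edge_margin:
                raise PlacementError(f"pinned position {pinned} does not fit")
            return start
        for _ in range(2000):
            start = int(rng.integers(edge_margin, n - edge_margin - block_len))
            if all(
                start + block_len + min_separation <= lo
                or start >= hi + min_separation
                for lo, hi in placed
            ):
                return start
        raise PlacementError(
            f"cannot place a {block_len} bp block with separation "
            f"{min_separation} in a {n} bp genome"
        )

    for spec_idx, spec in enumerate(specs):
        family = spec.family or f"fam{spec_idx + 1}"
        internal_len = spec.total_length - 2 * spec.tir_length
        if internal_len < 0:
            raise ValueError(
                f"spec {family}: total_length cannot hold two TIRs"
            )
        master_tir = _sample_tir(rng, spec.tir_length)
        master_internal = _random_bases(rng, internal_len)
        shared_flanks: tuple[str, str] | None = None
        if spec.duplicate_flanks > 0:
            shared_flanks = (
                _random_bases(rng, spec.duplicate_flanks),
                _random_bases(rng, spec.duplicate_flanks),
            )
        flags = spec.mismatch_flags()
        for copy_idx in range(spec.n_copies):
            copy_seq, meta = _assemble_copy(
                spec, master_tir, master_internal, flags[copy_idx], rng
            )
            flank_l, flank_r = shared_flanks or ("", "")
            block = flank_l + copy_seq + flank_r
            pinned = (
                spec.positions[copy_idx] - len(spec.tsd) - len(flank_l)
                if spec.positions is not None
                else None
            )
            start = reserve(len(block), pinned)
            seq[start : start + len(block)] = block.encode("ascii")
            placed.append((start, start + len(block)))
            elem_start = start + len(flank_l) + len(spec.tsd)
            elem_end = elem_start + meta["element_length"]
            if shared_flanks is not None:
                protected = (start, start + len(block))
            else:
                protected = (elem_start - len(spec.tsd), elem_end + len(spec.tsd))
            _sanitize_junction(seq, elem_start, elem_end, spec.tsd, rng, protected)
            truth.append(
                ImplantTruth(
                    record_id=genome.id,
                    start=elem_start,
                    end=elem_end,
                    tir_length=spec.tir_length,
                    tsd=spec.tsd,
                    family=family,
                    mismatch=flags[copy_idx],
                    is_valid=spec.is_valid,
                    element=bytes(seq[elem_start:elem_end]).decode(),
                )
            )

    truth.sort(key=lambda t: t.start)
    mutated = SequenceRecord(
        id=genome.id,
        description=(genome.description + " with implants").strip(),
        sequence=seq.decode("ascii"),
    )
    return mutated, truth


def truth_to_tsv(truth: Sequence[ImplantTruth], path) -> None:
    """Write the truth table as TSV with 1-based inclusive coordinates."""
    with open(path, "w") as fh:
        fh.write(
            "record_id\tstart\tend\ttir_length\ttsd\tfamily\tmismatch\tis_valid\n"
        )
        for t in truth:
            fh.write(
                f"{t.record_id}\t{t.start + 1}\t{t.end}\t{t.tir_length}\t"
                f"{t.tsd}\t{t.family}\t{int(t.mismatch)}\t{int(t.is_valid)}\n"
            )


def make_training_sets(
    n_pos: int,
    n_neg: int,
    motif: str = "GATCCA",
    enrichment: float = 32.0,
    seed: int | np.random.Generator = 0,
    seq_length: int = 200,
) -> tuple[list[str], list[str]]:
    """Motif-enriched positive sequences versus uniform null sequences.

    Each positive sequence is uniform background in which extra copies
    of ``motif`` are planted so that the per-window occurrence rate is
    ``enrichment`` times the uniform expectation; the null set is plain
    uniform background.  ``enrichment`` = 1 plants nothing.
    """
    if enrichment < 1:
        raise ValueError("enrichment must be at least 1")
    rng = _as_rng(seed)
    m = len(motif)
    n_windows = seq_length - m + 1
    rate = (enrichment - 1) / (4 ** m)

    def positive_seq() -> str:
        bases = list(_random_bases(rng, seq_length))
        n_extra = rng.binomial(n_windows, rate)
        taken: list[int] = []
        for _ in range(int(n_extra)):
            for _attempt in range(50):
                pos = int(rng.integers(0, n_windows))
                if all(abs(pos - p) >= m for p in taken):
                    bases[pos : pos + m] = motif
                    taken.append(pos)
                    break
        return "".join(bases)

    positives = [positive_seq() for _ in range(n_pos)]
    nulls = [_random_bases(rng, seq_length) for _ in range(n_neg)]
    return positives, nulls
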