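"""Brute-force inverted-repeat scanner used as an independent oracle.

The production code finds seeds through a hash index of k-mers and
chains them per anti-diagonal.  This oracle takes a different route:
for every anti-diagonal C it materialises the base-pairing array
m[p] = (seq[p] pairs with seq[C-p]) with numpy and reads seeds straight
off sliding-window sums — every window of k consecutive entries that is
all-ones (perfect) or has exactly one zero at an interior offset
(imperfect).  Merging semantics (chaining, bridging, splitting on a
second mismatch position, same-end suppression) are then replayed on
those seeds in plain form.
"""
from __future__ import annotations

import numpy as np

from mitescan.seed_search import is_low_complexity

_ENC = np.zeros(256, dtype=np.uint8)
for i, base in enumerate("ACGT", start=1):
    _ENC[ord(base)] = i
_COMP_ENC = np.zeros(256, dtype=np.uint8)
for x, y in zip("ACGT", "TGCA"):
    _COMP_ENC[ord(x)] = _ENC[ord(y)]


def oracle_seeds(
    seq: str,
    k: int = 10,
    min_length: int = 50,
    max_length: int = 800,
    max_mismatch: int = 1,
    complexity_filter: bool = True,
) -> list[tuple[int, int, int, int | None]]:
    """All (left, right, mis, mispos) seed pairs by exhaustive pairing."""
    L = len(seq)
    raw = np.frombuffer(seq.encode(), dtype=np.uint8)
    enc = _ENC[raw]          # 0 encodes N / unknown -> never matches
    comp = _COMP_ENC[raw]
    kernel = np.ones(k, dtype=np.int64)

    low_cache: dict[int, bool] = {}

    def low(pos: int) -> bool:
        if pos not in low_cache:
            low_cache[pos] = is_low_complexity(seq[pos : pos + k])
        return low_cache[pos]

    seeds: list[tuple[int, int, int, int | None]] = []
    for C in range(2 * k - 1, 2 * L - 2 * k + 1):
        # left windows i with span C+1-2i in [min_length, max_length]
        # and non-overlapping arms (right start C+1-k-i >= i+k)
        i_lo = max(0, -((-(C + 1 - max_length)) // 2))  # ceil
        i_hi = min((C + 1 - min_length) // 2, (C + 1 - 2 * k) // 2, L - k)
        if i_hi < i_lo:
            continue
        p_lo, p_hi = i_lo, i_hi + k - 1  # positions needed on the left side
        if C - p_lo > L - 1:
            p_lo = C - (L - 1)
            i_lo = max(i_lo, p_lo)
            if i_hi < i_lo:
                continue
        p = np.arange(p_lo, p_hi + 1)
        m = (enc[p] != 0) & (enc[p] == comp[C - p])
        sums = np.convolve(m.astype(np.int64), kernel, mode="valid")
        starts = p_lo + np.arange(len(sums))
        valid = (starts >= i_lo) & (starts <= i_hi)
        for idx in np.nonzero(valid & (sums == k))[0]:
            i = int(starts[idx])
            j = C + 1 - k - i
            if complexity_filter and (low(i) or low(j)):
                continue
            seeds.append((i, j, 0, None))
        if max_mismatch >= 1:
            zero_pos = np.convolve(
                (~m).astype(np.int64) * p, kernel, mode="valid"
            )
            for idx in np.nonzero(valid & (sums == k - 1))[0]:
                i = int(starts[idx])
                z = int(zero_pos[idx])  # the single zero's position
                if not (i + 1 <= z <= i + k - 2):
                    continue  # terminal mismatch on the left word
                if "N" in seq[i : i + k]:
                    continue
                j = C + 1 - k - i
                if "N" in seq[j : j + k]:
                    continue
                if complexity_filter and (low(i) or low(j)):
                    continue
                seeds.append((i, j, 1, z))
    seeds.sort()
    return seeds


def oracle_candidates(
    seq: str,
    k: int = 10,
    min_length: int = 50,
    max_length: int = 800,
    max_mismatch: int = 1,
    complexity_filter: bool = True,
) -> set[tuple[int, int, int, int]]:
    """Maximal merged inverted repeats as (start, end, tir_length, mis)."""
    seeds = oracle_seeds(
        seq, k, min_length, max_length, max_mismatch, complexity_filter
    )
    by_diag: dict[int, list[tuple[int, int, int, int | None]]] = {}
    for s in seeds:
        by_diag.setdefault(s[0] + s[1], []).append(s)

    merged: list[tuple[int, int, int, int]] = []

    def close(chain: list[tuple[int, int, int, int | None]]) -> None:
        first, last = chain[0], chain[-1]
        mis = 1 if any(s[2] for s in chain) else 0
        merged.append((first[0], first[1] + k, last[0] + k - first[0], mis))

    for diag in sorted(by_diag):
        chain: list[tuple[int, int, int, int | None]] = []
        mispos: int | None = None
        for s in sorted(by_diag[diag]):
            if chain:
                gap = s[0] - chain[-1][0]
                linked = gap == 1 or (gap == 2 and bool(s[2]) != bool(chain[-1][2]))
                if linked and s[2] and mispos is not None and s[3] != mispos:
                    linked = False
            else:
                linked = False
            if linked:
                chain.append(s)
                if s[2]:
                    mispos = s[3]
            else:
                if chain:
                    close(chain)
                chain = [s]
                mispos = s[3] if s[2] else None
        if chain:
            close(chain)

    best: dict[int, tuple[int, int, int, int]] = {}
    for cand in merged:
        start, end, tir, mis = cand
        cur = best.get(end)
        if cur is None or (tir, -start) > (cur[2], -cur[0]):
            best[end] = cand
    return set(best.values())
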