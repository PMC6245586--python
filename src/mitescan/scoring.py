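"""Log-ratio 6-mer likelihood scoring of MITE candidates.

Structural filters alone cannot distinguish a real MITE from any other
inverted-repeat locus, so candidates are scored against two training
sets: a positive set M of trusted MITE sequences and a null set N of
structural look-alikes.  Each 6-mer word s receives

    F(s) = log2( Pr(s | M) / Pr(s | N) )

with add-``pseudocount`` (Laplace) smoothing of both word distributions
— the raw ratio is undefined for words unseen in N.  A sequence of
length n is scored by the mean of F over its n-5 overlapping words, so
the score is length-free; candidates scoring strictly above the
threshold (default 0, i.e. more likely under M than N) are retained.
"""
from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .candidate_assembly import MiteCandidate
from .errors import FormatError, TrainingError

logger = logging.getLogger(__name__)

_BASES = "ACGT"


@dataclass
class LogRatioModel:
    """Per-word log2 likelihood-ratio table."""

    word_length: int = 6
    pseudocount: float = 1.0
    log_ratios: dict[str, float] = field(default_factory=dict)
    positive_total: float | None = None
    null_total: float | None = None


def _count_words(sequences: Iterable[str], k: int) -> tuple[dict[str, int], int]:
    counts: dict[str, int] = {}
    total = 0
    for seq in sequences:
        for i in range(len(seq) - k + 1):
            word = seq[i : i + k]
            if "N" in word:
                continue
            counts[word] = counts.get(word, 0) + 1
            total += 1
    return counts, total


def train_model(
    positive: Sequence[str],
    null: Sequence[str],
    word_length: int = 6,
    pseudocount: float = 1.0,
) -> LogRatioModel:
    """Train the log-ratio table from positive and null sequence sets."""
    if not positive or not null:
        raise TrainingError("both the positive and the null set must be non-empty")
    if pseudocount <= 0:
        raise TrainingError(
            "pseudocount must be positive: the likelihood ratio is undefined "
            "for words unseen in the null set"
        )
    for name, seqs in (("positive", positive), ("null", null)):
        short = [s for s in seqs if len(s) < word_length]
        if short:
            raise TrainingError(
                f"{len(short)} {name} sequences are shorter than the word "
                f"length ({word_length})"
            )
    pos_counts, pos_total = _count_words(positive, word_length)
    null_counts, null_total = _count_words(null, word_length)
    n_words = 4 ** word_length
    pos_denom = pos_total + pseudocount * n_words
    null_denom = null_total + pseudocount * n_words

    log_ratios: dict[str, float] = {}
    for word_tuple in itertools.product(_BASES, repeat=word_length):
        word = "".join(word_tuple)
        p_m = (pos_counts.get(word, 0) + pseudocount) / pos_denom
        p_n = (null_counts.get(word, 0) + pseudocount) / null_denom
        log_ratios[word] = math.log2(p_m / p_n)
    logger.info(
        "trained %d-mer model: %d positive words, %d null words",
        word_length,
        pos_total,
        null_total,
    )
    return LogRatioModel(
        word_length=word_length,
        pseudocount=pseudocount,
        log_ratios=log_ratios,
        positive_total=pos_denom,
        null_total=null_denom,
    )


def score_sequence(model: LogRatioModel, seq: str) -> float:
    """Mean F over the overlapping words of ``seq``.

    Words containing N are excluded from both the sum and the divisor;
    a sequence whose every window contains N scores 0.
    """
    k = model.word_length
    if len(seq) < k:
        raise ValueError(
            f"sequence of length {len(seq)} is shorter than the word length {k}"
        )
    total = 0.0
    n_windows = 0
    ratios = model.log_ratios
    for i in range(len(seq) - k + 1):
        word = seq[i : i + k]
        f = ratios.get(word)
        if f is None:  # window containing N (or foreign characters)
            continue
        total += f
        n_windows += 1
    return total / n_windows if n_windows else 0.0


def filter_by_score(
    candidates: list[MiteCandidate],
    model: LogRatioModel,
    threshold: float = 0.0,
) -> list[MiteCandidate]:
    """Score every candidate and keep those scoring strictly above ``threshold``."""
    retained = []
    for cand in candidates:
        cand.score = score_sequence(model, cand.sequence or "")
        if cand.score > threshold:
            retained.append(cand)
    return retained


def save_model(model: LogRatioModel, path: str | Path) -> None:
    """Write the model as plain text: two header lines, one WORD\\tF line per word."""
    with open(path, "w") as fh:
        fh.write(f"#word_length\t{model.word_length}\n")
        fh.write(f"#pseudocount\t{model.pseudocount:g}\n")
        for word in sorted(model.log_ratios):
            fh.write(f"{word}\t{model.log_ratios[word]:.6f}\n")


def load_model(path: str | Path) -> LogRatioModel:
    """Read a model written by :func:`save_model`."""
    path = Path(path)
    word_length: int | None = None
    pseudocount: float | None = None
    log_ratios: dict[str, float] = {}
    for line_no, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        if line.startswith("#"):
            key, _, value = line[1:].partition("\t")
            if key == "word_length":
                word_length = int(value)
            elif key == "pseudocount":
                pseudocount = float(value)
            continue
        word, _, value = line.partition("\t")
        log_ratios[word] = float(value)
    if word_length is None or pseudocount is None:
        raise FormatError(f"{path} is missing the model header lines")
    if len(log_ratios) != 4 ** word_length:
        raise FormatError(
            f"{path} holds {len(log_ratios)} words, expected {4 ** word_length}"
        )
    return LogRatioModel(
        word_length=word_length, pseudocount=pseudocount, log_ratios=log_ratios
    )
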