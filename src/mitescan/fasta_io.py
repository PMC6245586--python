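"""FASTA input, chromosome fragmenting, and report writing.

Internally every coordinate is 0-based half-open; the TSV report and the
FASTA deflines use 1-based inclusive coordinates, which is what genome
browsers and annotation pipelines expect.
"""
from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable

from Bio import SeqIO

from .errors import ConfigError, FormatError, InputError

if TYPE_CHECKING:  # pragma: no cover - import cycle guard
    from .candidate_assembly import MiteCandidate
    from .family_selection import MiteFamily

logger = logging.getLogger(__name__)

_NON_ACGTN = re.compile(r"[^ACGTN]")

REPORT_COLUMNS = [
    "record_id",
    "start",
    "end",
    "tir_length",
    "tsd",
    "mismatch_position",
    "score",
    "family_id",
    "superfamily",
    "is_representative",
]


@dataclass
class SequenceRecord:
    """One FASTA record: id, remainder of the header, uppercase sequence."""

    id: str
    description: str
    sequence: str


@dataclass
class GenomeFragment:
    """A chunk of one chromosome together with its absolute offset."""

    record_id: str
    offset: int
    sequence: str


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects.

    Sequences are uppercased; any character outside {A,C,G,T,N} is
    replaced by N (with a logged warning) so real genomes with IUPAC
    ambiguity codes or masking characters still parse.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"FASTA file not found: {path}")
    records: list[SequenceRecord] = []
    replaced = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"record {rec.id!r} in {path} has an empty sequence")
        cleaned, n_sub = _NON_ACGTN.subn("N", seq)
        replaced += n_sub
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        records.append(SequenceRecord(id=rec.id, description=desc, sequence=cleaned))
    if not records:
        raise FormatError(f"no FASTA records found in {path}")
    if replaced:
        logger.warning(
            "%d non-ACGTN characters replaced by N while reading %s", replaced, path
        )
    return records


def write_fasta(records: Iterable[tuple[str, str, str]], path: str | Path) -> None:
    """Write (id, description, sequence) triples as FASTA, 70 bp per line."""
    with open(path, "w") as fh:
        for rid, desc, seq in records:
            header = f">{rid} {desc}".rstrip()
            fh.write(header + "\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def fragment_sequence(
    record: SequenceRecord,
    fragment_length: int = 10000,
    overlap: int = 800,
) -> list[GenomeFragment]:
    """Cut a chromosome into overlapping fragments.

    Consecutive fragments overlap by exactly ``overlap`` bp (except
    possibly the last), so every window up to ``overlap`` bp long lies
    entirely inside at least one fragment and no element shorter than
    the overlap is split across all fragments containing it.
    """
    if fragment_length <= overlap:
        raise ConfigError(
            f"fragment_length ({fragment_length}) must exceed overlap ({overlap})"
        )
    seq = record.sequence
    step = fragment_length - overlap
    fragments: list[GenomeFragment] = []
    offset = 0
    while offset + fragment_length < len(seq):
        fragments.append(
            GenomeFragment(record.id, offset, seq[offset : offset + fragment_length])
        )
        offset += step
    fragments.append(GenomeFragment(record.id, offset, seq[offset:]))
    return fragments


def _candidate_rows(
    candidates: "Iterable[MiteCandidate]",
    family_of: dict[str, int],
    representative_ids: set[str],
    superfamily_of: dict[str, str],
) -> list[dict]:
    rows = []
    for c in candidates:
        rows.append(
            {
                "record_id": c.record_id,
                "start": c.start + 1,  # 1-based inclusive
                "end": c.end,
                "tir_length": c.tir_length,
                "tsd": c.tsd or "",
                "mismatch_position": (c.mispos + 1) if c.mispos is not None else "",
                "score": f"{c.score:.6f}" if c.score is not None else "",
                "family_id": family_of.get(c.id, ""),
                "superfamily": superfamily_of.get(c.id, ""),
                "is_representative": 1 if c.id in representative_ids else 0,
            }
        )
    return rows


def write_outputs(
    candidates: "list[MiteCandidate]",
    families: "list[MiteFamily]",
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write all pipeline artifacts.

    Produces a FASTA of every retained element, a FASTA of the family
    representatives, a TSV report (1-based inclusive coordinates) and a
    per-record superfamily count summary.  Returns the paths written.
    """
    from .family_selection import classify_superfamily

    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:  # pragma: no cover - depends on filesystem
        raise InputError(f"cannot create output directory {out_dir}: {exc}") from exc

    family_of: dict[str, int] = {}
    representative_ids: set[str] = set()
    for fam in families:
        for mid in fam.member_ids:
            family_of[mid] = fam.family_id
        representative_ids.add(fam.representative_id)

    superfamily_of = {
        c.id: classify_superfamily(c.tsd) if c.tsd else "Unknown" for c in candidates
    }

    paths = {
        "mites": out_dir / "mites.fasta",
        "representatives": out_dir / "representatives.fasta",
        "report": out_dir / "report.tsv",
        "superfamily_counts": out_dir / "superfamily_counts.tsv",
    }

    def defline(c: "MiteCandidate") -> tuple[str, str, str]:
        desc = (
            f"tir={c.tir_length} tsd={c.tsd or '.'} "
            f"superfamily={superfamily_of[c.id]} family={family_of.get(c.id, '.')}"
        )
        return (c.id, desc, c.sequence or "")

    write_fasta((defline(c) for c in candidates), paths["mites"])

    by_id = {c.id: c for c in candidates}
    reps = [by_id[f.representative_id] for f in families if f.representative_id in by_id]
    write_fasta((defline(c) for c in reps), paths["representatives"])

    rows = _candidate_rows(candidates, family_of, representative_ids, superfamily_of)
    with open(paths["report"], "w") as fh:
        fh.write("\t".join(REPORT_COLUMNS) + "\n")
        for row in rows:
            fh.write("\t".join(str(row[col]) for col in REPORT_COLUMNS) + "\n")

    counts: dict[tuple[str, str], int] = {}
    for c in candidates:
        key = (c.record_id, superfamily_of[c.id])
        counts[key] = counts.get(key, 0) + 1
    with open(paths["superfamily_counts"], "w") as fh:
        fh.write("record_id\tsuperfamily\tcount\n")
        for (rid, sf), n in sorted(counts.items()):
            fh.write(f"{rid}\t{sf}\t{n}\n")

    logger.info(
        "wrote %d elements, %d families to %s", len(candidates), len(families), out_dir
    )
    return paths
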