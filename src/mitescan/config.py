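"""Pipeline configuration.

All numeric defaults are the structural constants of the MITE model:
elements of 50-800 bp, terminal inverted repeats (TIRs) of at least 10 bp
with at most one interior mismatch, a 2-10 bp target site duplication
(TSD), and a 60 bp flank used for the segmental-duplication filter.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

from .errors import ConfigError


@dataclass
class PipelineConfig:
    """Tunable parameters of the detection pipeline.

    Attributes
    ----------
    k : int
        Seed word length; also the minimum TIR length reported.
    min_tir : int
        Minimum TIR length of a reported candidate (bp).
    min_length, max_length : int
        Total element span retained (left TIR start through right TIR
        end), in bp.
    max_mismatch : int
        Maximum number of TIR mismatches (0 or 1).
    fragment_length, overlap : int
        Chromosomes are scanned in fragments of ``fragment_length`` bp
        overlapping by ``overlap`` bp; the overlap must be at least
        ``max_length`` so no element is split across every fragment
        containing it.
    score_threshold : float
        Candidates with log-ratio score strictly greater than this are
        retained.
    flank : int
        Flank length (bp) extracted for the flanking-similarity filter.
    pident_min : float
        Minimum percent identity for a flank-filter partner hit.
    min_family_size : int
        Minimum connected-component size that forms a family.
    homopolymer_min : int
        Homopolymer / dinucleotide run length (bp) that marks a TIR as
        low complexity.
    composition_min_pct : float
        Minimum percentage of G+C and of A+T a TIR must contain.
    model_path : str or None
        Path to a trained scoring-model file.
    seed : int
        Seed for every source of randomness in the run.
    """

    k: int = 10
    min_tir: int = 10
    min_length: int = 50
    max_length: int = 800
    max_mismatch: int = 1
    fragment_length: int = 10000
    overlap: int = 800
    score_threshold: float = 0.0
    flank: int = 60
    pident_min: float = 80.0
    min_family_size: int = 3
    homopolymer_min: int = 8
    composition_min_pct: float = 20.0
    model_path: str | None = None
    seed: int = 1

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.fragment_length <= self.overlap:
            raise ConfigError(
                f"fragment_length ({self.fragment_length}) must exceed "
                f"overlap ({self.overlap})"
            )
        if self.overlap < self.max_length:
            raise ConfigError(
                f"overlap ({self.overlap}) must be at least max_length "
                f"({self.max_length}) so no element is split by fragmenting"
            )
        if not 0 <= self.max_mismatch <= 1:
            raise ConfigError("max_mismatch must be 0 or 1")
        if self.min_length > self.max_length:
            raise ConfigError("min_length must not exceed max_length")
        if self.k < 2:
            raise ConfigError("k must be at least 2")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - fields
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))
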