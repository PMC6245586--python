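"""End-to-end detection pipeline.

Stage order: read FASTA -> fragment/seed/merge/TSD assembly -> log-ratio
score filter -> flanking-similarity filter -> family network ->
representative selection -> report writing.  Identical inputs, config
and seed produce byte-identical outputs.
"""
from __future__ import annotations

import logging
from pathlib import Path

from .candidate_assembly import MiteCandidate, assemble_candidates
from .config import PipelineConfig
from .errors import MitescanError
from .family_selection import (
    MiteFamily,
    build_family_network,
    element_hits,
    flank_filter,
    flanked_hits,
    select_families,
)
from .fasta_io import read_fasta, write_outputs
from .scoring import LogRatioModel, filter_by_score, load_model, train_model
from .synthetic import ImplantSpec, _as_rng, _random_bases, make_mite

logger = logging.getLogger(__name__)

_DEFAULT_TSDS = ["TA", "TAA", "TTAG", "CGATG", "GATCCA", "TACGATCG"]


def default_synthetic_model(seed: int = 0, n: int = 150) -> LogRatioModel:
    """A fallback scoring model trained on synthetic structural elements.

    Positive examples are randomly generated TIR/internal/TIR elements,
    nulls are uniform random sequences.  Such a model knows nothing
    about real MITE word usage; it exists so the pipeline can run
    without user training data, and a warning is logged when it is
    used.  For real analyses train on curated MITE sequences.
    """
    rng = _as_rng(seed)
    positives = []
    for _ in range(n):
        spec = ImplantSpec(
            tir_length=int(rng.integers(10, 15)),
            total_length=int(rng.integers(100, 401)),
            tsd="TA",
        )
        _, meta = make_mite(spec, rng)
        positives.append(meta["element"])
    nulls = [_random_bases(rng, 200) for _ in range(n)]
    return train_model(positives, nulls)


class _Stage:
    """Context manager labelling pipeline errors with their stage."""

    def __init__(self, name: str):
        self.name = name

    def __enter__(self):
        logger.info("stage %s: started", self.name)
        return self

    def __exit__(self, exc_type, exc, tb):
        if exc is not None and isinstance(exc, MitescanError):
            raise type(exc)(f"[{self.name}] {exc}") from exc
        return False


def run_pipeline(
    genome_path: str | Path,
    config: PipelineConfig | None = None,
    out_dir: str | Path = "mitescan_out",
    model: LogRatioModel | None = None,
) -> dict:
    """Run detection end to end and write all artifacts to ``out_dir``.

    Returns a summary with per-stage candidate counts, the retained
    candidates, the families and the paths written.
    """
    cfg = config or PipelineConfig()

    with _Stage("input"):
        records = read_fasta(genome_path)
    chromosomes = {r.id: r for r in records}

    with _Stage("assembly"):
        candidates: list[MiteCandidate] = []
        for record in records:
            found = assemble_candidates(record, cfg)
            logger.info("stage assembly: %s -> %d candidates", record.id, len(found))
            candidates.extend(found)

    with _Stage("scoring"):
        if model is None:
            if cfg.model_path:
                model = load_model(cfg.model_path)
            else:
                logger.warning(
                    "no scoring model supplied; training a default synthetic "
                    "model (structure only, no real MITE word usage)"
                )
                model = default_synthetic_model(cfg.seed)
        scored = filter_by_score(candidates, model, cfg.score_threshold)
    logger.info("stage scoring: %d of %d candidates retained", len(scored), len(candidates))

    with _Stage("flank-filter"):
        hits = flanked_hits(scored, chromosomes, flank=cfg.flank)
        retained = flank_filter(scored, hits, pident_min=cfg.pident_min)
    logger.info(
        "stage flank-filter: %d of %d candidates retained", len(retained), len(scored)
    )

    with _Stage("families"):
        strict = element_hits(retained)
        graph = build_family_network(retained, strict)
        families: list[MiteFamily] = select_families(
            graph, retained, min_members=cfg.min_family_size
        )
    logger.info("stage families: %d families", len(families))

    with _Stage("output"):
        paths = write_outputs(retained, families, out_dir)

    return {
        "n_assembled": len(candidates),
        "n_scored": len(scored),
        "n_retained": len(retained),
        "n_families": len(families),
        "candidates": retained,
        "families": families,
        "paths": paths,
    }
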