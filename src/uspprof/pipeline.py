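"""End-to-end pipeline: parse -> patterns -> classify -> profiles -> tables.

This module owns the orchestration that the command-line tool and the
analysis drivers share.  ``run_pipeline`` is file-to-file; ``run_objects``
is the in-memory core that tests and the acceptance script call directly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import __version__
from .aggregation import (
    GenomeSummary,
    PatternFrequency,
    category_frame,
    category_table,
    genome_summary_frame,
    genome_usp_counts,
    pattern_frequencies,
    pattern_frequency_frame,
    profile_frame,
    site_pattern_frame,
    stratify_by_methylation,
)
from .architecture import SequenceProfile, build_profiles
from .cdsearch_io import (
    DEFAULT_USP_PSSM_ID,
    FeatureRecord,
    GenomeRecord,
    ProteinEntry,
    read_fasta,
    read_features,
    read_genome_metadata,
)
from .motif_classifier import DEFAULT_MOTIF, MotifSpec, classify_all
from .pattern_extraction import SitePattern, build_site_patterns

log = logging.getLogger("uspprof")

__all__ = ["RunConfig", "PipelineResult", "PipelineError", "run_objects", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failure, tagged with the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass(frozen=True)
class RunConfig:
    """Inputs, outputs and knobs for one full pipeline run."""

    features_path: Path
    fasta_path: Path
    metadata_path: Path
    out_dir: Path
    usp_pssm_ids: frozenset[int] = frozenset({DEFAULT_USP_PSSM_ID})
    motif: MotifSpec = DEFAULT_MOTIF
    genome_of_query: Optional[dict[str, str]] = None

    def __post_init__(self) -> None:
        paths = [Path(self.features_path), Path(self.fasta_path), Path(self.metadata_path)]
        if len({str(p) for p in paths}) != 3:
            raise ValueError("input paths must be distinct")


@dataclass
class PipelineResult:
    entries: list[ProteinEntry]
    records: list[FeatureRecord]
    patterns: list[SitePattern]
    profiles: list[SequenceProfile]
    genomes: list[GenomeRecord]
    summaries: list[GenomeSummary]
    frequencies: list[PatternFrequency]
    methylation: pd.DataFrame

    @property
    def category_counts(self):
        return category_table(self.profiles)


def infer_genome_of_query(
    entries: Sequence[ProteinEntry], genomes: Sequence[GenomeRecord]
) -> dict[str, str]:
    """Map query ids to genome ids by longest genome-id prefix.

    Locus tags conventionally embed the genome/strain tag as a prefix
    (``SYN0001_0003``, ``DND132_2657``); explicit mappings override this.
    """
    ids = sorted((g.genome_id for g in genomes), key=len, reverse=True)
    mapping: dict[str, str] = {}
    for e in entries:
        for gid in ids:
            if e.query_id.startswith(gid):
                mapping[e.query_id] = gid
                break
    return mapping


def run_objects(
    entries: Sequence[ProteinEntry],
    records: Sequence[FeatureRecord],
    genomes: Sequence[GenomeRecord],
    usp_pssm_ids: int | set[int] | frozenset[int] = DEFAULT_USP_PSSM_ID,
    motif: MotifSpec = DEFAULT_MOTIF,
    genome_of_query: Optional[dict[str, str]] = None,
) -> PipelineResult:
    """Run patterns -> classify -> profiles -> aggregation on parsed inputs."""
    usp_ids = {usp_pssm_ids} if isinstance(usp_pssm_ids, int) else set(usp_pssm_ids)
    patterns = build_site_patterns(records, usp_ids)
    patterns = classify_all(patterns, motif)
    seq2genome = genome_of_query or infer_genome_of_query(entries, genomes)
    profiles = build_profiles(entries, records, patterns, seq2genome, usp_ids)
    summaries = genome_usp_counts(profiles, genomes)
    frequencies = pattern_frequencies(patterns)
    methylation = stratify_by_methylation(profiles, genomes)
    return PipelineResult(
        entries=list(entries),
        records=list(records),
        patterns=patterns,
        profiles=profiles,
        genomes=list(genomes),
        summaries=summaries,
        frequencies=frequencies,
        methylation=methylation,
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> PipelineResult:
    """File-to-file run; writes all output TSVs plus a JSON run log.

    Any stage failure is re-raised as :class:`PipelineError` naming the
    stage (and, for parse errors, the file and line).
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    def stage(name: str, fn, *args):
        try:
            return fn(*args)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(name, str(exc)) from exc

    for name, path in (
        ("parse-features", config.features_path),
        ("parse-fasta", config.fasta_path),
        ("parse-metadata", config.metadata_path),
    ):
        if not Path(path).exists():
            raise PipelineError(name, f"input file not found: {path}")

    records = stage("parse-features", read_features, config.features_path)
    entries = stage("parse-fasta", read_fasta, config.fasta_path)
    genomes = stage("parse-metadata", read_genome_metadata, config.metadata_path)
    result = stage(
        "profile",
        run_objects,
        entries,
        records,
        genomes,
        set(config.usp_pssm_ids),
        config.motif,
        config.genome_of_query,
    )

    def write(df: pd.DataFrame, name: str) -> None:
        df.to_csv(out_dir / name, sep="\t", index=False)

    stage("write", write, site_pattern_frame(result.patterns), "site_patterns.tsv")
    stage("write", write, profile_frame(result.profiles), "profiles.tsv")
    stage("write", write, genome_summary_frame(result.summaries), "genome_summary.tsv")
    stage("write", write, category_frame(result.category_counts), "category_counts.tsv")
    stage("write", write, pattern_frequency_frame(result.frequencies), "pattern_frequencies.tsv")
    result.methylation.reset_index().to_csv(out_dir / "methylation_stratified.tsv", sep="\t", index=False)

    run_log = {
        "version": __version__,
        "inputs": {
            str(p): _sha256(Path(p))
            for p in (config.features_path, config.fasta_path, config.metadata_path)
        },
        "usp_pssm_ids": sorted(config.usp_pssm_ids),
        "n_sequences": len(result.entries),
        "n_profiles": len(result.profiles),
    }
    (out_dir / "run_log.json").write_text(json.dumps(run_log, indent=2, sort_keys=True))
    log.info("pipeline finished: %d sequences, outputs in %s", len(result.entries), out_dir)
    return result
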