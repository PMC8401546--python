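"""Summary tables: per-genome USP gene counts, architecture category
tallies, pattern frequencies, and mercury-methylation stratifications.

Conventions
-----------
* A genome's ``usp_gene_count`` counts protein sequences carrying at least
  one USP domain model (sequences whose hits are all non-USP domains, or
  that had no conserved-domain hit, are tallied separately as ``NO_USP``).
* Pattern frequencies are reported both per domain instance (a tandem
  sequence with two identical patterns contributes 2) and per gene
  (distinct query ids), because gene-level and instance-level counting
  coincide only for single-domain patterns.
* All outputs are deterministic: descending by count, ties broken
  lexicographically.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .architecture import ArchitectureCategory, SequenceProfile
from .cdsearch_io import GenomeRecord, SequencingStatus
from .pattern_extraction import MotifCallValue, SitePattern

__all__ = [
    "GenomeSummary",
    "PatternFrequency",
    "genome_usp_counts",
    "usp_count_distribution",
    "category_table",
    "pattern_frequencies",
    "pattern_type_counts",
    "stratify_by_methylation",
    "genome_summary_frame",
    "category_frame",
    "pattern_frequency_frame",
    "site_pattern_frame",
    "profile_frame",
]

#: Categories that mark a sequence as a USP gene.
_USP_CATEGORIES = tuple(c for c in ArchitectureCategory if c is not ArchitectureCategory.NO_USP)


@dataclass(frozen=True)
class GenomeSummary:
    """USP gene count and category tallies for one genome."""

    genome_id: str
    organism: str
    genus: str
    sequencing_status: SequencingStatus
    hgcab_present: bool
    usp_gene_count: int
    category_counts: Mapping[ArchitectureCategory, int]
    non_usp_count: int = 0
    total_gene_count: int | None = None

    def __post_init__(self) -> None:
        if self.usp_gene_count != sum(self.category_counts.values()):
            raise ValueError(f"{self.genome_id}: usp_gene_count != sum of category counts")


@dataclass(frozen=True)
class PatternFrequency:
    """Occurrence counts for one distinct amino-acid pattern."""

    aa_pattern: str
    motif_call: str  # unanimous call, or "MIXED" if layouts disagree
    total_occurrences: int
    per_position_pattern: Mapping[str, int]
    n_genes: int

    def __post_init__(self) -> None:
        if self.total_occurrences != sum(self.per_position_pattern.values()):
            raise ValueError(f"{self.aa_pattern}: occurrence total != position-pattern sum")


def genome_usp_counts(
    profiles: Sequence[SequenceProfile], genomes: Sequence[GenomeRecord]
) -> list[GenomeSummary]:
    """One summary per genome record, zero-count genomes included.

    Raises a consistency error listing every profile whose ``genome_id`` is
    absent from the metadata.
    """
    known = {g.genome_id for g in genomes}
    orphans = sorted({p.genome_id for p in profiles if p.genome_id not in known})
    if orphans:
        raise ValueError(f"profiles reference unknown genome id(s): {orphans}")

    by_genome: dict[str, list[SequenceProfile]] = {g.genome_id: [] for g in genomes}
    for p in profiles:
        by_genome[p.genome_id].append(p)

    summaries: list[GenomeSummary] = []
    for g in genomes:
        tally = Counter(p.category for p in by_genome[g.genome_id])
        category_counts = {c: tally.get(c, 0) for c in _USP_CATEGORIES}
        summaries.append(
            GenomeSummary(
                genome_id=g.genome_id,
                organism=g.organism,
                genus=g.genus,
                sequencing_status=g.sequencing_status,
                hgcab_present=g.hgcab_present,
                usp_gene_count=sum(category_counts.values()),
                category_counts=category_counts,
                non_usp_count=tally.get(ArchitectureCategory.NO_USP, 0),
                total_gene_count=g.total_gene_count,
            )
        )
    return summaries


def usp_count_distribution(summaries: Iterable[GenomeSummary]) -> dict[int, int]:
    """Map USP-gene-count -> number of genomes with that count."""
    return dict(sorted(Counter(s.usp_gene_count for s in summaries).items()))


def category_table(profiles: Iterable[SequenceProfile]) -> dict[ArchitectureCategory, int]:
    """Exhaustive category tally; zero-valued categories present."""
    tally = Counter(p.category for p in profiles)
    return {c: tally.get(c, 0) for c in ArchitectureCategory}


def pattern_frequencies(patterns: Iterable[SitePattern]) -> list[PatternFrequency]:
    """Frequency of each distinct amino-acid pattern, most frequent first.

    Only sited patterns count (placeholders for domains without reported
    functional sites carry no signature).  Ties in total occurrence are
    broken lexicographically by pattern for stable output files.
    """
    groups: dict[str, list[SitePattern]] = {}
    for pat in patterns:
        if pat.n_sites == 0:
            continue
        groups.setdefault(pat.aa_pattern, []).append(pat)

    rows: list[PatternFrequency] = []
    for aa, group in groups.items():
        calls = {p.motif_call for p in group}
        call = calls.pop().value if len(calls) == 1 else "MIXED"
        per_pos = Counter(p.pos_pattern for p in group)
        rows.append(
            PatternFrequency(
                aa_pattern=aa,
                motif_call=call,
                total_occurrences=sum(per_pos.values()),
                per_position_pattern=dict(sorted(per_pos.items())),
                n_genes=len({p.query_id for p in group}),
            )
        )
    rows.sort(key=lambda r: (-r.total_occurrences, r.aa_pattern))
    return rows


def pattern_type_counts(freqs: Iterable[PatternFrequency]) -> dict[str, int]:
    """Number of distinct amino-acid patterns per motif type."""
    tally = Counter(f.motif_call for f in freqs)
    return {
        call.value: tally.get(call.value, 0)
        for call in (MotifCallValue.ATP_BINDING, MotifCallValue.NON_ATP)
    } | ({"MIXED": tally["MIXED"]} if tally.get("MIXED") else {})


def stratify_by_methylation(
    profiles: Sequence[SequenceProfile], genomes: Sequence[GenomeRecord]
) -> pd.DataFrame:
    """Category x hgcAB-status contingency table of sequence counts.

    Rows are all architecture categories (zero rows kept), columns are
    methylator / non_methylator; row sums equal :func:`category_table` and
    column sums equal the per-flag profile totals.
    """
    flag_of = {g.genome_id: g.hgcab_present for g in genomes}
    orphans = sorted({p.genome_id for p in profiles if p.genome_id not in flag_of})
    if orphans:
        raise ValueError(f"profiles reference unknown genome id(s): {orphans}")
    table = pd.DataFrame(
        0,
        index=pd.Index([c.value for c in ArchitectureCategory], name="category"),
        columns=pd.Index(["methylator", "non_methylator"], name="hgcab"),
    )
    for p in profiles:
        col = "methylator" if flag_of[p.genome_id] else "non_methylator"
        table.loc[p.category.value, col] += 1
    return table


# ---------------------------------------------------------------------------
# DataFrame views for the TSV outputs
# ---------------------------------------------------------------------------

def genome_summary_frame(summaries: Sequence[GenomeSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        row = {
            "genome_id": s.genome_id,
            "organism": s.organism,
            "genus": s.genus,
            "sequencing_status": s.sequencing_status.value,
            "hgcab_present": s.hgcab_present,
            "usp_gene_count": s.usp_gene_count,
            "non_usp_count": s.non_usp_count,
            "total_gene_count": s.total_gene_count,
        }
        for c in _USP_CATEGORIES:
            row[f"n_{c.value.lower()}"] = s.category_counts.get(c, 0)
        rows.append(row)
    return pd.DataFrame(rows)


def category_frame(counts: Mapping[ArchitectureCategory, int]) -> pd.DataFrame:
    return pd.DataFrame(
        {"category": [c.value for c in counts], "n_sequences": list(counts.values())}
    )


def pattern_frequency_frame(freqs: Sequence[PatternFrequency]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "aa_pattern": [f.aa_pattern for f in freqs],
            "motif_call": [f.motif_call for f in freqs],
            "n_domain_instances": [f.total_occurrences for f in freqs],
            "n_genes": [f.n_genes for f in freqs],
            "n_position_patterns": [len(f.per_position_pattern) for f in freqs],
            "position_patterns": [
                "; ".join(f"{pp} ({n})" for pp, n in f.per_position_pattern.items())
                for f in freqs
            ],
        }
    )


def site_pattern_frame(patterns: Sequence[SitePattern]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "query_id": [p.query_id for p in patterns],
            "source_domain": [p.source_domain for p in patterns],
            "aa_pattern": [p.aa_pattern for p in patterns],
            "pos_pattern": [p.pos_pattern for p in patterns],
            "n_sites": [p.n_sites for p in patterns],
            "motif_call": [p.motif_call.value for p in patterns],
            "anchor_position": [p.anchor_position for p in patterns],
        }
    )


def profile_frame(profiles: Sequence[SequenceProfile]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "query_id": [p.query_id for p in profiles],
            "genome_id": [p.genome_id for p in profiles],
            "length_aa": [p.length_aa for p in profiles],
            "usp_domain_count": [p.usp_domain_count for p in profiles],
            "category": [p.category.value for p in profiles],
            "partial_flag": [p.partial for p in profiles],
            "other_domain_titles": [
                "; ".join(f"{title} [{sd}]" for sd, title in p.other_domains)
                for p in profiles
            ],
        }
    )
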