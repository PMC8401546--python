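"""Per-sequence domain-architecture profiles and category assignment.

A protein is profiled by how many USP domain models were mapped onto it and
by the ATP-binding call of each domain:

* one USP domain  -> SINGLE_ATP or SINGLE_NON_ATP,
* two USP domains -> the tandem three-way split: TANDEM_Y (both domains
  ATP-binding), TANDEM_N (neither), TANDEM_STAR (exactly one),
* USP domain(s) present but none with reported functional sites -> NO_SITES,
* no USP domain at all -> NO_USP (e.g. a query whose only hits are other
  domain families, or no conserved domain at all),
* more than two USP domains -> MULTI (not observed in the family studied
  here but supported and tallied separately).

A tandem sequence where exactly one domain has sites is categorized by the
sited domain and flagged ``partial``; partial sequences are excluded from
the Y/N/* tandem tallies so that three-way split stays a clean partition of
fully-sited tandems.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

from .cdsearch_io import FeatureRecord, ProteinEntry, DEFAULT_USP_PSSM_ID
from .pattern_extraction import MotifCallValue, SitePattern

__all__ = ["ArchitectureCategory", "SequenceProfile", "build_profiles", "categorize"]


class ArchitectureCategory(str, Enum):
    SINGLE_ATP = "SINGLE_ATP"
    SINGLE_NON_ATP = "SINGLE_NON_ATP"
    TANDEM_Y = "TANDEM_Y"
    TANDEM_N = "TANDEM_N"
    TANDEM_STAR = "TANDEM_STAR"
    NO_SITES = "NO_SITES"
    NO_USP = "NO_USP"
    MULTI = "MULTI"


#: Categories describing sequences that carry at least one USP domain.
USP_CATEGORIES = frozenset(
    c for c in ArchitectureCategory if c is not ArchitectureCategory.NO_USP
)


@dataclass(frozen=True)
class SequenceProfile:
    """All domain annotations and the architecture category of one protein."""

    query_id: str
    genome_id: str
    length_aa: int
    usp_domain_count: int
    usp_patterns: tuple[SitePattern, ...]
    other_domains: tuple[tuple[int, str], ...]
    category: ArchitectureCategory
    partial: bool = False

    def __post_init__(self) -> None:
        n_sited = sum(1 for p in self.usp_patterns if p.n_sites > 0)
        n_empty = sum(1 for p in self.usp_patterns if p.n_sites == 0)
        if self.usp_domain_count != n_sited + n_empty:
            raise ValueError(f"{self.query_id}: usp_domain_count inconsistent with patterns")


def _order_patterns(patterns: Sequence[SitePattern]) -> tuple[SitePattern, ...]:
    # Sited patterns by first contact position; no-site placeholders last.
    sited = sorted(
        (p for p in patterns if p.n_sites > 0), key=lambda p: p.first_position or 0
    )
    empty = [p for p in patterns if p.n_sites == 0]
    return tuple(sited + empty)


def categorize(
    usp_patterns: Sequence[SitePattern],
) -> tuple[ArchitectureCategory, bool]:
    """Category plus partial flag from the motif calls of a query's USP domains.

    Motif calls must already be assigned (UNCLASSIFIED means no reported
    sites).  The flag marks multi-domain sequences with a mix of sited and
    unsited domains, whose category comes from the sited domain(s) only.
    """
    n = len(usp_patterns)
    if n == 0:
        return ArchitectureCategory.NO_USP, False
    calls = [p.motif_call for p in usp_patterns]
    sited = [c for c in calls if c is not MotifCallValue.UNCLASSIFIED]
    if not sited:
        return ArchitectureCategory.NO_SITES, False
    partial = len(sited) < n
    if n > 2:
        return ArchitectureCategory.MULTI, partial
    if len(sited) == 1:
        single = (
            ArchitectureCategory.SINGLE_ATP
            if sited[0] is MotifCallValue.ATP_BINDING
            else ArchitectureCategory.SINGLE_NON_ATP
        )
        return single, partial
    n_atp = sum(1 for c in sited if c is MotifCallValue.ATP_BINDING)
    tandem = {
        2: ArchitectureCategory.TANDEM_Y,
        1: ArchitectureCategory.TANDEM_STAR,
        0: ArchitectureCategory.TANDEM_N,
    }[n_atp]
    return tandem, partial


def build_profiles(
    entries: Iterable[ProteinEntry],
    records: Iterable[FeatureRecord],
    patterns: Iterable[SitePattern],
    seq2genome: Mapping[str, str],
    usp_pssm_id: int | set[int] = DEFAULT_USP_PSSM_ID,
) -> list[SequenceProfile]:
    """Assemble one profile per FASTA entry.

    ``patterns`` must be the classified output of the motif classifier for
    the same ``records``; a pattern naming a query absent from ``entries``
    raises a consistency error.  Entries with no feature record at all (a
    query for which CD-Search found no conserved domain) come out NO_USP,
    as do entries whose only hits are non-USP domain families.
    """
    usp_ids = {usp_pssm_id} if isinstance(usp_pssm_id, int) else set(usp_pssm_id)
    entries = list(entries)
    known_queries = {e.query_id for e in entries}

    records_by_query: dict[str, list[FeatureRecord]] = {}
    for rec in records:
        records_by_query.setdefault(rec.query_id, []).append(rec)

    patterns_by_query: dict[str, list[SitePattern]] = {}
    for pat in patterns:
        if pat.query_id not in known_queries:
            raise ValueError(
                f"site pattern references unknown query {pat.query_id!r}"
            )
        patterns_by_query.setdefault(pat.query_id, []).append(pat)

    profiles: list[SequenceProfile] = []
    for entry in entries:
        recs = records_by_query.get(entry.query_id, [])
        usp_count = sum(1 for r in recs if r.source_domain in usp_ids)
        other = tuple(
            (r.source_domain, r.title) for r in recs if r.source_domain not in usp_ids
        )
        pats = _order_patterns(patterns_by_query.get(entry.query_id, []))
        if len(pats) != usp_count:
            raise ValueError(
                f"{entry.query_id}: {usp_count} USP feature records but "
                f"{len(pats)} site patterns — classify the same record set"
            )
        category, partial = categorize(pats)
        profiles.append(
            SequenceProfile(
                query_id=entry.query_id,
                genome_id=seq2genome.get(entry.query_id, ""),
                length_aa=entry.length_aa,
                usp_domain_count=usp_count,
                usp_patterns=pats,
                other_domains=other,
                category=category,
                partial=partial,
            )
        )
    return profiles
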