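"""Amino-acid and position patterns derived from functional-site coordinates.

From a coordinate list such as ``P9, V10, D11, C39, M108, G109, R111, G112,
G122, S123, V124, T125`` two signatures are derived: the amino-acid pattern
(``PVDCMGRGGSVT`` — the contact residues concatenated in position order) and
the position pattern (``9_10_11_39_108_109_111_112_122_123_124_125`` — all
positions joined with underscores).  Every position contributes one field, so
the two signatures always have the same length; this pairwise-complete rule
is the correctness contract for everything downstream.

Patterns are computed per domain instance: a tandem-USP sequence contributes
two patterns to any frequency table, because each domain is classified for
ATP binding separately.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum
from typing import Iterable, Sequence

from .cdsearch_io import ContactSite, FeatureRecord, DEFAULT_USP_PSSM_ID

__all__ = [
    "MotifCallValue",
    "SitePattern",
    "amino_acid_pattern",
    "position_pattern",
    "build_site_patterns",
]


class MotifCallValue(str, Enum):
    """Three-way ATP-binding call for one domain's functional sites."""

    ATP_BINDING = "ATP_BINDING"
    NON_ATP = "NON_ATP"
    UNCLASSIFIED = "UNCLASSIFIED"


def _require_sorted(sites: Sequence[ContactSite]) -> None:
    positions = [s.position for s in sites]
    if any(b <= a for a, b in zip(positions, positions[1:])):
        # Never silently re-sort: unsorted input means an upstream bug.
        raise ValueError("contact sites must be strictly increasing by position")


def amino_acid_pattern(sites: Sequence[ContactSite]) -> str:
    """Concatenate contact residues in position order."""
    _require_sorted(sites)
    return "".join(s.residue for s in sites)


def position_pattern(sites: Sequence[ContactSite]) -> str:
    """Join all contact positions with ``_``, ascending; one field per site."""
    _require_sorted(sites)
    return "_".join(str(s.position) for s in sites)


@dataclass(frozen=True)
class SitePattern:
    """Derived signatures plus the motif call for one domain instance."""

    query_id: str
    source_domain: int
    aa_pattern: str
    pos_pattern: str
    n_sites: int
    motif_call: MotifCallValue = MotifCallValue.UNCLASSIFIED
    anchor_position: int | None = None

    def __post_init__(self) -> None:
        n_pos = len(self.pos_pattern.split("_")) if self.pos_pattern else 0
        if not (len(self.aa_pattern) == n_pos == self.n_sites):
            raise ValueError(
                f"{self.query_id}: pattern lengths disagree "
                f"(aa {len(self.aa_pattern)}, pos {n_pos}, n_sites {self.n_sites})"
            )
        if self.pos_pattern:
            positions = [int(p) for p in self.pos_pattern.split("_")]
            if any(b <= a for a, b in zip(positions, positions[1:])):
                raise ValueError(f"{self.query_id}: position pattern not strictly increasing")

    @property
    def first_position(self) -> int | None:
        return int(self.pos_pattern.split("_", 1)[0]) if self.pos_pattern else None

    def with_call(self, call: MotifCallValue, anchor_position: int | None = None) -> "SitePattern":
        return replace(self, motif_call=call, anchor_position=anchor_position)

    @classmethod
    def from_sites(
        cls, query_id: str, source_domain: int, sites: Sequence[ContactSite]
    ) -> "SitePattern":
        return cls(
            query_id=query_id,
            source_domain=source_domain,
            aa_pattern=amino_acid_pattern(sites),
            pos_pattern=position_pattern(sites),
            n_sites=len(sites),
        )


def build_site_patterns(
    records: Iterable[FeatureRecord],
    usp_pssm_id: int | set[int] = DEFAULT_USP_PSSM_ID,
) -> list[SitePattern]:
    """One :class:`SitePattern` per USP-model feature record.

    Records whose ``source_domain`` is not in the configured USP id set are
    skipped (they stay visible on the sequence profile as "other domains").
    A USP record with an empty coordinate field yields an UNCLASSIFIED
    placeholder with empty patterns, mirroring CD-Search queries for which no
    functional sites were reported.
    """
    usp_ids = {usp_pssm_id} if isinstance(usp_pssm_id, int) else set(usp_pssm_id)
    patterns: list[SitePattern] = []
    for rec in records:
        if rec.source_domain not in usp_ids:
            continue
        patterns.append(SitePattern.from_sites(rec.query_id, rec.source_domain, rec.sites))
    return patterns
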