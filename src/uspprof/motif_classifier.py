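"""ATP-binding classification of USP domains under the G2XG9XG(S/T) motif.

The motif is a 15-residue signature: glycine, exactly two unconstrained
residues, glycine, exactly nine unconstrained residues, glycine, then serine
or threonine.  Relative to the first anchor glycine at position ``p`` the
anchors sit at ``p``, ``p+3``, ``p+13`` and ``p+14``; the intervening "X"
residues are unconstrained.  Both worked layouts observed in USP domains
(e.g. the AVDVMGHGGSVA contact pattern with anchors G113/G116/G126/S127) fit
these exact offsets, so the gaps are read as exact counts, not maxima.

Two classification routes exist:

* :func:`classify_sites` — the primary route; all four anchors must appear
  among a domain's *contact sites*, because the study object is the
  functional-site pattern, not the raw sequence.
* :func:`scan_sequence` — an independent full-sequence scan used for
  verification; it needs only the sequence letters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .cdsearch_io import ContactSite
from .pattern_extraction import MotifCallValue, SitePattern

__all__ = [
    "MotifSpec",
    "MotifCall",
    "DEFAULT_MOTIF",
    "parse_motif_string",
    "classify_sites",
    "scan_sequence",
    "classify_all",
]


@dataclass(frozen=True)
class MotifSpec:
    """Ordered (offset, allowed-residues) anchor constraints.

    Offsets are relative to the first anchor and strictly increasing,
    starting at 0.  The default is the ATP-binding motif G2XG9XG(S/T).
    """

    anchors: tuple[tuple[int, frozenset[str]], ...]

    def __post_init__(self) -> None:
        if not self.anchors:
            raise ValueError("motif needs at least one anchor")
        offsets = [off for off, _ in self.anchors]
        if offsets[0] != 0:
            raise ValueError("first anchor offset must be 0")
        if any(b <= a for a, b in zip(offsets, offsets[1:])):
            raise ValueError("anchor offsets must be strictly increasing")
        for off, residues in self.anchors:
            if not residues or any(
                not (len(r) == 1 and r.isalpha() and r.isupper()) for r in residues
            ):
                raise ValueError(f"invalid residue set {residues!r} at offset {off}")

    @property
    def span(self) -> int:
        """Number of residues the motif covers (15 for the default)."""
        return self.anchors[-1][0] + 1


DEFAULT_MOTIF = MotifSpec(
    anchors=(
        (0, frozenset("G")),
        (3, frozenset("G")),
        (13, frozenset("G")),
        (14, frozenset("ST")),
    )
)


def parse_motif_string(text: str) -> MotifSpec:
    """Parse the CLI motif grammar, e.g. ``"G,2,G,9,G,ST"``.

    Alternating residue sets and integer gap lengths: a residue token pins
    the next anchor, an integer token skips that many unconstrained
    residues.  ``"G,2,G,9,G,ST"`` is the default ATP-binding motif.
    """
    offset = 0
    anchors: list[tuple[int, frozenset[str]]] = []
    for token in text.split(","):
        token = token.strip()
        if not token:
            raise ValueError("empty token in motif string")
        if token.isdigit():
            offset += int(token)
        elif token.isalpha():
            anchors.append((offset, frozenset(token.upper())))
            offset += 1
        else:
            raise ValueError(f"motif token {token!r} is neither residues nor a gap length")
    return MotifSpec(anchors=tuple(anchors))


@dataclass(frozen=True)
class MotifCall:
    """Classification outcome; anchor position only when ATP-binding."""

    call: MotifCallValue
    anchor_position: int | None = None

    def __post_init__(self) -> None:
        if (self.call is MotifCallValue.ATP_BINDING) != (self.anchor_position is not None):
            raise ValueError("anchor_position present iff call is ATP_BINDING")


# Ambiguity codes never satisfy an anchor: frozensets above hold only the
# canonical letters, and residues are compared case-sensitively (uppercase).


def classify_sites(sites: Sequence[ContactSite], spec: MotifSpec = DEFAULT_MOTIF) -> MotifCall:
    """Classify a sorted contact-site list against the motif.

    ATP-binding iff some position ``p`` has every anchor of ``spec``
    realised *as a contact site* with an allowed residue.  Unconstrained
    motif positions need not be contacts.  Empty input is UNCLASSIFIED (no
    functional sites were reported); the smallest valid ``p`` is reported
    when several exist.
    """
    if not sites:
        return MotifCall(MotifCallValue.UNCLASSIFIED)
    by_position = {s.position: s.residue for s in sites}
    for p in sorted(by_position):
        if all(
            by_position.get(p + off) in allowed for off, allowed in spec.anchors
        ):
            return MotifCall(MotifCallValue.ATP_BINDING, anchor_position=p)
    return MotifCall(MotifCallValue.NON_ATP)


def scan_sequence(sequence: str, spec: MotifSpec = DEFAULT_MOTIF) -> list[int]:
    """All 1-based anchor positions where the motif matches the sequence."""
    if not sequence or not sequence.isalpha():
        raise ValueError("sequence must be non-empty and alphabetic")
    seq = sequence.upper()
    hits: list[int] = []
    last_start = len(seq) - spec.span
    for i in range(last_start + 1):
        if all(seq[i + off] in allowed for off, allowed in spec.anchors):
            hits.append(i + 1)
    return hits


def classify_all(
    patterns: Iterable[SitePattern], spec: MotifSpec = DEFAULT_MOTIF
) -> list[SitePattern]:
    """Fill ``motif_call`` for every pattern (three-way partition)."""
    out: list[SitePattern] = []
    for pat in patterns:
        sites = _sites_of(pat)
        call = classify_sites(sites, spec)
        out.append(pat.with_call(call.call, call.anchor_position))
    return out


def _sites_of(pattern: SitePattern) -> list[ContactSite]:
    if not pattern.pos_pattern:
        return []
    positions = [int(p) for p in pattern.pos_pattern.split("_")]
    return [
        ContactSite(position=pos, residue=res)
        for pos, res in zip(positions, pattern.aa_pattern)
    ]
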