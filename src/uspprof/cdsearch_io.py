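"""Readers and writers for the three pipeline inputs and for tabular outputs.

The central input is the "Features" table produced by the NCBI Batch Web
CD-Search tool: one tab-delimited row per (query sequence, conserved-domain
model) pair, listing the functionally annotated residues ("functional sites"
or contact sites) that the domain model maps onto the query.  The other two
inputs are a protein FASTA (the sequences that were submitted to CD-Search)
and a genome metadata table carrying, per genome, the sequencing status and
the mercury-methylation flag (presence of the hgcAB gene pair).

All records are validated at construction; downstream modules may assume the
invariants documented on each type.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "ContactSite",
    "FeatureRecord",
    "ProteinEntry",
    "GenomeRecord",
    "SequencingStatus",
    "FeaturesParseError",
    "MetadataSchemaError",
    "DEFAULT_USP_PSSM_ID",
    "parse_coordinate_string",
    "read_features",
    "write_features",
    "read_fasta",
    "write_fasta",
    "read_genome_metadata",
    "write_genome_metadata",
]

#: PSSM identifier of the universal stress protein (Usp, pfam00582) domain
#: model in the NCBI CDD release used here.  PSSM ids drift across CDD
#: releases, so every consumer accepts an override.
DEFAULT_USP_PSSM_ID = 23812

# CD-Search "Q#12 - >lcl|DND132_2657" query dialect: keep the part after '>'.
_QUERY_PREFIX_RE = re.compile(r"^Q#\d+\s*-\s*>?")
_COORD_TOKEN_RE = re.compile(r"^([A-Z])(\d+)$")

FEATURES_COLUMNS = (
    "Query",
    "Type",
    "Title",
    "Coordinates",
    "Complete size",
    "Mapped size",
    "Source domain",
)


class FeaturesParseError(ValueError):
    """A Features row or coordinate token that cannot be parsed."""


class MetadataSchemaError(ValueError):
    """Genome metadata table missing required columns or values."""


@dataclass(frozen=True, order=True)
class ContactSite:
    """One functional-site residue: one-letter code plus 1-based position.

    Positions are 1-based sequence coordinates exactly as CD-Search labels
    them ("P9" is proline at residue 9); no internal conversion is done.
    """

    position: int
    residue: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"contact position must be >= 1, got {self.position}")
        if not (len(self.residue) == 1 and self.residue.isalpha() and self.residue.isupper()):
            raise ValueError(f"residue must be a single uppercase letter, got {self.residue!r}")

    def __str__(self) -> str:  # "G109" notation
        return f"{self.residue}{self.position}"


@dataclass(frozen=True)
class FeatureRecord:
    """One parsed Features row: one domain model's sites on one query."""

    query_id: str
    feature_type: str
    title: str
    sites: tuple[ContactSite, ...]
    complete_size: int
    mapped_size: int
    source_domain: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "sites", tuple(self.sites))
        if self.complete_size < 0 or self.mapped_size < 0:
            raise ValueError("size fields must be non-negative")
        if self.mapped_size != len(self.sites):
            raise ValueError(
                f"{self.query_id}: mapped size {self.mapped_size} != "
                f"{len(self.sites)} parsed sites"
            )
        if self.mapped_size > self.complete_size:
            raise ValueError(
                f"{self.query_id}: mapped size {self.mapped_size} exceeds "
                f"complete size {self.complete_size}"
            )
        positions = [s.position for s in self.sites]
        if any(b <= a for a, b in zip(positions, positions[1:])):
            raise ValueError(f"{self.query_id}: site positions not strictly increasing")


@dataclass(frozen=True)
class ProteinEntry:
    """One FASTA record; ``query_id`` is the first header token."""

    query_id: str
    description: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence or not self.sequence.isalpha():
            raise ValueError(f"{self.query_id}: sequence must be non-empty and alphabetic")

    @property
    def length_aa(self) -> int:
        return len(self.sequence)


class SequencingStatus(str, Enum):
    DRAFT = "draft"
    FINISHED = "finished"
    PERMANENT_DRAFT = "permanent draft"


def _normalize_status(raw: str) -> SequencingStatus:
    key = re.sub(r"[\s_-]+", " ", raw.strip().lower())
    try:
        return SequencingStatus(key)
    except ValueError:
        raise MetadataSchemaError(f"unrecognized sequencing status {raw!r}") from None


_TRUE = {"1", "true", "yes", "y", "t"}
_FALSE = {"0", "false", "no", "n", "f"}


def _parse_bool(raw: str, context: str) -> bool:
    key = raw.strip().lower()
    if key in _TRUE:
        return True
    if key in _FALSE:
        return False
    raise MetadataSchemaError(f"{context}: cannot interpret {raw!r} as a boolean")


@dataclass(frozen=True)
class GenomeRecord:
    """Per-genome metadata.

    ``hgcab_present`` flags predicted mercury methylators (presence of the
    hgcAB corrinoid-protein/ferredoxin gene pair).  Duplicate sequencing
    projects for one strain stay distinct records keyed by ``genome_id``.
    """

    genome_id: str
    organism: str
    genus: str
    sequencing_status: SequencingStatus
    hgcab_present: bool
    total_gene_count: Optional[int] = None
    extra: Mapping[str, str] = field(default_factory=dict)


def normalize_query_id(raw: str, strip_prefix: Optional[re.Pattern] = _QUERY_PREFIX_RE) -> str:
    """First whitespace token, with the CD-Search ``Q#N - >`` prefix removed."""
    text = raw.strip()
    if strip_prefix is not None:
        text = strip_prefix.sub("", text)
    return text.split()[0] if text.split() else ""


def parse_coordinate_string(text: str) -> list[ContactSite]:
    """Parse a comma-separated coordinate list like ``"P9, V10, D11"``.

    Returns the sites in file order and validates that positions are
    strictly increasing (CD-Search always emits them sorted; a violation
    indicates a corrupted row).
    """
    text = text.strip()
    if not text:
        return []
    sites: list[ContactSite] = []
    for token in text.split(","):
        token = token.strip()
        m = _COORD_TOKEN_RE.match(token)
        if m is None:
            raise FeaturesParseError(f"malformed coordinate token {token!r}")
        try:
            sites.append(ContactSite(position=int(m.group(2)), residue=m.group(1)))
        except ValueError as exc:
            raise FeaturesParseError(f"invalid coordinate token {token!r}: {exc}") from None
    positions = [s.position for s in sites]
    if any(b <= a for a, b in zip(positions, positions[1:])):
        raise FeaturesParseError(f"coordinate positions not strictly increasing in {text!r}")
    return sites


def read_features(
    path: Union[str, Path],
    usp_pssm_id: int = DEFAULT_USP_PSSM_ID,
) -> list[FeatureRecord]:
    """Read a Batch CD-Search Features file into validated records.

    Lines starting with ``#`` and blank lines are skipped, so the raw
    download (with its comment preamble) and a preamble-stripped file parse
    identically.  Every non-comment row becomes a :class:`FeatureRecord`, in
    file order; filtering to the USP domain model happens downstream.
    ``usp_pssm_id`` is accepted for interface symmetry with the rest of the
    pipeline and recorded nowhere — parsing does not depend on it.

    Raises :class:`FeaturesParseError` naming the 1-based line number for any
    row with the wrong column count or non-integer size fields.
    """
    records: list[FeatureRecord] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            # Tolerate a header row repeating the column names.
            if fields[0].strip().lower() == "query":
                continue
            if len(fields) != len(FEATURES_COLUMNS):
                raise FeaturesParseError(
                    f"{path}:{lineno}: expected {len(FEATURES_COLUMNS)} tab-delimited "
                    f"fields, found {len(fields)}"
                )
            query_raw, ftype, title, coords, complete_raw, mapped_raw, source_raw = fields
            try:
                complete = int(complete_raw.replace(",", "").strip())
                mapped = int(mapped_raw.replace(",", "").strip())
                source = int(source_raw.replace(",", "").strip())
            except ValueError:
                raise FeaturesParseError(
                    f"{path}:{lineno}: non-integer size/source field"
                ) from None
            try:
                sites = parse_coordinate_string(coords)
                record = FeatureRecord(
                    query_id=normalize_query_id(query_raw),
                    feature_type=ftype.strip(),
                    title=title.strip(),
                    sites=tuple(sites),
                    complete_size=complete,
                    mapped_size=mapped,
                    source_domain=source,
                )
            except (FeaturesParseError, ValueError) as exc:
                raise FeaturesParseError(f"{path}:{lineno}: {exc}") from None
            records.append(record)
    return records


def write_features(records: Iterable[FeatureRecord], path: Union[str, Path]) -> None:
    """Write records back out in the tab-delimited Features dialect."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#" + "\t".join(FEATURES_COLUMNS) + "\n")
        for rec in records:
            coords = ", ".join(str(s) for s in rec.sites)
            fh.write(
                "\t".join(
                    [
                        rec.query_id,
                        rec.feature_type,
                        rec.title,
                        coords,
                        str(rec.complete_size),
                        str(rec.mapped_size),
                        str(rec.source_domain),
                    ]
                )
                + "\n"
            )


def read_fasta(path: Union[str, Path]) -> list[ProteinEntry]:
    """Read protein FASTA; wrapped sequence lines are concatenated."""
    entries: list[ProteinEntry] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        entries.append(
            ProteinEntry(
                query_id=rec.id,
                description=rec.description,
                sequence=str(rec.seq).upper(),
            )
        )
    return entries


def write_fasta(entries: Iterable[ProteinEntry], path: Union[str, Path], wrap: int = 60) -> None:
    records = [
        SeqRecord(Seq(e.sequence), id=e.query_id, description=_description_tail(e))
        for e in entries
    ]
    with open(path, "w", encoding="utf-8") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=wrap)
        writer.write_file(records)


def _description_tail(entry: ProteinEntry) -> str:
    desc = entry.description
    if desc.startswith(entry.query_id):
        desc = desc[len(entry.query_id):].strip()
    return desc


METADATA_REQUIRED = (
    "genome_id",
    "organism",
    "genus",
    "sequencing_status",
    "hgcab_present",
)


def read_genome_metadata(path: Union[str, Path]) -> list[GenomeRecord]:
    """Read the genome metadata table (TSV or CSV, sniffed from the header).

    Required columns: genome_id, organism, genus, sequencing_status,
    hgcab_present; total_gene_count is optional and any further columns are
    preserved verbatim in ``GenomeRecord.extra``.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
        delimiter = "\t" if first.count("\t") >= first.count(",") else ","
        fh.seek(0)
        reader = csv.DictReader(fh, delimiter=delimiter)
        header = reader.fieldnames or []
        missing = [c for c in METADATA_REQUIRED if c not in header]
        if missing:
            raise MetadataSchemaError(f"{path}: missing required column(s) {missing}")
        known = set(METADATA_REQUIRED) | {"total_gene_count"}
        records: list[GenomeRecord] = []
        for row in reader:
            gid = (row["genome_id"] or "").strip()
            total_raw = (row.get("total_gene_count") or "").strip()
            records.append(
                GenomeRecord(
                    genome_id=gid,
                    organism=(row["organism"] or "").strip(),
                    genus=(row["genus"] or "").strip(),
                    sequencing_status=_normalize_status(row["sequencing_status"]),
                    hgcab_present=_parse_bool(row["hgcab_present"], f"genome {gid}"),
                    total_gene_count=int(total_raw) if total_raw else None,
                    extra={k: (v or "") for k, v in row.items() if k not in known},
                )
            )
    return records


def write_genome_metadata(records: Iterable[GenomeRecord], path: Union[str, Path]) -> None:
    records = list(records)
    extra_cols: list[str] = []
    for rec in records:
        for col in rec.extra:
            if col not in extra_cols:
                extra_cols.append(col)
    cols = list(METADATA_REQUIRED) + ["total_gene_count"] + extra_cols
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(cols)
        for rec in records:
            row = [
                rec.genome_id,
                rec.organism,
                rec.genus,
                rec.sequencing_status.value,
                str(rec.hgcab_present).lower(),
                "" if rec.total_gene_count is None else str(rec.total_gene_count),
            ]
            row.extend(rec.extra.get(c, "") for c in extra_cols)
            writer.writerow(row)
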