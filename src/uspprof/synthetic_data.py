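"""Ground-truthed synthetic cohorts: FASTA + Features + metadata triples.

The generator emulates the study inputs — a family of sulfate-reducing
bacterial genomes, each encoding a handful of universal stress protein
genes — with full knowledge of the truth: which domains were planted with
the ATP-binding anchor layout, which sequences are tandem, which carry
decoy (non-USP) domains, and which report no functional sites at all.

Defaults mirror the observed study conditions: 93 genomes with 1–16 USP
genes each; roughly a quarter of USP sequences tandem; about 70 % of
single-domain sequences ATP-binding; tandem domains split ~2/85/13 % among
both-ATP / neither / exactly-one; rare no-site annotations and a sprinkle
of decoy-only queries (sequences retrieved by annotation keyword but whose
conserved-domain hits are all non-USP families).

Construction guarantees
-----------------------
* Contact residues are read back from the emitted sequence, so coordinates
  and FASTA always agree.
* ATP-binding domains carry the G / +3 G / +13 G / +14 (S|T) anchors among
  their contacts; non-ATP domains have at least one anchor broken.
* Backgrounds are screened by rejection sampling: the full sequence
  contains the motif exactly at the planted anchors (ATP domains) and
  nowhere else, so contact-level and sequence-level classification agree
  by construction.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .cdsearch_io import (
    ContactSite,
    FeatureRecord,
    GenomeRecord,
    ProteinEntry,
    SequencingStatus,
    DEFAULT_USP_PSSM_ID,
    write_fasta,
    write_features,
    write_genome_metadata,
)
from .motif_classifier import DEFAULT_MOTIF, MotifSpec, classify_sites, scan_sequence
from .pattern_extraction import MotifCallValue, amino_acid_pattern, position_pattern

__all__ = ["SimulationConfig", "SequenceTruth", "TruthManifest", "SimulationResult", "simulate"]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Canonical 12-slot contact layout, as offsets from the first contact.
#: Taken from the common observed layout 10_11_12_40_112_113_115_116_126_
#: 127_128_129 (first contact at 10).  Slots 5, 7, 8, 9 are the motif
#: anchors (G, G, G, S/T).
CANONICAL_LAYOUT = (0, 1, 2, 30, 102, 103, 105, 106, 116, 117, 118, 119)
ANCHOR_SLOTS = (5, 7, 8, 9)
CANONICAL_START = 10

#: Consensus residue per contact slot (from the most frequent family
#: pattern, AVDVMGHGGSVA).  Non-anchor slots draw the consensus residue
#: with probability ``residue_conservation``, so homologous domains share
#: recurring amino-acid patterns as in real families.
CANONICAL_RESIDUES = "AVDVMGHGGSVA"

#: Non-USP conserved-domain models used as decoys (id -> title), echoing the
#: other domain families seen fused to or alongside USP domains: a metal-ion
#: transporter, a sensor-kinase USP region, an OYE-like FMN-binding domain
#: and a histidine-kinase-like ATPase.
DECOY_DOMAINS = {
    460219: "NRAMP metal ion transporter family",
    212640: "Osmosensitive K+ channel histidine kinase sensor USP region",
    239967: "OYE-like FMN-binding domain",
    238030: "Histidine kinase-like ATPase domain",
}

GENERA = (
    "Bilophila",
    "Desulfobaculum",
    "Desulfocurvibacter",
    "Desulfocurvus",
    "Desulfohalovibrio",
    "Desulfovibrio",
    "Halodesulfovibrio",
    "Lawsonia",
    "Mailhella",
    "Pseudodesulfovibrio",
)

_STATUS_CHOICES = (
    SequencingStatus.FINISHED,
    SequencingStatus.PERMANENT_DRAFT,
    SequencingStatus.DRAFT,
)
# 23 finished / 69 permanent draft / 1 draft out of 93 genomes.
_STATUS_PROBS = (23 / 93, 69 / 93, 1 / 93)


class ConfigError(ValueError):
    """Infeasible or inconsistent simulation configuration."""


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition knobs for one synthetic cohort."""

    n_genomes: int = 93
    usp_count_range: tuple[int, int] = (1, 16)
    fraction_methylators: float = 0.5
    fraction_tandem: float = 163 / 651
    fraction_atp_single: float = 340 / 488
    tandem_mix: tuple[float, float, float] = (3 / 162, 138 / 162, 21 / 162)  # Y, N, *
    fraction_no_sites: float = 3 / 719
    fraction_decoy_domains: float = 67 / 719
    fraction_fusion: float = 0.05
    residue_conservation: float = 0.7
    contact_layout_jitter: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.usp_count_range
        if not (1 <= lo <= hi):
            raise ConfigError(f"usp_count_range must satisfy 1 <= min <= max, got {self.usp_count_range}")
        for name in (
            "fraction_methylators",
            "fraction_tandem",
            "fraction_atp_single",
            "fraction_no_sites",
            "fraction_decoy_domains",
            "fraction_fusion",
            "residue_conservation",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be a probability, got {v}")
        if len(self.tandem_mix) != 3 or any(p < 0 for p in self.tandem_mix):
            raise ConfigError("tandem_mix must be three non-negative probabilities")
        if abs(sum(self.tandem_mix) - 1.0) > 1e-9:
            raise ConfigError(f"tandem_mix must sum to 1, got {sum(self.tandem_mix)}")
        if self.n_genomes < 1:
            raise ConfigError("n_genomes must be >= 1")
        if not 0 <= self.contact_layout_jitter <= CANONICAL_START - 2:
            raise ConfigError(
                f"contact_layout_jitter must be in [0, {CANONICAL_START - 2}] so the "
                "first contact stays inside the sequence"
            )


@dataclass(frozen=True)
class SequenceTruth:
    """Ground truth for one emitted protein sequence."""

    query_id: str
    genome_id: str
    length_aa: int
    usp_domain_count: int
    domain_calls: tuple[str, ...]  # per USP domain, in position order
    category: str
    aa_patterns: tuple[str, ...]
    pos_patterns: tuple[str, ...]
    planted_anchors: tuple[int, ...]
    decoy_domains: tuple[int, ...] = ()


@dataclass
class TruthManifest:
    """Per-sequence and per-genome ground truth for a simulated cohort."""

    sequences: dict[str, SequenceTruth] = field(default_factory=dict)
    genome_usp_counts: dict[str, int] = field(default_factory=dict)
    genome_hgcab: dict[str, bool] = field(default_factory=dict)

    def category_counts(self) -> dict[str, int]:
        return dict(Counter(t.category for t in self.sequences.values()))

    def motif_call_counts(self) -> dict[str, int]:
        return dict(Counter(c for t in self.sequences.values() for c in t.domain_calls))

    def methylation_table(self) -> dict[tuple[str, bool], int]:
        return dict(
            Counter(
                (t.category, self.genome_hgcab[t.genome_id])
                for t in self.sequences.values()
            )
        )


@dataclass(frozen=True)
class SimulationResult:
    fasta_path: Path
    features_path: Path
    metadata_path: Path
    manifest_path: Path
    manifest: TruthManifest


# ---------------------------------------------------------------------------
# sequence construction
# ---------------------------------------------------------------------------

def _random_background(rng: np.random.Generator, length: int) -> list[str]:
    return [AMINO_ACIDS[i] for i in rng.integers(0, len(AMINO_ACIDS), size=length)]


def _plant_domain(
    rng: np.random.Generator,
    seq: list[str],
    start: int,
    atp: bool,
    conservation: float = 0.7,
) -> list[int]:
    """Write one 12-slot contact layout into ``seq`` (1-based ``start``).

    Returns the 1-based contact positions.  Anchors get G/G/G/(S|T) when
    ``atp``; otherwise one or two anchors are broken with residues outside
    the anchor set.
    """
    positions = [start + off for off in CANONICAL_LAYOUT]
    anchor_residues = ["G", "G", "G", "ST"[rng.integers(0, 2)]]
    if not atp:
        n_break = int(rng.integers(1, 3))
        for slot in rng.choice(len(ANCHOR_SLOTS), size=n_break, replace=False):
            allowed = anchor_residues[slot]
            forbidden = set("G") if allowed == "G" else set("ST")
            choices = [a for a in AMINO_ACIDS if a not in forbidden]
            anchor_residues[slot] = choices[rng.integers(0, len(choices))]
    for slot, pos in enumerate(positions):
        if slot in ANCHOR_SLOTS:
            seq[pos - 1] = anchor_residues[ANCHOR_SLOTS.index(slot)]
        elif rng.random() < conservation:
            seq[pos - 1] = CANONICAL_RESIDUES[slot]
        else:
            seq[pos - 1] = AMINO_ACIDS[rng.integers(0, len(AMINO_ACIDS))]
    return positions


def _build_usp_sequence(
    rng: np.random.Generator,
    atp_flags: tuple[bool, ...],
    jitter: int,
    conservation: float = 0.7,
    motif: MotifSpec = DEFAULT_MOTIF,
    max_tries: int = 200,
) -> tuple[str, list[list[int]], list[int]]:
    """Sequence with one planted layout per flag; screened backgrounds.

    Returns (sequence, per-domain contact positions, planted anchor
    positions).  Rejection sampling redraws the whole sequence until the
    full-sequence motif scan finds exactly the planted anchors, so the
    contact-level call and the sequence-level scan agree by construction.
    """
    domain_span = CANONICAL_LAYOUT[-1] + 1  # 120 residues
    anchor_off = CANONICAL_LAYOUT[ANCHOR_SLOTS[0]]
    for _ in range(max_tries):
        starts = []
        cursor = CANONICAL_START
        for _flag in atp_flags:
            j = int(rng.integers(-jitter, jitter + 1)) if jitter else 0
            starts.append(max(2, cursor + j))
            cursor += domain_span + 20  # inter-domain linker
        tail = int(rng.integers(8, 25))
        length = starts[-1] + domain_span + tail
        seq = _random_background(rng, length)
        domains = [
            _plant_domain(rng, seq, start, atp, conservation)
            for start, atp in zip(starts, atp_flags)
        ]
        expected = sorted(s + anchor_off for s, a in zip(starts, atp_flags) if a)
        text = "".join(seq)
        if scan_sequence(text, motif) != expected:
            continue
        # Guard against accidental contact-level motifs in non-ATP layouts.
        ok = True
        for positions, atp in zip(domains, atp_flags):
            sites = [ContactSite(position=p, residue=text[p - 1]) for p in positions]
            call = classify_sites(sites, motif).call
            want = MotifCallValue.ATP_BINDING if atp else MotifCallValue.NON_ATP
            if call is not want:
                ok = False
                break
        if ok:
            return text, domains, expected
    raise ConfigError("could not construct a screened sequence; layout infeasible")


def _build_plain_sequence(
    rng: np.random.Generator, length: int, motif: MotifSpec = DEFAULT_MOTIF, max_tries: int = 200
) -> str:
    """Motif-free background sequence (for decoy-only / no-site queries)."""
    for _ in range(max_tries):
        text = "".join(_random_background(rng, length))
        if not scan_sequence(text, motif):
            return text
    raise ConfigError("could not construct a motif-free background")


def _decoy_sites(rng: np.random.Generator, sequence: str, n: int = 4) -> list[ContactSite]:
    positions = sorted(rng.choice(np.arange(1, len(sequence) + 1), size=n, replace=False).tolist())
    return [ContactSite(position=int(p), residue=sequence[int(p) - 1]) for p in positions]


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------

def _tandem_flags(rng: np.random.Generator, mix: tuple[float, float, float]) -> tuple[bool, bool]:
    kind = rng.choice(3, p=np.asarray(mix) / sum(mix))
    if kind == 0:  # Y: both ATP
        return (True, True)
    if kind == 1:  # N: neither
        return (False, False)
    order = rng.integers(0, 2)  # *: exactly one, position randomised
    return (True, False) if order == 0 else (False, True)


def _category_of(domain_calls: tuple[str, ...]) -> str:
    if not domain_calls:
        return "NO_USP"
    sited = [c for c in domain_calls if c != "UNCLASSIFIED"]
    if not sited:
        return "NO_SITES"
    if len(domain_calls) == 1:
        return "SINGLE_ATP" if sited[0] == "ATP_BINDING" else "SINGLE_NON_ATP"
    n_atp = sum(1 for c in sited if c == "ATP_BINDING")
    return {2: "TANDEM_Y", 1: "TANDEM_STAR", 0: "TANDEM_N"}[n_atp]


def simulate(
    config: SimulationConfig,
    out_dir: str | Path,
    usp_pssm_id: int = DEFAULT_USP_PSSM_ID,
) -> SimulationResult:
    """Emit a cohort (FASTA, Features, metadata, manifest) under ``out_dir``.

    Deterministic: identical config (including seed) gives byte-identical
    files.  The manifest is written both as TSV (per-sequence) and YAML
    (per-genome plus the config used).
    """
    rng = np.random.default_rng(config.seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    entries: list[ProteinEntry] = []
    records: list[FeatureRecord] = []
    genomes: list[GenomeRecord] = []
    manifest = TruthManifest()
    decoy_ids = sorted(DECOY_DOMAINS)

    lo, hi = config.usp_count_range
    for gi in range(config.n_genomes):
        genome_id = f"SYN{gi + 1:04d}"
        genus = GENERA[rng.integers(0, len(GENERA))]
        status = _STATUS_CHOICES[rng.choice(3, p=_STATUS_PROBS)]
        hgcab = bool(rng.random() < config.fraction_methylators)
        n_usp = int(rng.integers(lo, hi + 1))
        genomes.append(
            GenomeRecord(
                genome_id=genome_id,
                organism=f"{genus} sp. {genome_id}",
                genus=genus,
                sequencing_status=status,
                hgcab_present=hgcab,
                total_gene_count=int(rng.integers(2800, 4600)),
            )
        )
        manifest.genome_usp_counts[genome_id] = n_usp
        manifest.genome_hgcab[genome_id] = hgcab

        seq_no = 0

        def next_query_id() -> str:
            nonlocal seq_no
            seq_no += 1
            return f"{genome_id}_{seq_no:04d}"

        for _ in range(n_usp):
            query_id = next_query_id()
            if rng.random() < config.fraction_no_sites:
                # USP row reported without functional sites.
                text = _build_plain_sequence(rng, int(rng.integers(130, 320)))
                records.append(
                    FeatureRecord(
                        query_id=query_id,
                        feature_type="specific",
                        title="Ligand-Binding Site",
                        sites=(),
                        complete_size=12,
                        mapped_size=0,
                        source_domain=usp_pssm_id,
                    )
                )
                truth = SequenceTruth(
                    query_id=query_id,
                    genome_id=genome_id,
                    length_aa=len(text),
                    usp_domain_count=1,
                    domain_calls=("UNCLASSIFIED",),
                    category="NO_SITES",
                    aa_patterns=("",),
                    pos_patterns=("",),
                    planted_anchors=(),
                )
            else:
                if rng.random() < config.fraction_tandem:
                    atp_flags = _tandem_flags(rng, config.tandem_mix)
                else:
                    atp_flags = (bool(rng.random() < config.fraction_atp_single),)
                text, domain_positions, anchors = _build_usp_sequence(
                    rng, atp_flags, config.contact_layout_jitter,
                    config.residue_conservation,
                )
                aa_pats, pos_pats, calls = [], [], []
                for positions, atp in zip(domain_positions, atp_flags):
                    sites = [
                        ContactSite(position=p, residue=text[p - 1]) for p in positions
                    ]
                    records.append(
                        FeatureRecord(
                            query_id=query_id,
                            feature_type="specific",
                            title="Ligand-Binding Site",
                            sites=tuple(sites),
                            complete_size=len(sites),
                            mapped_size=len(sites),
                            source_domain=usp_pssm_id,
                        )
                    )
                    aa_pats.append(amino_acid_pattern(sites))
                    pos_pats.append(position_pattern(sites))
                    calls.append("ATP_BINDING" if atp else "NON_ATP")
                decoys: tuple[int, ...] = ()
                if len(atp_flags) == 1 and rng.random() < config.fraction_fusion:
                    # USP fused with another domain family (e.g. a metal-ion
                    # transporter), as seen in multi-domain stress proteins.
                    decoy_id = decoy_ids[rng.integers(0, len(decoy_ids))]
                    records.append(
                        FeatureRecord(
                            query_id=query_id,
                            feature_type="specific",
                            title=DECOY_DOMAINS[decoy_id],
                            sites=tuple(_decoy_sites(rng, text)),
                            complete_size=4,
                            mapped_size=4,
                            source_domain=decoy_id,
                        )
                    )
                    decoys = (decoy_id,)
                truth = SequenceTruth(
                    query_id=query_id,
                    genome_id=genome_id,
                    length_aa=len(text),
                    usp_domain_count=len(atp_flags),
                    domain_calls=tuple(calls),
                    category=_category_of(tuple(calls)),
                    aa_patterns=tuple(aa_pats),
                    pos_patterns=tuple(pos_pats),
                    planted_anchors=tuple(anchors),
                    decoy_domains=decoys,
                )
            entries.append(
                ProteinEntry(
                    query_id=truth.query_id,
                    description=f"{truth.query_id} synthetic {genomes[-1].organism}",
                    sequence=text,
                )
            )
            manifest.sequences[truth.query_id] = truth

        # Decoy-only queries: retrieved by annotation but whose hits are all
        # non-USP families.  Not counted in the genome's USP gene count.
        n_decoy_only = int(rng.binomial(n_usp, config.fraction_decoy_domains))
        for _ in range(n_decoy_only):
            query_id = next_query_id()
            text = _build_plain_sequence(rng, int(rng.integers(150, 420)))
            decoy_id = decoy_ids[rng.integers(0, len(decoy_ids))]
            records.append(
                FeatureRecord(
                    query_id=query_id,
                    feature_type="specific",
                    title=DECOY_DOMAINS[decoy_id],
                    sites=tuple(_decoy_sites(rng, text)),
                    complete_size=4,
                    mapped_size=4,
                    source_domain=decoy_id,
                )
            )
            entries.append(
                ProteinEntry(
                    query_id=query_id,
                    description=f"{query_id} synthetic {genomes[-1].organism}",
                    sequence=text,
                )
            )
            manifest.sequences[query_id] = SequenceTruth(
                query_id=query_id,
                genome_id=genome_id,
                length_aa=len(text),
                usp_domain_count=0,
                domain_calls=(),
                category="NO_USP",
                aa_patterns=(),
                pos_patterns=(),
                planted_anchors=(),
                decoy_domains=(decoy_id,),
            )

    fasta_path = out_dir / "sequences.fasta"
    features_path = out_dir / "features.tsv"
    metadata_path = out_dir / "genomes.tsv"
    manifest_path = out_dir / "manifest.yaml"
    write_fasta(entries, fasta_path)
    write_features(records, features_path)
    write_genome_metadata(genomes, metadata_path)
    _write_manifest(manifest, config, manifest_path, out_dir / "manifest.tsv")
    return SimulationResult(fasta_path, features_path, metadata_path, manifest_path, manifest)


def _write_manifest(
    manifest: TruthManifest, config: SimulationConfig, yaml_path: Path, tsv_path: Path
) -> None:
    with open(tsv_path, "w", encoding="utf-8") as fh:
        fh.write(
            "query_id\tgenome_id\tlength_aa\tusp_domain_count\tdomain_calls\t"
            "category\taa_patterns\tpos_patterns\tplanted_anchors\tdecoy_domains\n"
        )
        for t in manifest.sequences.values():
            fh.write(
                "\t".join(
                    [
                        t.query_id,
                        t.genome_id,
                        str(t.length_aa),
                        str(t.usp_domain_count),
                        ";".join(t.domain_calls),
                        t.category,
                        ";".join(t.aa_patterns),
                        ";".join(t.pos_patterns),
                        ";".join(map(str, t.planted_anchors)),
                        ";".join(map(str, t.decoy_domains)),
                    ]
                )
                + "\n"
            )
    doc = {
        "config": {
            **asdict(config),
            "usp_count_range": list(config.usp_count_range),
            "tandem_mix": list(config.tandem_mix),
        },
        "genomes": {
            gid: {
                "usp_gene_count": manifest.genome_usp_counts[gid],
                "hgcab_present": manifest.genome_hgcab[gid],
            }
            for gid in manifest.genome_usp_counts
        },
        "category_counts": manifest.category_counts(),
    }
    with open(yaml_path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def load_manifest_tsv(path: str | Path) -> TruthManifest:
    """Re-read the per-sequence manifest TSV (genome maps rebuilt from it)."""
    manifest = TruthManifest()
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        for line in fh:
            (
                query_id,
                genome_id,
                length_aa,
                n_dom,
                calls,
                category,
                aa_pats,
                pos_pats,
                anchors,
                decoys,
            ) = line.rstrip("\n").split("\t")
            manifest.sequences[query_id] = SequenceTruth(
                query_id=query_id,
                genome_id=genome_id,
                length_aa=int(length_aa),
                usp_domain_count=int(n_dom),
                domain_calls=tuple(c for c in calls.split(";") if c),
                category=category,
                aa_patterns=tuple(aa_pats.split(";")) if aa_pats else (),
                pos_patterns=tuple(pos_pats.split(";")) if pos_pats else (),
                planted_anchors=tuple(int(a) for a in anchors.split(";") if a),
                decoy_domains=tuple(int(d) for d in decoys.split(";") if d),
            )
    for t in manifest.sequences.values():
        if t.usp_domain_count:
            manifest.genome_usp_counts[t.genome_id] = (
                manifest.genome_usp_counts.get(t.genome_id, 0) + 1
            )
    return manifest
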