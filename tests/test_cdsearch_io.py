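"""I/O layer: coordinate parsing, Features round-trips, FASTA, metadata."""

import pytest

from uspprof.cdsearch_io import (
    ContactSite,
    FeatureRecord,
    FeaturesParseError,
    MetadataSchemaError,
    ProteinEntry,
    SequencingStatus,
    normalize_query_id,
    parse_coordinate_string,
    read_fasta,
    read_features,
    read_genome_metadata,
    write_fasta,
    write_features,
    write_genome_metadata,
    GenomeRecord,
)


class TestCoordinateParsing:
    def test_twelve_site_example(self, atp_sites):
        assert len(atp_sites) == 12
        assert (atp_sites[0].residue, atp_sites[0].position) == ("P", 9)
        assert (atp_sites[-1].residue, atp_sites[-1].position) == ("T", 125)

    def test_empty_string_gives_empty_list(self):
        assert parse_coordinate_string("") == []
        assert parse_coordinate_string("   ") == []

    def test_no_spaces_dialect(self):
        sites = parse_coordinate_string("G1,G4,G14,S15")
        assert [(s.residue, s.position) for s in sites] == [
            ("G", 1), ("G", 4), ("G", 14), ("S", 15),
        ]

    @pytest.mark.parametrize("bad", ["P9, 10V", "P9,,V10", "p9", "P0", "P9 V10"])
    def test_malformed_token_raises(self, bad):
        with pytest.raises(FeaturesParseError):
            parse_coordinate_string(bad)

    def test_non_increasing_positions_raise(self):
        with pytest.raises(FeaturesParseError, match="increasing"):
            parse_coordinate_string("P9, V9")
        with pytest.raises(FeaturesParseError, match="increasing"):
            parse_coordinate_string("V10, P9")


class TestContactSiteAndRecordInvariants:
    def test_contact_site_validation(self):
        with pytest.raises(ValueError):
            ContactSite(position=0, residue="G")
        with pytest.raises(ValueError):
            ContactSite(position=5, residue="g")
        with pytest.raises(ValueError):
            ContactSite(position=5, residue="GG")

    def test_mapped_size_must_match_sites(self, atp_sites):
        with pytest.raises(ValueError, match="mapped size"):
            FeatureRecord(
                query_id="q", feature_type="specific", title="t",
                sites=tuple(atp_sites), complete_size=12, mapped_size=11,
                source_domain=23812,
            )

    def test_mapped_cannot_exceed_complete(self, atp_sites):
        with pytest.raises(ValueError, match="exceeds"):
            FeatureRecord(
                query_id="q", feature_type="specific", title="t",
                sites=tuple(atp_sites), complete_size=11, mapped_size=12,
                source_domain=23812,
            )


class TestFeaturesFile:
    def make_records(self, atp_sites):
        return [
            FeatureRecord(
                query_id="SYN0001_0001", feature_type="specific",
                title="Ligand-Binding Site", sites=tuple(atp_sites),
                complete_size=12, mapped_size=12, source_domain=23812,
            ),
            FeatureRecord(
                query_id="SYN0001_0002", feature_type="specific",
                title="no sites reported", sites=(),
                complete_size=12, mapped_size=0, source_domain=23812,
            ),
        ]

    def test_round_trip_identity(self, tmp_path, atp_sites):
        records = self.make_records(atp_sites)
        path = tmp_path / "features.tsv"
        write_features(records, path)
        assert read_features(path) == records

    def test_comment_preamble_skipped(self, tmp_path, atp_sites):
        path = tmp_path / "raw.tsv"
        write_features(self.make_records(atp_sites), path)
        raw = "#Batch CD-search tool\t\n#Start time\t\n\n" + path.read_text()
        path.write_text(raw)
        assert len(read_features(path)) == 2

    def test_empty_after_comments(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("#only comments\n\n# more\n")
        assert read_features(path) == []

    def test_wrong_column_count_names_line(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("q1\tspecific\ttitle\tP9\t1\t1\n")  # 6 fields
        with pytest.raises(FeaturesParseError, match=":1:"):
            read_features(path)

    def test_non_integer_size_is_parse_error(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("q1\tspecific\ttitle\tP9\ttwelve\t1\t23812\n")
        with pytest.raises(FeaturesParseError, match="non-integer"):
            read_features(path)

    def test_query_prefix_dialect_stripped(self):
        assert normalize_query_id("Q#12 - >DND132_2657 some desc") == "DND132_2657"
        assert normalize_query_id("DND132_2657") == "DND132_2657"


class TestFasta:
    def test_wrapped_sequences_concatenate(self, tmp_path):
        entries = [
            ProteinEntry("A1", "A1 first", "M" + "AVDL" * 40),
            ProteinEntry("B2", "B2 second", "MKV"),
            ProteinEntry("C3", "C3 third", "M" + "GHST" * 36 + "K"),
        ]
        path = tmp_path / "seqs.fasta"
        write_fasta(entries, path, wrap=60)
        back = read_fasta(path)
        assert [(e.query_id, e.sequence) for e in back] == [
            (e.query_id, e.sequence) for e in entries
        ]
        assert back[0].length_aa == 161 and back[2].length_aa == 146

    def test_query_id_is_first_header_token(self, tmp_path):
        path = tmp_path / "one.fasta"
        path.write_text(">DND132_2657 hypothetical protein\nMKVLIT\n")
        (entry,) = read_fasta(path)
        assert entry.query_id == "DND132_2657"
        assert entry.length_aa == 6


class TestGenomeMetadata:
    HEADER = "genome_id\torganism\tgenus\tsequencing_status\thgcab_present\ttotal_gene_count\thabitat\n"

    def test_read_and_status_normalization(self, tmp_path):
        path = tmp_path / "genomes.tsv"
        path.write_text(
            self.HEADER
            + "G1\tDesulfovibrio sp. G1\tDesulfovibrio\tFinished\ttrue\t3500\tmarine\n"
            + "G2\tBilophila sp. G2\tBilophila\t Permanent Draft \tno\t\tgut\n"
        )
        recs = read_genome_metadata(path)
        assert len(recs) == 2
        assert recs[0].sequencing_status is SequencingStatus.FINISHED
        assert recs[0].hgcab_present is True and recs[0].total_gene_count == 3500
        assert recs[1].sequencing_status is SequencingStatus.PERMANENT_DRAFT
        assert recs[1].total_gene_count is None
        assert recs[1].extra["habitat"] == "gut"

    def test_missing_column_is_schema_error(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("genome_id\torganism\n" "G1\tx\n")
        with pytest.raises(MetadataSchemaError, match="missing required"):
            read_genome_metadata(path)

    def test_unrecognized_status_is_error(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(self.HEADER + "G1\to\tg\tcomplete\ttrue\t\t\n")
        with pytest.raises(MetadataSchemaError, match="sequencing status"):
            read_genome_metadata(path)

    def test_round_trip(self, tmp_path):
        recs = [
            GenomeRecord("G1", "Desulfovibrio sp. G1", "Desulfovibrio",
                         SequencingStatus.DRAFT, False, 4000, {"habitat": "mud"}),
        ]
        path = tmp_path / "rt.tsv"
        write_genome_metadata(recs, path)
        assert read_genome_metadata(path) == recs
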