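"""ATP-binding motif: contact-level and sequence-level classification."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from uspprof.cdsearch_io import ContactSite, parse_coordinate_string
from uspprof.motif_classifier import (
    DEFAULT_MOTIF,
    MotifCall,
    MotifSpec,
    classify_all,
    classify_sites,
    parse_motif_string,
    scan_sequence,
)
from uspprof.pattern_extraction import MotifCallValue, SitePattern


class TestMotifSpec:
    def test_default_anchors(self):
        assert DEFAULT_MOTIF.anchors == (
            (0, frozenset("G")), (3, frozenset("G")),
            (13, frozenset("G")), (14, frozenset("ST")),
        )
        assert DEFAULT_MOTIF.span == 15

    def test_grammar_round_trip(self):
        assert parse_motif_string("G,2,G,9,G,ST") == DEFAULT_MOTIF

    @pytest.mark.parametrize("bad", ["G,,G", "G,2,G,9,G,S-T", ""])
    def test_bad_grammar(self, bad):
        with pytest.raises(ValueError):
            parse_motif_string(bad)

    def test_offsets_validated(self):
        with pytest.raises(ValueError):
            MotifSpec(anchors=((1, frozenset("G")),))
        with pytest.raises(ValueError):
            MotifSpec(anchors=((0, frozenset("G")), (0, frozenset("S"))))


class TestClassifySites:
    def test_mj0577_style_pattern_is_atp(self, atp_sites):
        call = classify_sites(atp_sites)
        assert call.call is MotifCallValue.ATP_BINDING
        assert call.anchor_position == 109  # G109, G112, G122, S123

    def test_common_family_pattern_is_atp(self):
        sites = parse_coordinate_string(
            "A10, V11, D12, V40, M112, G113, H115, G116, G126, S127, V128, A129"
        )
        call = classify_sites(sites)
        assert call.call is MotifCallValue.ATP_BINDING
        assert call.anchor_position == 113

    def test_transporter_fusion_pattern_is_non_atp(self):
        # ALGVMGHGGETV: every candidate G fails some anchor (E at +14 etc).
        sites = parse_coordinate_string(
            "A9, L10, G11, V39, M111, G112, H114, G115, G125, E126, T127, V128"
        )
        assert classify_sites(sites).call is MotifCallValue.NON_ATP

    def test_empty_sites_unclassified(self):
        call = classify_sites([])
        assert call.call is MotifCallValue.UNCLASSIFIED
        assert call.anchor_position is None

    def test_smallest_anchor_reported(self):
        # Two complete anchor sets, at p=1 and p=101.
        sites = parse_coordinate_string("G1, G4, G14, S15, G101, G104, G114, T115")
        call = classify_sites(sites)
        assert (call.call, call.anchor_position) == (MotifCallValue.ATP_BINDING, 1)

    def test_anchor_must_be_contact_site(self):
        # Drop the final S/T from a complete anchor set: no longer ATP,
        # even if the underlying sequence might hold the motif.
        sites = parse_coordinate_string("G1, G4, G14")
        assert classify_sites(sites).call is MotifCallValue.NON_ATP

    def test_monotone_destruction(self, atp_sites):
        base = classify_sites(atp_sites)
        p = base.anchor_position
        for drop in (p, p + 3, p + 13, p + 14):
            remaining = [s for s in atp_sites if s.position != drop]
            assert classify_sites(remaining).call is MotifCallValue.NON_ATP
        # Substituting an anchor G also destroys the call.
        mutated = [
            ContactSite(position=s.position, residue="A" if s.position == p else s.residue)
            for s in atp_sites
        ]
        assert classify_sites(mutated).call is MotifCallValue.NON_ATP

    def test_ambiguity_codes_never_anchor(self):
        sites = parse_coordinate_string("X1, X4, X14, B15")
        assert classify_sites(sites).call is MotifCallValue.NON_ATP

    @settings(max_examples=150, deadline=None)
    @given(
        extra=st.lists(
            st.tuples(st.integers(130, 400), st.sampled_from("ACDEFHIKLMNPQRVWY")),
            max_size=10, unique_by=lambda t: t[0],
        )
    )
    def test_adding_non_anchor_sites_never_flips_atp(self, extra):
        base = parse_coordinate_string(
            "P9, V10, D11, C39, M108, G109, R111, G112, G122, S123, V124, T125"
        )
        augmented = sorted(
            base + [ContactSite(position=p, residue=r) for p, r in extra],
            key=lambda s: s.position,
        )
        assert classify_sites(augmented).call is MotifCallValue.ATP_BINDING


class TestScanSequence:
    def test_minimal_exact_fit(self):
        assert scan_sequence("G" + "AA" + "G" + "A" * 9 + "G" + "S") == [1]

    def test_broken_tail_no_hit(self):
        assert scan_sequence("G" + "AA" + "G" + "A" * 9 + "G" + "A") == []

    def test_interior_hit_position(self):
        seq = "M" * 112 + "G" + "AA" + "G" + "A" * 9 + "G" + "T" + "M" * 10
        assert scan_sequence(seq) == [113]

    def test_invalid_sequence_rejected(self):
        with pytest.raises(ValueError):
            scan_sequence("")
        with pytest.raises(ValueError):
            scan_sequence("MKV1")


class TestClassifyAll:
    def test_partition_and_determinism(self, atp_sites):
        patterns = [
            SitePattern.from_sites("q1", 23812, atp_sites),
            SitePattern.from_sites(
                "q2", 23812,
                parse_coordinate_string("A9, L10, G11, V39, M111, G112, H114, G115, G125, E126, T127, V128"),
            ),
            SitePattern("q3", 23812, "", "", 0),
        ]
        out1 = classify_all(patterns)
        out2 = classify_all(patterns)
        assert out1 == out2
        calls = [p.motif_call for p in out1]
        assert calls == [
            MotifCallValue.ATP_BINDING, MotifCallValue.NON_ATP, MotifCallValue.UNCLASSIFIED,
        ]
        assert out1[0].anchor_position == 109

    def test_all_empty_sites_all_unclassified(self):
        patterns = [SitePattern(f"q{i}", 23812, "", "", 0) for i in range(4)]
        assert all(
            p.motif_call is MotifCallValue.UNCLASSIFIED for p in classify_all(patterns)
        )


class TestContactVsSequenceEquivalence:
    def test_planted_domains_agree_both_routes(self):
        """Contact-level call and full-sequence scan agree on generated domains."""
        from uspprof.synthetic_data import _build_usp_sequence

        rng = np.random.default_rng(7)
        for i in range(60):
            atp = bool(i % 2)
            text, domains, anchors = _build_usp_sequence(rng, (atp,), jitter=3)
            sites = [ContactSite(position=p, residue=text[p - 1]) for p in domains[0]]
            call = classify_sites(sites)
            hits = scan_sequence(text)
            assert (call.call is MotifCallValue.ATP_BINDING) == bool(hits)
            if atp:
                assert hits == [call.anchor_position] == anchors
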