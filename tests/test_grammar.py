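"""Slot table, part validation, flanking, plasmid assembly and metadata."""

import itertools

import pytest

from ptgr.errors import GrammarError, RegistryError
from ptgr.grammar import (
    BACKBONE_ROLES,
    Part,
    PartMetadata,
    SLOTS,
    TU_FLANKS,
    TU_ROLES,
    assemble_single_tu,
    excise_core,
    flank_part,
    measure_sd_spacing,
    normalize_fluorescence,
    rank_constructs,
    validate_part,
    validate_plasmid,
)
from ptgr.seqcore import ENZYMES, digest, scan_sites


class TestSlotTable:
    def test_exactly_eight_roles(self):
        assert len(SLOTS) == 8
        assert set(SLOTS) == set(TU_ROLES) | set(BACKBONE_ROLES)

    def test_shipped_flanking_contract(self):
        assert SLOTS["ecoli_ori"] == ("BglII", "SphI")
        assert SLOTS["marker"] == ("SphI", "PstI")
        assert SLOTS["host_ori"] == ("PstI", "KpnI")
        assert SLOTS["regulator"] == ("BamHI", "BglII")
        assert SLOTS["promoter"] == ("XbaI", "NheI")
        assert SLOTS["rbs"] == ("NheI", "NdeI")
        assert SLOTS["orf"] == ("NdeI", "EcoRI")
        assert SLOTS["terminator"] == ("AvrII", "SpeI")
        assert TU_FLANKS == ("XbaI", "SpeI")

    def test_enzyme_chain_is_consistent(self):
        """Adjacent slots share their boundary enzyme."""
        for left, right in (
            ("promoter", "rbs"),
            ("rbs", "orf"),
            ("regulator", "ecoli_ori"),
            ("ecoli_ori", "marker"),
            ("marker", "host_ori"),
        ):
            assert SLOTS[left][1] == SLOTS[right][0]
        assert SLOTS["promoter"][0] == TU_FLANKS[0]
        assert SLOTS["terminator"][1] == TU_FLANKS[1]


class TestValidatePart:
    def test_planted_cassette_site_is_an_error(self, registry):
        orf = registry.get("eGFP")
        poisoned = Part("bad", "orf", orf.core_seq[:-3] + "GAATTC" + orf.core_seq[-3:])
        rep = validate_part(poisoned)
        assert any(f.code == "forbidden-site" for f in rep.errors)
        pos = next(f.position for f in rep.errors if f.code == "forbidden-site")
        assert poisoned.core_seq[pos : pos + 6] == "GAATTC"

    def test_fixture_parts_are_clean(self, registry):
        for part in registry.parts.values():
            assert validate_part(part).ok or not validate_part(part).errors

    def test_orf_frame_and_stop_rules(self):
        assert any(
            f.code == "orf-start" for f in validate_part(Part("x", "orf", "TTGAAATAA")).errors
        )
        assert any(
            f.code == "orf-frame" for f in validate_part(Part("x", "orf", "ATGAAATA")).errors
        )
        assert any(
            f.code == "orf-stop" for f in validate_part(Part("x", "orf", "ATGAAAGCC")).errors
        )
        assert any(
            f.code == "orf-internal-stop"
            for f in validate_part(Part("x", "orf", "ATGTAAGCCTAA")).errors
        )

    def test_rbs_spacing_mismatch_warns(self, registry):
        rbs = registry.get("sod_rbs")
        measured = measure_sd_spacing(rbs.core_seq)
        declared_wrong = Part(
            "rbs2", "rbs", rbs.core_seq, PartMetadata(native_spacing=measured + 2)
        )
        rep = validate_part(declared_wrong)
        assert any(f.code == "rbs-spacing" for f in rep.warnings)

    def test_unknown_role_rejected(self):
        with pytest.raises(GrammarError):
            Part("x", "operator", "ACGT")


class TestFlankPart:
    def test_promoter_flanks(self, registry):
        p = registry.get("tac")
        flanked = flank_part(p)
        assert flanked == "TCTAGA" + p.core_seq + "GCTAGC"

    def test_terminator_flanks(self, registry):
        t = registry.get("rrnBT1T2")
        assert flank_part(t) == "CCTAGG" + t.core_seq + "ACTAGT"

    def test_orf_atg_embedded_in_ndei(self, registry):
        orf = registry.get("eGFP")
        flanked = flank_part(orf)
        assert flanked.startswith("CATATG")
        assert flanked.endswith("GAATTC")
        assert flanked.count("CATATG") == 1 and flanked.count("GAATTC") == 1

    @pytest.mark.parametrize("pid", ["tac", "sod_rbs", "eGFP", "rrnBT1T2", "pGA1"])
    def test_flank_then_excise_recovers_core(self, registry, pid):
        part = registry.get(pid)
        assert excise_core(flank_part(part), part.role) == part.core_seq

    def test_boundary_site_creation_rejected(self):
        # promoter core ending CCTAG + the NheI flank's G forms a stray AvrII
        with pytest.raises(GrammarError, match="AvrII"):
            flank_part(Part("p", "promoter", "TTTTTCCTAG"))


class TestAssembleSingleTu:
    def test_full_eight_part_plasmid(self, registry):
        parts = [registry.get(i) for i in
                 ("pGA1", "colE1", "kanR", "rrnBT1T2", "tac", "sod_rbs", "eGFP", "lacI")]
        m = assemble_single_tu(parts, name="pTGR5-like")
        assert validate_plasmid(m).ok
        roles = {f.role for f in m.features if f.role in SLOTS}
        assert roles == set(SLOTS)
        for name in ENZYMES:
            assert len(scan_sites(m, name)) == 1, name

    def test_promoterless_degenerate_form(self, registry):
        parts = [registry.get(i) for i in ("pGA1", "colE1", "kanR", "rrnBT1T2", "eGFP")]
        m = assemble_single_tu(parts, name="pTGR1-like")
        assert validate_plasmid(m).ok
        for name in ENZYMES:
            assert len(scan_sites(m, name)) == 1, name

    def test_duplicate_role_rejected(self, registry):
        parts = [registry.get(i) for i in ("pGA1", "pCRY4", "colE1", "kanR", "rrnBT1T2")]
        with pytest.raises(GrammarError, match="host_ori"):
            assemble_single_tu(parts)

    def test_inducible_promoter_requires_regulator(self, registry):
        parts = [registry.get(i) for i in
                 ("pGA1", "colE1", "kanR", "rrnBT1T2", "tac", "sod_rbs", "eGFP")]
        with pytest.raises(GrammarError, match="lacI"):
            assemble_single_tu(parts)

    def test_all_fixture_combinations_validate(self, registry):
        """3 promoters x 3 RBSs x 2 ORFs x 3 replicons assemble cleanly."""
        promoters = ("tac", "cspB", "sod")
        rbss = ("sod_rbs", "lacZ_rbs", "cspB_rbs")
        orfs = ("eGFP", "mCherry")
        replicons = ("pGA1", "pCRY4", "pNG2")
        for prom, rbs, orf, repl in itertools.product(promoters, rbss, orfs, replicons):
            ids = [repl, "colE1", "kanR", "rrnBT1T2", prom, rbs, orf]
            if registry.get(prom).meta.regulator:
                ids.append(registry.get(prom).meta.regulator)
            m = assemble_single_tu([registry.get(i) for i in ids])
            assert validate_plasmid(m).ok, (prom, rbs, orf, repl)

    def test_slot_excision_roundtrip_on_assembled_plasmid(self, registry):
        """Digesting any slot out of a plasmid recovers the part core."""
        parts = [registry.get(i) for i in
                 ("pGA1", "colE1", "kanR", "rrnBT1T2", "tac", "sod_rbs", "eGFP", "lacI")]
        m = assemble_single_tu(parts)
        for part in parts:
            left, right = SLOTS[part.role]
            frags = digest(m, [left, right])
            slot_frag = next(
                f for f in frags if any(x.label == part.id for x in f.features)
            )
            (feat,) = [x for x in slot_frag.features if x.label == part.id]
            assert slot_frag.seq[feat.start : feat.end] == part.core_seq


class TestPlasmidAudit:
    def test_stray_site_in_orf_is_an_error(self, registry, backbone):
        poisoned = backbone.seq[:100] + "ACTAGT" + backbone.seq[100:]
        from ptgr.seqcore import DnaMolecule

        rep = validate_plasmid(DnaMolecule(poisoned, "circular"))
        assert any(
            f.code == "duplicate-site" and "SpeI" in f.message for f in rep.errors
        )

    def test_findings_ordered_by_position(self, backbone):
        from ptgr.seqcore import DnaMolecule

        poisoned = backbone.seq[:100] + "ACTAGTTCTAGA" + backbone.seq[100:]
        rep = validate_plasmid(DnaMolecule(poisoned, "circular"))
        positions = [f.position for f in rep.findings]
        assert positions == sorted(positions)


class TestMetadata:
    def test_brightness_normalisation(self, registry):
        assert normalize_fluorescence(34, "eGFP", registry) == 1.0
        assert normalize_fluorescence(16, "mCherry", registry) == 1.0
        assert normalize_fluorescence(0, "eGFP", registry) == 0.0

    def test_unknown_fluorophore_rejected(self, registry):
        with pytest.raises(RegistryError):
            normalize_fluorescence(10, "sfGFP", registry)

    def test_shipped_ranks(self, registry):
        assert registry.get("tac").meta.strength_rank == "high"
        assert registry.get("cspB").meta.strength_rank == "medium"
        assert registry.get("sod").meta.strength_rank == "low"
        assert registry.get("sod_rbs").meta.strength_rank == "high"
        assert registry.get("lacZ_rbs").meta.strength_rank == "medium"
        assert registry.get("cspB_rbs").meta.strength_rank == "low"

    def test_construct_partial_order(self, registry):
        constructs = [
            ("tac", "sod_rbs", "pGA1"),
            ("sod", "sod_rbs", "pGA1"),
            ("sod", "lacZ_rbs", "pGA1"),
            ("tac", "cspB_rbs", "pGA1"),
        ]
        order = rank_constructs(constructs, registry)
        assert order.compare(0, 1) == "ge"  # promoter rank decides
        assert order.compare(0, 2) == "ge"  # both rankings agree
        assert order.compare(3, 1) == "incomparable"  # ranks conflict
        assert order.compare(1, 0) == "le"
        assert order.compare(2, 2) == "eq"

    def test_unranked_part_excluded_with_warning(self, registry):
        order = rank_constructs(
            [("tac", "sod_rbs", "pGA1"), ("tac", "sod_rbs", "colE1")], registry
        )
        assert order.excluded == [1]
        assert order.warnings
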