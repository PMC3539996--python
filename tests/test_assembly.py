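"""Cloning procedures: insertion, operon/cluster extension, swaps, planning."""

import random

import pytest

from ptgr.assembly import (
    CloningStep,
    Design,
    GeneSpec,
    TuSpec,
    assemble_monolithic,
    build_series,
    execute_plan,
    extend_cluster,
    extend_operon,
    insert_orf,
    plan_assembly,
    reference_series,
    swap_slot,
)
from ptgr.errors import AssemblyError, RegulatorRequiredWarning
from ptgr.grammar import assemble_single_tu, validate_plasmid
from ptgr.seqcore import DnaMolecule, digest, scan_sites, site_census


def single_tu(registry, prom, rbs, orf, repl="pGA1", name="v"):
    ids = [repl, "colE1", "kanR", "rrnBT1T2"]
    if prom:
        ids.append(prom)
        if registry.get(prom).meta.regulator:
            ids.append(registry.get(prom).meta.regulator)
    if rbs:
        ids.append(rbs)
    if orf:
        ids.append(orf)
    return assemble_single_tu([registry.get(i) for i in ids], name=name)


class TestInsertOrf:
    def test_insertion_into_empty_slot(self, registry):
        vector = single_tu(registry, None, "sod_rbs", None, name="pTGR2-like")
        product = insert_orf(vector, registry.get("eGFP"))
        assert len(scan_sites(product, "NdeI")) == 1
        assert len(scan_sites(product, "EcoRI")) == 1
        assert product.features_by_role("orf")
        assert not validate_plasmid(product).errors

    def test_roundtrip_excision_recovers_flanked_orf(self, registry):
        from ptgr.grammar import flank_part

        vector = single_tu(registry, None, "sod_rbs", None)
        product = insert_orf(vector, registry.get("eGFP"))
        frags = digest(product, ["NdeI", "EcoRI"])
        insert = next(f for f in frags if f.features_by_role("orf"))
        flanked = flank_part(registry.get("eGFP"))
        # fragment spans from the NdeI top cut to the EcoRI top cut
        assert insert.seq == flanked[2:-5]

    def test_duplicated_site_rejected(self, registry, backbone):
        poisoned = DnaMolecule(
            backbone.seq[:50] + "GAATTC" + backbone.seq[50:], "circular",
        )
        with pytest.raises(AssemblyError, match="EcoRI"):
            insert_orf(poisoned, registry.get("eGFP"))

    def test_backbone_must_be_identifiable(self, registry):
        naked = DnaMolecule("CATATG" + "ACGGCA" * 20 + "GAATTC" + "TGGCAT" * 30, "circular")
        with pytest.raises(AssemblyError):
            insert_orf(naked, registry.get("eGFP"))


@pytest.fixture(scope="module")
def acceptor(registry):
    return single_tu(registry, "tac", "sod_rbs", "mCherry", name="acc")


@pytest.fixture(scope="module")
def donor(registry):
    return single_tu(registry, "tac", "sod_rbs", "eGFP", name="don")


class TestExtendOperon:
    def test_gene_order_and_census(self, registry, acceptor, donor):
        product = extend_operon(acceptor, donor)
        census = site_census(product)
        assert census["NheI"] == 1 and census["AvrII"] == 1
        assert census["NdeI"] == 2 and census["EcoRI"] == 2
        orfs = sorted(product.features_by_role("orf"), key=lambda f: f.start)
        # resident gene first, incoming gene downstream
        labels = [f.label.split("#")[0] for f in orfs]
        assert labels == ["mCherry", "eGFP"]
        assert any(f.label.startswith("scar:NheI/AvrII") for f in product.features)

    def test_length_additivity(self, registry, acceptor, donor):
        product = extend_operon(acceptor, donor)
        cassette = next(
            f for f in digest(donor, ["NheI", "AvrII"]) if f.features_by_role("orf")
        )
        assert len(product) == len(acceptor) + len(cassette)

    def test_recursive_extension_closure(self, registry, acceptor, donor):
        """After k extensions: 1 promoter, k+1 RBS/ORF features, NdeI x(k+1)."""
        plasmid = acceptor
        for k in (1, 2):
            plasmid = extend_operon(plasmid, donor)
            census = site_census(plasmid)
            assert census["NheI"] == 1 and census["AvrII"] == 1
            assert census["NdeI"] == k + 1 and census["EcoRI"] == k + 1
            assert len(plasmid.features_by_role("promoter")) == 1
            assert len(plasmid.features_by_role("rbs")) == k + 1
            assert len(plasmid.features_by_role("orf")) == k + 1
            assert len(plasmid.features_by_role("terminator")) == 1
            assert not validate_plasmid(plasmid).errors

    def test_multi_tu_acceptor_refused(self, registry, cluster_design):
        two_tu = execute_plan(plan_assembly(cluster_design, registry), registry)
        donor = single_tu(registry, "tac", "sod_rbs", "eGFP")
        assert len(scan_sites(two_tu, "AvrII")) == 2
        with pytest.raises(AssemblyError, match="targeted"):
            extend_operon(two_tu, donor)


class TestExtendCluster:
    def test_cluster_joint_scars(self, registry):
        acceptor = single_tu(registry, "tac", "sod_rbs", "eGFP", name="accT")
        donor = single_tu(registry, "sod", "sod_rbs", "mCherry", name="donT")
        product = extend_cluster(acceptor, donor)
        census = site_census(product)
        assert census["XbaI"] == 1 and census["SpeI"] == 1
        for name in ("NheI", "AvrII", "NdeI", "EcoRI"):
            assert census[name] == 2
        scars = [f for f in product.features if f.label.startswith("scar:XbaI/SpeI")]
        assert len(scars) == 1
        # dead joint reads ACTAGA; regenerated SpeI downstream
        scar = scars[0]
        assert product.subseq(scar.start, 6) == "ACTAGA"

    def test_recursive_third_unit(self, registry):
        acceptor = single_tu(registry, "tac", "sod_rbs", "eGFP")
        donor = single_tu(registry, "sod", "sod_rbs", "mCherry")
        two = extend_cluster(acceptor, donor)
        three = extend_cluster(two, donor)
        census = site_census(three)
        assert census["XbaI"] == 1 and census["SpeI"] == 1
        assert len(three.features_by_role("terminator")) == 3
        joints = [f for f in three.features if f.label.startswith("scar:XbaI/SpeI")]
        assert len(joints) == 2
        assert not validate_plasmid(three).errors


class TestSwapSlot:
    def test_replicon_swap_reaches_low_copy_variant(self, registry):
        p5 = single_tu(registry, "tac", "sod_rbs", "eGFP", name="p5")
        p17 = single_tu(registry, "tac", "sod_rbs", "eGFP", repl="pCRY4", name="p17")
        swapped = swap_slot(p5, "host_ori", registry.get("pCRY4"))
        assert swapped.same_sequence(p17)

    def test_identity_swap_is_identity(self, registry):
        p5 = single_tu(registry, "tac", "sod_rbs", "eGFP")
        assert swap_slot(p5, "host_ori", registry.get("pGA1")).same_sequence(p5)

    def test_promoter_swap_flags_missing_regulator(self, registry):
        p3 = single_tu(registry, "sod", "sod_rbs", "eGFP")
        with pytest.warns(RegulatorRequiredWarning):
            swapped = swap_slot(p3, "promoter", registry.get("tac"))
        (prom,) = swapped.features_by_role("promoter")
        assert prom.label == "tac"

    def test_role_mismatch_rejected(self, registry):
        p5 = single_tu(registry, "tac", "sod_rbs", "eGFP")
        with pytest.raises(AssemblyError):
            swap_slot(p5, "host_ori", registry.get("kanR"))


class TestPlanning:
    def test_two_gene_operon_needs_two_stages(self, registry, operon_design):
        assert plan_assembly(operon_design, registry).n_stages == 2

    def test_two_tu_cluster_needs_two_stages(self, registry, cluster_design):
        assert plan_assembly(cluster_design, registry).n_stages == 2

    def test_single_gene_single_stage(self, registry):
        d = Design("one", (TuSpec("tac", (GeneSpec("sod_rbs", "eGFP"),)),), "pGA1")
        assert plan_assembly(d, registry).n_stages == 1

    def test_stage_count_equals_gene_count_randomised(self, registry):
        """n genes -> n stages for arbitrary TU partitions, n = 1..6."""
        rng = random.Random(23)
        rbss = ("sod_rbs", "lacZ_rbs", "cspB_rbs")
        proms = ("tac", "cspB", "sod")
        for n in range(1, 7):
            for _ in range(10):
                genes = [GeneSpec(rng.choice(rbss), rng.choice(("eGFP", "mCherry"))) for _ in range(n)]
                cutpoints = sorted(rng.sample(range(1, n), rng.randint(0, n - 1))) if n > 1 else []
                tus, prev = [], 0
                for c in cutpoints + [n]:
                    tus.append(TuSpec(rng.choice(proms), tuple(genes[prev:c])))
                    prev = c
                d = Design(f"rand{n}", tuple(tus), "pGA1")
                assert plan_assembly(d, registry).n_stages == n

    def test_step_enzyme_contract_enforced(self):
        with pytest.raises(AssemblyError):
            CloningStep("insert_orf", "a", "b", "c", ("NheI", "AvrII"))

    def test_empty_plan_rejected(self, registry, operon_design):
        from ptgr.assembly import CloningPlan

        with pytest.raises(AssemblyError, match="empty"):
            CloningPlan(operon_design, []).validate()


class TestExecution:
    def test_operon_plan_reproduces_worked_example(self, registry, operon_design):
        product = execute_plan(plan_assembly(operon_design, registry), registry)
        acceptor = single_tu(registry, "tac", "sod_rbs", "mCherry")
        donor = single_tu(registry, "tac", "sod_rbs", "eGFP")
        assert product.same_sequence(extend_operon(acceptor, donor))

    def test_cluster_plan_reproduces_worked_example(self, registry, cluster_design):
        product = execute_plan(plan_assembly(cluster_design, registry), registry)
        acceptor = single_tu(registry, "tac", "sod_rbs", "eGFP")
        donor = single_tu(registry, "sod", "sod_rbs", "mCherry")
        assert product.same_sequence(extend_cluster(acceptor, donor))

    def test_execution_matches_monolithic_assembly(self, registry, operon_design, cluster_design):
        for design in (operon_design, cluster_design):
            simulated = execute_plan(plan_assembly(design, registry), registry)
            assert simulated.same_sequence(assemble_monolithic(design, registry))


class TestSeries:
    def test_reference_series_builds_seventeen_constructs(self, registry):
        built, dupes = build_series(reference_series(), registry)
        assert len(built) == 17 and not dupes
        canonicals = {m.canonical for m in built.values()}
        assert len(canonicals) == 17  # all structurally distinct
        for name, m in built.items():
            assert not validate_plasmid(m).errors, name
        # the two dual-gene formats are present
        assert site_census(built["pTGR8"])["NdeI"] == 2  # operon
        assert len(built["pTGR9"].features_by_role("terminator")) == 2  # cluster

    def test_cartesian_subseries_count(self, registry):
        designs = [
            Design(f"c{p}{r}", (TuSpec(p, (GeneSpec(r, "eGFP"),)),), "pGA1")
            for p in ("tac", "cspB", "sod")
            for r in ("sod_rbs", "lacZ_rbs", "cspB_rbs")
        ]
        built, dupes = build_series(designs, registry)
        assert len(built) == 9 and not dupes

    def test_duplicate_rows_deduplicated_with_warning(self, registry):
        d = Design("a", (TuSpec("tac", (GeneSpec("sod_rbs", "eGFP"),)),), "pGA1")
        d2 = Design("b", d.tus, "pGA1")
        built, dupes = build_series([d, d2], registry)
        assert list(built) == ["a"]
        assert len(dupes) == 1 and "duplicates" in dupes[0]
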