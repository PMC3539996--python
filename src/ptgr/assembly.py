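"""Cloning procedures of the pTGR standard as executable algorithms.

Four wet-lab moves cover every construction the standard supports:

* **insert_orf** -- clone a gene between the unique NdeI and EcoRI sites
  (directional: TA and AATT overhangs force the orientation).
* **extend_operon** -- excise the NheI-AvrII cassette (RBS + ORF) from a
  donor and insert it into the unique AvrII site of an acceptor.  The
  correct-orientation product carries a dead NheI/AvrII scar between the
  upstream gene's stop and the incoming RBS, and regenerates AvrII
  downstream, so the move is recursive.
* **extend_cluster** -- excise a whole transcriptional unit with XbaI and
  SpeI and insert it into the unique SpeI site of an acceptor; a dead
  XbaI/SpeI scar forms at the joint and SpeI is regenerated.
* **swap_slot** -- exchange any single part using its slot's flanking pair
  (e.g. the replicon via PstI/KpnI).

``plan_assembly`` turns a multi-gene design into a staged plan that needs
exactly as many cloning steps as genes (parallel clonings share a stage),
and ``execute_plan`` runs each step through the digestion/ligation
simulator, so the planner's output can be cross-checked against a
monolithic in-silico assembly of the same design.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

from .errors import AssemblyError, RegulatorRequiredWarning
from . import grammar
from .grammar import (
    Part,
    Registry,
    SLOTS,
    SPACER,
    assemble_single_tu,
    validate_plasmid,
)
from .ligation import ligate_circular, scar_label
from .seqcore import ENZYMES, DnaMolecule, digest, scan_sites

log = logging.getLogger("ptgr.assembly")


# ---------------------------------------------------------------------------
# designs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneSpec:
    """One gene inside a transcriptional unit: its RBS and ORF part ids."""

    rbs: str | None
    orf: str


@dataclass(frozen=True)
class TuSpec:
    """One transcriptional unit: a promoter and an ordered run of genes."""

    promoter: str | None
    genes: tuple[GeneSpec, ...]

    def __post_init__(self) -> None:
        if not self.genes:
            raise AssemblyError("a transcriptional unit needs at least one gene")


@dataclass(frozen=True)
class Design:
    """An ordered list of TUs plus the shared backbone configuration."""

    name: str
    tus: tuple[TuSpec, ...]
    replicon: str
    marker: str = "kanR"
    ecoli_ori: str = "colE1"
    terminator: str = "rrnBT1T2"

    def __post_init__(self) -> None:
        if not self.tus:
            raise AssemblyError("a design needs at least one transcriptional unit")

    @property
    def gene_count(self) -> int:
        return sum(len(tu.genes) for tu in self.tus)


# ---------------------------------------------------------------------------
# plans
# ---------------------------------------------------------------------------

_STEP_ENZYMES = {
    "insert_orf": ("NdeI", "EcoRI"),
    "transfer_operon_cassette": ("NheI", "AvrII"),
    "transfer_tu": ("XbaI", "SpeI"),
}


@dataclass(frozen=True)
class CloningStep:
    kind: str  # insert_orf | transfer_operon_cassette | transfer_tu | swap_slot
    donor: str  # part id (insert_orf/swap) or intermediate plasmid id
    acceptor: str  # vector id or intermediate plasmid id
    product: str
    enzymes: tuple[str, ...]
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind in _STEP_ENZYMES and tuple(self.enzymes) != _STEP_ENZYMES[self.kind]:
            raise AssemblyError(
                f"step kind {self.kind} must use {_STEP_ENZYMES[self.kind]}"
            )
        if self.kind == "swap_slot" and tuple(self.enzymes) not in {
            tuple(v) for v in SLOTS.values()
        }:
            raise AssemblyError("swap_slot enzymes must be a slot flanking pair")


@dataclass
class CloningPlan:
    """Ordered stages; steps within one stage run in parallel."""

    design: Design
    stages: list[list[CloningStep]]

    @property
    def n_stages(self) -> int:
        return len(self.stages)

    def validate(self) -> None:
        if not self.stages or not any(self.stages):
            raise AssemblyError("empty plan")
        known: set[str] = set()
        for si, stage in enumerate(self.stages):
            for step in stage:
                if step.kind != "insert_orf" and (
                    step.donor not in known or step.acceptor not in known
                ):
                    raise AssemblyError(
                        f"stage {si}: step {step.product} uses an intermediate "
                        "that does not exist yet"
                    )
            known |= {step.product for step in stage}

    def to_dict(self) -> dict:
        return {
            "design": self.design.name,
            "stages": [
                [
                    {
                        "kind": s.kind,
                        "donor": s.donor,
                        "acceptor": s.acceptor,
                        "product": s.product,
                        "enzymes": list(s.enzymes),
                        "params": s.params,
                    }
                    for s in stage
                ]
                for stage in self.stages
            ],
        }


# ---------------------------------------------------------------------------
# fragment selection helpers
# ---------------------------------------------------------------------------


def _fragment_with_roles(fragments, required, excluded=()):
    """Pick the unique fragment carrying features of every required role."""
    hits = []
    for f in fragments:
        roles = {feat.role for feat in f.features}
        if all(r in roles for r in required) and not (roles & set(excluded)):
            hits.append(f)
    if len(hits) != 1:
        raise AssemblyError(
            f"cannot identify fragment with roles {required}: {len(hits)} candidates"
        )
    return hits[0]


def _insert_fragment(part: Part) -> DnaMolecule:
    """The flanked part as it comes out of a digestion with its slot pair."""
    from .seqcore import Feature, StickyEnd, revcomp

    left_name, right_name = SLOTS[part.role]
    le, re_ = ENZYMES[left_name], ENZYMES[right_name]
    flanked = grammar.flank_part(part)
    seq = flanked[le.cut_top : len(flanked) - (re_.site_len - re_.cut_top)]
    core_start = (3 if part.role == "orf" else le.site_len) - le.cut_top

    def right_side(e):
        if e.overhang_kind == "five_prime":
            return StickyEnd("five_prime", e.overhang, e.name)
        return StickyEnd("three_prime", revcomp(e.overhang), e.name)

    def left_side(e):
        if e.overhang_kind == "five_prime":
            return StickyEnd("five_prime", revcomp(e.overhang), e.name)
        return StickyEnd("three_prime", e.overhang, e.name)

    return DnaMolecule(
        seq,
        "linear",
        [Feature(part.id, part.role, core_start, core_start + len(part.core_seq))],
        left_end=right_side(le),
        right_end=left_side(re_),
        id=f"{part.id}.insert",
    )


def _require_unique(m: DnaMolecule, enzyme: str, what: str) -> int:
    hits = scan_sites(m, enzyme)
    if len(hits) != 1:
        raise AssemblyError(
            f"{what} {m.id} needs exactly one {enzyme} site, found {len(hits)}"
        )
    return hits[0]


# ---------------------------------------------------------------------------
# the four moves
# ---------------------------------------------------------------------------


def insert_orf(vector: DnaMolecule, orf: Part) -> DnaMolecule:
    """Clone an ORF between the vector's unique NdeI and EcoRI sites."""
    if orf.role != "orf":
        raise AssemblyError(f"part {orf.id} has role {orf.role}, not orf")
    _require_unique(vector, "NdeI", "vector")
    _require_unique(vector, "EcoRI", "vector")
    fragments = digest(vector, ["NdeI", "EcoRI"])
    backbone = _fragment_with_roles(
        fragments, required=("host_ori",), excluded=("orf",)
    )
    products = ligate_circular([backbone, _insert_fragment(orf)])
    if len(products) != 1:
        raise AssemblyError(
            f"expected one directional product, got {len(products)}"
        )
    product = products[0]
    product.id = f"{vector.id}+{orf.id}"
    _require_unique(product, "NdeI", "product")
    _require_unique(product, "EcoRI", "product")
    log.info("insert_orf: %s into %s -> %s", orf.id, vector.id, product.id)
    return product


def _grammar_filtered_extension(
    acceptor: DnaMolecule,
    donor: DnaMolecule,
    cassette_enzymes: tuple[str, str],
    acceptor_site: str,
    cassette_roles: tuple[str, ...],
    dead_label: str,
) -> DnaMolecule:
    left, right = cassette_enzymes
    _require_unique(donor, left, "donor")
    _require_unique(donor, right, "donor")
    hits = scan_sites(acceptor, acceptor_site)
    if len(hits) != 1:
        raise AssemblyError(
            f"acceptor {acceptor.id} has {len(hits)} {acceptor_site} sites; "
            "a multi-TU acceptor needs targeted assembly, not blind extension"
        )
    cassette = _fragment_with_roles(
        digest(donor, [left, right]), required=cassette_roles, excluded=("host_ori",)
    )
    (linearised,) = digest(acceptor, [acceptor_site])
    products = ligate_circular([linearised, cassette])
    accepted = []
    for prod in products:
        cassette_forward = all(
            f.strand == "+" for f in prod.features if f.role in cassette_roles
        )
        has_dead_scar = any(
            f.role == "scar" and f.label.startswith(dead_label) for f in prod.features
        )
        regenerated = len(scan_sites(prod, acceptor_site)) == 1
        site_left_unique = len(scan_sites(prod, left)) == len(scan_sites(acceptor, left))
        if cassette_forward and has_dead_scar and regenerated and site_left_unique:
            accepted.append(prod)
        else:
            log.debug("discarding chemical product %s (fails grammar filter)", prod.id)
    if len(accepted) != 1:
        raise AssemblyError(
            f"grammar filter selected {len(accepted)} of {len(products)} "
            f"ligation products for {acceptor.id} + {donor.id}"
        )
    return accepted[0]


def extend_operon(acceptor: DnaMolecule, donor: DnaMolecule) -> DnaMolecule:
    """Move the donor's NheI-AvrII (RBS+ORF) cassette into the acceptor's AvrII site.

    The accepted product has the incoming gene downstream of the resident
    one(s), a dead NheI/AvrII scar between the upstream stop codon and the
    incoming RBS, and a regenerated AvrII after the incoming gene; NheI and
    AvrII stay unique so the move can be repeated.
    """
    product = _grammar_filtered_extension(
        acceptor,
        donor,
        ("NheI", "AvrII"),
        acceptor_site="AvrII",
        cassette_roles=("rbs", "orf"),
        dead_label=scar_label("AvrII", "NheI"),
    )
    product.id = f"{acceptor.id}::operon+{donor.id}"
    log.info("extend_operon: %s + %s -> %s", acceptor.id, donor.id, product.id)
    return product


def extend_cluster(acceptor: DnaMolecule, donor: DnaMolecule) -> DnaMolecule:
    """Move the donor's XbaI-SpeI transcriptional unit into the acceptor's SpeI site.

    The accepted product carries a dead XbaI/SpeI scar at the cluster joint
    and a regenerated SpeI at the far end, keeping the move recursive.
    """
    product = _grammar_filtered_extension(
        acceptor,
        donor,
        ("XbaI", "SpeI"),
        acceptor_site="SpeI",
        cassette_roles=("orf", "terminator"),
        dead_label=scar_label("SpeI", "XbaI"),
    )
    product.id = f"{acceptor.id}::cluster+{donor.id}"
    log.info("extend_cluster: %s + %s -> %s", acceptor.id, donor.id, product.id)
    return product


def swap_slot(plasmid: DnaMolecule, role: str, new_part: Part) -> DnaMolecule:
    """Exchange one slot's content using its flanking pair; all else untouched."""
    if role not in SLOTS:
        raise AssemblyError(f"unknown slot role {role!r}")
    if new_part.role != role:
        raise AssemblyError(
            f"part {new_part.id} has role {new_part.role}, cannot fill {role}"
        )
    left, right = SLOTS[role]
    _require_unique(plasmid, left, "plasmid")
    _require_unique(plasmid, right, "plasmid")
    anchor = "marker" if role in ("host_ori", "marker") else "host_ori"
    if role == "marker":
        anchor = "host_ori"
    backbone = _fragment_with_roles(
        digest(plasmid, [left, right]),
        required=(anchor,),
        excluded=(role,),
    )
    products = ligate_circular([backbone, _insert_fragment(new_part)])
    accepted = [
        prod
        for prod in products
        if all(f.strand == "+" for f in prod.features if f.role == role)
        and len(scan_sites(prod, left)) == 1
        and len(scan_sites(prod, right)) == 1
    ]
    if len(accepted) != 1:
        raise AssemblyError(
            f"slot swap selected {len(accepted)} of {len(products)} products"
        )
    product = accepted[0]
    product.id = f"{plasmid.id}::{role}={new_part.id}"
    if (
        role == "promoter"
        and new_part.meta.regulator
        and not plasmid.features_by_role("regulator")
    ):
        warnings.warn(
            f"promoter {new_part.id} requires a {new_part.meta.regulator} "
            "regulator cassette (BamHI-BglII slot is empty)",
            RegulatorRequiredWarning,
            stacklevel=2,
        )
    log.info("swap_slot: %s %s -> %s", plasmid.id, role, product.id)
    return product


# ---------------------------------------------------------------------------
# planning and virtual execution
# ---------------------------------------------------------------------------


def _design_regulator(design: Design, registry: Registry) -> str | None:
    """Regulator the finished construct's backbone must carry.

    Any inducible promoter anywhere in the design demands the regulator;
    the final backbone descends from the first TU's vector, so every
    stage-1 vector carries it regardless of which TU holds that promoter.
    """
    reg_ids = {
        registry.get(tu.promoter).meta.regulator
        for tu in design.tus
        if tu.promoter and registry.get(tu.promoter).meta.regulator
    }
    if len(reg_ids) > 1:
        raise AssemblyError("multiple distinct regulators are not supported")
    return reg_ids.pop() if reg_ids else None


def _resolve_vector_parts(design: Design, tu: TuSpec, gene: GeneSpec, registry: Registry) -> list[Part]:
    parts = [
        registry.get(design.replicon),
        registry.get(design.ecoli_ori),
        registry.get(design.marker),
        registry.get(design.terminator),
    ]
    regulator = _design_regulator(design, registry)
    if regulator is not None:
        parts.append(registry.get(regulator))
    if tu.promoter is not None:
        parts.append(registry.get(tu.promoter))
    if gene.rbs is not None:
        parts.append(registry.get(gene.rbs))
    return parts


def plan_assembly(design: Design, registry: Registry) -> CloningPlan:
    """Staged plan needing exactly ``design.gene_count`` cloning steps.

    Stage 1 inserts every ORF, in parallel, into its configured single-TU
    vector.  Each later stage performs one cassette transfer: first the
    NheI-AvrII operon extensions within each TU (always onto a single-TU
    acceptor), then the XbaI-SpeI transfers that concatenate the TUs.
    """
    for tu in design.tus:
        for g in tu.genes:
            registry.get(g.orf)
            if g.rbs is not None:
                registry.get(g.rbs)
    stage1: list[CloningStep] = []
    singles: dict[tuple[int, int], str] = {}
    for ti, tu in enumerate(design.tus):
        for gi, gene in enumerate(tu.genes):
            pid = f"{design.name}.tu{ti}.gene{gi}"
            singles[(ti, gi)] = pid
            stage1.append(
                CloningStep(
                    "insert_orf",
                    donor=gene.orf,
                    acceptor=f"{pid}.vector",
                    product=pid,
                    enzymes=("NdeI", "EcoRI"),
                    params={"tu": ti, "gene": gi},
                )
            )
    stages: list[list[CloningStep]] = [stage1]
    tu_products: dict[int, str] = {}
    for ti, tu in enumerate(design.tus):
        acc = singles[(ti, 0)]
        for gi in range(1, len(tu.genes)):
            product = f"{design.name}.tu{ti}.operon{gi + 1}"
            stages.append(
                [
                    CloningStep(
                        "transfer_operon_cassette",
                        donor=singles[(ti, gi)],
                        acceptor=acc,
                        product=product,
                        enzymes=("NheI", "AvrII"),
                    )
                ]
            )
            acc = product
        tu_products[ti] = acc
    cluster = tu_products[0]
    for ti in range(1, len(design.tus)):
        product = f"{design.name}.cluster{ti + 1}"
        stages.append(
            [
                CloningStep(
                    "transfer_tu",
                    donor=tu_products[ti],
                    acceptor=cluster,
                    product=product,
                    enzymes=("XbaI", "SpeI"),
                )
            ]
        )
        cluster = product
    plan = CloningPlan(design, stages)
    plan.validate()
    assert plan.n_stages == design.gene_count
    return plan


def execute_plan(plan: CloningPlan, registry: Registry) -> DnaMolecule:
    """Run every step through the simulator and return the final product."""
    plan.validate()
    design = plan.design
    bench: dict[str, DnaMolecule] = {}
    final = None
    for stage in plan.stages:
        for step in stage:
            if step.kind == "insert_orf":
                ti, gi = step.params["tu"], step.params["gene"]
                tu = design.tus[ti]
                vector = assemble_single_tu(
                    _resolve_vector_parts(design, tu, tu.genes[gi], registry),
                    name=step.acceptor,
                )
                product = insert_orf(vector, registry.get(step.donor))
            elif step.kind == "transfer_operon_cassette":
                product = extend_operon(bench[step.acceptor], bench[step.donor])
            elif step.kind == "transfer_tu":
                product = extend_cluster(bench[step.acceptor], bench[step.donor])
            elif step.kind == "swap_slot":
                product = swap_slot(
                    bench[step.acceptor], step.params["role"], registry.get(step.donor)
                )
            else:
                raise AssemblyError(f"unknown step kind {step.kind!r}")
            product.id = step.product
            bench[step.product] = product
            final = product
    assert final is not None
    report = validate_plasmid(final)
    if report.errors:
        raise AssemblyError(f"final product fails the plasmid audit:\n{report}")
    final.id = design.name
    return final


def assemble_monolithic(design: Design, registry: Registry) -> DnaMolecule:
    """Directly write down the finished construct's sequence (no simulation).

    Independent of the digestion/ligation code path: the expected scars are
    emitted literally (CCTAGC between operon genes, ACTAGA between TUs).
    Used to cross-check ``execute_plan``.
    """
    E = {n: ENZYMES[n].recognition for n in ENZYMES}
    chunks: list[str] = []

    def tu_body(tu: TuSpec) -> str:
        prom = registry.get(tu.promoter).core_seq if tu.promoter else ""
        out = [prom, E["NheI"]]
        for gi, gene in enumerate(tu.genes):
            if gi > 0:
                out.append("C" + "CTAGC")  # dead NheI/AvrII scar
            rbs = registry.get(gene.rbs).core_seq if gene.rbs else ""
            out += [rbs, "CAT", registry.get(gene.orf).core_seq, E["EcoRI"], SPACER]
        out += [E["AvrII"], registry.get(design.terminator).core_seq]
        return "".join(out)

    chunks.append(E["XbaI"])
    for ti, tu in enumerate(design.tus):
        if ti > 0:
            chunks.append("A" + "CTAGA")  # dead XbaI/SpeI scar
        chunks.append(tu_body(tu))
    chunks.append(E["SpeI"])
    reg_id = _design_regulator(design, registry)
    regulator = registry.get(reg_id).core_seq if reg_id else ""
    chunks += [
        grammar.LINKER,
        E["BamHI"],
        regulator,
        E["BglII"],
        registry.get(design.ecoli_ori).core_seq,
        E["SphI"],
        registry.get(design.marker).core_seq,
        E["PstI"],
        registry.get(design.replicon).core_seq,
        E["KpnI"],
        grammar.LINKER,
    ]
    return DnaMolecule("".join(chunks), "circular", [], id=f"{design.name}.monolithic")


# ---------------------------------------------------------------------------
# combinatorial series
# ---------------------------------------------------------------------------


def build_series(
    designs: list[Design], registry: Registry
) -> tuple[dict[str, DnaMolecule], list[str]]:
    """One validated construct per design; duplicates deduplicated with a warning."""
    out: dict[str, DnaMolecule] = {}
    dupes: list[str] = []
    seen: dict[tuple, str] = {}
    for design in designs:
        key = (
            tuple(
                (tu.promoter, tuple((g.rbs, g.orf) for g in tu.genes))
                for tu in design.tus
            ),
            design.replicon,
            design.marker,
            design.ecoli_ori,
            design.terminator,
        )
        if key in seen:
            dupes.append(f"{design.name} duplicates {seen[key]}; skipped")
            log.warning("%s", dupes[-1])
            continue
        seen[key] = design.name
        plan = plan_assembly(design, registry)
        out[design.name] = execute_plan(plan, registry)
    return out, dupes


def reference_series() -> list[Design]:
    """The seventeen-construct reference series of the standard.

    Single-gene probe vectors sweeping promoter, RBS and replicon strength,
    one dual-gene operon family, and two-TU clusters with promoter
    combinations; reporter ORFs are the eGFP and mCherry stand-ins.
    """

    def single(n, prom, rbs, orf="eGFP", repl="pGA1"):
        return Design(
            name=f"pTGR{n}",
            tus=(TuSpec(prom, (GeneSpec(rbs, orf),)),),
            replicon=repl,
        )

    def operon(n, prom, genes):
        return Design(
            name=f"pTGR{n}",
            tus=(TuSpec(prom, tuple(GeneSpec(r, o) for r, o in genes)),),
            replicon="pGA1",
        )

    def cluster(n, tus):
        return Design(
            name=f"pTGR{n}",
            tus=tuple(
                TuSpec(prom, tuple(GeneSpec(r, o) for r, o in genes))
                for prom, genes in tus
            ),
            replicon="pGA1",
        )

    return [
        single(1, None, None),
        single(2, None, "sod_rbs"),
        single(3, "sod", "sod_rbs"),
        single(4, "cspB", "sod_rbs"),
        single(5, "tac", "sod_rbs"),
        single(6, "tac", "lacZ_rbs"),
        single(7, "tac", "cspB_rbs"),
        operon(8, "tac", [("sod_rbs", "mCherry"), ("sod_rbs", "eGFP")]),
        cluster(9, [("tac", [("sod_rbs", "eGFP")]), ("sod", [("sod_rbs", "mCherry")])]),
        operon(10, "tac", [("lacZ_rbs", "mCherry"), ("sod_rbs", "eGFP")]),
        operon(11, "tac", [("lacZ_rbs", "mCherry"), ("lacZ_rbs", "eGFP")]),
        operon(12, "tac", [("sod_rbs", "mCherry"), ("lacZ_rbs", "eGFP")]),
        cluster(13, [("sod", [("sod_rbs", "eGFP")]), ("tac", [("sod_rbs", "mCherry")])]),
        cluster(14, [("tac", [("sod_rbs", "eGFP")]), ("cspB", [("sod_rbs", "mCherry")])]),
        cluster(15, [("cspB", [("sod_rbs", "eGFP")]), ("tac", [("sod_rbs", "mCherry")])]),
        single(16, "tac", "sod_rbs", repl="pNG2"),
        single(17, "tac", "sod_rbs", repl="pCRY4"),
    ]
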