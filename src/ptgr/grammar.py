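"""The pTGR slot grammar: part roles, flanking contracts, validation, metadata.

The standard arranges eight parts around a circular shuttle vector, each
flanked by a dedicated pair of unique restriction sites so that any part can
be exchanged in one digestion/ligation cycle:

====================  ==================
role                  flanks
====================  ==================
promoter (+operator)  XbaI .. NheI
RBS                   NheI .. NdeI
ORF                   NdeI .. EcoRI
terminator            AvrII .. SpeI
regulator             BamHI .. BglII
E. coli ori           BglII .. SphI
selectable marker     SphI .. PstI
host ori              PstI .. KpnI
====================  ==================

The whole transcriptional unit (TU) is the XbaI..SpeI cassette.  The ORF's
start codon is embedded in the NdeI site (CAT|ATG), so ORF parts carry their
own ATG and stop codon but not the CAT.  Parts placed inside the TU must be
free of the six cassette sites (NdeI, EcoRI, XbaI, SpeI, NheI, AvrII);
backbone parts must additionally avoid the five backbone sites.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .errors import GrammarError, RegistryError
from .seqcore import (
    ENZYMES,
    DnaMolecule,
    Feature,
    scan_sites,
)
from .seqcore import _check_alphabet  # shared validation primitive

log = logging.getLogger("ptgr.grammar")

# ---------------------------------------------------------------------------
# slot table
# ---------------------------------------------------------------------------

#: the eight part roles and their flanking-enzyme contract, in plasmid order
SLOTS: dict[str, tuple[str, str]] = {
    "promoter": ("XbaI", "NheI"),
    "rbs": ("NheI", "NdeI"),
    "orf": ("NdeI", "EcoRI"),
    "terminator": ("AvrII", "SpeI"),
    "regulator": ("BamHI", "BglII"),
    "ecoli_ori": ("BglII", "SphI"),
    "marker": ("SphI", "PstI"),
    "host_ori": ("PstI", "KpnI"),
}

#: the whole transcriptional unit moves as one cassette
TU_FLANKS: tuple[str, str] = ("XbaI", "SpeI")

TU_ROLES: tuple[str, ...] = ("promoter", "rbs", "orf", "terminator")
BACKBONE_ROLES: tuple[str, ...] = ("regulator", "ecoli_ori", "marker", "host_ori")
ROLES: tuple[str, ...] = TU_ROLES + BACKBONE_ROLES

#: sites that synthetic genes and TU parts must avoid
CASSETTE_ENZYMES: tuple[str, ...] = ("NdeI", "EcoRI", "XbaI", "SpeI", "NheI", "AvrII")
BACKBONE_ENZYMES: tuple[str, ...] = ("BamHI", "BglII", "SphI", "PstI", "KpnI")

#: cyclic order of the eleven standard sites on a single-TU plasmid
SITE_ORDER: tuple[str, ...] = (
    "XbaI", "NheI", "NdeI", "EcoRI", "AvrII", "SpeI",
    "BamHI", "BglII", "SphI", "PstI", "KpnI",
)

#: fixed neutral joint between EcoRI and AvrII (the standard leaves it open)
SPACER = "TGGCAA"
#: fixed neutral joints SpeI->BamHI and KpnI->XbaI
LINKER = "CACGTG"

STOP_CODONS = ("TAA", "TAG", "TGA")

#: Shine-Dalgarno motifs searched when auditing RBS spacing (longest, then
#: rightmost occurrence wins)
_SD_MOTIFS = ("AGGAGG", "GGAGG", "AGGAG", "AGGA", "GGAG", "GAGG")


# ---------------------------------------------------------------------------
# parts and metadata
# ---------------------------------------------------------------------------


@dataclass
class PartMetadata:
    """Characterisation data attached to a part.

    ``strength_rank`` is the qualitative high/medium/low class measured with
    the reporter assay; ``copy_number`` a per-cell plasmid count range for
    replicons; ``brightness`` the fluorophore brightness constant in
    1/(mM*cm) used to put two reporters on one scale; ``native_spacing`` the
    SD->ATG distance (nt) preserved from the RBS's source gene;
    ``regulator`` names the repressor/activator an inducible promoter needs.
    """

    strength_rank: str = "unranked"
    copy_number: tuple[int, int] | None = None
    brightness: float | None = None
    native_spacing: int | None = None
    regulator: str | None = None

    def __post_init__(self) -> None:
        if self.strength_rank not in ("high", "medium", "low", "unranked"):
            raise RegistryError(f"bad strength_rank {self.strength_rank!r}")


@dataclass
class Part:
    id: str
    role: str
    core_seq: str
    meta: PartMetadata = field(default_factory=PartMetadata)

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise GrammarError(f"unknown part role {self.role!r}")
        _check_alphabet(self.core_seq)


class Registry:
    """A keyed collection of parts with convenience metadata accessors."""

    def __init__(self, parts: list[Part] | None = None):
        self.parts: dict[str, Part] = {}
        for p in parts or []:
            self.add(p)

    def add(self, part: Part) -> None:
        if part.id in self.parts:
            raise RegistryError(f"duplicate part id {part.id!r}")
        self.parts[part.id] = part

    def __contains__(self, pid: str) -> bool:
        return pid in self.parts

    def __len__(self) -> int:
        return len(self.parts)

    def get(self, pid: str) -> Part:
        try:
            return self.parts[pid]
        except KeyError:
            raise RegistryError(f"unknown part {pid!r}") from None

    def by_role(self, role: str) -> list[Part]:
        return [p for p in self.parts.values() if p.role == role]

    def brightness(self, pid: str) -> float:
        b = self.get(pid).meta.brightness
        if b is None:
            raise RegistryError(f"part {pid!r} has no brightness constant")
        return b


# ---------------------------------------------------------------------------
# validation reports
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Finding:
    severity: str  # error | warning | info
    code: str
    position: int
    message: str


@dataclass
class ValidationReport:
    findings: list[Finding] = field(default_factory=list)

    def add(self, severity: str, code: str, position: int, message: str) -> None:
        self.findings.append(Finding(severity, code, position, message))

    def sort(self) -> "ValidationReport":
        self.findings.sort(key=lambda f: (f.position, f.code))
        return self

    @property
    def errors(self) -> list[Finding]:
        return [f for f in self.findings if f.severity == "error"]

    @property
    def warnings(self) -> list[Finding]:
        return [f for f in self.findings if f.severity == "warning"]

    @property
    def ok(self) -> bool:
        return not self.findings

    def __bool__(self) -> bool:  # truthy iff clean
        return self.ok

    def __str__(self) -> str:
        if self.ok:
            return "clean"
        return "\n".join(
            f"{f.severity.upper():7s} {f.code} @{f.position}: {f.message}"
            for f in self.findings
        )


# ---------------------------------------------------------------------------
# part validation and flanking
# ---------------------------------------------------------------------------


def _occurrences(text: str, sub: str) -> list[int]:
    out, i = [], text.find(sub)
    while i != -1:
        out.append(i)
        i = text.find(sub, i + 1)
    return out


def measure_sd_spacing(core_seq: str) -> int | None:
    """SD->ATG distance implied by an RBS core.

    The start codon sits three nucleotides past the core's right edge (the
    CAT of the NdeI flank), so spacing = tail after the SD motif + 3.
    Returns None when no purine-rich SD-like motif is found.
    """
    best: tuple[int, int] | None = None  # (motif length, index)
    for motif in _SD_MOTIFS:
        idx = core_seq.rfind(motif)
        if idx == -1:
            continue
        cand = (len(motif), idx)
        if best is None or cand > best:
            best = cand
    if best is None:
        return None
    mlen, idx = best
    return len(core_seq) - (idx + mlen) + 3


def validate_part(p: Part) -> ValidationReport:
    """Audit a part core against the grammar's cleanliness rules."""
    rep = ValidationReport()
    if p.role in TU_ROLES:
        forbidden, advisory = CASSETTE_ENZYMES, BACKBONE_ENZYMES
    else:
        forbidden, advisory = CASSETTE_ENZYMES + BACKBONE_ENZYMES, ()
    for name in forbidden:
        for pos in _occurrences(p.core_seq, ENZYMES[name].recognition):
            rep.add("error", "forbidden-site", pos, f"{name} site inside {p.role} core")
    for name in advisory:
        for pos in _occurrences(p.core_seq, ENZYMES[name].recognition):
            rep.add(
                "warning",
                "backbone-site",
                pos,
                f"{name} site inside {p.role} core would duplicate a backbone flank",
            )
    if p.role == "orf":
        core = p.core_seq
        if not core.startswith("ATG"):
            rep.add("error", "orf-start", 0, "ORF core must begin with ATG")
        if len(core) % 3:
            rep.add("error", "orf-frame", len(core), "ORF length not divisible by 3")
        else:
            codons = [core[i : i + 3] for i in range(0, len(core), 3)]
            if codons and codons[-1] not in STOP_CODONS:
                rep.add("error", "orf-stop", len(core) - 3, "ORF must end with a stop codon")
            for i, c in enumerate(codons[:-1]):
                if c in STOP_CODONS:
                    rep.add("error", "orf-internal-stop", 3 * i, f"in-frame stop {c} at codon {i}")
    if p.role == "rbs":
        measured = measure_sd_spacing(p.core_seq)
        declared = p.meta.native_spacing
        if declared is not None and measured is not None and declared != measured:
            rep.add(
                "warning",
                "rbs-spacing",
                0,
                f"declared SD->ATG spacing {declared} differs from measured {measured}",
            )
        elif measured is None:
            rep.add("info", "rbs-no-sd", 0, "no SD-like motif found; spacing not audited")
    return rep.sort()


def flank_part(p: Part) -> str:
    """Core sequence wrapped in its slot's flanking sites.

    For ORFs the upstream flank contributes only ``CAT``: the part's own ATG
    completes the NdeI site and sits in frame.  Raises when the part fails
    validation or when a flank boundary creates a stray standard site.
    """
    rep = validate_part(p)
    if rep.errors:
        raise GrammarError(f"part {p.id} fails validation:\n{rep}")
    left_name, right_name = SLOTS[p.role]
    left = ENZYMES[left_name].recognition
    right = ENZYMES[right_name].recognition
    if p.role == "orf":
        flanked = "CAT" + p.core_seq + right
        expected = {left_name: [0], right_name: [len(flanked) - 6]}
    else:
        flanked = left + p.core_seq + right
        expected = {left_name: [0], right_name: [len(flanked) - 6]}
        if left_name == right_name:  # no such slot in the shipped table
            expected = {left_name: [0, len(flanked) - 6]}
    for name, e in ENZYMES.items():
        hits = _occurrences(flanked, e.recognition)
        extra = [h for h in hits if h not in expected.get(name, [])]
        if extra:
            raise GrammarError(
                f"flanking {p.id} creates stray {name} site(s) at {extra}"
            )
        if sorted(hits) != sorted(expected.get(name, [])) and name in expected:
            raise GrammarError(f"flank of {p.id} lost its {name} site")
    return flanked


def excise_core(flanked: str, role: str) -> str:
    """Inverse of :func:`flank_part` on the flanked string."""
    left_name, right_name = SLOTS[role]
    if role == "orf":
        return flanked[3:-6]
    return flanked[6:-6]


# ---------------------------------------------------------------------------
# plasmid assembly and audit
# ---------------------------------------------------------------------------

_REQUIRED = ("host_ori", "ecoli_ori", "marker", "terminator")
_OPTIONAL = ("promoter", "rbs", "orf", "regulator")


def assemble_single_tu(parts, name: str = "plasmid") -> DnaMolecule:
    """Assemble a single-transcriptional-unit pTGR plasmid from parts.

    ``parts`` is an iterable of :class:`Part`; each role may appear at most
    once.  host ori, E. coli ori, marker and terminator are required.
    Promoter, RBS, ORF and regulator may be omitted (promoterless and
    empty-ORF probe vectors are supported degenerate forms; empty slots keep
    their flanking sites).  A promoter whose metadata names a regulator
    requires that regulator part.
    """
    by_role: dict[str, Part] = {}
    for p in parts:
        if p.role in by_role:
            raise GrammarError(f"two parts with role {p.role!r}: "
                               f"{by_role[p.role].id} and {p.id}")
        by_role[p.role] = p
    for role in _REQUIRED:
        if role not in by_role:
            raise GrammarError(f"missing required part for slot {role!r}")
    prom = by_role.get("promoter")
    if prom is not None and prom.meta.regulator and "regulator" not in by_role:
        raise GrammarError(
            f"promoter {prom.id} is inducible and requires a "
            f"{prom.meta.regulator} regulator part"
        )
    for p in by_role.values():
        rep = validate_part(p)
        if rep.errors:
            raise GrammarError(f"part {p.id} fails validation:\n{rep}")

    pieces: list[str] = []
    features: list[Feature] = []
    pos = 0

    def emit(text: str, label: str | None = None, role: str | None = None) -> None:
        nonlocal pos
        if text and label:
            features.append(Feature(label, role or "linker", pos, pos + len(text)))
        pieces.append(text)
        pos += len(text)

    def emit_site(enzname: str) -> None:
        emit(ENZYMES[enzname].recognition, enzname, "site")

    def core(role: str) -> str:
        p = by_role.get(role)
        return p.core_seq if p else ""

    def part_label(role: str) -> str | None:
        p = by_role.get(role)
        return p.id if p else None

    emit_site("XbaI")
    emit(core("promoter"), part_label("promoter"), "promoter")
    emit_site("NheI")
    emit(core("rbs"), part_label("rbs"), "rbs")
    if "orf" in by_role:
        emit("CAT", "NdeI", "site")  # completed by the ORF's ATG
        # re-point the site feature at the full CATATG hexamer
        features[-1] = Feature("NdeI", "site", pos - 3, pos + 3)
        emit(core("orf"), part_label("orf"), "orf")
    else:
        emit_site("NdeI")
    emit_site("EcoRI")
    emit(SPACER, "spacer", "linker")
    emit_site("AvrII")
    emit(core("terminator"), part_label("terminator"), "terminator")
    emit_site("SpeI")
    emit(LINKER, "linker.tu-backbone", "linker")
    emit_site("BamHI")
    emit(core("regulator"), part_label("regulator"), "regulator")
    emit_site("BglII")
    emit(core("ecoli_ori"), part_label("ecoli_ori"), "ecoli_ori")
    emit_site("SphI")
    emit(core("marker"), part_label("marker"), "marker")
    emit_site("PstI")
    emit(core("host_ori"), part_label("host_ori"), "host_ori")
    emit_site("KpnI")
    emit(LINKER, "linker.ori-tu", "linker")

    m = DnaMolecule("".join(pieces), "circular", features, id=name)
    rep = validate_plasmid(m)
    if rep.errors:
        raise GrammarError(f"assembled plasmid {name} is invalid:\n{rep}")
    return m


def n_transcription_units(m: DnaMolecule) -> int:
    """TU count inferred from dead XbaI/SpeI cluster-joint scars."""
    return 1 + sum(
        1 for f in m.features if f.role == "scar" and f.label.startswith("scar:XbaI/SpeI")
    )


def validate_plasmid(m: DnaMolecule) -> ValidationReport:
    """Audit standard-site uniqueness, slot order, and the scar inventory.

    Site duplications that would break further extension (XbaI/SpeI always;
    NheI/AvrII on single-TU plasmids; the five backbone sites) are errors.
    Duplications expected of multi-gene constructs (NdeI/EcoRI in operons;
    NheI/NdeI/EcoRI/AvrII in multi-TU clusters) are reported as info.
    """
    if not m.is_circular:
        raise GrammarError("validate_plasmid expects a circular molecule")
    rep = ValidationReport()
    census = {name: scan_sites(m, name) for name in ENZYMES}
    ntu = n_transcription_units(m)
    for name, hits in census.items():
        if not hits:
            rep.add("warning", "missing-site", 0, f"no {name} site on the plasmid")
            continue
        if len(hits) == 1:
            continue
        if name in ("XbaI", "SpeI") or name in BACKBONE_ENZYMES:
            rep.add(
                "error",
                "duplicate-site",
                hits[1],
                f"{name} duplicated at {hits}; extension/exchange would be ambiguous",
            )
        elif name in ("NheI", "AvrII") and ntu == 1:
            rep.add(
                "error",
                "duplicate-site",
                hits[1],
                f"{name} duplicated at {hits} on a single-TU plasmid",
            )
        else:
            rep.add(
                "info",
                "expected-duplicate",
                hits[1],
                f"{name} x{len(hits)} as expected for a multi-gene construct",
            )
    # slot order: on a fully unique single-TU plasmid the eleven sites must
    # appear in the canonical cyclic order
    if ntu == 1 and all(len(census[n]) == 1 for n in ENZYMES):
        order = sorted(ENZYMES, key=lambda n: census[n][0])
        start = order.index(SITE_ORDER[0])
        cyclic = tuple(order[start:] + order[:start])
        if cyclic != SITE_ORDER:
            rep.add(
                "error",
                "slot-order",
                census[cyclic[0]][0],
                f"site order {cyclic} deviates from the standard layout",
            )
    labels: dict[str, int] = {}
    for f in m.features:
        if f.role == "site":
            continue
        labels[f.label] = labels.get(f.label, 0) + 1
    for lbl, n in labels.items():
        if n > 1:
            rep.add("warning", "duplicate-label", 0, f"feature label {lbl!r} x{n}")
    for f in m.features:
        if f.role == "scar":
            rep.add("info", "scar", f.start, f"{f.label} at {f.start}")
    return rep.sort()


# ---------------------------------------------------------------------------
# metadata operations
# ---------------------------------------------------------------------------


def normalize_fluorescence(raw: float, protein: str, registry: "Registry | None" = None) -> float:
    """Raw arbitrary-units signal divided by the fluorophore's brightness.

    Puts eGFP (34 1/(mM*cm)) and mCherry (16 1/(mM*cm)) readouts on a
    comparable scale.
    """
    if registry is None:
        from .fixtures import default_registry

        registry = default_registry()
    return raw / registry.brightness(protein)


_RANK_VALUE = {"low": 0, "medium": 1, "high": 2}


@dataclass
class RankResult:
    """Pairwise partial order over construct configurations."""

    relations: dict[tuple[int, int], str]
    excluded: list[int]
    warnings: list[str]

    def compare(self, i: int, j: int) -> str:
        if i == j:
            return "eq"
        if (i, j) in self.relations:
            return self.relations[(i, j)]
        rel = self.relations.get((j, i), "incomparable")
        return {"ge": "le", "le": "ge"}.get(rel, rel)


def _copy_number_value(part: Part) -> int | None:
    cn = part.meta.copy_number
    return None if cn is None else max(cn)


def rank_constructs(
    constructs: list[tuple[str, str, str]], registry: "Registry | None" = None
) -> RankResult:
    """Partial order of (promoter, rbs, replicon) configurations.

    A >= B iff A's promoter rank, RBS rank and replicon copy number are all
    >= B's; conflicting coordinates make the pair incomparable.  No numeric
    expression level is predicted.  Constructs with an unranked coordinate
    are excluded with a warning.
    """
    if registry is None:
        from .fixtures import default_registry

        registry = default_registry()
    coords: dict[int, tuple[int, int, int] | None] = {}
    excluded, warnings = [], []
    for idx, (prom, rbs, rep) in enumerate(constructs):
        pr = _RANK_VALUE.get(registry.get(prom).meta.strength_rank)
        rr = _RANK_VALUE.get(registry.get(rbs).meta.strength_rank)
        cn = _copy_number_value(registry.get(rep))
        if pr is None or rr is None or cn is None:
            excluded.append(idx)
            warnings.append(
                f"construct {idx} ({prom},{rbs},{rep}) has an unranked part; excluded"
            )
            coords[idx] = None
        else:
            coords[idx] = (pr, rr, cn)
    relations: dict[tuple[int, int], str] = {}
    ranked = [i for i in range(len(constructs)) if coords[i] is not None]
    for ai in range(len(ranked)):
        for bi in range(ai + 1, len(ranked)):
            i, j = ranked[ai], ranked[bi]
            a, b = coords[i], coords[j]
            ge = all(x >= y for x, y in zip(a, b))
            le = all(x <= y for x, y in zip(a, b))
            if ge and le:
                relations[(i, j)] = "eq"
            elif ge:
                relations[(i, j)] = "ge"
            elif le:
                relations[(i, j)] = "le"
            else:
                relations[(i, j)] = "incomparable"
    return RankResult(relations, excluded, warnings)
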