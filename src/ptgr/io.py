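"""GenBank/FASTA readers and writers, registry and design-config loading.

GenBank flat files have no field for single-stranded overhangs, so linear
molecules serialise their ends into a structured COMMENT block::

    ptgr_ends: left=five_prime:CTAG:AvrII right=five_prime:CTAG:NheI

(kind : overhang : producing enzyme; blunt ends are ``blunt::``).  Reading
the block back restores the ends losslessly; files without it get blunt
ends.  Topology is carried on the LOCUS line.  Origin-spanning features of
circular molecules round-trip through compound (join) locations.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from .assembly import Design, GeneSpec, TuSpec
from .errors import RegistryError, SequenceError
from .grammar import Part, PartMetadata, Registry, ROLES
from .seqcore import BLUNT, DnaMolecule, Feature, StickyEnd

log = logging.getLogger("ptgr.io")

_ENDS_TAG = "ptgr_ends:"


def _ends_comment(m: DnaMolecule) -> str:
    def enc(e: StickyEnd) -> str:
        return f"{e.kind}:{e.overhang}:{e.enzyme or ''}"

    return f"{_ENDS_TAG} left={enc(m.left_end)} right={enc(m.right_end)}"


def _parse_end(token: str) -> StickyEnd:
    kind, overhang, enzyme = token.split(":")
    return StickyEnd(kind, overhang, enzyme or None)


def write_genbank(m: DnaMolecule, path: str | Path) -> None:
    rec = SeqRecord(
        Seq(m.seq),
        id=m.id[:16] or "plasmid",
        name=(m.id or "plasmid").replace(" ", "_")[:16],
        description=m.id,
        annotations={
            "molecule_type": "DNA",
            "topology": m.topology,
            "data_file_division": "SYN",
        },
    )
    if not m.is_circular:
        rec.annotations["comment"] = _ends_comment(m)
    L = len(m.seq)
    for f in m.features:
        strand = 1 if f.strand == "+" else -1
        if f.end <= L:
            loc = SimpleLocation(f.start, f.end, strand)
        else:  # origin-spanning
            loc = CompoundLocation(
                [SimpleLocation(f.start, L, strand), SimpleLocation(0, f.end - L, strand)]
            )
        rec.features.append(
            SeqFeature(loc, type="misc_feature", qualifiers={"label": [f.label], "note": [f.role]})
        )
    SeqIO.write(rec, str(path), "genbank")


def read_genbank(path: str | Path) -> DnaMolecule:
    path = Path(path)
    if path.stat().st_size == 0:
        raise SequenceError(f"{path}: empty file")
    try:
        rec = SeqIO.read(str(path), "genbank")
    except ValueError as exc:
        raise SequenceError(f"{path}: malformed GenBank record ({exc})") from exc
    topology = rec.annotations.get("topology", "linear")
    seq = str(rec.seq).upper()
    L = len(seq)
    feats: list[Feature] = []
    for sf in rec.features:
        if sf.type == "source":
            continue
        label = (sf.qualifiers.get("label") or [sf.type])[0]
        role = (sf.qualifiers.get("note") or ["site"])[0]
        strand = "-" if sf.location.strand == -1 else "+"
        parts = list(sf.location.parts)
        if (
            len(parts) == 2
            and int(parts[0].end) == L
            and int(parts[1].start) == 0
            and topology == "circular"
        ):
            start, end = int(parts[0].start), L + int(parts[1].end)
        else:
            start, end = int(sf.location.start), int(sf.location.end)
        feats.append(Feature(label, role, start, end, strand))
    left = right = None
    if topology == "linear":
        left = right = BLUNT
        comment = rec.annotations.get("comment", "")
        for line in comment.splitlines():
            line = line.strip()
            if line.startswith(_ENDS_TAG):
                fields = dict(tok.split("=", 1) for tok in line[len(_ENDS_TAG):].split())
                left = _parse_end(fields["left"])
                right = _parse_end(fields["right"])
    return DnaMolecule(
        seq,
        topology,
        feats,
        left_end=left,
        right_end=right,
        id=rec.description or rec.id,
    )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    return [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")]


def write_fasta(entries: list[tuple[str, str]], path: str | Path) -> None:
    SeqIO.write(
        [SeqRecord(Seq(s), id=i, description="") for i, s in entries],
        str(path),
        "fasta",
    )


# ---------------------------------------------------------------------------
# part registry (JSON)
# ---------------------------------------------------------------------------


def registry_to_dict(reg: Registry) -> dict:
    parts = []
    for p in reg.parts.values():
        meta = {
            "strength_rank": p.meta.strength_rank,
            "copy_number": list(p.meta.copy_number) if p.meta.copy_number else None,
            "brightness": p.meta.brightness,
            "native_spacing": p.meta.native_spacing,
            "regulator": p.meta.regulator,
        }
        parts.append(
            {"id": p.id, "role": p.role, "core_seq": p.core_seq, "meta": meta}
        )
    return {"parts": parts}


def save_registry(reg: Registry, path: str | Path) -> None:
    Path(path).write_text(json.dumps(registry_to_dict(reg), indent=1) + "\n")


_META_KEYS = {"strength_rank", "copy_number", "brightness", "native_spacing", "regulator"}


def registry_from_dict(data: dict) -> Registry:
    if not isinstance(data, dict) or "parts" not in data:
        raise RegistryError("registry must be an object with a 'parts' list")
    reg = Registry()
    for entry in data["parts"]:
        missing = {"id", "role", "core_seq"} - set(entry)
        if missing:
            raise RegistryError(f"registry entry misses keys {sorted(missing)}")
        if entry["role"] not in ROLES:
            raise RegistryError(f"unknown role {entry['role']!r} for part {entry['id']!r}")
        meta_raw = entry.get("meta") or {}
        unknown = set(meta_raw) - _META_KEYS
        if unknown:
            raise RegistryError(f"unknown meta keys {sorted(unknown)} on {entry['id']!r}")
        cn = meta_raw.get("copy_number")
        meta = PartMetadata(
            strength_rank=meta_raw.get("strength_rank", "unranked"),
            copy_number=tuple(cn) if cn else None,
            brightness=meta_raw.get("brightness"),
            native_spacing=meta_raw.get("native_spacing"),
            regulator=meta_raw.get("regulator"),
        )
        reg.add(Part(entry["id"], entry["role"], entry["core_seq"].upper(), meta))
    return reg


def load_registry(path: str | Path) -> Registry:
    try:
        data = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise RegistryError(f"{path}: not valid JSON ({exc})") from exc
    return registry_from_dict(data)


# ---------------------------------------------------------------------------
# design configs (JSON or YAML)
# ---------------------------------------------------------------------------


def design_from_dict(data: dict) -> Design:
    try:
        tus = tuple(
            TuSpec(
                tu.get("promoter"),
                tuple(GeneSpec(g.get("rbs"), g["orf"]) for g in tu["genes"]),
            )
            for tu in data["tus"]
        )
        return Design(
            name=data.get("name", "construct"),
            tus=tus,
            replicon=data["replicon"],
            marker=data.get("marker", "kanR"),
            ecoli_ori=data.get("ecoli_ori", "colE1"),
            terminator=data.get("terminator", "rrnBT1T2"),
        )
    except (KeyError, TypeError) as exc:
        raise RegistryError(f"malformed design spec: {exc}") from exc


def load_design(path: str | Path) -> Design:
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    return design_from_dict(data)
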