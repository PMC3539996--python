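"""Sticky-end compatibility, junction (scar) arithmetic, circular ligation.

The pTGR procedures lean on isocaudomer chemistry: XbaI, SpeI, NheI and
AvrII all leave the self-complementary 5'-CTAG extension (BamHI/BglII leave
5'-GATC), so ends produced by different enzymes of a family ligate.  Joining
two ends cut by the *same* palindromic enzyme regenerates its site; joining
ends from two different isocaudomers leaves a "dead" scar cut by neither --
the algebra that makes operon and cluster extension recursive.

This module reports every chemically possible circular product; selecting
the product "in the correct orientation" is grammar, not chemistry, and is
done by the assembly layer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .errors import LigationError
from .seqcore import (
    ENZYMES,
    DnaMolecule,
    Feature,
    StickyEnd,
    revcomp,
    uniquify_labels,
)

log = logging.getLogger("ptgr.ligation")

#: isocaudomer families get the field's customary pair names
_PAIR_NAMES = {
    frozenset(("NheI", "AvrII")): "NheI/AvrII",
    frozenset(("XbaI", "SpeI")): "XbaI/SpeI",
    frozenset(("BamHI", "BglII")): "BamHI/BglII",
}


def scar_label(up: str | None, down: str | None) -> str:
    names = [n for n in (up, down) if n]
    if not names:
        return "scar:?"
    key = frozenset(names)
    if key in _PAIR_NAMES:
        return "scar:" + _PAIR_NAMES[key]
    if len(key) == 1:
        return f"scar:{names[0]}"
    return "scar:" + "/".join(sorted(key))


def ends_compatible(a: StickyEnd, b: StickyEnd) -> bool:
    """True iff the two termini can anneal and be sealed by ligase.

    Both blunt, or the same overhang kind with extensions that are reverse
    complements of each other (for the self-complementary CTAG/GATC/AATT/TA
    family this reduces to identity).
    """
    if a.kind != b.kind:
        return False
    if a.kind == "blunt":
        return True
    return revcomp(a.overhang) == b.overhang


@dataclass(frozen=True)
class Junction:
    """The sealed joint between an upstream and a downstream end."""

    scar_seq: str
    sites_present: frozenset[str]
    upstream_enzyme: str | None
    downstream_enzyme: str | None
    #: top-strand context contributed upstream of the junction point
    upstream_context: int

    @property
    def label(self) -> str:
        return scar_label(self.upstream_enzyme, self.downstream_enzyme)

    @property
    def is_dead(self) -> bool:
        """Neither parent enzyme can re-cut the scar."""
        parents = {self.upstream_enzyme, self.downstream_enzyme} - {None}
        return not (parents & self.sites_present)


def junction_sequence(upstream: StickyEnd, downstream: StickyEnd) -> Junction:
    """Duplex sequence across a joint and the shipped sites recreated there.

    The scar is reconstructed from the cut geometry of the two producing
    enzymes: the upstream side contributes ``recognition[:cut_top]``, the
    downstream side ``recognition[cut_top:]`` (the annealed overhang is
    counted once).  Ends without enzyme provenance fall back to the bare
    overhang.
    """
    if not ends_compatible(upstream, downstream):
        raise LigationError(
            f"incompatible ends: {upstream.kind}/{upstream.overhang or '-'} vs "
            f"{downstream.kind}/{downstream.overhang or '-'}"
        )
    up_e = ENZYMES.get(upstream.enzyme) if upstream.enzyme else None
    down_e = ENZYMES.get(downstream.enzyme) if downstream.enzyme else None
    up_part = up_e.recognition[: up_e.cut_top] if up_e else ""
    down_part = down_e.recognition[down_e.cut_top :] if down_e else downstream.overhang
    scar = up_part + down_part
    present = frozenset(
        name for name, e in ENZYMES.items() if e.recognition in scar
    )
    return Junction(
        scar_seq=scar,
        sites_present=present,
        upstream_enzyme=up_e.name if up_e else None,
        downstream_enzyme=down_e.name if down_e else None,
        upstream_context=len(up_part),
    )


def _scar_feature(j: Junction, position: int, length: int) -> Feature:
    """Scar annotation centred on junction ``position`` of a circular product."""
    start = (position - j.upstream_context) % length
    return Feature(j.label, "scar", start, start + len(j.scar_seq))


def ligate_circular(fragments: list[DnaMolecule]) -> list[DnaMolecule]:
    """Every distinct circularisation of one or two linear fragments.

    One fragment: self-circularisation when its own ends are compatible.
    Two fragments: both relative orientations of the second fragment are
    tried; products are deduplicated under canonical rotation (including the
    reverse complement).  An empty list means no compatible end pairing --
    that is a result, not an error.
    """
    if not 1 <= len(fragments) <= 2:
        raise LigationError("ligate_circular takes one or two fragments")
    for f in fragments:
        if f.is_circular:
            raise LigationError(f"{f.id} is circular; only linear fragments ligate")

    products: list[DnaMolecule] = []
    seen: set[str] = set()

    def emit(seq: str, features: list[Feature], junctions: list[tuple[Junction, int]], name: str) -> None:
        L = len(seq)
        feats = list(features)
        for j, pos in junctions:
            feats.append(_scar_feature(j, pos, L))
        feats.sort(key=lambda f: (f.start, f.end))
        m = DnaMolecule(seq, "circular", uniquify_labels(feats), id=name)
        if m.canonical in seen:
            return
        seen.add(m.canonical)
        products.append(m)

    if len(fragments) == 1:
        f = fragments[0]
        if ends_compatible(f.right_end, f.left_end):
            j = junction_sequence(f.right_end, f.left_end)
            emit(f.seq, f.features, [(j, len(f.seq))], f"{f.id}.circ")
        else:
            log.debug("self-ligation of %s rejected: incompatible ends", f.id)
        return products

    a, b = fragments
    for b_or in (b, b.reverse_complement()):
        if not (
            ends_compatible(a.right_end, b_or.left_end)
            and ends_compatible(b_or.right_end, a.left_end)
        ):
            log.debug(
                "pairing %s + %s rejected: incompatible ends", a.id, b_or.id
            )
            continue
        j1 = junction_sequence(a.right_end, b_or.left_end)
        j2 = junction_sequence(b_or.right_end, a.left_end)
        seq = a.seq + b_or.seq
        feats = list(a.features) + [f.shifted(len(a.seq)) for f in b_or.features]
        emit(seq, feats, [(j1, len(a.seq)), (j2, len(seq))], f"{a.id}+{b_or.id}")
    return products
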