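"""Deterministic synthetic stand-ins for every part class of the standard.

The real promoter, RBS, reporter and replicon sequences of the pTGR series
are not bundled (the published pTGR5 record, NCBI JX559328, can be imported
by users who want the genuine article).  This module generates synthetic
placeholder parts -- random sequences of realistic lengths, scrubbed of all
eleven standard sites in their flanking context -- and attaches the
measured metadata of the platform: promoter ranks tac > cspB > sod, RBS
ranks sod > lacZ > cspB, replicon copy numbers pGA1 ~30 vs pCRY4/pNG2 1-2
per cell, and fluorophore brightness 34 (eGFP) / 16 (mCherry) 1/(mM*cm).

Identical seeds produce byte-identical registries; every generated part
passes :func:`ptgr.grammar.validate_part`.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass, field

from .errors import PtgrError
from .geneprep import design_orf
from .grammar import (
    ENZYMES,
    Part,
    PartMetadata,
    Registry,
    SLOTS,
    assemble_single_tu,
)
from .seqcore import DnaMolecule

log = logging.getLogger("ptgr.fixtures")

DEFAULT_SEED = 2012

#: realistic part lengths (nt) used by the generator
DEFAULT_LENGTHS = {
    "promoter": 200,
    "rbs": 20,
    "orf_protein": (99, 239),  # residues; 300-720 nt including the stop
    "terminator": 150,
    "host_ori": 1000,
    "ecoli_ori": 700,
    "marker": 950,
    "regulator": 1100,
}

_ALL_RECOGNITIONS = [e.recognition for e in ENZYMES.values()]
_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class FixtureSpec:
    seed: int = DEFAULT_SEED
    lengths: dict = field(default_factory=lambda: dict(DEFAULT_LENGTHS))


def _clean_random_seq(rng: random.Random, length: int, left: str, right: str) -> str:
    """Random core whose flanked context contains no stray standard site."""
    for _ in range(200):
        core = "".join(rng.choice("ACGT") for _ in range(length))
        text = left + core + right
        ok = True
        for rec in _ALL_RECOGNITIONS:
            i = text.find(rec)
            while i != -1:
                if not (i == 0 and left.endswith(rec) or text.endswith(rec) and i == len(text) - len(rec)):
                    ok = False
                    break
                i = text.find(rec, i + 1)
            if not ok:
                break
        if ok:
            return core
    raise PtgrError("could not generate a site-free core")  # pragma: no cover


def _flanks(role: str) -> tuple[str, str]:
    ln, rn = SLOTS[role]
    return ENZYMES[ln].recognition, ENZYMES[rn].recognition


def _rbs_core(rng: random.Random, native_spacing: int) -> str:
    """SD motif followed by a G-free spacer giving the declared SD->ATG gap.

    The start codon sits 3 nt past the core (inside the NdeI flank), so the
    core tail after AGGAGG has native_spacing - 3 nt.
    """
    left, right = _flanks("rbs")
    tail_len = native_spacing - 3
    for _ in range(200):
        prefix = "".join(rng.choice("ACT") for _ in range(8))
        tail = "".join(rng.choice("ACT") for _ in range(tail_len))
        core = prefix + "AGGAGG" + tail
        text = left + core + right
        if not any(
            rec in text and not (text.startswith(rec) or text.endswith(rec))
            for rec in _ALL_RECOGNITIONS
        ):
            return core
    raise PtgrError("could not generate an RBS core")  # pragma: no cover


def _random_protein(rng: random.Random, n_residues: int) -> str:
    return "M" + "".join(rng.choice(_AA) for _ in range(n_residues - 1))


def generate_fixtures(spec: FixtureSpec | int | None = None) -> tuple[Registry, DnaMolecule]:
    """Synthetic part registry plus an assembled promoterless backbone.

    Returns (registry, backbone) where the backbone is a pTGR1-like
    promoterless eGFP probe vector on the medium-copy host replicon.
    """
    if spec is None:
        spec = FixtureSpec()
    elif isinstance(spec, int):
        spec = FixtureSpec(seed=spec)
    rng = random.Random(spec.seed)
    L = spec.lengths
    reg = Registry()

    for pid, rank, regulator in (
        ("tac", "high", "lacI"),
        ("cspB", "medium", None),
        ("sod", "low", None),
    ):
        left, right = _flanks("promoter")
        reg.add(
            Part(
                pid,
                "promoter",
                _clean_random_seq(rng, L["promoter"], left, right),
                PartMetadata(strength_rank=rank, regulator=regulator),
            )
        )
    for pid, rank, spacing in (
        ("sod_rbs", "high", 8),
        ("lacZ_rbs", "medium", 7),
        ("cspB_rbs", "low", 9),
    ):
        reg.add(
            Part(
                pid,
                "rbs",
                _rbs_core(rng, spacing),
                PartMetadata(strength_rank=rank, native_spacing=spacing),
            )
        )
    lo, hi = L["orf_protein"]
    for pid, brightness in (("eGFP", 34.0), ("mCherry", 16.0)):
        protein = _random_protein(rng, rng.randint(lo, hi))
        part = design_orf(
            protein,
            forbidden=tuple(ENZYMES),
            part_id=pid,
            meta=PartMetadata(brightness=brightness),
        )
        reg.add(part)
    left, right = _flanks("terminator")
    reg.add(
        Part(
            "rrnBT1T2",
            "terminator",
            _clean_random_seq(rng, L["terminator"], left, right),
            PartMetadata(),
        )
    )
    for pid, copies in (("pGA1", (25, 35)), ("pCRY4", (1, 2)), ("pNG2", (1, 2))):
        left, right = _flanks("host_ori")
        reg.add(
            Part(
                pid,
                "host_ori",
                _clean_random_seq(rng, L["host_ori"], left, right),
                PartMetadata(copy_number=copies),
            )
        )
    left, right = _flanks("ecoli_ori")
    reg.add(
        Part("colE1", "ecoli_ori", _clean_random_seq(rng, L["ecoli_ori"], left, right))
    )
    left, right = _flanks("marker")
    reg.add(Part("kanR", "marker", _clean_random_seq(rng, L["marker"], left, right)))
    left, right = _flanks("regulator")
    reg.add(
        Part("lacI", "regulator", _clean_random_seq(rng, L["regulator"], left, right))
    )

    backbone = assemble_single_tu(
        [reg.get(p) for p in ("pGA1", "colE1", "kanR", "rrnBT1T2", "eGFP")],
        name="pTGR1-backbone",
    )
    log.info("generated %d fixture parts (seed %d)", len(reg), spec.seed)
    return reg, backbone


_DEFAULT: tuple[Registry, DnaMolecule] | None = None


def default_registry() -> Registry:
    """The bundled registry: fixture parts at the fixed default seed."""
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = generate_fixtures(DEFAULT_SEED)
    return _DEFAULT[0]
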