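"""One-step gene design: reverse translation and forbidden-site removal.

Synthetic genes destined for the NdeI-EcoRI slot must avoid the six cassette
sites (NdeI, EcoRI, XbaI, SpeI, NheI, AvrII), including sites that would
only materialise in the cloning context: the upstream flank contributes CAT
ahead of the start codon and the downstream flank appends GAATTC after the
stop, and a 6-cutter can straddle either boundary.  Recoding is strictly
synonymous, deterministic, and table-driven: each residue gets its most
frequent codon, and each violating site is repaired by swapping, among the
codons overlapping it, to the highest-usage alternative that breaks it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources

from Bio.Seq import Seq

from .errors import GeneDesignError
from .grammar import CASSETTE_ENZYMES, Part, PartMetadata, validate_part
from .seqcore import ENZYMES, Enzyme

log = logging.getLogger("ptgr.geneprep")

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


def _translate(dna: str) -> str:
    return str(Seq(dna).translate())


@dataclass(frozen=True)
class CodonUsageTable:
    """aa -> [(codon, relative frequency)], descending by frequency."""

    usage: tuple[tuple[str, tuple[tuple[str, float], ...]], ...]

    def __post_init__(self) -> None:
        aas = {aa for aa, _ in self.usage}
        missing = (set(AMINO_ACIDS) | {"*"}) - aas
        if missing:
            raise GeneDesignError(f"usage table misses residues {sorted(missing)}")
        for aa, codons in self.usage:
            total = sum(f for _, f in codons)
            if abs(total - 1.0) > 1e-6:
                raise GeneDesignError(f"frequencies for {aa} sum to {total}, not 1")

    @classmethod
    def from_mapping(cls, mapping: dict[str, list[tuple[str, float]]]) -> "CodonUsageTable":
        entries = []
        for aa, codons in sorted(mapping.items()):
            # descending frequency, codon text as deterministic tie-break
            ordered = tuple(sorted(codons, key=lambda cf: (-cf[1], cf[0])))
            for codon, _ in ordered:
                if _translate(codon) != aa:
                    raise GeneDesignError(f"codon {codon} does not encode {aa}")
            entries.append((aa, ordered))
        return cls(tuple(entries))

    @classmethod
    def from_tsv(cls, text: str) -> "CodonUsageTable":
        mapping: dict[str, list[tuple[str, float]]] = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            aa, codon, freq = line.split("\t")
            mapping.setdefault(aa, []).append((codon.upper(), float(freq)))
        return cls.from_mapping(mapping)

    def _entry(self, aa: str) -> tuple[tuple[str, float], ...]:
        for a, codons in self.usage:
            if a == aa:
                return codons
        raise GeneDesignError(f"unknown residue {aa!r}")

    def preferred(self, aa: str) -> str:
        return self._entry(aa)[0][0]

    def synonyms(self, aa: str) -> tuple[tuple[str, float], ...]:
        return self._entry(aa)

    def frequency(self, codon: str) -> float:
        aa = _translate(codon)
        for c, f in self._entry(aa):
            if c == codon:
                return f
        raise GeneDesignError(f"codon {codon} not in table")


def default_usage_table() -> CodonUsageTable:
    text = resources.files("ptgr.data").joinpath("codon_usage_synthetic_cgl.tsv").read_text()
    return CodonUsageTable.from_tsv(text)


_DEFAULT_TABLE: CodonUsageTable | None = None


def _table(table: CodonUsageTable | None) -> CodonUsageTable:
    global _DEFAULT_TABLE
    if table is not None:
        return table
    if _DEFAULT_TABLE is None:
        _DEFAULT_TABLE = default_usage_table()
    return _DEFAULT_TABLE


def _recognitions(forbidden) -> list[tuple[str, str]]:
    out = []
    for item in forbidden:
        if isinstance(item, Enzyme):
            out.append((item.name, item.recognition))
        else:
            out.append((item, ENZYMES[item].recognition))
    return out


def reverse_translate(protein: str, table: CodonUsageTable | None = None) -> str:
    """Greedy most-frequent-codon encoding; appends the preferred stop."""
    table = _table(table)
    if not protein:
        raise GeneDesignError("empty protein")
    protein = protein.removesuffix("*")
    for i, aa in enumerate(protein):
        if aa not in AMINO_ACIDS:
            raise GeneDesignError(f"unknown residue {aa!r} at position {i}")
    return "".join(table.preferred(aa) for aa in protein) + table.preferred("*")


def _find_violations(
    dna: str, recs: list[tuple[str, str]], left_ctx: str, right_ctx: str
) -> list[tuple[int, str, str]]:
    """(start-in-core, enzyme, recognition) for every forbidden occurrence.

    The scan runs over left_ctx + dna + right_ctx; occurrences living
    entirely inside a context (the intended flank sites themselves) are not
    violations, occurrences overlapping the core are.  Core-relative starts
    may be negative for boundary-straddling sites.
    """
    text = left_ctx + dna + right_ctx
    off = len(left_ctx)
    out = []
    for name, rec in recs:
        i = text.find(rec)
        while i != -1:
            start, end = i - off, i - off + len(rec)
            if end > 0 and start < len(dna):
                # skip the canonical flank hexamers: NdeI completed by the
                # CAT context at core position -3, EcoRI appended at the end
                if not (
                    (left_ctx and start == -len(left_ctx))
                    or (right_ctx and start == len(dna))
                ):
                    out.append((start, name, rec))
            i = text.find(rec, i + 1)
    out.sort()
    return out


def remove_forbidden_sites(
    dna: str,
    table: CodonUsageTable | None = None,
    forbidden=CASSETTE_ENZYMES,
    _left_ctx: str = "",
    _right_ctx: str = "",
) -> str:
    """Synonymous-only recoding until no forbidden site remains.

    For each violation (scanned left to right) the candidate replacement
    codons overlapping the site are tried in descending usage; the first
    substitution that destroys the occurrence wins.  Translation never
    changes.  Raises :class:`GeneDesignError` if some site cannot be broken
    synonymously (cannot happen for a 6-cutter spanning two codons with any
    degenerate residue, but the contract is checked).
    """
    table = _table(table)
    if len(dna) % 3:
        raise GeneDesignError("DNA length not divisible by 3; recoding needs a frame")
    recs = _recognitions(forbidden)
    codons = [dna[i : i + 3] for i in range(0, len(dna), 3)]
    for _ in range(10 * len(codons) + 10):
        seq = "".join(codons)
        violations = _find_violations(seq, recs, _left_ctx, _right_ctx)
        if not violations:
            return seq
        start, name, rec = violations[0]
        lo = max(start, 0) // 3
        hi = min(start + len(rec) - 1, len(seq) - 1) // 3
        candidates = []
        for ci in range(lo, hi + 1):
            current = codons[ci]
            for alt, freq in table.synonyms(_translate(current)):
                if alt != current:
                    candidates.append((-freq, ci, alt))
        repaired = False
        for _negfreq, ci, alt in sorted(candidates):
            trial = codons.copy()
            trial[ci] = alt
            # acceptance test: the specific occurrence at `start` is gone
            ctx_text = _left_ctx + "".join(trial) + _right_ctx
            occ = ctx_text[start + len(_left_ctx) : start + len(_left_ctx) + len(rec)]
            if occ != rec:
                codons = trial
                repaired = True
                log.debug("broke %s at %d via codon %d -> %s", name, start, ci, alt)
                break
        if not repaired:
            raise GeneDesignError(
                f"{name} site at {start} cannot be removed by synonymous substitution"
            )
    raise GeneDesignError("recoding did not converge")


def design_orf(
    protein: str,
    table: CodonUsageTable | None = None,
    forbidden=CASSETTE_ENZYMES,
    part_id: str = "designed_orf",
    meta: PartMetadata | None = None,
) -> Part:
    """Compose reverse translation and site removal into a clean ORF part.

    The cloning-context boundaries are included in the scan: CAT upstream
    (the NdeI flank that completes the start codon) and GAATTC downstream
    (the EcoRI flank after the stop), so no forbidden site can straddle the
    part's edges once flanked.
    """
    table = _table(table)
    if not protein or protein == "*":
        raise GeneDesignError("empty protein")
    if not protein.startswith("M"):
        raise GeneDesignError("ORF design requires an initial methionine")
    dna = reverse_translate(protein, table)
    core = remove_forbidden_sites(
        dna, table, forbidden, _left_ctx="CAT", _right_ctx="GAATTC"
    )
    part = Part(part_id, "orf", core, meta or PartMetadata())
    rep = validate_part(part)
    if rep.errors:  # the pipeline guarantees cleanliness; guard regardless
        raise GeneDesignError(f"designed ORF fails validation:\n{rep}")
    return part
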