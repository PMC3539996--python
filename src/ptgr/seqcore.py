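"""Double-stranded DNA model, restriction enzymes, site scanning, digestion.

Coordinate conventions
----------------------
All intervals are 0-based, half-open, expressed on the top strand (5'->3').
Circular molecules use modular arithmetic; a feature on a circular molecule
may span the origin, in which case ``end`` exceeds the sequence length
(``start < L <= end <= start + L``).

Enzyme model
------------
A type-II enzyme is its recognition sequence plus two cut offsets measured
from the recognition start: ``cut_top`` for the top strand and ``cut_bottom``
for the position (in top-strand coordinates) where the bottom strand is cut.
``cut_top < cut_bottom`` yields a 5' overhang, the reverse a 3' overhang,
equality a blunt cut.  All eleven shipped enzymes recognise unambiguous
palindromic hexamers, so a single top-strand scan finds every site; an
extension to non-palindromic enzymes would have to scan both strands.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable

from .errors import (
    DigestError,
    SequenceError,
    SiteCollisionError,
    UncutPlasmid,
)

log = logging.getLogger("ptgr.seqcore")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
ALPHABET = frozenset("ACGT")

#: roles a Feature may carry besides the eight part roles
AUX_ROLES = ("scar", "site", "linker")


def revcomp(seq: str) -> str:
    """Watson-Crick reverse complement of strict A/C/G/T text."""
    if not seq:
        raise SequenceError("empty sequence")
    for i, ch in enumerate(seq):
        if ch not in ALPHABET:
            raise SequenceError(f"invalid character {ch!r} at position {i}")
    return seq.translate(_COMPLEMENT)[::-1]


def _check_alphabet(seq: str) -> None:
    if not seq:
        raise SequenceError("empty sequence")
    for i, ch in enumerate(seq):
        if ch not in ALPHABET:
            raise SequenceError(f"invalid character {ch!r} at position {i}")


def _least_rotation(s: str) -> int:
    """Index of the lexicographically minimal rotation (Booth's algorithm)."""
    s2 = s + s
    f = [-1] * len(s2)
    k = 0
    for j in range(1, len(s2)):
        sj = s2[j]
        i = f[j - k - 1]
        while i != -1 and sj != s2[k + i + 1]:
            if sj < s2[k + i + 1]:
                k = j - i - 1
            i = f[i]
        if sj != s2[k + i + 1]:
            if sj < s2[k]:
                k = j
            f[j - k] = -1
        else:
            f[j - k] = i + 1
    return k


def canonical_rotation(seq: str) -> str:
    k = _least_rotation(seq)
    return seq[k:] + seq[:k]


def canonical_form(seq: str) -> str:
    """Rotation- and strand-invariant identity for a circular top strand."""
    return min(canonical_rotation(seq), canonical_rotation(revcomp(seq)))


@dataclass(frozen=True)
class StickyEnd:
    """One terminus of a linear duplex.

    ``overhang`` is given 5'->3' on the protruding strand and is empty iff
    the end is blunt.  ``enzyme`` records which enzyme produced the end
    (needed to reconstruct the ligated junction context); it may be None for
    synthetic or imported ends.
    """

    kind: str = "blunt"  # blunt | five_prime | three_prime
    overhang: str = ""
    enzyme: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("blunt", "five_prime", "three_prime"):
            raise SequenceError(f"unknown end kind {self.kind!r}")
        if (self.kind == "blunt") != (self.overhang == ""):
            raise SequenceError("overhang must be empty iff end is blunt")
        if self.overhang:
            _check_alphabet(self.overhang)
        if len(self.overhang) > 4:
            raise SequenceError("overhangs longer than 4 nt are not supported")


BLUNT = StickyEnd()


@dataclass(frozen=True)
class Enzyme:
    name: str
    recognition: str
    cut_top: int
    cut_bottom: int

    def __post_init__(self) -> None:
        _check_alphabet(self.recognition)
        n = len(self.recognition)
        if not (0 <= self.cut_top <= n and 0 <= self.cut_bottom <= n):
            raise SequenceError(f"{self.name}: cut offsets outside recognition")
        if revcomp(self.recognition) != self.recognition:
            # palindromes only in v1; the derived overhang would otherwise
            # differ between strands
            raise SequenceError(f"{self.name}: non-palindromic recognition")
        if self.cut_bottom != n - self.cut_top:
            raise SequenceError(f"{self.name}: cuts not symmetric on a palindrome")

    @property
    def site_len(self) -> int:
        return len(self.recognition)

    @property
    def overhang_kind(self) -> str:
        if self.cut_top < self.cut_bottom:
            return "five_prime"
        if self.cut_top > self.cut_bottom:
            return "three_prime"
        return "blunt"

    @property
    def overhang(self) -> str:
        """Single-stranded extension, 5'->3' on the protruding strand."""
        lo, hi = sorted((self.cut_top, self.cut_bottom))
        return self.recognition[lo:hi]


def _load_enzymes() -> dict[str, Enzyme]:
    table: dict[str, Enzyme] = {}
    text = resources.files("ptgr.data").joinpath("enzymes.tsv").read_text()
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        name, rec, ct, cb = line.split("\t")
        table[name] = Enzyme(name, rec, int(ct), int(cb))
    return table


#: the eleven enzymes of the pTGR standard, keyed by name
ENZYMES: dict[str, Enzyme] = _load_enzymes()


def get_enzyme(name: str) -> Enzyme:
    try:
        return ENZYMES[name]
    except KeyError:
        raise DigestError(f"unknown enzyme {name!r}") from None


@dataclass
class Feature:
    label: str
    role: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise SequenceError(f"feature {self.label!r}: empty interval")
        if self.strand not in "+-":
            raise SequenceError(f"feature {self.label!r}: bad strand")

    def __len__(self) -> int:
        return self.end - self.start

    def shifted(self, delta: int) -> "Feature":
        return replace(self, start=self.start + delta, end=self.end + delta)


def uniquify_labels(features: list[Feature]) -> list[Feature]:
    """Suffix duplicate labels (#2, #3 ...); ``site`` features are exempt."""
    seen: dict[str, int] = {}
    out: list[Feature] = []
    for f in features:
        if f.role == "site":
            out.append(f)
            continue
        n = seen.get(f.label, 0) + 1
        seen[f.label] = n
        out.append(f if n == 1 else replace(f, label=f"{f.label}#{n}"))
    return out


@dataclass
class DnaMolecule:
    """Annotated double-stranded DNA, linear or circular.

    ``seq`` is the top strand.  For linear molecules the top strand spans
    from the left top-strand cut to the right top-strand cut, so top-strand
    lengths are additive under digestion and ligation.
    """

    seq: str
    topology: str = "circular"
    features: list[Feature] = field(default_factory=list)
    left_end: StickyEnd | None = None
    right_end: StickyEnd | None = None
    id: str = "molecule"
    source_id: str | None = None
    cut_coords: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        _check_alphabet(self.seq)
        if self.topology not in ("linear", "circular"):
            raise SequenceError(f"bad topology {self.topology!r}")
        if self.is_circular:
            if self.left_end is not None or self.right_end is not None:
                raise SequenceError("circular molecules carry no ends")
        else:
            if self.left_end is None:
                self.left_end = BLUNT
            if self.right_end is None:
                self.right_end = BLUNT
        L = len(self.seq)
        for f in self.features:
            if not (0 <= f.start < L):
                raise SequenceError(f"feature {f.label!r} start out of range")
            limit = f.start + L if self.is_circular else L
            if f.end > limit:
                raise SequenceError(f"feature {f.label!r} end out of range")

    # -- basic geometry ----------------------------------------------------

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def is_circular(self) -> bool:
        return self.topology == "circular"

    def subseq(self, start: int, length: int) -> str:
        """Top-strand text of length ``length`` starting at ``start`` (wraps)."""
        L = len(self.seq)
        if self.is_circular:
            start %= L
            return (self.seq * 2)[start : start + length]
        return self.seq[start : start + length]

    def rotated(self, offset: int) -> "DnaMolecule":
        """Circular molecule re-origined at ``offset``."""
        if not self.is_circular:
            raise SequenceError("only circular molecules can be rotated")
        L = len(self.seq)
        offset %= L
        seq = self.seq[offset:] + self.seq[:offset]
        feats = []
        for f in self.features:
            s = (f.start - offset) % L
            feats.append(replace(f, start=s, end=s + len(f)))
        return replace(self, seq=seq, features=feats)

    def reverse_complement(self) -> "DnaMolecule":
        L = len(self.seq)
        feats = []
        for f in self.features:
            if self.is_circular:
                s = (L - f.end) % L
            else:
                s = L - f.end
            feats.append(
                replace(
                    f,
                    start=s,
                    end=s + len(f),
                    strand="-" if f.strand == "+" else "+",
                )
            )
        feats.sort(key=lambda f: (f.start, f.end))
        if self.is_circular:
            return replace(self, seq=revcomp(self.seq), features=feats)
        return replace(
            self,
            seq=revcomp(self.seq),
            features=feats,
            left_end=self.right_end,
            right_end=self.left_end,
        )

    # -- identity ----------------------------------------------------------

    @property
    def canonical(self) -> str:
        if self.is_circular:
            return canonical_form(self.seq)
        return min(self.seq, revcomp(self.seq))

    def same_sequence(self, other: "DnaMolecule") -> bool:
        """Equality of the underlying DNA, rotation/strand-invariant."""
        return self.topology == other.topology and self.canonical == other.canonical

    # -- features ----------------------------------------------------------

    def features_by_role(self, role: str) -> list[Feature]:
        return [f for f in self.features if f.role == role]

    def find_feature(self, label: str) -> Feature | None:
        for f in self.features:
            if f.label == label:
                return f
        return None


# ---------------------------------------------------------------------------
# site scanning
# ---------------------------------------------------------------------------


def scan_sites(m: DnaMolecule, enzyme: Enzyme | str) -> list[int]:
    """Start positions of every recognition-site occurrence on the top strand.

    On circular molecules origin-spanning occurrences are included and all
    positions are reported mod len(seq).  The shipped enzyme set is
    palindromic, so this single-strand scan is complete.
    """
    e = get_enzyme(enzyme) if isinstance(enzyme, str) else enzyme
    rec = e.recognition
    text = m.seq + (m.seq[: len(rec) - 1] if m.is_circular else "")
    out = []
    i = text.find(rec)
    while i != -1:
        if i < len(m.seq):
            out.append(i)
        i = text.find(rec, i + 1)
    return out


def site_census(m: DnaMolecule, enzymes: Iterable[str] | None = None) -> dict[str, int]:
    names = list(enzymes) if enzymes is not None else list(ENZYMES)
    return {n: len(scan_sites(m, n)) for n in names}


# ---------------------------------------------------------------------------
# digestion
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class _Cut:
    site: int  # recognition start
    top: int  # top-strand cut (absolute, un-wrapped where possible)
    bottom: int
    enzyme: Enzyme

    @property
    def span(self) -> tuple[int, int]:
        lo, hi = sorted((self.top, self.bottom))
        return lo, hi


def _right_side_end(e: Enzyme) -> StickyEnd:
    """End of the fragment *downstream* of a cut (its new left terminus)."""
    if e.overhang_kind == "five_prime":
        return StickyEnd("five_prime", e.overhang, e.name)
    if e.overhang_kind == "three_prime":
        return StickyEnd("three_prime", revcomp(e.overhang), e.name)
    return StickyEnd("blunt", "", e.name)


def _left_side_end(e: Enzyme) -> StickyEnd:
    """End of the fragment *upstream* of a cut (its new right terminus)."""
    if e.overhang_kind == "five_prime":
        return StickyEnd("five_prime", revcomp(e.overhang), e.name)
    if e.overhang_kind == "three_prime":
        return StickyEnd("three_prime", e.overhang, e.name)
    return StickyEnd("blunt", "", e.name)


def _collect_cuts(m: DnaMolecule, enzymes: Iterable[Enzyme | str]) -> list[_Cut]:
    cuts: list[_Cut] = []
    for enz in enzymes:
        e = get_enzyme(enz) if isinstance(enz, str) else enz
        for p in scan_sites(m, e):
            cuts.append(_Cut(p, p + e.cut_top, p + e.cut_bottom, e))
    cuts.sort(key=lambda c: c.span)
    # overlapping or touching cut intervals leave no duplex between the two
    # overhangs -- nothing a ligase could ever seal again
    L = len(m.seq)
    for a, b in zip(cuts, cuts[1:]):
        if b.span[0] <= a.span[1]:
            raise SiteCollisionError(
                f"cut sites of {a.enzyme.name} at {a.site} and "
                f"{b.enzyme.name} at {b.site} collide"
            )
    if m.is_circular and len(cuts) > 1:
        first, last = cuts[0], cuts[-1]
        if first.span[0] + L <= last.span[1]:
            raise SiteCollisionError(
                f"cut sites of {last.enzyme.name} at {last.site} and "
                f"{first.enzyme.name} at {first.site} collide across the origin"
            )
    return cuts


def _slice_features(
    m: DnaMolecule, start: int, length: int
) -> list[Feature]:
    """Features of ``m`` clipped to the arc [start, start+length).

    Recognition-site annotations are dropped (they are cheap to recompute and
    are typically destroyed by the cut); part/scar/linker features are
    clipped and re-anchored to the fragment frame.
    """
    L = len(m.seq)
    out: list[Feature] = []
    for f in m.features:
        if f.role == "site":
            continue
        rel = (f.start - start) % L if m.is_circular else f.start - start
        flen = len(f)
        pieces = []
        if 0 <= rel < length:
            pieces.append((rel, min(rel + flen, length)))
        if m.is_circular and rel + flen > L:
            tail = rel + flen - L
            pieces.append((0, min(tail, length)))
        if not m.is_circular and rel < 0 < rel + flen:
            pieces.append((0, min(rel + flen, length)))
        for s, e_ in pieces:
            if e_ > s:
                out.append(replace(f, start=s, end=e_))
    out.sort(key=lambda f: (f.start, f.end))
    return uniquify_labels(out)


def digest(
    m: DnaMolecule, enzymes: Iterable[Enzyme | str]
) -> list[DnaMolecule]:
    """Complete digestion; returns linear fragments in top-strand order.

    A circular molecule with k cut positions yields exactly k fragments, a
    linear one k+1.  Each fragment's ends carry the producing enzyme so that
    downstream ligation can reconstruct junction scars.
    """
    enzymes = list(enzymes)
    if not enzymes:
        raise DigestError("at least one enzyme required")
    cuts = _collect_cuts(m, enzymes)
    L = len(m.seq)
    if not cuts:
        if m.is_circular:
            raise UncutPlasmid(f"{m.id}: no site for the given enzymes")
        return [replace(m, features=list(m.features))]
    frags: list[DnaMolecule] = []
    if m.is_circular:
        k = len(cuts)
        for i in range(k):
            c0, c1 = cuts[i], cuts[(i + 1) % k]
            flen = (c1.top - c0.top) % L or L
            seq = (m.seq * 2)[c0.top % L : c0.top % L + flen]
            frags.append(
                DnaMolecule(
                    seq,
                    "linear",
                    _slice_features(m, c0.top % L, flen),
                    left_end=_right_side_end(c0.enzyme),
                    right_end=_left_side_end(c1.enzyme),
                    id=f"{m.id}.frag{i}",
                    source_id=m.id,
                    cut_coords=(c0.top % L, c1.top % L),
                )
            )
    else:
        bounds = [0] + [c.top for c in cuts] + [L]
        left_ends = [m.left_end] + [_right_side_end(c.enzyme) for c in cuts]
        right_ends = [_left_side_end(c.enzyme) for c in cuts] + [m.right_end]
        for i in range(len(bounds) - 1):
            s, e_ = bounds[i], bounds[i + 1]
            frags.append(
                DnaMolecule(
                    m.seq[s:e_],
                    "linear",
                    _slice_features(m, s, e_ - s),
                    left_end=left_ends[i],
                    right_end=right_ends[i],
                    id=f"{m.id}.frag{i}",
                    source_id=m.id,
                    cut_coords=(s, e_),
                )
            )
    log.debug(
        "digest %s with %s -> %d fragment(s)",
        m.id,
        "+".join(e if isinstance(e, str) else e.name for e in enzymes),
        len(frags),
    )
    return frags
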