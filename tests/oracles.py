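"""Independent brute-force oracles used to cross-check the simulator.

These deliberately avoid the library's digestion/ligation code paths: they
work on raw strings with their own site search, cut arithmetic and
end-pairing enumeration.
"""

from __future__ import annotations

_COMP = str.maketrans("ACGT", "TGCA")


def rc(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def find_sites(seq: str, rec: str, circular: bool) -> list[int]:
    text = seq + seq[: len(rec) - 1] if circular else seq
    return [
        i
        for i in range(len(text) - len(rec) + 1)
        if text[i : i + len(rec)] == rec and i < len(seq)
    ]


def fragment_lengths(
    seq: str, enzymes: list[tuple[str, int]], circular: bool
) -> list[int] | None:
    """Sorted top-strand fragment lengths; None if a circular seq is uncut.

    ``enzymes`` is a list of (recognition, top-strand cut offset).
    """
    L = len(seq)
    cuts = sorted(
        {
            (p + ct) % L if circular else p + ct
            for rec, ct in enzymes
            for p in find_sites(seq, rec, circular)
        }
    )
    if circular:
        if not cuts:
            return None
        return sorted(
            ((cuts[(i + 1) % len(cuts)] - c) % L or L) for i, c in enumerate(cuts)
        )
    bounds = [0] + cuts + [L]
    return sorted(b - a for a, b in zip(bounds, bounds[1:]))


def count_cuts(seq: str, enzymes: list[tuple[str, int]], circular: bool) -> int:
    L = len(seq)
    return len(
        {
            (p + ct) % L if circular else p + ct
            for rec, ct in enzymes
            for p in find_sites(seq, rec, circular)
        }
    )


# -- ligation enumeration ----------------------------------------------------
# a fragment for the oracle is (seq, left_end, right_end) with ends encoded
# as (kind, overhang) tuples


def _compatible(a: tuple[str, str], b: tuple[str, str]) -> bool:
    if a[0] != b[0]:
        return False
    if a[0] == "blunt":
        return True
    return rc(a[1]) == b[1]


def _flip(frag):
    seq, left, right = frag
    return rc(seq), right, left


def _canon(seq: str) -> str:
    rots = [seq[i:] + seq[:i] for i in range(len(seq))]
    r = rc(seq)
    rots += [r[i:] + r[:i] for i in range(len(r))]
    return min(rots)


def circular_products(frags: list[tuple]) -> set[str]:
    """Canonical top strands of every circularisation of 1 or 2 fragments.

    Exhaustive: all orderings and all orientation combinations are tried,
    then deduplicated under rotation and reverse complement.
    """
    out: set[str] = set()
    if len(frags) == 1:
        for f in (frags[0], _flip(frags[0])):
            seq, left, right = f
            if _compatible(right, left):
                out.add(_canon(seq))
        return out
    assert len(frags) == 2
    a, b = frags
    for first in (a, _flip(a)):
        for second in (b, _flip(b)):
            for x, y in ((first, second), (second, first)):
                if _compatible(x[2], y[1]) and _compatible(y[2], x[1]):
                    out.add(_canon(x[0] + y[0]))
    return out
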