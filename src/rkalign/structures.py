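"""Data model for pseudoknotted RNA secondary structures.

A :class:`Structure` is a nucleotide sequence plus a set of disjoint base
pairs, 1-based, with no restriction against crossing pairs — pseudoknots are
first-class citizens.  The aligner does not operate on raw positions but on
*elements*: an element is either a single (unpaired) base or a whole base
pair.  Aligning a single base with a base pair is prohibited, so the element
sequence is the natural unit for both the dynamic programs and the decoder.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable

_VALID_NTS = set("ACGUN")

SINGLE = "single"
PAIR = "pair"


class StructureError(ValueError):
    """Raised for invalid structure definitions."""


def _normalize_sequence(seq: str) -> str:
    seq = seq.strip().upper().replace("T", "U")
    bad = set(seq) - _VALID_NTS
    if bad:
        raise StructureError(f"invalid nucleotide characters: {sorted(bad)}")
    return seq


@dataclass(frozen=True)
class Structure:
    """An RNA secondary structure, possibly pseudoknotted.

    Parameters
    ----------
    id : str
        Label for the structure.
    sequence : str
        Nucleotides over {A, C, G, U, N}; T is normalized to U on input.
    pairs : frozenset of (int, int)
        Base pairs (i, j), 1-based with i < j.  Every position participates
        in at most one pair; crossing pairs are allowed.
    """

    id: str
    sequence: str
    pairs: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        object.__setattr__(self, "sequence", _normalize_sequence(self.sequence))
        pairs = frozenset((int(i), int(j)) for i, j in self.pairs)
        object.__setattr__(self, "pairs", pairs)
        m = len(self.sequence)
        if m < 1:
            raise StructureError("sequence must be non-empty")
        seen: set[int] = set()
        for i, j in pairs:
            if not (1 <= i < j <= m):
                raise StructureError(f"pair ({i},{j}) out of range for length {m}")
            if i in seen or j in seen:
                raise StructureError(f"position reused by pair ({i},{j})")
            seen.add(i)
            seen.add(j)

    def __len__(self) -> int:
        return len(self.sequence)

    def nt(self, i: int) -> str:
        """Nucleotide at 1-based position ``i``."""
        return self.sequence[i - 1]

    @property
    def partner(self) -> dict[int, int]:
        """Map of position -> pairing partner (both directions)."""
        d: dict[int, int] = {}
        for i, j in self.pairs:
            d[i] = j
            d[j] = i
        return d


@dataclass(frozen=True, order=True)
class Element:
    """The alignment unit: a single base or a whole base pair.

    ``left == right`` for singles.  The forward DP visits a pair at its
    *right* base; the suffix DP visits it at its *left* base.
    """

    left: int
    right: int
    kind: str

    def __post_init__(self):
        if self.kind not in (SINGLE, PAIR):
            raise StructureError(f"bad element kind {self.kind!r}")
        if self.kind == SINGLE and self.left != self.right:
            raise StructureError("single element must have left == right")
        if self.kind == PAIR and not self.left < self.right:
            raise StructureError("pair element must have left < right")

    @property
    def anchor(self) -> int:
        """Position at which the (prefix) DP visits this element."""
        return self.right

    def nts(self, s: Structure) -> str:
        """The element's nucleotide(s) in structure ``s``."""
        if self.kind == SINGLE:
            return s.nt(self.left)
        return s.nt(self.left) + s.nt(self.right)


def single(pos: int) -> Element:
    return Element(pos, pos, SINGLE)


def pair(i: int, j: int) -> Element:
    return Element(i, j, PAIR)


def elementize(s: Structure) -> list[Element]:
    """Reduce a structure to its element sequence, ordered by right anchor.

    Left bases of pairs produce no element of their own; the element count is
    the number of single bases plus the number of base pairs, i.e.
    ``len(s) - len(s.pairs)``.
    """
    partner = s.partner
    out: list[Element] = []
    for p in range(1, len(s) + 1):
        q = partner.get(p)
        if q is None:
            out.append(single(p))
        elif q < p:  # right base of the pair (q, p)
            out.append(pair(q, p))
    return out


def _cross(a: tuple[int, int], b: tuple[int, int]) -> bool:
    (i, j), (u, v) = a, b
    return (i < u < j < v) or (u < i < v < j)


def crossing_pairs(s: Structure) -> set[frozenset]:
    """All unordered pairs of base pairs that cross (i < u < j < v)."""
    out: set[frozenset] = set()
    for a, b in itertools.combinations(sorted(s.pairs), 2):
        if _cross(a, b):
            out.add(frozenset((a, b)))
    return out


def is_pseudoknotted(s: Structure) -> bool:
    return bool(crossing_pairs(s))


@dataclass(frozen=True)
class Stem:
    """A maximal run of consecutively stacked base pairs."""

    pairs: tuple

    def __post_init__(self):
        ps = tuple(sorted(self.pairs))
        object.__setattr__(self, "pairs", ps)
        for (i1, j1), (i2, j2) in zip(ps, ps[1:]):
            if i2 != i1 + 1 or j2 != j1 - 1:
                raise StructureError("stem pairs must stack consecutively")

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def span(self) -> tuple[int, int]:
        """Outermost (left, right) positions covered by the stem."""
        return self.pairs[0][0], self.pairs[0][1]


def find_stems(s: Structure) -> list[Stem]:
    """Partition the pair set into maximal stacked runs."""
    pairs = sorted(s.pairs)
    pairset = set(pairs)
    stems: list[Stem] = []
    used: set[tuple[int, int]] = set()
    for p in pairs:
        if p in used:
            continue
        i, j = p
        # p starts a stem iff (i-1, j+1) is not also a pair
        if (i - 1, j + 1) in pairset:
            continue
        run = [p]
        used.add(p)
        while (run[-1][0] + 1, run[-1][1] - 1) in pairset:
            nxt = (run[-1][0] + 1, run[-1][1] - 1)
            run.append(nxt)
            used.add(nxt)
        stems.append(Stem(tuple(run)))
    return stems


PK_NONE = "none"
PK_H_TYPE = "H-type"
PK_RECURSIVE = "recursive"


def classify_pseudoknot_type(s: Structure) -> str:
    """Classify the pseudoknot topology of a structure.

    ``none`` if no two base pairs cross.  ``H-type`` if the crossing relation
    involves exactly two stems, interleaved ABAB, with no further stem nested
    inside the region the pseudoknot spans.  Anything else is ``recursive``.
    """
    if not is_pseudoknotted(s):
        return PK_NONE
    stems = find_stems(s)
    crossing_stems = set()
    for a, b in itertools.combinations(range(len(stems)), 2):
        if any(_cross(x, y) for x in stems[a].pairs for y in stems[b].pairs):
            crossing_stems.add(a)
            crossing_stems.add(b)
    if len(crossing_stems) != 2:
        return PK_RECURSIVE
    sa, sb = (stems[t] for t in sorted(crossing_stems))
    lo = min(sa.span[0], sb.span[0])
    hi = max(sa.span[1], sb.span[1])
    for t, stem in enumerate(stems):
        if t in crossing_stems:
            continue
        l, r = stem.span
        if lo < l and r < hi:
            return PK_RECURSIVE
    return PK_H_TYPE
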