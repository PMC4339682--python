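"""Greedy maximum-expected-accuracy pairwise alignment.

Alignment lines (matched element pairs) are accepted in descending posterior
order.  A candidate is discarded permanently if it reuses an element already
covered by an accepted line or if, against any accepted line, the six
non-crossing biconditionals fail (singles are treated as degenerate pairs
with i = j).  Iteration runs until the smallest posterior has been
considered; elements left uncovered are aligned to gaps.  The expected
accuracy of the result is the sum of accepted line posteriors divided by
max{h, k}, where h and k count elements (single bases plus base pairs) of
the two structures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .metrics import AlignmentColumns, TAG_LEFT, TAG_RIGHT, TAG_SINGLE
from .posterior import PosteriorMatrix, posterior_matrix
from .scoring import ScoringParams
from .structures import Element, Structure


@dataclass(frozen=True)
class AlignmentLine:
    """A matched same-kind element pair with its backing posterior."""

    a_elem: Element
    b_elem: Element
    posterior: float

    def __post_init__(self):
        if self.a_elem.kind != self.b_elem.kind:
            raise ValueError("alignment line must join elements of the same kind")


def check_noncrossing(l1: AlignmentLine, l2: AlignmentLine) -> bool:
    """True iff the two lines can coexist (all six biconditionals hold)."""
    return _compatible(l1.a_elem, l1.b_elem, l2.a_elem, l2.b_elem)


def _compatible(a1: Element, b1: Element, a2: Element, b2: Element) -> bool:
    i, j = a1.left, a1.right
    p, q = b1.left, b1.right
    i2, j2 = a2.left, a2.right
    p2, q2 = b2.left, b2.right
    return (
        (i2 < i) == (p2 < p)
        and (i < i2 < j) == (p < p2 < q)
        and (i2 > j) == (p2 > q)
        and (j2 < i) == (q2 < p)
        and (i < j2 < j) == (p < q2 < q)
        and (j2 > j) == (q2 > q)
    )


def greedy_select(
    entries: list[tuple[float, int, int]],
    elems_a: list[Element],
    elems_b: list[Element],
) -> list[tuple[float, int, int]]:
    """Core greedy line selection over (posterior, a_index, b_index) entries.

    Ties are broken by (posterior desc, A anchor asc, B anchor asc), giving a
    total order and deterministic output.
    """
    order = sorted(
        entries,
        key=lambda t: (-t[0], elems_a[t[1]].anchor, elems_b[t[2]].anchor),
    )
    used_a: set[int] = set()
    used_b: set[int] = set()
    accepted: list[tuple[float, int, int]] = []
    for v, ai, bi in order:
        if ai in used_a or bi in used_b:
            continue
        ea, eb = elems_a[ai], elems_b[bi]
        if all(
            _compatible(ea, eb, elems_a[aj], elems_b[bj]) for _, aj, bj in accepted
        ):
            accepted.append((v, ai, bi))
            used_a.add(ai)
            used_b.add(bi)
    return accepted


def merge_layout(
    matched: list[tuple[int, int]], m: int, n: int
) -> list[tuple[int | None, int | None]]:
    """Lay out two coordinate ranges 1..m and 1..n into columns.

    ``matched`` are monotone matched position pairs.  Unmatched positions
    between consecutive matches are emitted left-most: A-side first, then
    B-side, then the matched column; trailing unmatched positions follow the
    last match in the same order.
    """
    cols: list[tuple[int | None, int | None]] = []
    ia, ib = 1, 1
    for pa, pb in sorted(matched):
        while ia < pa:
            cols.append((ia, None))
            ia += 1
        while ib < pb:
            cols.append((None, ib))
            ib += 1
        cols.append((pa, pb))
        ia, ib = pa + 1, pb + 1
    while ia <= m:
        cols.append((ia, None))
        ia += 1
    while ib <= n:
        cols.append((None, ib))
        ib += 1
    return cols


def position_tag(s: Structure, pos: int) -> str:
    q = s.partner.get(pos)
    if q is None:
        return TAG_SINGLE
    return TAG_LEFT if pos < q else TAG_RIGHT


@dataclass
class PairwiseAlignment:
    """A set of non-crossing alignment lines between two structures."""

    A: Structure
    B: Structure
    lines: list[AlignmentLine]
    elements_a: list[Element] = field(default_factory=list)
    elements_b: list[Element] = field(default_factory=list)

    @property
    def gapped_a(self) -> list[Element]:
        covered = {l.a_elem for l in self.lines}
        return [e for e in self.elements_a if e not in covered]

    @property
    def gapped_b(self) -> list[Element]:
        covered = {l.b_elem for l in self.lines}
        return [e for e in self.elements_b if e not in covered]

    def matched_positions(self) -> list[tuple[int, int]]:
        """Nucleotide-level matched position pairs, sorted; always monotone."""
        out = []
        for l in self.lines:
            out.append((l.a_elem.left, l.b_elem.left))
            if l.a_elem.kind == "pair":
                out.append((l.a_elem.right, l.b_elem.right))
        return sorted(out)

    def expected_accuracy(self) -> float:
        h = len(self.elements_a)
        k = len(self.elements_b)
        if max(h, k) == 0:
            return 0.0
        return sum(l.posterior for l in self.lines) / max(h, k)

    def to_columns(self) -> AlignmentColumns:
        layout = merge_layout(self.matched_positions(), len(self.A), len(self.B))
        cells = []
        for pa, pb in layout:
            ca = (self.A.nt(pa), position_tag(self.A, pa)) if pa else None
            cb = (self.B.nt(pb), position_tag(self.B, pb)) if pb else None
            cells.append([ca, cb])
        return AlignmentColumns([self.A.id, self.B.id], cells)


def expected_accuracy(aln: PairwiseAlignment) -> float:
    return aln.expected_accuracy()


def greedy_align(P: PosteriorMatrix, A: Structure, B: Structure) -> PairwiseAlignment:
    """Decode a posterior matrix into a (sub)optimal pairwise alignment."""
    entries = [(v, ai, bi) for (ai, bi), v in P.values.items()]
    accepted = greedy_select(entries, P.elements_a, P.elements_b)
    lines = [
        AlignmentLine(P.elements_a[ai], P.elements_b[bi], v) for v, ai, bi in accepted
    ]
    lines.sort(key=lambda l: l.a_elem.anchor)
    aln = PairwiseAlignment(A, B, lines, P.elements_a, P.elements_b)
    _assert_valid(aln)
    return aln


def _assert_valid(aln: PairwiseAlignment) -> None:
    seen_a: set[Element] = set()
    seen_b: set[Element] = set()
    for l in aln.lines:
        if l.a_elem in seen_a or l.b_elem in seen_b:
            raise AssertionError("element covered by more than one line")
        seen_a.add(l.a_elem)
        seen_b.add(l.b_elem)
    for x in aln.lines:
        for y in aln.lines:
            if x is not y and not check_noncrossing(x, y):
                raise AssertionError("crossing alignment lines in output")


def align(
    A: Structure, B: Structure, params: ScoringParams | None = None
) -> PairwiseAlignment:
    """Posterior matrix + greedy decoding in one call."""
    params = params or ScoringParams()
    return greedy_align(posterior_matrix(A, B, params), A, B)
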