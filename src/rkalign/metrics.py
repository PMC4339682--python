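"""Alignment quality measures.

The base_mismatch ratio penalizes columns that align a single base with a
paired base, or a nucleotide with a gap.  The stem_mismatch ratio asks how
many maximal stems are matched exclusively and pair-coherently across the
two structures.  For multiple alignments the base mismatch is averaged over
all projected record pairs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

from .structures import Structure, find_stems

TAG_SINGLE = "single"
TAG_LEFT = "left"
TAG_RIGHT = "right"

Cell = tuple[str, str] | None  # (nucleotide, tag) or None for a gap


@dataclass
class AlignmentColumns:
    """Column view of an alignment at nucleotide resolution.

    ``cells[col][rec]`` is ``(nucleotide, tag)`` with tag single/left/right,
    or ``None`` for a gap.
    """

    ids: list[str]
    cells: list[list[Cell]]

    @property
    def n_records(self) -> int:
        return len(self.ids)

    def __len__(self) -> int:
        return len(self.cells)

    def project(self, r1: int, r2: int) -> "AlignmentColumns":
        """Two-record projection; columns gapped in both records dropped."""
        cols = [
            [col[r1], col[r2]]
            for col in self.cells
            if col[r1] is not None or col[r2] is not None
        ]
        return AlignmentColumns([self.ids[r1], self.ids[r2]], cols)


def _is_base_mismatch(a: Cell, b: Cell) -> bool:
    if a is None and b is None:
        return False
    if a is None or b is None:  # nucleotide aligned to a gap
        return True
    # single base aligned with the left or right base of a base pair
    return (a[1] == TAG_SINGLE) != (b[1] == TAG_SINGLE)


def base_mismatch_ratio(cols: AlignmentColumns) -> float:
    """Percentage of columns that are base mismatches (two records)."""
    if cols.n_records != 2:
        raise ValueError("base_mismatch_ratio is defined for two records")
    if len(cols) == 0:
        return 0.0
    bad = sum(1 for col in cols.cells if _is_base_mismatch(col[0], col[1]))
    return 100.0 * bad / len(cols)


def count_gaps(cols: AlignmentColumns) -> int:
    """Total number of gap characters across all records."""
    return sum(1 for col in cols.cells for cell in col if cell is None)


def stem_mismatch_ratio(aln, A: Structure, B: Structure) -> float:
    """(1 - matched-stem fraction) x 100%.

    A stem of A matches a stem of B when the two are aligned together
    exclusively (neither has bases aligned into any other stem) and
    pair-coherently: whenever a base of a pair of one stem is aligned with a
    base of a pair of the other, the partner bases are aligned too.  Both
    members of a matched stem pair count toward M, so aligning a structure
    with itself scores 0%.

    ``aln`` must expose ``matched_positions()`` -> list of (pos_a, pos_b).
    """
    stems_a = find_stems(A)
    stems_b = find_stems(B)
    total = len(stems_a) + len(stems_b)
    if total == 0:
        return 0.0
    matched = dict(aln.matched_positions())  # pos_a -> pos_b
    inv = {v: k for k, v in matched.items()}

    def stem_of(stems, pos):
        for t, st in enumerate(stems):
            if any(pos in p for p in st.pairs):
                return t
        return None

    # which B stems each A stem touches through the alignment, and vice versa
    touch_a = [set() for _ in stems_a]
    touch_b = [set() for _ in stems_b]
    for pa, pb in matched.items():
        ta = stem_of(stems_a, pa)
        tb = stem_of(stems_b, pb)
        if ta is not None and tb is not None:
            touch_a[ta].add(tb)
            touch_b[tb].add(ta)

    def coherent(sa, sb) -> bool:
        for (i, j) in sa.pairs:
            for (p, q) in sb.pairs:
                ends_b = {p, q}
                for left, other in ((i, j), (j, i)):
                    if matched.get(left) in ends_b:
                        partner = p if matched[left] == q else q
                        if matched.get(other) != partner:
                            return False
        return True

    n_matched = 0
    for ta, tb in itertools.product(range(len(stems_a)), range(len(stems_b))):
        if touch_a[ta] == {tb} and touch_b[tb] == {ta}:
            if coherent(stems_a[ta], stems_b[tb]):
                n_matched += 2  # both members of the matched pair
    return (1.0 - n_matched / total) * 100.0


def multiple_base_mismatch_ratio(cols: AlignmentColumns) -> float:
    """Mean pairwise base_mismatch ratio over all projected record pairs."""
    k = cols.n_records
    if k < 2:
        raise ValueError("need at least two records")
    ratios = [
        base_mismatch_ratio(cols.project(r1, r2))
        for r1, r2 in itertools.combinations(range(k), 2)
    ]
    return sum(ratios) / len(ratios)
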