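"""Partition functions over element-sequence alignments.

Three dynamic programs share one engine: the *forward* table over prefixes,
the *backward* table over suffixes, and the *inside* table over the interior
of a fixed aligned base-pair anchor.  Each cell decomposes as

    Z[c,d] = Z^M[c,d] + Z^E[c,d] + Z^F[c,d]

where M matches the two current elements (weight ``exp(score/T)``), E gaps
the B-side element, and F gaps the A-side element; each state's recursion
sums all three predecessor states, so the partition function is a sum over
monotone edit paths of the element grid, each gap interleaving counted once.

The reduction to element sequences makes the positional skipping rules
structural: a prefix DP never sees the left base of a pair (pairs are
anchored at their right base), the suffix DP anchors pairs at their left
base, and the inside DP for anchor ((i,j),(p,q)) sees only elements wholly
inside the interval — pairs crossing out of it are excluded and are handled
by their own posterior entries.

All arithmetic is in log space (log-sum-exp over anti-diagonals); cells with
no legal alignment carry ``-inf``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .scoring import ScoringParams, element_score, gap_score
from .structures import Element, Structure, elementize

FORWARD = "forward"
BACKWARD = "backward"
INSIDE = "inside"

# Running count of DP cell updates, for complexity measurements.
_cell_updates = 0


def reset_cell_updates() -> None:
    global _cell_updates
    _cell_updates = 0


def cell_updates() -> int:
    return _cell_updates


def elements_left_anchored(s: Structure) -> list[Element]:
    """Element sequence ordered by left anchor (suffix-DP order)."""
    return sorted(elementize(s), key=lambda e: e.left)


def _log_weights(
    ea: list[Element],
    sa: Structure,
    eb: list[Element],
    sb: Structure,
    params: ScoringParams,
):
    ca, cb = len(ea), len(eb)
    S = np.full((ca + 1, cb + 1), -np.inf)
    for c, x in enumerate(ea, 1):
        for d, y in enumerate(eb, 1):
            if x.kind == y.kind:
                S[c, d] = element_score(x, sa, y, sb, params) / params.T
    ga = np.zeros(ca + 1)
    gb = np.zeros(cb + 1)
    for c, x in enumerate(ea, 1):
        ga[c] = gap_score(x, params) / params.T
    for d, y in enumerate(eb, 1):
        gb[d] = gap_score(y, params) / params.T
    return S, ga, gb


def _grid_log_partition(S: np.ndarray, ga: np.ndarray, gb: np.ndarray) -> np.ndarray:
    """Path-sum DP on the (ca+1) x (cb+1) grid, anti-diagonal vectorized."""
    global _cell_updates
    ca = S.shape[0] - 1
    cb = S.shape[1] - 1
    logZ = np.full((ca + 1, cb + 1), -np.inf)
    logZ[0, 0] = 0.0
    logZ[1:, 0] = np.cumsum(ga[1:])
    logZ[0, 1:] = np.cumsum(gb[1:])
    for k in range(2, ca + cb + 1):
        lo = max(1, k - cb)
        hi = min(ca, k - 1)
        if lo > hi:
            continue
        cs = np.arange(lo, hi + 1)
        ds = k - cs
        m = logZ[cs - 1, ds - 1] + S[cs, ds]
        e = logZ[cs, ds - 1] + gb[ds]
        f = logZ[cs - 1, ds] + ga[cs]
        logZ[cs, ds] = np.logaddexp(np.logaddexp(m, e), f)
        _cell_updates += len(cs)
    return logZ


@dataclass
class PartitionTable:
    """A computed partition-function table over two element sequences.

    ``logZ[c, d]`` is the log partition function of all alignments of the
    first ``c`` elements of the A-side sequence with the first ``d`` of the
    B-side sequence (for the backward table the sequences run right-to-left;
    for the inside table they are the interior element subsequences of the
    anchoring aligned pair).
    """

    kind: str
    elements_a: list[Element]
    elements_b: list[Element]
    logZ: np.ndarray
    _S: np.ndarray
    _ga: np.ndarray
    _gb: np.ndarray
    anchor: tuple | None = None

    @property
    def log_total(self) -> float:
        return float(self.logZ[-1, -1])

    def state_components(self, c: int, d: int) -> tuple[float, float, float]:
        """(log Z^M, log Z^E, log Z^F) of cell (c, d), c, d >= 1."""
        m = self.logZ[c - 1, d - 1] + self._S[c, d]
        e = self.logZ[c, d - 1] + self._gb[d]
        f = self.logZ[c - 1, d] + self._ga[c]
        return float(m), float(e), float(f)


def _table(kind, ea, sa, eb, sb, params, anchor=None) -> PartitionTable:
    S, ga, gb = _log_weights(ea, sa, eb, sb, params)
    logZ = _grid_log_partition(S, ga, gb)
    return PartitionTable(kind, ea, eb, logZ, S, ga, gb, anchor)


def forward(
    A: Structure,
    B: Structure,
    params: ScoringParams,
    limit_a: int | None = None,
    limit_b: int | None = None,
) -> PartitionTable:
    """Prefix partition table; pairs are visited at their right base.

    ``limit_a``/``limit_b`` restrict to the prefixes A[1, limit_a] and
    B[1, limit_b]: only elements lying wholly inside the prefix take part
    (a pair whose right base lies beyond the limit contributes nothing,
    which realizes the rule of skipping left-base cells).
    """
    ea = [e for e in elementize(A) if limit_a is None or e.right <= limit_a]
    eb = [e for e in elementize(B) if limit_b is None or e.right <= limit_b]
    return _table(FORWARD, ea, A, eb, B, params)


def backward(
    A: Structure,
    B: Structure,
    params: ScoringParams,
    start_a: int = 1,
    start_b: int = 1,
) -> PartitionTable:
    """Suffix partition table over A[start_a, m] and B[start_b, n].

    Mirror of :func:`forward` on reversed element sequences with pairs
    anchored at their left base: a pair whose left base precedes the start
    takes no part.
    """
    ea = [e for e in elements_left_anchored(A) if e.left >= start_a][::-1]
    eb = [e for e in elements_left_anchored(B) if e.left >= start_b][::-1]
    return _table(BACKWARD, ea, A, eb, B, params)


def inside_elements(s: Structure, i: int, j: int) -> list[Element]:
    """Elements wholly inside the open interval (i, j) of a pair anchor."""
    return [e for e in elementize(s) if e.left >= i + 1 and e.right <= j - 1]


def inside(
    A: Structure,
    B: Structure,
    anchor: tuple[tuple[int, int], tuple[int, int]],
    params: ScoringParams,
) -> PartitionTable:
    """Interior partition table for the aligned pair anchor ((i,j), (p,q)).

    Pairs with a partner outside the interior (crossing the anchor) are
    excluded from the interior element sequences; they receive their own
    posterior entries instead.  Empty interiors give Z'' = 1.
    """
    (i, j), (p, q) = anchor
    if (i, j) not in A.pairs:
        raise ValueError(f"anchor pair ({i},{j}) not in structure {A.id!r}")
    if (p, q) not in B.pairs:
        raise ValueError(f"anchor pair ({p},{q}) not in structure {B.id!r}")
    ea = inside_elements(A, i, j)
    eb = inside_elements(B, p, q)
    return _table(INSIDE, ea, A, eb, B, params, anchor=anchor)
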