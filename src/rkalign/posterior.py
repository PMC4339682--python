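"""Posterior scores for element-to-element alignment lines.

For every same-kind element pair — base pair (i,j) of A against (p,q) of B,
or single base against single base — the posterior value is

    Prob((i,j) ~ (p,q)) =
        Z[1..i-1, 1..p-1] * Z''[(i,j),(p,q)] * Z'[j+1..m, q+1..n]
        / Z[1..m, 1..n] * exp(score((i,j),(p,q)) / T)

the Boltzmann-weighted fraction of alignments consistent with that line.
For single/single lines the interior factor is 1.  Crossing partners are
excluded from the restricted prefix/suffix/interior computations by the
element reduction (a pair whose partner leaves the region contributes no
element there); each such pair still gets its own posterior entry, so no
same-kind element pair is missed.

Values are stored on the linear (probability) scale, computed in log space.
No renormalization is applied: the restricted partition functions of a
pseudoknotted structure do not guarantee row sums of 1, and the expected
accuracy sums the raw values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .partition import (
    backward,
    elements_left_anchored,
    forward,
    inside,
)
from .scoring import ScoringParams, element_score
from .structures import Element, PAIR, SINGLE, Structure, elementize


@dataclass
class PosteriorMatrix:
    """Element-of-A x element-of-B posterior values.

    Only same-kind element pairs are populated; a single-vs-pair entry never
    exists.  ``values[(ai, bi)]`` indexes into ``elements_a``/``elements_b``.
    """

    elements_a: list[Element]
    elements_b: list[Element]
    values: dict = field(default_factory=dict)

    def get(self, ai: int, bi: int) -> float | None:
        return self.values.get((ai, bi))

    def dense(self) -> np.ndarray:
        """Matrix with NaN at prohibited (mixed-kind) entries."""
        out = np.full((len(self.elements_a), len(self.elements_b)), np.nan)
        for (ai, bi), v in self.values.items():
            out[ai, bi] = v
        return out

    def transpose(self) -> "PosteriorMatrix":
        return PosteriorMatrix(
            self.elements_b,
            self.elements_a,
            {(bi, ai): v for (ai, bi), v in self.values.items()},
        )


def posterior_matrix(
    A: Structure, B: Structure, params: ScoringParams | None = None
) -> PosteriorMatrix:
    """Compute the full posterior matrix for structures ``A`` and ``B``."""
    params = params or ScoringParams()
    ea = elementize(A)
    eb = elementize(B)
    fwd = forward(A, B, params)
    bwd = backward(A, B, params)
    log_total = fwd.log_total

    m, n = len(A), len(B)
    # prefix_a[pos]: how many A elements lie wholly within A[1, pos]
    prefix_a = np.zeros(m + 2, dtype=int)
    for e in ea:
        prefix_a[e.right] += 1
    prefix_a = np.cumsum(prefix_a)
    prefix_b = np.zeros(n + 2, dtype=int)
    for e in eb:
        prefix_b[e.right] += 1
    prefix_b = np.cumsum(prefix_b)
    # suffix counts, by left anchor (backward table row/col indices)
    suffix_a = np.zeros(m + 3, dtype=int)
    for e in elements_left_anchored(A):
        suffix_a[e.left] += 1
    suffix_a = np.cumsum(suffix_a[::-1])[::-1]
    suffix_b = np.zeros(n + 3, dtype=int)
    for e in elements_left_anchored(B):
        suffix_b[e.left] += 1
    suffix_b = np.cumsum(suffix_b[::-1])[::-1]

    values: dict[tuple[int, int], float] = {}
    for ai, x in enumerate(ea):
        for bi, y in enumerate(eb):
            if x.kind != y.kind:
                continue
            i, j = x.left, x.right
            p, q = y.left, y.right
            log_pre = fwd.logZ[prefix_a[i - 1], prefix_b[p - 1]]
            log_suf = bwd.logZ[suffix_a[j + 1], suffix_b[q + 1]]
            if x.kind == PAIR:
                log_in = inside(A, B, ((i, j), (p, q)), params).log_total
            else:
                log_in = 0.0
            s = element_score(x, A, y, B, params) / params.T
            values[(ai, bi)] = float(
                np.exp(log_pre + log_in + log_suf + s - log_total)
            )
    return PosteriorMatrix(ea, eb, values)
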