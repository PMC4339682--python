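"""Independent brute-force oracles for the test suite.

Everything here works by explicit enumeration — monotone edit paths, line
subsets, orderings — and never calls the dynamic programs or the greedy
decoder it is used to check.
"""

from __future__ import annotations

import itertools
import math

from rkalign.scoring import ScoringParams, element_score, gap_score
from rkalign.structures import Element, Structure


def path_weight_sum(
    ea: list[Element],
    sa: Structure,
    eb: list[Element],
    sb: Structure,
    params: ScoringParams,
) -> float:
    """Sum of Boltzmann weights over all monotone edit paths (explicit DFS).

    A path is a sequence of moves (match both current elements, gap the
    B-side element, gap the A-side element); every interleaving of gap moves
    is a distinct path, matching the alignment grammar of the DP.
    """
    T = params.T

    def rec(c: int, d: int) -> float:
        if c == len(ea) and d == len(eb):
            return 1.0
        total = 0.0
        if c < len(ea) and d < len(eb) and ea[c].kind == eb[d].kind:
            w = math.exp(element_score(ea[c], sa, eb[d], sb, params) / T)
            total += w * rec(c + 1, d + 1)
        if d < len(eb):
            total += math.exp(gap_score(eb[d], params) / T) * rec(c, d + 1)
        if c < len(ea):
            total += math.exp(gap_score(ea[c], params) / T) * rec(c + 1, d)
        return total

    return rec(0, 0)


def _elements_in(s: Structure, lo: int, hi: int, order: str = "prefix") -> list[Element]:
    """Elements of s wholly inside [lo, hi], from first principles.

    ``order="prefix"`` lists elements as the prefix/interior grammars visit
    them (ascending positions, pairs at their right base); ``order="suffix"``
    as the suffix grammar does (pairs anchored at their left base — listed
    ascending here, which by joint reversal sums the same paths as the
    descending traversal).
    """
    from rkalign.structures import pair, single

    partner = s.partner
    out = []
    for p in range(lo, hi + 1):
        q = partner.get(p)
        if q is None:
            out.append(single(p))
        elif order == "prefix" and lo <= q < p:  # right base, partner inside
            out.append(pair(q, p))
        elif order == "suffix" and p < q <= hi:  # left base, partner inside
            out.append(pair(p, q))
    return out


def posterior_oracle(
    A: Structure,
    B: Structure,
    x: Element,
    y: Element,
    params: ScoringParams,
) -> float:
    """Posterior of the line x ~ y by brute-force enumeration of each factor.

    Prefix, interior and suffix element sequences are rebuilt from the
    region definitions (pairs wholly inside the region take part; pairs
    crossing out of it are ignored), each partition function is an explicit
    path enumeration, and the ratio of Eq-style restricted products over the
    total is returned.
    """
    i, j = x.left, x.right
    p, q = y.left, y.right
    pre = path_weight_sum(
        _elements_in(A, 1, i - 1), A, _elements_in(B, 1, p - 1), B, params
    )
    suf = path_weight_sum(
        _elements_in(A, j + 1, len(A), "suffix"),
        A,
        _elements_in(B, q + 1, len(B), "suffix"),
        B,
        params,
    )
    if x.kind == "pair":
        inner = path_weight_sum(
            _elements_in(A, i + 1, j - 1), A, _elements_in(B, p + 1, q - 1), B, params
        )
    else:
        inner = 1.0
    total = path_weight_sum(
        _elements_in(A, 1, len(A)), A, _elements_in(B, 1, len(B)), B, params
    )
    w = math.exp(element_score(x, A, y, B, params) / params.T)
    return pre * inner * suf * w / total


def lines_drawable_without_crossing(
    a1: Element, b1: Element, a2: Element, b2: Element
) -> bool:
    """Joint-diagram check: endpoint matches must be jointly monotone."""
    matches = [(a1.left, b1.left), (a2.left, b2.left)]
    if a1.kind == "pair":
        matches.append((a1.right, b1.right))
    if a2.kind == "pair":
        matches.append((a2.right, b2.right))
    matches.sort()
    return all(
        pb1 < pb2 for (_, pb1), (_, pb2) in zip(matches, matches[1:])
    )


def best_line_set(
    entries: list[tuple[float, int, int]],
    elems_a: list[Element],
    elems_b: list[Element],
) -> tuple[float, list]:
    """Exhaustive search for the constraint-satisfying line set with the
    maximum posterior sum (optimal expected-accuracy decoder at tiny n)."""
    from rkalign.pairwise import _compatible

    best = (0.0, [])

    def rec(idx: int, chosen: list, used_a: set, used_b: set, total: float):
        nonlocal best
        if total > best[0]:
            best = (total, list(chosen))
        if idx == len(entries):
            return
        v, ai, bi = entries[idx]
        rec(idx + 1, chosen, used_a, used_b, total)
        if ai in used_a or bi in used_b:
            return
        if all(
            _compatible(elems_a[ai], elems_b[bi], elems_a[aj], elems_b[bj])
            for _, aj, bj in chosen
        ):
            chosen.append(entries[idx])
            rec(idx + 1, chosen, used_a | {ai}, used_b | {bi}, total + v)
            chosen.pop()

    rec(0, [], set(), set(), 0.0)
    return best


def average_linkage_reference(n: int, sim: dict) -> list[tuple[frozenset, frozenset]]:
    """Straightforward agglomerative clustering; returns the merge sequence."""

    def s(i, j):
        return sim[(i, j) if i < j else (j, i)]

    clusters = [frozenset([i]) for i in range(n)]
    merges = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(clusters, 2):
            val = sum(s(i, j) for i in a for j in b) / (len(a) * len(b))
            key = (-val, min(min(a), min(b)), max(min(a), min(b)))
            if best is None or key < best[0]:
                best = (key, a, b)
        _, a, b = best
        merges.append((a, b))
        clusters = [c for c in clusters if c not in (a, b)] + [a | b]
    return merges


def random_structure(rng, max_len=12, pair_prob=0.5, sid="rand") -> Structure:
    """Small random structure, crossing pairs allowed."""
    m = int(rng.integers(1, max_len + 1))
    positions = list(range(1, m + 1))
    rng.shuffle(positions)
    pairs = set()
    used = set()
    t = 0
    while t + 1 < len(positions):
        if rng.random() < pair_prob:
            i, j = positions[t], positions[t + 1]
            if abs(i - j) >= 2:
                pairs.add((min(i, j), max(i, j)))
                used.update((i, j))
                t += 2
                continue
        t += 1
    seq = "".join("ACGU"[rng.integers(4)] for _ in range(m))
    return Structure(sid, seq, pairs)
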