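"""Progressive multiple alignment of pseudoknot structures.

A guide tree is built by agglomerative average-linkage clustering, where the
similarity of two structures is the expected accuracy of their pairwise
greedy alignment.  Internal nodes are resolved by profile-profile alignment:
a profile is a multiple alignment viewed as a sequence of single-base
columns and base-pair column pairs, and profile elements are aligned with
the same greedy decoder, driven by transformed probabilities

    Prob'((i',j') ~ (p',q')) =
        sum over member pairs (i,j) in (i',j'), (p,q) in (p',q')
        of Prob((i,j) ~ (p,q))  /  (|A'| |B'|)

i.e. the member-level posteriors averaged over the full cluster-size
product; members contributing gaps at a profile element contribute zero to
the sum.  Once two members are aligned within a profile their columns are
never rearranged at later merges.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from .metrics import AlignmentColumns
from .pairwise import greedy_select, merge_layout, position_tag
from .posterior import PosteriorMatrix, posterior_matrix
from .scoring import ScoringParams
from .structures import Element, PAIR, SINGLE, Structure, elementize, pair, single


@dataclass
class Profile:
    """A multiple alignment as an alignable column structure.

    ``colmaps[r]`` maps 1-based positions of member ``r`` to 1-based columns.
    """

    records: list[Structure]
    colmaps: list[dict]
    ncols: int

    @classmethod
    def singleton(cls, s: Structure) -> "Profile":
        return cls([s], [{i: i for i in range(1, len(s) + 1)}], len(s))

    def __len__(self) -> int:
        return len(self.records)

    def elements(self) -> list[Element]:
        """Profile elements in column coordinates, ordered by right anchor.

        A profile element is a pair element iff at least one member
        contributes a base pair at its columns.
        """
        pair_cols = set()
        for r, s in enumerate(self.records):
            cm = self.colmaps[r]
            for i, j in s.pairs:
                pair_cols.add((cm[i], cm[j]))
        covered = {c for lr in pair_cols for c in lr}
        elems = [pair(l, r) for l, r in pair_cols]
        elems += [single(c) for c in range(1, self.ncols + 1) if c not in covered]
        return sorted(elems, key=lambda e: e.anchor)

    def member_element_at(self, r: int, elem: Element) -> Element | None:
        """Member r's element occupying a profile element's columns, if any."""
        inv = {c: p for p, c in self.colmaps[r].items()}
        if elem.kind == PAIR:
            i = inv.get(elem.left)
            j = inv.get(elem.right)
            if i is None or j is None:
                return None
            if (i, j) in self.records[r].pairs:
                return pair(i, j)
            return None
        p = inv.get(elem.left)
        if p is None or p in self.records[r].partner:
            return None
        return single(p)

    def to_columns(self) -> AlignmentColumns:
        invs = [{c: p for p, c in cm.items()} for cm in self.colmaps]
        cells = []
        for col in range(1, self.ncols + 1):
            row = []
            for r, s in enumerate(self.records):
                p = invs[r].get(col)
                row.append((s.nt(p), position_tag(s, p)) if p else None)
            cells.append(row)
        return AlignmentColumns([s.id for s in self.records], cells)


@dataclass
class GuideTree:
    """Binary merge tree; leaves carry structure indices."""

    index: int | None = None
    left: "GuideTree | None" = None
    right: "GuideTree | None" = None
    similarity: float | None = None

    @property
    def is_leaf(self) -> bool:
        return self.index is not None

    @property
    def leaves(self) -> list[int]:
        if self.is_leaf:
            return [self.index]
        return self.left.leaves + self.right.leaves

    def newick(self, names: list[str] | None = None) -> str:
        def fmt(node):
            if node.is_leaf:
                return names[node.index] if names else str(node.index)
            return f"({fmt(node.left)},{fmt(node.right)}){node.similarity:.6g}"

        return fmt(self) + ";"


def build_guide_tree(
    n: int, similarity: dict[tuple[int, int], float]
) -> GuideTree:
    """Agglomerative average-linkage clustering over pairwise similarities.

    ``similarity[(i, j)]`` for i < j are leaf-level similarities (pairwise
    expected accuracies).  Ties are broken by the smallest leaf index pair.
    """
    if n < 2:
        raise ValueError("need at least two structures")

    def sim(i, j):
        return similarity[(i, j) if i < j else (j, i)]

    clusters: list[GuideTree] = [GuideTree(index=i) for i in range(n)]
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(range(len(clusters)), 2):
            la, lb = clusters[a].leaves, clusters[b].leaves
            s = sum(sim(i, j) for i in la for j in lb) / (len(la) * len(lb))
            key = (-s, min(min(la), min(lb)), max(min(la), min(lb)))
            if best is None or key < best[0]:
                best = (key, a, b, s)
        _, a, b, s = best
        merged = GuideTree(left=clusters[a], right=clusters[b], similarity=s)
        clusters = [c for t, c in enumerate(clusters) if t not in (a, b)]
        clusters.append(merged)
    return clusters[0]


def profile_posterior(
    pa: "Profile",
    pb: "Profile",
    leaf_indices_a: list[int],
    leaf_indices_b: list[int],
    posteriors: dict,
) -> list[tuple[float, int, int]]:
    """Transformed probabilities over profile element pairs.

    Returns sparse entries (value, a_elem_index, b_elem_index) for same-kind
    profile element pairs.  ``posteriors[(i, j)]`` (leaf indices, i < j) are
    member-level posterior matrices.
    """
    ea = pa.elements()
    eb = pb.elements()
    denom = len(pa) * len(pb)
    # per-member caches of member elements at each profile element
    mem_a = [
        [pa.member_element_at(r, e) for e in ea] for r in range(len(pa))
    ]
    mem_b = [
        [pb.member_element_at(r, e) for e in eb] for r in range(len(pb))
    ]
    lookups = {}
    for ra, ia in enumerate(leaf_indices_a):
        for rb, ib in enumerate(leaf_indices_b):
            if ia < ib:
                P = posteriors[(ia, ib)]
                idx_a = {e: t for t, e in enumerate(P.elements_a)}
                idx_b = {e: t for t, e in enumerate(P.elements_b)}
                lookups[(ra, rb)] = (P.values, idx_a, idx_b, False)
            else:
                P = posteriors[(ib, ia)]
                idx_a = {e: t for t, e in enumerate(P.elements_a)}
                idx_b = {e: t for t, e in enumerate(P.elements_b)}
                lookups[(ra, rb)] = (P.values, idx_b, idx_a, True)
    entries = []
    for aj, x in enumerate(ea):
        for bj, y in enumerate(eb):
            if x.kind != y.kind:
                continue
            total = 0.0
            for ra in range(len(pa)):
                me_a = mem_a[ra][aj]
                if me_a is None:
                    continue
                for rb in range(len(pb)):
                    me_b = mem_b[rb][bj]
                    if me_b is None:
                        continue
                    values, ix, iy, swapped = lookups[(ra, rb)]
                    key = (
                        (iy[me_b], ix[me_a]) if swapped else (ix[me_a], iy[me_b])
                    )
                    v = values.get(key)
                    if v:
                        total += v
            entries.append((total / denom, aj, bj))
    return entries


def merge_profiles(
    pa: Profile,
    pb: Profile,
    leaf_indices_a: list[int],
    leaf_indices_b: list[int],
    posteriors: dict,
) -> Profile:
    """Align two profiles with the greedy decoder and merge their columns."""
    ea = pa.elements()
    eb = pb.elements()
    entries = profile_posterior(pa, pb, leaf_indices_a, leaf_indices_b, posteriors)
    accepted = greedy_select(entries, ea, eb)
    matched_cols = []
    for _, ai, bi in accepted:
        matched_cols.append((ea[ai].left, eb[bi].left))
        if ea[ai].kind == PAIR:
            matched_cols.append((ea[ai].right, eb[bi].right))
    layout = merge_layout(matched_cols, pa.ncols, pb.ncols)
    map_a = {ca: t + 1 for t, (ca, cb) in enumerate(layout) if ca is not None}
    map_b = {cb: t + 1 for t, (ca, cb) in enumerate(layout) if cb is not None}
    records = pa.records + pb.records
    colmaps = [
        {p: map_a[c] for p, c in cm.items()} for cm in pa.colmaps
    ] + [{p: map_b[c] for p, c in cm.items()} for cm in pb.colmaps]
    return Profile(records, colmaps, len(layout))


@dataclass
class MultipleAlignment:
    """Result of progressive alignment: merged profile plus the guide tree."""

    profile: Profile
    tree: GuideTree
    posteriors: dict = field(repr=False, default_factory=dict)

    def to_columns(self) -> AlignmentColumns:
        return self.profile.to_columns()


def progressive_align(
    structures: list[Structure], params: ScoringParams | None = None
) -> MultipleAlignment:
    """Align two or more pseudoknot structures progressively.

    Pairwise posterior matrices and alignments are computed for every
    structure pair; expected accuracies drive average-linkage guide-tree
    construction; profiles are merged bottom-up along the tree.
    """
    from .pairwise import greedy_align

    if len(structures) < 2:
        raise ValueError("need at least two structures")
    params = params or ScoringParams()
    posteriors: dict[tuple[int, int], PosteriorMatrix] = {}
    sims: dict[tuple[int, int], float] = {}
    for i, j in itertools.combinations(range(len(structures)), 2):
        P = posterior_matrix(structures[i], structures[j], params)
        posteriors[(i, j)] = P
        sims[(i, j)] = greedy_align(
            P, structures[i], structures[j]
        ).expected_accuracy()
    tree = build_guide_tree(len(structures), sims)

    def realize(node: GuideTree) -> tuple[Profile, list[int]]:
        if node.is_leaf:
            return Profile.singleton(structures[node.index]), [node.index]
        pa, la = realize(node.left)
        pb, lb = realize(node.right)
        return merge_profiles(pa, pb, la, lb, posteriors), la + lb

    profile, _ = realize(tree)
    return MultipleAlignment(profile, tree, posteriors)
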