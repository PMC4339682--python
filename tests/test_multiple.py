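import itertools

import numpy as np
import pytest

from rkalign import (
    GeneratorConfig,
    ScoringParams,
    Structure,
    align,
    build_guide_tree,
    generate_family,
    multiple_base_mismatch_ratio,
    posterior_matrix,
    progressive_align,
)
from rkalign.multiple import Profile, merge_profiles, profile_posterior
from rkalign.pairwise import _compatible
from rkalign.structures import elementize

from oracles import average_linkage_reference


class TestGuideTree:
    def test_two_structures_single_merge(self):
        tree = build_guide_tree(2, {(0, 1): 0.7})
        assert sorted(tree.leaves) == [0, 1]
        assert tree.similarity == pytest.approx(0.7)

    def test_average_linkage_arithmetic_on_three_leaves(self):
        sims = {(0, 1): 0.9, (0, 2): 0.2, (1, 2): 0.3}
        tree = build_guide_tree(3, sims)
        first = tree.left if not tree.left.is_leaf else tree.right
        assert sorted(first.leaves) == [0, 1]
        assert first.similarity == pytest.approx(0.9)
        # average linkage: sim({0,1}, {2}) = (0.2 + 0.3) / 2
        assert tree.similarity == pytest.approx(0.25)

    def test_matches_reference_clustering_on_random_sets(self, rng):
        for _ in range(20):
            n = 5
            sims = {
                (i, j): float(rng.random())
                for i, j in itertools.combinations(range(n), 2)
            }
            tree = build_guide_tree(n, sims)
            ref = average_linkage_reference(n, sims)

            merges = set()

            def walk(node):
                if node.is_leaf:
                    return frozenset([node.index])
                a = walk(node.left)
                b = walk(node.right)
                merges.add(frozenset((a, b)))
                return a | b

            walk(tree)
            # identical dendrogram: same parent/children splits throughout
            assert merges == {frozenset((a, b)) for a, b in ref}

    def test_newick_lists_all_leaf_names(self):
        tree = build_guide_tree(3, {(0, 1): 0.9, (0, 2): 0.2, (1, 2): 0.3})
        nwk = tree.newick(["x", "y", "z"])
        assert nwk.endswith(";")
        for name in ("x", "y", "z"):
            assert name in nwk


class TestProfilePosterior:
    def test_singleton_profiles_reduce_to_pairwise_posteriors(self, params, h_type_toy):
        other = Structure("o", h_type_toy.sequence, h_type_toy.pairs)
        P = posterior_matrix(h_type_toy, other, params)
        pa = Profile.singleton(h_type_toy)
        pb = Profile.singleton(other)
        entries = profile_posterior(pa, pb, [0], [1], {(0, 1): P})
        ea, eb = pa.elements(), pb.elements()
        assert ea == elementize(h_type_toy)
        got = {(ai, bi): v for v, ai, bi in entries}
        assert set(got) == set(P.values)
        for key, v in P.values.items():
            assert got[key] == pytest.approx(v, rel=1e-12)

    def test_gapped_members_contribute_zero_but_denominator_is_full(self, params):
        # align two structures of different lengths, then aim the 2-profile
        # at a third structure: profile elements where one member is gapped
        # average a single member posterior over |A'||B'| = 2
        A = Structure("a", "GGAAACC", {(1, 7), (2, 6)})
        B = Structure("b", "GGAAAAACC", {(1, 9), (2, 8)})
        C = Structure("c", "GGAAACC", {(1, 7), (2, 6)})
        posts = {
            (0, 1): posterior_matrix(A, B, params),
            (0, 2): posterior_matrix(A, C, params),
            (1, 2): posterior_matrix(B, C, params),
        }
        pab = merge_profiles(Profile.singleton(A), Profile.singleton(B), [0], [1], posts)
        pc = Profile.singleton(C)
        entries = profile_posterior(pab, pc, [0, 1], [2], posts)
        ea = pab.elements()
        idx_ac = {e: t for t, e in enumerate(posts[(0, 2)].elements_a)}
        idx_bc = {e: t for t, e in enumerate(posts[(1, 2)].elements_a)}
        idx_c = {e: t for t, e in enumerate(posts[(0, 2)].elements_b)}
        for v, ai, bi in entries:
            me_a = pab.member_element_at(0, ea[ai])
            me_b = pab.member_element_at(1, ea[ai])
            mc = pc.member_element_at(0, pc.elements()[bi])
            expected = 0.0
            if me_a is not None:
                expected += posts[(0, 2)].values.get(
                    (idx_ac[me_a], idx_c[mc]), 0.0
                )
            if me_b is not None:
                expected += posts[(1, 2)].values.get(
                    (idx_bc[me_b], idx_c[mc]), 0.0
                )
            assert v == pytest.approx(expected / 2.0, rel=1e-12)


class TestProgressiveAlign:
    def test_identical_copies_align_gaplessly(self, params, h_type_toy):
        copies = [
            Structure(f"c{i}", h_type_toy.sequence, h_type_toy.pairs)
            for i in range(4)
        ]
        maln = progressive_align(copies, params)
        assert multiple_base_mismatch_ratio(maln.to_columns()) == 0.0
        assert maln.profile.ncols == len(h_type_toy)

    def test_two_structures_equal_pairwise_alignment(self, params):
        fam = generate_family(GeneratorConfig(seed=21, length=(30, 45)), 2)
        maln = progressive_align(fam, params)
        pw = align(fam[0], fam[1], params)
        assert {tuple(c) for c in maln.to_columns().cells} == {
            tuple(c) for c in pw.to_columns().cells
        }
        assert maln.to_columns().cells == pw.to_columns().cells

    def test_projected_pairs_satisfy_noncrossing(self, params):
        fam = generate_family(GeneratorConfig(seed=22, length=(30, 45)), 3)
        maln = progressive_align(fam, params)
        prof = maln.profile
        # every member pair: matched columns induce monotone, compatible lines
        for r1, r2 in itertools.combinations(range(len(prof)), 2):
            inv1 = {c: p for p, c in prof.colmaps[r1].items()}
            inv2 = {c: p for p, c in prof.colmaps[r2].items()}
            shared = sorted(set(inv1) & set(inv2))
            matched = [(inv1[c], inv2[c]) for c in shared]
            assert matched == sorted(matched)
            bs = [b for _, b in matched]
            assert bs == sorted(bs)

    def test_once_a_gap_always_a_gap(self, params):
        # member columns, once fixed inside a profile, are never reordered
        fam = generate_family(GeneratorConfig(seed=23, length=(30, 40)), 3)
        maln = progressive_align(fam, params)
        tree = maln.tree
        first = tree.left if not tree.left.is_leaf else tree.right
        if first.is_leaf:
            pytest.skip("caterpillar tree had leaf-first merge")
        i, j = sorted(first.leaves)
        pw = align(fam[i], fam[j], params)
        pw_matched = set(pw.matched_positions())
        prof = maln.profile
        order = [s.id for s in prof.records]
        ri, rj = order.index(fam[i].id), order.index(fam[j].id)
        inv_i = {c: p for p, c in prof.colmaps[ri].items()}
        inv_j = {c: p for p, c in prof.colmaps[rj].items()}
        final_matched = {
            (inv_i[c], inv_j[c]) for c in set(inv_i) & set(inv_j)
        }
        assert final_matched == pw_matched

    def test_requires_at_least_two_structures(self, params, h_type_toy):
        with pytest.raises(ValueError):
            progressive_align([h_type_toy], params)
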