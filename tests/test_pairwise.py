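import itertools

import pytest

from rkalign import (
    AlignmentLine,
    ScoringParams,
    Structure,
    align,
    base_mismatch_ratio,
    check_noncrossing,
    greedy_align,
    posterior_matrix,
    stem_mismatch_ratio,
)
from rkalign.pairwise import PairwiseAlignment, greedy_select, merge_layout
from rkalign.structures import elementize, pair, single

from oracles import best_line_set, lines_drawable_without_crossing, random_structure


class TestNonCrossing:
    def test_nested_on_both_sides_is_compatible(self):
        l1 = AlignmentLine(pair(1, 10), pair(1, 12), 1.0)
        l2 = AlignmentLine(pair(3, 8), pair(4, 9), 0.5)
        assert check_noncrossing(l1, l2)

    def test_nested_versus_outside_is_incompatible(self):
        l1 = AlignmentLine(pair(1, 10), pair(1, 12), 1.0)
        l2 = AlignmentLine(pair(3, 8), pair(11, 15), 0.5)
        assert not check_noncrossing(l1, l2)

    def test_interleaved_pseudoknot_lines_are_compatible(self):
        # ABAB pair lines on both sides may coexist
        l1 = AlignmentLine(pair(1, 8), pair(1, 8), 1.0)
        l2 = AlignmentLine(pair(4, 12), pair(4, 12), 0.5)
        assert check_noncrossing(l1, l2)

    def test_agrees_with_joint_diagram_check_over_all_orderings(self):
        # all relative orderings of two pair elements per structure
        positions = list(itertools.permutations(range(1, 5)))
        count = 0
        for aperm in positions:
            i, j = sorted(aperm[:2])
            i2, j2 = sorted(aperm[2:])
            for bperm in positions:
                p, q = sorted(bperm[:2])
                p2, q2 = sorted(bperm[2:])
                l1 = AlignmentLine(pair(i, j), pair(p, q), 1.0)
                l2 = AlignmentLine(pair(i2, j2), pair(p2, q2), 1.0)
                assert check_noncrossing(l1, l2) == lines_drawable_without_crossing(
                    pair(i, j), pair(p, q), pair(i2, j2), pair(p2, q2)
                )
                count += 1
        assert count == len(positions) ** 2

    def test_singles_treated_as_degenerate_pairs(self):
        l1 = AlignmentLine(pair(2, 8), pair(2, 8), 1.0)
        inside_line = AlignmentLine(single(5), single(5), 0.5)
        outside_line = AlignmentLine(single(5), single(9), 0.5)
        assert check_noncrossing(l1, inside_line)
        assert not check_noncrossing(l1, outside_line)


class TestGreedyAlign:
    def test_self_alignment_is_identity_with_no_gaps(self, params, h_type_structure):
        aln = align(h_type_structure, h_type_structure, params)
        assert not aln.gapped_a and not aln.gapped_b
        for l in aln.lines:
            assert l.a_elem == l.b_elem
        assert base_mismatch_ratio(aln.to_columns()) == 0.0
        assert stem_mismatch_ratio(aln, h_type_structure, h_type_structure) == 0.0

    def test_deterministic_under_ties(self):
        elems = [single(1), single(2)]
        entries = [(0.5, 0, 0), (0.5, 0, 1), (0.5, 1, 0), (0.5, 1, 1)]
        picked = greedy_select(entries, elems, elems)
        # tie-break: A anchor asc, then B anchor asc
        assert [(ai, bi) for _, ai, bi in picked] == [(0, 0), (1, 1)]

    def test_greedy_never_beats_exhaustive_optimum(self, params, rng):
        dominated = 0
        for _ in range(40):
            A = random_structure(rng, max_len=7, sid="A")
            B = random_structure(rng, max_len=7, sid="B")
            P = posterior_matrix(A, B, params)
            entries = [(v, ai, bi) for (ai, bi), v in P.values.items()]
            aln = greedy_align(P, A, B)
            greedy_sum = sum(l.posterior for l in aln.lines)
            best_sum, _ = best_line_set(entries, P.elements_a, P.elements_b)
            assert greedy_sum <= best_sum + 1e-12
            dominated += 1
        assert dominated == 40

    def test_greedy_is_optimal_on_dominant_line_fixture(self, params, h_type_toy):
        # self-comparison: the diagonal dominates every row/column, so the
        # greedy result must equal the exhaustive optimum
        A = h_type_toy
        P = posterior_matrix(A, A, params)
        entries = [(v, ai, bi) for (ai, bi), v in P.values.items()]
        aln = greedy_align(P, A, A)
        best_sum, _ = best_line_set(entries, P.elements_a, P.elements_b)
        assert sum(l.posterior for l in aln.lines) == pytest.approx(best_sum, rel=1e-12)

    def test_mirror_symmetry(self, params, rng):
        from rkalign import GeneratorConfig, generate_structure, mutate_homolog

        A = generate_structure(GeneratorConfig(seed=5, length=(30, 40)), sid="A")
        B = mutate_homolog(A, GeneratorConfig(seed=6, mutation_rate=0.3), sid="B")
        ab = align(A, B, params)
        ba = align(B, A, params)
        assert {(l.a_elem, l.b_elem) for l in ab.lines} == {
            (l.b_elem, l.a_elem) for l in ba.lines
        }


class TestExpectedAccuracy:
    def test_all_gap_alignment_scores_zero(self, h_type_toy):
        aln = PairwiseAlignment(
            h_type_toy, h_type_toy, [], elementize(h_type_toy), elementize(h_type_toy)
        )
        assert aln.expected_accuracy() == 0.0

    def test_hand_built_two_line_arithmetic(self):
        A = Structure("a", "ACGU")  # h = 4 elements
        B = Structure("b", "ACG")  # k = 3
        lines = [
            AlignmentLine(single(1), single(1), 0.5),
            AlignmentLine(single(2), single(2), 0.3),
        ]
        aln = PairwiseAlignment(A, B, lines, elementize(A), elementize(B))
        assert aln.expected_accuracy() == pytest.approx(0.2)

    def test_self_alignment_sums_diagonal_posteriors(self, params, h_type_toy):
        P = posterior_matrix(h_type_toy, h_type_toy, params)
        aln = greedy_align(P, h_type_toy, h_type_toy)
        diag = sum(P.get(i, i) for i in range(len(P.elements_a)))
        assert aln.expected_accuracy() == pytest.approx(diag / len(P.elements_a))


class TestColumnLayout:
    def test_merge_layout_places_gaps_leftmost(self):
        cols = merge_layout([(2, 1), (3, 3)], 3, 3)
        assert cols == [(1, None), (2, 1), (None, 2), (3, 3)]

    def test_length_difference_forces_gaps(self, params):
        A = Structure("a", "AAA")
        B = Structure("b", "AAAAA")
        aln = align(A, B, params)
        cols = aln.to_columns()
        gaps = sum(1 for col in cols.cells for cell in col if cell is None)
        assert gaps >= 2
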