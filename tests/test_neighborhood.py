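import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import qmotif as qm
from qmotif.errors import ParameterError
from conftest import oracle_ball


def brute_three_ball(c1, c2, c3, r1, r2, r3, alphabet=qm.DNA):
    """Exhaustive three-ball intersection over the whole l-mer space."""
    for cand in itertools.product(alphabet.symbols, repeat=len(c1)):
        if (
            sum(a != b for a, b in zip(cand, c1)) <= r1
            and sum(a != b for a, b in zip(cand, c2)) <= r2
            and sum(a != b for a, b in zip(cand, c3)) <= r3
        ):
            return True
    return False


class TestBallSize:
    @pytest.mark.parametrize(
        "l,d,sigma,expected",
        [(3, 0, 4, 1), (2, 2, 4, 16), (3, 1, 4, 10)],
    )
    def test_examples(self, l, d, sigma, expected):
        assert qm.ball_size(l, d, sigma) == expected

    def test_matches_brute_force(self, rng):
        for _ in range(10):
            l = int(rng.integers(1, 6))
            d = int(rng.integers(0, l + 1))
            x = "".join(rng.choice(list("ACGT"), l))
            assert qm.ball_size(l, d, 4) == len(oracle_ball(x, d))

    def test_range_errors(self):
        with pytest.raises(ParameterError):
            qm.ball_size(3, 4, 4)
        with pytest.raises(ParameterError):
            qm.ball_size(3, 1, 1)


class TestEnumerateBall:
    def test_d0_is_center(self):
        assert set(qm.enumerate_ball("AC", 0)) == {"AC"}

    def test_radius1_example(self):
        got = list(qm.enumerate_ball("AC", 1))
        assert len(got) == len(set(got)) == 7
        assert set(got) == oracle_ball("AC", 1)

    def test_full_space(self):
        assert set(qm.enumerate_ball("AAA", 3)) == oracle_ball("AAA", 3)

    @given(st.text(alphabet="ACGT", min_size=1, max_size=6), st.integers(0, 6))
    def test_matches_brute_force(self, x, d):
        d = min(d, len(x))
        got = list(qm.enumerate_ball(x, d))
        assert len(got) == len(set(got)) == qm.ball_size(len(x), d, 4)
        assert set(got) == oracle_ball(x, d)

    def test_protein_ball(self):
        got = list(qm.enumerate_ball("ACD", 1, qm.PROTEIN))
        assert len(got) == len(set(got)) == qm.ball_size(3, 1, 20)
        assert all(qm.hamming(t, "ACD") <= 1 for t in got)


class TestMutationTree:
    def collect(self, x, d, alphabet=qm.DNA):
        entered, left = [], []
        stats = qm.dfs_mutation_tree(
            x, d, alphabet, enter=entered.append, leave=left.append
        )
        return entered, left, stats

    def test_example_structure(self):
        # T_1("AA"): root + three mutants at p=1 + three at p=2
        entered, _, stats = self.collect("AA", 1)
        assert stats["nodes"] == 7
        assert entered[0] == qm.SearchNode("AA", 0, 0)
        by_p = {}
        for node in entered[1:]:
            by_p.setdefault(node.p, []).append(node.t)
        assert by_p == {1: ["CA", "GA", "TA"], 2: ["AC", "AG", "AT"]}

    def test_d0_single_node(self):
        _, _, stats = self.collect("ACGT", 0)
        assert stats["nodes"] == 1

    def test_depth_equals_distance_and_coverage(self, rng):
        for _ in range(8):
            l = int(rng.integers(1, 6))
            d = int(rng.integers(0, min(l, 3) + 1))
            x = "".join(rng.choice(list("ACGT"), l))
            entered, _, stats = self.collect(x, d)
            seen = [n.t for n in entered]
            assert len(seen) == len(set(seen)) == qm.ball_size(l, d, 4)
            assert set(seen) == oracle_ball(x, d)
            for node in entered:
                assert node.depth == qm.hamming(node.t, x)
                # t agrees with the pivot right of the last mutated position
                assert node.t[node.p :] == x[node.p :]

    def test_enter_leave_nesting(self):
        depth = 0
        max_depth = 0

        def enter(node):
            nonlocal depth, max_depth
            depth += 1
            max_depth = max(max_depth, depth)

        def leave(node):
            nonlocal depth
            depth -= 1
            assert depth >= 0

        qm.dfs_mutation_tree("ACG", 2, enter=enter, leave=leave)
        assert depth == 0 and max_depth == 3  # root + 2 tree levels

    def test_matches_kernel_ball_codes(self, rng):
        for _ in range(5):
            l = int(rng.integers(2, 7))
            d = int(rng.integers(0, min(l, 3) + 1))
            x = "".join(rng.choice(list("ACGT"), l))
            entered, _, _ = self.collect(x, d)
            codes, depths = qm.ball_codes(x, d)
            decoded = [qm.DNA.decode_int(int(c), l) for c in codes]
            assert decoded == [n.t for n in entered]
            assert list(depths) == [n.depth for n in entered]


class TestMinDescendantDistance:
    def test_identity(self):
        node = qm.SearchNode("ACGT", 2, 1)
        assert qm.min_descendant_distance(node, "ACGT", 2) == 0

    def test_root_reaches_into_ball(self):
        root = qm.SearchNode("AAAA", 0, 0)
        assert qm.min_descendant_distance(root, "TTTT", 2) == 2

    def test_leaf_is_exact_distance(self):
        leaf = qm.SearchNode("TTGG", 4, 2)  # depth == d: no moves left
        assert qm.min_descendant_distance(leaf, "ACGG", 2) == qm.hamming("TTGG", "ACGG")

    def test_equals_brute_force_over_descendants(self, rng):
        # enumerate small trees, collect each node's descendants, compare
        for _ in range(6):
            l = int(rng.integers(2, 6))
            d = int(rng.integers(1, min(l, 3) + 1))
            x = "".join(rng.choice(list("ACGT"), l))
            y = "".join(rng.choice(list("ACGT"), l))
            stack, per_node = [], {}
            order = []

            def enter(node):
                stack.append(node)
                order.append(node)
                for anc in stack:
                    per_node.setdefault(anc, []).append(node.t)

            def leave(node):
                stack.pop()

            qm.dfs_mutation_tree(x, d, enter=enter, leave=leave)
            for node in order:
                expected = min(qm.hamming(t, y) for t in per_node[node])
                assert qm.min_descendant_distance(node, y, d) == expected


class TestBallIntersections:
    def test_two_ball_examples(self):
        B = qm.BallSpec
        assert qm.two_ball_nonempty(B("AAA", 0), B("AAA", 0))
        assert not qm.two_ball_nonempty(B("AAA", 1), B("TTT", 1))
        assert qm.two_ball_nonempty(B("AAT", 0), B("ATT", 1))

    def test_three_ball_examples(self):
        B = qm.BallSpec
        assert qm.three_ball_nonempty(B("AA", 0), B("AA", 0), B("AA", 0))
        assert not qm.three_ball_nonempty(B("AA", 0), B("CC", 0), B("AA", 2))
        assert qm.three_ball_nonempty(B("AAAA", 2), B("TTTT", 2), B("AATT", 2))

    def test_length_mismatch(self):
        with pytest.raises(ParameterError):
            qm.three_ball_nonempty(
                qm.BallSpec("AA", 1), qm.BallSpec("AAA", 1), qm.BallSpec("AA", 1)
            )

    def test_reduces_to_two_ball_when_r3_full(self, rng):
        for _ in range(40):
            L = int(rng.integers(1, 6))
            mk = lambda: "".join(rng.choice(list("ACGT"), L))
            c1, c2, c3 = mk(), mk(), mk()
            r1, r2 = int(rng.integers(0, L + 1)), int(rng.integers(0, L + 1))
            b = qm.three_ball_nonempty(
                qm.BallSpec(c1, r1), qm.BallSpec(c2, r2), qm.BallSpec(c3, L)
            )
            assert b == qm.two_ball_nonempty(qm.BallSpec(c1, r1), qm.BallSpec(c2, r2))

    def test_matches_exhaustive_dna(self, rng):
        for _ in range(25):
            L = int(rng.integers(1, 5))
            mk = lambda: "".join(rng.choice(list("ACGT"), L))
            c1, c2, c3 = mk(), mk(), mk()
            for r1 in range(L + 1):
                for r2 in range(L + 1):
                    for r3 in range(L + 1):
                        got = qm.three_ball_nonempty(
                            qm.BallSpec(c1, r1), qm.BallSpec(c2, r2), qm.BallSpec(c3, r3)
                        )
                        assert got == brute_three_ball(c1, c2, c3, r1, r2, r3)

    def test_matches_exhaustive_protein(self, rng):
        # exhaustive over 20^L strings; exercises alphabet sizes > 4
        for _ in range(4):
            L = int(rng.integers(1, 4))
            mk = lambda: "".join(rng.choice(list(qm.PROTEIN.symbols), L))
            c1, c2, c3 = mk(), mk(), mk()
            for r1 in range(L + 1):
                for r2 in range(L + 1):
                    for r3 in range(L + 1):
                        got = qm.three_ball_nonempty(
                            qm.BallSpec(c1, r1), qm.BallSpec(c2, r2), qm.BallSpec(c3, r3)
                        )
                        assert got == brute_three_ball(
                            c1, c2, c3, r1, r2, r3, qm.PROTEIN
                        )

    def test_binary_alphabet_exact(self, rng):
        # sigma = 2: only the centers' own characters exist
        binary = qm.Alphabet("01")
        for _ in range(10):
            L = int(rng.integers(1, 5))
            mk = lambda: "".join(rng.choice(list("01"), L))
            c1, c2, c3 = mk(), mk(), mk()
            for r1 in range(L + 1):
                for r2 in range(L + 1):
                    for r3 in range(L + 1):
                        got = qm.three_ball_nonempty(
                            qm.BallSpec(c1, r1), qm.BallSpec(c2, r2), qm.BallSpec(c3, r3)
                        )
                        assert got == brute_three_ball(c1, c2, c3, r1, r2, r3, binary)
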