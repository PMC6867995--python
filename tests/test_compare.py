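import subprocess

import numpy as np
import pytest

from introscan.compare import (
    ClusterTree,
    DistanceMatrix,
    StructureTree,
    pairwise_matrix,
    tree_edit_distance,
    upgma,
)

from _oracles import random_dot_bracket, ted_oracle


class TestStructureTree:
    @pytest.mark.parametrize(
        "db", ["", ".....", "(...)", "((..))..((..))", "(((...)))..", "(.)"]
    )
    def test_round_trip(self, db):
        assert StructureTree.from_dot_bracket(db).to_dot_bracket() == db

    def test_unbalanced_rejected(self):
        with pytest.raises(ValueError):
            StructureTree.from_dot_bracket("(()")
        with pytest.raises(ValueError):
            StructureTree.from_dot_bracket("())")


class TestTreeEditDistance:
    def test_identity_is_zero(self):
        assert tree_edit_distance("((...))", "((...))") == 0

    def test_hairpin_vs_unpaired_oracle_value(self):
        expected = ted_oracle("(...)", ".....")
        assert tree_edit_distance("(...)", ".....") == expected
        # ancestry-preserving mappings cannot relabel P to a leaf and keep
        # its children, so the optimum is delete-P + insert two U's
        assert expected == 3

    def test_matches_oracle_on_random_pairs(self, rng):
        for _ in range(250):
            a = random_dot_bracket(rng, int(rng.integers(0, 13)))
            b = random_dot_bracket(rng, int(rng.integers(0, 13)))
            assert tree_edit_distance(a, b) == ted_oracle(a, b)

    def test_metric_axioms_on_random_triples(self, rng):
        for _ in range(400):
            a, b, c = (
                random_dot_bracket(rng, int(rng.integers(0, 15)))
                for _ in range(3)
            )
            dab = tree_edit_distance(a, b)
            dba = tree_edit_distance(b, a)
            dac = tree_edit_distance(a, c)
            dcb = tree_edit_distance(c, b)
            assert dab == dba
            assert dab == 0 or a != b or True
            assert dab <= dac + dcb  # triangle inequality

    def test_zero_iff_identical_tree(self, rng):
        for _ in range(100):
            a = random_dot_bracket(rng, int(rng.integers(0, 13)))
            b = random_dot_bracket(rng, int(rng.integers(0, 13)))
            if tree_edit_distance(a, b) == 0:
                assert a == b


class TestViennaCrossCheck:
    def test_vienna_scheme_matches_reference_program(self, rng):
        pairs = [
            ("(...)", "....."),
            ("((..((...))..))", "((...))"),
            (".(...).", "((...))"),
            ("(....)", "(...)."),
            (".", "(.)"),
        ]
        for _ in range(20):
            pairs.append(
                (
                    random_dot_bracket(rng, int(rng.integers(1, 25))),
                    random_dot_bracket(rng, int(rng.integers(1, 25))),
                )
            )
        stdin = "".join(f"{a}\n{b}\n" for a, b in pairs)
        out = subprocess.run(
            ["RNAdistance"], input=stdin, capture_output=True, text=True,
            check=True,
        ).stdout.split()
        ref = [float(tok) for tok in out if tok not in ("f:",)]
        ours = [tree_edit_distance(a, b, scheme="vienna") for a, b in pairs]
        assert ours == ref


class TestPairwiseMatrix:
    def test_identical_structures_zero_offdiagonal(self):
        m = pairwise_matrix([("a", "(...)"), ("b", "(...)"), ("c", "(...)")])
        assert np.all(m.values == 0)

    def test_symmetric_with_spot_checks(self, rng):
        structs = [
            (f"s{i}", random_dot_bracket(rng, 10)) for i in range(6)
        ]
        m = pairwise_matrix(structs)
        assert np.allclose(m.values, m.values.T)
        assert np.all(np.diag(m.values) == 0)
        for _ in range(5):
            i, j = rng.integers(0, 6, 2)
            assert m.values[i, j] == tree_edit_distance(
                structs[i][1], structs[j][1]
            )

    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValueError):
            pairwise_matrix([("a", "."), ("a", "..")])


class TestUPGMA:
    def test_two_leaves_forced_cherry(self):
        m = DistanceMatrix(("A", "B"), np.array([[0.0, 4.0], [4.0, 0.0]]))
        t = upgma(m)
        assert t.height == 2.0
        assert sorted(t.leaf_labels()) == ["A", "B"]
        assert t.is_ultrametric()

    def test_hand_computed_four_leaf_tree(self):
        labels = ("A", "B", "C", "D")
        v = np.array(
            [
                [0, 2, 4, 6],
                [2, 0, 4, 6],
                [4, 4, 0, 6],
                [6, 6, 6, 0],
            ],
            dtype=float,
        )
        t = upgma(DistanceMatrix(labels, v))
        # topology (((A,B),C),D) with heights 1, 2, 3
        assert t.height == 3.0
        inner = [c for c in t.children if c.children]
        assert len(inner) == 1 and inner[0].height == 2.0
        inner2 = [c for c in inner[0].children if c.children]
        assert len(inner2) == 1 and inner2[0].height == 1.0
        assert sorted(inner2[0].leaf_labels()) == ["A", "B"]
        depths = t.leaf_depths()
        assert all(abs(d - 3.0) < 1e-12 for d in depths.values())

    def test_ultrametric_input_reconstructed_exactly(self, rng):
        """Cophenetic distances of a random ultrametric tree are recovered."""
        for _ in range(20):
            n = int(rng.integers(3, 9))
            labels = [f"L{i}" for i in range(n)]
            # build a random ultrametric tree by random sequential merging
            nodes = [(ClusterTree(0.0, (), lab), [lab]) for lab in labels]
            h = 0.0
            while len(nodes) > 1:
                h += float(rng.uniform(0.5, 2.0))
                i, j = sorted(rng.choice(len(nodes), 2, replace=False))
                (ta, la), (tb, lb) = nodes[i], nodes[j]
                merged = (ClusterTree(h, (ta, tb)), la + lb)
                nodes = [x for k, x in enumerate(nodes) if k not in (i, j)]
                nodes.append(merged)
            tree = nodes[0][0]
            # cophenetic matrix
            v = np.zeros((n, n))

            def fill(node):
                if not node.children:
                    return [node.label]
                sides = [fill(c) for c in node.children]
                for a in sides[0]:
                    for b in sides[1]:
                        ia, ib = labels.index(a), labels.index(b)
                        v[ia, ib] = v[ib, ia] = 2 * node.height
                return sides[0] + sides[1]

            fill(tree)
            rebuilt = upgma(DistanceMatrix(tuple(labels), v))
            w = np.zeros((n, n))

            def fill2(node, mat):
                if not node.children:
                    return [node.label]
                sides = [fill2(c, mat) for c in node.children]
                for a in sides[0]:
                    for b in sides[1]:
                        ia, ib = labels.index(a), labels.index(b)
                        mat[ia, ib] = mat[ib, ia] = 2 * node.height
                return sides[0] + sides[1]

            fill2(rebuilt, w)
            assert np.allclose(v, w)

    def test_ultrametric_for_any_valid_matrix(self, rng):
        for _ in range(20):
            n = int(rng.integers(3, 8))
            a = rng.uniform(1, 10, size=(n, n))
            v = (a + a.T) / 2
            np.fill_diagonal(v, 0.0)
            t = upgma(DistanceMatrix(tuple(f"x{i}" for i in range(n)), v))
            assert t.is_ultrametric(tol=1e-9)
            assert sorted(t.leaf_labels()) == sorted(f"x{i}" for i in range(n))

    def test_matches_scipy_average_linkage_heights(self, rng):
        from scipy.cluster.hierarchy import average
        from scipy.spatial.distance import squareform

        for _ in range(10):
            n = int(rng.integers(4, 9))
            a = rng.uniform(1, 10, size=(n, n))
            v = (a + a.T) / 2
            np.fill_diagonal(v, 0.0)
            t = upgma(DistanceMatrix(tuple(f"x{i}" for i in range(n)), v))
            Z = average(squareform(v))
            ours = []

            def heights(node):
                if node.children:
                    ours.append(round(2 * node.height, 9))
                    for c in node.children:
                        heights(c)

            heights(t)
            assert sorted(ours) == sorted(round(h, 9) for h in Z[:, 2])

    def test_invalid_matrix_rejected(self):
        v = np.array([[0.0, np.nan], [np.nan, 0.0]])
        with pytest.raises(ValueError):
            upgma(DistanceMatrix(("a", "b"), v))

    def test_newick_output_parses(self):
        m = DistanceMatrix(
            ("A", "B", "C"),
            np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], dtype=float),
        )
        nwk = upgma(m).to_newick()
        import dendropy

        tree = dendropy.Tree.get(data=nwk, schema="newick")
        assert {leaf.taxon.label for leaf in tree.leaf_node_iter()} == {
            "A", "B", "C",
        }
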