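"""Newick I/O, FAD/LAD time-scaling, zero-branch resolution, and the
Brownian covariance matrix."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import ppmbite as pb
from ppmbite.tree import StratRange


class TestParse:
    def test_two_tip_tree(self):
        t = pb.parse_newick("(A:1,B:1);")
        assert sorted(t.tip_labels) == ["A", "B"]
        assert t.tip_depths() == {"A": 1.0, "B": 1.0}

    def test_three_tip_depths(self, three_tip_tree):
        assert three_tip_tree.n_tips == 3
        assert all(d == pytest.approx(2.0) for d in three_tip_tree.tip_depths().values())

    @pytest.mark.parametrize("bad", ["(A:1,B:1", "(A:1,B:1));", "not a tree"])
    def test_malformed_newick_raises(self, bad):
        with pytest.raises(pb.TreeError, match="malformed"):
            pb.parse_newick(bad)

    def test_duplicate_tips_rejected(self):
        with pytest.raises(pb.TreeError, match="duplicate"):
            pb.parse_newick("(A:1,A:1);")

    def test_missing_branch_length_rejected(self):
        with pytest.raises(pb.TreeError, match="branch length"):
            pb.parse_newick("(A:1,B);")

    def test_spaces_and_underscores_equivalent(self):
        t = pb.parse_newick("('Tyrannosaurus rex':1,Tarbosaurus_bataar:1);")
        assert sorted(t.tip_labels) == ["Tarbosaurus_bataar", "Tyrannosaurus_rex"]

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), n=st.integers(3, 40))
    def test_newick_roundtrip(self, seed, n):
        tree = pb.simulate_tree(pb.SimSpec(n_tips=n, tree_style="fossil", seed=seed))
        back = pb.parse_newick(pb.write_newick(tree))
        d1, d2 = tree.tip_depths(), back.tip_depths()
        assert set(d1) == set(d2)
        for k in d1:  # 9 significant digits in the writer -> relative check
            assert d1[k] == pytest.approx(d2[k], rel=1e-7)


class TestTimescale:
    def test_fossil_terminal_branch_spans_full_range(self):
        # tip diverging at 110 Ma, FAD 100, LAD 90 -> terminal branch 20 Myr
        t = pb.parse_newick("((F:10,G:110):40,H:150);")  # root age 150, F at FAD 100
        out = pb.timescale_fad_lad(t, [StratRange("F", 100, 90)])
        tips = {l.taxon.label: l.edge.length for l in out._tree.leaf_node_iter()}
        assert tips["F"] == pytest.approx(20.0)  # 110 - 90
        assert out.tip_depths()["F"] == pytest.approx(150 - 90)  # ends at LAD 90 Ma

    def test_extant_tip_extends_to_present(self):
        t = pb.parse_newick("((E:10,F:10):90,G:100);")
        out = pb.timescale_fad_lad(t, [])
        assert out.tip_depths() == pytest.approx({"E": 100.0, "F": 100.0, "G": 100.0})

    def test_sister_fossils_non_ultrametric(self):
        # sisters diverging at 150 Ma, LADs 140 and 120 -> branches 10 and 30
        t = pb.parse_newick("((F:10,G:10):100,H:250);")
        out = pb.timescale_fad_lad(t, [StratRange("F", 140, 140), StratRange("G", 140, 120)])
        tips = {
            leaf.taxon.label: leaf.edge.length
            for leaf in out._tree.leaf_node_iter()
        }
        assert tips["F"] == pytest.approx(10.0)
        assert tips["G"] == pytest.approx(30.0)
        assert not out.is_ultrametric()

    def test_missing_taxa_listed(self):
        t = pb.parse_newick("((F:10,G:10):100,H:250);")
        with pytest.raises(pb.TreeError, match="G"):
            pb.timescale_fad_lad(t, [StratRange("F", 140, 120)], extant=["H"])

    def test_lad_older_than_divergence_rejected(self):
        # explicit root calibration at 150 Ma puts the divergence at 50 Ma,
        # older than G's claimed LAD of 80 Ma
        t = pb.parse_newick("((F:10,G:10):100,H:150);")
        with pytest.raises(pb.TreeError, match="older than"):
            pb.timescale_fad_lad(
                t,
                [StratRange("F", 45, 40), StratRange("G", 90, 80)],
                root_age=150.0,
            )

    def test_fossil_diagonal_is_root_age_minus_lad(self):
        t = pb.parse_newick("((F:10,G:10):100,H:250);")
        out = pb.timescale_fad_lad(t, [StratRange("F", 140, 120), StratRange("G", 140, 100)])
        v = pb.phylo_vcv(out, ["F", "G", "H"])
        root_age = out.root_age
        assert v.matrix[0, 0] == pytest.approx(root_age - 120)
        assert v.matrix[1, 1] == pytest.approx(root_age - 100)


class TestZeroBranchResolution:
    def test_single_zero_branch_shares_donor_time(self):
        # root -2- n1 -0- n2 -2- tip  ->  1, 1, 2
        t = pb.parse_newick("(((X:2):0):2,Y:4);")
        out = pb.resolve_zero_branches_equal(t)
        lengths = _path_lengths_to(out, "X")
        assert lengths == pytest.approx([2.0, 1.0, 1.0])
        assert out.tip_depths()["X"] == pytest.approx(4.0)

    def test_run_of_two_zeros_split_three_ways(self):
        # root -3- n1 -0- n2 -0- n3 -3- tip -> 1, 1, 1, depth 6
        t = pb.parse_newick("((((X:3):0):0):3,Y:6);")
        out = pb.resolve_zero_branches_equal(t)
        assert _path_lengths_to(out, "X") == pytest.approx([3.0, 1.0, 1.0, 1.0])
        assert out.tip_depths()["X"] == pytest.approx(6.0)

    def test_tree_without_zero_branches_unchanged(self, three_tip_tree):
        out = pb.resolve_zero_branches_equal(three_tip_tree)
        assert pb.write_newick(out) == pb.write_newick(three_tip_tree)

    def test_zero_branch_at_root_rejected(self):
        t = pb.parse_newick("((A:1,B:1):0,C:1);")
        with pytest.raises(pb.TreeError, match="cannot allocate"):
            pb.resolve_zero_branches_equal(t)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_depths_preserved_and_zeros_removed(self, seed):
        tree = pb.simulate_tree(pb.SimSpec(n_tips=25, seed=seed))
        # plant zeros on some internal branches
        rng = np.random.default_rng(seed)
        internals = [
            n for n in tree._tree.preorder_node_iter()
            if n is not tree._tree.seed_node and not n.is_leaf()
        ]
        planted = 0
        before = tree.tip_depths()
        for node in internals:
            if rng.uniform() < 0.3 and node.parent_node is not tree._tree.seed_node:
                # push the node up to its parent, donating its length downward
                for child in node.child_nodes():
                    child.edge.length += node.edge.length
                node.edge.length = 0.0
                planted += 1
        tree = pb.TimeTree(tree._tree)
        assert tree.tip_depths() == pytest.approx(before, abs=1e-9)
        out = pb.resolve_zero_branches_equal(tree)
        after = out.tip_depths()
        for k, v in before.items():
            assert after[k] == pytest.approx(v, abs=1e-9)
        for node in out._tree.preorder_node_iter():
            if node is out._tree.seed_node or node.is_leaf():
                continue
            assert node.edge.length > 0


class TestPhyloCovariance:
    def test_independent_tips(self):
        v = pb.phylo_vcv(pb.parse_newick("(A:1,B:1);"))
        assert np.allclose(v.matrix, np.eye(2))

    def test_shared_path(self, three_tip_tree):
        v = pb.phylo_vcv(three_tip_tree, ["A", "B", "C"])
        expected = np.array([[2, 1, 0], [1, 2, 0], [0, 0, 2]], dtype=float)
        assert np.allclose(v.matrix, expected)

    def test_subset_and_order(self, three_tip_tree):
        v = pb.phylo_vcv(three_tip_tree, ["C", "A"])
        assert v.taxa == ("C", "A")
        assert np.allclose(v.matrix, np.array([[2, 0], [0, 2]], dtype=float))

    def test_unknown_taxon_named(self, three_tip_tree):
        with pytest.raises(pb.TreeError, match="Z"):
            pb.phylo_vcv(three_tip_tree, ["A", "Z"])

    def test_polytomy_supported(self):
        v = pb.phylo_vcv(pb.parse_newick("((A:1,B:1,C:1):1,D:2);"))
        m = v.matrix
        assert m[0, 1] == m[0, 2] == m[1, 2] == pytest.approx(1.0)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), n=st.integers(3, 30))
    def test_symmetric_positive_semidefinite(self, seed, n):
        tree = pb.simulate_tree(pb.SimSpec(n_tips=n, tree_style="fossil", seed=seed))
        m = pb.phylo_vcv(tree).matrix
        assert np.allclose(m, m.T)
        assert np.all(np.diag(m)[:, None] >= m - 1e-9)
        assert np.linalg.eigvalsh(m).min() >= -1e-9 * m.max()


def _path_lengths_to(tree, label):
    """Branch lengths from the named tip back to the root."""
    leaf = next(
        l for l in tree._tree.leaf_node_iter() if l.taxon.label == label
    )
    out = []
    node = leaf
    while node is not tree._tree.seed_node:
        out.append(node.edge.length)
        node = node.parent_node
    return out
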