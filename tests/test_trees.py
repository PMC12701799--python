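"""Tree parsing, bipartitions, and topological distance metrics."""

import numpy as np
import pytest

from treebench import random_tree
from treebench.trees import (
    NewickError,
    TreeError,
    bipartitions,
    mean_pairwise_rf,
    ntd_distance,
    parse_newick,
    quartet_distance,
    rf_distance,
    unique_topology_count,
    write_newick,
)

from conftest import quartet_distance_oracle, splits_by_edge_removal


class TestParseNewick:
    def test_four_leaf_tree_structure(self):
        t = parse_newick("((A:1,B:1):1,C:1,D:1);")
        assert t.n_leaves() == 4
        assert len(t.edges()) == 5  # 2n - 3

    def test_degree_two_root_suppressed(self):
        t = parse_newick("((A,B),(C,D));")
        assert bipartitions(t) == frozenset({frozenset({"C", "D"})})
        # the suppressed root leaves 2n-3 edges
        assert len(t.edges()) == 5

    def test_root_suppression_sums_branch_lengths(self):
        t = parse_newick("((A:1,B:1):0.25,(C:1,D:1):0.5);")
        internal = t.internal_edges()
        assert len(internal) == 1
        assert internal[0][2] == pytest.approx(0.75)

    @pytest.mark.parametrize(
        "bad",
        [
            "((A,B),(A,C));",  # duplicate label
            "(A,B);",  # < 3 leaves
            "((A,B),C;",  # unbalanced
            "((A,B),C)",  # missing semicolon
            "((A:x,B),C);",  # bad length token
        ],
    )
    def test_malformed_input_rejected(self, bad):
        with pytest.raises(NewickError):
            parse_newick(bad)

    def test_support_values_ignored(self):
        t = parse_newick("((A:1,B:1)95:0.5,C:1,D:1);")
        assert bipartitions(t) == frozenset({frozenset({"C", "D"})})

    def test_missing_lengths_default_zero(self):
        t = parse_newick("((A,B),C,D);")
        assert all(ln == 0.0 for _, _, ln in t.edges())


class TestWriteNewick:
    @pytest.mark.parametrize("seed", range(5))
    def test_round_trip_preserves_splits_and_lengths(self, seed):
        t = random_tree(9, bl_mean=0.3, seed=seed)
        back = parse_newick(write_newick(t))
        assert bipartitions(back) == bipartitions(t)
        _, d1 = _sorted_leaf_dists(t)
        _, d2 = _sorted_leaf_dists(back)
        np.testing.assert_allclose(d1, d2, atol=1e-12)

    def test_precision_at_least_nine_significant_digits(self):
        t = parse_newick("((A:0.123456789,B:1):1,C:1,D:1);")
        assert "0.123456789" in write_newick(t)

    def test_multifurcation_preserved(self):
        t = parse_newick("(A,B,C,D,(E,F));")
        out = parse_newick(write_newick(t))
        assert bipartitions(out) == bipartitions(t)
        degrees = sorted(len(nbs) for n, nbs in out.adj.items() if n not in out.labels)
        assert degrees[-1] == 5  # the degree-5 hub survives


def _sorted_leaf_dists(tree):
    from conftest import path_distances

    labels, d = path_distances(tree)
    order = np.argsort(labels)
    return [labels[i] for i in order], d[np.ix_(order, order)]


class TestBipartitions:
    def test_hand_enumerated_splits(self):
        t = parse_newick("((A,B),C,(D,(E,F)));")
        assert bipartitions(t) == {
            frozenset({"E", "F"}),
            frozenset({"D", "E", "F"}),
            frozenset({"C", "D", "E", "F"}),
        }

    def test_star_tree_has_no_splits(self):
        assert bipartitions(parse_newick("(A,B,C,D);")) == frozenset()

    def test_binary_tree_split_count(self):
        for seed in range(5):
            t = random_tree(10, seed=seed)
            assert len(bipartitions(t)) == 10 - 3

    @pytest.mark.parametrize("seed", range(10))
    def test_agrees_with_edge_removal_oracle(self, seed):
        t = random_tree(8, seed=seed)
        assert set(bipartitions(t)) == splits_by_edge_removal(t)


class TestRFDistance:
    def test_maximally_different_four_leaf(self):
        t1 = parse_newick("((A,B),(C,D));")
        t2 = parse_newick("((A,C),(B,D));")
        assert rf_distance(t1, t2) == (2, 1.0)

    def test_identity_is_zero(self):
        t = random_tree(12, seed=0)
        assert rf_distance(t, t) == (0, 0.0)

    def test_hand_derived_six_leaf_case(self):
        t1 = parse_newick("((A,B),C,(D,(E,F)));")
        t2 = parse_newick("((A,C),B,(D,(E,F)));")
        assert rf_distance(t1, t2) == (2, pytest.approx(1 / 3))

    def test_mismatched_leaf_sets_rejected(self):
        t1 = parse_newick("((A,B),(C,D));")
        t2 = parse_newick("((A,B),(C,E));")
        with pytest.raises(TreeError, match="E"):
            rf_distance(t1, t2)

    @pytest.mark.parametrize("seed", range(8))
    def test_symmetric_and_bounded(self, seed):
        rng = np.random.default_rng(seed)
        t1 = random_tree(9, seed=rng.integers(2**31))
        t2 = random_tree(9, seed=rng.integers(2**31))
        r12 = rf_distance(t1, t2)
        r21 = rf_distance(t2, t1)
        assert r12 == r21
        assert 0.0 <= r12[1] <= 1.0


class TestNTD:
    def test_identical_binary_trees(self):
        t = random_tree(8, seed=1)
        assert ntd_distance(t, t.copy()) == 0.0

    def test_four_leaf_maximal(self):
        t1 = parse_newick("((A,B),(C,D));")
        t2 = parse_newick("((A,C),(B,D));")
        assert ntd_distance(t1, t2) == 1.0

    def test_binary_vs_star_tree(self):
        binary = parse_newick("((A,B),(C,(D,E)));")
        star = parse_newick("(A,B,C,D,E);")
        assert ntd_distance(binary, star) == 1.0

    def test_two_star_trees_defined_as_zero(self):
        s1 = parse_newick("(A,B,C,D);")
        s2 = parse_newick("(A,B,C,D);")
        assert ntd_distance(s1, s2) == 0.0

    def test_equals_normalized_rf_for_binary_trees(self):
        for seed in range(5):
            t1 = random_tree(9, seed=seed)
            t2 = random_tree(9, seed=seed + 100)
            assert ntd_distance(t1, t2) == pytest.approx(rf_distance(t1, t2)[1])


class TestQuartetDistance:
    def test_single_quartet_resolved_differently(self):
        t1 = parse_newick("((A,B),(C,D));")
        t2 = parse_newick("((A,C),(B,D));")
        assert quartet_distance(t1, t2) == 1.0

    def test_hand_enumerated_five_leaf_case(self):
        t1 = parse_newick("((A,B),C,(D,E));")
        t2 = parse_newick("((A,C),B,(D,E));")
        assert quartet_distance(t1, t2) == pytest.approx(0.4)

    def test_identity(self):
        t = random_tree(7, seed=3)
        assert quartet_distance(t, t.copy()) == 0.0

    @pytest.mark.parametrize("seed", range(6))
    def test_agrees_with_path_length_oracle(self, seed):
        n = int(np.random.default_rng(seed).integers(5, 13))
        t1 = random_tree(n, seed=seed * 2 + 1)
        t2 = random_tree(n, seed=seed * 2 + 2)
        assert quartet_distance(t1, t2) == pytest.approx(
            quartet_distance_oracle(t1, t2)
        )

    def test_unresolved_quartet_counts_as_differing(self):
        star = parse_newick("(A,B,C,D);")
        binary = parse_newick("((A,B),(C,D));")
        assert quartet_distance(star, binary) == 1.0
        assert quartet_distance(star, star) == 0.0

    def test_cap_guard(self):
        t1 = random_tree(12, seed=0)
        t2 = random_tree(12, seed=1)
        with pytest.raises(TreeError, match="cap"):
            quartet_distance(t1, t2, max_leaves=10)


class TestTopologySets:
    def test_unique_topology_count_ignores_lengths(self):
        base = random_tree(7, seed=5)
        variants = []
        for i in range(4):
            c = base.copy()
            for u, v, ln in c.edges():
                c.adj[u][v] = c.adj[v][u] = ln * (i + 1)
            variants.append(c)
        assert unique_topology_count(variants) == 1

    def test_unique_topology_count_mixed(self):
        a = parse_newick("((A,B),(C,D));")
        b = parse_newick("((A,C),(B,D));")
        assert unique_topology_count([a, b, a.copy()]) == 2
        assert unique_topology_count([]) == 0

    def test_mean_pairwise_rf_cases(self):
        a = parse_newick("((A,B),(C,D));")
        b = parse_newick("((A,C),(B,D));")
        assert mean_pairwise_rf([a] * 5) == 0.0
        assert mean_pairwise_rf([a, b]) == 1.0
        assert mean_pairwise_rf([a, a.copy(), b]) == pytest.approx(2 / 3)
        assert mean_pairwise_rf([a]) == 0.0
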