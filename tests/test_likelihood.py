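"""Likelihood engine: pruning correctness, closed forms, optimization."""

import numpy as np
import pytest

from treebench import (
    GTRGammaModel,
    evaluate_tree,
    optimize_branch_lengths,
    random_tree,
    simulate_gapless,
    site_log_likelihoods,
    tree_log_likelihood,
)
from treebench.likelihood import SiteLnLMatrix
from treebench.msa import MSA
from treebench.trees import Tree, parse_newick

from conftest import exhaustive_log_likelihood


def two_taxon_tree(t: float) -> Tree:
    tr = Tree()
    a = tr.add_node("X")
    b = tr.add_node("Y")
    tr.add_edge(a, b, t)
    return tr


class TestClosedForms:
    def test_identical_bases_zero_branch(self, jc1):
        tr = two_taxon_tree(0.0)
        msa = MSA.from_sequences(["X", "Y"], ["A", "A"])
        assert tree_log_likelihood(tr, msa, jc1) == pytest.approx(np.log(0.25))

    def test_all_gap_column_contributes_zero(self, jc1):
        tr = two_taxon_tree(0.3)
        msa = MSA.from_sequences(["X", "Y"], ["A-", "A-"])
        v = site_log_likelihoods(tr, msa, jc1)
        assert v[1] == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("t", [0.1, 1.0])
    def test_jc_mismatch_column(self, jc1, t):
        tr = two_taxon_tree(t)
        msa = MSA.from_sequences(["X", "Y"], ["A", "C"])
        p_diff = 0.25 - 0.25 * np.exp(-4 * t / 3)
        assert tree_log_likelihood(tr, msa, jc1) == pytest.approx(
            np.log(0.25 * p_diff)
        )

    @pytest.mark.parametrize("t", [0.1, 1.0])
    def test_jc_match_column(self, jc1, t):
        tr = two_taxon_tree(t)
        msa = MSA.from_sequences(["X", "Y"], ["G", "G"])
        p_same = 0.25 + 0.75 * np.exp(-4 * t / 3)
        assert tree_log_likelihood(tr, msa, jc1) == pytest.approx(
            np.log(0.25 * p_same)
        )


class TestPruningVsExhaustiveOracle:
    @pytest.mark.parametrize("seed", range(6))
    def test_random_small_instances(self, seed, gtr_model):
        rng = np.random.default_rng(seed)
        n_taxa = int(rng.integers(3, 6))
        n_sites = int(rng.integers(1, 5))
        tree = random_tree(n_taxa, bl_mean=0.3, seed=seed)
        msa = simulate_gapless(tree, gtr_model, n_sites, seed=seed + 50)
        got = tree_log_likelihood(tree, msa, gtr_model)
        want = exhaustive_log_likelihood(tree, msa, gtr_model)
        assert got == pytest.approx(want, abs=1e-8)

    def test_with_gaps_and_ambiguity(self, jc1):
        tree = parse_newick("((A:0.2,B:0.3):0.1,C:0.4,D:0.15);")
        msa = MSA.from_sequences(["A", "B", "C", "D"], ["ARG", "A-G", "ANG", "ACG"])
        got = tree_log_likelihood(tree, msa, jc1)
        want = exhaustive_log_likelihood(tree, msa, jc1)
        assert got == pytest.approx(want, abs=1e-8)

    def test_star_tree_four_taxa(self, gtr_model):
        tree = parse_newick("(A:0.1,B:0.2,C:0.3,D:0.4);")
        msa = MSA.from_sequences(["A", "B", "C", "D"], ["ACG", "ACG", "ATG", "GCA"])
        assert tree_log_likelihood(tree, msa, gtr_model) == pytest.approx(
            exhaustive_log_likelihood(tree, msa, gtr_model), abs=1e-8
        )

    def test_invariant_sites_mixture(self):
        model = GTRGammaModel.jc(alpha=0.8, k=3, p_inv=0.3)
        tree = random_tree(4, 0.2, seed=3)
        msa = simulate_gapless(tree, model, 3, seed=4)
        assert tree_log_likelihood(tree, msa, model) == pytest.approx(
            _exhaustive_with_pinv(tree, msa, model), abs=1e-8
        )


def _exhaustive_with_pinv(tree, msa, model):
    from dataclasses import replace

    from treebench.msa import IUPAC_SETS

    gamma_part = exhaustive_log_likelihood(tree, msa, replace(model, p_inv=0.0))
    # recompute per site to mix components
    total = 0.0
    for s in range(msa.n_sites):
        one = MSA(list(msa.taxa), msa.data[:, s : s + 1])
        lg = np.exp(exhaustive_log_likelihood(tree, one, replace(model, p_inv=0.0)))
        compat = set("ACGT")
        for row in one.data[:, 0]:
            compat &= IUPAC_SETS[row]
        pi = dict(zip("ACGT", model.pi_array()))
        inv = sum(pi[b] for b in compat)
        total += np.log((1 - model.p_inv) * lg + model.p_inv * inv)
    return total


class TestStructuralInvariants:
    def test_sum_of_site_vector_equals_total(self, gtr_model):
        tree = random_tree(7, seed=5)
        msa = simulate_gapless(tree, gtr_model, 200, seed=6)
        v = site_log_likelihoods(tree, msa, gtr_model)
        assert v.sum() == pytest.approx(tree_log_likelihood(tree, msa, gtr_model), abs=1e-10)

    def test_duplicating_columns_doubles_lnl(self, gtr_model):
        tree = random_tree(5, seed=7)
        msa = simulate_gapless(tree, gtr_model, 60, seed=8)
        doubled = MSA(list(msa.taxa), np.hstack([msa.data, msa.data]))
        assert tree_log_likelihood(tree, doubled, gtr_model) == pytest.approx(
            2 * tree_log_likelihood(tree, msa, gtr_model), abs=1e-8
        )

    def test_pattern_compression_changes_nothing(self, gtr_model):
        tree = random_tree(6, seed=9)
        msa = simulate_gapless(tree, gtr_model, 150, seed=10)
        a = site_log_likelihoods(tree, msa, gtr_model, compress=True)
        b = site_log_likelihoods(tree, msa, gtr_model, compress=False)
        np.testing.assert_allclose(a, b, atol=1e-8)

    def test_leaf_order_permutation_invariance(self, gtr_model):
        tree = random_tree(6, seed=11)
        msa = simulate_gapless(tree, gtr_model, 80, seed=12)
        perm = msa.row_order(list(reversed(msa.taxa)))
        assert tree_log_likelihood(tree, perm, gtr_model) == pytest.approx(
            tree_log_likelihood(tree, msa, gtr_model), abs=1e-9
        )

    def test_taxa_mismatch_rejected(self, jc1):
        tree = random_tree(4, seed=13)
        msa = MSA.from_sequences(["x", "y", "z", "w"], ["A", "C", "G", "T"])
        with pytest.raises(ValueError, match="mismatch"):
            tree_log_likelihood(tree, msa, jc1)


class TestBranchLengthOptimization:
    def test_jc_pairwise_distance_recovered(self, jc1):
        # 10% observed differences over 1000 sites
        tr = two_taxon_tree(0.5)
        msa = MSA.from_sequences(["X", "Y"], ["A" * 900 + "C" * 100,
                                              "A" * 900 + "G" * 100])
        opt, _ = optimize_branch_lengths(tr, msa, jc1, tol=1e-8)
        t_hat = next(iter(opt.adj[0].values()))
        expected = -0.75 * np.log(1 - 4 / 3 * 0.1)
        assert t_hat == pytest.approx(expected, abs=1e-4)

    def test_never_decreases_lnl(self, gtr_model):
        tree = random_tree(8, seed=14)
        msa = simulate_gapless(tree, gtr_model, 300, seed=15)
        before = tree_log_likelihood(tree, msa, gtr_model)
        _, after = optimize_branch_lengths(tree, msa, gtr_model)
        assert after >= before - 1e-9

    def test_fixed_point_when_already_optimal(self, gtr_model):
        tree = random_tree(6, seed=16)
        msa = simulate_gapless(tree, gtr_model, 200, seed=17)
        opt1, lnl1 = optimize_branch_lengths(tree, msa, gtr_model, tol=1e-6)
        _, lnl2 = optimize_branch_lengths(opt1, msa, gtr_model, tol=1e-3)
        assert lnl2 - lnl1 < 1e-3

    def test_input_tree_not_modified(self, jc1):
        tree = random_tree(5, seed=18)
        before = [ln for _, _, ln in tree.edges()]
        msa = simulate_gapless(tree, jc1, 100, seed=19)
        optimize_branch_lengths(tree, msa, jc1)
        assert [ln for _, _, ln in tree.edges()] == before


class TestEvaluateTree:
    def test_no_flags_is_plain_likelihood(self, gtr_model):
        tree = random_tree(5, seed=20)
        msa = simulate_gapless(tree, gtr_model, 120, seed=21)
        lnl, _, _ = evaluate_tree(tree, msa, gtr_model, optimize=frozenset())
        assert lnl == pytest.approx(tree_log_likelihood(tree, msa, gtr_model))

    def test_brlens_only_matches_direct_optimizer(self, gtr_model):
        tree = random_tree(5, seed=22)
        msa = simulate_gapless(tree, gtr_model, 150, seed=23)
        lnl_eval, _, _ = evaluate_tree(tree, msa, gtr_model, optimize={"brlens"})
        _, lnl_direct = optimize_branch_lengths(tree, msa, gtr_model)
        assert lnl_eval == pytest.approx(lnl_direct, abs=0.05)

    def test_unknown_flag_rejected(self, jc1):
        tree = random_tree(4, seed=24)
        msa = simulate_gapless(tree, jc1, 50, seed=25)
        with pytest.raises(ValueError, match="flags"):
            evaluate_tree(tree, msa, jc1, optimize={"topology"})

    def test_alpha_recovery_on_simulated_data(self):
        # data simulated at alpha = 0.5; estimates should land near it
        truth = GTRGammaModel.jc(alpha=0.5, k=4)
        hits = 0
        for seed in range(5):
            tree = random_tree(6, 0.2, seed=100 + seed)
            msa = simulate_gapless(tree, truth, 5000, seed=200 + seed)
            _, _, fitted = evaluate_tree(
                tree, msa, GTRGammaModel.jc(alpha=1.0, k=4),
                optimize={"brlens", "alpha"}, max_outer=3,
            )
            hits += 0.35 <= fitted.alpha <= 0.7
        assert hits >= 4


class TestSiteLnLMatrix:
    def test_tsv_round_trip(self, tmp_path):
        rng = np.random.default_rng(26)
        m = SiteLnLMatrix(["a", "b"], rng.normal(-2, 1, size=(2, 30)))
        p = tmp_path / "sitelnl.tsv"
        m.to_tsv(p)
        back = SiteLnLMatrix.from_tsv(p)
        assert back.tree_ids == m.tree_ids
        np.testing.assert_allclose(back.matrix, m.matrix, rtol=1e-9)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            SiteLnLMatrix(["a"], np.array([[0.0, np.inf]]))
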