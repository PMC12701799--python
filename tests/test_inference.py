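"""Built-in inferrers: JC distances, BIONJ, Fitch parsimony, NNI-ML search."""

import numpy as np
import pytest

from treebench import (
    GTRGammaModel,
    bionj,
    evaluate_tree,
    fitch_score,
    jc_distance_matrix,
    nni_ml_search,
    parsimony_tree,
    random_tree,
    simulate_gapless,
)
from treebench.inference import DistanceMatrix, run_external_tool
from treebench.msa import MSA
from treebench.trees import parse_newick, rf_distance, write_newick

from conftest import enumerate_topologies, fitch_brute_force, path_distances


def additive_matrix(tree) -> DistanceMatrix:
    labels, d = path_distances(tree)
    return DistanceMatrix(labels, d)


class TestJCDistances:
    def test_identical_sequences_zero(self):
        m = MSA.from_sequences(["a", "b"], ["ACGT" * 10, "ACGT" * 10])
        assert jc_distance_matrix(m).d[0, 1] == 0.0

    def test_ten_percent_mismatch_closed_form(self):
        m = MSA.from_sequences(["a", "b"], ["A" * 90 + "C" * 10, "A" * 90 + "G" * 10])
        expected = -0.75 * np.log(1 - 4 / 3 * 0.1)
        assert jc_distance_matrix(m).d[0, 1] == pytest.approx(expected)

    def test_saturated_pair_clamped(self):
        m = MSA.from_sequences(["a", "b"], ["A" * 100, "C" * 75 + "A" * 25])
        assert jc_distance_matrix(m).d[0, 1] == 10.0

    def test_gap_sites_excluded_pairwise(self):
        m = MSA.from_sequences(["a", "b"], ["AC-T", "ACGT"])
        assert jc_distance_matrix(m).d[0, 1] == 0.0

    def test_no_comparable_sites_is_error(self):
        m = MSA.from_sequences(["a", "b"], ["A---", "-CGT"])
        with pytest.raises(ValueError, match="comparable"):
            jc_distance_matrix(m)


class TestBIONJ:
    def test_three_point_formulas(self):
        dm = DistanceMatrix(
            ["A", "B", "C"], np.array([[0, 0.3, 0.4], [0.3, 0, 0.5], [0.4, 0.5, 0]])
        )
        t = bionj(dm)
        lengths = sorted(ln for _, _, ln in t.edges())
        np.testing.assert_allclose(lengths, [0.1, 0.2, 0.3], atol=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_exact_on_additive_matrices(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 13))
        tree = random_tree(n, bl_mean=0.2, seed=seed + 1000)
        rec = bionj(additive_matrix(tree))
        assert rf_distance(tree, rec) == (0, 0.0)
        # edge lengths recovered as well
        _, d1 = path_distances(tree)
        _, d2 = path_distances(rec)
        labels1, _ = path_distances(tree)
        labels2, _ = path_distances(rec)
        order = [labels2.index(l) for l in labels1]
        np.testing.assert_allclose(d1, d2[np.ix_(order, order)], atol=1e-9)

    def test_taxon_order_invariance(self):
        tree = random_tree(8, seed=5)
        dm = additive_matrix(tree)
        perm = np.random.default_rng(0).permutation(len(dm.taxa))
        dm2 = DistanceMatrix(
            [dm.taxa[i] for i in perm], dm.d[np.ix_(perm, perm)]
        )
        assert rf_distance(bionj(dm), bionj(dm2)) == (0, 0.0)

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(["a", "b"], np.array([[0, 1.0], [2.0, 0]]))


class TestFitch:
    def test_hand_worked_four_taxon_cases(self):
        m = MSA.from_sequences(["1", "2", "3", "4"], ["A", "A", "C", "C"])
        assert fitch_score(parse_newick("((1,2),(3,4));"), m) == 1
        assert fitch_score(parse_newick("((1,3),(2,4));"), m) == 2

    def test_constant_column_zero_changes(self):
        m = MSA.from_sequences(["1", "2", "3", "4"], ["G", "G", "G", "G"])
        assert fitch_score(parse_newick("((1,2),(3,4));"), m) == 0

    def test_gap_counts_as_any_state(self):
        m = MSA.from_sequences(["1", "2", "3", "4"], ["A", "-", "C", "C"])
        assert fitch_score(parse_newick("((1,2),(3,4));"), m) == 1

    @pytest.mark.parametrize("seed", range(8))
    def test_equals_brute_force_on_small_instances(self, seed, jc1):
        rng = np.random.default_rng(seed)
        n_taxa = int(rng.integers(4, 7))
        n_sites = int(rng.integers(1, 5))
        tree = random_tree(n_taxa, bl_mean=0.5, seed=seed + 300)
        msa = simulate_gapless(tree, jc1, n_sites, seed=seed + 400)
        assert fitch_score(tree, msa) == fitch_brute_force(tree, msa)

    def test_rooting_invariance(self, jc1):
        tree = random_tree(7, seed=6)
        msa = simulate_gapless(tree, jc1, 40, seed=7)
        base = fitch_score(tree, msa)
        # re-parse from Newick (different internal ids / traversal root)
        again = fitch_score(parse_newick(write_newick(tree)), msa)
        assert base == again


class TestParsimonyTree:
    def test_recovers_topology_on_strong_signal(self, jc1):
        # balanced tree, moderate pendant and internal branches: no
        # long-branch attraction, plenty of changes on every internal edge
        hits = 0
        truth = parse_newick(
            "((T1:0.1,T2:0.1):0.15,(T3:0.1,T4:0.1):0.15,(T5:0.1,T6:0.1):0.15);"
        )
        for seed in range(10):
            msa = simulate_gapless(truth, jc1, 2000, seed=seed)
            t = parsimony_tree(msa, seed=seed)
            hits += rf_distance(truth, t) == (0, 0.0)
        assert hits >= 9

    def test_deterministic_per_seed(self, jc1):
        msa = simulate_gapless(random_tree(7, seed=8), jc1, 300, seed=9)
        a = parsimony_tree(msa, seed=5)
        b = parsimony_tree(msa, seed=5)
        assert rf_distance(a, b) == (0, 0.0)

    def test_nni_never_worsens_stepwise_score(self, jc1):
        msa = simulate_gapless(random_tree(8, 0.4, seed=10), jc1, 200, seed=11)
        stepwise = parsimony_tree(msa, seed=3, nni_rounds=0)
        refined = parsimony_tree(msa, seed=3, nni_rounds=5)
        assert fitch_score(refined, msa) <= fitch_score(stepwise, msa)

    def test_beats_random_topologies(self, jc1):
        rng = np.random.default_rng(12)
        wins = 0
        for trial in range(5):
            truth = random_tree(7, 0.3, seed=500 + trial)
            msa = simulate_gapless(truth, jc1, 500, seed=600 + trial)
            best_random = min(
                fitch_score(random_tree(7, seed=int(rng.integers(2**31))), msa)
                for _ in range(100)
            )
            wins += fitch_score(parsimony_tree(msa, seed=trial), msa) <= best_random
        assert wins == 5


class TestNNIMLSearch:
    def test_retains_true_tree_on_easy_data(self, jc1):
        truth = random_tree(6, 0.2, seed=13)
        msa = simulate_gapless(truth, jc1, 2000, seed=14)
        start_lnl, _, _ = evaluate_tree(truth, msa, jc1, optimize={"brlens"})
        tree, lnl = nni_ml_search(msa, jc1, truth, tol=0.1)
        assert lnl >= start_lnl - 0.1  # within the search's lnL tolerance

    def test_reaches_global_optimum_on_five_leaves(self, jc1):
        # verified against exhaustive evaluation of all 15 topologies
        truth = random_tree(5, 0.25, seed=15)
        msa = simulate_gapless(truth, jc1, 2000, seed=16)
        start = random_tree(5, 0.1, seed=999)
        found, found_lnl = nni_ml_search(msa, jc1, start)
        best = max(
            (evaluate_tree(t, msa, jc1, optimize={"brlens"})[0], t)
            for t in enumerate_topologies(["T1", "T2", "T3", "T4", "T5"])
        )
        assert rf_distance(found, best[1]) == (0, 0.0)
        assert found_lnl == pytest.approx(best[0], abs=0.2)


class TestExternalToolAdapter:
    def test_unregistered_tool_lists_names(self, tmp_path):
        with pytest.raises(ValueError, match="registered"):
            run_external_tool("mystery", tmp_path / "x.fasta", {"tools": {"a": {}}})

    def test_missing_binary_is_skipped(self, tmp_path):
        cfg = {"tools": {"ghost": {"cmd": "no-such-binary-xyz {msa}",
                                   "best_tree": "{prefix}.nwk"}}}
        res = run_external_tool("ghost", tmp_path / "x.fasta", cfg, workdir=tmp_path)
        assert res.status == "skipped"

    def test_builtin_names_bypass(self, tmp_path):
        with pytest.raises(ValueError, match="built-in"):
            run_external_tool("bionj", tmp_path / "x.fasta", {"tools": {}})

    def test_failing_command_recorded(self, tmp_path):
        cfg = {"tools": {"bad": {"cmd": "false", "best_tree": "{prefix}.nwk"}}}
        res = run_external_tool("bad", tmp_path / "x.fasta", cfg, workdir=tmp_path)
        assert res.status == "failed"

    def test_working_command_parses_tree(self, tmp_path):
        out = tmp_path / "best.nwk"
        cfg = {
            "tools": {
                "echo-tree": {
                    "cmd": f"cp {tmp_path}/input.nwk {out}",
                    "best_tree": str(out),
                }
            }
        }
        (tmp_path / "input.nwk").write_text("((A:1,B:1):1,C:1,D:1);\n")
        res = run_external_tool("echo-tree", tmp_path / "x.fasta", cfg, workdir=tmp_path)
        assert res.status == "ok"
        assert res.tree.n_leaves() == 4
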