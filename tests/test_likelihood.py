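import numpy as np
import pytest
from scipy.stats import chi2

from mtclock.alignment import Alignment
from mtclock.likelihood import (BranchTree, ClockTree, IndexedTree,
                                ancestral_states, clock_lrt,
                                estimate_root_height_se, fit_no_clock,
                                fit_strict_clock, site_log_likelihoods)
from mtclock.simulate import (Scenario, TimeTree, default_cheetah_scenario,
                              simulate_alignment)
from mtclock.substitution import TN93GParams, discretize_gamma
from mtclock.treespace import Topology
from oracles import brute_site_logliks


def branch_tree(newick, lengths_by_leafset):
    """BranchTree with edge lengths looked up by the edge's below-leafset."""
    topo = Topology.from_newick(newick)
    itree = IndexedTree.from_topology(topo)
    lens = np.zeros(itree.n_nodes)
    for v, ls in enumerate(itree.leafsets()):
        if v != itree.root:
            lens[v] = lengths_by_leafset[frozenset(ls)]
    return BranchTree(topo, itree, lens)


class TestSiteLogLikelihoods:
    def test_two_taxa_jc_closed_form(self, jc_params):
        t = 0.3
        itree = IndexedTree.from_rooted(("A", "B"))
        heights = np.zeros(itree.n_nodes)
        heights[itree.root] = t / 2
        aln = Alignment(("A", "B"), ("A", "A"))
        ll = site_log_likelihoods(aln, ClockTree(itree, heights), jc_params)
        expected = np.log(0.25 * (0.25 + 0.75 * np.exp(-4 * t / 3)))
        np.testing.assert_allclose(ll, [expected], atol=1e-12)

    def test_fully_missing_column_contributes_zero(self, tn93_params):
        aln = Alignment(("A", "B", "C"), ("N", "N", "-"))
        bt = branch_tree("(A,B,C);", {
            frozenset({"A"}): 0.1, frozenset({"B"}): 0.2, frozenset({"C"}): 0.3,
        })
        ll = site_log_likelihoods(aln, bt, tn93_params)
        np.testing.assert_allclose(ll, [0.0], atol=1e-12)

    @pytest.mark.parametrize("newick", ["((A,B),(C,D));", "(A,(B,(C,D)));",
                                        "((A,C),(B,D));"])
    def test_matches_exhaustive_state_oracle(self, newick, tn93_params,
                                             random_alignment4):
        rng = np.random.default_rng(3)
        topo = Topology.from_newick(newick)
        itree = IndexedTree.from_topology(topo)
        lens = rng.uniform(0.01, 0.5, itree.n_nodes)
        lens[itree.root] = 0.0
        bt = BranchTree(topo, itree, lens)
        ll = site_log_likelihoods(random_alignment4, bt, tn93_params)
        rates, _ = discretize_gamma(tn93_params.gamma_shape,
                                    tn93_params.n_categories)
        oracle = brute_site_logliks(random_alignment4, itree, lens,
                                    tn93_params, rates)
        np.testing.assert_allclose(ll, oracle, atol=1e-8)

    def test_five_taxa_with_ambiguity_codes_vs_oracle(self, tn93_params):
        aln = Alignment(
            ("a", "b", "c", "d", "e"),
            ("ACGRN", "ACGTA", "AMGTC", "AC-TC", "ACGYC"),
        )
        topo = Topology.from_newick("((a,b),(c,(d,e)));")
        itree = IndexedTree.from_topology(topo)
        rng = np.random.default_rng(5)
        lens = rng.uniform(0.02, 0.4, itree.n_nodes)
        lens[itree.root] = 0.0
        ll = site_log_likelihoods(aln, BranchTree(topo, itree, lens), tn93_params)
        rates, _ = discretize_gamma(tn93_params.gamma_shape,
                                    tn93_params.n_categories)
        oracle = brute_site_logliks(aln, itree, lens, tn93_params, rates)
        np.testing.assert_allclose(ll, oracle, atol=1e-8)

    def test_root_placement_invariance(self, tn93_params, random_alignment4):
        """Reversibility: splitting an edge around the root arbitrarily and
        re-rooting leaves the likelihood unchanged (pulley principle)."""
        lengths = {
            frozenset({"A"}): 0.11, frozenset({"B"}): 0.23,
            frozenset({"C"}): 0.08, frozenset({"D"}): 0.31,
            frozenset({"A", "B"}): 0.17, frozenset({"C", "D"}): 0.17,
        }
        # trifurcating representation: central edge carried entirely by (C,D)
        tri = branch_tree("((A,B),(C,D));", {
            frozenset({"A"}): 0.11, frozenset({"B"}): 0.23,
            frozenset({"C"}): 0.08, frozenset({"D"}): 0.31,
            frozenset({"C", "D"}): 0.34,
        })
        ll_tri = site_log_likelihoods(random_alignment4, tri, tn93_params)
        # bifurcating rooting on the central edge, split 0.17/0.17
        itree = IndexedTree.from_rooted((("A", "B"), ("C", "D")))
        lens = np.zeros(itree.n_nodes)
        for v, ls in enumerate(itree.leafsets()):
            if v != itree.root:
                lens[v] = lengths[frozenset(ls)]
        bt = BranchTree(Topology.from_newick("((A,B),(C,D));"), itree, lens)
        ll_rooted = site_log_likelihoods(random_alignment4, bt, tn93_params)
        np.testing.assert_allclose(ll_tri, ll_rooted, atol=1e-8)

    def test_taxon_mismatch_rejected(self, tn93_params, random_alignment4):
        bt = branch_tree("(A,B,Z);", {
            frozenset({"A"}): 0.1, frozenset({"B"}): 0.1, frozenset({"Z"}): 0.1,
        })
        with pytest.raises(ValueError, match="absent"):
            site_log_likelihoods(random_alignment4, bt, tn93_params)


class TestFits:
    def test_identical_sequences_give_zero_cherry_lengths(self, jc_params):
        rng = np.random.default_rng(0)
        base = "".join(rng.choice(list("ACGT"), 500))
        other = "".join(rng.choice(list("ACGT"), 500))
        aln = Alignment(("X1", "X2", "Y", "Z"), (base, base, other, base))
        topo = Topology.from_newick("((X1,X2),(Y,Z));")
        fit = fit_no_clock(aln, topo, model_init=jc_params, optimize_model=False)
        for v, ls in enumerate(fit.tree.tree.leafsets()):
            if ls == frozenset({"X1"}) or ls == frozenset({"X2"}):
                assert fit.tree.lengths[v] < 1e-6

    def test_total_equals_sum_of_per_site(self, cheetah_sim_small):
        scenario, aln, _ = cheetah_sim_small
        topo = Topology.from_newick(
            "((Puma,Jaguarundi),((NEAfr1,NEAfr2),(India1,(SEAfr1,SEAfr2))));"
        )
        fit = fit_no_clock(aln, topo, model_init=scenario.model,
                           optimize_model=False)
        assert abs(fit.log_likelihood
                   - fit.per_site_log_likelihoods.sum()) < 1e-6

    def test_branch_length_recovery_within_3se(self, jc_params):
        # 2-taxon divergence: ML distance has SE sqrt(p(1-p)/n)/|dp/dd|
        tt = TimeTree(("A", "B"), {frozenset({"A", "B"}): 0.06 / 2 / 1e-8})
        sc = Scenario(time_tree=tt, mutation_rate=1e-8, model=jc_params,
                      length=10000, seed=21)
        aln, true_clock = simulate_alignment(sc)
        topo = Topology.from_newick("(A,B,C);")  # need >=3 taxa: add twin
        aln3 = Alignment(("A", "B", "C"),
                         (aln.sequences[0], aln.sequences[1], aln.sequences[1]))
        fit = fit_no_clock(aln3, topo, model_init=jc_params, optimize_model=False)
        total = fit.tree.total_length
        d_true = 0.06
        p = 0.75 * (1 - np.exp(-4 * d_true / 3))
        se = np.sqrt(p * (1 - p) / 10000) / np.exp(-4 * d_true / 3)
        assert abs(total - d_true) < 3 * se

    def test_no_clock_dominates_clock(self, cheetah_sim_small):
        scenario, aln, _ = cheetah_sim_small
        topo = Topology.from_newick(
            "((Puma,Jaguarundi),((NEAfr1,NEAfr2),(India1,(SEAfr1,SEAfr2))));"
        )
        free = fit_no_clock(aln, topo, model_init=scenario.model,
                            optimize_model=False)
        clock = fit_strict_clock(aln, scenario.time_tree.nested,
                                 model_init=scenario.model,
                                 optimize_model=False, estimate_se=False)
        assert free.log_likelihood >= clock.log_likelihood - 1e-4

    def test_clock_height_recovery_within_3se(self):
        sc = default_cheetah_scenario(seed=31, length=10000, with_masks=False)
        aln, true_clock = simulate_alignment(sc)
        fit = fit_strict_clock(aln, sc.time_tree.nested, model_init=sc.model,
                               optimize_model=False, estimate_se=True)
        err = abs(fit.tree.root_height - true_clock.root_height)
        assert err < 3 * fit.tree.root_height_se

    def test_identical_sequences_give_zero_heights(self, jc_params):
        seq = "ACGTACGTAC" * 30
        aln = Alignment(("A", "B", "C", "D"), (seq,) * 4)
        fit = fit_strict_clock(aln, (("A", "B"), ("C", "D")),
                               model_init=jc_params, optimize_model=False,
                               estimate_se=False)
        assert fit.tree.root_height < 1e-5


class TestRootHeightSE:
    def test_doubling_data_shrinks_se_by_sqrt2(self):
        sc = default_cheetah_scenario(seed=41, length=2000, with_masks=False)
        aln, _ = simulate_alignment(sc)
        fit1 = fit_strict_clock(aln, sc.time_tree.nested, model_init=sc.model,
                                optimize_model=False)
        doubled = aln.concatenate(aln)
        fit2 = fit_strict_clock(doubled, sc.time_tree.nested,
                                model_init=sc.model, optimize_model=False)
        ratio = fit2.tree.root_height_se / fit1.tree.root_height_se
        assert abs(ratio - 1 / np.sqrt(2)) < 0.08

    def test_se_calibrated_against_replicate_scatter(self):
        """Empirical SD of the root-height MLE across replicates should be
        within ~30% of the mean reported SE."""
        heights, ses = [], []
        for seed in range(30):
            sc = default_cheetah_scenario(seed=600 + seed, length=1500,
                                          with_masks=False)
            aln, _ = simulate_alignment(sc)
            fit = fit_strict_clock(aln, sc.time_tree.nested,
                                   model_init=sc.model, optimize_model=False)
            heights.append(fit.tree.root_height)
            ses.append(fit.tree.root_height_se)
        sd = np.std(heights, ddof=1)
        mean_se = np.mean(ses)
        assert abs(sd - mean_se) / mean_se < 0.30


class TestClockLRT:
    def test_printed_worked_example(self):
        """The published PAML log-likelihoods give df 5, p = 0.09 (2 dp)."""
        stat, df, p = clock_lrt(-29341.106115, -29345.873227, n_taxa=7)
        assert df == 5
        np.testing.assert_allclose(stat, 9.534224, atol=1e-6)
        assert round(p, 2) == 0.09

    def test_equal_likelihoods(self):
        stat, df, p = clock_lrt(-100.0, -100.0, n_taxa=7)
        assert stat == 0.0 and p == 1.0

    def test_quantile_inversion(self):
        crit = chi2.ppf(0.95, 5)
        _, _, p = clock_lrt(-100.0, -100.0 - crit / 2, n_taxa=7)
        np.testing.assert_allclose(p, 0.05, atol=1e-10)

    def test_negative_statistic_rejected(self):
        with pytest.raises(ValueError, match="optimi"):
            clock_lrt(-105.0, -100.0, n_taxa=7)


class TestAncestralStates:
    def test_uniform_column_maps_to_observed_state(self, tn93_params):
        aln = Alignment(("A", "B", "C", "D"), ("G" * 5,) * 4)
        topo = Topology.from_newick("((A,B),(C,D));")
        itree = IndexedTree.from_topology(topo)
        lens = np.full(itree.n_nodes, 0.01)
        lens[itree.root] = 0.0
        rec = ancestral_states(aln, BranchTree(topo, itree, lens), tn93_params)
        assert all(s == "G" * 5 for s in rec.map_states)

    def test_posteriors_normalised(self, tn93_params, random_alignment4):
        topo = Topology.from_newick("((A,B),(C,D));")
        itree = IndexedTree.from_topology(topo)
        lens = np.full(itree.n_nodes, 0.1)
        lens[itree.root] = 0.0
        rec = ancestral_states(random_alignment4,
                               BranchTree(topo, itree, lens), tn93_params)
        np.testing.assert_allclose(rec.posteriors.sum(axis=2), 1.0, atol=1e-10)

    def test_three_taxon_star_matches_bayes_oracle(self, tn93_params):
        from scipy.linalg import expm

        from oracles import tn93_rate_matrix

        aln = Alignment(("A", "B", "C"), ("A", "C", "A"))
        topo = Topology.from_newick("(A,B,C);")
        itree = IndexedTree.from_topology(topo)
        lens = np.zeros(itree.n_nodes)
        for v in range(itree.n_nodes):
            if itree.parent[v] >= 0:
                lens[v] = 0.08 * (v + 1)
        rec = ancestral_states(aln, BranchTree(topo, itree, lens), tn93_params)
        post, _ = rec.for_clade({"A", "B", "C"})

        Q = tn93_rate_matrix(tn93_params.base_freqs, 2.0, 3.0, 1.0)
        rates, _ = discretize_gamma(tn93_params.gamma_shape,
                                    tn93_params.n_categories)
        pi = np.asarray(tn93_params.base_freqs)
        state = {"A": 0, "C": 1, "G": 2, "T": 3}
        joint = np.zeros(4)
        for r in rates:
            P = {v: expm(Q * r * lens[v]) for v in range(itree.n_nodes)
                 if itree.parent[v] >= 0}
            for root_state in range(4):
                pr = pi[root_state] / len(rates)
                for v in range(itree.n_nodes):
                    if itree.parent[v] < 0:
                        continue
                    pr *= P[v][root_state,
                               state[aln.sequence(itree.labels[v])[0]]]
                joint[root_state] += pr
        np.testing.assert_allclose(post[0], joint / joint.sum(), atol=1e-10)
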