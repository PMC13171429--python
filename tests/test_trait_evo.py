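import math

import numpy as np
import pytest

from oracles import brute_mk_loglik
from vertitrace import synthetic_data as sim
from vertitrace import trait_evo
from vertitrace.seqio import read_newick
from vertitrace.trait_evo import (
    CalibrationPoint,
    MkModel,
    date_nodes,
    lgt_flags,
    mk_asr,
    mk_loglik,
    transfer_recipients,
    transition_matrix,
)


class TestMkLikelihood:
    def test_two_tip_closed_form(self):
        """Root marginal and likelihood of a cherry match the closed-form 2-state P(t)."""
        tree = read_newick("(A:0.5,B:0.5);")
        traits = {"A": 1, "B": 0}
        q = 0.7
        P = transition_matrix(q, q, 0.5)
        closed = math.log(0.5 * (P[0, 1] * P[0, 0] + P[1, 1] * P[1, 0]))
        assert mk_loglik(tree, traits, q, q) == pytest.approx(closed, abs=1e-10)
        # marginal P(present) at the root, same construction
        asr_marg_num = 0.5 * P[1, 1] * P[1, 0]
        expected = asr_marg_num / (0.5 * (P[0, 1] * P[0, 0] + P[1, 1] * P[1, 0]))
        marg = trait_evo._marginals(tree, traits, q, q, np.array([0.5, 0.5]))
        assert marg[tree.seed_node] == pytest.approx(expected, abs=1e-10)

    def test_pruning_equals_enumeration_oracle(self):
        for seed in range(12):
            tree = sim.sim_yule_tree(4 + seed % 6, seed=seed)
            traits, _ = sim.sim_trait_on_tree(tree, 0.4, 0.3, seed=seed + 99)
            q01, q10 = 0.3 + 0.05 * seed, 0.5
            assert mk_loglik(tree, traits, q01, q10) == pytest.approx(
                brute_mk_loglik(tree, traits, q01, q10), abs=1e-10
            )

    def test_er_state_relabeling_invariance(self):
        tree = sim.sim_yule_tree(10, seed=4)
        traits, _ = sim.sim_trait_on_tree(tree, 0.5, 0.5, seed=8)
        flipped = {k: 1 - v for k, v in traits.items()}
        q = 0.4
        assert mk_loglik(tree, traits, q, q) == pytest.approx(
            mk_loglik(tree, flipped, q, q), abs=1e-12
        )

    def test_all_zero_branch_lengths_rejected(self):
        tree = read_newick("((A:0,B:0):0,C:0);")
        with pytest.raises(ValueError, match="zero"):
            mk_asr(tree, {"A": 1, "B": 0, "C": 0})


class TestAsr:
    def test_uniform_presence_rate_collapses(self):
        tree = sim.sim_yule_tree(8, seed=2)
        traits = {l.taxon.label: 1 for l in tree.leaf_node_iter()}
        res = mk_asr(tree, traits)
        assert all(p > 0.5 for p in res.marginals.values())
        assert res.rates["q"] < 1e-4
        assert res.gains == [] and res.losses == []

    def test_single_clade_yields_one_gain(self):
        tree = read_newick(
            "(((A:1,B:1):1,(C:1,D:1):1):1,((E:1,F:1):1,(G:1,H:1):1):1);"
        )
        traits = {t: 1 if t in "AB" else 0 for t in "ABCDEFGH"}
        res = mk_asr(tree, traits)
        assert len(res.gains) == 1 and len(res.losses) == 0

    def test_marginals_are_probabilities(self):
        tree = sim.sim_yule_tree(16, seed=6)
        traits, _ = sim.sim_trait_on_tree(tree, 0.3, 0.3, seed=7)
        res = mk_asr(tree, traits)
        assert all(0.0 <= p <= 1.0 for p in res.marginals.values())

    def test_labeling_and_rate_recovery_on_simulations(self):
        """Max-marginal labels recover most true node states; ML rate within 2x."""
        accs, within2 = [], 0
        n_done = 0
        for k in range(30):
            tree = sim.sim_yule_tree(64, seed=k)
            traits, truth = sim.sim_trait_on_tree(tree, 0.2, 0.2, seed=k + 777)
            if len(set(traits.values())) < 2:
                continue
            n_done += 1
            res = mk_asr(tree, traits)
            ids = trait_evo.assign_node_ids(tree)
            internal = [i for n, i in ids.items() if not n.is_leaf()]
            accs.append(
                np.mean([res.labels[i] == truth.node_states[i] for i in internal])
            )
            within2 += 0.5 <= res.rates["q"] / 0.2 <= 2.0
        assert np.mean(accs) >= 0.85
        assert within2 / n_done >= 0.75


class TestOriginNode:
    def test_confident_clade_root(self):
        tree = read_newick(
            "(((A:1,B:1):1,(C:1,D:1):1):1,((E:1,F:1):1,(G:1,H:1):1):1);"
        )
        traits = {t: 1 if t in "ABCD" else 0 for t in "ABCDEFGH"}
        res = mk_asr(tree, traits)
        ids = trait_evo.assign_node_ids(tree)
        clade = tree.mrca(taxon_labels=list("ABCD"))
        assert res.origin == ids[clade]

    def test_unattainable_threshold_falls_back_to_mrca(self):
        tree = read_newick("((A:1,B:1):1,(C:1,D:1):1);")
        traits = {"A": 1, "B": 1, "C": 0, "D": 0}
        res = mk_asr(tree, traits)
        with pytest.warns(UserWarning, match="MRCA"):
            fallback = trait_evo.origin_node(res, tree, threshold=1.01)
        ids = trait_evo.assign_node_ids(tree)
        assert fallback == ids[tree.mrca(taxon_labels=["A", "B"])]


class TestDating:
    def test_single_calibration_identity(self):
        tree = read_newick("((A:1,B:1):1,(C:1,D:1):1);")  # ultrametric, depth 2
        res = date_nodes(tree, [CalibrationPoint(("A", "C"), age=100.0)])
        ids = trait_evo.assign_node_ids(tree)
        root = ids[tree.seed_node]
        assert res.ages[root] == pytest.approx(100.0)
        assert res.rate == pytest.approx(2.0 / 100.0)
        assert all(res.ages[ids[l]] == 0.0 for l in tree.leaf_node_iter())

    def test_two_clock_consistent_calibrations_exact(self):
        tree = read_newick("(((A:1,B:1):1,C:2):2,D:4);")  # clock-like, root depth 4
        cals = [
            CalibrationPoint(("A", "D"), age=400.0, ci=(300.0, 500.0)),
            CalibrationPoint(("A", "B"), age=100.0, ci=(80.0, 120.0)),
        ]
        res = date_nodes(tree, cals)
        ids = trait_evo.assign_node_ids(tree)
        assert res.ages[ids[tree.seed_node]] == pytest.approx(400.0)
        assert res.ages[ids[tree.mrca(taxon_labels=["A", "B"])]] == pytest.approx(100.0)
        lo, hi = res.age_ci[ids[tree.seed_node]]
        assert lo < 400.0 < hi

    def test_child_age_below_parent_on_random_trees(self):
        for seed in range(20):
            tree = sim.sim_yule_tree(20, seed=seed)
            res = date_nodes(
                tree,
                [CalibrationPoint(
                    tuple(l.taxon.label for l in tree.leaf_node_iter())[:2], age=50.0
                )],
            )
            ids = trait_evo.assign_node_ids(tree)
            for node in tree.preorder_node_iter():
                for child in node.child_nodes():
                    assert res.ages[ids[child]] <= res.ages[ids[node]] + 1e-9

    def test_tip_calibration_rejected(self):
        tree = read_newick("((A:1,B:1):1,C:2);")
        with pytest.raises(ValueError):
            date_nodes(tree, [CalibrationPoint(("A",), age=10.0)])


class TestLgtFlags:
    def test_identical_topologies_unflagged(self):
        sp = read_newick("((A:1,B:1):1,(C:1,D:1):1);")
        gt = read_newick("((A:2,B:2):1,(C:1,D:1):1);")
        assert all(not f.flagged for f in lgt_flags(gt, sp))

    def test_swapped_cherries_flag_all_four(self):
        sp = read_newick("((A:1,B:1):1,(C:1,D:1):1);")
        gt = read_newick("((A:1,C:1):1,(B:1,D:1):1);")
        flags = lgt_flags(gt, sp)
        assert all(f.flagged for f in flags)

    def test_engineered_transfer_flags_recipient_with_donor(self):
        sp = sim.sim_yule_tree(16, seed=12)
        tips = [l.taxon.label for l in sp.leaf_node_iter()]
        donor, recipient = tips[1], tips[10]
        gt = sim.apply_transfer(sp, donor, recipient)
        flags = {f.tip: f for f in lgt_flags(gt, sp)}
        assert flags[recipient].flagged
        assert donor in flags[recipient].proposed_donor
        assert transfer_recipients(gt, sp) == [recipient]

    def test_no_shared_tips_rejected(self):
        sp = read_newick("((A:1,B:1):1,C:1);")
        gt = read_newick("((X:1,Y:1):1,Z:1);")
        with pytest.raises(ValueError):
            lgt_flags(gt, sp)
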