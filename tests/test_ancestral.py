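import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.linalg

from phylotrait.phylo_io import Phylogeny, TreeSet
from phylotrait.mk_engine import ConstraintMap, RateMatrix, build_rate_matrix, fit_ml
from phylotrait.mk_engine.likelihood import root_weights, tip_partials
from phylotrait.ancestral import (
    TransitionEvent,
    ancestral_continuous,
    count_transitions,
    marginal_asr,
    sample_history,
    summarize_root,
    transition_context_compare,
)
from phylotrait.synthetic_data import (
    simulate_continuous_bm,
    simulate_discrete,
    simulate_tree,
)


def enumeration_marginals(tree, tip_states, Q, root_mode="flat"):
    """Brute-force node marginals by summing over all internal assignments."""
    k = Q.k
    part = tip_partials(tree, tip_states, k)
    w = root_weights(Q, root_mode, k)
    P = {u: scipy.linalg.expm(Q.q * tree.edge_length[u]) for u in range(tree.n_nodes - 1)}
    internal = [u for u in range(tree.n_nodes) if not tree.is_tip[u]]
    pos = {u: i for i, u in enumerate(internal)}
    marg = np.zeros((tree.n_nodes, k))
    for assign in itertools.product(range(k), repeat=len(internal)):
        prob = w[assign[pos[tree.root]]]
        for u in range(tree.n_nodes - 1):
            ps = assign[pos[tree.parent[u]]]
            if tree.is_tip[u]:
                prob *= float(P[u][ps] @ part[u])
            else:
                prob *= P[u][ps, assign[pos[u]]]
        for u in internal:
            marg[u, assign[pos[u]]] += prob
    return marg[internal] / marg[internal].sum(axis=1, keepdims=True), internal


class TestMarginalASR:
    def test_symmetric_cherry_root_half(self):
        t = Phylogeny.from_newick("(A:1,B:1);")
        Q = build_rate_matrix({"rate": 0.5}, ConstraintMap.equal_rates(2))
        asr = marginal_asr(t, {"A": 0, "B": 1}, Q)
        np.testing.assert_allclose(asr.root_probabilities, [0.5, 0.5], atol=1e-12)

    def test_vanishing_rates_pin_root(self):
        t = Phylogeny.from_newick("((A:1,B:1):1,C:2);")
        Q = build_rate_matrix({"rate": 1e-8}, ConstraintMap.equal_rates(2))
        asr = marginal_asr(t, {"A": 0, "B": 0, "C": 0}, Q)
        assert asr.root_probabilities[0] > 0.999999

    def test_matches_enumeration(self, three_tip_tree, q4_random):
        tips = {"A": 0, "B": 2, "C": 3}
        asr = marginal_asr(three_tip_tree, tips, q4_random)
        expected, internal = enumeration_marginals(three_tip_tree, tips, q4_random)
        np.testing.assert_allclose(asr.probs[internal], expected, atol=1e-9)

    def test_matches_enumeration_randomized(self):
        from conftest import random_rate_matrix, random_small_tree

        rng = np.random.default_rng(99)
        for _ in range(10):
            tree = random_small_tree(rng, int(rng.integers(3, 6)))
            Q = random_rate_matrix(rng, int(rng.integers(2, 4)))
            tips = {lab: int(rng.integers(Q.k)) for lab in tree.tip_labels}
            try:
                asr = marginal_asr(tree, tips, Q)
            except ValueError:
                continue  # impossible data under structural zeros
            expected, internal = enumeration_marginals(tree, tips, Q)
            np.testing.assert_allclose(asr.probs[internal], expected, atol=1e-9)

    def test_rows_sum_to_one(self, four_tip_tree, q4_random):
        asr = marginal_asr(four_tip_tree, {"A": 0, "B": 1, "C": 2, "D": 3}, q4_random)
        np.testing.assert_allclose(asr.probs.sum(axis=1), 1.0, atol=1e-9)


class TestSummarizeRoot:
    def test_identical_vectors_zero_width(self):
        df = summarize_root([np.array([0.7, 0.3])] * 5)
        assert df.loc["state_0", "ci_lower"] == df.loc["state_0", "ci_upper"] == 0.7

    def test_two_opposite_trees(self):
        df = summarize_root([np.array([1.0, 0.0]), np.array([0.0, 1.0])])
        np.testing.assert_allclose(df["mean"], [0.5, 0.5])

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            summarize_root([])


class TestCountTransitions:
    def _fit_er(self, tree, states, k=2):
        return fit_ml(tree, states, ConstraintMap.equal_rates(k), seed=0).rate_matrix

    def test_no_variation_zero_counts(self):
        t = simulate_tree(20, 1.0, seed=1)
        states = {lab: 0 for lab in t.tip_labels}
        Q = build_rate_matrix({"rate": 0.01}, ConstraintMap.equal_rates(2))
        res = count_transitions(t, states, Q)
        assert res.mean_counts.sum() == 0

    def test_joint_counts_equal_discordant_edges(self):
        t = simulate_tree(50, 1.0, seed=2)
        Q = build_rate_matrix({"rate": 0.4}, ConstraintMap.equal_rates(2))
        d = simulate_discrete(t, Q, seed=3)
        states = {sp: int(v) for sp, v in d.tip_data["state"].items()}
        res = count_transitions(t, states, Q, method="joint")
        asr = marginal_asr(t, states, Q)
        st = asr.max_states()
        discordant = sum(
            1 for u in range(t.n_nodes - 1) if st[t.parent[u]] != st[u]
        )
        assert res.mean_counts.sum() == discordant
        assert len(res.events) == discordant

    def test_stochastic_map_at_least_joint(self):
        """Maps include multiple hits, so average >= parsimony-like joint count."""
        t = simulate_tree(100, 1.0, seed=4)
        Q = build_rate_matrix({"rate": 0.5}, ConstraintMap.equal_rates(2))
        joint_tot, map_tot = 0.0, 0.0
        for s in range(5):
            d = simulate_discrete(t, Q, seed=10 + s)
            states = {sp: int(v) for sp, v in d.tip_data["state"].items()}
            joint_tot += count_transitions(t, states, Q, method="joint").mean_counts.sum()
            map_tot += count_transitions(
                t, states, Q, method="stochastic-map", n_maps=20, seed=s
            ).mean_counts.sum()
        assert map_tot >= joint_tot

    def test_stochastic_map_consistent_with_truth(self):
        t = simulate_tree(150, 1.0, seed=5)
        Q = build_rate_matrix({"rate": 0.3}, ConstraintMap.equal_rates(2))
        d = simulate_discrete(t, Q, seed=6)
        states = {sp: int(v) for sp, v in d.tip_data["state"].items()}
        res = count_transitions(t, states, Q, method="stochastic-map", n_maps=40, seed=7)
        truth = d.truth["n_changes"]
        assert truth > 0
        assert abs(res.mean_counts.sum() - truth) <= max(0.6 * truth, 4)

    def test_across_treeset(self):
        base = simulate_tree(40, 1.0, seed=8)
        from phylotrait.synthetic_data import jitter_tree_set

        ts = jitter_tree_set(base, 4, seed=9)
        Q = build_rate_matrix({"rate": 0.4}, ConstraintMap.equal_rates(2))
        d = simulate_discrete(base, Q, seed=10)
        states = {sp: int(v) for sp, v in d.tip_data["state"].items()}
        res = count_transitions(ts, states, Q, method="joint")
        assert res.per_tree.shape == (4, 2, 2)
        np.testing.assert_allclose(res.mean_counts, res.per_tree.mean(axis=0))


class TestAncestralContinuous:
    def test_constant_tips(self, four_tip_tree):
        vals = pd.Series(3.14, index=four_tip_tree.tip_labels)
        df = ancestral_continuous(four_tip_tree, vals)
        np.testing.assert_allclose(df["estimate"], 3.14, atol=1e-9)

    def test_star_tree_root_is_mean(self, star_tree_5):
        vals = pd.Series([1.0, 2.0, 3.0, 4.0, 10.0], index=star_tree_5.tip_labels)
        df = ancestral_continuous(star_tree_5, vals)
        assert df.loc[star_tree_5.root, "estimate"] == pytest.approx(4.0)

    def test_root_equals_gls_phylogenetic_mean(self):
        t = simulate_tree(40, 1.0, seed=11)
        sim = simulate_continuous_bm(t, 1.0, root_value=2.0, seed=12)
        df = ancestral_continuous(t, sim.tip_data["value"])
        # cross-module consistency with the GLS mean used by the regressions
        from phylotrait.regression_paths import pgls_fit

        fit = pgls_fit(sim.tip_data["value"], None, t)
        assert df.loc[t.root, "estimate"] == pytest.approx(
            fit.coefficients["(Intercept)"], abs=1e-9
        )

    def test_calibration(self):
        """Mean error ~ 0 and 95% interval coverage in [0.85, 1.0]."""
        t = simulate_tree(30, 1.0, seed=13)
        errs, hits, tot = [], 0, 0
        for s in range(60):
            sim = simulate_continuous_bm(t, 1.0, seed=100 + s)
            df = ancestral_continuous(t, sim.tip_data["value"])
            truth = sim.truth["node_values"]
            for u in range(t.n_nodes):
                if t.is_tip[u]:
                    continue
                est, se = df.loc[u, "estimate"], df.loc[u, "se"]
                errs.append(est - truth[u])
                hits += abs(est - truth[u]) <= 1.96 * se
                tot += 1
        assert abs(np.mean(errs)) < 0.1
        assert 0.85 <= hits / tot <= 1.0

    def test_too_few_tips(self):
        t = Phylogeny.from_newick("(A:1,B:1);")
        with pytest.raises(ValueError):
            ancestral_continuous(t, pd.Series([1.0, 2.0], index=["A", "B"]))


class TestTransitionContext:
    def _setup(self, seed=14):
        t = simulate_tree(60, 1.0, seed=seed)
        Q = build_rate_matrix({"rate": 0.4}, ConstraintMap.equal_rates(2))
        d = simulate_discrete(t, Q, seed=seed + 1)
        states = {sp: int(v) for sp, v in d.tip_data["state"].items()}
        res = count_transitions(t, states, Q, method="joint")
        return t, res

    def test_constant_trait_zero_difference(self):
        t, res = self._setup()
        if not res.events:
            pytest.skip("no transitions in this draw")
        vals = {0: ancestral_continuous(t, pd.Series(1.0, index=t.tip_labels))}
        for mode in ("origin-vs-nonorigin", "before-vs-after"):
            ctx = transition_context_compare(res.events, vals, t, mode=mode)
            assert ctx.difference == pytest.approx(0.0, abs=1e-9)

    def test_no_transitions_typed_empty(self):
        t = simulate_tree(10, 1.0, seed=16)
        vals = {0: ancestral_continuous(t, pd.Series(np.arange(10.0), index=t.tip_labels))}
        ctx = transition_context_compare([], vals, t)
        assert ctx.empty and ctx.difference is None

    def test_planted_signal_detected(self):
        """Transitions seeded only on large-value lineages => positive contrast."""
        detected = 0
        reps = 10
        for r in range(reps):
            t = simulate_tree(80, 1.0, seed=300 + r)
            sim = simulate_continuous_bm(t, 1.0, seed=400 + r)
            node_vals = sim.truth["node_values"]
            internal = [u for u in range(t.n_nodes) if not t.is_tip[u] and u != t.root]
            big = sorted(internal, key=lambda u: node_vals[u], reverse=True)[:5]
            events = [
                TransitionEvent(0, int(u), int(t.children_of(u)[0]), 0, 1, "joint-reconstruction")
                for u in big
            ]
            vals = {0: ancestral_continuous(t, sim.tip_data["value"])}
            ctx = transition_context_compare(events, vals, t, mode="origin-vs-nonorigin")
            detected += ctx.difference is not None and ctx.difference > 0
        assert detected >= 0.8 * reps


class TestSampleHistory:
    def test_endpoint_consistency(self):
        t = simulate_tree(30, 1.0, seed=17)
        Q = build_rate_matrix({"rate": 0.5}, ConstraintMap.equal_rates(2))
        d = simulate_discrete(t, Q, seed=18)
        states = {sp: int(v) for sp, v in d.tip_data["state"].items()}
        st, counts = sample_history(t, states, Q, seed=19)
        tips = t.tip_ids
        for i in tips:
            assert st[i] == states[t.labels[i]]
        assert counts.sum() >= 0
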