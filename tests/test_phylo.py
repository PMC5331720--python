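"""Mk likelihood/ASR, D statistic, PGLMM, recoding experiment."""

import dendropy
import numpy as np
import pandas as pd
import pytest

import phyloclim as pc
from phyloclim.phylo import (
    build_q,
    count_transitions,
    fit_mk,
    marginal_asr,
    mk_loglik,
    phylo_d,
    select_model_aic,
)
from phyloclim.trees import as_arrays

from _oracles import enum_loglik, enum_marginals, random_rate_matrix


def two_tip_tree(t1=1.0, t2=1.0):
    tree = dendropy.Tree.get(data=f"(a:{t1},b:{t2});", schema="newick")
    return tree


class TestMkLoglik:
    def test_zero_rate_two_tips(self):
        # q = 0: both tips keep the root state; flat root prior gives L = 1/2
        Q = np.zeros((2, 2))
        lnl = mk_loglik(two_tip_tree(), {"a": 0, "b": 0}, Q)
        assert lnl == pytest.approx(-np.log(2.0))

    def test_saturated_two_tips(self):
        # 2-state symmetric chain: P(t) -> 1/2 as q*t -> inf; tips (0,1) -> 1/4
        Q = np.array([[-1.0, 1.0], [1.0, -1.0]])
        lnl = mk_loglik(two_tip_tree(500.0, 500.0), {"a": 0, "b": 1}, Q)
        assert lnl == pytest.approx(-np.log(4.0), abs=1e-9)

    def test_closed_form_two_state(self):
        # L = sum_s pi_s P(s->a, t1) P(s->b, t2) with P01 = 1/2 - exp(-2qt)/2
        q, t1, t2 = 0.3, 1.7, 0.9
        Q = np.array([[-q, q], [q, -q]])
        p_same = lambda t: 0.5 + 0.5 * np.exp(-2 * q * t)
        p_diff = lambda t: 0.5 - 0.5 * np.exp(-2 * q * t)
        expected = 0.5 * (p_same(t1) * p_diff(t2) + p_diff(t1) * p_same(t2))
        lnl = mk_loglik(two_tip_tree(t1, t2), {"a": 0, "b": 1}, Q)
        assert lnl == pytest.approx(np.log(expected), abs=1e-12)

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(40):
            n = int(rng.integers(4, 7))
            k = int(rng.integers(2, 4))
            ta = as_arrays(pc.simulate_yule_tree(n, 0.5, seed=int(rng.integers(2**31))))
            Q = random_rate_matrix(rng, k)
            states = rng.integers(0, k, n)
            tips = dict(zip(ta.tip_labels, map(int, states)))
            assert mk_loglik(ta, tips, Q) == pytest.approx(
                enum_loglik(ta, states, Q), abs=1e-10
            )

    def test_missing_tip_state_rejected(self, small_tree):
        Q = np.array([[-0.5, 0.5], [0.5, -0.5]])
        with pytest.raises(ValueError):
            mk_loglik(small_tree, {"sp0001": 0}, Q)

    def test_tip_order_invariance(self):
        rng = np.random.default_rng(1)
        ta = as_arrays(pc.simulate_yule_tree(6, 0.5, seed=5))
        Q = random_rate_matrix(rng, 3)
        tips = {lab: int(rng.integers(3)) for lab in ta.tip_labels}
        shuffled = dict(reversed(list(tips.items())))
        assert mk_loglik(ta, tips, Q) == pytest.approx(
            mk_loglik(ta, shuffled, Q), abs=1e-12
        )

    def test_reroot_invariance_symmetric_model(self):
        # SYM has a uniform stationary distribution, matching the flat root
        # prior, so the likelihood must not depend on root placement.
        tree = pc.simulate_yule_tree(8, 0.4, seed=6)
        rng = np.random.default_rng(2)
        Q = build_q("SYM", 3, [0.2, 0.5, 0.3])
        tips = {
            t.taxon.label: int(rng.integers(3)) for t in tree.leaf_node_iter()
        }
        l0 = mk_loglik(tree, tips, Q)
        edge = list(tree.preorder_node_iter())[3].edge
        half = edge.length / 2.0
        tree.reroot_at_edge(edge, length1=half, length2=half,
                            update_bipartitions=False)
        assert mk_loglik(tree, tips, Q) == pytest.approx(l0, abs=1e-8)


class TestFitMk:
    def test_nested_loglik_monotone(self):
        ta = as_arrays(pc.simulate_yule_tree(60, 0.2, seed=7))
        Q = random_rate_matrix(np.random.default_rng(3), 3, 0.05, 0.3)
        tips = pc.simulate_mk_trait(ta, Q, seed=4)
        fits = {m: fit_mk(ta, tips, model=m, seed=1) for m in ("ER", "SYM", "ARD")}
        assert fits["SYM"].lnl >= fits["ER"].lnl - 1e-4
        assert fits["ARD"].lnl >= fits["SYM"].lnl - 1e-4

    def test_er_rate_recovery(self):
        # median over seeds of the ER rate estimate within 50% of truth
        q_true = 0.3
        Q = np.array([[-q_true, q_true], [q_true, -q_true]])
        est = []
        for seed in range(12):
            # fast speciation keeps edges short relative to 1/q, so the
            # data stay informative rather than saturating
            ta = as_arrays(pc.simulate_yule_tree(300, 1.0, seed=800 + seed))
            tips = pc.simulate_mk_trait(ta, Q, seed=900 + seed)
            if len(set(tips.values())) < 2:
                continue
            est.append(fit_mk(ta, tips, model="ER", seed=1).rates[0])
        med = np.median(est)
        assert abs(med - q_true) / q_true < 0.5

    def test_binary_aic_formula(self, small_arrays):
        Q = np.array([[-0.4, 0.4], [0.4, -0.4]])
        tips = pc.simulate_mk_trait(small_arrays, Q, seed=2)
        if len(set(tips.values())) < 2:
            pytest.skip("degenerate draw")
        f = fit_mk(small_arrays, tips, model="ER", seed=1)
        assert f.aic == pytest.approx(-2 * f.lnl + 2.0)

    def test_constant_states_boundary_flag(self, small_arrays):
        tips = {lab: 0 for lab in small_arrays.tip_labels}
        f = fit_mk(small_arrays, tips, model="ER", seed=1)
        assert f.boundary


class TestModelSelection:
    def _fit_like(self, model, aic, key=("x",)):
        from phyloclim.phylo import MkFit

        k = 2
        return MkFit(model=model, k=k, states=[0, 1], rates=np.ones(1),
                     Q=np.zeros((2, 2)), lnl=0.0, aic=aic, converged=True,
                     boundary=False, data_key=key)

    def test_minimum_aic_wins(self):
        fits = [self._fit_like("ER", 10.0), self._fit_like("SYM", 12.0),
                self._fit_like("ARD", 15.0)]
        assert select_model_aic(fits).model == "ER"

    def test_tie_prefers_fewer_parameters(self):
        fits = [self._fit_like("ARD", 10.0), self._fit_like("ER", 10.0)]
        assert select_model_aic(fits).model == "ER"

    def test_different_data_rejected(self):
        fits = [self._fit_like("ER", 10.0, key=("x",)),
                self._fit_like("SYM", 11.0, key=("y",))]
        with pytest.raises(ValueError):
            select_model_aic(fits)

    def test_asymmetric_rates_select_ard(self):
        # strong rate asymmetry: ARD must win AIC in a majority of seeds
        Q = np.array([[-0.05, 0.05], [0.6, -0.6]])
        wins = 0
        n_seeds = 8
        for seed in range(n_seeds):
            ta = as_arrays(pc.simulate_yule_tree(500, 0.2, seed=600 + seed))
            tips = pc.simulate_mk_trait(ta, Q, root_freqs=[0.9, 0.1],
                                        seed=700 + seed)
            if len(set(tips.values())) < 2:
                continue
            fits = [fit_mk(ta, tips, model=m, seed=1) for m in ("ER", "ARD")]
            wins += select_model_aic(fits).model == "ARD"
        assert wins > n_seeds / 2


class TestMarginalAsr:
    def test_zero_rate_constant_states(self, small_arrays):
        Q = np.zeros((2, 2))
        tips = {lab: 1 for lab in small_arrays.tip_labels}
        asr = marginal_asr(small_arrays, Q, tip_states=tips)
        assert np.allclose(asr.probs[small_arrays.n_tips:, 1], 1.0)

    def test_probabilities_sum_to_one(self, small_arrays):
        rng = np.random.default_rng(4)
        Q = random_rate_matrix(rng, 3)
        tips = {lab: int(rng.integers(3)) for lab in small_arrays.tip_labels}
        asr = marginal_asr(small_arrays, Q, tip_states=tips)
        np.testing.assert_allclose(asr.probs.sum(axis=1), 1.0, atol=1e-9)

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(15):
            n = int(rng.integers(4, 6))
            k = int(rng.integers(2, 4))
            ta = as_arrays(
                pc.simulate_yule_tree(n, 0.5, seed=int(rng.integers(2**31)))
            )
            Q = random_rate_matrix(rng, k)
            states = rng.integers(0, k, n)
            tips = dict(zip(ta.tip_labels, map(int, states)))
            asr = marginal_asr(ta, Q, tip_states=tips)
            oracle = enum_marginals(ta, states, Q)
            for u in range(ta.n_tips, ta.n_nodes):
                np.testing.assert_allclose(asr.probs[u], oracle[u], atol=1e-10)


class TestTransitionCounts:
    def test_uniform_states_no_transitions(self, small_arrays):
        Q = np.zeros((2, 2))
        tips = {lab: 0 for lab in small_arrays.tip_labels}
        asr = marginal_asr(small_arrays, Q, tip_states=tips)
        assert count_transitions(small_arrays, asr, tip_states=tips) == {}

    def test_single_divergent_tip(self):
        # one tip flipped on a slowly-evolving background: exactly one change
        ta = as_arrays(pc.simulate_yule_tree(12, 0.3, seed=9))
        tips = {lab: 0 for lab in ta.tip_labels}
        tips[ta.tip_labels[0]] = 1
        Q = np.array([[-0.01, 0.01], [0.01, -0.01]])
        asr = marginal_asr(ta, Q, tip_states=tips)
        counts = count_transitions(ta, asr, tip_states=tips)
        assert sum(counts.values()) == 1
        assert counts == {(0, 1): 1}

    def test_recovers_true_history_at_slow_rates(self):
        # slow 3-state evolution: MAP counting matches the recorded true
        # number of changes in most replicates
        Q = random_rate_matrix(np.random.default_rng(6), 3, 0.005, 0.01)
        hits = 0
        reps = 30
        for seed in range(reps):
            ta = as_arrays(pc.simulate_yule_tree(50, 0.3, seed=1500 + seed))
            tips, changes = pc.simulate_mk_trait(
                ta, Q, seed=1600 + seed, return_changes=True
            )
            asr = marginal_asr(ta, Q, tip_states=tips)
            counted = sum(count_transitions(ta, asr, tip_states=tips).values())
            hits += counted == changes.sum()
        assert hits >= 0.8 * reps


class TestPhyloD:
    def test_constant_trait_rejected(self, small_arrays):
        tips = {lab: 1 for lab in small_arrays.tip_labels}
        with pytest.raises(ValueError):
            phylo_d(small_arrays, tips)

    def test_shuffled_trait_near_one(self):
        rng = np.random.default_rng(7)
        Ds = []
        for rep in range(15):
            ta = as_arrays(pc.simulate_yule_tree(150, 0.2, seed=2000 + rep))
            y = np.zeros(150, int)
            y[:45] = 1
            rng.shuffle(y)
            Ds.append(phylo_d(ta, dict(zip(ta.tip_labels, y)), 500, 500,
                              seed=rep).D)
        assert abs(np.mean(Ds) - 1.0) < 0.2

    def test_clumped_trait_negative_d(self):
        # perfectly clade-restricted trait: more conserved than Brownian
        ta = as_arrays(pc.simulate_yule_tree(80, 0.2, seed=31))
        # mark the tips of one deep subtree
        depth = ta.depths()
        internal = [u for u in range(ta.n_tips, ta.n_nodes - 1)]
        # pick an internal node subtending ~1/4 of the tips
        sizes = {}
        for u in range(ta.n_nodes):
            if u < ta.n_tips:
                sizes[u] = {u}
            else:
                sizes[u] = set().union(*(sizes[v] for v in ta.children[u]))
        cands = [u for u in internal if 10 <= len(sizes[u]) <= 30]
        clade = sizes[cands[0]]
        y = {lab: (1 if i in clade else 0) for i, lab in enumerate(ta.tip_labels)}
        res = phylo_d(ta, y, 500, 500, seed=0)
        assert res.D < 0

    def test_deterministic_given_seed(self, small_arrays):
        y = {lab: i % 2 for i, lab in enumerate(small_arrays.tip_labels)}
        a = phylo_d(small_arrays, y, 200, 200, seed=5)
        b = phylo_d(small_arrays, y, 200, 200, seed=5)
        assert a.D == b.D


class TestBinaryPglmm:
    def test_reduces_to_logistic_at_zero_variance(self):
        rng = np.random.default_rng(8)
        ta = as_arrays(pc.simulate_yule_tree(80, 0.2, seed=40))
        x = rng.normal(size=80)
        y = (rng.random(80) < 1 / (1 + np.exp(-(0.3 + 0.8 * x)))).astype(float)
        pg = pc.binary_pglmm(ta, y, pd.DataFrame({"x": x}), s2_fixed=0.0)
        gl = pc.glm_logistic(y, pd.DataFrame({"x": x}))
        np.testing.assert_allclose(pg.coef.values, gl.coef.values, atol=1e-4)

    def test_star_tree_matches_iid_random_effect_limit(self):
        # star phylogeny: C = I, the model is logistic with iid normal
        # frailty; with s2 -> 0 it collapses to plain logistic
        rng = np.random.default_rng(9)
        n = 100
        C = np.eye(n)
        x = rng.normal(size=n)
        y = (rng.random(n) < 1 / (1 + np.exp(-x))).astype(float)
        pg = pc.binary_pglmm(C, y, pd.DataFrame({"x": x}), s2_fixed=0.0)
        gl = pc.glm_logistic(y, pd.DataFrame({"x": x}))
        np.testing.assert_allclose(pg.coef.values, gl.coef.values, atol=1e-4)

    def test_slope_recovery_with_signal(self):
        ok = 0
        reps = 10
        for rep in range(reps):
            ta = as_arrays(pc.simulate_yule_tree(200, 0.2, seed=3000 + rep))
            C = ta.vcv()
            C /= C.diagonal().mean()
            g = np.random.default_rng(rep)
            b = np.linalg.cholesky(C + 1e-10 * np.eye(200)) @ g.normal(size=200)
            x = g.normal(size=200)
            eta = 1.2 * x + b
            y = (g.random(200) < 1 / (1 + np.exp(-eta))).astype(float)
            res = pc.binary_pglmm(ta, y, pd.DataFrame({"x": x}))
            ok += (res.coef["x"] > 0) and (abs(res.coef["x"] - 1.2) < 3 * res.se["x"])
        assert ok >= 0.9 * reps

    def test_type_one_error_near_nominal(self):
        # data generated from the null model itself (beta1 = 0, s2 = 0.5)
        rej = 0
        n_sims = 200
        for i in range(n_sims):
            ta = as_arrays(pc.simulate_yule_tree(150, 0.2, seed=5000 + i))
            C = ta.vcv()
            C /= C.diagonal().mean()
            g = np.random.default_rng(i)
            b = np.linalg.cholesky(C + 1e-10 * np.eye(150)) @ g.normal(size=150)
            b *= np.sqrt(0.5)
            x = g.normal(size=150)
            y = (g.random(150) < 1 / (1 + np.exp(-b))).astype(float)
            if y.sum() in (0, 150):
                continue
            res = pc.binary_pglmm(ta, y, pd.DataFrame({"x": x}))
            rej += res.p["x"] < 0.05
        assert 0.02 <= rej / n_sims <= 0.10

    def test_variance_nonnegative(self):
        rng = np.random.default_rng(10)
        ta = as_arrays(pc.simulate_yule_tree(60, 0.2, seed=50))
        x = rng.normal(size=60)
        y = rng.integers(0, 2, 60).astype(float)
        res = pc.binary_pglmm(ta, y, pd.DataFrame({"x": x}))
        assert res.s2 >= 0.0


class TestRecoding:
    @staticmethod
    def _coupled_world(seed, n=60, coupling=0.0):
        ta = as_arrays(pc.simulate_yule_tree(n, 0.2, seed=seed))
        rng = np.random.default_rng(seed)
        mapv = rng.uniform(400, 2400, n)
        z = (mapv - mapv.mean()) / mapv.std(ddof=1)
        p_simple = 1 / (1 + np.exp(-(-0.5 + coupling * z)))
        leaf = (rng.random(n) >= p_simple).astype(int)  # 1 = compound
        leaf_map = dict(zip(ta.tip_labels, map(int, leaf)))
        map_map = dict(zip(ta.tip_labels, mapv))
        return ta, leaf_map, map_map

    def test_baseline_significant_short_circuits(self):
        ta, leaf, mapv = self._coupled_world(seed=1, coupling=2.5)
        res = pc.recoding_experiment(ta, leaf, mapv, map_threshold=1250)
        assert res.baseline_significant
        assert res.transitions_needed == res.baseline_transitions
        assert res.n_recoded == 0

    def test_not_achievable_without_candidates(self):
        ta, leaf, mapv = self._coupled_world(seed=2, coupling=0.0)
        low_map = {sp: min(v, 1200.0) for sp, v in mapv.items()}
        res = pc.recoding_experiment(ta, leaf, low_map, map_threshold=1250)
        if not res.baseline_significant:
            assert not res.achieved
            assert res.transitions_needed is None

    def test_moderate_coupling_needs_extra_transitions(self):
        for seed in (3, 4, 5, 6):
            ta, leaf, mapv = self._coupled_world(seed=seed, coupling=0.6)
            res = pc.recoding_experiment(ta, leaf, mapv, map_threshold=1250)
            if res.achieved and not res.baseline_significant:
                assert res.transitions_needed >= res.baseline_transitions
                assert res.trajectory[-1]["p"] < 0.05
                return
        pytest.fail("no replicate exercised the recoding loop")
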