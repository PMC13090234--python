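import math

import numpy as np
import pandas as pd
import pytest

from bdbias import prob, simulate
from bdbias.params import BDParams
from bdbias.simulate import (
    CompleteTree,
    SimOutcome,
    apply_censoring,
    bd_design,
    lhs_design,
    prune_extinct,
    simulate_crown_tree,
    simulate_crown_tree_conditioned,
    stem_tip_count,
)
from bdbias.treeio import parse_newick, write_newick


def three_se(p, n):
    return 3 * math.sqrt(p * (1 - p) / n)


class TestLHS:
    def test_one_sample_per_stratum(self):
        df = lhs_design(4, {"x": (0.0, 1.0)}, seed=0)
        strata = np.floor(df["x"] * 4).astype(int)
        assert sorted(strata) == [0, 1, 2, 3]

    def test_bd_design_mu_column(self):
        df = bd_design(100, seed=1)
        np.testing.assert_allclose(df["mu"], df["lam"] * df["epsilon"])
        assert df["age"].between(0, 10).all()
        assert df["lam"].between(0, 1).all()

    def test_deterministic(self):
        a = lhs_design(50, {"x": (0, 1), "y": (-1, 3)}, seed=9)
        b = lhs_design(50, {"x": (0, 1), "y": (-1, 3)}, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            lhs_design(5, {}, seed=0)
        with pytest.raises(ValueError):
            lhs_design(5, {"x": (1.0, 1.0)}, seed=0)


class TestSimulator:
    def test_no_events_without_rates(self):
        for _ in range(5):
            out = simulate_crown_tree(BDParams(0.0, 0.0), 3.0, seed=1)
            assert out.status == "cherry" and out.n_extant == 2

    def test_yule_mean_tip_count(self):
        rng = np.random.default_rng(11)
        ns = [simulate_crown_tree(BDParams(0.2, 0.0), 5.0, rng).n_extant for _ in range(10000)]
        expect = 2 * math.exp(0.2 * 5)
        # crown tip count is a sum of two independent geometrics
        var = 2 * math.exp(1.0) * (math.exp(1.0) - 1)
        assert abs(np.mean(ns) - expect) < 3 * math.sqrt(var / len(ns))

    def test_crown_survival_fraction(self):
        params = BDParams(0.1, 0.05)
        rng = np.random.default_rng(12)
        outs = [simulate_crown_tree(params, 10.0, rng) for _ in range(20000)]
        surv = np.mean([o.status != "extinct" for o in outs])
        expect = (1 - prob.p_zero(params, 10.0)) ** 2
        assert abs(surv - expect) < three_se(expect, len(outs))

    def test_conditional_cherry_fraction(self):
        params = BDParams(0.1, 0.05)
        rng = np.random.default_rng(13)
        outs = [simulate_crown_tree(params, 10.0, rng) for _ in range(20000)]
        alive = [o for o in outs if o.status != "extinct"]
        frac = np.mean([o.status == "cherry" for o in alive])
        expect = prob.p_one(params, 10.0) ** 2 / (1 - prob.p_zero(params, 10.0)) ** 2
        assert abs(frac - expect) < three_se(expect, len(alive))

    def test_yule_tip_count_distribution(self):
        lam, t = 0.5, 1.0
        rng = np.random.default_rng(14)
        ns = np.array([simulate_crown_tree(BDParams(lam, 0.0), t, rng).n_extant
                       for _ in range(50000)])
        for n in range(2, 9):
            expect = prob.p_n_yule(n, lam, t)
            assert abs(np.mean(ns == n) - expect) < three_se(expect, ns.size)

    def test_critical_stem_tip_count_distribution(self):
        lam, t = 0.5, 2.0  # lam*t = 1: P_n = 1 / 2^{n+1}
        rng = np.random.default_rng(15)
        ns = np.array([stem_tip_count(BDParams(lam, lam), t, rng) for _ in range(20000)])
        for n in range(0, 6):
            expect = prob.p_n_critical(n, lam, t)
            assert abs(np.mean(ns == n) - expect) < three_se(expect, ns.size)

    def test_usable_trees_are_valid(self):
        rng = np.random.default_rng(16)
        checked = 0
        while checked < 20:
            out = simulate_crown_tree(BDParams(0.4, 0.2), 6.0, rng)
            if out.status != "usable":
                continue
            tree = out.tree
            assert tree.n == out.n_extant > 2
            again = parse_newick(write_newick(tree))
            assert again.n == tree.n and again.s == pytest.approx(tree.s, abs=1e-9)
            checked += 1

    def test_rejects_nonpositive_age(self):
        with pytest.raises(ValueError):
            simulate_crown_tree(BDParams(0.1, 0.0), 0.0, seed=0)

    def test_reproducible_from_seed(self):
        a = simulate_crown_tree(BDParams(0.3, 0.1), 8.0, seed=99)
        b = simulate_crown_tree(BDParams(0.3, 0.1), 8.0, seed=99)
        assert a.status == b.status and a.n_extant == b.n_extant
        if a.tree is not None:
            np.testing.assert_array_equal(a.tree.age, b.tree.age)

    def test_conditioned_simulation_always_survives(self):
        for seed in range(5):
            out = simulate_crown_tree_conditioned(BDParams(0.2, 0.15), 5.0, seed=seed)
            assert out is not None and out.status in ("cherry", "usable")


class TestPrune:
    def test_hand_built_complete_tree(self):
        # crown at age 3; lineage 0 speciates at t=1 into (2, 3); lineage 3
        # goes extinct at t=2; lineage 1 survives.  Reconstructed tree:
        # 3 tips? no - lineage 3 extinct leaves (0->2) chain collapsed.
        complete = CompleteTree(
            age=3.0,
            parent=np.array([-1, -1, 0, 0]),
            t_start=np.array([0.0, 0.0, 1.0, 1.0]),
            t_end=np.array([1.0, 3.0, 3.0, 2.0]),
            fate=np.array([2, 0, 0, 1], dtype=np.int8),
        )
        tree = prune_extinct(complete)
        assert tree.n == 2  # cherry: one tip per crown side
        assert tree.crown_age == pytest.approx(3.0)
        assert tree.s == pytest.approx(6.0)

    def test_four_tip_with_one_extinction(self):
        # both crown lineages speciate; one grandchild dies -> 3-tip tree
        complete = CompleteTree(
            age=4.0,
            parent=np.array([-1, -1, 0, 0, 1, 1]),
            t_start=np.array([0.0, 0.0, 1.0, 1.0, 2.0, 2.0]),
            t_end=np.array([1.0, 2.0, 4.0, 4.0, 4.0, 3.0]),
            fate=np.array([2, 2, 0, 0, 0, 1], dtype=np.int8),
        )
        tree = prune_extinct(complete)
        assert tree.n == 3
        # edges: crown->node(age 3) = 1, node->two tips = 3+3, crown->tip = 4
        assert tree.s == pytest.approx(1.0 + 3.0 + 3.0 + 4.0)
        np.testing.assert_allclose(tree.branching_times, [4.0, 3.0])

    def test_dead_crown_side_gives_none(self):
        complete = CompleteTree(
            age=2.0,
            parent=np.array([-1, -1]),
            t_start=np.array([0.0, 0.0]),
            t_end=np.array([1.0, 2.0]),
            fate=np.array([1, 0], dtype=np.int8),
        )
        assert prune_extinct(complete) is None

    def test_no_extinction_is_identity(self):
        rng = np.random.default_rng(17)
        while True:
            out = simulate_crown_tree(BDParams(0.5, 0.0), 3.0, rng, keep_complete=True)
            if out.status == "usable":
                break
        assert out.tree.n == out.complete.n_extant
        assert out.tree.s == pytest.approx(
            np.sum(out.complete.t_end - out.complete.t_start), abs=1e-9
        )


class TestCensoring:
    def _outcomes(self):
        mk = lambda status, n: SimOutcome(status=status, tree=None, n_extant=n)
        return [mk("extinct", 0), mk("cherry", 2), mk("usable", 5)]

    def test_rules(self):
        outs = self._outcomes()
        assert [o.status for o in apply_censoring(outs, "n_gt_2")] == ["usable"]
        assert [o.status for o in apply_censoring(outs, "survival")] == ["cherry", "usable"]
        with pytest.raises(ValueError):
            apply_censoring(outs, "bogus")

    def test_yule_retention_matches_theory(self):
        # retained fraction under n>2 censoring ~ design average of 1 - e^{-2 lam t}
        design = lhs_design(5000, {"age": (0, 5), "lam": (0, 0.5)}, seed=21)
        outcomes = simulate.simulate_design(design, master_seed=22)
        kept = len(apply_censoring(outcomes, "n_gt_2"))
        p = 1 - np.exp(-2 * design["lam"] * design["age"])
        expect = p.mean()
        se = math.sqrt(np.sum(p * (1 - p))) / len(design)
        assert abs(kept / len(design) - expect) < 3 * se
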