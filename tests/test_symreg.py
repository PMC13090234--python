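import numpy as np
import pandas as pd
import pytest

from bdbias import symreg
from bdbias.symreg import (
    BinOp,
    Const,
    ExpressionCandidate,
    Leaf,
    build_grammar,
    candidate_fingerprint,
    enumerate_expressions,
    huber_raw_score,
    make_candidate,
    rank_alpha_grid,
    score_candidates,
    score_expression,
)


def f1():
    return Leaf("f1")


def f2():
    return Leaf("f2")


def synthetic_dataset(rng, n_rows=2000, factor=None, noise=0.0, eps=False):
    n = rng.integers(3, 120, n_rows).astype(float)
    theta_hat = rng.uniform(0.05, 1.0, n_rows)
    cols = {"theta_hat": theta_hat, "n": n}
    if eps:
        cols["eps_hat"] = rng.uniform(0, 1, n_rows)
    mult = factor(n) if factor is not None else 1.0
    cols["theta_true"] = theta_hat * mult + rng.normal(0, noise, n_rows)
    return pd.DataFrame(cols)


class TestGrammar:
    def test_variable_sets(self):
        assert "eps" not in build_grammar("lambda").leaf_tokens
        assert "eps" in build_grammar("mu").leaf_tokens
        assert "eps" in build_grammar("netdiv").leaf_tokens
        with pytest.raises(ValueError):
            build_grammar("gamma")

    def test_depth_two_lambda_forms(self):
        cands = enumerate_expressions(build_grammar("lambda"), 2)
        canon = {c.canonical for c in cands}
        # the sample-size ratio corrections and the bare estimator
        assert {"lambda_hat", "lambda_hat*(n-1)/(n-2)", "lambda_hat*n/(n-1)"} <= canon
        assert all(c.depth <= 2 for c in cands)

    def test_multiplying_by_one_collapses(self):
        cands = enumerate_expressions(build_grammar("lambda"), 4)
        plain = next(c for c in cands if c.canonical == "lambda_hat*(n-1)/(n-2)")
        with_one = make_candidate("lambda", BinOp("*", f1(), Const(1)))
        assert candidate_fingerprint(with_one) == candidate_fingerprint(plain)
        assert sum(
            candidate_fingerprint(c) == candidate_fingerprint(plain) for c in cands
        ) == 1

    def test_mu_grammar_generates_winning_correction(self):
        cands = enumerate_expressions(build_grammar("mu"), 4)
        target = make_candidate("mu", BinOp("+", f2(), Leaf("eps")))
        key = candidate_fingerprint(target)
        matches = [c for c in cands if candidate_fingerprint(c) == key]
        assert len(matches) == 1 and matches[0].depth == 4

    def test_depth_bookkeeping(self):
        assert make_candidate("mu", None).depth == 1
        assert make_candidate("mu", Const(2)).depth == 2
        assert make_candidate("mu", BinOp("/", Const(2), f1())).depth == 3
        assert make_candidate("mu", Leaf("eps")).depth == 3
        assert make_candidate("mu", BinOp("+", f2(), Leaf("eps"))).depth == 4

    def test_enumeration_deterministic(self):
        a = [c.canonical for c in enumerate_expressions(build_grammar("mu"), 4)]
        b = [c.canonical for c in enumerate_expressions(build_grammar("mu"), 4)]
        assert a == b

    def test_depth_guard(self):
        with pytest.raises(ValueError):
            enumerate_expressions(build_grammar("lambda"), 5)


class TestScoring:
    def test_perfect_correction_scores_zero(self):
        rng = np.random.default_rng(0)
        data = synthetic_dataset(rng, factor=lambda n: (n - 1) / (n - 2))
        cand = make_candidate("lambda", f1())
        assert score_expression(cand, data) == pytest.approx(0.0, abs=1e-12)
        assert cand.slope == pytest.approx(1.0, abs=1e-8)
        assert cand.resid_score == pytest.approx(0.0, abs=1e-12)

    def test_known_factor_recovered_from_noisy_data(self):
        rng = np.random.default_rng(1)
        data = synthetic_dataset(rng, factor=lambda n: (n - 1) / (n - 2), noise=0.01)
        cands = enumerate_expressions(build_grammar("lambda"), 4)
        score_candidates(cands, data)
        winner = rank_alpha_grid(cands, (0.0, 0.02)).winner_at(0.0)
        target = make_candidate("lambda", f1())
        assert candidate_fingerprint(winner) == candidate_fingerprint(target)

    def test_non_finite_rows_disqualify(self):
        data = pd.DataFrame({"theta_hat": [0.1, 0.2], "n": [2.0, 5.0],
                             "theta_true": [0.1, 0.2]})
        cand = make_candidate("lambda", f1())  # divides by n-2 = 0
        assert score_expression(cand, data) == np.inf

    def test_residual_ranking_scale_invariant(self):
        rng = np.random.default_rng(2)
        data = synthetic_dataset(rng, factor=lambda n: (n - 1) / (n - 2), noise=0.02)
        doubled = data.copy()
        doubled["theta_hat"] *= 2
        doubled["theta_true"] *= 2
        cands = [make_candidate("lambda", c) for c in
                 (f1(), f2(), Const(2), BinOp("*", f1(), f2()), None)]
        for d in (data, doubled):
            for c in cands:
                score_expression(c, d)
        ranks_a = np.argsort([c.resid_score for c in cands])
        for c in cands:
            score_expression(c, doubled)
        ranks_b = np.argsort([c.resid_score for c in cands])
        np.testing.assert_array_equal(ranks_a, ranks_b)

    def test_huber_raw_score_basics(self):
        assert huber_raw_score(np.zeros(100)) == 0.0
        assert huber_raw_score(np.array([0.0, np.inf])) == np.inf
        clean = np.random.default_rng(3).normal(0, 1, 2000)
        spiked = clean.copy()
        spiked[:20] += 50
        # the robust loss grows far slower than the squared loss under spikes
        assert huber_raw_score(spiked) < 1.5 * huber_raw_score(clean) + 1.0


class TestAlphaRanking:
    def _scored(self, raws_by_depth):
        cands = []
        for depth, raw in raws_by_depth:
            c = make_candidate("lambda", None)
            c.depth = depth
            c.canonical = f"expr_d{depth}_{raw}"
            c.raw_score = raw
            cands.append(c)
        return cands

    def test_breakpoints_at_analytic_crossings(self):
        cands = self._scored([(1, 0.10), (2, 0.04), (3, 0.01)])
        ranking = rank_alpha_grid(cands, (0.0, 0.1), n_grid=5000)
        # depth3 wins until (0.04-0.01)/(3-2)=0.03, depth2 until 0.06, then depth1
        assert [iv.candidate.depth for iv in ranking.intervals] == [3, 2, 1]
        assert ranking.intervals[0].alpha_max == pytest.approx(0.03, abs=1e-4)
        assert ranking.intervals[1].alpha_max == pytest.approx(0.06, abs=1e-4)

    def test_intervals_partition_range(self):
        cands = self._scored([(1, 0.2), (2, 0.05), (4, 0.01)])
        ranking = rank_alpha_grid(cands, (0.0, 0.5))
        assert ranking.intervals[0].alpha_min == 0.0
        assert ranking.intervals[-1].alpha_max == 0.5
        for prev, nxt in zip(ranking.intervals, ranking.intervals[1:]):
            assert prev.alpha_max == nxt.alpha_min
        assert ranking.intervals[0].omega_max == pytest.approx(
            ranking.intervals[0].alpha_max * ranking.intervals[0].candidate.depth
        )

    def test_penalized_monotone_in_alpha(self):
        c = self._scored([(3, 0.02)])[0]
        alphas = np.linspace(0, 1, 11)
        vals = [c.penalized(a) for a in alphas]
        assert np.all(np.diff(vals) > 0)

    def test_tie_break_is_lexicographic(self):
        a = make_candidate("lambda", None)
        a.depth, a.raw_score, a.canonical = 2, 0.05, "aaa"
        b = make_candidate("lambda", None)
        b.depth, b.raw_score, b.canonical = 2, 0.05, "bbb"
        ranking = rank_alpha_grid([a, b], (0.0, 0.1))
        assert ranking.winner_at(0.05).canonical == "aaa"

    def test_to_frame_columns(self):
        cands = self._scored([(1, 0.1), (2, 0.01)])
        frame = rank_alpha_grid(cands, (0.0, 0.2)).to_frame()
        assert list(frame.columns) == [
            "expression", "depth", "raw_score", "alpha_min", "alpha_max",
            "omega_min", "omega_max",
        ]
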