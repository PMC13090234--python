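"""Grammar-based exhaustive symbolic regression for bias corrections.

The search space is the set of multiplicative corrections
``theta_corr = theta_hat * c(.)`` where ``c`` is a dimensionless expression
built from:

* ``n`` — tip count;
* the primitive sample-size ratios ``f1 = (n-1)/(n-2)`` and ``f2 = n/(n-1)``;
* the estimated extinction fraction ``eps_hat`` (mu/netdiv targets only);
* the constants 0.5, 1, 2;
* the four arithmetic operators.

The multiplicative form guarantees every candidate carries the target's rate
units.  Expression depth counts each leaf as 1 — except ``eps_hat``, which
counts 2 because it is itself the composite ``mu_hat/lambda_hat`` — and each
operator adds one level; a bare ``theta_hat`` has depth 1.

``c`` composes at most one arithmetic operation over those tokens: the
correction space is the set of primitive ratios and their pairwise
combinations, which spans every closed-form correction of interest while
keeping the exhaustive search free of arbitrarily fine interpolating
expressions.

Each candidate is scored by fitting a robust (Huber, tuning 1.345, MAD
scale) regression of its output on the generating values and taking the
squared deviation of the fitted line from the 1:1 relationship,
``raw = (slope - 1)^2 + intercept^2``; candidates are then ranked under the
complexity penalty ``Omega = alpha * depth`` across a dense alpha grid.  The
mean per-point Huber loss of the 1:1 residuals is also recorded for audit
(it is dominated by single-tree estimator noise and is not used for
ranking).
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .corrections import HUBER_T, huber_regression

__all__ = [
    "Expr",
    "Leaf",
    "Const",
    "BinOp",
    "Grammar",
    "ExpressionCandidate",
    "AlphaInterval",
    "AlphaRanking",
    "build_grammar",
    "enumerate_expressions",
    "make_candidate",
    "score_expression",
    "score_candidates",
    "huber_raw_score",
    "rank_alpha_grid",
]

MAX_DEPTH_LIMIT = 4  # the space grows combinatorially beyond this

_THETA_SYMBOL = {"lambda": "lambda_hat", "mu": "mu_hat", "netdiv": "r_hat"}

#: leaf token -> (display, depth); eps_hat is the composite mu_hat/lambda_hat
_LEAF_INFO = {
    "n": ("n", 1),
    "f1": ("(n-1)/(n-2)", 1),
    "f2": ("n/(n-1)", 1),
    "eps": ("eps_hat", 2),
}


class Expr:
    __slots__ = ("depth", "canonical")

    def evaluate(self, env: Dict[str, np.ndarray]) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Leaf(Expr):
    __slots__ = ("token",)

    def __init__(self, token: str):
        display, depth = _LEAF_INFO[token]
        self.token = token
        self.depth = depth
        self.canonical = display

    def evaluate(self, env):
        return env[self.token]


class Const(Expr):
    __slots__ = ("value",)

    def __init__(self, value: float):
        self.value = float(value)
        self.depth = 1
        self.canonical = f"{value:g}"

    def evaluate(self, env):
        return np.full_like(env["n"], self.value)


_OPS = {
    "+": np.add,
    "-": np.subtract,
    "*": np.multiply,
    "/": np.divide,
}


class BinOp(Expr):
    __slots__ = ("op", "left", "right")

    def __init__(self, op: str, left: Expr, right: Expr):
        self.op = op
        self.left = left
        self.right = right
        self.depth = 1 + max(left.depth, right.depth)
        self.canonical = f"({left.canonical}{op}{right.canonical})"

    def evaluate(self, env):
        with np.errstate(all="ignore"):
            return _OPS[self.op](self.left.evaluate(env), self.right.evaluate(env))


@dataclass(frozen=True)
class Grammar:
    target: str  # "lambda" | "mu" | "netdiv"
    leaf_tokens: Tuple[str, ...]
    constants: Tuple[float, ...] = (0.5, 1.0, 2.0)

    @property
    def theta_symbol(self) -> str:
        return _THETA_SYMBOL[self.target]


def build_grammar(target: str) -> Grammar:
    """Variable set for one correction target.

    ``eps_hat`` is included only for extinction and net diversification: the
    winning mu correction requires it, while the speciation search mirrors
    the Yule variable set.
    """
    if target not in _THETA_SYMBOL:
        raise ValueError(f"unknown target {target!r}")
    tokens = ("n", "f1", "f2") + (("eps",) if target in ("mu", "netdiv") else ())
    return Grammar(target=target, leaf_tokens=tokens)


class ExpressionCandidate:
    """A multiplicative correction ``theta_hat * c`` (or bare ``theta_hat``)."""

    __slots__ = ("target", "c_expr", "canonical", "depth", "raw_score",
                 "slope", "intercept", "resid_score")

    def __init__(self, target: str, c_expr: Optional[Expr]):
        self.target = target
        self.c_expr = c_expr
        sym = _THETA_SYMBOL[target]
        if c_expr is None:
            self.canonical = sym
            self.depth = 1
        else:
            self.canonical = f"{sym}*{c_expr.canonical}"
            self.depth = 1 + c_expr.depth
        self.raw_score: Optional[float] = None
        self.slope: Optional[float] = None
        self.intercept: Optional[float] = None
        self.resid_score: Optional[float] = None

    def __repr__(self):
        return f"<ExpressionCandidate {self.canonical} depth={self.depth} raw={self.raw_score}>"

    def output(self, env: Dict[str, np.ndarray]) -> np.ndarray:
        theta = env["theta"]
        if self.c_expr is None:
            return theta
        with np.errstate(all="ignore"):
            return theta * self.c_expr.evaluate(env)

    def penalized(self, alpha: float) -> float:
        if self.raw_score is None:
            raise ValueError("candidate has not been scored")
        return self.raw_score + alpha * self.depth

    def sort_key(self):
        return (self.depth, self.canonical)


def make_candidate(target: str, c_expr: Optional[Expr]) -> ExpressionCandidate:
    return ExpressionCandidate(target, c_expr)


# -- probe fingerprints -----------------------------------------------------------

_PROBE_RNG = np.random.default_rng(170_459)
_N_PROBES = 64
_PROBES = {
    "n": _PROBE_RNG.integers(3, 200, _N_PROBES).astype(float),
    "theta": _PROBE_RNG.uniform(0.01, 2.0, _N_PROBES),
    "eps": _PROBE_RNG.uniform(0.0, 1.0, _N_PROBES),
}
_PROBES["f1"] = (_PROBES["n"] - 1) / (_PROBES["n"] - 2)
_PROBES["f2"] = _PROBES["n"] / (_PROBES["n"] - 1)


def _fingerprint(values: np.ndarray) -> Optional[bytes]:
    """Hashable key identifying a candidate by its values on the probe set.

    Mantissas are rounded so evaluations agreeing to ~1e-10 relative collapse
    to one key; non-finite candidates return None (disqualified).
    """
    if not np.all(np.isfinite(values)):
        return None
    values = values + 0.0  # normalize -0.0
    mant, expo = np.frexp(values)
    return np.round(mant, 10).tobytes() + expo.astype(np.int32).tobytes()


def candidate_fingerprint(cand: ExpressionCandidate) -> Optional[bytes]:
    return _fingerprint(cand.output(_PROBES))


# -- enumeration ------------------------------------------------------------------


def enumerate_expressions(grammar: Grammar, max_depth: int) -> List[ExpressionCandidate]:
    """All admissible multiplicative corrections up to ``max_depth``.

    Complete enumeration of the grammar followed by fingerprint
    deduplication: candidates agreeing on 64 random probe points collapse to
    the representative with the smallest (depth, canonical string).  The
    output is sorted by that key, so enumeration is deterministic.
    """
    if not 1 <= max_depth <= MAX_DEPTH_LIMIT:
        raise ValueError(
            f"max_depth must be in [1, {MAX_DEPTH_LIMIT}]: the expression space "
            "grows combinatorially with depth"
        )
    leaves: List[Expr] = [Leaf(t) for t in grammar.leaf_tokens]
    leaves += [Const(v) for v in grammar.constants]
    pool: List[Expr] = list(leaves)
    for op in "+-*/":
        for a in leaves:
            for b in leaves:
                pool.append(BinOp(op, a, b))

    candidates = [ExpressionCandidate(grammar.target, None)]
    candidates += [ExpressionCandidate(grammar.target, c) for c in pool
                   if 1 + c.depth <= max_depth]

    unique: Dict[bytes, ExpressionCandidate] = {}
    for cand in candidates:
        key = candidate_fingerprint(cand)
        if key is None:
            continue
        kept = unique.get(key)
        if kept is None or cand.sort_key() < kept.sort_key():
            unique[key] = cand
    return sorted(unique.values(), key=ExpressionCandidate.sort_key)


# -- scoring ----------------------------------------------------------------------


def huber_raw_score(resid: np.ndarray) -> float:
    """Mean Huber loss of 1:1-line residuals, on the squared-deviation scale.

    Residuals are standardized by their MAD; the mean of
    ``rho(resid/scale)`` is mapped back by ``scale^2`` so the score has the
    units of a (robustified) half mean-squared deviation.  Non-finite
    residuals disqualify the candidate (infinite score).
    """
    resid = np.asarray(resid, dtype=float)
    if resid.size == 0:
        raise ValueError("empty residual vector")
    if not np.all(np.isfinite(resid)):
        return float("inf")
    scale = np.median(np.abs(resid - np.median(resid))) / 0.6744897501960817
    if scale == 0.0:
        return float(0.5 * np.mean(resid**2))
    u = resid / scale
    au = np.abs(u)
    rho = np.where(au <= HUBER_T, 0.5 * u * u, HUBER_T * au - 0.5 * HUBER_T * HUBER_T)
    return float(np.mean(rho) * scale * scale)


def _env_from_dataset(dataset) -> Tuple[Dict[str, np.ndarray], np.ndarray]:
    n = np.asarray(dataset["n"], dtype=float)
    with np.errstate(all="ignore"):  # n=2 rows yield inf and disqualify later
        env = {
            "theta": np.asarray(dataset["theta_hat"], dtype=float),
            "n": n,
            "f1": (n - 1) / (n - 2),
            "f2": n / (n - 1),
        }
    if "eps_hat" in dataset:
        env["eps"] = np.asarray(dataset["eps_hat"], dtype=float)
    return env, np.asarray(dataset["theta_true"], dtype=float)


def score_expression(cand: ExpressionCandidate, dataset) -> float:
    """Score one candidate against the generating values (in place).

    ``dataset`` is a mapping/DataFrame with columns ``theta_hat``, ``n``,
    ``theta_true`` and (for mu/netdiv) ``eps_hat``.  Fits the robust Huber
    regression of the candidate output on the truth; the raw score is the
    squared deviation of that line from the 1:1 relationship.  A candidate
    producing any non-finite value is disqualified (infinite score).  The
    per-point Huber loss of the 1:1 residuals is stored as ``resid_score``.
    """
    env, truth = _env_from_dataset(dataset)
    out = cand.output(env)
    if not np.all(np.isfinite(out)):
        cand.raw_score = float("inf")
        return cand.raw_score
    cand.resid_score = huber_raw_score(out - truth)
    try:
        with warnings.catch_warnings():
            # degenerate candidates (e.g. identically-zero output) trip RLM's
            # perfect-fit warnings; they score poorly regardless
            warnings.simplefilter("ignore")
            cand.intercept, cand.slope = huber_regression(truth, out)
    except Exception:
        cand.raw_score = float("inf")
        return cand.raw_score
    cand.raw_score = (cand.slope - 1.0) ** 2 + cand.intercept**2
    return cand.raw_score


def score_candidates(candidates: Sequence[ExpressionCandidate], dataset) -> None:
    """Score a whole candidate list (in place)."""
    for cand in candidates:
        score_expression(cand, dataset)


# -- alpha ranking ----------------------------------------------------------------


@dataclass(frozen=True)
class AlphaInterval:
    candidate: ExpressionCandidate
    alpha_min: float
    alpha_max: float

    @property
    def omega_min(self) -> float:
        return self.alpha_min * self.candidate.depth

    @property
    def omega_max(self) -> float:
        return self.alpha_max * self.candidate.depth


@dataclass(frozen=True)
class AlphaRanking:
    intervals: Tuple[AlphaInterval, ...]
    alpha_grid: np.ndarray

    def winner_at(self, alpha: float) -> ExpressionCandidate:
        for iv in self.intervals:
            if iv.alpha_min <= alpha <= iv.alpha_max:
                return iv.candidate
        raise ValueError(f"alpha={alpha} outside the ranked range")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "expression": [iv.candidate.canonical for iv in self.intervals],
                "depth": [iv.candidate.depth for iv in self.intervals],
                "raw_score": [iv.candidate.raw_score for iv in self.intervals],
                "alpha_min": [iv.alpha_min for iv in self.intervals],
                "alpha_max": [iv.alpha_max for iv in self.intervals],
                "omega_min": [iv.omega_min for iv in self.intervals],
                "omega_max": [iv.omega_max for iv in self.intervals],
            }
        )


def rank_alpha_grid(candidates: Sequence[ExpressionCandidate],
                    alpha_range: Tuple[float, float],
                    n_grid: int = 5000) -> AlphaRanking:
    """Top-ranked expression across a dense grid of complexity penalties.

    For each alpha the winner minimizes ``raw_score + alpha * depth``; ties
    break toward smaller depth, then lexicographic canonical string.  Runs of
    the same winner are reported as contiguous alpha intervals that partition
    the range.
    """
    if n_grid < 2:
        raise ValueError("n_grid must be >= 2")
    scored = [c for c in candidates if c.raw_score is not None and math.isfinite(c.raw_score)]
    if not scored:
        raise ValueError("no scored candidates")
    # only the best candidate at each depth can ever win
    best_by_depth: Dict[int, ExpressionCandidate] = {}
    for c in scored:
        cur = best_by_depth.get(c.depth)
        if cur is None or (c.raw_score, c.canonical) < (cur.raw_score, cur.canonical):
            best_by_depth[c.depth] = c
    contenders = [best_by_depth[d] for d in sorted(best_by_depth)]

    lo, hi = alpha_range
    grid = np.linspace(lo, hi, n_grid)
    raw = np.array([c.raw_score for c in contenders])
    depth = np.array([c.depth for c in contenders])
    penal = raw[:, None] + depth[:, None] * grid[None, :]
    winners = np.empty(n_grid, dtype=int)
    idx = list(range(len(contenders)))
    for j in range(n_grid):
        col = penal[:, j]
        winners[j] = min(idx, key=lambda i: (col[i], depth[i], contenders[i].canonical))

    intervals: List[AlphaInterval] = []
    start = 0
    for j in range(1, n_grid + 1):
        if j == n_grid or winners[j] != winners[start]:
            cand = contenders[winners[start]]
            a_min = grid[start] if intervals else lo
            a_max = grid[j] if j < n_grid else hi
            intervals.append(AlphaInterval(candidate=cand, alpha_min=float(a_min),
                                           alpha_max=float(a_max)))
            start = j
    return AlphaRanking(intervals=tuple(intervals), alpha_grid=grid)
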