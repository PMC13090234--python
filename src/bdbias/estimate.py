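"""Maximum-likelihood estimation of birth-death rates.

The two-parameter fit works in the (log turnover, extinction fraction)
parameterization — ``tau = lam + mu``, ``epsilon = mu / lam`` — and
back-transforms to (lam, mu).  This decorrelates the parameters relative to
raw (lam, mu) and keeps the near-critical ridge away from the search
interior.  Optimization is derivative-free (Nelder-Mead) from several
Latin-hypercube starting points; the best restart wins.

Cherry trees (n = 2) are refused outright: they contain a single waiting
time, and the two-parameter likelihood has no interior maximum on them, so
speciation and extinction are not separately identifiable.
"""
from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import optimize

from .likelihoods import ConditionRule, bd_loglik_branch, yule_loglik, yule_mle_closed
from .params import BDParams
from .treeio import ReconstructedTree

__all__ = ["EstimateResult", "NonIdentifiableError", "fit_bd", "fit_yule", "hessian_check"]

LOG_TAU_BOUNDS = (math.log(1e-6), math.log(1e3))
EPS_BOUNDS = (1e-9, 0.999999)


class NonIdentifiableError(ValueError):
    """Raised when a tree cannot identify the requested parameters."""


@dataclass(frozen=True)
class EstimateResult:
    tau_hat: float
    eps_hat: float
    lambda_hat: float
    mu_hat: float
    r_hat: float
    loglik_at_max: float
    converged: bool
    hessian_valid: Optional[bool]
    n: int
    condition: ConditionRule
    #: optimum pinned at a search-box boundary (a constrained maximum; the
    #: negative-variance diagnostic is undefined there)
    at_bound: Optional[bool] = None

    @classmethod
    def from_tau_eps(cls, tau: float, eps: float, loglik: float, converged: bool,
                     n: int, condition: ConditionRule) -> "EstimateResult":
        lam = tau / (1.0 + eps)
        mu = tau - lam
        interior = (EPS_BOUNDS[0] * 1.001 < eps < 0.9999
                    and math.exp(LOG_TAU_BOUNDS[0]) * 1.1 < tau < math.exp(LOG_TAU_BOUNDS[1]) * 0.9)
        return cls(tau_hat=tau, eps_hat=eps, lambda_hat=lam, mu_hat=mu,
                   r_hat=lam - mu, loglik_at_max=loglik, converged=converged,
                   hessian_valid=None, n=n, condition=ConditionRule(condition),
                   at_bound=not interior)


def _neg_loglik_factory(tree: ReconstructedTree, condition: ConditionRule):
    """Lean closure over precomputed branch arrays for the optimizer loop.

    Algebraically identical to ``-bd_loglik_branch`` (asserted by the test
    suite); the bounds keep eps strictly below 1, so the near-critical
    dispatch can never trigger inside the search box.
    """
    t_root = tree.branch_rootward_ages
    t_tip = tree.branch_tipward_ages
    s = tree.s
    t_crown = tree.crown_age
    m = tree.m
    survival = condition is ConditionRule.SURVIVAL
    n_gt_2 = condition is ConditionRule.N_GT_2
    log = np.log
    exp = np.exp

    def neg(theta) -> float:
        log_tau, eps = theta
        tau = math.exp(log_tau)
        lam = tau / (1.0 + eps)
        mu = tau - lam
        r = lam - mu
        with np.errstate(all="ignore"):
            core = (
                -r * s
                + 2.0 * log(np.abs(lam - mu * exp(-r * t_tip))).sum()
                - 2.0 * log(np.abs(lam - mu * exp(-r * t_root))).sum()
            )
            if survival or n_gt_2:
                x = -r * t_crown
                if x > 700.0:  # supercritical runaway; reject smoothly via inf
                    return np.inf
                ert = math.exp(x)
                denom = lam - mu * ert
                surv = r / denom
                div = surv * surv
                if n_gt_2:
                    p1 = r * r * ert / (denom * denom)
                    div -= p1 * p1
                ll = core + (m - 1) * (log_tau - math.log1p(eps)) \
                    - math.log(max(div, 1e-300))
            else:
                ll = core + m * (log_tau - math.log1p(eps))
        if not np.isfinite(ll):
            return np.inf
        return -ll

    return neg


def _restart_points(tree: ReconstructedTree, n_restarts: int, seed: int,
                    eps_bounds) -> np.ndarray:
    """Latin-hypercube starting points inside the bounds.

    The log-turnover strata are centred on the crude Yule rate scale
    (n-2)/s so restarts begin at plausible magnitudes.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(tree.n, 0)))
    scale = max(yule_mle_closed(tree), 1.0 / max(tree.s, 1e-12))
    lo = max(LOG_TAU_BOUNDS[0], math.log(scale) - math.log(10.0))
    hi = min(LOG_TAU_BOUNDS[1], math.log(scale) + math.log(20.0))
    pts = np.empty((n_restarts, 2))
    for j, (a, b) in enumerate(((lo, hi), eps_bounds)):
        strata = rng.permutation(n_restarts)
        pts[:, j] = a + (strata + rng.random(n_restarts)) * (b - a) / n_restarts
    return pts


def _nelder_mead_2d(f, x0, bounds, xatol=1e-6, fatol=1e-8, maxiter=400):
    """Minimal bounded Nelder-Mead for the 2-d rate problem.

    The scipy wrapper spends more time in bookkeeping than in the objective
    for trees this small, so the simplex loop is inlined; iterates are
    clipped to the box.  Returns (x, fx, converged).
    """
    lo = [bounds[0][0], bounds[1][0]]
    hi = [bounds[0][1], bounds[1][1]]

    def clip(x):
        return [min(max(x[0], lo[0]), hi[0]), min(max(x[1], lo[1]), hi[1])]

    sim = [clip(list(x0))]
    for k in range(2):
        y = list(sim[0])
        step = 0.05 * (hi[k] - lo[k])
        y[k] = y[k] + step if y[k] + step <= hi[k] else y[k] - step
        sim.append(y)
    fs = [f(p) for p in sim]
    converged = False
    for _ in range(maxiter):
        order = sorted(range(3), key=fs.__getitem__)
        sim = [sim[i] for i in order]
        fs = [fs[i] for i in order]
        if (abs(fs[2] - fs[0]) <= fatol
                and max(abs(sim[2][0] - sim[0][0]), abs(sim[2][1] - sim[0][1]),
                        abs(sim[1][0] - sim[0][0]), abs(sim[1][1] - sim[0][1])) <= xatol):
            converged = True
            break
        cx = 0.5 * (sim[0][0] + sim[1][0])
        cy = 0.5 * (sim[0][1] + sim[1][1])
        xr = clip([2 * cx - sim[2][0], 2 * cy - sim[2][1]])
        fr = f(xr)
        if fr < fs[0]:
            xe = clip([3 * cx - 2 * sim[2][0], 3 * cy - 2 * sim[2][1]])
            fe = f(xe)
            if fe < fr:
                sim[2], fs[2] = xe, fe
            else:
                sim[2], fs[2] = xr, fr
        elif fr < fs[1]:
            sim[2], fs[2] = xr, fr
        else:
            if fr < fs[2]:
                xc = clip([1.5 * cx - 0.5 * sim[2][0], 1.5 * cy - 0.5 * sim[2][1]])
            else:
                xc = clip([0.5 * cx + 0.5 * sim[2][0], 0.5 * cy + 0.5 * sim[2][1]])
            fc = f(xc)
            if fc < min(fr, fs[2]):
                sim[2], fs[2] = xc, fc
            else:  # shrink toward the best vertex
                for k in (1, 2):
                    sim[k] = clip([0.5 * (sim[k][0] + sim[0][0]),
                                   0.5 * (sim[k][1] + sim[0][1])])
                    fs[k] = f(sim[k])
    order = sorted(range(3), key=fs.__getitem__)
    return sim[order[0]], fs[order[0]], converged


def fit_bd(tree: ReconstructedTree, condition=ConditionRule.N_GT_2, *,
           seed: int = 0, n_restarts: int = 5, check_hessian: bool = False,
           eps_bounds=EPS_BOUNDS) -> EstimateResult:
    """Maximize the branch-product birth-death likelihood over (log tau, eps)."""
    condition = ConditionRule(condition)
    if tree.n <= 2:
        raise NonIdentifiableError(
            "cherry trees cannot identify speciation and extinction separately"
        )
    neg = _neg_loglik_factory(tree, condition)
    bounds = (LOG_TAU_BOUNDS, eps_bounds)
    best = None
    for x0 in _restart_points(tree, n_restarts, seed, eps_bounds):
        x, fx, ok = _nelder_mead_2d(neg, x0, bounds)
        if best is None or fx < best[1] - 1e-12 or (
            abs(fx - best[1]) <= 1e-12 and x[0] < best[0][0]
        ):
            best = (x, fx, ok)
    tau, eps = math.exp(best[0][0]), float(best[0][1])
    result = EstimateResult.from_tau_eps(tau, eps, -float(best[1]), bool(best[2]),
                                         tree.n, condition)
    if check_hessian:
        result = hessian_check(tree, result)
    return result


def fit_yule(tree: ReconstructedTree, condition=ConditionRule.NONE) -> EstimateResult:
    """Yule speciation-rate MLE.

    ``NONE``/``SURVIVAL`` use the closed form (n-2)/s (crown survival is
    automatic without extinction); ``N_GT_2`` maximizes the conditioned
    likelihood numerically in one dimension.
    """
    condition = ConditionRule(condition)
    s = tree.s
    if s <= 0:
        raise ValueError("total edge length must be positive")
    if condition in (ConditionRule.NONE, ConditionRule.SURVIVAL):
        lam = yule_mle_closed(tree)
        ll = yule_loglik(tree, lam, ConditionRule.NONE) if lam > 0 else -np.inf
        return _yule_result(lam, ll, tree, condition)
    if tree.n <= 2:
        raise NonIdentifiableError("n>2 conditioning requires a tree with n > 2")
    hi = max(10.0 * (tree.n - 1) / s, 1.0)
    res = optimize.minimize_scalar(
        lambda lam: -yule_loglik(tree, lam, ConditionRule.N_GT_2),
        bounds=(1e-9, hi), method="bounded",
        options={"xatol": 1e-10},
    )
    return _yule_result(float(res.x), -float(res.fun), tree, condition)


def _yule_result(lam: float, ll: float, tree: ReconstructedTree,
                 condition: ConditionRule) -> EstimateResult:
    return EstimateResult(tau_hat=lam, eps_hat=0.0, lambda_hat=lam, mu_hat=0.0,
                          r_hat=lam, loglik_at_max=ll, converged=True,
                          hessian_valid=None, n=tree.n, condition=condition)


def hessian_check(tree: ReconstructedTree, result: EstimateResult,
                  rel_step: float = 1e-4) -> EstimateResult:
    """Finite-difference observed-information check at the optimum.

    Computes the central-difference Hessian of the negative log-likelihood in
    (tau, eps), inverts it, and marks the fit valid only when both implied
    variances are positive.  An optimum within one step of the bounds is
    marked invalid rather than extrapolated.
    """
    if not result.converged:
        return dataclasses.replace(result, hessian_valid=False)
    tau, eps = result.tau_hat, result.eps_hat

    def neg(tau_i: float, eps_i: float) -> float:
        if tau_i <= 0:
            return np.inf
        params = BDParams.from_turnover(tau_i, eps_i)
        try:
            return -bd_loglik_branch(tree, params, result.condition)
        except (ValueError, FloatingPointError):
            return np.inf

    h_tau = rel_step * max(abs(tau), 1e-8)
    h_eps = rel_step * max(abs(eps), 1e-8)
    tau_bounds = (math.exp(LOG_TAU_BOUNDS[0]), math.exp(LOG_TAU_BOUNDS[1]))
    if not (tau_bounds[0] + h_tau < tau < tau_bounds[1] - h_tau):
        return dataclasses.replace(result, hessian_valid=False)
    if not (EPS_BOUNDS[0] + h_eps < eps < EPS_BOUNDS[1] - h_eps):
        return dataclasses.replace(result, hessian_valid=False)

    f0 = neg(tau, eps)
    f_tt = (neg(tau + h_tau, eps) - 2 * f0 + neg(tau - h_tau, eps)) / h_tau**2
    f_ee = (neg(tau, eps + h_eps) - 2 * f0 + neg(tau, eps - h_eps)) / h_eps**2
    f_te = (
        neg(tau + h_tau, eps + h_eps) - neg(tau + h_tau, eps - h_eps)
        - neg(tau - h_tau, eps + h_eps) + neg(tau - h_tau, eps - h_eps)
    ) / (4 * h_tau * h_eps)
    hess = np.array([[f_tt, f_te], [f_te, f_ee]])
    valid = False
    if np.all(np.isfinite(hess)):
        try:
            cov = np.linalg.inv(hess)
            valid = bool(cov[0, 0] > 0 and cov[1, 1] > 0)
        except np.linalg.LinAlgError:
            valid = False
    return dataclasses.replace(result, hessian_valid=valid)
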