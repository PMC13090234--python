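"""Log-likelihoods of reconstructed trees under Yule, birth-death and
critical branching models, with three conditioning variants.

Conditioning variants
---------------------
``NONE``
    the raw process density of the reconstructed tree;
``SURVIVAL``
    conditioned on the crown surviving (both root daughters leave extant
    descendants): divide by ``[1 - P0(t)]^2`` and drop one factor of lambda
    for the crown speciation event;
``N_GT_2``
    additionally conditioned on the clade having more than two extant tips
    (the event defining a dataset from which cherry trees were censored):
    divide by ``[1 - P0(t)]^2 - P1(t)^2`` instead.

All functions return natural-log likelihoods.  Combinatorial labelled-tree
constants differ between the branch-product form, the oriented
branching-times form and the Yule (n-1)! form; they are parameter-free, so
maximum-likelihood estimates are unaffected.  No attempt is made to unify
them.
"""
from __future__ import annotations

import enum
import math

import numpy as np

from . import prob
from .params import BDParams
from .treeio import ReconstructedTree

__all__ = [
    "ConditionRule",
    "NotDefinedForCherryError",
    "yule_loglik",
    "yule_mle_closed",
    "bd_loglik_branch",
    "bd_loglik_oriented",
    "critical_loglik",
]


class ConditionRule(str, enum.Enum):
    NONE = "none"
    SURVIVAL = "survival"
    N_GT_2 = "n_gt_2"


class NotDefinedForCherryError(ValueError):
    """The oriented branching-times likelihood is undefined for n = 2 trees."""


def _as_rule(condition) -> ConditionRule:
    return ConditionRule(condition)


# -- Yule --------------------------------------------------------------------


def yule_loglik(tree: ReconstructedTree, lam: float, condition=ConditionRule.NONE) -> float:
    """Nee's Yule likelihood ``(n-1)! lam^{n-2} e^{-lam s}`` in log space.

    Survival of a Yule clade is automatic, so ``NONE`` and ``SURVIVAL`` agree;
    ``N_GT_2`` subtracts ``log(1 - e^{-2 lam t})`` (the probability that a
    clade of the same age has more than two tips).
    """
    condition = _as_rule(condition)
    if lam <= 0:
        raise ValueError("lam must be positive")
    n, s, t = tree.n, tree.s, tree.crown_age
    ll = math.lgamma(n) + (n - 2) * math.log(lam) - lam * s
    if condition is ConditionRule.N_GT_2:
        if n <= 2:
            raise NotDefinedForCherryError(
                "n>2 conditioning assumes cherry trees were censored from the data"
            )
        ll -= math.log1p(-math.exp(-2.0 * lam * t))
    return ll


def yule_mle_closed(tree: ReconstructedTree) -> float:
    """Closed-form Yule MLE ``(n - 2) / s``; zero for a cherry tree."""
    s = tree.s
    if s <= 0:
        raise ValueError("total edge length must be positive")
    return (tree.n - 2) / s


# -- general birth-death -------------------------------------------------------


def _bd_branch_core(params: BDParams, t_root: np.ndarray, t_tip: np.ndarray) -> float:
    """Sum over branches of the per-branch log density factor (Maddison form)."""
    lam, mu, r = params.lam, params.mu, params.r
    # for mu > lam every g factor is negative, so the per-branch squared
    # ratio is positive and |g| is exact in log space
    g_tip = np.abs(lam - mu * np.exp(-r * t_tip))
    g_root = np.abs(lam - mu * np.exp(-r * t_root))
    return float(
        -r * np.sum(t_root - t_tip) + 2.0 * np.sum(np.log(g_tip)) - 2.0 * np.sum(np.log(g_root))
    )


def _log_divisor(params: BDParams, t: float, condition: ConditionRule) -> float:
    if condition is ConditionRule.SURVIVAL:
        surv = 1.0 - prob.p_zero(params, t)
        return 2.0 * math.log(max(surv, 1e-300))
    if condition is ConditionRule.N_GT_2:
        return math.log(max(prob.p_gt2_crown(params, t), 1e-300))
    return 0.0


def bd_loglik_branch(tree: ReconstructedTree, params: BDParams, condition=ConditionRule.NONE) -> float:
    """Branch-product birth-death log-likelihood (defined even for cherries).

    Unconditioned, the product over the 2m branches carries ``lam^m``;
    conditioning on crown survival replaces it with ``lam^{m-1}`` (the crown
    speciation is part of the conditioning event) and divides by the
    corresponding crown probability, and ``N_GT_2`` divides instead by
    ``[1-P0]^2 - P1^2``.  Dispatches to :func:`critical_loglik` when
    lam == mu.
    """
    condition = _as_rule(condition)
    if params.lam <= 0:
        raise ValueError("lam must be positive")
    if params.mu < 0:
        raise ValueError("mu must be nonnegative")
    if condition is ConditionRule.N_GT_2 and tree.n <= 2:
        raise NotDefinedForCherryError(
            "n>2 conditioning assumes cherry trees were censored from the data"
        )
    if params.mu > 0 and params.is_critical:
        return critical_loglik(tree, params.lam, condition)
    core = _bd_branch_core(params, tree.branch_rootward_ages, tree.branch_tipward_ages)
    m = tree.m
    log_lam = math.log(params.lam)
    if condition is ConditionRule.NONE:
        return core + m * log_lam
    return core + (m - 1) * log_lam - _log_divisor(params, tree.crown_age, condition)


def bd_loglik_oriented(tree: ReconstructedTree, params: BDParams) -> float:
    """Oriented branching-times likelihood conditioned on crown survival.

    ``[p1(t1)/(1-p0(t1))]^2 * prod_{i=2}^{n-1} lam p1(t_i)`` over the n-1
    branching times.  The product is empty-by-construction undefined for a
    cherry tree (n = 2), which is raised explicitly rather than returned as a
    silent zero.
    """
    if tree.n < 3:
        raise NotDefinedForCherryError(
            "the vector of non-crown speciation times is empty for a cherry tree"
        )
    if params.lam <= 0:
        raise ValueError("lam must be positive")
    t1 = tree.crown_age
    p1_t1 = prob.p_one(params, t1)
    surv = 1.0 - prob.p_zero(params, t1)
    times = tree.branching_times[1:]
    lam, mu, r = params.lam, params.mu, params.r
    if params.mu > 0 and params.is_critical:
        log_p1 = -2.0 * np.log1p(lam * times)
    else:
        ert = np.exp(-r * times)
        log_p1 = 2.0 * math.log(abs(r)) - r * times - 2.0 * np.log(lam - mu * ert)
    return float(
        2.0 * (math.log(p1_t1) - math.log(surv))
        + times.size * math.log(lam)
        + np.sum(log_p1)
    )


# -- critical branching --------------------------------------------------------


def critical_loglik(tree: ReconstructedTree, lam: float, condition=ConditionRule.NONE) -> float:
    """Likelihood under the critical branching process (lam == mu).

    Unconditioned: ``prod_i (1 + lam t_{i,t})^2 / (1 + lam t_{i,r})^2 * lam^m``.
    Conditioned variants mirror the general case with the critical kernels.
    """
    condition = _as_rule(condition)
    if lam <= 0:
        raise ValueError("lam must be positive")
    if condition is ConditionRule.N_GT_2 and tree.n <= 2:
        raise NotDefinedForCherryError(
            "n>2 conditioning assumes cherry trees were censored from the data"
        )
    t_root = tree.branch_rootward_ages
    t_tip = tree.branch_tipward_ages
    core = float(2.0 * np.sum(np.log1p(lam * t_tip)) - 2.0 * np.sum(np.log1p(lam * t_root)))
    m = tree.m
    t = tree.crown_age
    if condition is ConditionRule.NONE:
        return core + m * math.log(lam)
    if condition is ConditionRule.SURVIVAL:
        surv = 1.0 - prob.p_zero_critical(lam, t)
        return core + (m - 1) * math.log(lam) - 2.0 * math.log(max(surv, 1e-300))
    div = max(prob.p_gt2_crown_critical(lam, t), 1e-300)
    return core + (m - 1) * math.log(lam) - math.log(div)
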