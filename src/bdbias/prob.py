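"""Closed-form tip-count probability kernels for conditioning likelihoods.

All kernels describe a clade of crown age ``t`` (time before present) evolving
under a constant-rate birth-death process.  ``p_zero``/``p_one`` are
single-lineage kernels (probability that one lineage leaves 0 or exactly 1
extant descendant after time ``t``); the crown quantities combine two
independent daughter lineages.

The near-critical case (lam ~= mu) is dispatched to the exact critical
branching forms to avoid catastrophic cancellation in ``exp(-(lam-mu) t)``.
"""
from __future__ import annotations

import numpy as np

from .params import BDParams

__all__ = [
    "p_zero",
    "p_one",
    "p_gt2_crown",
    "p_n_yule",
    "p_n_critical",
    "p_zero_critical",
    "p_one_critical",
    "p_gt2_crown_critical",
]


def _critical(params: BDParams) -> bool:
    return params.mu > 0 and params.is_critical


def p_zero(params: BDParams, t: float) -> float:
    """P(single lineage has no extant descendant after time t).

    General form ``1 - (lam - mu) / (lam - mu e^{-(lam-mu) t})``; equals 0 for
    a Yule lineage (mu = 0) and dispatches to the critical kernel when
    lam == mu.
    """
    if t < 0:
        raise ValueError("t must be nonnegative")
    if params.mu == 0:
        return 0.0
    if _critical(params):
        return p_zero_critical(params.lam, t)
    r = params.r
    return 1.0 - r / (params.lam - params.mu * np.exp(-r * t))


def p_one(params: BDParams, t: float) -> float:
    """P(single lineage has exactly one extant descendant after time t).

    ``(lam - mu)^2 e^{-(lam-mu) t} / (lam - mu e^{-(lam-mu) t})^2``.
    Satisfies p_one(., 0) = 1.
    """
    if t < 0:
        raise ValueError("t must be nonnegative")
    if _critical(params):
        return p_one_critical(params.lam, t)
    r = params.r
    ert = np.exp(-r * t)
    denom = params.lam - params.mu * ert
    return float(r * r * ert / (denom * denom))


def p_gt2_crown(params: BDParams, t: float) -> float:
    """P(a crown clade of age t survives with more than two extant tips).

    ``[1 - P0(t)]^2 - P1(t)^2``: both crown daughters survive, minus the event
    that each leaves exactly one tip (the clade is a cherry).
    """
    surv = 1.0 - p_zero(params, t)
    return float(surv * surv - p_one(params, t) ** 2)


def p_n_yule(n: int, lam: float, t: float) -> float:
    """P(a crown Yule clade of age t has exactly n tips), n >= 2.

    ``(n-1) e^{-2 lam t} (1 - e^{-lam t})^{n-2}``.
    """
    if n < 2:
        raise ValueError("a surviving crown clade has at least 2 tips")
    if lam <= 0 or t < 0:
        raise ValueError("lam must be positive and t nonnegative")
    q = np.exp(-lam * t)
    return float((n - 1) * q * q * (1.0 - q) ** (n - 2))


def p_zero_critical(lam: float, t: float) -> float:
    """Extinction probability of a single lineage when lam == mu."""
    x = lam * t
    return x / (1.0 + x)


def p_one_critical(lam: float, t: float) -> float:
    """P(exactly one extant descendant) for a single critical lineage."""
    x = lam * t
    return 1.0 / (1.0 + x) ** 2


def p_n_critical(n: int, lam: float, t: float) -> float:
    """Single-lineage tip-count probability under the critical process.

    Bailey's form ``(lam t)^{n-1} / (1 + lam t)^{n+1}`` for n >= 1, with the
    separate extinction probability ``lam t / (1 + lam t)`` at n = 0.
    """
    if n < 0:
        raise ValueError("n must be nonnegative")
    if lam <= 0 or t < 0:
        raise ValueError("lam must be positive and t nonnegative")
    x = lam * t
    if n == 0:
        return x / (1.0 + x)
    return float(x ** (n - 1) / (1.0 + x) ** (n + 1))


def p_gt2_crown_critical(lam: float, t: float) -> float:
    """Critical-process analogue of :func:`p_gt2_crown`."""
    surv = 1.0 - p_zero_critical(lam, t)
    return surv * surv - p_one_critical(lam, t) ** 2
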