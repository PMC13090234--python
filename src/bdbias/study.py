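"""Reduced-scale simulation studies: structural bias, Yule validation of the
symbolic-regression search, the general birth-death correction study, and the
derived-parameter (turnover / net diversification) slope analysis.

Default problem sizes are reduced relative to the original full-scale
experiments (10^5 to 5*10^5 trees): 5,000 trees per clade age for the
structural-bias table and 30,000 design points for the Latin-hypercube
studies.  Median/slope summaries stabilize well below full scale; every run
is reproducible from its master seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import corrections, symreg
from .estimate import EstimateResult, fit_bd, fit_yule
from .likelihoods import ConditionRule
from .params import BDParams
from .simulate import (
    SimOutcome,
    apply_censoring,
    bd_design,
    child_rng,
    lhs_design,
    simulate_crown_tree,
    simulate_crown_tree_conditioned,
    simulate_design,
)

__all__ = [
    "run_table1",
    "run_yule_validation",
    "run_bd_study",
    "fig2_stats",
    "YuleValidationResult",
    "BDStudyResult",
]


# -- structural bias (survival vs n>2 conditioning) --------------------------------


def run_table1(ages: Sequence[float] = (5, 10, 15, 20, 25, 30),
               n_trees: int = 5000, lam: float = 0.1, mu: float = 0.05,
               seed: int = 0) -> pd.DataFrame:
    """Median/mean rate estimates on cherry-censored trees, per clade age.

    For every age, ``n_trees`` crown trees are simulated at the generating
    rates, trees with n <= 2 are censored, and each remaining tree is fitted
    twice: with the survival-conditioned likelihood (which ignores the
    censoring) and with the n>2-conditioned likelihood (which accounts for
    it).  Younger clades show the inflation of survival-conditioned rates.
    """
    params = BDParams(lam=lam, mu=mu)
    rows = []
    for age_idx, age in enumerate(ages):
        outcomes = [
            simulate_crown_tree(params, age, child_rng(seed, age_idx * n_trees + i), row_id=i)
            for i in range(n_trees)
        ]
        usable = apply_censoring(outcomes, "n_gt_2")
        fits: Dict[str, List[EstimateResult]] = {"survival": [], "n_gt_2": []}
        for out in usable:
            fits["survival"].append(fit_bd(out.tree, ConditionRule.SURVIVAL))
            fits["n_gt_2"].append(fit_bd(out.tree, ConditionRule.N_GT_2))
        row = {
            "age": age,
            "n_simulated": n_trees,
            "n_analyzed": len(usable),
            "median_clade_size": float(np.median([o.tree.n for o in usable])) if usable else np.nan,
        }
        for cond, results in fits.items():
            lam_hats = np.array([r.lambda_hat for r in results])
            mu_hats = np.array([r.mu_hat for r in results])
            row[f"lambda_median_{cond}"] = float(np.median(lam_hats))
            row[f"lambda_mean_{cond}"] = float(np.mean(lam_hats))
            row[f"mu_median_{cond}"] = float(np.median(mu_hats))
            row[f"mu_mean_{cond}"] = float(np.mean(mu_hats))
        rows.append(row)
    return pd.DataFrame(rows)


# -- Yule validation -----------------------------------------------------------------


@dataclass
class YuleValidationResult:
    estimates: pd.DataFrame
    uncorrected_fit: Tuple[float, float]  # (intercept, slope)
    corrected_fit: Tuple[float, float]
    ranking: Optional[symreg.AlphaRanking]
    n_design: int
    n_retained: int


def run_yule_validation(n_points: int = 30000, seed: int = 0,
                        age_range=(0.0, 5.0), lam_range=(0.0, 0.5),
                        alpha_max: float = 0.02, max_depth: int = 4,
                        run_symreg: bool = True) -> YuleValidationResult:
    """Latin-hypercube Yule study validating the symbolic-regression search.

    Clade age and speciation rate are LHS-uniform; one tree per design
    point; cherries (and failed points) are discarded.  The per-tree
    speciation estimate entering the regressions and the symbolic search is
    the n>2-conditioned MLE (the estimator matched to the censored data);
    the unconditioned closed form (n-2)/s is also recorded for comparison.
    """
    design = lhs_design(n_points, {"age": age_range, "lam": lam_range}, seed)
    outcomes = simulate_design(design, master_seed=seed + 1)
    usable = apply_censoring(outcomes, "n_gt_2")
    lam_by_row = design["lam"].to_numpy()
    age_by_row = design["age"].to_numpy()
    recs = []
    for out in usable:
        tree = out.tree
        est_closed = fit_yule(tree, ConditionRule.SURVIVAL)
        est = fit_yule(tree, ConditionRule.N_GT_2)
        recs.append(
            (out.row_id, tree.n, tree.s, age_by_row[out.row_id], lam_by_row[out.row_id],
             est.lambda_hat, est_closed.lambda_hat)
        )
    est_df = pd.DataFrame(
        recs, columns=["row_id", "n", "s", "age", "lam_true", "lam_hat", "lam_hat_closed"]
    )
    n_arr = est_df["n"].to_numpy(dtype=float)
    est_df["lam_corr"] = est_df["lam_hat"] * (n_arr - 1) / (n_arr - 2)
    uncorr = corrections.huber_regression(est_df["lam_true"], est_df["lam_hat"])
    corr = corrections.huber_regression(est_df["lam_true"], est_df["lam_corr"])
    ranking = None
    if run_symreg:
        dataset = pd.DataFrame(
            {"theta_hat": est_df["lam_hat"], "n": est_df["n"], "theta_true": est_df["lam_true"]}
        )
        cands = symreg.enumerate_expressions(symreg.build_grammar("lambda"), max_depth)
        symreg.score_candidates(cands, dataset)
        ranking = symreg.rank_alpha_grid(cands, (0.0, alpha_max))
    return YuleValidationResult(
        estimates=est_df, uncorrected_fit=uncorr, corrected_fit=corr,
        ranking=ranking, n_design=n_points, n_retained=len(est_df),
    )


# -- general birth-death study --------------------------------------------------------


@dataclass
class BDStudyResult:
    estimates: pd.DataFrame  # all usable trees, with validity flags
    stats: pd.DataFrame  # derived-parameter regression slopes/intercepts
    ranking_lambda: Optional[symreg.AlphaRanking]
    ranking_mu: Optional[symreg.AlphaRanking]
    n_design: int
    n_usable: int
    n_valid: int

    @property
    def valid(self) -> pd.DataFrame:
        """Fits retained for the regressions: converged, and either a
        boundary-constrained optimum or an interior one with positive
        implied variances."""
        df = self.estimates
        return df[df["converged"] & (df["hessian_valid"] | df["at_bound"])]


def run_bd_study(n_points: int = 30000, seed: int = 0,
                 age_range=(0.0, 10.0), lam_range=(0.0, 1.0), eps_range=(0.0, 1.0),
                 alpha_max_lambda: float = 1e-3, alpha_max_mu: float = 1e-1,
                 max_depth: int = 4, run_symreg: bool = True) -> BDStudyResult:
    """LHS birth-death study: fit, Hessian-filter, correct, regress, search.

    Clade age ~ U[0,10], speciation ~ U[0,1], extinction fraction ~ U[0,1]
    with mu = lam * eps.  Each design point is simulated conditional on crown
    survival (redrawn until the crown survives); cherries are then censored
    without resampling, mirroring a collection of surviving clades from which
    two-taxon trees are excluded.  Rates are estimated in the (turnover,
    extinction-fraction) parameterization with the n>2-conditioned
    likelihood.  Replicates whose interior optimum fails the
    observed-information check (negative implied variance) are excluded from
    all summaries; boundary-constrained optima are genuine constrained maxima
    and are retained.
    """
    design = bd_design(n_points, seed, age_range, lam_range, eps_range)
    lam_true = design["lam"].to_numpy()
    mu_true = design["mu"].to_numpy()
    age_arr = design["age"].to_numpy()
    outcomes = []
    for row in design.itertuples(index=False):
        out = simulate_crown_tree_conditioned(
            BDParams(lam=row.lam, mu=row.mu), row.age,
            child_rng(seed + 1, int(row.row_id)), row_id=int(row.row_id),
        )
        if out is not None:
            outcomes.append(out)
    usable = apply_censoring(outcomes, "n_gt_2")
    recs = []
    for out in usable:
        est = fit_bd(out.tree, ConditionRule.N_GT_2, check_hessian=True)
        rid = out.row_id
        recs.append(
            (rid, out.tree.n, age_arr[rid], lam_true[rid], mu_true[rid],
             est.lambda_hat, est.mu_hat, est.eps_hat, est.tau_hat, est.r_hat,
             est.loglik_at_max, est.converged, bool(est.hessian_valid), bool(est.at_bound))
        )
    est_df = pd.DataFrame(
        recs,
        columns=["row_id", "n", "age", "lam_true", "mu_true", "lam_hat", "mu_hat",
                 "eps_hat", "tau_hat", "r_hat", "loglik", "converged", "hessian_valid",
                 "at_bound"],
    )
    n_arr = est_df["n"].to_numpy(dtype=float)
    est_df["lam_corr"] = est_df["lam_hat"] * (n_arr - 1) / (n_arr - 2)
    est_df["mu_corr"] = est_df["mu_hat"] * (n_arr / (n_arr - 1) + est_df["eps_hat"])
    est_df["tau_corr"] = est_df["lam_corr"] + est_df["mu_corr"]
    est_df["r_corr"] = est_df["r_hat"] * (n_arr / (n_arr - 1) + est_df["eps_hat"])

    valid = est_df[est_df["converged"] & (est_df["hessian_valid"] | est_df["at_bound"])]
    stats = fig2_stats(valid)

    ranking_lambda = ranking_mu = None
    if run_symreg:
        lam_dataset = pd.DataFrame(
            {"theta_hat": valid["lam_hat"], "n": valid["n"], "theta_true": valid["lam_true"]}
        )
        cands = symreg.enumerate_expressions(symreg.build_grammar("lambda"), max_depth)
        symreg.score_candidates(cands, lam_dataset)
        ranking_lambda = symreg.rank_alpha_grid(cands, (0.0, alpha_max_lambda))

        mu_dataset = pd.DataFrame(
            {"theta_hat": valid["mu_hat"], "n": valid["n"], "eps_hat": valid["eps_hat"],
             "theta_true": valid["mu_true"]}
        )
        cands_mu = symreg.enumerate_expressions(symreg.build_grammar("mu"), max_depth)
        symreg.score_candidates(cands_mu, mu_dataset)
        ranking_mu = symreg.rank_alpha_grid(cands_mu, (0.0, alpha_max_mu))

    return BDStudyResult(
        estimates=est_df, stats=stats, ranking_lambda=ranking_lambda,
        ranking_mu=ranking_mu, n_design=n_points, n_usable=len(est_df),
        n_valid=int(len(valid)),
    )


def fig2_stats(df: pd.DataFrame) -> pd.DataFrame:
    """Huber regression slopes of (corrected) estimates on generating values.

    Rows cover the four derived-parameter relationships: corrected turnover,
    net diversification recomputed from the corrected rates, the direct
    net-diversification correction applied to the raw MLE difference, and
    expectation-recalibrated variants obtained by inverting the robust
    regressions of corrected rates on truth.
    """
    required = {"lam_true", "mu_true", "lam_corr", "mu_corr", "r_hat", "eps_hat", "n"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"estimates table lacks columns {sorted(missing)}")
    tau_true = df["lam_true"] + df["mu_true"]
    r_true = df["lam_true"] - df["mu_true"]
    n_arr = df["n"].to_numpy(dtype=float)

    lam_map = corrections.expectation_recalibrate(
        np.column_stack([df["lam_corr"], df["lam_true"]]), tag="lambda")
    mu_map = corrections.expectation_recalibrate(
        np.column_stack([df["mu_corr"], df["mu_true"]]), tag="mu")
    lam_recal = corrections.apply_map(df["lam_corr"], lam_map)
    mu_recal = corrections.apply_map(df["mu_corr"], mu_map)
    r_direct = df["r_hat"] * (n_arr / (n_arr - 1) + df["eps_hat"])

    quantities = {
        "lambda_corr": (df["lam_true"], df["lam_corr"]),
        "mu_corr": (df["mu_true"], df["mu_corr"]),
        "turnover_corr": (tau_true, df["lam_corr"] + df["mu_corr"]),
        "turnover_recalibrated": (tau_true, lam_recal + mu_recal),
        "netdiv_from_corrected": (r_true, df["lam_corr"] - df["mu_corr"]),
        "netdiv_table_correction": (r_true, r_direct),
        "netdiv_recalibrated": (r_true, lam_recal - mu_recal),
    }
    rows = []
    for name, (x, y) in quantities.items():
        a, b = corrections.huber_regression(np.asarray(x, float), np.asarray(y, float))
        rows.append({"quantity": name, "slope": b, "intercept": a, "n": len(df)})
    out = pd.DataFrame(rows).set_index("quantity")
    out.attrs["recalibration"] = {"lambda": lam_map, "mu": mu_map}
    return out
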