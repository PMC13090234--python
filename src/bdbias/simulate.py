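"""Forward simulation of constant-rate birth-death trees and study designs.

The simulator is event-driven (Gillespie) on the whole-tree scale: with
``k`` lineages alive the waiting time to the next event is exponential with
rate ``k (lam + mu)``, the event hits a uniformly chosen lineage and is a
speciation with probability ``lam / (lam + mu)``.  A crown simulation starts
from the two daughters of the crown node and runs for a fixed duration
(clade age); extinct subtrees are then pruned to produce the reconstructed
tree the likelihoods consume.

Censoring statuses
------------------
``extinct``
    at least one crown daughter left no extant descendant (the reconstructed
    crown tree does not exist);
``cherry``
    the crown survived with exactly two extant tips;
``usable``
    the crown survived with more than two extant tips.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .params import BDParams
from .treeio import ReconstructedTree

__all__ = [
    "CompleteTree",
    "SimOutcome",
    "lhs_design",
    "bd_design",
    "simulate_crown_tree",
    "stem_tip_count",
    "prune_extinct",
    "apply_censoring",
    "simulate_design",
    "child_rng",
]

# lineage fates in a CompleteTree
EXTANT, EXTINCT, SPECIATED = 0, 1, 2


@dataclass(frozen=True)
class CompleteTree:
    """Full lineage table of one simulation, extinct lineages included.

    Times run forward from the crown (0) to the present (``age``).  Lineage i
    exists on ``[t_start[i], t_end[i]]``; ``fate`` records how it ended.  The
    first ``n_roots`` lineages are the crown daughters (parent -1).
    """

    age: float
    parent: np.ndarray
    t_start: np.ndarray
    t_end: np.ndarray
    fate: np.ndarray
    n_roots: int = 2

    @property
    def n_extant(self) -> int:
        return int(np.sum(self.fate == EXTANT))


@dataclass(frozen=True)
class SimOutcome:
    status: str  # "extinct" | "cherry" | "usable"
    tree: Optional[ReconstructedTree]
    n_extant: int
    row_id: int = 0
    seed: Optional[int] = None
    complete: Optional[CompleteTree] = None


def child_rng(master_seed: int, row_id: int) -> np.random.Generator:
    """Deterministic per-row generator so design runs are reproducible."""
    return np.random.default_rng(np.random.SeedSequence(master_seed, spawn_key=(row_id,)))


# -- experiment designs --------------------------------------------------------


def lhs_design(n_points: int, ranges: Dict[str, Sequence[float]], seed: int) -> pd.DataFrame:
    """Latin-hypercube design: one uniform draw per equal-width stratum.

    Each variable is sampled independently: its n_points strata are assigned
    a random permutation, with one uniform point inside each stratum.
    """
    if not ranges:
        raise ValueError("at least one variable range is required")
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    rng = np.random.default_rng(seed)
    cols = {}
    for name, (lo, hi) in ranges.items():
        if not lo < hi:
            raise ValueError(f"range for {name!r} must have lo < hi")
        strata = rng.permutation(n_points)
        u = rng.random(n_points)
        cols[name] = lo + (strata + u) * (hi - lo) / n_points
    df = pd.DataFrame(cols)
    df.insert(0, "row_id", np.arange(n_points))
    return df


def bd_design(n_points: int, seed: int,
              age_range=(0.0, 10.0), lam_range=(0.0, 1.0), eps_range=(0.0, 1.0)) -> pd.DataFrame:
    """Birth-death study design: age, lam, epsilon LHS-uniform; mu = lam * epsilon."""
    df = lhs_design(n_points, {"age": age_range, "lam": lam_range, "epsilon": eps_range}, seed)
    df["mu"] = df["lam"] * df["epsilon"]
    return df


# -- core event loop -----------------------------------------------------------


def _simulate_lineages(params: BDParams, age: float, rng: np.random.Generator,
                       n_roots: int = 2) -> CompleteTree:
    if age <= 0:
        raise ValueError("age must be positive")
    lam, mu = params.lam, params.mu
    total = lam + mu
    p_birth = lam / total if total > 0 else 0.0
    parent = [-1] * n_roots
    t_start = [0.0] * n_roots
    t_end = [age] * n_roots
    fate = [EXTANT] * n_roots
    alive = list(range(n_roots))
    t = 0.0
    random = rng.random  # local binding; this loop dominates study runtime
    while alive and total > 0.0:
        k = len(alive)
        t += -np.log(random()) / (k * total)
        if t >= age:
            break
        idx = int(random() * k)
        lineage = alive[idx]
        alive[idx] = alive[-1]
        alive.pop()
        t_end[lineage] = t
        if random() < p_birth:
            fate[lineage] = SPECIATED
            for _ in range(2):
                alive.append(len(parent))
                parent.append(lineage)
                t_start.append(t)
                t_end.append(age)
                fate.append(EXTANT)
        else:
            fate[lineage] = EXTINCT
    return CompleteTree(
        age=age,
        parent=np.asarray(parent, dtype=np.int64),
        t_start=np.asarray(t_start),
        t_end=np.asarray(t_end),
        fate=np.asarray(fate, dtype=np.int8),
        n_roots=n_roots,
    )


def simulate_crown_tree(params: BDParams, age: float, seed, row_id: int = 0,
                        keep_complete: bool = False) -> SimOutcome:
    """Simulate one crown clade for a fixed duration and classify it.

    ``seed`` may be an integer or a ready ``numpy.random.Generator``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    complete = _simulate_lineages(params, age, rng, n_roots=2)
    tree = prune_extinct(complete)
    n_extant = complete.n_extant
    if tree is None:
        status = "extinct"
    elif tree.n == 2:
        status = "cherry"
    else:
        status = "usable"
    return SimOutcome(
        status=status,
        tree=tree,
        n_extant=n_extant,
        row_id=row_id,
        seed=seed if isinstance(seed, int) else None,
        complete=complete if keep_complete else None,
    )


def simulate_crown_tree_conditioned(params: BDParams, age: float, seed, row_id: int = 0,
                                    max_tries: int = 100) -> Optional[SimOutcome]:
    """Simulate a crown clade conditioned on crown survival.

    Redraws the realization until both crown daughters have extant
    descendants (the conditional distribution the survival-conditioned
    likelihoods describe).  Returns None when no surviving realization is
    found within ``max_tries`` — at very low rate*age products survival can
    be arbitrarily rare, and such design points are dropped rather than
    simulated forever.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    for _ in range(max_tries):
        out = simulate_crown_tree(params, age, rng, row_id=row_id)
        if out.status != "extinct":
            return out
    return None


def stem_tip_count(params: BDParams, age: float, seed) -> int:
    """Number of extant tips left by a single stem lineage after ``age``."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return _simulate_lineages(params, age, rng, n_roots=1).n_extant


# -- pruning ---------------------------------------------------------------------


def prune_extinct(complete: CompleteTree) -> Optional[ReconstructedTree]:
    """Reconstructed (extant-only) tree, or None if the crown did not survive.

    Extinct subtrees are removed and the resulting degree-2 nodes suppressed
    (their branch lengths summed).  The reconstructed internal nodes are the
    speciation events whose both daughter subtrees reach the present.
    """
    size = complete.parent.size
    n_desc = (complete.fate == EXTANT).astype(np.int64)
    # children are created after their parent, so a reverse sweep accumulates
    for i in range(size - 1, complete.n_roots - 1, -1):
        n_desc[complete.parent[i]] += n_desc[i]
    if complete.n_roots != 2 or n_desc[0] == 0 or n_desc[1] == 0:
        return None

    age = complete.age
    children: List[List[int]] = [[] for _ in range(size)]
    for i in range(complete.n_roots, size):
        children[complete.parent[i]].append(i)

    new_parent = [-1]
    new_age = [age]
    new_labels: List[Optional[str]] = [None]
    # attach[i]: reconstructed node that the branch through lineage i hangs from
    attach = np.zeros(size, dtype=np.int64)
    for i in range(size):
        if n_desc[i] == 0:
            continue
        anc = 0 if complete.parent[i] < 0 else attach[i]
        if complete.fate[i] == EXTANT:
            new_parent.append(anc)
            new_age.append(0.0)
            new_labels.append(f"t{i}")
        elif complete.fate[i] == SPECIATED:
            kids = children[i]
            kept = [k for k in kids if n_desc[k] > 0]
            if len(kept) == 2:
                node = len(new_parent)
                new_parent.append(anc)
                new_age.append(age - complete.t_end[i])
                new_labels.append(None)
                for k in kept:
                    attach[k] = node
            else:
                attach[kept[0]] = anc
    return ReconstructedTree(
        parent=np.asarray(new_parent),
        age=np.asarray(new_age),
        labels=tuple(new_labels),
    )


# -- censoring & design execution -------------------------------------------------


def apply_censoring(outcomes: Iterable[SimOutcome], rule: str) -> List[SimOutcome]:
    """Drop outcomes failing the rule; discarded points are never resampled.

    ``survival`` keeps crown-surviving trees (cherries included); ``n_gt_2``
    keeps only trees with more than two extant tips.
    """
    if rule == "survival":
        keep = {"cherry", "usable"}
    elif rule == "n_gt_2":
        keep = {"usable"}
    else:
        raise ValueError(f"unknown censoring rule {rule!r}")
    return [o for o in outcomes if o.status in keep]


def simulate_design(design: pd.DataFrame, master_seed: int,
                    keep_complete: bool = False) -> List[SimOutcome]:
    """One simulated tree per design row, with per-row child seeds."""
    outcomes = []
    for row in design.itertuples(index=False):
        params = BDParams(lam=row.lam, mu=getattr(row, "mu", 0.0))
        rng = child_rng(master_seed, int(row.row_id))
        outcomes.append(
            simulate_crown_tree(params, row.age, rng, row_id=int(row.row_id),
                                keep_complete=keep_complete)
        )
    return outcomes
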