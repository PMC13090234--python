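"""Reading, validating and writing ultrametric bifurcating trees.

Trees are stored in a flat array form (parent pointers plus node ages) rather
than as linked node objects: the simulation studies handle tens of thousands
of trees and the likelihoods only ever need branch endpoint ages.  Ages are
measured backward from the present, so every extant tip sits at age 0 and the
root (crown) node at age ``crown_age``.

Newick input/output goes through dendropy.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property
from typing import Iterable, Iterator, NamedTuple, Optional, Sequence

import dendropy
import numpy as np

__all__ = [
    "BranchSegment",
    "ReconstructedTree",
    "TreeError",
    "parse_newick",
    "write_newick",
    "tree_summaries",
    "read_newick_file",
    "write_newick_file",
]

#: relative tolerance (times crown age) for declaring tips contemporaneous
ULTRAMETRIC_RTOL = 1e-8


class TreeError(ValueError):
    """Raised for malformed or unsupported input trees."""


class BranchSegment(NamedTuple):
    """One branch of the reconstructed tree, by its endpoint ages."""

    rootward_age: float
    tipward_age: float


class TreeSummary(NamedTuple):
    n: int
    m: int
    s: float
    crown_age: float
    branching_times: np.ndarray


@dataclass(frozen=True)
class ReconstructedTree:
    """Rooted, strictly bifurcating, ultrametric extant-only phylogeny.

    ``parent[i]`` is the index of node i's parent (-1 for the root) and
    ``age[i]`` its age before the present.  Parents always precede children,
    i.e. ``parent[i] < i`` for every non-root node.  ``labels[i]`` is the tip
    label (None for internal nodes).
    """

    parent: np.ndarray
    age: np.ndarray
    labels: tuple

    _n_children: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        parent = np.asarray(self.parent, dtype=np.int64)
        age = np.asarray(self.age, dtype=np.float64)
        object.__setattr__(self, "parent", parent)
        object.__setattr__(self, "age", age)
        if parent.shape != age.shape or parent.ndim != 1:
            raise TreeError("parent and age must be 1-d arrays of equal length")
        size = parent.size
        if size < 3 or size % 2 == 0:
            raise TreeError("a bifurcating tree with n >= 2 tips has 2n-1 >= 3 nodes")
        if parent[0] != -1 or np.any(parent[1:] < 0) or np.any(parent[1:] >= np.arange(1, size)):
            raise TreeError("nodes must be topologically ordered with the root first")
        counts = np.bincount(parent[1:], minlength=size)
        if not np.all((counts == 0) | (counts == 2)):
            raise TreeError("tree must be strictly bifurcating")
        object.__setattr__(self, "_n_children", counts)
        # zero-length (degenerate) edges are tolerated; negative ones are not
        if np.any(age[1:] > age[parent[1:]]):
            bad = int(np.argmax(age[1:] > age[parent[1:]])) + 1
            raise TreeError(
                f"branch to node {bad} has negative length "
                f"(rootward age {age[parent[bad]]}, tipward age {age[bad]})"
            )
        tip_ages = age[counts == 0]
        tol = ULTRAMETRIC_RTOL * max(self.crown_age, 1e-300)
        if np.any(np.abs(tip_ages) > tol):
            raise TreeError("tree is not ultrametric: extant tips must sit at age 0")

    # -- summaries (cached: the fitter evaluates these in tight loops) ------

    @cached_property
    def is_tip(self) -> np.ndarray:
        return self._n_children == 0

    @cached_property
    def n(self) -> int:
        """Number of extant tips."""
        return int(self.is_tip.sum())

    @cached_property
    def m(self) -> int:
        """Number of internal nodes (= n - 1 for a crown tree)."""
        return self.parent.size - self.n

    @property
    def crown_age(self) -> float:
        return float(self.age[0])

    @cached_property
    def s(self) -> float:
        """Total edge length: sum of (rootward age - tipward age) over branches."""
        return float(np.sum(self.age[self.parent[1:]] - self.age[1:]))

    @cached_property
    def branching_times(self) -> np.ndarray:
        """Internal node ages sorted descending; first element is the crown age."""
        times = self.age[~self.is_tip]
        return np.sort(times)[::-1]

    @cached_property
    def branch_rootward_ages(self) -> np.ndarray:
        """Rootward endpoint ages of the 2m branches (root's edge excluded)."""
        return self.age[self.parent[1:]]

    @cached_property
    def branch_tipward_ages(self) -> np.ndarray:
        return self.age[1:]

    @property
    def branch_segments(self) -> list:
        return [
            BranchSegment(float(r), float(t))
            for r, t in zip(self.branch_rootward_ages, self.branch_tipward_ages)
        ]

    def _children(self) -> list:
        kids: list = [[] for _ in range(self.parent.size)]
        for i, p in enumerate(self.parent[1:], start=1):
            kids[p].append(i)
        return kids


def tree_summaries(tree: ReconstructedTree) -> TreeSummary:
    """(n, m, s, crown_age, branching_times) — everything the likelihoods need."""
    return TreeSummary(tree.n, tree.m, tree.s, tree.crown_age, tree.branching_times)


# -- newick ----------------------------------------------------------------


def parse_newick(text: str) -> ReconstructedTree:
    """Parse a single rooted, bifurcating, ultrametric newick tree.

    Rejects polytomies, missing branch lengths and trees whose tips are not
    contemporaneous (beyond ``1e-8`` relative to the crown age, after which
    tip ages are snapped to exactly 0).
    """
    dtree = dendropy.Tree.get(
        data=text,
        schema="newick",
        suppress_internal_node_taxa=True,
        rooting="default-rooted",
    )
    root = dtree.seed_node
    if len(root.child_nodes()) != 2:
        raise TreeError(
            f"root must have exactly two children, found {len(root.child_nodes())} "
            "(unrooted or polytomous tree)"
        )

    order = [root]
    index = {id(root): 0}
    parent = [-1]
    depth = [0.0]
    for node in order:
        children = node.child_nodes()
        if children and len(children) != 2:
            raise TreeError(f"polytomy at internal node with {len(children)} children")
        for child in children:
            if child.edge.length is None:
                label = child.taxon.label if child.taxon else "<internal>"
                raise TreeError(f"missing branch length on the edge to {label!r}")
            index[id(child)] = len(order)
            parent.append(index[id(node)])
            depth.append(depth[index[id(node)]] + float(child.edge.length))
            order.append(child)

    depth_arr = np.asarray(depth)
    is_tip = np.array([not nd.child_nodes() for nd in order])
    tip_depths = depth_arr[is_tip]
    crown = float(tip_depths.max())
    if crown <= 0:
        raise TreeError("tree has zero height")
    tol = ULTRAMETRIC_RTOL * crown
    off = np.abs(tip_depths - crown) > tol
    if np.any(off):
        bad = np.flatnonzero(is_tip)[np.argmax(np.abs(tip_depths - crown))]
        label = order[bad].taxon.label if order[bad].taxon else f"node {bad}"
        raise TreeError(
            f"tree is not ultrametric: tip {label!r} has depth {depth_arr[bad]:.12g} "
            f"vs crown height {crown:.12g}"
        )
    age = crown - depth_arr
    age[is_tip] = 0.0  # snap accumulated floating-point error
    labels = tuple(
        (nd.taxon.label if nd.taxon is not None else None) if tip else None
        for nd, tip in zip(order, is_tip)
    )
    return ReconstructedTree(parent=np.asarray(parent), age=age, labels=labels)


def write_newick(tree: ReconstructedTree) -> str:
    """Serialize to newick with branch lengths; round-trip safe to 1e-10."""
    children = tree._children()
    parts: dict = {}
    # iterative postorder over the topologically ordered node list
    for i in range(tree.parent.size - 1, -1, -1):
        kids = children[i]
        if not kids:
            label = tree.labels[i] if tree.labels[i] is not None else f"t{i}"
            parts[i] = _quote(label)
        else:
            parts[i] = "(" + ",".join(parts[k] for k in kids) + ")"
        if i > 0:
            length = tree.age[tree.parent[i]] - tree.age[i]
            parts[i] += f":{length:.17g}"
    return parts[0] + ";"


def _quote(label: str) -> str:
    if any(ch in label for ch in " ,():;[]'"):
        return "'" + label.replace("'", "''") + "'"
    return label


def read_newick_file(path) -> Iterator[ReconstructedTree]:
    """Yield trees from a file with one newick per line; '#' lines ignored."""
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            yield parse_newick(line)


def write_newick_file(path, trees: Iterable[ReconstructedTree]) -> None:
    with open(path, "w") as fh:
        for tree in trees:
            fh.write(write_newick(tree) + "\n")
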