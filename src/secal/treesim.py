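"""Pure-birth (Yule) chronogram simulation and molecular-clock rescaling.

A :class:`TimeTree` is a rooted, fully bifurcating, ultrametric tree whose
internal nodes carry ages in absolute time units (tips at age 0).  A
:class:`SubstTree` shares a TimeTree's topology but carries per-branch rates
and branch lengths in expected substitutions per site, as produced by a
strict clock or by independent lognormal branch rates (the uncorrelated
lognormal, UCLN, relaxed clock).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TimeTree",
    "SubstTree",
    "simulate_pure_birth",
    "rescale_to_age",
    "strict_clock_subst_tree",
    "ucln_subst_tree",
]


class TimeTree:
    """Rooted ultrametric bifurcating tree stored in flat arrays.

    Nodes are indexed ``0..2n-2`` for ``n`` tips; tips occupy indices
    ``0..n-1``.  ``parent[root] == -1`` and ``children[tip] == (-1, -1)``.
    Child order is meaningful and preserved through I/O ("left" is
    ``children[v, 0]``, "right" is ``children[v, 1]``).

    Parameters
    ----------
    parent : (M,) int array
        Parent index per node, -1 for the root.
    children : (M, 2) int array
        Ordered child indices per node, -1 for tips.
    ages : (M,) float array
        Node ages, time units before present; 0 for every tip.
    tip_labels : sequence of str
        Labels for tips ``0..n-1``.
    """

    def __init__(self, parent, children, ages, tip_labels):
        self.parent = np.asarray(parent, dtype=np.int64)
        self.children = np.asarray(children, dtype=np.int64)
        self.ages = np.asarray(ages, dtype=np.float64)
        self.tip_labels = list(tip_labels)
        self.n_tips = len(self.tip_labels)
        self.n_nodes = self.parent.shape[0]
        roots = np.flatnonzero(self.parent < 0)
        if roots.size != 1:
            raise ValueError("tree must have exactly one root")
        self.root = int(roots[0])
        self._postorder = None
        self._clades = None
        self.validate()

    # -- structure -------------------------------------------------------

    @property
    def n_internal(self) -> int:
        return self.n_nodes - self.n_tips

    @property
    def root_age(self) -> float:
        return float(self.ages[self.root])

    def is_tip(self, v: int) -> bool:
        return v < self.n_tips

    @property
    def internal_nodes(self) -> np.ndarray:
        return np.arange(self.n_tips, self.n_nodes)

    @property
    def postorder(self) -> np.ndarray:
        """Internal nodes ordered so children precede parents."""
        if self._postorder is None:
            order = []
            stack = [(self.root, False)]
            while stack:
                v, done = stack.pop()
                if v < self.n_tips:
                    continue
                if done:
                    order.append(v)
                else:
                    stack.append((v, True))
                    stack.append((int(self.children[v, 1]), False))
                    stack.append((int(self.children[v, 0]), False))
            self._postorder = np.array(order, dtype=np.int64)
        return self._postorder

    @property
    def preorder(self) -> np.ndarray:
        """All nodes, parents before children, left before right."""
        order = []
        stack = [self.root]
        while stack:
            v = stack.pop()
            order.append(v)
            if v >= self.n_tips:
                stack.append(int(self.children[v, 1]))
                stack.append(int(self.children[v, 0]))
        return np.array(order, dtype=np.int64)

    def clade(self, v: int) -> frozenset:
        """Frozen set of tip labels descending from node ``v``."""
        return self.clades[v]

    @property
    def clades(self):
        """Per-node frozenset of descendant tip labels (node identity key)."""
        if self._clades is None:
            out = [None] * self.n_nodes
            for t in range(self.n_tips):
                out[t] = frozenset([self.tip_labels[t]])
            for v in self.postorder:
                a, b = self.children[v]
                out[v] = out[a] | out[b]
            self._clades = out
        return self._clades

    def branch_durations(self) -> np.ndarray:
        """Per-node duration of the branch above it (nan for the root)."""
        dur = self.ages[self.parent] - self.ages
        dur[self.root] = np.nan
        return dur

    def validate(self) -> None:
        if self.n_tips < 2:
            raise ValueError("need at least 2 tips")
        if self.n_nodes != 2 * self.n_tips - 1:
            raise ValueError("tree is not fully bifurcating")
        if np.any(self.ages[: self.n_tips] != 0.0):
            raise ValueError("tip ages must all be 0")
        for v in range(self.n_tips, self.n_nodes):
            a, b = self.children[v]
            if a < 0 or b < 0:
                raise ValueError(f"internal node {v} lacks two children")
            if self.ages[v] <= max(self.ages[a], self.ages[b]):
                raise ValueError(f"node {v} is not older than its children")

    def copy(self) -> "TimeTree":
        return TimeTree(
            self.parent.copy(), self.children.copy(), self.ages.copy(), list(self.tip_labels)
        )

    def with_ages(self, ages) -> "TimeTree":
        return TimeTree(self.parent, self.children, np.asarray(ages, float), self.tip_labels)

    # -- subtree extraction ---------------------------------------------

    def subtree(self, v: int) -> "TimeTree":
        """Induced subtree rooted at node ``v`` (ages kept on the original
        scale, so the subtree root keeps its age in the full tree)."""
        if self.is_tip(v):
            raise ValueError("cannot extract a subtree rooted at a tip")
        keep = []
        stack = [v]
        while stack:
            u = stack.pop()
            keep.append(u)
            if u >= self.n_tips:
                stack.append(int(self.children[u, 0]))
                stack.append(int(self.children[u, 1]))
        tips = sorted(u for u in keep if u < self.n_tips)
        internals = [u for u in keep if u >= self.n_tips]
        new_id = {u: i for i, u in enumerate(tips)}
        new_id.update({u: len(tips) + i for i, u in enumerate(internals)})
        m = len(keep)
        parent = np.full(m, -1, dtype=np.int64)
        children = np.full((m, 2), -1, dtype=np.int64)
        ages = np.zeros(m)
        for u in keep:
            i = new_id[u]
            ages[i] = self.ages[u]
            if u >= self.n_tips:
                children[i, 0] = new_id[int(self.children[u, 0])]
                children[i, 1] = new_id[int(self.children[u, 1])]
                parent[children[i, 0]] = i
                parent[children[i, 1]] = i
        labels = [self.tip_labels[u] for u in tips]
        return TimeTree(parent, children, ages, labels)

    # -- serialization ---------------------------------------------------

    def newick(self, lengths: np.ndarray | None = None, precision: int = 12) -> str:
        """Newick string; branch lengths default to branch durations."""
        if lengths is None:
            lengths = self.branch_durations()

        def rec(v: int) -> str:
            if v < self.n_tips:
                s = self.tip_labels[v]
            else:
                a, b = self.children[v]
                s = f"({rec(int(a))},{rec(int(b))})"
            if v == self.root:
                return s
            return f"{s}:{lengths[v]:.{precision}g}"

        return rec(self.root) + ";"

    def __repr__(self):
        return f"<TimeTree n_tips={self.n_tips} root_age={self.root_age:.4g}>"


@dataclass
class SubstTree:
    """A TimeTree topology with per-branch substitution rates and lengths.

    ``rates[v]`` and ``lengths[v]`` describe the branch above node ``v``
    (undefined for the root).  ``lengths = branch duration × rate`` always
    holds, in expected substitutions per site.
    """

    tree: TimeTree
    rates: np.ndarray

    lengths: np.ndarray = field(init=False)

    def __post_init__(self):
        self.rates = np.asarray(self.rates, dtype=np.float64)
        if self.rates.shape != (self.tree.n_nodes,):
            raise ValueError("need one rate per node (branch above each node)")
        nonroot = np.arange(self.tree.n_nodes) != self.tree.root
        if np.any(self.rates[nonroot] <= 0):
            raise ValueError("branch rates must be positive")
        dur = self.tree.branch_durations()
        self.lengths = dur * self.rates
        self.lengths[self.tree.root] = np.nan

    def newick(self, precision: int = 12) -> str:
        return self.tree.newick(lengths=self.lengths, precision=precision)


def simulate_pure_birth(n_tips: int, birth_rate: float, seed) -> TimeTree:
    """Simulate an ultrametric pure-birth (Yule) tree with ``n_tips`` tips.

    Split intervals, ordered from the root toward the present, are
    independent exponentials: the k-th interval (k = 1..n-1) has rate
    ``k * birth_rate``, and at each split a uniformly chosen extant lineage
    divides.  The root age is then the total accumulated waiting time, with
    expectation ``sum_{k=1..n-1} 1/(k*birth_rate)`` — the duration law of a
    pure-birth process grown from a single lineage until ``n_tips`` lineages
    exist.  Tips are labelled ``t1..tn`` in preorder; deterministic given
    ``seed``.
    """
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    if birth_rate <= 0:
        raise ValueError("birth_rate must be > 0")
    rng = np.random.default_rng(seed)
    n = int(n_tips)
    k = np.arange(1, n)
    gaps = rng.exponential(1.0 / (k * birth_rate))  # interval k below split k
    # age of split j (1-based, root = 1) = sum of gaps j..n-1
    split_ages = np.cumsum(gaps[::-1])[::-1]

    m = 2 * n - 1
    parent = np.full(m, -1, dtype=np.int64)
    children = np.full((m, 2), -1, dtype=np.int64)
    ages = np.zeros(m)

    root = n  # internal ids n..2n-2 in birth order
    ages[root] = split_ages[0]
    # open edges: (parent node, child slot) awaiting a subtree
    open_edges = [(root, 0), (root, 1)]
    for b in range(1, n - 1):
        v = n + b
        ages[v] = split_ages[b]
        i = int(rng.integers(len(open_edges)))
        p, slot = open_edges[i]
        children[p, slot] = v
        parent[v] = p
        open_edges[i] = (v, 0)
        open_edges.append((v, 1))
    for t, (p, slot) in enumerate(open_edges):
        children[p, slot] = t
        parent[t] = p

    tree = TimeTree(parent, children, ages, [f"x{i}" for i in range(n)])
    # relabel tips t1..tn in preorder encounter order
    order = [int(v) for v in tree.preorder if v < n]
    labels = [""] * n
    for rank, v in enumerate(order, start=1):
        labels[v] = f"t{rank}"
    tree.tip_labels = labels
    tree._clades = None
    return tree


def rescale_to_age(tree: TimeTree, root_age: float) -> TimeTree:
    """Linearly rescale all node ages so the root sits at ``root_age``."""
    if root_age <= 0:
        raise ValueError("root_age must be > 0")
    factor = root_age / tree.root_age
    return tree.with_ages(tree.ages * factor)


def strict_clock_subst_tree(tree: TimeTree, clock_rate: float) -> SubstTree:
    """Constant-rate substitution tree: every branch gets ``clock_rate``."""
    if clock_rate <= 0:
        raise ValueError("clock_rate must be > 0")
    rates = np.full(tree.n_nodes, float(clock_rate))
    return SubstTree(tree, rates)


def ucln_subst_tree(tree: TimeTree, mean_rate: float, sd_log: float, seed) -> SubstTree:
    """Uncorrelated-lognormal relaxed clock rescaling of a chronogram.

    Each branch's rate is an independent lognormal draw whose *real-space*
    mean is ``mean_rate`` and whose *log-space* standard deviation is
    ``sd_log`` (so the log-space mean is ``ln(mean_rate) - sd_log**2 / 2``).
    ``sd_log = 0`` degenerates to the strict clock.
    """
    if mean_rate <= 0:
        raise ValueError("mean_rate must be > 0")
    if sd_log < 0:
        raise ValueError("sd_log must be >= 0")
    if sd_log == 0.0:
        return strict_clock_subst_tree(tree, mean_rate)
    rng = np.random.default_rng(seed)
    mu = np.log(mean_rate) - 0.5 * sd_log**2
    rates = rng.lognormal(mu, sd_log, size=tree.n_nodes)
    rates[tree.root] = mean_rate  # unused; keeps the array positive
    return SubstTree(tree, rates)
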