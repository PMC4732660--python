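"""HKY85 sequence simulation along a substitution tree.

States are coded 0=A, 1=C, 2=G, 3=T throughout the package.  The HKY rate
matrix is normalized so that branch lengths are measured in expected
substitutions per site at stationarity (the conventional scaling).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .treesim import SubstTree

__all__ = ["HKYParams", "Alignment", "hky_transition_matrix", "simulate_alignment", "NUC"]

NUC = "ACGT"


@dataclass(frozen=True)
class HKYParams:
    """HKY85 substitution model parameters.

    kappa : transition/transversion rate ratio (> 0).
    freqs : stationary base frequencies (pi_A, pi_C, pi_G, pi_T), sum to 1.
    """

    kappa: float = 2.0
    freqs: tuple = (0.30, 0.26, 0.23, 0.21)

    def __post_init__(self):
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")
        f = np.asarray(self.freqs, dtype=float)
        if f.shape != (4,) or np.any(f < 0) or abs(f.sum() - 1.0) > 1e-12:
            raise ValueError("freqs must be 4 nonnegative values summing to 1")
        object.__setattr__(self, "freqs", tuple(float(x) for x in f))

    @property
    def pi(self) -> np.ndarray:
        return np.asarray(self.freqs, dtype=float)

    @property
    def beta(self) -> float:
        """Rate-matrix scaler giving one expected substitution per unit length."""
        a, c, g, t = self.freqs
        r, y = a + g, c + t
        return 1.0 / (2.0 * self.kappa * (a * g + c * t) + 2.0 * r * y)


def hky_transition_matrix(branch_length: float, params: HKYParams) -> np.ndarray:
    """Closed-form HKY transition-probability matrix P(t).

    ``branch_length`` is in expected substitutions per site; rows index the
    parent state, columns the child state (row-stochastic).
    """
    if branch_length < 0:
        raise ValueError("branch_length must be >= 0")
    pi = params.pi
    a, c, g, t = pi
    r, y = a + g, c + t
    bt = params.beta * branch_length
    e2 = np.exp(-bt)
    eR = np.exp(-bt * (r * params.kappa + y))
    eY = np.exp(-bt * (y * params.kappa + r))

    P = np.empty((4, 4))
    purine = (0, 2)
    pyrim = (1, 3)
    for i in range(4):
        i_pur = i in purine
        grp, pg, eg = (purine, r, eR) if i_pur else (pyrim, y, eY)
        other = y if i_pur else r
        for j in range(4):
            pj = pi[j]
            if j == i:
                P[i, j] = pj + pj * (other / pg) * e2 + ((pg - pj) / pg) * eg
            elif j in grp:  # transition within purines / pyrimidines
                P[i, j] = pj + pj * (other / pg) * e2 - (pj / pg) * eg
            else:  # transversion
                P[i, j] = pj * (1.0 - e2)
    return P


@dataclass
class Alignment:
    """Gap-free nucleotide alignment: taxa × sites matrix of codes 0..3."""

    labels: list
    seqs: np.ndarray

    def __post_init__(self):
        self.seqs = np.asarray(self.seqs, dtype=np.int8)
        if self.seqs.ndim != 2 or self.seqs.shape[0] != len(self.labels):
            raise ValueError("seqs must be (n_taxa, n_sites) with one row per label")
        if self.seqs.size and (self.seqs.min() < 0 or self.seqs.max() > 3):
            raise ValueError("states must be coded 0..3 (A,C,G,T)")

    @property
    def n_taxa(self) -> int:
        return len(self.labels)

    @property
    def n_sites(self) -> int:
        return self.seqs.shape[1]

    def sequence(self, label: str) -> str:
        row = self.seqs[self.labels.index(label)]
        return "".join(NUC[s] for s in row)

    def restrict(self, labels) -> "Alignment":
        idx = [self.labels.index(l) for l in labels]
        return Alignment(list(labels), self.seqs[idx].copy())


def simulate_alignment(tree: SubstTree, params: HKYParams, n_sites: int, seed) -> Alignment:
    """Simulate an i.i.d.-site HKY alignment down a substitution tree.

    Root states are drawn from the stationary frequencies; each child's state
    is drawn from the transition matrix of its branch length.  Deterministic
    given ``seed``.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    tt = tree.tree
    rng = np.random.default_rng(seed)
    states = np.empty((tt.n_nodes, n_sites), dtype=np.int8)
    states[tt.root] = rng.choice(4, size=n_sites, p=params.pi)
    for v in tt.preorder:
        v = int(v)
        if v == tt.root:
            continue
        P = hky_transition_matrix(float(tree.lengths[v]), params)
        cum = np.cumsum(P, axis=1)
        u = rng.random(n_sites)
        parent_states = states[tt.parent[v]]
        states[v] = (u[:, None] > cum[parent_states]).sum(axis=1).astype(np.int8)
    return Alignment(list(tt.tip_labels), states[: tt.n_tips].copy())
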