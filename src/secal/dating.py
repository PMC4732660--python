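"""Fixed-topology Bayesian node dating by Metropolis–Hastings MCMC.

The model is the standard relaxed-clock node-dating setup: an HKY likelihood
computed by Felsenstein pruning, a pure-birth (Yule) prior on internal node
ages, independent lognormal branch rates (the uncorrelated lognormal clock,
UCLN) with estimated log-space mean and standard deviation, and arbitrary
node-age calibration densities (lognormal, uniform, truncated normal).
Topology is always fixed; nodes are identified by their frozen set of
descendant tip labels, which is a bijection under a fixed topology.

Hyperpriors (recorded, testable choices): the UCLN log-mean is flat on
[ln 1e-8, ln 1e2]; the UCLN log-sd is exponential with mean 1; kappa is
lognormal(ln 2, 1); base frequencies are uniform on the simplex; the birth
rate, when estimated, is flat on the log scale within [1e-6, 1e3].
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from ._pruning import full_pruning_fill, hky_pruning, path_update_fill, root_loglik
from .calibrate import CalibrationPrior
from .seqsim import Alignment, HKYParams
from .treesim import TimeTree

__all__ = [
    "McmcConfig",
    "Trace",
    "NodeSummary",
    "pruning_log_likelihood",
    "yule_log_prior",
    "ucln_log_prior",
    "hyperprior_log_density",
    "calibration_log_prior",
    "run_mcmc",
    "hpd_interval",
    "summarize_trace",
    "effective_sample_size",
]

_LN_2PI = math.log(2.0 * math.pi)
_MU_BOUNDS = (math.log(1e-8), math.log(1e2))
_LAMBDA_BOUNDS = (1e-6, 1e3)


# ---------------------------------------------------------------------------
# configuration / result containers


@dataclass
class McmcConfig:
    """Sampler configuration.

    ``chain_length`` counts single-operator generations (one proposal per
    generation); states are recorded every ``sample_every`` generations and
    the first ``burnin_fraction`` of recorded samples is discarded at
    summary time.  ``fix_clock_rate`` switches to a strict clock with that
    known rate (no rate moves); ``likelihood_on=False`` samples the joint
    prior, the strongest available correctness check for the sampler.
    """

    chain_length: int = 200_000
    sample_every: int = 100
    burnin_fraction: float = 0.5
    seed: int = 0
    likelihood_on: bool = True
    fix_clock_rate: float | None = None
    fix_kappa: bool = False
    fix_freqs: bool = False
    estimate_birth_rate: bool = True
    birth_rate_init: float = 0.1
    clock_rate_init: float = 0.01
    sigma_init: float = 0.5
    # proposal scales (multiplicative moves use exp(scale*(u-1/2)))
    root_scale: float = 0.2
    tree_scale: float = 0.1
    updown_scale: float = 0.3
    rate_scale: float = 0.8
    kappa_scale: float = 0.3
    freq_delta: float = 0.04
    mu_step: float = 0.25
    sigma_scale: float = 0.5
    lambda_scale: float = 0.6
    weights: dict | None = None

    def __post_init__(self):
        if not (self.chain_length >= self.sample_every >= 1):
            raise ValueError("need chain_length >= sample_every >= 1")
        if not (0.0 <= self.burnin_fraction < 1.0):
            raise ValueError("burnin_fraction must be in [0, 1)")


@dataclass
class Trace:
    """Posterior samples from one MCMC run (one row per recorded state)."""

    generations: np.ndarray
    loglik: np.ndarray
    logprior: np.ndarray
    kappa: np.ndarray
    freqs: np.ndarray  # (S, 4)
    mu_log: np.ndarray
    sd_log: np.ndarray
    birth_rate: np.ndarray
    node_keys: list  # frozensets, one per internal node, fixed order
    node_ages: np.ndarray  # (S, n_internal)
    rate_keys: list  # frozensets, one per non-root branch (child clade)
    rates: np.ndarray  # (S, n_branches)

    @property
    def n_samples(self) -> int:
        return len(self.generations)


@dataclass(frozen=True)
class NodeSummary:
    """Posterior summary of one node's age: median and 95% HPD bounds."""

    key: frozenset
    median: float
    hpd_lo: float
    hpd_hi: float

    @property
    def ci_width(self) -> float:
        return self.hpd_hi - self.hpd_lo

    def __post_init__(self):
        if not (self.hpd_lo <= self.median <= self.hpd_hi):
            raise ValueError("need hpd_lo <= median <= hpd_hi")


# ---------------------------------------------------------------------------
# model densities


def _compress_alignment(alignment: Alignment, tree: TimeTree):
    """Reorder rows to tip-index order and collapse identical site patterns."""
    if set(alignment.labels) != set(tree.tip_labels):
        raise ValueError("alignment taxa do not match tree tips")
    idx = [alignment.labels.index(l) for l in tree.tip_labels]
    mat = alignment.seqs[idx]
    patterns, counts = np.unique(mat.T, axis=0, return_counts=True)
    return np.ascontiguousarray(patterns.T), counts.astype(np.float64)


def pruning_log_likelihood(
    topology: TimeTree,
    branch_rates: np.ndarray,
    params: HKYParams,
    alignment: Alignment,
) -> float:
    """log P(alignment | topology ages, branch rates, HKY params).

    ``branch_rates[v]`` applies to the branch above node ``v``; the branch's
    substitution length is its duration times its rate.
    """
    tip_states, counts = _compress_alignment(alignment, topology)
    blens = (topology.ages[topology.parent] - topology.ages) * np.asarray(branch_rates, float)
    blens[topology.root] = 0.0
    if np.any(blens < 0):
        raise ValueError("negative branch length (invalid ages or rates)")
    L = np.empty((topology.n_nodes, tip_states.shape[1], 4))
    logscale = np.empty(tip_states.shape[1])
    return float(
        hky_pruning(
            topology.postorder,
            topology.children,
            blens,
            tip_states,
            counts,
            float(params.kappa),
            params.pi,
            topology.n_tips,
            L,
            logscale,
        )
    )


class _LikEngine:
    """Cached pruning partials with ancestor-path updates.

    Each internal node stores max-normalized partials plus a cumulative
    log-scaler per site pattern.  A proposal touching one node's branches
    only recomputes the path from that node to the root (into buffers that
    are copied back on acceptance); kappa/frequency/whole-tree moves do a
    full refill into a second buffer pair that is swapped in on acceptance.
    """

    def __init__(self, tree: TimeTree, alignment: Alignment):
        if alignment is None:
            raise ValueError("likelihood requires an alignment")
        self.tree = tree
        self.tip_states, self.counts = _compress_alignment(alignment, tree)
        M = tree.n_nodes
        n_pat = self.tip_states.shape[1]
        self.L = np.empty((M, n_pat, 4))
        self.C = np.empty((M, n_pat))
        self.L2 = np.empty((M, n_pat, 4))
        self.C2 = np.empty((M, n_pat))
        # ancestor path (self -> root) per node
        self.paths = []
        for v in range(M):
            path = []
            u = v
            while u >= 0:
                if u >= tree.n_tips:
                    path.append(u)
                u = int(tree.parent[u])
            self.paths.append(np.array(path, dtype=np.int64))
        maxlen = max(len(p) for p in self.paths)
        self.Lb = np.empty((maxlen, n_pat, 4))
        self.Cb = np.empty((maxlen, n_pat))

    def full(self, blens, kappa, freqs) -> float:
        full_pruning_fill(
            self.tree.postorder, self.tree.children, blens, self.tip_states,
            self.tree.n_tips, kappa, freqs, self.L, self.C,
        )
        r = self.tree.root
        return float(root_loglik(self.L[r], self.C[r], freqs, self.counts))

    def propose_full(self, blens, kappa, freqs) -> float:
        full_pruning_fill(
            self.tree.postorder, self.tree.children, blens, self.tip_states,
            self.tree.n_tips, kappa, freqs, self.L2, self.C2,
        )
        r = self.tree.root
        return float(root_loglik(self.L2[r], self.C2[r], freqs, self.counts))

    def accept_full(self):
        self.L, self.L2 = self.L2, self.L
        self.C, self.C2 = self.C2, self.C

    def propose_path(self, v: int, blens, kappa, freqs) -> float:
        path = self.paths[v]
        k = len(path)
        path_update_fill(
            path, self.tree.children, blens, self.tip_states, self.tree.n_tips,
            kappa, freqs, self.L, self.C, self.Lb[:k], self.Cb[:k],
        )
        return float(root_loglik(self.Lb[k - 1], self.Cb[k - 1], freqs, self.counts))

    def accept_path(self, v: int):
        path = self.paths[v]
        k = len(path)
        self.L[path] = self.Lb[:k]
        self.C[path] = self.Cb[:k]


def yule_log_prior(tree: TimeTree, birth_rate: float, ages=None) -> float:
    """Log density of internal node ages under the pure-birth construction.

    For the fixed topology, the joint density of node ages implied by
    :func:`secal.treesim.simulate_pure_birth` is proportional to
    ``exp(-birth_rate * sum(ages))`` on the region respecting the tree's
    parent-older-than-child partial order; the normalizing topology terms are
    constant across states and kept as ``(n-1) * log(birth_rate)``.
    Returns ``-inf`` for any age vector violating the ordering.  ``ages``
    optionally overrides the tree's own age vector (same indexing).
    """
    if birth_rate <= 0:
        raise ValueError("birth_rate must be > 0")
    ages = tree.ages if ages is None else np.asarray(ages, float)
    for v in range(tree.n_tips, tree.n_nodes):
        a, b = tree.children[v]
        if ages[v] <= max(ages[a], ages[b]):
            return -math.inf
    n1 = tree.n_tips - 1
    return n1 * math.log(birth_rate) - birth_rate * float(ages[tree.n_tips :].sum())


def _yule_log_prior_raw(internal_ages: np.ndarray, birth_rate: float, n_tips: int) -> float:
    return (n_tips - 1) * math.log(birth_rate) - birth_rate * float(internal_ages.sum())


def ucln_log_prior(rates: np.ndarray, mu_log: float, sd_log: float) -> float:
    """Sum of independent lognormal log-densities over branch rates.

    ``mu_log`` and ``sd_log`` are the log-space mean and standard deviation.
    ``sd_log = 0`` is the degenerate point mass at ``exp(mu_log)``.
    """
    if sd_log < 0:
        raise ValueError("sd_log must be >= 0")
    r = np.asarray(rates, dtype=float)
    if np.any(r <= 0):
        return -math.inf
    if sd_log == 0.0:
        return 0.0 if np.allclose(np.log(r), mu_log) else -math.inf
    z = (np.log(r) - mu_log) / sd_log
    return float(np.sum(-np.log(r * sd_log) - 0.5 * _LN_2PI - 0.5 * z * z))


def hyperprior_log_density(
    mu_log: float, sd_log: float, kappa: float, freqs, birth_rate: float | None = None
) -> float:
    """Joint log density of the sampler's hyperpriors (see module docstring)."""
    lp = 0.0
    if not (_MU_BOUNDS[0] <= mu_log <= _MU_BOUNDS[1]):
        return -math.inf
    if sd_log < 0:
        return -math.inf
    lp += -sd_log  # Exp(1)
    if kappa <= 0:
        return -math.inf
    zk = math.log(kappa) - math.log(2.0)
    lp += -math.log(kappa) - 0.5 * _LN_2PI - 0.5 * zk * zk  # LN(ln 2, 1)
    f = np.asarray(freqs, float)
    if np.any(f <= 0) or abs(f.sum() - 1.0) > 1e-9:
        return -math.inf
    if birth_rate is not None:
        if not (_LAMBDA_BOUNDS[0] <= birth_rate <= _LAMBDA_BOUNDS[1]):
            return -math.inf
        lp += -math.log(birth_rate)  # flat on the log scale
    return lp


def calibration_log_prior(prior: CalibrationPrior, age: float) -> float:
    """Log density of a calibration prior evaluated at a node age."""
    kind = prior.kind
    p = prior.params
    if kind == "uniform":
        lo, hi = p["lo"], p["hi"]
        return -math.log(hi - lo) if lo <= age <= hi else -math.inf
    if kind == "lognormal":
        if age <= 0:
            return -math.inf
        m, s = p["log_mean"], p["log_sd"]
        z = (math.log(age) - m) / s
        return -math.log(age * s) - 0.5 * _LN_2PI - 0.5 * z * z
    if kind == "normal":
        if age < 0:
            return -math.inf
        m, s = p["mean"], p["sd"]
        z = (age - m) / s
        # truncated at zero and renormalized: divide by P(X > 0)
        log_tail = math.log(0.5 * math.erfc(-m / (s * math.sqrt(2.0))))
        return -math.log(s) - 0.5 * _LN_2PI - 0.5 * z * z - log_tail
    raise ValueError(f"unknown calibration kind {kind!r}")


# ---------------------------------------------------------------------------
# MCMC


def _lognorm_logpdf(x: float, mu: float, sd: float) -> float:
    z = (math.log(x) - mu) / sd
    return -math.log(x * sd) - 0.5 * _LN_2PI - 0.5 * z * z


def run_mcmc(
    alignment: Alignment | None,
    topology: TimeTree,
    calibrations: list[CalibrationPrior],
    params0: HKYParams,
    config: McmcConfig,
) -> Trace:
    """Sample node ages, branch rates and model parameters by MCMC.

    ``topology`` provides both the fixed topology and the starting ages
    (which must satisfy every calibration's support).  Returns a
    :class:`Trace`; summarize with :func:`summarize_trace`.
    """
    cfg = config
    tree = topology.copy()
    n_tips, M, root = tree.n_tips, tree.n_nodes, tree.root
    rng = np.random.default_rng(cfg.seed)

    if cfg.likelihood_on and alignment is None:
        raise ValueError("likelihood_on requires an alignment")
    if cfg.likelihood_on and not calibrations and cfg.fix_clock_rate is None:
        raise ValueError(
            "no time-scale information: provide a calibration or fix the clock rate"
        )

    # node bookkeeping
    clade_of = {tree.clades[v]: v for v in range(M)}
    calib_by_node: dict[int, CalibrationPrior] = {}
    for c in calibrations:
        if c.key not in clade_of:
            raise ValueError(f"calibration clade not in tree: {sorted(c.key)[:4]}...")
        v = clade_of[c.key]
        if v < n_tips:
            raise ValueError("cannot calibrate a tip")
        calib_by_node[v] = c

    internal = list(range(n_tips, M))
    nonroot_internal = np.array([v for v in internal if v != root], dtype=np.int64)
    branches = np.array([v for v in range(M) if v != root], dtype=np.int64)

    # state
    ages = tree.ages.copy()
    strict = cfg.fix_clock_rate is not None
    if strict:
        mu = math.log(cfg.fix_clock_rate)
        sigma = 0.0
        rates = np.full(M, cfg.fix_clock_rate, dtype=float)
    else:
        mu = math.log(cfg.clock_rate_init)
        sigma = cfg.sigma_init
        rates = np.full(M, math.exp(mu), dtype=float)
    kappa = float(params0.kappa)
    freqs = params0.pi.copy()
    lam = float(cfg.birth_rate_init)

    # likelihood machinery: cached per-node partials with path updates
    engine = _LikEngine(tree, alignment) if cfg.likelihood_on else None

    def fresh_blens():
        b = (ages[tree.parent] - ages) * rates
        b[root] = 0.0
        return b

    blens = fresh_blens()

    def calib_lp(node: int, age: float) -> float:
        c = calib_by_node.get(node)
        return 0.0 if c is None else calibration_log_prior(c, age)

    cur_ll = engine.full(blens, kappa, freqs) if engine else 0.0
    cur_yule = _yule_log_prior_raw(ages[n_tips:], lam, n_tips)
    cur_ucln = 0.0 if strict else ucln_log_prior(rates[branches], mu, sigma)
    cur_calib = sum(calib_lp(v, ages[v]) for v in calib_by_node)
    mu_eff = 0.0 if strict else mu
    sigma_eff = 0.0 if strict else sigma
    cur_hyper = hyperprior_log_density(
        mu_eff, sigma_eff, kappa, freqs, lam if cfg.estimate_birth_rate else None
    )
    if not np.isfinite(cur_ll + cur_yule + cur_ucln + cur_calib + cur_hyper):
        raise ValueError("initial state has zero posterior density")

    # move schedule
    w = {
        "age": 30.0 * max(len(nonroot_internal), 1) / max(M, 1),
        "root": 4.0,
        # under data the likelihood pins branch lengths, so whole-tree
        # scaling is handled by the (cheap, length-preserving) updown move;
        # the pure tree-scale move earns its keep in prior-only runs
        "treescale": 1.0 if cfg.likelihood_on else 4.0,
        "updown": 0.0 if strict else 8.0,
        "rate": 0.0 if strict else 30.0 * len(branches) / M,
        "kappa": 0.0 if cfg.fix_kappa else 1.0,
        "freqs": 0.0 if cfg.fix_freqs else 1.5,
        "mu": 0.0 if strict else 4.0,
        "sigma": 0.0 if strict else 4.0,
        "lambda": 4.0 if cfg.estimate_birth_rate else 0.0,
    }
    if len(nonroot_internal) == 0:
        w["age"] = 0.0
    if cfg.weights:
        w.update(cfg.weights)
    move_names = [k for k, wt in w.items() if wt > 0]
    move_p = np.array([w[k] for k in move_names])
    move_p = move_p / move_p.sum()

    n_rec = cfg.chain_length // cfg.sample_every
    S = n_rec + 1
    rec_gen = np.empty(S, dtype=np.int64)
    rec_ll = np.empty(S)
    rec_lp = np.empty(S)
    rec_kappa = np.empty(S)
    rec_freqs = np.empty((S, 4))
    rec_mu = np.empty(S)
    rec_sigma = np.empty(S)
    rec_lam = np.empty(S)
    rec_ages = np.empty((S, len(internal)))
    rec_rates = np.empty((S, len(branches)))

    def record(i, gen):
        rec_gen[i] = gen
        rec_ll[i] = cur_ll
        rec_lp[i] = cur_yule + cur_ucln + cur_calib + cur_hyper
        rec_kappa[i] = kappa
        rec_freqs[i] = freqs
        rec_mu[i] = mu
        rec_sigma[i] = sigma
        rec_lam[i] = lam
        rec_ages[i] = ages[n_tips:]
        rec_rates[i] = rates[branches]

    record(0, 0)
    rec_i = 1

    children_arr = tree.children
    parent_arr = tree.parent

    moves = rng.choice(len(move_names), size=cfg.chain_length, p=move_p)
    for gen in range(1, cfg.chain_length + 1):
        name = move_names[moves[gen - 1]]

        if name == "age":
            v = int(nonroot_internal[rng.integers(len(nonroot_internal))])
            a, b = children_arr[v]
            pv = parent_arr[v]
            lo = max(ages[a], ages[b])
            hi = ages[pv]
            new = lo + (hi - lo) * rng.random()
            dlp = -lam * (new - ages[v]) + calib_lp(v, new) - calib_lp(v, ages[v])
            old = ages[v]
            old_b = (blens[v], blens[a], blens[b])
            ages[v] = new
            blens[v] = (ages[pv] - new) * rates[v]
            blens[a] = (new - ages[a]) * rates[a]
            blens[b] = (new - ages[b]) * rates[b]
            new_ll = engine.propose_path(v, blens, kappa, freqs) if engine else 0.0
            if math.log(rng.random()) < (new_ll - cur_ll) + dlp:
                if engine:
                    engine.accept_path(v)
                cur_ll = new_ll
                cur_yule += -lam * (new - old)
                cur_calib += calib_lp(v, new) - calib_lp(v, old)
            else:
                ages[v] = old
                blens[v], blens[a], blens[b] = old_b

        elif name == "root":
            c = math.exp(cfg.root_scale * (rng.random() - 0.5))
            a, b = children_arr[root]
            old = ages[root]
            new = old * c
            if new > max(ages[a], ages[b]):
                dlp = -lam * (new - old) + calib_lp(root, new) - calib_lp(root, old)
                old_b = (blens[a], blens[b])
                ages[root] = new
                blens[a] = (new - ages[a]) * rates[a]
                blens[b] = (new - ages[b]) * rates[b]
                new_ll = engine.propose_path(root, blens, kappa, freqs) if engine else 0.0
                if math.log(rng.random()) < (new_ll - cur_ll) + dlp + math.log(c):
                    if engine:
                        engine.accept_path(root)
                    cur_ll = new_ll
                    cur_yule += -lam * (new - old)
                    cur_calib += calib_lp(root, new) - calib_lp(root, old)
                else:
                    ages[root] = old
                    blens[a], blens[b] = old_b

        elif name == "treescale":
            # multiply every internal age by c; tips stay at zero so the
            # partial order is preserved automatically
            c = math.exp(cfg.tree_scale * (rng.random() - 0.5))
            old_int = ages[n_tips:].copy()
            old_calib_part = sum(calib_lp(v, ages[v]) for v in calib_by_node)
            ages[n_tips:] = old_int * c
            new_calib = sum(calib_lp(v, ages[v]) for v in calib_by_node)
            dlp = -lam * (c - 1.0) * float(old_int.sum()) + (new_calib - old_calib_part)
            new_blens = fresh_blens()
            new_ll = engine.propose_full(new_blens, kappa, freqs) if engine else 0.0
            n_int = len(internal)
            if math.log(rng.random()) < (new_ll - cur_ll) + dlp + n_int * math.log(c):
                if engine:
                    engine.accept_full()
                blens = new_blens
                cur_ll = new_ll
                cur_yule += -lam * (c - 1.0) * float(old_int.sum())
                cur_calib += new_calib - old_calib_part
            else:
                ages[n_tips:] = old_int

        elif name == "updown":
            # ages up, rates (and their lognormal mean) down: branch lengths
            # (duration x rate) are invariant, so the likelihood is
            # untouched -- the key operator for mixing over the time/rate
            # scale.  Shifting mu_log with the rates keeps every rate's
            # z-score fixed, so the UCLN prior change reduces to the
            # density's 1/rate terms.
            c = math.exp(cfg.updown_scale * (rng.random() - 0.5))
            new_mu = mu - math.log(c)
            if _MU_BOUNDS[0] <= new_mu <= _MU_BOUNDS[1]:
                old_int = ages[n_tips:].copy()
                old_rates = rates.copy()
                old_calib_part = sum(calib_lp(v, ages[v]) for v in calib_by_node)
                ages[n_tips:] = old_int * c
                rates = rates / c
                new_calib = sum(calib_lp(v, ages[v]) for v in calib_by_node)
                new_ucln = ucln_log_prior(rates[branches], new_mu, sigma)
                dlp = (
                    -lam * (c - 1.0) * float(old_int.sum())
                    + (new_calib - old_calib_part)
                    + (new_ucln - cur_ucln)
                )
                hast = (len(internal) - len(branches)) * math.log(c)
                if math.log(rng.random()) < dlp + hast:
                    cur_yule += -lam * (c - 1.0) * float(old_int.sum())
                    cur_calib += new_calib - old_calib_part
                    cur_ucln = new_ucln
                    mu = new_mu
                else:
                    ages[n_tips:] = old_int
                    rates = old_rates

        elif name == "rate":
            v = int(branches[rng.integers(len(branches))])
            c = math.exp(cfg.rate_scale * (rng.random() - 0.5))
            old = rates[v]
            new = old * c
            dprior = _lognorm_logpdf(new, mu, sigma) - _lognorm_logpdf(old, mu, sigma)
            old_bl = blens[v]
            rates[v] = new
            blens[v] = old_bl * c
            pv = int(parent_arr[v])
            new_ll = engine.propose_path(pv, blens, kappa, freqs) if engine else 0.0
            if math.log(rng.random()) < (new_ll - cur_ll) + dprior + math.log(c):
                if engine:
                    engine.accept_path(pv)
                cur_ll = new_ll
                cur_ucln += dprior
            else:
                rates[v] = old
                blens[v] = old_bl

        elif name == "kappa":
            c = math.exp(cfg.kappa_scale * (rng.random() - 0.5))
            old = kappa
            new = old * c
            new_hyper = hyperprior_log_density(
                0.0 if strict else mu, 0.0 if strict else sigma, new, freqs,
                lam if cfg.estimate_birth_rate else None,
            )
            new_ll = engine.propose_full(blens, new, freqs) if engine else 0.0
            if math.log(rng.random()) < (new_ll - cur_ll) + (new_hyper - cur_hyper) + math.log(c):
                if engine:
                    engine.accept_full()
                kappa = new
                cur_ll = new_ll
                cur_hyper = new_hyper

        elif name == "freqs":
            i, j = rng.choice(4, size=2, replace=False)
            d = cfg.freq_delta * (2.0 * rng.random() - 1.0)
            newf = freqs.copy()
            newf[i] -= d
            newf[j] += d
            if newf[i] > 1e-4 and newf[j] > 1e-4 and newf[i] < 1 and newf[j] < 1:
                new_ll = engine.propose_full(blens, kappa, newf) if engine else 0.0
                if math.log(rng.random()) < (new_ll - cur_ll):
                    if engine:
                        engine.accept_full()
                    freqs = newf
                    cur_ll = new_ll

        elif name == "mu":
            new = mu + cfg.mu_step * (2.0 * rng.random() - 1.0)
            if _MU_BOUNDS[0] <= new <= _MU_BOUNDS[1]:
                new_ucln = ucln_log_prior(rates[branches], new, sigma)
                if math.log(rng.random()) < (new_ucln - cur_ucln):
                    mu = new
                    cur_ucln = new_ucln

        elif name == "sigma":
            c = math.exp(cfg.sigma_scale * (rng.random() - 0.5))
            new = sigma * c
            new_ucln = ucln_log_prior(rates[branches], mu, new)
            dhyper = -(new - sigma)
            if math.log(rng.random()) < (new_ucln - cur_ucln) + dhyper + math.log(c):
                cur_hyper += dhyper
                sigma = new
                cur_ucln = new_ucln

        elif name == "lambda":
            c = math.exp(cfg.lambda_scale * (rng.random() - 0.5))
            new = lam * c
            if _LAMBDA_BOUNDS[0] <= new <= _LAMBDA_BOUNDS[1]:
                new_yule = _yule_log_prior_raw(ages[n_tips:], new, n_tips)
                dhyper = -(math.log(new) - math.log(lam))
                if math.log(rng.random()) < (new_yule - cur_yule) + dhyper + math.log(c):
                    cur_hyper += dhyper
                    lam = new
                    cur_yule = new_yule

        if gen % cfg.sample_every == 0:
            record(rec_i, gen)
            rec_i += 1

    return Trace(
        generations=rec_gen[:rec_i],
        loglik=rec_ll[:rec_i],
        logprior=rec_lp[:rec_i],
        kappa=rec_kappa[:rec_i],
        freqs=rec_freqs[:rec_i],
        mu_log=rec_mu[:rec_i],
        sd_log=rec_sigma[:rec_i],
        birth_rate=rec_lam[:rec_i],
        node_keys=[tree.clades[v] for v in internal],
        node_ages=rec_ages[:rec_i],
        rate_keys=[tree.clades[v] for v in branches],
        rates=rec_rates[:rec_i],
    )


# ---------------------------------------------------------------------------
# trace summarization


def hpd_interval(samples, prob: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval of sorted samples holding ceil(prob*n)."""
    x = np.sort(np.asarray(samples, dtype=float))
    n = x.size
    if n == 0:
        raise ValueError("hpd_interval needs at least one sample")
    if not (0.0 < prob < 1.0):
        raise ValueError("prob must be in (0, 1)")
    m = min(n, int(math.ceil(prob * n)))
    if m == n:
        return float(x[0]), float(x[-1])
    widths = x[m - 1 + np.arange(n - m + 1)] - x[: n - m + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + m - 1])


def summarize_trace(trace: Trace, burnin_fraction: float = 0.5) -> dict:
    """Per-node posterior median and 95% HPD after burn-in.

    Returns ``{clade key (frozenset): NodeSummary}``.
    """
    n = trace.n_samples
    start = int(math.floor(burnin_fraction * n))
    if start >= n:
        raise ValueError("burn-in discards every sample")
    out = {}
    for j, key in enumerate(trace.node_keys):
        post = trace.node_ages[start:, j]
        lo, hi = hpd_interval(post, 0.95)
        med = float(np.median(post))
        med = min(max(med, lo), hi)
        out[key] = NodeSummary(key=key, median=med, hpd_lo=lo, hpd_hi=hi)
    return out


def effective_sample_size(series) -> float:
    """ESS = n / (1 + 2 * sum of autocorrelations), truncated at the first
    non-positive Geyer pair (rho_{2k} + rho_{2k+1} <= 0)."""
    x = np.asarray(series, dtype=float)
    n = x.size
    if n < 10:
        raise ValueError("need at least 10 samples")
    v = np.var(x)
    if v == 0:
        warnings.warn("constant series: ESS reported as n", RuntimeWarning)
        return float(n)
    xc = x - x.mean()
    nfft = int(2 ** math.ceil(math.log2(2 * n)))
    f = np.fft.rfft(xc, nfft)
    acov = np.fft.irfft(f * np.conj(f), nfft)[:n].real / n
    rho = acov / acov[0]
    s = 0.0
    k = 1
    while k + 1 < n:
        pair = rho[k] + rho[k + 1]
        if pair <= 0:
            break
        s += pair
        k += 2
    return float(n / (1.0 + 2.0 * s))
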