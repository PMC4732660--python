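"""Construction of primary and secondary node-age calibration priors.

Primary calibrations emulate fossil information: lognormal priors (log-space
sd 1) whose median equals the calibrated node's true age, placed on randomly
chosen internal nodes plus the root.  Secondary calibrations are built from
a primary analysis's posterior 95% HPD: either a uniform density between the
HPD bounds, or a normal density whose central 95% mass spans them
(truncated at zero, since negative ages are meaningless).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .treesim import TimeTree

__all__ = [
    "CalibrationPrior",
    "IneligibleReplicateError",
    "sample_primary_calibrations",
    "uniform_secondary_prior",
    "normal_secondary_prior",
    "second_calibration_node",
    "Z_975",
]

Z_975 = 1.959963984540054  # standard normal 97.5% quantile


class IneligibleReplicateError(ValueError):
    """Raised when a replicate cannot host the requested calibration node."""


@dataclass(frozen=True)
class CalibrationPrior:
    """A node-age prior: the node's clade key plus a distribution over age.

    kind is one of ``lognormal`` (params ``log_mean``, ``log_sd``),
    ``uniform`` (``lo``, ``hi``) or ``normal`` (``mean``, ``sd``; truncated
    at zero).  All kinds place zero mass on negative ages.
    """

    key: frozenset
    kind: str
    params: dict

    def __post_init__(self):
        object.__setattr__(self, "key", frozenset(self.key))
        p = self.params
        if self.kind == "uniform":
            if not (0 <= p["lo"] < p["hi"]):
                raise ValueError("uniform prior needs 0 <= lo < hi")
        elif self.kind == "normal":
            if p["sd"] <= 0:
                raise ValueError("normal prior needs sd > 0")
        elif self.kind == "lognormal":
            if p["log_sd"] <= 0:
                raise ValueError("lognormal prior needs log_sd > 0")
        else:
            raise ValueError(f"unknown calibration kind {self.kind!r}")

    @property
    def median(self) -> float:
        if self.kind == "uniform":
            return 0.5 * (self.params["lo"] + self.params["hi"])
        if self.kind == "lognormal":
            return math.exp(self.params["log_mean"])
        return float(
            stats.truncnorm.median(
                -self.params["mean"] / self.params["sd"], np.inf,
                loc=self.params["mean"], scale=self.params["sd"],
            )
        )

    def interval(self, prob: float = 0.95) -> tuple[float, float]:
        """Central ``prob`` interval of the prior."""
        a = (1.0 - prob) / 2.0
        if self.kind == "uniform":
            lo, hi = self.params["lo"], self.params["hi"]
            w = hi - lo
            return lo + a * w, hi - a * w
        if self.kind == "lognormal":
            d = stats.lognorm(s=self.params["log_sd"], scale=math.exp(self.params["log_mean"]))
            return float(d.ppf(a)), float(d.ppf(1 - a))
        m, s = self.params["mean"], self.params["sd"]
        d = stats.truncnorm(-m / s, np.inf, loc=m, scale=s)
        return float(d.ppf(a)), float(d.ppf(1 - a))

    def to_dict(self) -> dict:
        return {"tips": sorted(self.key), "kind": self.kind, "params": dict(self.params)}

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationPrior":
        return cls(frozenset(d["tips"]), d["kind"], dict(d["params"]))


def sample_primary_calibrations(
    true_tree: TimeTree, n_internal: int, seed, log_sd: float = 1.0
) -> list[CalibrationPrior]:
    """Lognormal calibrations on ``n_internal`` random internal nodes + root.

    Each prior's log-space mean is ``ln(true age)`` so its median equals the
    node's true age, with log-space sd ``log_sd`` (default 1).
    """
    candidates = [v for v in true_tree.internal_nodes if v != true_tree.root]
    if n_internal >= len(candidates) + 1:
        raise ValueError(
            f"requested {n_internal} internal calibrations but only "
            f"{len(candidates)} non-root internal nodes exist"
        )
    rng = np.random.default_rng(seed)
    chosen = list(rng.choice(candidates, size=n_internal, replace=False))
    chosen.append(true_tree.root)
    out = []
    for v in chosen:
        age = float(true_tree.ages[v])
        out.append(
            CalibrationPrior(
                true_tree.clades[int(v)],
                "lognormal",
                {"log_mean": math.log(age), "log_sd": float(log_sd)},
            )
        )
    return out


def uniform_secondary_prior(hpd_lo: float, hpd_hi: float, node_key) -> CalibrationPrior:
    """Uniform secondary prior spanning a primary 95% HPD interval."""
    if not (0 <= hpd_lo < hpd_hi):
        raise ValueError("need 0 <= hpd_lo < hpd_hi (non-degenerate interval)")
    return CalibrationPrior(frozenset(node_key), "uniform", {"lo": float(hpd_lo), "hi": float(hpd_hi)})


def normal_secondary_prior(hpd_lo: float, hpd_hi: float, node_key) -> CalibrationPrior:
    """Normal secondary prior whose central 95% mass spans a primary HPD.

    mean = interval midpoint; sd = width / (2 * z_0.975).  The density is
    truncated at zero when evaluated, so the 95%-span property is exact
    whenever the interval sits away from zero.
    """
    if not (0 <= hpd_lo < hpd_hi):
        raise ValueError("need 0 <= hpd_lo < hpd_hi (non-degenerate interval)")
    mean = 0.5 * (hpd_lo + hpd_hi)
    sd = (hpd_hi - hpd_lo) / (2.0 * Z_975)
    return CalibrationPrior(frozenset(node_key), "normal", {"mean": mean, "sd": sd})


def second_calibration_node(subtree: TimeTree) -> frozenset:
    """Clade key of the node two steps tipward of the root on the right side.

    "Right" is the second child in stored (Newick) order.  Raises
    :class:`IneligibleReplicateError` when that position is a tip, in which
    case the caller substitutes the next eligible replicate.
    """
    r = subtree.root
    c1 = int(subtree.children[r, 1])
    if subtree.is_tip(c1):
        raise IneligibleReplicateError("root's right child is a tip")
    c2 = int(subtree.children[c1, 1])
    if subtree.is_tip(c2):
        raise IneligibleReplicateError("node two tipward on the right is a tip")
    return subtree.clades[c2]
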