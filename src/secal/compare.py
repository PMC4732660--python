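"""Difference statistics between primary and secondary dating analyses.

Sign convention throughout: differences are primary − secondary, so a
positive median difference means the secondary estimate is *younger* and a
positive CI-width difference means the secondary interval is *narrower*.
Per replicate, the four absolute sums (|Δmin|, |Δmax|, |Δmedian|, |Δwidth|
over matched nodes) measure total error; paired t-tests (two-sided, with
Bonferroni correction across replicates) test the median shift; a pooled
paired t-test over every matched node of every replicate tests CI-width
narrowing.  These are descriptive: overlapping nodes across replicates are
not independent, and no correction for that is attempted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "NodeDifference",
    "ReplicateComparison",
    "TTestResult",
    "RegressionResult",
    "node_differences",
    "summed_absolute_differences",
    "paired_t_test",
    "bonferroni_flags",
    "pooled_ci_width_test",
    "standardized_node_ages",
    "regress_summaries",
]


@dataclass(frozen=True)
class NodeDifference:
    """Signed primary-minus-secondary differences for one matched node."""

    key: frozenset
    d_median: float
    d_min: float
    d_max: float
    d_width: float


@dataclass
class ReplicateComparison:
    """Per-replicate error summary for one secondary analysis."""

    replicate_id: int
    arm: str
    n_tips: int
    root_age: float  # secondary posterior median of the clade root
    sum_abs_min: float
    sum_abs_max: float
    sum_abs_median: float
    sum_abs_width: float
    t_median: float
    df: int
    p_median: float
    significant: bool | None = None  # set after Bonferroni across replicates


class TTestResult(NamedTuple):
    t: float
    df: int
    p: float
    defined: bool


class RegressionResult(NamedTuple):
    response: str
    predictor: str
    slope: float
    intercept: float
    p: float
    defined: bool


def node_differences(pairs: Sequence[tuple]) -> list[NodeDifference]:
    """Per-pair signed differences (primary − secondary) of the four summaries."""
    if len(pairs) == 0:
        raise ValueError("need at least one matched pair")
    out = []
    for prim, sec in pairs:
        if prim.key != sec.key:
            raise ValueError("mismatched pair: clade keys differ")
        out.append(
            NodeDifference(
                key=prim.key,
                d_median=prim.median - sec.median,
                d_min=prim.hpd_lo - sec.hpd_lo,
                d_max=prim.hpd_hi - sec.hpd_hi,
                d_width=prim.ci_width - sec.ci_width,
            )
        )
    return out


def summed_absolute_differences(diffs: Sequence[NodeDifference]) -> tuple[float, float, float, float]:
    """(Σ|Δmin|, Σ|Δmax|, Σ|Δmedian|, Σ|Δwidth|) over matched nodes."""
    if len(diffs) == 0:
        raise ValueError("need at least one difference")
    return (
        float(sum(abs(d.d_min) for d in diffs)),
        float(sum(abs(d.d_max) for d in diffs)),
        float(sum(abs(d.d_median) for d in diffs)),
        float(sum(abs(d.d_width) for d in diffs)),
    )


def paired_t_test(x, y) -> TTestResult:
    """Two-sided Student's paired t-test: t = mean(d) / (sd(d)/sqrt(n))."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("need two equal-length vectors with n >= 2")
    d = x - y
    n = d.size
    sd = d.std(ddof=1)
    if sd == 0.0:
        return TTestResult(math.nan, n - 1, math.nan, False)
    t = d.mean() / (sd / math.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), n - 1)
    return TTestResult(float(t), n - 1, float(p), True)


def bonferroni_flags(p_values, alpha: float = 0.05) -> list[bool]:
    """flag_i = (p_i < alpha / m); NaN p-values are never significant."""
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    p = list(p_values)
    m = len(p)
    return [bool(not math.isnan(pi) and pi < alpha / m) for pi in p]


def pooled_ci_width_test(all_pairs: Sequence[tuple]) -> TTestResult:
    """Paired t on (primary width, secondary width) pooled over every matched
    node of every replicate."""
    if len(all_pairs) < 2:
        raise ValueError("need at least two pooled pairs")
    pw = [p.ci_width for p, _ in all_pairs]
    sw = [s.ci_width for _, s in all_pairs]
    return paired_t_test(pw, sw)


def standardized_node_ages(node_ages, root_age: float) -> np.ndarray:
    """Ages divided by root age: root maps to 1, tips to 0."""
    if root_age <= 0:
        raise ValueError("root_age must be > 0")
    a = np.asarray(node_ages, float)
    if np.any(a > root_age * (1 + 1e-12)):
        raise ValueError("node age exceeds root age")
    return a / root_age


_RESPONSES = ("sum_abs_min", "sum_abs_max", "sum_abs_median", "sum_abs_width")


def regress_summaries(
    comparisons: Sequence[ReplicateComparison],
    predictor: str,
    alpha: float = 0.05,
) -> list[RegressionResult]:
    """OLS of each per-replicate absolute sum on one predictor.

    ``predictor`` is ``"root_age"`` or ``"n_tips"``.  Returns one result per
    response; the caller applies :func:`bonferroni_flags` across the full
    regression family (4 responses × 2 predictors).
    """
    if predictor not in ("root_age", "n_tips"):
        raise ValueError("predictor must be 'root_age' or 'n_tips'")
    if len(comparisons) < 3:
        raise ValueError("need at least 3 replicates")
    x = np.array([getattr(c, predictor) for c in comparisons], float)
    out = []
    for resp in _RESPONSES:
        y = np.array([getattr(c, resp) for c in comparisons], float)
        if np.all(x == x[0]):
            out.append(RegressionResult(resp, predictor, math.nan, math.nan, math.nan, False))
            continue
        fit = stats.linregress(x, y)
        out.append(
            RegressionResult(resp, predictor, float(fit.slope), float(fit.intercept),
                             float(fit.pvalue), True)
        )
    return out
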