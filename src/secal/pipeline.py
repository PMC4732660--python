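"""End-to-end secondary-calibration experiment.

The experiment mirrors a two-stage dating study.  A "primary" analysis dates
a large simulated chronogram from HKY sequence data under a relaxed clock,
anchored by lognormal calibrations on randomly chosen nodes plus the root.
Random clades of the primary tree are then re-dated as independent
"secondary" studies whose only time information is a prior built from the
primary posterior's 95% HPD on the clade root.  Four arms are compared:

* ``uniform``  — uniform root prior spanning the primary HPD (every replicate);
* ``normal``   — normal root prior whose central 95% spans the HPD (every
  m-th replicate, duplicated from the uniform arm);
* ``two_node`` — uniform priors on the root *and* on the node two steps
  tipward of the root on the right side (every m-th replicate);
* ``relaxed``  — data re-simulated under an uncorrelated-lognormal clock,
  with both primary and secondary dating re-run (every m-th replicate).

Differences are always primary − secondary, summarized per replicate by the
four absolute sums and a paired t-test on median node ages.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as sio
from .calibrate import (
    IneligibleReplicateError,
    normal_secondary_prior,
    sample_primary_calibrations,
    second_calibration_node,
    uniform_secondary_prior,
)
from .compare import (
    ReplicateComparison,
    bonferroni_flags,
    node_differences,
    paired_t_test,
    pooled_ci_width_test,
    regress_summaries,
    standardized_node_ages,
    summed_absolute_differences,
)
from .dating import McmcConfig, run_mcmc, summarize_trace
from .seqsim import HKYParams, simulate_alignment
from .subsample import extract_random_clades, match_nodes, restrict_alignment
from .treesim import TimeTree, rescale_to_age, simulate_pure_birth, strict_clock_subst_tree, ucln_subst_tree

__all__ = ["ExperimentConfig", "ExperimentResult", "preset", "run_experiment", "make_table1"]

_ARMS = ("uniform", "normal", "two_node", "relaxed")


@dataclass
class ExperimentConfig:
    """All knobs of the experiment; see :func:`preset` for standard scales."""

    # tree simulation
    n_tips: int = 1500
    birth_rate: float = 0.7
    root_age: float = 70.0
    # sequence simulation
    n_sites: int = 2000
    kappa: float = 2.0
    base_freqs: tuple = (0.30, 0.26, 0.23, 0.21)
    clock_rate: float = 0.01
    # primary calibrations
    n_calibrations: int = 29
    calibration_log_sd: float = 1.0
    # clade subsampling
    n_clades: int = 100
    min_tips: int = 20
    # experiment arms (0 disables an arm)
    normal_prior_every: int = 10
    two_node_every: int = 10
    relaxed_every: int = 10
    # relaxed-clock data simulation
    relaxed_mean_rate: float = 0.020
    relaxed_sd_log: float = 2.017
    relaxed_n_sites: int = 3000
    # MCMC
    primary_chain_length: int = 100_000_000
    primary_sample_every: int = 2000
    chain_length_small: int = 30_000_000
    chain_length_large: int = 60_000_000
    large_tip_threshold: int = 200
    sample_every: int = 3000
    burnin_fraction: float = 0.5
    # bookkeeping
    master_seed: int = 1
    out_dir: str | None = None
    save_traces: bool = False

    def hky_params(self) -> HKYParams:
        return HKYParams(kappa=self.kappa, freqs=tuple(self.base_freqs))

    def secondary_chain_length(self, n_tips: int) -> int:
        if n_tips >= self.large_tip_threshold:
            return self.chain_length_large
        return self.chain_length_small


_PRESETS = {
    # full publication-scale conditions: reference only, beyond desktop budgets
    "paper": {},
    # ~1-2 h on one CPU; preserves the full structure
    "desk": dict(
        n_tips=120, n_sites=800, n_calibrations=11, n_clades=12, min_tips=10,
        normal_prior_every=10, two_node_every=10, relaxed_every=10,
        relaxed_n_sites=800,
        primary_chain_length=400_000, primary_sample_every=200,
        chain_length_small=200_000, chain_length_large=200_000,
        sample_every=100,
    ),
    # minutes on one CPU; used by the test suite and the acceptance script.
    # Keeps the clade-eligibility condition at the full study's value
    # (clades of >= 20 tips) and scales tree size, clade count and chain
    # lengths down.
    "test": dict(
        n_tips=120, n_sites=300, n_calibrations=9, n_clades=6, min_tips=20,
        normal_prior_every=3, two_node_every=3, relaxed_every=3,
        relaxed_n_sites=300,
        primary_chain_length=1_200_000, primary_sample_every=600,
        chain_length_small=400_000, chain_length_large=1_200_000,
        large_tip_threshold=50,
        sample_every=200,
    ),
}


def preset(name: str, **overrides) -> ExperimentConfig:
    """Named experiment scale: ``paper``, ``desk`` or ``test``."""
    if name not in _PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(_PRESETS)}")
    kw = dict(_PRESETS[name])
    kw.update(overrides)
    return ExperimentConfig(**kw)


@dataclass
class ExperimentResult:
    config: ExperimentConfig
    primary_tree: TimeTree
    primary_summaries: dict
    relaxed_primary_summaries: dict | None
    replicates: list
    comparisons: list  # ReplicateComparison, all arms
    matched_pairs: dict  # arm -> {replicate_id: [(primary, secondary), ...]}
    pooled_width_test: tuple
    table1: pd.DataFrame
    regressions: list
    regression_flags: list

    def comparisons_by_arm(self, arm: str) -> list:
        return [c for c in self.comparisons if c.arm == arm]

    def node_table(self, arm: str = "uniform") -> pd.DataFrame:
        """Plot-ready long table of per-node differences and standardized ages."""
        rows = []
        for rid, pairs in sorted(self.matched_pairs[arm].items()):
            sec_root = max((s for _, s in pairs), key=lambda s: len(s.key))
            diffs = node_differences(pairs)
            sec = {s.key: s for _, s in pairs}
            std = {
                d.key: float(standardized_node_ages([sec[d.key].median], sec_root.median)[0])
                for d in diffs
            }
            for d in diffs:
                rows.append(
                    dict(replicate=rid, key=sio.clade_key_str(d.key), n_tips=len(d.key),
                         std_age=std[d.key], d_median=d.d_median, d_min=d.d_min,
                         d_max=d.d_max, d_width=d.d_width)
                )
        return pd.DataFrame(rows)


def _seed(master: int, stage: str, rep: int = 0) -> int:
    tag = sum(ord(c) * 131**i for i, c in enumerate(stage)) % (2**20)
    ss = np.random.SeedSequence(entropy=master, spawn_key=(tag, rep))
    return int(ss.generate_state(1)[0] % (2**31))


def _init_subtree(sub: TimeTree, root_target: float, node_cals: list) -> TimeTree:
    """Starting ages: true subtree ages scaled so the root hits its prior's
    bulk, then any extra calibrated node nudged into its support."""
    scale = root_target / sub.root_age
    tree = sub.with_ages(sub.ages * scale)
    clade_of = {tree.clades[v]: v for v in tree.internal_nodes}
    for cal in node_cals:
        if cal.kind != "uniform":
            continue
        v = clade_of[cal.key]
        if v == tree.root:
            continue
        lo, hi = cal.params["lo"], cal.params["hi"]
        a, b = tree.children[v]
        floor = max(tree.ages[a], tree.ages[b])
        ceil_ = tree.ages[tree.parent[v]]
        lo2, hi2 = max(lo, floor), min(hi, ceil_)
        if not (lo2 < hi2):
            raise IneligibleReplicateError(
                "secondary calibration support incompatible with starting ages"
            )
        if not (lo2 < tree.ages[v] < hi2):
            ages = tree.ages.copy()
            ages[v] = 0.5 * (lo2 + hi2)
            tree = tree.with_ages(ages)
    return tree


def _date_secondary(cfg, sub, alignment, cals, root_target, seed):
    chain = cfg.secondary_chain_length(sub.n_tips)
    start = _init_subtree(sub, root_target, cals)
    mcfg = McmcConfig(
        chain_length=chain,
        sample_every=cfg.sample_every,
        burnin_fraction=cfg.burnin_fraction,
        seed=seed,
        clock_rate_init=cfg.clock_rate,
    )
    trace = run_mcmc(alignment, start, cals, cfg.hky_params(), mcfg)
    return trace, summarize_trace(trace, cfg.burnin_fraction)


def _compare_replicate(rep, arm, primary_summaries, secondary_summaries):
    prim_sub = {k: primary_summaries[k] for k in secondary_summaries}
    pairs = match_nodes(prim_sub, secondary_summaries)
    diffs = node_differences(pairs)
    s_min, s_max, s_med, s_wid = summed_absolute_differences(diffs)
    t = paired_t_test([p.median for p, _ in pairs], [s.median for _, s in pairs])
    sec_root = secondary_summaries[rep.root_key]
    comp = ReplicateComparison(
        replicate_id=rep.replicate_id, arm=arm, n_tips=rep.n_tips,
        root_age=sec_root.median,
        sum_abs_min=s_min, sum_abs_max=s_max, sum_abs_median=s_med, sum_abs_width=s_wid,
        t_median=t.t, df=t.df, p_median=t.p,
    )
    return comp, pairs


def make_table1(comparisons: list) -> pd.DataFrame:
    """Per-arm averages of the four absolute sums plus the proportion of
    replicates whose median paired t-test is significant at P < 0.05."""
    cols = {}
    for arm in _ARMS:
        cs = [c for c in comparisons if c.arm == arm]
        if not cs:
            continue
        n = len(cs)
        defined = [c for c in cs if not math.isnan(c.p_median)]
        prop = float(np.mean([c.p_median < 0.05 for c in defined])) if defined else math.nan
        cols[arm] = {
            "Avg Min": float(np.mean([c.sum_abs_min for c in cs])),
            "Avg Max": float(np.mean([c.sum_abs_max for c in cs])),
            "Avg Median": float(np.mean([c.sum_abs_median for c in cs])),
            "Avg CI": float(np.mean([c.sum_abs_width for c in cs])),
            "T-test median": prop,
            "n replicates": n,
        }
    return pd.DataFrame(cols)


def run_experiment(config: ExperimentConfig) -> ExperimentResult:
    """Run the full experiment; see the module docstring for the design."""
    cfg = config
    params = cfg.hky_params()
    out = Path(cfg.out_dir) if cfg.out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)

    # 1. true chronogram and strict-clock data
    raw = simulate_pure_birth(cfg.n_tips, cfg.birth_rate, _seed(cfg.master_seed, "tree"))
    true_tree = rescale_to_age(raw, cfg.root_age)
    subst = strict_clock_subst_tree(true_tree, cfg.clock_rate)
    alignment = simulate_alignment(subst, params, cfg.n_sites, _seed(cfg.master_seed, "seq"))

    # 2. primary calibrations and primary dating
    cals = sample_primary_calibrations(
        true_tree, cfg.n_calibrations, _seed(cfg.master_seed, "cal"),
        log_sd=cfg.calibration_log_sd,
    )
    pcfg = McmcConfig(
        chain_length=cfg.primary_chain_length, sample_every=cfg.primary_sample_every,
        burnin_fraction=cfg.burnin_fraction, seed=_seed(cfg.master_seed, "primary"),
        clock_rate_init=cfg.clock_rate,
    )
    primary_trace = run_mcmc(alignment, true_tree, cals, params, pcfg)
    primary_summaries = summarize_trace(primary_trace, cfg.burnin_fraction)

    # 3. clade replicates
    replicates = extract_random_clades(
        true_tree, cfg.n_clades, cfg.min_tips, _seed(cfg.master_seed, "clades"),
        primary_summaries=primary_summaries,
    )

    # 4. relaxed-clock data + relaxed primary dating (only if the arm runs)
    relaxed_primary_summaries = None
    relaxed_alignment = None
    if cfg.relaxed_every:
        rsub = ucln_subst_tree(
            true_tree, cfg.relaxed_mean_rate, cfg.relaxed_sd_log,
            _seed(cfg.master_seed, "relaxedtree"),
        )
        relaxed_alignment = simulate_alignment(
            rsub, params, cfg.relaxed_n_sites, _seed(cfg.master_seed, "relaxedseq")
        )
        rcfg = dataclasses.replace(
            pcfg, seed=_seed(cfg.master_seed, "relaxedprimary"),
            clock_rate_init=cfg.relaxed_mean_rate,
        )
        relaxed_trace = run_mcmc(relaxed_alignment, true_tree, cals, params, rcfg)
        relaxed_primary_summaries = summarize_trace(relaxed_trace, cfg.burnin_fraction)

    # 5. secondary analyses
    comparisons: list[ReplicateComparison] = []
    matched: dict = {arm: {} for arm in _ARMS}

    def secondary(rep, arm, summaries_src, aln_src, extra_cals=()):
        root_s = summaries_src[rep.root_key]
        root_prior = (
            normal_secondary_prior(root_s.hpd_lo, root_s.hpd_hi, rep.root_key)
            if arm == "normal"
            else uniform_secondary_prior(root_s.hpd_lo, root_s.hpd_hi, rep.root_key)
        )
        cals_r = [root_prior, *extra_cals]
        aln = restrict_alignment(aln_src, rep.root_key)
        root_target = root_prior.median
        _, summ = _date_secondary(
            cfg, rep.subtree, aln, cals_r, root_target,
            _seed(cfg.master_seed, arm, rep.replicate_id),
        )
        comp, pairs = _compare_replicate(rep, arm, summaries_src, summ)
        comparisons.append(comp)
        matched[arm][rep.replicate_id] = pairs

    for rep in replicates:
        secondary(rep, "uniform", primary_summaries, alignment)

    if cfg.normal_prior_every:
        for rep in replicates[:: cfg.normal_prior_every]:
            secondary(rep, "normal", primary_summaries, alignment)

    if cfg.two_node_every:
        used = set()
        for start in range(0, len(replicates), cfg.two_node_every):
            # substitute the next eligible replicate (wrapping around) if the
            # two-tipward node on the right is a tip
            for rep in replicates[start:] + replicates[:start]:
                if rep.replicate_id in used:
                    continue
                try:
                    key2 = second_calibration_node(rep.subtree)
                    s2 = primary_summaries[key2]
                    extra = uniform_secondary_prior(s2.hpd_lo, s2.hpd_hi, key2)
                    secondary(rep, "two_node", primary_summaries, alignment, (extra,))
                except IneligibleReplicateError:
                    continue
                used.add(rep.replicate_id)
                break

    if cfg.relaxed_every:
        for rep in replicates[:: cfg.relaxed_every]:
            secondary(rep, "relaxed", relaxed_primary_summaries, relaxed_alignment)

    # 6. statistics
    for arm in _ARMS:
        cs = [c for c in comparisons if c.arm == arm]
        flags = bonferroni_flags([c.p_median for c in cs], 0.05) if cs else []
        for c, f in zip(cs, flags):
            c.significant = f

    pooled_pairs = [pair for pairs in matched["uniform"].values() for pair in pairs]
    pooled = pooled_ci_width_test(pooled_pairs)

    table1 = make_table1(comparisons)

    uniform_cs = [c for c in comparisons if c.arm == "uniform"]
    regressions = []
    if len(uniform_cs) >= 3:
        for pred in ("root_age", "n_tips"):
            regressions.extend(regress_summaries(uniform_cs, pred))
    reg_flags = bonferroni_flags([r.p for r in regressions], 0.05) if regressions else []

    result = ExperimentResult(
        config=cfg, primary_tree=true_tree, primary_summaries=primary_summaries,
        relaxed_primary_summaries=relaxed_primary_summaries, replicates=replicates,
        comparisons=comparisons, matched_pairs=matched, pooled_width_test=pooled,
        table1=table1, regressions=regressions, regression_flags=reg_flags,
    )

    if out:
        _write_outputs(result, out, alignment, cals, primary_trace if cfg.save_traces else None)
    return result


def _write_outputs(result: ExperimentResult, out: Path, alignment, cals, primary_trace):
    cfg = result.config
    sio.write_newick(result.primary_tree, out / "primary_tree.nwk")
    sio.write_fasta(alignment, out / "alignment.fasta")
    sio.write_calibrations_yaml(cals, out / "primary_calibrations.yaml")
    sio.write_summaries(result.primary_summaries, out / "primary_summaries.tsv")
    sio.write_annotated_nexus(
        result.primary_tree, result.primary_summaries, out / "primary_summary.nex"
    )
    if primary_trace is not None:
        sio.write_trace(primary_trace, out / "primary_trace.tsv")
    if result.relaxed_primary_summaries:
        sio.write_summaries(result.relaxed_primary_summaries, out / "relaxed_primary_summaries.tsv")

    rows = [
        dict(replicate=c.replicate_id, arm=c.arm, n_tips=c.n_tips, root_age=c.root_age,
             sum_abs_min=c.sum_abs_min, sum_abs_max=c.sum_abs_max,
             sum_abs_median=c.sum_abs_median, sum_abs_width=c.sum_abs_width,
             t_median=c.t_median, df=c.df, p_median=c.p_median,
             bonferroni_significant=c.significant)
        for c in result.comparisons
    ]
    pd.DataFrame(rows).to_csv(out / "replicate_comparisons.tsv", sep="\t", index=False)
    result.table1.to_csv(out / "table1.tsv", sep="\t")
    result.node_table("uniform").to_csv(out / "node_differences_uniform.csv", index=False)
    if result.regressions:
        pd.DataFrame(
            [r._asdict() | {"bonferroni_significant": f}
             for r, f in zip(result.regressions, result.regression_flags)]
        ).to_csv(out / "regressions.tsv", sep="\t", index=False)

    t, df, p, defined = result.pooled_width_test
    manifest = {
        "master_seed": cfg.master_seed,
        "n_replicates": len(result.replicates),
        "pooled_ci_width_test": {"t": t, "df": df, "p": p, "defined": defined},
    }
    (out / "results.json").write_text(json.dumps(manifest, indent=2))
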