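"""Date a fixed topology by MCMC and summarize the posterior.

Simulates strict-clock HKY data on a 20-tip chronogram, calibrates four
random nodes plus the root with lognormal priors (median at the true age,
log-sd 1), runs the relaxed-clock sampler, and prints per-node posterior
medians with 95% HPD intervals next to the true ages.
"""

from secal import (
    HKYParams,
    McmcConfig,
    effective_sample_size,
    rescale_to_age,
    run_mcmc,
    sample_primary_calibrations,
    simulate_alignment,
    simulate_pure_birth,
    strict_clock_subst_tree,
    summarize_trace,
)

params = HKYParams(kappa=2.0, freqs=(0.30, 0.26, 0.23, 0.21))
tree = rescale_to_age(simulate_pure_birth(20, 0.7, seed=4), 70.0)
aln = simulate_alignment(strict_clock_subst_tree(tree, 0.01), params, 1000, seed=5)
cals = sample_primary_calibrations(tree, n_internal=4, seed=6)

cfg = McmcConfig(chain_length=200_000, sample_every=100, seed=7)
trace = run_mcmc(aln, tree, cals, params, cfg)
summaries = summarize_trace(trace, burnin_fraction=0.5)

half = trace.n_samples // 2
print(f"{trace.n_samples} recorded states; post-burn-in ESS of the "
      f"log-likelihood: {effective_sample_size(trace.loglik[half:]):.0f}")
print(f"{'clade size':>10} {'true age':>9} {'median':>8} {'95% HPD':>16}")
calibrated = {c.key for c in cals}
for v in sorted(tree.internal_nodes, key=lambda v: -tree.ages[v]):
    key = tree.clades[v]
    s = summaries[key]
    mark = "*" if key in calibrated else " "
    print(f"{len(key):>10} {tree.ages[v]:>9.2f} {s.median:>8.2f} "
          f"[{s.hpd_lo:>6.2f},{s.hpd_hi:>6.2f}] {mark}")
print("* = calibrated node.  With only 5 calibrations and an estimated "
      "clock, posterior ages track the calibration priors' bulk; HPDs "
      "quantify the genuine dating uncertainty.")
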