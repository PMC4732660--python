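# Methods

`secal` asks a single question with simulated data: when a "secondary"
dating study calibrates itself with nothing but the posterior of a
"primary" dating study, does the primary study's uncertainty carry over, or
is it distorted?  Everything in the package serves that experiment: the
simulators that build the known truth, the Bayesian dating engine that
plays the role of the primary and secondary analyses, the calibration
builders, and the difference statistics.

## Generating process (the known truth)

**Chronogram.** A pure-birth (Yule) tree is grown to `n_tips` tips.  The
split intervals, ordered from the root toward the present, are independent
exponentials: the k-th interval (k = 1..n−1) has rate `k·λ`, and at each
split a uniformly chosen extant lineage divides.  The root age is the total
accumulated waiting time, with expectation `Σ_{k=1..n−1} 1/(k·λ)` — the
duration law of a pure-birth process grown from one lineage until `n_tips`
exist.  The tree is then rescaled linearly so the root sits at a chosen
age, 70 Ma by default (a typical family/superfamily depth); the default
birth rate is 0.7/Ma.  Defaults: fully bifurcating, no extinction, no
serial sampling.

**Clocks.** A strict clock converts durations to expected
substitutions/site at a single rate (default 0.01/site/Ma, giving ~0.7
substitutions/site root-to-tip on a 70-Ma tree — a typical empirical
signal).  The relaxed-clock variant draws an independent lognormal rate
per branch with *real-space* mean 0.020 and *log-space* standard deviation
2.017.  A real-space standard deviation of 2.017 at mean 0.020 would be
physically implausible (rates would be negative-heavy-tailed), so the
mean/sd pair is read as real-space mean + log-space sd; `sd_log = 0`
degenerates exactly to the strict clock.

**Sequences.** Sites evolve independently down the substitution tree under
HKY85 (default κ = 2, stationary frequencies 0.30/0.26/0.23/0.21), with
root states drawn from the stationary distribution.  The rate matrix is
normalized to one expected substitution per unit branch length.  Transition
probabilities use the HKY closed form; a numerical matrix exponential
serves only as a test oracle.  No rate-across-sites heterogeneity, indels,
or ambiguity codes — the experiment deliberately uses a simple, correctly
specified substitution process so calibration effects are not confounded
with model misspecification.

## The dating model

A fixed-topology Bayesian node-dating model, sampled by
Metropolis–Hastings MCMC:

* **Likelihood** — HKY via Felsenstein pruning over compressed site
  patterns.  Per-node partials are cached with per-pattern scaling;
  proposals that touch one node's branches recompute only the path to the
  root, which is what makes chains of 10⁵–10⁶ generations cheap.
* **Tree prior** — the pure-birth age density implied by the simulator:
  on a fixed topology, `p(ages) ∝ exp(−λ·Σ ages)` on the region respecting
  parent-older-than-child.  This makes the likelihood-free sampler exactly
  comparable to direct simulation, which the test suite exploits as its
  strongest sampler-correctness check.  The birth rate is estimated by
  default (log-flat prior on [10⁻⁶, 10³]); it can be fixed for validation
  runs.
* **Clock** — uncorrelated lognormal branch rates with estimated log-mean
  `μ_r` (flat on [ln 10⁻⁸, ln 10²]) and log-sd `σ_r` (exponential prior,
  mean 1).  A strict-clock mode fixes the rate and disables rate moves.
* **Other priors** — κ lognormal(ln 2, 1); frequencies uniform on the
  simplex.  Calibration densities (lognormal / uniform / zero-truncated
  normal) multiply in on their nodes, which are identified by frozen
  descendant-tip sets (a bijection under fixed topology).
* **Operators** — uniform node-age slide within (oldest child, parent);
  root-age scale; whole-tree age scale; a joint "ages up, rates down" scale
  that leaves every branch length — and hence the likelihood — invariant
  and shifts `μ_r` along with the rates (the workhorse for time/rate-scale
  mixing); multiplicative moves on single rates, κ, `σ_r`, λ; a two-
  frequency exchange; a `μ_r` slide.  Weights put ~2/3 of proposals on
  ages and rates; full-likelihood moves (κ, frequencies, tree scale) are
  kept rare because they cost a whole-tree recompute.
* **Summaries** — node-age median and shortest-interval 95% HPD after
  discarding the first half of the recorded chain; effective sample size
  by the initial-positive-pair autocorrelation truncation.

### A note on calibration pull

Lognormal calibrations with log-sd 1 and median at the true age put most
of their mass below the median (the mode sits at `e^{−1}` of it).  When the
data cannot inform absolute time (rate and time are jointly unidentified),
the posterior time scale settles near the calibrations' joint bulk, below
the true ages.  This is a property of the model, not a defect; the
experiment's comparisons are primary-vs-secondary and are unaffected by
the common pull.

## The experiment

1. Simulate the true chronogram and a strict-clock HKY alignment.
2. Date it ("primary") with lognormal calibrations (log-sd 1, median =
   true age) on `n_calibrations` random internal nodes plus the root.
3. Extract `n_clades` random clades with at least `min_tips` tips
   (uniformly over eligible nodes, distinct clade roots, nesting allowed —
   disjointness is impossible in general).
4. Re-date each clade ("secondary") from its true subtree topology and
   the same sites, with a single uniform root prior spanning the primary
   posterior's 95% HPD on that clade's root.  Arms on every m-th
   replicate: a normal root prior whose central 95% spans the same HPD;
   a second uniform calibration on the node two steps tipward of the root
   along second-child ("right") order, substituting the next eligible
   replicate when that position is a tip; and a full re-run (primary +
   secondary) on data simulated under the relaxed clock.
5. Compare matched nodes (by tip set): signed differences
   primary − secondary of median, HPD bounds, and CI width; per-replicate
   sums of absolute differences; a paired t-test on medians per replicate
   with Bonferroni correction across replicates; a pooled paired t-test on
   CI widths over every matched node; OLS regressions of the four sums on
   clade root age and tip count (Bonferroni over the 8 fits).  All tests
   two-sided.  Matched nodes overlap across replicates, so these are
   descriptive statistics, not independent-sample inference; no correction
   for that non-independence is attempted.

Secondary chains start from the true subtree ages rescaled so the root
sits at its prior's center (extra calibrated nodes nudged into their
support if needed); with 50% burn-in and the scale operators above, the
starting point is immaterial.

## Problem sizes

Three presets fix the experiment scale:

* `paper` — 1500 tips, 2000 bp, 29+root calibrations, 100 clades ≥ 20
  tips, 10⁸-generation primary chain, 3–6×10⁷-generation secondaries.
  The full-scale experiment's conditions; far beyond a desktop session, kept
  for reference/cluster use.
* `desk` — 120 tips, 800 bp, 12 clades ≥ 10 tips, 2–4×10⁵-generation
  chains; roughly an hour on one CPU.
* `test` — the scale this repository's tests and acceptance script run:
  120 tips, 300 bp, 9+root calibrations, 6 clades with the full study's
  eligibility threshold of ≥ 20 tips, arms on every 3rd replicate,
  1.2×10⁶-generation primary chains, and — following the full study's
  tip-dependent rule — 4×10⁵-generation secondary chains below 50 tips
  and 1.2×10⁶ at or above it (~10 minutes on one CPU).  Chain-length
  checks at this scale: seed-to-seed differences in the primary root HPD
  are ~10%, tripling the chain moves mean CI widths by <10%, and
  per-replicate statistics are stable under further tripling of the
  secondary chains, so summaries are dominated by the posterior, not by
  Monte-Carlo error.

## What passing tests do and do not show

The simulators match their analytic laws (Yule depth, lognormal rate mean,
HKY stationarity and reversibility); the likelihood matches exhaustive
enumeration; the likelihood-free sampler reproduces the simulator's prior
(Kolmogorov–Smirnov on 5000 thinned draws); strict-clock HPDs show nominal
frequentist coverage under a correctly specified model; and the scaled-
down experiment reproduces the qualitative findings: secondary estimates
shift significantly in every uniform replicate and secondary credible
intervals are narrower than primary on average.  None of this speaks to
real data: the simulation has a correct topology, one unpartitioned locus,
no rate-across-sites variation, no model misspecification, and no fossil
error — conditions that flatter secondary calibrations.  The full-scale
study's absolute numbers (Table-1-type averages) also scale with tree
size, clade count and tree depth, so only directions and proportions are
comparable across scales.

## Numerical choices

* HPD: shortest window containing ⌈0.95·n⌉ sorted samples; ties broken by
  the first minimal window.
* ESS: `n / (1 + 2Σρ)` truncated at the first non-positive consecutive
  autocorrelation pair; a constant series reports ESS = n with a warning.
* Paired t with zero-variance differences returns an explicit undefined
  flag (NaN p) rather than ±∞; undefined tests are excluded from
  significance proportions and never count as significant under
  Bonferroni.
* Normal secondary priors are truncated at zero and renormalized; with
  intervals away from zero the truncation is numerically invisible.
* Degenerate two-node replicates (the two-tipward-right position is a
  tip) are substituted by the next eligible replicate, wrapping around.
* All randomness flows from explicit integer seeds; per-stage,
  per-replicate seeds derive deterministically from the master seed, so
  the whole experiment is reproducible bit-for-bit.
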