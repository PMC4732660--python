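import itertools
import math

import numpy as np
import pytest
from scipy import integrate, stats

from secal.calibrate import CalibrationPrior, sample_primary_calibrations
from secal.dating import (
    McmcConfig,
    calibration_log_prior,
    effective_sample_size,
    hpd_interval,
    hyperprior_log_density,
    pruning_log_likelihood,
    run_mcmc,
    summarize_trace,
    ucln_log_prior,
    yule_log_prior,
)
from secal.seqsim import HKYParams, hky_transition_matrix, simulate_alignment
from secal.treesim import simulate_pure_birth, strict_clock_subst_tree

from conftest import tree_from_newick


def enumeration_log_likelihood(tree, rates, params, aln):
    """Brute-force likelihood: sum over all internal-state assignments."""
    idx = [aln.labels.index(l) for l in tree.tip_labels]
    mat = aln.seqs[idx]
    blens = (tree.ages[tree.parent] - tree.ages) * rates
    internals = list(tree.internal_nodes)
    pmats = {
        v: hky_transition_matrix(float(blens[v]), params)
        for v in range(tree.n_nodes)
        if v != tree.root
    }
    total = 0.0
    for site in range(mat.shape[1]):
        site_p = 0.0
        for assign in itertools.product(range(4), repeat=len(internals)):
            st = dict(zip(internals, assign))
            for t in range(tree.n_tips):
                st[t] = int(mat[t, site])
            p = params.pi[st[tree.root]]
            for v in range(tree.n_nodes):
                if v != tree.root:
                    p *= pmats[v][st[int(tree.parent[v])], st[v]]
            site_p += p
        total += math.log(site_p)
    return total


class TestPruningLikelihood:
    def test_matches_enumeration(self, hky):
        tree = simulate_pure_birth(4, 0.7, seed=3)
        rng = np.random.default_rng(0)
        rates = rng.uniform(0.1, 0.5, tree.n_nodes)
        aln = simulate_alignment(strict_clock_subst_tree(tree, 0.3), hky, 6, seed=7)
        got = pruning_log_likelihood(tree, rates, hky, aln)
        want = enumeration_log_likelihood(tree, rates, hky, aln)
        assert got == pytest.approx(want, abs=1e-10)

    def test_zero_branches_constant_site(self, hky):
        tree = tree_from_newick("((a:1,b:1):1,c:2);")
        rates = np.full(tree.n_nodes, 1e-300)
        aln = type(simulate_alignment(strict_clock_subst_tree(tree, 0.1), hky, 1, 0))(
            ["a", "b", "c"], np.array([[2], [2], [2]], dtype=np.int8)
        )
        got = pruning_log_likelihood(tree, rates, hky, aln)
        assert got == pytest.approx(math.log(hky.pi[2]), abs=1e-9)

    def test_rate_time_nonidentifiability(self, hky):
        tree = simulate_pure_birth(8, 0.7, seed=1)
        rates = np.full(tree.n_nodes, 0.2)
        aln = simulate_alignment(strict_clock_subst_tree(tree, 0.2), hky, 100, seed=2)
        ll1 = pruning_log_likelihood(tree, rates, hky, aln)
        c = 3.7
        ll2 = pruning_log_likelihood(tree.with_ages(tree.ages / c), rates * c, hky, aln)
        assert ll2 == pytest.approx(ll1, abs=1e-8)

    def test_taxon_mismatch_rejected(self, hky):
        tree = simulate_pure_birth(4, 0.7, seed=3)
        aln = simulate_alignment(strict_clock_subst_tree(tree, 0.3), hky, 5, seed=7)
        aln.labels[0] = "not_a_tip"
        with pytest.raises(ValueError):
            pruning_log_likelihood(tree, np.ones(tree.n_nodes), hky, aln)


class TestPriors:
    def test_yule_density_shape(self):
        # under the pure-birth construction the age density on a fixed
        # topology is proportional to exp(-lambda * sum of ages)
        t1 = tree_from_newick("((a:1,b:1):1,c:2);")
        t2 = t1.with_ages(np.array([0, 0, 0, 2.0, 1.5]))
        lam = 0.7
        dsum = t2.ages[3:].sum() - t1.ages[3:].sum()
        assert yule_log_prior(t2, lam) - yule_log_prior(t1, lam) == pytest.approx(-lam * dsum)

    def test_yule_support(self):
        t = tree_from_newick("((a:1,b:1):1,c:2);")
        assert math.isfinite(yule_log_prior(t, 0.7))
        # child older than root -> zero density
        assert yule_log_prior(t, 0.7, ages=np.array([0, 0, 0, 1.0, 1.5])) == -math.inf

    def test_ucln_closed_form_at_median(self):
        mu = math.log(0.02)
        got = ucln_log_prior(np.array([math.exp(mu)]), mu, 1.0)
        assert got == pytest.approx(-mu - 0.5 * math.log(2 * math.pi))

    def test_ucln_additive_over_branches(self):
        rng = np.random.default_rng(1)
        rates = rng.lognormal(-3, 1, size=6)
        total = ucln_log_prior(rates, -3.0, 0.8)
        parts = sum(ucln_log_prior(rates[i : i + 1], -3.0, 0.8) for i in range(6))
        assert total == pytest.approx(parts)

    def test_ucln_normalized(self):
        mu, sd = math.log(0.05), 0.7
        val, err = integrate.quad(
            lambda r: math.exp(ucln_log_prior(np.array([r]), mu, sd)), 0, np.inf
        )
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_ucln_rejects_negative_sd(self):
        with pytest.raises(ValueError):
            ucln_log_prior(np.array([0.1]), -3.0, -1.0)

    def test_calibration_uniform(self):
        c = CalibrationPrior(frozenset({"a"}), "uniform", {"lo": 2.0, "hi": 6.0})
        assert calibration_log_prior(c, 4.0) == pytest.approx(-math.log(4.0))
        assert calibration_log_prior(c, 1.0) == -math.inf
        assert calibration_log_prior(c, 7.0) == -math.inf

    def test_calibration_lognormal_median(self):
        c = CalibrationPrior(frozenset({"a"}), "lognormal", {"log_mean": math.log(30), "log_sd": 1.0})
        d = stats.lognorm(s=1.0, scale=30.0)
        assert d.cdf(c.median) == pytest.approx(0.5)
        assert calibration_log_prior(c, 12.3) == pytest.approx(d.logpdf(12.3))

    def test_calibration_normal_mode(self):
        # far from zero the truncation is negligible
        c = CalibrationPrior(frozenset({"a"}), "normal", {"mean": 50.0, "sd": 3.0})
        assert calibration_log_prior(c, 50.0) == pytest.approx(
            -math.log(3.0 * math.sqrt(2 * math.pi))
        )

    def test_calibration_normal_truncated_normalizes(self):
        c = CalibrationPrior(frozenset({"a"}), "normal", {"mean": 1.0, "sd": 2.0})
        val, err = integrate.quad(
            lambda x: math.exp(calibration_log_prior(c, x)), 0, np.inf
        )
        assert val == pytest.approx(1.0, abs=1e-8)

    def test_hyperprior_support(self):
        assert math.isfinite(hyperprior_log_density(-4.0, 0.5, 2.0, (0.25,) * 4, 0.5))
        assert hyperprior_log_density(99.0, 0.5, 2.0, (0.25,) * 4) == -math.inf
        assert hyperprior_log_density(-4.0, 0.5, -1.0, (0.25,) * 4) == -math.inf


class TestHpd:
    def test_degenerate(self):
        assert hpd_interval([3.3, 3.3, 3.3], 0.95) == (3.3, 3.3)

    def test_integers_window(self):
        lo, hi = hpd_interval(np.arange(100), 0.95)
        assert hi - lo == 94

    def test_matches_bruteforce(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            x = np.sort(rng.lognormal(0, 1, size=rng.integers(5, 60)))
            m = math.ceil(0.9 * x.size)
            best = min(
                ((x[i + m - 1] - x[i], (x[i], x[i + m - 1])) for i in range(x.size - m + 1)),
                key=lambda w: w[0],
            )[1]
            assert hpd_interval(x, 0.9) == best

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            hpd_interval([], 0.95)


class TestEss:
    def test_iid(self):
        x = np.random.default_rng(0).normal(size=10_000)
        assert effective_sample_size(x) == pytest.approx(10_000, rel=0.10)

    def test_ar1(self):
        rho, n = 0.7, 60_000
        rng = np.random.default_rng(1)
        x = np.empty(n)
        x[0] = rng.normal()
        eps = rng.normal(size=n) * math.sqrt(1 - rho**2)
        for i in range(1, n):
            x[i] = rho * x[i - 1] + eps[i]
        expected = n * (1 - rho) / (1 + rho)
        assert effective_sample_size(x) == pytest.approx(expected, rel=0.15)

    def test_constant_series_flagged(self):
        with pytest.warns(RuntimeWarning):
            assert effective_sample_size(np.ones(50)) == 50


class TestMcmc:
    @pytest.fixture(scope="class")
    def small_run(self, hky):
        tree = simulate_pure_birth(6, 0.7, seed=10)
        aln = simulate_alignment(strict_clock_subst_tree(tree, 0.05), hky, 200, seed=11)
        cals = sample_primary_calibrations(tree, 2, seed=12)
        cfg = McmcConfig(chain_length=20_000, sample_every=20, seed=13)
        trace = run_mcmc(aln, tree, cals, hky, cfg)
        return tree, aln, cals, cfg, trace

    def test_sampled_states_respect_age_order(self, small_run):
        tree, _, _, _, trace = small_run
        idx = {k: j for j, k in enumerate(trace.node_keys)}
        for v in tree.internal_nodes:
            for ch in tree.children[v]:
                if ch >= tree.n_tips:
                    a = trace.node_ages[:, idx[tree.clades[int(v)]]]
                    b = trace.node_ages[:, idx[tree.clades[int(ch)]]]
                    assert np.all(a > b)
        assert np.all(trace.node_ages > 0)

    def test_seeded_determinism(self, small_run):
        tree, aln, cals, cfg, trace = small_run
        again = run_mcmc(aln, tree, cals, HKYParams(), cfg)
        assert np.array_equal(trace.node_ages, again.node_ages)
        assert np.array_equal(trace.loglik, again.loglik)
        assert np.array_equal(trace.rates, again.rates)

    def test_requires_time_information(self, hky):
        tree = simulate_pure_birth(4, 0.7, seed=1)
        aln = simulate_alignment(strict_clock_subst_tree(tree, 0.05), hky, 50, seed=2)
        with pytest.raises(ValueError):
            run_mcmc(aln, tree, [], hky, McmcConfig(chain_length=100, sample_every=10))

    def test_kappa_recovery(self, hky):
        # strict-clock data with the clock fixed at truth: posterior median
        # kappa should land within 10% of the generating value 2
        tree = simulate_pure_birth(20, 0.7, seed=21)
        aln = simulate_alignment(strict_clock_subst_tree(tree, 0.05), hky, 2000, seed=22)
        cfg = McmcConfig(
            chain_length=60_000, sample_every=30, seed=23,
            fix_clock_rate=0.05, estimate_birth_rate=False, birth_rate_init=0.7,
        )
        trace = run_mcmc(aln, tree, [], hky, cfg)
        post = trace.kappa[trace.n_samples // 2 :]
        assert np.median(post) == pytest.approx(2.0, rel=0.10)


class TestSummaries:
    def test_constant_trace(self, hky):
        tree = simulate_pure_birth(4, 0.7, seed=1)
        aln = simulate_alignment(strict_clock_subst_tree(tree, 0.05), hky, 50, seed=2)
        cals = sample_primary_calibrations(tree, 1, seed=3)
        cfg = McmcConfig(chain_length=100, sample_every=10, seed=4)
        trace = run_mcmc(aln, tree, cals, hky, cfg)
        trace.node_ages[:] = trace.node_ages[0]
        s = summarize_trace(trace, 0.5)
        for summ in s.values():
            assert summ.hpd_lo == summ.median == summ.hpd_hi

    def test_burnin_discards_first_half(self):
        from secal.dating import Trace

        n = 100
        ages = np.concatenate([np.full(50, 5.0), np.full(50, 9.0)])[:, None]
        trace = Trace(
            generations=np.arange(n), loglik=np.zeros(n), logprior=np.zeros(n),
            kappa=np.full(n, 2.0), freqs=np.full((n, 4), 0.25), mu_log=np.zeros(n),
            sd_log=np.zeros(n), birth_rate=np.full(n, 0.7),
            node_keys=[frozenset({"a", "b"})], node_ages=ages,
            rate_keys=[], rates=np.zeros((n, 0)),
        )
        s = summarize_trace(trace, 0.5)
        assert s[frozenset({"a", "b"})].median == 9.0
        with pytest.raises(ValueError):
            summarize_trace(trace, 1.0)
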