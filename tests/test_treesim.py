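import numpy as np
import pytest

from secal.treesim import (
    SubstTree,
    TimeTree,
    rescale_to_age,
    simulate_pure_birth,
    strict_clock_subst_tree,
    ucln_subst_tree,
)


def root_to_tip_depths(tree: TimeTree) -> np.ndarray:
    """Sum of branch durations from root to every tip."""
    depth = np.zeros(tree.n_nodes)
    for v in tree.preorder:
        v = int(v)
        if v == tree.root:
            continue
        p = int(tree.parent[v])
        depth[v] = depth[p] + (tree.ages[p] - tree.ages[v])
    return depth[: tree.n_tips]


class TestPureBirth:
    def test_minimal_two_tip_tree(self):
        t = simulate_pure_birth(2, 0.7, seed=0)
        assert t.n_tips == 2
        assert t.n_internal == 1
        assert np.all(t.ages[:2] == 0.0)

    @pytest.mark.parametrize("n", [5, 47, 200])
    def test_bifurcating_with_n_minus_1_internals(self, n):
        t = simulate_pure_birth(n, 0.7, seed=3)
        assert t.n_internal == n - 1
        t.validate()

    @pytest.mark.parametrize("n", [6, 33])
    def test_ultrametric(self, n):
        t = rescale_to_age(simulate_pure_birth(n, 0.7, seed=11), 70.0)
        depths = root_to_tip_depths(t)
        assert np.allclose(depths, t.root_age, rtol=1e-9)

    def test_mean_root_age_matches_waiting_time_sum(self):
        # E[root age] = sum_{k=1..n-1} 1/(k*lambda) for the pure-birth law
        n, lam, reps = 6, 1.3, 2500
        roots = np.fromiter(
            (simulate_pure_birth(n, lam, seed=s).root_age for s in range(reps)), float
        )
        analytic = sum(1.0 / (k * lam) for k in range(1, n))
        var = sum(1.0 / (k * lam) ** 2 for k in range(1, n))
        se = np.sqrt(var / reps)
        assert abs(roots.mean() - analytic) < 3 * se

    def test_deterministic_given_seed(self):
        a = simulate_pure_birth(20, 0.7, seed=42)
        b = simulate_pure_birth(20, 0.7, seed=42)
        assert a.newick() == b.newick()
        assert simulate_pure_birth(20, 0.7, seed=43).newick() != a.newick()

    def test_tip_labels_are_preorder_t1_tn(self):
        t = simulate_pure_birth(12, 0.7, seed=5)
        seen = [t.tip_labels[int(v)] for v in t.preorder if v < t.n_tips]
        assert seen == [f"t{i}" for i in range(1, 13)]

    @pytest.mark.parametrize("bad", [(1, 0.7), (0, 0.7), (5, 0.0), (5, -1.0)])
    def test_invalid_parameters(self, bad):
        with pytest.raises(ValueError):
            simulate_pure_birth(bad[0], bad[1], seed=0)


class TestRescale:
    def test_identity(self):
        t = simulate_pure_birth(10, 0.7, seed=2)
        r = rescale_to_age(t, t.root_age)
        assert np.allclose(r.ages, t.ages)

    def test_doubling(self):
        t = rescale_to_age(simulate_pure_birth(10, 0.7, seed=2), 35.0)
        r = rescale_to_age(t, 70.0)
        assert np.allclose(r.ages, 2 * t.ages)
        assert r.root_age == pytest.approx(70.0)

    def test_rejects_nonpositive_target(self):
        t = simulate_pure_birth(5, 0.7, seed=1)
        with pytest.raises(ValueError):
            rescale_to_age(t, 0.0)


class TestSubstTrees:
    def test_strict_clock_lengths(self):
        t = rescale_to_age(simulate_pure_birth(15, 0.7, seed=4), 70.0)
        s = strict_clock_subst_tree(t, 0.01)
        dur = t.branch_durations()
        nonroot = np.arange(t.n_nodes) != t.root
        assert np.allclose(s.lengths[nonroot], dur[nonroot] * 0.01)
        # root-to-tip path length = 70 * 0.01
        depth = np.zeros(t.n_nodes)
        for v in t.preorder:
            v = int(v)
            if v != t.root:
                depth[v] = depth[int(t.parent[v])] + s.lengths[v]
        assert np.allclose(depth[: t.n_tips], 0.7)

    def test_strict_clock_linearity(self):
        t = simulate_pure_birth(8, 0.7, seed=9)
        s1 = strict_clock_subst_tree(t, 0.01)
        s2 = strict_clock_subst_tree(t, 0.02)
        nonroot = np.arange(t.n_nodes) != t.root
        assert np.allclose(s2.lengths[nonroot], 2 * s1.lengths[nonroot])

    def test_ucln_degenerate_equals_strict(self):
        t = simulate_pure_birth(8, 0.7, seed=9)
        u = ucln_subst_tree(t, 0.02, 0.0, seed=1)
        s = strict_clock_subst_tree(t, 0.02)
        nonroot = np.arange(t.n_nodes) != t.root
        assert np.allclose(u.lengths[nonroot], s.lengths[nonroot])

    def test_ucln_mean_rate(self):
        # real-space mean of lognormal branch rates equals the requested mean
        t = simulate_pure_birth(5001, 0.7, seed=7)  # 10000 branches
        u = ucln_subst_tree(t, 0.020, 2.017, seed=8)
        nonroot = np.arange(t.n_nodes) != t.root
        rates = u.rates[nonroot]
        se = rates.std() / np.sqrt(rates.size)
        assert abs(rates.mean() - 0.020) < 3 * se

    def test_rate_length_consistency(self):
        t = rescale_to_age(simulate_pure_birth(30, 0.7, seed=3), 70.0)
        u = ucln_subst_tree(t, 0.02, 1.0, seed=2)
        dur = t.branch_durations()
        for v in range(t.n_nodes):
            if v == t.root:
                continue
            assert u.lengths[v] == pytest.approx(dur[v] * u.rates[v], rel=1e-12)

    def test_invalid_parameters(self):
        t = simulate_pure_birth(5, 0.7, seed=1)
        with pytest.raises(ValueError):
            strict_clock_subst_tree(t, 0.0)
        with pytest.raises(ValueError):
            ucln_subst_tree(t, -0.1, 1.0, seed=0)
        with pytest.raises(ValueError):
            ucln_subst_tree(t, 0.1, -1.0, seed=0)
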