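import math

import numpy as np
import pytest
from scipy import stats

from secal.compare import (
    ReplicateComparison,
    bonferroni_flags,
    node_differences,
    paired_t_test,
    pooled_ci_width_test,
    regress_summaries,
    standardized_node_ages,
    summed_absolute_differences,
)
from secal.dating import NodeSummary


def _pair(key, p_med, p_lo, p_hi, s_med, s_lo, s_hi):
    k = frozenset(key)
    return (
        NodeSummary(key=k, median=p_med, hpd_lo=p_lo, hpd_hi=p_hi),
        NodeSummary(key=k, median=s_med, hpd_lo=s_lo, hpd_hi=s_hi),
    )


def random_pairs(rng, n=12):
    out = []
    for i in range(n):
        m = rng.uniform(5, 50)
        w1, w2 = rng.uniform(1, 8, size=2)
        m2 = m + rng.normal(0, 2)
        out.append(
            _pair({f"t{i}", f"u{i}"}, m, m - w1, m + w1, m2, m2 - w2, m2 + w2)
        )
    return out


class TestNodeDifferences:
    def test_identical_summaries(self):
        pairs = [_pair({"a", "b"}, 10, 8, 14, 10, 8, 14)]
        d = node_differences(pairs)[0]
        assert (d.d_median, d.d_min, d.d_max, d.d_width) == (0, 0, 0, 0)

    def test_hand_example(self):
        # primary (median 10, HPD 8-14), secondary (median 9, HPD 8.5-12)
        d = node_differences([_pair({"a"}, 10, 8, 14, 9, 8.5, 12)])[0]
        assert d.d_median == pytest.approx(1.0)
        assert d.d_min == pytest.approx(-0.5)
        assert d.d_max == pytest.approx(2.0)
        assert d.d_width == pytest.approx(2.5)

    def test_sign_convention_secondary_older(self):
        d = node_differences([_pair({"a"}, 10, 8, 14, 12, 9, 15)])[0]
        assert d.d_median < 0

    def test_antisymmetry_and_scale_equivariance(self):
        rng = np.random.default_rng(0)
        pairs = random_pairs(rng)
        fwd = node_differences(pairs)
        rev = node_differences([(s, p) for p, s in pairs])
        for a, b in zip(fwd, rev):
            assert a.d_median == pytest.approx(-b.d_median)
            assert a.d_width == pytest.approx(-b.d_width)
        assert summed_absolute_differences(fwd) == pytest.approx(
            summed_absolute_differences(rev)
        )
        c = 3.5
        scaled = [
            _pair(p.key, c * p.median, c * p.hpd_lo, c * p.hpd_hi,
                  c * s.median, c * s.hpd_lo, c * s.hpd_hi)
            for p, s in pairs
        ]
        assert np.allclose(
            np.array(summed_absolute_differences(node_differences(scaled))),
            c * np.array(summed_absolute_differences(fwd)),
        )

    def test_sums_use_absolute_values(self):
        pairs = [
            _pair({"a"}, 11, 10, 12, 10, 9, 11),  # d_median = +1
            _pair({"b"}, 10, 9, 11, 11, 10, 12),  # d_median = -1
        ]
        s_min, s_max, s_med, s_wid = summed_absolute_differences(node_differences(pairs))
        assert s_med == pytest.approx(2.0)

    def test_manual_five_node_fixture(self):
        rows = [
            # p_med p_lo p_hi  s_med s_lo s_hi
            (20.0, 15.0, 26.0, 18.0, 16.0, 21.0),
            (12.0, 9.0, 16.0, 11.5, 10.0, 13.0),
            (8.0, 6.0, 11.0, 8.5, 7.0, 10.0),
            (5.0, 3.5, 7.0, 4.0, 3.0, 5.0),
            (2.0, 1.0, 3.5, 2.2, 1.5, 2.8),
        ]
        pairs = [_pair({f"n{i}"}, *r) for i, r in enumerate(rows)]
        s_min, s_max, s_med, s_wid = summed_absolute_differences(node_differences(pairs))
        # spreadsheet-style recomputation
        assert s_min == pytest.approx(sum(abs(r[1] - r[4]) for r in rows))
        assert s_max == pytest.approx(sum(abs(r[2] - r[5]) for r in rows))
        assert s_med == pytest.approx(sum(abs(r[0] - r[3]) for r in rows))
        assert s_wid == pytest.approx(
            sum(abs((r[2] - r[1]) - (r[5] - r[4])) for r in rows)
        )

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            node_differences([])


class TestPairedT:
    def test_closed_form_example(self):
        t, df, p, ok = paired_t_test([1, 2, 3], [0, 0, 0])
        assert ok
        assert t == pytest.approx(2 / (1 / math.sqrt(3)))
        assert t == pytest.approx(3.4641, abs=1e-4)
        assert df == 2

    def test_zero_variance_flagged(self):
        t, df, p, ok = paired_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert not ok and math.isnan(p)

    def test_matches_reference_implementation(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=30), rng.normal(size=30)
        t, df, p, ok = paired_t_test(x, y)
        ref = stats.ttest_rel(x, y)
        assert t == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_null_p_uniform(self):
        rng = np.random.default_rng(2)
        ps = []
        for _ in range(300):
            x, y = rng.normal(size=20), rng.normal(size=20)
            ps.append(paired_t_test(x, y).p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_scale_invariance(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(10, 2, 15), rng.normal(9, 2, 15)
        a = paired_t_test(x, y)
        b = paired_t_test(7.3 * x, 7.3 * y)
        assert a.t == pytest.approx(b.t)
        assert a.p == pytest.approx(b.p)


class TestBonferroni:
    def test_single_test_uncorrected(self):
        assert bonferroni_flags([0.04]) == [True]
        assert bonferroni_flags([0.06]) == [False]

    def test_family_of_100(self):
        ps = [4e-4] + [1e-3] * 99
        flags = bonferroni_flags(ps, alpha=0.05)
        assert flags[0] is True and not any(flags[1:])

    def test_nan_never_significant(self):
        assert bonferroni_flags([float("nan"), 1e-9]) == [False, True]


class TestPooledWidthTest:
    def test_direction_with_known_narrowing(self):
        rng = np.random.default_rng(4)
        pairs = []
        for i in range(200):
            m = rng.uniform(10, 40)
            wp = rng.uniform(4, 6)
            ws = wp * rng.uniform(0.5, 0.8)  # secondary systematically narrower
            pairs.append(_pair({f"n{i}"}, m, m - wp / 2, m + wp / 2, m, m - ws / 2, m + ws / 2))
        t, df, p, ok = pooled_ci_width_test(pairs)
        assert ok and t > 0 and p < 1e-6
        assert df == 199

    def test_identical_widths_flagged(self):
        pairs = [_pair({f"n{i}"}, 10, 8, 12, 9, 7, 11) for i in range(5)]
        assert not pooled_ci_width_test(pairs).defined


class TestStandardizedAges:
    def test_endpoints_and_midpoint(self):
        out = standardized_node_ages([0.0, 35.0, 70.0], 70.0)
        assert np.allclose(out, [0.0, 0.5, 1.0])

    def test_monotone(self):
        ages = np.sort(np.random.default_rng(5).uniform(0, 70, 20))
        out = standardized_node_ages(ages, 70.0)
        assert np.all(np.diff(out) >= 0)

    def test_age_above_root_rejected(self):
        with pytest.raises(ValueError):
            standardized_node_ages([80.0], 70.0)


def _comp(i, root_age, n_tips, sums):
    return ReplicateComparison(
        replicate_id=i, arm="uniform", n_tips=n_tips, root_age=root_age,
        sum_abs_min=sums[0], sum_abs_max=sums[1], sum_abs_median=sums[2],
        sum_abs_width=sums[3], t_median=1.0, df=9, p_median=0.5,
    )


class TestRegression:
    def test_exact_line_recovered(self):
        comps = [_comp(i, 10.0 + 2 * i, 20, (5 + 3 * i,) * 4) for i in range(10)]
        res = regress_summaries(comps, "root_age")
        for r in res:
            assert r.slope == pytest.approx(1.5, abs=1e-10)
            assert r.intercept == pytest.approx(-10.0, abs=1e-9)
            assert r.p < 1e-12

    def test_known_slope_with_noise(self):
        rng = np.random.default_rng(6)
        comps = []
        for i in range(200):
            x = rng.uniform(0, 50)
            y = x + rng.normal(0, 5)
            comps.append(_comp(i, x, 20, (y,) * 4))
        r = regress_summaries(comps, "root_age")[0]
        x = np.array([c.root_age for c in comps])
        y = np.array([c.sum_abs_min for c in comps])
        se = stats.linregress(x, y).stderr
        assert abs(r.slope - 1.0) < 3 * se

    def test_constant_predictor_flagged(self):
        comps = [_comp(i, 10.0, 20, (float(i),) * 4) for i in range(5)]
        res = regress_summaries(comps, "n_tips")
        assert all(not r.defined for r in res)

    def test_null_p_uniform(self):
        rng = np.random.default_rng(7)
        ps = []
        for _ in range(200):
            comps = [
                _comp(i, rng.uniform(0, 50), 20, (rng.normal(),) * 4) for i in range(15)
            ]
            ps.append(regress_summaries(comps, "root_age")[0].p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01
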