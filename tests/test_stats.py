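"""Estimation statistics: BCa bootstrap, rank tests, box statistics."""

from itertools import combinations
from math import comb

import numpy as np
import pytest
from scipy import stats as sps

from axovuln.stats import (
    bonferroni,
    class_comparison,
    mann_whitney,
    mean_difference_bca,
    omnibus_and_posthoc,
    shared_control_design,
    tukey_box,
    welch_t,
)


def exact_mwu_pvalue(a, b):
    """Two-sided Mann-Whitney p by full enumeration of group assignments."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    pooled = np.concatenate([a, b])
    n, m = len(a), len(b)
    ranks = sps.rankdata(pooled)
    u_obs = ranks[:n].sum() - n * (n + 1) / 2
    mean_u = n * m / 2
    count = 0
    total = comb(n + m, n)
    for idx in combinations(range(n + m), n):
        u = ranks[list(idx)].sum() - n * (n + 1) / 2
        if abs(u - mean_u) >= abs(u_obs - mean_u) - 1e-9:
            count += 1
    return count / total


class TestMeanDifferenceBca:
    def test_identical_samples(self):
        r = mean_difference_bca([1, 2, 3], [1, 2, 3], seed=0)
        assert r.difference == 0.0
        assert r.ci_low <= 0.0 <= r.ci_high

    def test_observed_difference_exact(self):
        r = mean_difference_bca([1, 2, 3], [2, 3, 4], seed=0)
        assert r.difference == pytest.approx(1.0)

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(0, 1, 12), rng.normal(1, 1, 15)
        r1 = mean_difference_bca(a, b, n_resamples=2000, seed=99)
        r2 = mean_difference_bca(a, b, n_resamples=2000, seed=99)
        assert (r1.ci_low, r1.ci_high) == (r2.ci_low, r2.ci_high)
        r3 = mean_difference_bca(a, b, n_resamples=2000, seed=100)
        assert (r3.ci_low, r3.ci_high) != (r1.ci_low, r1.ci_high)

    def test_zero_variance_degenerates(self):
        r = mean_difference_bca([5, 5, 5], [7, 7, 7], seed=0)
        assert r.degenerate
        assert r.ci_low == r.ci_high == r.difference == 2.0

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            mean_difference_bca([1, 2], [1, 2, 3])

    def test_agrees_with_scipy_bca(self):
        # independent implementation of the same interval
        rng = np.random.default_rng(3)
        a, b = rng.normal(0, 1, 15), rng.normal(0.8, 1.5, 18)
        mine = mean_difference_bca(a, b, n_resamples=20000, seed=9)
        ref = sps.bootstrap(
            (a, b),
            lambda a, b, axis=-1: np.mean(b, axis=axis) - np.mean(a, axis=axis),
            n_resamples=20000,
            method="BCa",
            random_state=np.random.default_rng(4),
        )
        width = ref.confidence_interval.high - ref.confidence_interval.low
        assert mine.ci_low == pytest.approx(ref.confidence_interval.low, abs=0.05 * width)
        assert mine.ci_high == pytest.approx(ref.confidence_interval.high, abs=0.05 * width)

    def test_reduces_to_percentile_when_symmetric(self):
        # symmetric samples: bias z0 ~ 0 and jackknife acceleration exactly 0,
        # so the BCa interval must match the plain percentile interval
        a = np.tile([-1.0, 0.0, 1.0], 5)
        b = np.tile([0.0, 1.0, 2.0], 5)
        r = mean_difference_bca(a, b, n_resamples=4000, seed=21)
        rng = np.random.default_rng(21)
        ra = rng.integers(0, a.size, size=(4000, a.size))
        rb = rng.integers(0, b.size, size=(4000, b.size))
        boot = b[rb].mean(axis=1) - a[ra].mean(axis=1)
        lo, hi = np.quantile(boot, [0.025, 0.975])
        half = (hi - lo) / 2
        assert r.ci_low == pytest.approx(lo, abs=0.1 * half)
        assert r.ci_high == pytest.approx(hi, abs=0.1 * half)


class TestSharedControl:
    @staticmethod
    def _groups(seed=0):
        rng = np.random.default_rng(seed)
        labels = ["SNc", "VTA", "LC", "R", "DMV", "XII", "STR"]
        return {lab: rng.normal(i * 0.2, 1, 10) for i, lab in enumerate(labels)}

    def test_one_result_per_noncontrol_group(self):
        results = shared_control_design(self._groups(), "SNc", n_resamples=200)
        assert len(results) == 6
        assert all(r.group_a == "SNc" for r in results)

    def test_order_invariant_under_master_seed(self):
        groups = self._groups()
        r1 = shared_control_design(groups, "SNc", n_resamples=500, master_seed=5)
        shuffled = dict(reversed(list(groups.items())))
        r2 = shared_control_design(shuffled, "SNc", n_resamples=500, master_seed=5)
        by_label = {r.group_b: r for r in r2}
        for r in r1:
            assert (r.ci_low, r.ci_high) == (
                by_label[r.group_b].ci_low, by_label[r.group_b].ci_high
            )

    def test_control_vs_itself(self):
        results = shared_control_design(
            self._groups(), "SNc", n_resamples=200, include_control=True
        )
        self_r = next(r for r in results if r.group_b == "SNc")
        assert self_r.difference == 0.0

    def test_missing_control_rejected(self):
        with pytest.raises(ValueError):
            shared_control_design({"VTA": np.ones(5)}, "SNc")


class TestMannWhitney:
    def test_identical_multisets_midpoint(self):
        vals = [1.0, 2.0, 3.0, 4.0]
        r = mann_whitney(vals, vals)
        assert r.statistic == pytest.approx(len(vals) ** 2 / 2)
        assert r.p_raw > 0.9

    def test_fully_separated_five_vs_five(self):
        r = mann_whitney([1, 2, 3, 4, 5], [6, 7, 8, 9, 10])
        assert r.p_raw == pytest.approx(2 / comb(10, 5))

    def test_shift_invariance(self):
        rng = np.random.default_rng(8)
        a, b = rng.normal(0, 1, 8), rng.normal(1, 1, 9)
        r1 = mann_whitney(a, b)
        r2 = mann_whitney(a + 100.0, b + 100.0)
        assert r1.statistic == r2.statistic
        assert r1.p_raw == r2.p_raw

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_exact_p_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 7))
        m = int(rng.integers(3, 13 - n))
        a = rng.normal(0, 1, n)
        b = rng.normal(0.8, 1, m)
        r = mann_whitney(a, b)
        assert r.p_raw == pytest.approx(exact_mwu_pvalue(a, b), abs=1e-12)


class TestOmnibusAndPosthoc:
    @staticmethod
    def _normal_groups(shift=0.0, seed=0, n=20):
        rng = np.random.default_rng(seed)
        return {
            "g1": rng.normal(0, 1, n),
            "g2": rng.normal(0, 1, n),
            "g3": rng.normal(shift, 1, n),
        }

    def test_identical_groups_not_significant(self):
        results = omnibus_and_posthoc(self._normal_groups(seed=13))
        assert results[0].p_raw > 0.05

    def test_large_shift_detected_everywhere_relevant(self):
        results = omnibus_and_posthoc(self._normal_groups(shift=5.0, seed=1))
        omnibus = results[0]
        assert omnibus.p_raw < 0.001
        for r in results[1:]:
            if "g3" in r.groups:
                assert r.p_adjusted < 0.001

    def test_bonferroni_formula(self):
        assert bonferroni(0.01, 3) == pytest.approx(0.03)
        assert bonferroni(0.5, 4) == 1.0

    def test_parametric_route_runs_anova_tukey(self):
        results = omnibus_and_posthoc(self._normal_groups(seed=2), route="parametric")
        assert results[0].name == "one_way_anova"
        assert {r.name for r in results[1:]} == {"tukey_hsd"}

    def test_nonparametric_route_bonferroni_adjusts(self):
        results = omnibus_and_posthoc(
            self._normal_groups(seed=3), route="nonparametric"
        )
        assert results[0].name == "kruskal_wallis"
        for r in results[1:]:
            assert r.adjustment == "bonferroni"
            assert r.p_adjusted >= r.p_raw

    def test_nonnormal_data_routes_nonparametric(self):
        rng = np.random.default_rng(4)
        groups = {k: rng.exponential(1, 25) ** 3 for k in ("a", "b", "c")}
        results = omnibus_and_posthoc(groups)
        assert results[0].name == "kruskal_wallis"

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            omnibus_and_posthoc({"a": [1, 2], "b": [1, 2, 3]})


class TestClassComparison:
    def test_population_labels_mapped(self):
        rng = np.random.default_rng(0)
        labels = ["SNc", "LC", "R", "DMV", "VTA", "XII", "STR"] * 3
        values = [
            rng.normal(2 if lab in ("SNc", "LC", "R", "DMV") else 0, 0.5)
            for lab in labels
        ]
        test, est = class_comparison(values, labels, n_resamples=500, seed=1)
        assert test.name == "mann_whitney_u"
        assert test.p_raw < 0.01
        assert est.group_a == "vulnerable"
        assert est.difference < 0  # resilient minus vulnerable

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            class_comparison([1.0, 2.0], ["SNc", "LC"])

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            class_comparison([1.0, 2.0], ["SNc", "cortex"])


class TestWelch:
    def test_matches_scipy(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(0, 1, 10), rng.normal(1, 2, 14)
        r = welch_t(a, b)
        ref = sps.ttest_ind(a, b, equal_var=False)
        assert r.statistic == pytest.approx(ref.statistic)
        assert r.p_raw == pytest.approx(ref.pvalue)


class TestTukeyBox:
    def test_one_to_hundred(self):
        tb = tukey_box(np.arange(1, 101))
        assert tb.median == pytest.approx(50.5)
        assert tb.lower_hinge == pytest.approx(25.75)
        assert tb.upper_hinge == pytest.approx(75.25)
        assert tb.whisker_low == 1.0
        assert tb.whisker_high == 100.0

    def test_constant_sample(self):
        tb = tukey_box([3.0] * 10)
        assert tb.median == tb.lower_hinge == tb.upper_hinge == 3.0
        assert tb.whisker_low == tb.whisker_high == 3.0

    def test_outlier_excluded_from_whisker(self):
        data = list(range(1, 21)) + [1000.0]
        tb = tukey_box(data)
        assert tb.whisker_high == 20.0

    def test_whiskers_are_data_values_and_ordered(self):
        rng = np.random.default_rng(6)
        x = rng.lognormal(0, 1, 50)
        tb = tukey_box(x)
        assert tb.whisker_low in x and tb.whisker_high in x
        assert (
            tb.whisker_low <= tb.lower_hinge <= tb.median
            <= tb.upper_hinge <= tb.whisker_high
        )

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            tukey_box([1, 2, 3, 4])
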