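"""Test-retest statistics: hand examples, oracle equivalence, ICC properties."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from brainvitals.reliability import (
    PairedMeasures,
    anova_one_way,
    cronbach_alpha,
    icc_two_way_absolute_single,
    reliability_result,
    reliability_table,
)


def pairs_of(x, y):
    return PairedMeasures([str(i) for i in range(len(x))], np.asarray(x, float), np.asarray(y, float))


def brute_force_icc_a1(x, y):
    """ICC(A,1) from explicit two-way ANOVA sums (independent oracle)."""
    table = np.column_stack([x, y]).astype(float)
    n, k = table.shape
    grand = table.mean()
    ss_rows = sum(k * (table[i].mean() - grand) ** 2 for i in range(n))
    ss_cols = sum(n * (table[:, j].mean() - grand) ** 2 for j in range(k))
    ss_tot = sum((table[i, j] - grand) ** 2 for i in range(n) for j in range(k))
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = (ss_tot - ss_rows - ss_cols) / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


class TestAnova:
    def test_identical_groups_give_zero_f(self):
        f, p = anova_one_way(pairs_of([1, 2, 3], [1, 2, 3]))
        assert f == 0.0 and p == 1.0

    def test_zero_within_variance_flagged_infinite(self):
        f, p = anova_one_way(pairs_of([0, 0, 0], [1, 1, 1]))
        assert np.isinf(f) and p == 0.0

    def test_all_equal_everything_undefined(self):
        f, _ = anova_one_way(pairs_of([2, 2, 2], [2, 2, 2]))
        assert np.isnan(f)

    def test_f_equals_squared_pooled_t(self):
        x, y = [1.0, 2.0, 3.0, 4.0], [2.0, 3.0, 4.0, 5.0]
        f, p = anova_one_way(pairs_of(x, y))
        t, pt = stats.ttest_ind(x, y)
        assert f == pytest.approx(t**2, rel=1e-12)
        assert p == pytest.approx(pt, rel=1e-12)


class TestCronbach:
    def test_identical_sessions_alpha_one(self):
        assert cronbach_alpha(pairs_of([3, 5, 9], [3, 5, 9])) == pytest.approx(1.0)

    def test_hand_computed_negative_alpha(self):
        # var(x)=1, var(y)=1, var(x+y)=1 -> alpha = 2*(1 - 2/1) = -2
        assert cronbach_alpha(pairs_of([1, 2, 3], [3, 1, 2])) == pytest.approx(-2.0)

    def test_constant_total_is_undefined(self):
        assert np.isnan(cronbach_alpha(pairs_of([1, 2, 3], [4, 3, 2])))


class TestIcc:
    def test_identical_sessions_icc_one(self):
        icc, (lo, hi), p = icc_two_way_absolute_single(pairs_of([1, 2, 3, 4], [1, 2, 3, 4]))
        assert icc == pytest.approx(1.0)
        assert p == 0.0

    def test_constant_shift_penalized_matches_brute_force(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        y = [2.0, 3.0, 4.0, 5.0, 6.0]
        icc, _, _ = icc_two_way_absolute_single(pairs_of(x, y))
        assert icc < 1.0  # absolute agreement penalizes the +1 shift
        assert icc == pytest.approx(brute_force_icc_a1(x, y), rel=1e-12)

    def test_matches_brute_force_on_random_data(self, rng):
        for _ in range(20):
            n = int(rng.integers(4, 25))
            x = rng.normal(size=n)
            y = 0.6 * x + rng.normal(size=n) * 0.7
            icc, _, _ = icc_two_way_absolute_single(pairs_of(x, y))
            assert icc == pytest.approx(brute_force_icc_a1(x, y), rel=1e-10, abs=1e-12)

    def test_invariant_to_common_affine_transform(self, rng):
        x, y = rng.normal(size=12), rng.normal(size=12)
        base, _, _ = icc_two_way_absolute_single(pairs_of(x, y))
        moved, _, _ = icc_two_way_absolute_single(pairs_of(3.5 * x + 7, 3.5 * y + 7))
        assert moved == pytest.approx(base, rel=1e-9)

    def test_shifting_one_session_lowers_icc(self, rng):
        x = rng.normal(size=40)
        y = x + rng.normal(size=40) * 0.2
        base, _, _ = icc_two_way_absolute_single(pairs_of(x, y))
        shifted, _, _ = icc_two_way_absolute_single(pairs_of(x, y + 1.5))
        assert shifted < base

    def test_ci_brackets_estimate(self, rng):
        x = rng.normal(size=30)
        y = 0.7 * x + rng.normal(size=30) * 0.5
        icc, (lo, hi), _ = icc_two_way_absolute_single(pairs_of(x, y))
        assert lo <= icc <= hi

    def test_too_few_pairs_raises(self):
        with pytest.raises(ValueError):
            icc_two_way_absolute_single(pairs_of([1, 2], [2, 3]))

    def test_bivariate_normal_recovery(self):
        rng = np.random.default_rng(99)
        rho = 0.7
        cov = [[1, rho], [rho, 1]]
        xy = rng.multivariate_normal([0, 0], cov, size=2000)
        icc, _, _ = icc_two_way_absolute_single(pairs_of(xy[:, 0], xy[:, 1]))
        assert abs(icc - rho) < 0.05


class TestTableInterface:
    def test_listwise_deletion_of_incomplete_pairs(self):
        x = np.array([1.0, 2.0, np.nan, 4.0])
        y = np.array([1.5, np.nan, 3.0, 4.5])
        pairs = PairedMeasures(["a", "b", "c", "d"], x, y)
        assert pairs.n == 2
        assert pairs.subjects == ["a", "d"]

    def test_reliability_table_from_long_format(self, rng):
        rows = []
        for i in range(12):
            base = rng.normal(280, 40)
            for s, v in ((1, base), (2, base + rng.normal(0, 10))):
                rows.append(dict(participant_id=f"p{i}", group="A", age=16, sex="m",
                                 session=s, measure="p300_latency", value=v, unit="ms"))
        table = reliability_table(pd.DataFrame(rows))
        assert len(table) == 1
        row = table.iloc[0]
        assert row["n"] == 12
        assert row["icc_ci_low"] <= row["icc"] <= row["icc_ci_high"]

    def test_result_bundle_consistency(self, rng):
        x = rng.normal(size=15)
        y = 0.8 * x + rng.normal(size=15) * 0.4
        res = reliability_result(pairs_of(x, y), "p300_amplitude")
        assert res.n == 15
        assert -1.0 <= res.icc <= 1.0
        assert res.icc_ci_low <= res.icc <= res.icc_ci_high
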