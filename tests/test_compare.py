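"""Multivariate and univariate group comparison with an age covariate."""

import numpy as np
import pandas as pd
import pytest

from brainvitals import MEASURES
from brainvitals.compare import (
    age_regression,
    comparison_tables,
    estimated_marginal_means,
    fit_mancova,
    pivot_measurements,
    univariate_ancova,
)


def make_dataset(rng, n=80, group_shift=0.0, age_slope=0.0, responses=3,
                 confounded=False):
    """Wide table with `responses` outcome columns, age and a two-level group."""
    group = np.array(["A"] * (n // 2) + ["B"] * (n - n // 2))
    if confounded:
        age = np.where(group == "A", rng.uniform(10, 40, n), rng.uniform(40, 80, n))
    else:
        age = rng.uniform(10, 80, n)
    cols = {}
    names = list(MEASURES[:responses])
    for j, name in enumerate(names):
        cols[name] = (10.0 + age_slope * age + group_shift * (group == "B")
                      + rng.normal(size=n))
    frame = pd.DataFrame(cols)
    frame["age"] = age
    frame["group"] = group
    return frame, names


class TestMancova:
    def test_single_df_f_identity(self, rng):
        data, names = make_dataset(rng, n=90, group_shift=0.6, age_slope=0.05)
        for res in fit_mancova(data, responses=names):
            lam, p_resp = res.wilks_lambda, res.df_hypothesis
            expected_f = (1 - lam) / lam * res.df_error / p_resp
            assert res.f == pytest.approx(expected_f, rel=1e-12)
            assert res.partial_eta_squared == pytest.approx(1 - lam, rel=1e-12)

    def test_lambda_invariant_under_nonsingular_response_transform(self, rng):
        data, names = make_dataset(rng, n=70, group_shift=0.5)
        base = {r.term: r.wilks_lambda for r in fit_mancova(data, responses=names)}
        T = rng.normal(size=(len(names), len(names))) + 3 * np.eye(len(names))
        transformed = data.copy()
        transformed[names] = data[names].to_numpy() @ T
        moved = {r.term: r.wilks_lambda for r in fit_mancova(transformed, responses=names)}
        for term in base:
            assert moved[term] == pytest.approx(base[term], rel=1e-8)

    def test_achieved_error_df_reported(self, rng):
        data, names = make_dataset(rng, n=80, responses=3)
        res = fit_mancova(data, responses=names)
        assert all(r.df_error == 80 - 3 - 3 + 1 for r in res)

    def test_degenerate_responses_raise(self, rng):
        data, names = make_dataset(rng, n=40)
        data[names[1]] = data[names[0]]  # exactly collinear responses
        with pytest.raises((ValueError, np.linalg.LinAlgError)):
            fit_mancova(data, responses=names)

    def test_strong_group_effect_detected(self, rng):
        data, names = make_dataset(rng, n=120, group_shift=1.5)
        group_res = [r for r in fit_mancova(data, responses=names) if r.term == "group"][0]
        assert group_res.p < 0.001
        assert group_res.wilks_lambda < 0.9


class TestUnivariateAndMarginalMeans:
    def test_confounded_age_effect_removed_by_adjustment(self, rng):
        # groups differ only through age; the adjusted difference vanishes
        data, names = make_dataset(rng, n=200, age_slope=0.2, confounded=True)
        m = names[0]
        raw_diff = data.loc[data.group == "B", m].mean() - data.loc[data.group == "A", m].mean()
        emm = estimated_marginal_means(data, m)
        assert abs(raw_diff) > 4.0
        assert abs(emm.difference) < 1.0
        assert emm.ci_low <= emm.difference <= emm.ci_high

    def test_marginal_difference_matches_group_coefficient_sign_convention(self, rng):
        data, names = make_dataset(rng, n=150, group_shift=2.0)
        emm = estimated_marginal_means(data, names[0])
        assert emm.difference == pytest.approx(2.0, abs=0.6)  # B minus A

    def test_univariate_terms_present_and_f_positive(self, rng):
        data, names = make_dataset(rng, n=100, group_shift=1.0, age_slope=0.1)
        out = univariate_ancova(data, names[0])
        assert set(out) == {"corrected_model", "intercept", "age", "group"}
        assert all(f >= 0 for f, _ in out.values())
        assert out["age"][1] < 0.01 and out["group"][1] < 0.01

    def test_group_f_equals_squared_t_of_emm(self, rng):
        data, names = make_dataset(rng, n=90, group_shift=0.8)
        m = names[0]
        f, _ = univariate_ancova(data, m)["group"]
        emm = estimated_marginal_means(data, m)
        assert f == pytest.approx((emm.difference / emm.se) ** 2, rel=1e-8)


class TestAgeRegression:
    def test_exact_line_recovered(self):
        age = np.arange(10.0, 80.0)
        data = pd.DataFrame({"age": age, "p300_amplitude": 2.0 * age + 5.0,
                             "group": ["B"] * len(age)})
        (res,) = age_regression(data, "p300_amplitude")
        assert res.slope == pytest.approx(2.0)
        assert res.r_squared == pytest.approx(1.0)
        width = res.predictions["ci_high"] - res.predictions["ci_low"]
        assert np.all(width < 1e-8)

    def test_permuted_age_gives_near_zero_r_squared(self, rng):
        n = 135
        age = rng.uniform(8, 83, n)
        y = -0.05 * age + rng.normal(size=n)
        hits = 0
        for _ in range(20):
            data = pd.DataFrame({"age": rng.permutation(age), "p300_amplitude": y,
                                 "group": ["B"] * n})
            (res,) = age_regression(data, "p300_amplitude")
            hits += res.r_squared < 0.05
        assert hits >= 18

    def test_configured_slope_recovered_within_ci(self, rng):
        covered = 0
        for _ in range(30):
            age = rng.uniform(8, 83, 135)
            y = 5.0 - 0.046 * age + rng.normal(size=135) * 2.0
            data = pd.DataFrame({"age": age, "n400_amplitude": y, "group": ["B"] * 135})
            (res,) = age_regression(data, "n400_amplitude")
            covered += res.slope_ci[0] <= -0.046 <= res.slope_ci[1]
        assert covered >= 27  # ~95% nominal coverage

    def test_empty_bins_skipped(self, rng):
        data = pd.DataFrame({"age": rng.uniform(30, 40, 30),
                             "n100_latency": rng.normal(100, 10, 30),
                             "group": ["B"] * 30})
        (res,) = age_regression(data, "n100_latency")
        assert set(res.predictions["bin_mid"]) <= {35.0, 45.0}


class TestTables:
    def test_comparison_tables_shape_and_holm_flag(self, rng):
        data, names = make_dataset(rng, n=100, group_shift=0.5, responses=6)
        tabs = comparison_tables(data, holm=True)
        assert set(tabs) == {"multivariate", "univariate", "marginal_means"}
        assert list(tabs["multivariate"]["term"]) == ["intercept", "age", "group"]
        assert len(tabs["univariate"]) == 6
        assert "p_holm" in tabs["marginal_means"].columns
        assert (tabs["marginal_means"]["p_holm"] >= tabs["marginal_means"]["p"] - 1e-12).all()

    def test_pivot_round_trip(self, rng):
        rows = []
        for i in range(5):
            for m in MEASURES:
                rows.append(dict(participant_id=f"p{i}", group="A", age=16.0, sex="m",
                                 session=1, measure=m, value=float(i), unit="uV"))
        wide = pivot_measurements(pd.DataFrame(rows))
        assert len(wide) == 5
        assert set(MEASURES) <= set(wide.columns)
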