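"""Group comparison with age as covariate: MANCOVA, follow-ups, age curves.

The multivariate test fits all six measures jointly on an intercept, age and
a group dummy (reference group first), forms hypothesis and error
cross-product matrices per term, and reports Wilks' Lambda
(det(E)/det(H+E)) with Rao's F approximation — exact for the single-df terms
used here — and partial eta squared (1 - Lambda for single-df terms).
Univariate follow-ups, covariate-adjusted estimated marginal means and
per-group age regressions are ordinary least squares through statsmodels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy.stats import f as f_dist

from .measures import MEASURES


@dataclass
class MultivariateTestResult:
    term: str
    wilks_lambda: float
    f: float
    df_hypothesis: float
    df_error: float
    p: float
    partial_eta_squared: float


@dataclass
class MarginalMeansResult:
    measure: str
    difference: float      # group B - group A, at the grand mean of age
    se: float
    ci_low: float
    ci_high: float
    p: float


def _complete_cases(data: pd.DataFrame, responses: list[str],
                    covariate: str, group_col: str) -> pd.DataFrame:
    cols = responses + [covariate, group_col]
    return data.dropna(subset=cols).reset_index(drop=True)


def pivot_measurements(measurements: pd.DataFrame) -> pd.DataFrame:
    """Long-format measurement table -> one row per participant-session."""
    wide = measurements.pivot_table(
        index=["participant_id", "group", "age", "session"],
        columns="measure", values="value", aggfunc="first").reset_index()
    wide.columns.name = None
    return wide


def fit_mancova(data: pd.DataFrame, responses: list[str] | None = None,
                covariate: str = "age", group_col: str = "group",
                reference_group: str | None = None) -> list[MultivariateTestResult]:
    """Wilks' Lambda MANCOVA for intercept, covariate and group terms.

    ``data`` is wide (one row per case). Listwise-complete cases across all
    responses are used; the achieved error df is reported in the results.
    """
    responses = responses or list(MEASURES)
    df = _complete_cases(data, responses, covariate, group_col)
    levels = sorted(df[group_col].unique())
    if reference_group is None:
        reference_group = levels[0]
    if len(levels) != 2:
        raise ValueError(f"group factor must have exactly 2 levels, got {levels}")
    other = [g for g in levels if g != reference_group][0]

    n = len(df)
    p = len(responses)
    X = np.column_stack([
        np.ones(n),
        df[covariate].to_numpy(float),
        (df[group_col] == other).astype(float).to_numpy(),
    ])
    terms = ["intercept", covariate, group_col]
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    if n <= X.shape[1] + p:
        raise ValueError("too few complete cases for the multivariate test")

    Y = df[responses].to_numpy(float)
    XtX = X.T @ X
    XtX_inv = np.linalg.inv(XtX)
    B = XtX_inv @ X.T @ Y
    E = Y.T @ Y - B.T @ XtX @ B
    df_e = n - rank
    sign, logdet = np.linalg.slogdet(E)
    if sign <= 0 or not np.isfinite(logdet) or np.linalg.matrix_rank(E) < p:
        raise ValueError("error cross-product matrix is singular; responses degenerate")

    results = []
    for j, term in enumerate(terms):
        b = B[j][:, None]                      # p x 1
        H = (b @ b.T) / XtX_inv[j, j]          # single-df hypothesis SSCP
        lam = float(np.linalg.det(E) / np.linalg.det(E + H))
        # Rao's F, exact for a single-df hypothesis
        df2 = df_e - p + 1
        f_val = (1.0 - lam) / lam * df2 / p
        p_val = float(f_dist.sf(f_val, p, df2))
        results.append(MultivariateTestResult(
            term=term, wilks_lambda=lam, f=float(f_val), df_hypothesis=float(p),
            df_error=float(df2), p=p_val, partial_eta_squared=1.0 - lam))
    return results


def _ols_fit(data: pd.DataFrame, measure: str, covariate: str, group_col: str,
             reference_group: str):
    df = data.dropna(subset=[measure, covariate, group_col]).copy()
    formula = f"{measure} ~ {covariate} + C({group_col}, Treatment('{reference_group}'))"
    return smf.ols(formula, data=df).fit(), df


def univariate_ancova(data: pd.DataFrame, measure: str, covariate: str = "age",
                      group_col: str = "group", reference_group: str = "A",
                      ) -> dict[str, tuple[float, float]]:
    """Per-measure ANCOVA: corrected-model, intercept, age and group F tests.

    Returns ``{"corrected_model"|"intercept"|covariate|group_col: (F, p)}``
    using partial (Type III) sums of squares, matching the follow-up table
    convention of multivariate covariance analyses.
    """
    fit, _ = _ols_fit(data, measure, covariate, group_col, reference_group)
    aov = sm.stats.anova_lm(fit, typ=3)
    group_term = [ix for ix in aov.index if ix.startswith("C(")][0]
    return {
        "corrected_model": (float(fit.fvalue), float(fit.f_pvalue)),
        "intercept": (float(aov.loc["Intercept", "F"]), float(aov.loc["Intercept", "PR(>F)"])),
        covariate: (float(aov.loc[covariate, "F"]), float(aov.loc[covariate, "PR(>F)"])),
        group_col: (float(aov.loc[group_term, "F"]), float(aov.loc[group_term, "PR(>F)"])),
    }


def estimated_marginal_means(data: pd.DataFrame, measure: str, covariate: str = "age",
                             group_col: str = "group", reference_group: str = "A",
                             ci_level: float = 0.95) -> MarginalMeansResult:
    """Covariate-adjusted group difference (non-reference minus reference).

    With an additive model the estimated marginal means are the model
    predictions at the covariate's grand mean, so their difference is exactly
    the group coefficient; SE, CI and p come from the coefficient's t
    distribution, with no multiplicity adjustment.
    """
    fit, _ = _ols_fit(data, measure, covariate, group_col, reference_group)
    name = [p for p in fit.params.index if p.startswith("C(")][0]
    ci = fit.conf_int(alpha=1 - ci_level).loc[name]
    return MarginalMeansResult(
        measure=measure, difference=float(fit.params[name]), se=float(fit.bse[name]),
        ci_low=float(ci[0]), ci_high=float(ci[1]), p=float(fit.pvalues[name]))


@dataclass
class AgeRegressionResult:
    group: str
    measure: str
    slope: float
    intercept: float
    slope_ci: tuple[float, float]
    r_squared: float
    predictions: pd.DataFrame  # bin_mid, predicted, ci_low, ci_high, n


def age_regression(data: pd.DataFrame, measure: str, bins: list[tuple[float, float]] | None = None,
                   covariate: str = "age", group_col: str = "group",
                   ci_level: float = 0.95) -> list[AgeRegressionResult]:
    """Per-group OLS of a measure on age, with decade-binned predictions.

    Empty bins are skipped. The prediction CI is the confidence band of the
    regression mean at each bin midpoint.
    """
    if bins is None:
        bins = [(lo, lo + 10.0) for lo in range(0, 90, 10)]
    out = []
    for grp, sub in data.groupby(group_col):
        sub = sub.dropna(subset=[measure, covariate])
        if len(sub) < 3:
            continue
        fit = smf.ols(f"{measure} ~ {covariate}", data=sub).fit()
        rows = []
        for lo, hi in bins:
            in_bin = sub[(sub[covariate] >= lo) & (sub[covariate] < hi)]
            if len(in_bin) == 0:
                continue
            mid = (lo + hi) / 2.0
            pred = fit.get_prediction(pd.DataFrame({covariate: [mid]}))
            frame = pred.summary_frame(alpha=1 - ci_level)
            rows.append(dict(bin_mid=mid, predicted=float(frame["mean"].iloc[0]),
                             ci_low=float(frame["mean_ci_lower"].iloc[0]),
                             ci_high=float(frame["mean_ci_upper"].iloc[0]),
                             n=len(in_bin)))
        ci = fit.conf_int(alpha=1 - ci_level).loc[covariate]
        out.append(AgeRegressionResult(
            group=str(grp), measure=measure, slope=float(fit.params[covariate]),
            intercept=float(fit.params["Intercept"]), slope_ci=(float(ci[0]), float(ci[1])),
            r_squared=float(fit.rsquared), predictions=pd.DataFrame(rows)))
    return out


def comparison_tables(data: pd.DataFrame, covariate: str = "age", group_col: str = "group",
                      reference_group: str = "A", holm: bool = False,
                      ) -> dict[str, pd.DataFrame]:
    """All group-comparison outputs as tidy frames.

    ``data`` is wide (one row per case; typically session 1 only). Returns
    ``{"multivariate", "univariate", "marginal_means"}``. ``holm=True``
    applies a Holm adjustment to the six marginal-means p-values (off by
    default, matching the convention of reporting unadjusted follow-ups).
    """
    mv = fit_mancova(data, covariate=covariate, group_col=group_col,
                     reference_group=reference_group)
    mv_frame = pd.DataFrame([vars(r) for r in mv])
    uni_rows, emm_rows = [], []
    for m in MEASURES:
        if m not in data.columns:
            continue
        uni = univariate_ancova(data, m, covariate, group_col, reference_group)
        uni_rows.append(dict(measure=m,
                             corrected_model_f=uni["corrected_model"][0],
                             corrected_model_p=uni["corrected_model"][1],
                             intercept_f=uni["intercept"][0], intercept_p=uni["intercept"][1],
                             age_f=uni[covariate][0], age_p=uni[covariate][1],
                             group_f=uni[group_col][0], group_p=uni[group_col][1]))
        emm_rows.append(vars(estimated_marginal_means(data, m, covariate, group_col,
                                                      reference_group)))
    emm_frame = pd.DataFrame(emm_rows)
    if holm and len(emm_frame):
        from statsmodels.stats.multitest import multipletests
        emm_frame["p_holm"] = multipletests(emm_frame["p"], method="holm")[1]
    return {"multivariate": mv_frame, "univariate": pd.DataFrame(uni_rows),
            "marginal_means": emm_frame}
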