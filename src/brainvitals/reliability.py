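"""Test-retest reliability: one-way ANOVA, Cronbach's alpha, ICC(A,1).

All three statistics are computed from mean squares of the paired
session-1/session-2 data. The intraclass correlation is the single-measures,
absolute-agreement form ICC(A,1) from the two-way subjects x sessions
decomposition (the "two-way mixed" and "two-way random" absolute-agreement
estimators share the same arithmetic; the distinction is interpretive only).
Its confidence interval and p-value follow the McGraw & Wong (1996)
F-distribution procedure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist

from .measures import MEASURES


@dataclass
class PairedMeasures:
    """Complete session-1/session-2 pairs for one measure."""

    subjects: list[str]
    session1: np.ndarray
    session2: np.ndarray

    def __post_init__(self) -> None:
        self.session1 = np.asarray(self.session1, dtype=float)
        self.session2 = np.asarray(self.session2, dtype=float)
        if self.session1.shape != self.session2.shape or self.session1.ndim != 1:
            raise ValueError("sessions must be 1-D arrays of equal length")
        keep = np.isfinite(self.session1) & np.isfinite(self.session2)
        if not keep.all():  # listwise deletion of incomplete pairs
            self.subjects = [s for s, k in zip(self.subjects, keep) if k]
            self.session1 = self.session1[keep]
            self.session2 = self.session2[keep]

    @property
    def n(self) -> int:
        return len(self.session1)

    @classmethod
    def from_long(cls, measurements: pd.DataFrame, measure: str) -> "PairedMeasures":
        """Extract complete pairs for one measure from a long-format table."""
        sub = measurements[measurements["measure"] == measure]
        wide = sub.pivot_table(index="participant_id", columns="session",
                               values="value", aggfunc="first")
        if 1 not in wide.columns or 2 not in wide.columns:
            raise ValueError(f"measure {measure!r} lacks two sessions")
        wide = wide.dropna(subset=[1, 2])
        return cls(list(wide.index), wide[1].to_numpy(), wide[2].to_numpy())


@dataclass
class ReliabilityResult:
    measure: str
    n: int
    anova_f: float
    anova_p: float
    cronbach_alpha: float
    icc: float
    icc_ci_low: float
    icc_ci_high: float
    icc_p: float


def _two_way_mean_squares(x: np.ndarray) -> tuple[float, float, float]:
    """(MS_rows, MS_cols, MS_error) of an n x k subjects-by-sessions table."""
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    return ss_rows / (n - 1), ss_cols / (k - 1), ss_err / ((n - 1) * (k - 1))


def anova_one_way(pairs: PairedMeasures) -> tuple[float, float]:
    """One-way ANOVA treating the two sessions as independent groups.

    Returns (F, p) with df (1, 2n-2). With zero within-group variance the F
    is infinite (returned as ``inf`` with p = 0) unless the between-group
    variance is also zero, in which case F is undefined (``nan``).
    """
    if pairs.n < 2:
        raise ValueError("one-way ANOVA needs at least 2 pairs")
    groups = [pairs.session1, pairs.session2]
    n_tot = 2 * pairs.n
    grand = np.concatenate(groups).mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(np.sum((g - g.mean()) ** 2) for g in groups)
    df_b, df_w = 1, n_tot - 2
    ms_b, ms_w = ss_between / df_b, ss_within / df_w
    if ms_w == 0:
        return (math.nan, math.nan) if ms_b == 0 else (math.inf, 0.0)
    f = ms_b / ms_w
    return float(f), float(f_dist.sf(f, df_b, df_w))


def cronbach_alpha(pairs: PairedMeasures) -> float:
    """Cronbach's alpha over the two sessions (k = 2, sample variances n-1)."""
    if pairs.n < 2:
        raise ValueError("Cronbach's alpha needs at least 2 pairs")
    k = 2
    item_vars = np.var(pairs.session1, ddof=1) + np.var(pairs.session2, ddof=1)
    total_var = np.var(pairs.session1 + pairs.session2, ddof=1)
    if total_var == 0:
        return math.nan
    return float(k / (k - 1) * (1.0 - item_vars / total_var))


def icc_two_way_absolute_single(pairs: PairedMeasures, ci_level: float = 0.95,
                                ) -> tuple[float, tuple[float, float], float]:
    """ICC(A,1) with its McGraw-Wong confidence interval and p-value.

    Returns ``(icc, (ci_low, ci_high), p)``. The p-value tests ICC = 0 via
    F = MS_rows / MS_error on ((n-1), (n-1)(k-1)) df.
    """
    if pairs.n < 3:
        raise ValueError("ICC confidence interval needs at least 3 pairs")
    x = np.column_stack([pairs.session1, pairs.session2])
    n, k = x.shape
    msr, msc, mse = _two_way_mean_squares(x)
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        return math.nan, (math.nan, math.nan), math.nan
    icc = (msr - mse) / denom
    if mse == 0:
        return float(icc), (float(icc), float(icc)), 0.0

    alpha = 1.0 - ci_level
    df1, df2 = n - 1, (n - 1) * (k - 1)
    f_stat = msr / mse
    p = float(f_dist.sf(f_stat, df1, df2))

    fj = msc / mse
    a = n * (1 + (k - 1) * icc) - k * icc
    vn = df2 * (k * icc * fj + a) ** 2
    vd = df1 * k**2 * icc**2 * fj**2 + a**2
    v = vn / vd
    f_u = f_dist.ppf(1 - alpha / 2, df1, v)
    f_l = f_dist.ppf(1 - alpha / 2, v, df1)
    lo = n * (msr - f_u * mse) / (f_u * (k * msc + (k * n - k - n) * mse) + n * msr)
    hi = n * (f_l * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f_l * msr)
    return float(icc), (float(lo), float(hi)), p


def reliability_result(pairs: PairedMeasures, measure: str = "",
                       ci_level: float = 0.95) -> ReliabilityResult:
    """All test-retest statistics for one measure's pairs."""
    f, p = anova_one_way(pairs)
    alpha = cronbach_alpha(pairs)
    icc, (lo, hi), icc_p = icc_two_way_absolute_single(pairs, ci_level)
    return ReliabilityResult(measure, pairs.n, f, p, alpha, icc, lo, hi, icc_p)


def reliability_table(measurements: pd.DataFrame, ci_level: float = 0.95) -> pd.DataFrame:
    """Test-retest statistics for every measure present with two sessions."""
    rows = []
    for m in MEASURES:
        try:
            pairs = PairedMeasures.from_long(measurements, m)
        except ValueError:
            continue
        if pairs.n < 3:
            continue
        r = reliability_result(pairs, m, ci_level)
        rows.append(vars(r))
    return pd.DataFrame(rows)
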