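"""Cohort statistics: reproducibility ICC, group comparisons, correlations
and the univariate-to-multivariate regression procedure.

The intraclass correlation is the consistency-type two-way mixed model
(Shrout-Fleiss ICC(3,1) for single measures, ICC(3,k) for the k-measure
average), computed from the two-way ANOVA decomposition of the subjects x
raters rating matrix with the standard F-based 95% confidence intervals.
Group comparisons use the independent t-test (two groups) or one-way
ANOVA plus Kruskal-Wallis (more groups), and Pearson's chi-square (no
continuity correction, matching the SPSS default) for categorical
variables.  Regressions are ordinary least squares: every candidate is
screened univariately and survivors at P < 0.2 enter the multivariate
model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "ICCResult",
    "RegressionReport",
    "icc_two_way_mixed",
    "compare_groups",
    "correlation_matrix",
    "regression_tables",
    "summarize_mean_sd",
]


# --------------------------------------------------------------------------
# ICC
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ICCResult:
    """Two-way mixed, consistency-type ICC (single and average measures)."""

    icc_single: float
    icc_average: float
    ci95_single: tuple[float, float]
    ci95_average: tuple[float, float]
    n_subjects: int
    k_raters: int


def icc_two_way_mixed(ratings: np.ndarray, alpha: float = 0.05) -> ICCResult:
    """ICC(3,1) and ICC(3,k) from an ``n_subjects x k_raters`` matrix.

    From the two-way ANOVA mean squares (rows = subjects, columns = raters):
    ``ICC(3,1) = (MS_rows - MS_err) / (MS_rows + (k-1) MS_err)`` and
    ``ICC(3,k) = (MS_rows - MS_err) / MS_rows``; 95% CIs via the F
    distribution of ``MS_rows / MS_err``.  A matrix with zero residual error
    (e.g. two identical columns) is perfect agreement, ICC = 1.
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2:
        raise ValueError("ratings must be a 2D n_subjects x k_raters matrix")
    n, k = x.shape
    if n < 3:
        raise ValueError(f"need at least 3 subjects, got {n}")
    if k < 2:
        raise ValueError(f"need at least 2 raters, got {k}")
    if not np.isfinite(x).all():
        raise ValueError("ratings must not contain missing values")

    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * float(((row_means - grand) ** 2).sum())
    # residual-based error SS avoids the catastrophic cancellation of
    # SS_total - SS_rows - SS_cols for (near-)perfect agreement
    resid = x - row_means[:, None] - col_means[None, :] + grand
    ss_err = float((resid**2).sum())
    ms_rows = ss_rows / (n - 1)
    df_err = (n - 1) * (k - 1)
    ms_err = ss_err / df_err

    if ms_rows == 0.0 and ms_err == 0.0:
        raise ValueError("ratings have no between-subject variance and no error")
    if ms_err <= 1e-12 * ms_rows:  # perfect agreement at machine precision
        return ICCResult(1.0, 1.0, (1.0, 1.0), (1.0, 1.0), n, k)

    icc_single = (ms_rows - ms_err) / (ms_rows + (k - 1) * ms_err)
    icc_average = (ms_rows - ms_err) / ms_rows

    f_obs = ms_rows / ms_err
    df1, df2 = n - 1, df_err
    f_lower = f_obs / stats.f.ppf(1 - alpha / 2, df1, df2)
    f_upper = f_obs * stats.f.ppf(1 - alpha / 2, df2, df1)
    ci_single = ((f_lower - 1) / (f_lower + k - 1), (f_upper - 1) / (f_upper + k - 1))
    ci_average = (1 - 1 / f_lower, 1 - 1 / f_upper)
    return ICCResult(
        icc_single=float(icc_single),
        icc_average=float(icc_average),
        ci95_single=(float(ci_single[0]), float(ci_single[1])),
        ci95_average=(float(ci_average[0]), float(ci_average[1])),
        n_subjects=n,
        k_raters=k,
    )


# --------------------------------------------------------------------------
# Group comparisons
# --------------------------------------------------------------------------


def summarize_mean_sd(
    table: pd.DataFrame, variables: list[str], by: str, decimals: int = 2
) -> pd.DataFrame:
    """Per-group ``mean ± SD`` presentation strings (one row per variable)."""
    out = {}
    for name, sub in table.groupby(by, observed=True):
        col = {}
        for v in variables:
            vals = pd.to_numeric(sub[v], errors="coerce").dropna()
            col[v] = f"{vals.mean():.{decimals}f} ± {vals.std(ddof=1):.{decimals}f}"
        out[str(name)] = col
    return pd.DataFrame(out).loc[variables]


def compare_groups(
    table: pd.DataFrame,
    grouping: str,
    continuous: list[str] | None = None,
    categorical: list[str] | None = None,
) -> pd.DataFrame:
    """Per-variable group comparison in the published tables' layout.

    Two groups: independent t-test; more: one-way ANOVA and Kruskal-Wallis
    (both emitted).  Categorical variables use Pearson's chi-square on the
    contingency table.  Returns one row per variable with per-group
    ``mean ± SD`` (or level counts), the statistic(s) and P value(s).
    """
    continuous = continuous or []
    categorical = categorical or []
    groups = [str(g) for g in sorted(table[grouping].dropna().unique())]
    if len(groups) < 2:
        raise ValueError(f"need >= 2 groups in {grouping!r}, got {groups}")
    for g in groups:
        if (table[grouping] == g).sum() == 0:  # pragma: no cover - unique() guards
            raise ValueError(f"group {g!r} is empty")

    rows = []
    for v in continuous:
        samples = []
        for g in groups:
            vals = pd.to_numeric(
                table.loc[table[grouping].astype(str) == g, v], errors="coerce"
            ).dropna().to_numpy()
            if vals.size < 2:
                raise ValueError(f"group {g!r} has fewer than 2 observations for {v!r}")
            samples.append(vals)
        row = {"variable": v, "type": "continuous"}
        for g, vals in zip(groups, samples):
            row[g] = f"{vals.mean():.2f} ± {vals.std(ddof=1):.2f}"
        if len(groups) == 2:
            t, p = stats.ttest_ind(samples[0], samples[1], equal_var=True)
            row.update(test="t-test", statistic=float(t), p_value=float(p))
        else:
            f, p_anova = stats.f_oneway(*samples)
            h, p_kw = stats.kruskal(*samples)
            row.update(
                test="anova+kruskal",
                statistic=float(f),
                p_value=float(p_anova),
                kruskal_statistic=float(h),
                kruskal_p_value=float(p_kw),
            )
        rows.append(row)

    for v in categorical:
        crosstab = pd.crosstab(table[v], table[grouping].astype(str))
        chi2, p, _, _ = stats.chi2_contingency(crosstab.to_numpy(), correction=False)
        row = {"variable": v, "type": "categorical", "test": "chi-square",
               "statistic": float(chi2), "p_value": float(p)}
        for g in groups:
            counts = crosstab[g] if g in crosstab else pd.Series(dtype=int)
            row[g] = ":".join(str(int(c)) for c in counts)
        rows.append(row)
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Correlations
# --------------------------------------------------------------------------


def correlation_matrix(table: pd.DataFrame, variables: list[str]) -> pd.DataFrame:
    """Pairwise Pearson R and P for the listed variables (long form).

    Zero-variance variables are flagged and their R left undefined (NaN).
    """
    rows = []
    for i, a in enumerate(variables):
        for b in variables[i + 1 :]:
            sub = table[[a, b]].apply(pd.to_numeric, errors="coerce").dropna()
            n = len(sub)
            if n < 3:
                raise ValueError(f"fewer than 3 complete pairs for ({a}, {b})")
            xa, xb = sub[a].to_numpy(), sub[b].to_numpy()
            if np.std(xa) == 0.0 or np.std(xb) == 0.0:
                rows.append(
                    {"var1": a, "var2": b, "r": np.nan, "p_value": np.nan,
                     "n": n, "flag": "zero_variance"}
                )
                continue
            r, p = stats.pearsonr(xa, xb)
            rows.append({"var1": a, "var2": b, "r": float(r), "p_value": float(p),
                         "n": n, "flag": ""})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Regression
# --------------------------------------------------------------------------

_CONDITION_WARN = 1e4


@dataclass(frozen=True)
class RegressionReport:
    """Univariate screen plus multivariate OLS in the published layout."""

    dependent: str
    univariate: pd.DataFrame  # variable, beta, p_value
    multivariate: pd.DataFrame  # variable, beta, ci_low, ci_high, p_value
    selected: tuple[str, ...]
    screen_p: float
    condition_warning: bool = False
    notes: tuple[str, ...] = field(default=())


def regression_tables(
    table: pd.DataFrame,
    dependent: str,
    candidates: list[str],
    screen_p: float = 0.2,
) -> RegressionReport:
    """Univariate OLS per candidate, multivariate on the P < screen survivors.

    Collinear survivor sets are kept (drop-none policy) but flagged through
    ``condition_warning`` when the design matrix condition number is large.
    """
    data = table[[dependent] + list(candidates)].apply(pd.to_numeric, errors="coerce").dropna()
    n = len(data)
    if n <= len(candidates) + 2:
        raise ValueError(f"n={n} too small for {len(candidates)} candidates")
    y = data[dependent].to_numpy()

    uni_rows = []
    for v in candidates:
        model = sm.OLS(y, sm.add_constant(data[v].to_numpy())).fit()
        uni_rows.append(
            {"variable": v, "beta": float(model.params[1]), "p_value": float(model.pvalues[1])}
        )
    univariate = pd.DataFrame(uni_rows)
    selected = tuple(univariate.loc[univariate.p_value < screen_p, "variable"])

    multi_rows = []
    condition_warning = False
    if selected:
        X = sm.add_constant(data[list(selected)].to_numpy())
        model = sm.OLS(y, X).fit()
        condition_warning = bool(np.linalg.cond(X) > _CONDITION_WARN)
        ci = model.conf_int(alpha=0.05)
        for j, v in enumerate(selected, start=1):
            multi_rows.append(
                {
                    "variable": v,
                    "beta": float(model.params[j]),
                    "ci_low": float(ci[j][0]),
                    "ci_high": float(ci[j][1]),
                    "p_value": float(model.pvalues[j]),
                }
            )
    multivariate = pd.DataFrame(
        multi_rows, columns=["variable", "beta", "ci_low", "ci_high", "p_value"]
    )
    return RegressionReport(
        dependent=dependent,
        univariate=univariate,
        multivariate=multivariate,
        selected=selected,
        screen_p=screen_p,
        condition_warning=condition_warning,
    )
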