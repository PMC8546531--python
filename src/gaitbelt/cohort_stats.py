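"""Cohort-level statistical reporting: group comparisons, Pearson
correlation matrices, and linear regression with standardized coefficients
and variance inflation factors.

Conventions: the two-group continuous comparison is a Welch (unequal
variance) t test, two tailed; more than two groups use one-way ANOVA;
discrete variables use the Pearson chi-square test, switching to the Fisher
exact test for 2x2 tables with any expected cell below 5.  Correlations use
pairwise-complete observations; regression uses listwise deletion.  No
multiple-testing correction is applied by default (a Holm adjustment can be
requested).
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.outliers_influence import variance_inflation_factor

from .exceptions import DegenerateInputError, ParameterError, SingularDesignError


@dataclasses.dataclass
class GroupComparison:
    variable: str
    kind: str                      # "continuous" | "discrete"
    groups: dict                   # name -> {n, mean, sd} or name -> {category: count}
    test: str                      # "welch-t" | "anova" | "chi-square" | "fisher"
    statistic: float
    p_value: float


@dataclasses.dataclass
class RegressionReport:
    """OLS fit summary: per-predictor B, standardized beta, t, p and VIF."""

    table: pd.DataFrame            # index: predictor; columns: B, beta, t, p_value, vif
    intercept: float
    r_squared: float
    n: int


def compare_groups(
    values_by_group: Mapping[str, Sequence],
    variable_kind: str = "continuous",
    variable: str = "",
) -> GroupComparison:
    """Compare a variable across groups with the convention-appropriate test.

    Continuous data with two groups use the Welch two-tailed t test, with
    more than two groups one-way ANOVA.  Discrete data (category labels per
    observation) use Pearson chi-square, or Fisher exact for a 2x2 table
    with any expected count below 5.
    """
    names = list(values_by_group)
    if len(names) < 2 or any(len(values_by_group[g]) == 0 for g in names):
        raise ParameterError("need at least two non-empty groups")
    if variable_kind == "continuous":
        arrays = [np.asarray(values_by_group[g], dtype=float) for g in names]
        groups = {
            g: {"n": a.size, "mean": float(a.mean()),
                "sd": float(a.std(ddof=1)) if a.size > 1 else 0.0}
            for g, a in zip(names, arrays)
        }
        if len(arrays) == 2:
            if all(np.ptp(a) == 0 for a in arrays):
                raise DegenerateInputError(
                    f"{variable or 'variable'}: zero variance in both groups"
                )
            stat, p = stats.ttest_ind(*arrays, equal_var=False)
            test = "welch-t"
        else:
            stat, p = stats.f_oneway(*arrays)
            test = "anova"
        return GroupComparison(variable, "continuous", groups, test, float(stat), float(p))
    if variable_kind == "discrete":
        categories = sorted({str(v) for g in names for v in values_by_group[g]})
        table = np.array(
            [[sum(str(v) == c for v in values_by_group[g]) for c in categories]
             for g in names],
            dtype=float,
        )
        groups = {
            g: dict(zip(categories, map(int, row))) for g, row in zip(names, table)
        }
        expected = stats.contingency.expected_freq(table)
        if table.shape == (2, 2) and expected.min() < 5:
            stat, p = stats.fisher_exact(table)
            test = "fisher"
        else:
            stat, p, _, _ = stats.chi2_contingency(table, correction=False)
            test = "chi-square"
        return GroupComparison(variable, "discrete", groups, test, float(stat), float(p))
    raise ParameterError(f"unknown variable_kind {variable_kind!r}")


def correlation_matrix(
    data: pd.DataFrame, min_obs: int = 3
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise-complete Pearson correlations with two-tailed p values.

    Returns ``(r, p)`` frames; the diagonal of ``r`` is 1 and of ``p`` NaN.

    Raises
    ------
    ParameterError
        A pair has fewer than ``min_obs`` complete observations.
    DegenerateInputError
        A variable is constant on a pair's complete observations.
    """
    columns = list(data.columns)
    r = pd.DataFrame(np.eye(len(columns)), index=columns, columns=columns)
    p = pd.DataFrame(np.full((len(columns), len(columns)), np.nan),
                     index=columns, columns=columns)
    for i, a in enumerate(columns):
        for j in range(i + 1, len(columns)):
            b = columns[j]
            pair = data[[a, b]].dropna()
            if len(pair) < min_obs:
                raise ParameterError(
                    f"pair ({a}, {b}): {len(pair)} complete observations < {min_obs}"
                )
            if pair[a].nunique() < 2 or pair[b].nunique() < 2:
                raise DegenerateInputError(
                    f"pair ({a}, {b}): constant variable, correlation undefined"
                )
            result = stats.pearsonr(pair[a], pair[b])
            r.loc[a, b] = r.loc[b, a] = float(result.statistic)
            p.loc[a, b] = p.loc[b, a] = float(result.pvalue)
    return r, p


def fit_linear_model(response, predictors: pd.DataFrame) -> RegressionReport:
    """Ordinary least squares with standardized betas and VIFs.

    Standardized beta is ``B * sd(x) / sd(y)``; VIF_j is ``1 / (1 - R_j**2)``
    from regressing predictor j on the remaining predictors (1.0 for a
    single predictor).  Rows with missing values are dropped listwise.
    """
    predictors = pd.DataFrame(predictors).astype(float)
    y = pd.Series(np.asarray(response, dtype=float), index=predictors.index, name="y")
    frame = pd.concat([y, predictors], axis=1).dropna()
    y, X = frame["y"], frame[predictors.columns]
    n, n_predictors = X.shape
    if n <= n_predictors + 1:
        raise ParameterError(f"need n > p + 1 observations, got n={n}, p={n_predictors}")
    for column in X.columns:
        if X[column].nunique() < 2:
            raise DegenerateInputError(f"predictor '{column}' is constant")
    design = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
        raise SingularDesignError("perfectly collinear predictors")
    fit = sm.OLS(y, design).fit()
    sd_y = y.std(ddof=1)
    rows = {}
    for j, column in enumerate(X.columns):
        b = float(fit.params[column])
        rows[column] = {
            "B": b,
            "beta": b * float(X[column].std(ddof=1)) / float(sd_y),
            "t": float(fit.tvalues[column]),
            "p_value": float(fit.pvalues[column]),
            "vif": (1.0 if n_predictors == 1
                    else float(variance_inflation_factor(design.to_numpy(), j + 1))),
        }
    return RegressionReport(
        table=pd.DataFrame.from_dict(rows, orient="index"),
        intercept=float(fit.params["const"]),
        r_squared=float(fit.rsquared),
        n=int(n),
    )


def holm_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Holm step-down adjusted p values (opt-in; nothing applies it by default)."""
    return multipletests(np.asarray(p_values, dtype=float), method="holm")[1]
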