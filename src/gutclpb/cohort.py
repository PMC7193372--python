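"""Cohort-level statistics for case-control microbiome studies.

Group comparisons dispatch the test from the data: chi-square for
categorical variables; for continuous variables, Shapiro-Wilk normality
per group at alpha = 0.05 decides between a t test (Student or Welch,
per median-centered Levene) and the Mann-Whitney U test.  Group
summaries follow the usual reporting rule — mean (SD) when the
parametric branch was taken, median [IQR] otherwise.

Associations: Spearman rank correlation, covariate-adjusted partial
Spearman (rank-transform everything, residualise the ranked variables
on the ranked covariates by least squares, correlate the residuals),
ordinary least squares with optional standardized coefficients, and
Benjamini-Hochberg FDR adjustment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.api import OLS
from statsmodels.stats.multitest import multipletests

ALPHA_NORMALITY = 0.05
ALPHA_VARIANCE = 0.05


@dataclass(frozen=True)
class GroupComparison:
    variable: str
    test_name: str  # chi2 | t | welch_t | mann_whitney
    statistic: float
    p: float
    group_summaries: Dict[str, str] = field(default_factory=dict)


@dataclass(frozen=True)
class AssociationResult:
    x: str
    y: str
    covariates: Tuple[str, ...]
    r: float
    p: float
    n: int
    method: str  # spearman | partial_spearman | ols_beta

    def __post_init__(self) -> None:
        if self.method in ("spearman", "partial_spearman") and abs(self.r) > 1 + 1e-12:
            raise ValueError("correlation outside [-1, 1]")


def _summaries(groups: Dict[str, np.ndarray], parametric: bool) -> Dict[str, str]:
    out = {}
    for name, vals in groups.items():
        if parametric:
            out[name] = f"{np.mean(vals):.3g} ({np.std(vals, ddof=1):.3g})"
        else:
            q1, med, q3 = np.percentile(vals, [25, 50, 75])
            out[name] = f"{med:.3g} [{q3 - q1:.3g}]"
    return out


def compare_groups(
    values: Sequence,
    group_labels: Sequence,
    variable_kind: str = "continuous",
    variable_name: str = "variable",
) -> GroupComparison:
    """Two-group comparison with data-driven test dispatch.

    Categorical variables use the chi-square test on the contingency
    table (no continuity correction).  Continuous variables require
    exactly two groups: both groups Shapiro-normal at alpha = 0.05 ->
    Student or Welch t (per Levene), otherwise Mann-Whitney U
    (two-sided).  Groups too small for normality testing (n < 3) fall
    back to Mann-Whitney with a warning.
    """
    values = np.asarray(values)
    labels = np.asarray(group_labels)
    if variable_kind == "categorical":
        table = pd.crosstab(labels, values)
        stat, p, _, _ = stats.chi2_contingency(table.to_numpy(), correction=False)
        summaries = {
            str(g): ", ".join(f"{v}: {c}" for v, c in table.loc[g].items()) for g in table.index
        }
        return GroupComparison(variable_name, "chi2", float(stat), float(p), summaries)
    if variable_kind != "continuous":
        raise ValueError(f"unknown variable_kind {variable_kind!r}")

    group_names = sorted(map(str, set(labels)))
    if len(group_names) != 2:
        raise ValueError("continuous comparison requires exactly 2 groups")
    groups = {g: values[labels.astype(str) == g].astype(float) for g in group_names}
    a, b = groups[group_names[0]], groups[group_names[1]]

    if min(len(a), len(b)) < 3:
        warnings.warn("group too small for normality testing; using Mann-Whitney", stacklevel=2)
        normal = False
    else:
        normal = all(stats.shapiro(g).pvalue >= ALPHA_NORMALITY for g in (a, b))

    if normal:
        equal_var = stats.levene(a, b, center="median").pvalue >= ALPHA_VARIANCE
        res = stats.ttest_ind(a, b, equal_var=equal_var)
        name = "t" if equal_var else "welch_t"
        return GroupComparison(
            variable_name, name, float(res.statistic), float(res.pvalue), _summaries(groups, True)
        )
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return GroupComparison(
        variable_name, "mann_whitney", float(res.statistic), float(res.pvalue),
        _summaries(groups, False),
    )


def spearman(
    x: Sequence[float],
    y: Sequence[float],
    x_name: str = "x",
    y_name: str = "y",
) -> AssociationResult:
    """Spearman rank correlation with average ranks and t-based p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need paired samples with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: Spearman correlation undefined")
    r, p = stats.spearmanr(x, y)
    return AssociationResult(x_name, y_name, (), float(r), float(p), len(x), "spearman")


def partial_spearman(
    x: Sequence[float],
    y: Sequence[float],
    covariates: Optional[pd.DataFrame] = None,
    x_name: str = "x",
    y_name: str = "y",
) -> AssociationResult:
    """Rank-based partial correlation adjusting for covariates.

    x, y and every covariate are rank-transformed (average ranks); the
    ranked x and y are residualised on the ranked covariates (plus an
    intercept) by least squares, and the residuals are Pearson-
    correlated.  The p-value uses n - 2 - #covariates degrees of
    freedom.  With no covariates this reduces exactly to
    :func:`spearman`.
    """
    if covariates is None or (hasattr(covariates, "shape") and covariates.shape[1] == 0):
        return spearman(x, y, x_name, y_name)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    cov = pd.DataFrame(covariates)
    n, k = len(x), cov.shape[1]
    if n <= k + 3:
        raise ValueError("need n > #covariates + 3")

    design = np.column_stack(
        [np.ones(n)] + [stats.rankdata(cov[c].to_numpy(dtype=float)) for c in cov.columns]
    )
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError(f"collinear covariates among {list(cov.columns)}")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    res_x = rx - design @ np.linalg.lstsq(design, rx, rcond=None)[0]
    res_y = ry - design @ np.linalg.lstsq(design, ry, rcond=None)[0]
    denom = np.sqrt((res_x @ res_x) * (res_y @ res_y))
    if denom == 0:
        raise ValueError("residuals are constant; partial correlation undefined")
    r = float(np.clip((res_x @ res_y) / denom, -1.0, 1.0))
    df = n - 2 - k
    tstat = r * np.sqrt(df / max(1.0 - r**2, 1e-300))
    p = float(2.0 * stats.t.sf(abs(tstat), df=df))
    return AssociationResult(
        x_name, y_name, tuple(map(str, cov.columns)), r, p, n, "partial_spearman"
    )


def linear_model(
    y: Sequence[float],
    design: pd.DataFrame,
    y_name: str = "y",
    standardize: bool = False,
) -> List[AssociationResult]:
    """OLS of y on named predictors; one coefficient per column.

    An intercept is added unless a constant column is already present.
    With ``standardize=True`` the response and every non-constant
    predictor are z-scored first, so coefficients are standardized
    betas.  Rank-deficient designs are rejected.
    """
    y = np.asarray(y, dtype=float)
    X = pd.DataFrame(design).astype(float).copy()
    if not (X.nunique() == 1).any():
        X.insert(0, "intercept", 1.0)
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("rank-deficient design matrix")
    if standardize:
        y = (y - y.mean()) / y.std(ddof=1)
        for col in X.columns:
            if X[col].nunique() > 1:
                X[col] = (X[col] - X[col].mean()) / X[col].std(ddof=1)
    fit = OLS(y, X).fit()
    covs = tuple(X.columns)
    return [
        AssociationResult(
            x=str(col),
            y=y_name,
            covariates=tuple(c for c in covs if c != col),
            r=float(fit.params[col]),
            p=float(fit.pvalues[col]),
            n=len(y),
            method="ols_beta",
        )
        for col in X.columns
    ]


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment (q-values)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
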