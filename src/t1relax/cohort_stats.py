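"""Longitudinal cohort statistics for two-timepoint MS studies.

Implements the analysis plan of a paired-design atrophy study: percent
change between timepoints, paired Student's t-tests on compartment
volumes and ROI T1 values, Spearman rank correlation of compartment
change against whole-brain change (PBVC), and univariate / multivariate
ordinary least-squares regression of PBVC on clinical covariates.

Sign convention: PBVC and all percent changes are negative for volume
loss. Tests are two-sided; no multiple-testing correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm

__all__ = [
    "PairedTestResult",
    "RegressionTerm",
    "RegressionResult",
    "percent_change",
    "paired_t_test",
    "spearman_rho",
    "regress_pbvc",
    "paired_volume_report",
]


@dataclass(frozen=True)
class PairedTestResult:
    """Paired t-test summary. ``degenerate`` is set when the differences
    have zero variance (t undefined); the t statistic and p-value are
    then None rather than +/-inf."""

    n: int
    mean_diff: float
    t_statistic: float | None
    p_value: float | None
    direction: str  # "increase", "decrease" or "none"
    degenerate: bool = False


@dataclass(frozen=True)
class RegressionTerm:
    name: str
    coefficient: float
    ci_low: float
    ci_high: float
    p_value: float


@dataclass(frozen=True)
class RegressionResult:
    """OLS fit summary: per-term coefficient with 95% CI and p, plus R²."""

    terms: tuple[RegressionTerm, ...]
    r_squared: float
    n: int
    mode: str  # "univariate" or "multivariate"


def percent_change(baseline: float, followup: float) -> float:
    """100 * (followup - baseline) / baseline; negative = decrease."""
    b = np.asarray(baseline, dtype=float)
    if np.any(b <= 0):
        raise ValueError("baseline must be > 0")
    out = 100.0 * (np.asarray(followup, dtype=float) - b) / b
    return float(out) if np.isscalar(baseline) else out


def paired_t_test(baseline, followup) -> PairedTestResult:
    """Classic paired Student's t on followup - baseline differences."""
    b = np.asarray(baseline, dtype=float)
    f = np.asarray(followup, dtype=float)
    if b.shape != f.shape or b.ndim != 1:
        raise ValueError("baseline and followup must be equal-length 1-D vectors")
    n = b.size
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = f - b
    mean_diff = float(d.mean())
    direction = "increase" if mean_diff > 0 else "decrease" if mean_diff < 0 else "none"
    if np.allclose(d.std(ddof=1), 0.0):
        return PairedTestResult(n, mean_diff, None, None, direction, degenerate=True)
    t, p = st.ttest_rel(f, b)
    return PairedTestResult(n, mean_diff, float(t), float(p), direction)


def spearman_rho(x, y) -> tuple[float, float | None]:
    """Spearman rank correlation with average ranks for ties.

    Returns (rho, two-sided p). A constant input vector makes rho
    undefined: returns (nan, None).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        return float("nan"), None
    res = st.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def _design_matrix(records: pd.DataFrame, terms: list[str]) -> pd.DataFrame:
    """Numeric design columns; a categorical 'race' column is encoded as
    indicator contrasts against the largest category."""
    cols = {}
    for t in terms:
        if t not in records.columns:
            raise ValueError(f"covariate {t!r} missing from records")
        col = records[t]
        if col.isna().any():
            raise ValueError(f"covariate {t!r} has missing values")
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            reference = col.value_counts().idxmax()
            for level in sorted(set(col) - {reference}):
                cols[f"{t}[{level}]"] = (col == level).astype(float)
        else:
            cols[t] = col.astype(float)
    return pd.DataFrame(cols, index=records.index)


def _fit_ols(y: np.ndarray, X: pd.DataFrame, mode: str) -> RegressionResult:
    design = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
        raise ValueError("rank-deficient design: collinear covariates")
    fit = sm.OLS(y, design).fit()
    ci = fit.conf_int(alpha=0.05)
    terms = tuple(
        RegressionTerm(
            name=name,
            coefficient=float(fit.params[name]),
            ci_low=float(ci.loc[name, 0]),
            ci_high=float(ci.loc[name, 1]),
            p_value=float(fit.pvalues[name]),
        )
        for name in X.columns
    )
    return RegressionResult(terms=terms, r_squared=float(fit.rsquared),
                            n=int(fit.nobs), mode=mode)


def regress_pbvc(
    records: pd.DataFrame,
    terms: list[str],
    multivariate: bool = False,
    outcome: str = "pbvc",
) -> list[RegressionResult]:
    """OLS regression of PBVC (negative = loss) on clinical covariates.

    Univariate mode fits each term separately against the outcome;
    multivariate mode fits all terms jointly. Always includes an
    intercept; 95% confidence intervals throughout.
    """
    if not terms:
        raise ValueError("at least one covariate term is required")
    if outcome not in records.columns:
        raise ValueError(f"outcome column {outcome!r} missing")
    y = records[outcome].to_numpy(dtype=float)
    if multivariate:
        X = _design_matrix(records, list(terms))
        if len(records) <= X.shape[1] + 1:
            raise ValueError("too few subjects for the number of terms")
        return [_fit_ols(y, X, "multivariate")]
    out = []
    for t in terms:
        X = _design_matrix(records, [t])
        if len(records) <= X.shape[1] + 1:
            raise ValueError("too few subjects for the number of terms")
        out.append(_fit_ols(y, X, "univariate"))
    return out


def paired_volume_report(records: pd.DataFrame,
                         compartments: list[str]) -> pd.DataFrame:
    """Paired t-test per compartment on `<name>_baseline` vs
    `<name>_followup` columns, plus the mean percent change.

    Returns a tidy DataFrame (one row per compartment) suitable for CSV
    output; percent change is negative for volume loss.
    """
    rows = []
    for name in compartments:
        b = records[f"{name}_baseline"].to_numpy(dtype=float)
        f = records[f"{name}_followup"].to_numpy(dtype=float)
        res = paired_t_test(b, f)
        rows.append({
            "compartment": name,
            "n": res.n,
            "mean_baseline": b.mean(),
            "mean_followup": f.mean(),
            "mean_pct_change": float(np.mean(percent_change(b, f))),
            "mean_diff": res.mean_diff,
            "t_statistic": res.t_statistic,
            "p_value": res.p_value,
            "degenerate": res.degenerate,
        })
    return pd.DataFrame(rows)
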