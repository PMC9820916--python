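"""Classical statistics: descriptives, intra-rater ICC, Kendall τ, PCA.

The ICC is the two-way mixed-effects, absolute-agreement, single-measure
coefficient (ICC(A,1) in McGraw & Wong's nomenclature, the recommended
form for intra-rater reliability with a fixed rater), computed from the
two-way ANOVA mean squares with F-based 95% confidence limits.  Kendall's
τ-b with tie correction is used for pairwise association because the
measurement tables are non-normal and contain ties after rounding.  PCA
is performed on the correlation matrix of standardized variables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


# ------------------------------------------------------------ descriptives
def describe(table: pd.DataFrame) -> pd.DataFrame:
    """Per-variable mean, SD, median, quartiles, min, max (one row each)."""
    if len(table) < 2:
        raise ValueError("need at least 2 rows to describe")
    num = table.select_dtypes("number")
    out = pd.DataFrame({
        "mean": num.mean(),
        "sd": num.std(ddof=1),
        "median": num.median(),
        "q1": num.quantile(0.25),
        "q3": num.quantile(0.75),
        "min": num.min(),
        "max": num.max(),
    })
    out.index.name = "variable"
    return out


# ------------------------------------------------------------- Kendall tau
def kendall_tau(x, y) -> tuple[float, float]:
    """Kendall τ-b with tie correction and its asymptotic p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Kendall tau undefined for a constant vector")
    res = sps.kendalltau(x, y, variant="b", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


@dataclass
class CorrelationMatrix:
    """Pairwise τ-b matrix with p-values and an α=0.05 significance mask."""

    variables: tuple[str, ...]
    tau: pd.DataFrame
    p: pd.DataFrame
    significant: pd.DataFrame  # True where p < alpha
    alpha: float = 0.05


def kendall_matrix(table: pd.DataFrame, alpha: float = 0.05,
                   fdr: bool = False) -> CorrelationMatrix:
    """Pairwise Kendall τ-b over the numeric columns of ``table``.

    With ``fdr`` the off-diagonal p-values are Benjamini–Hochberg adjusted
    before thresholding (off by default: the study used per-pair α=0.05).
    """
    num = table.select_dtypes("number")
    cols = tuple(num.columns)
    k = len(cols)
    tau = np.eye(k)
    p = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            t, pv = kendall_tau(num.iloc[:, i], num.iloc[:, j])
            tau[i, j] = tau[j, i] = t
            p[i, j] = p[j, i] = pv
    if fdr:
        iu = np.triu_indices(k, 1)
        adj = _benjamini_hochberg(p[iu])
        p[iu] = adj
        p[(iu[1], iu[0])] = adj
    as_df = lambda m: pd.DataFrame(m, index=cols, columns=cols)
    return CorrelationMatrix(variables=cols, tau=as_df(tau), p=as_df(p),
                             significant=as_df(p < alpha), alpha=alpha)


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    m = p.size
    order = np.argsort(p)
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out


# --------------------------------------------------------------------- ICC
@dataclass
class ICCResult:
    """ICC(A,1) point estimate with 95% CI and variance components."""

    estimate: float
    ci_low: float
    ci_high: float
    var_subjects: float
    var_sessions: float
    var_error: float
    n_subjects: int
    k_sessions: int
    p_value: float


def icc_intra(session1, session2, alpha: float = 0.05) -> ICCResult:
    """Two-way mixed, absolute-agreement, single-measure ICC for two sessions.

    Computed from the two-way ANOVA mean squares of the n×2 table; the
    confidence interval uses the McGraw–Wong F-distribution method.
    Requires n ≥ 5 paired observations (the CI is unreliable below that).
    """
    x = np.asarray(session1, dtype=float)
    y = np.asarray(session2, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("sessions must be equal-length 1D vectors")
    n = x.size
    if n < 5:
        raise ValueError("ICC requires at least 5 paired measurements")
    data = np.column_stack([x, y])
    k = 2

    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols

    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))

    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom <= 0:
        raise ValueError("degenerate data: zero total variance")
    icc = min((msr - mse) / denom, 1.0)  # guard float overshoot at perfect agreement

    # McGraw & Wong CI for ICC(A,1)
    if mse <= 0 and msr > 0:  # perfect agreement
        lo, hi, pval = 1.0, 1.0, 0.0
    else:
        a = k * icc / (n * (1.0 - icc)) if icc < 1 else np.inf
        b = 1.0 + k * icc * (n - 1.0) / (n * (1.0 - icc)) if icc < 1 else np.inf
        v = ((a * msc + b * mse) ** 2 /
             ((a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))))
        f_l = sps.f.ppf(1 - alpha / 2, n - 1, v)
        f_u = sps.f.ppf(1 - alpha / 2, v, n - 1)
        lo = n * (msr - f_l * mse) / (
            f_l * (k * msc + (k * n - k - n) * mse) + n * msr)
        hi = n * (f_u * msr - mse) / (
            k * msc + (k * n - k - n) * mse + n * f_u * msr)
        pval = float(sps.f.sf(msr / mse, n - 1, (n - 1) * (k - 1)))

    return ICCResult(
        estimate=float(icc), ci_low=float(lo), ci_high=float(hi),
        var_subjects=float(max((msr - mse) / k, 0.0)),
        var_sessions=float(max((msc - mse) / n, 0.0)),
        var_error=float(mse), n_subjects=n, k_sessions=k, p_value=float(pval))


def icc_consistency(session1, session2) -> float:
    """Two-way mixed, consistency, single-measure ICC(C,1) (for comparison)."""
    x = np.asarray(session1, dtype=float)
    y = np.asarray(session2, dtype=float)
    n, k = x.size, 2
    data = np.column_stack([x, y])
    grand = data.mean()
    ss_rows = k * np.sum((data.mean(axis=1) - grand) ** 2)
    ss_cols = n * np.sum((data.mean(axis=0) - grand) ** 2)
    ss_err = np.sum((data - grand) ** 2) - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return float((msr - mse) / (msr + (k - 1) * mse))


def icc_table(table1: pd.DataFrame, table2: pd.DataFrame) -> pd.DataFrame:
    """Per-measure ICC between two session tables (shared columns)."""
    rows = []
    for col in table1.columns:
        if col not in table2.columns:
            continue
        a, b = table1[col].to_numpy(), table2[col].to_numpy()
        if np.isnan(a).any() or np.isnan(b).any():
            continue
        try:
            r = icc_intra(a, b)
        except ValueError:  # degenerate column (e.g. constant covariate)
            continue
        rows.append({"variable": col, "icc": r.estimate, "ci_low": r.ci_low,
                     "ci_high": r.ci_high, "p_value": r.p_value})
    return pd.DataFrame(rows).set_index("variable")


# --------------------------------------------------------------------- PCA
@dataclass
class PCAResult:
    """Correlation-matrix PCA: eigenvalues, explained %, variable map."""

    eigenvalues: np.ndarray
    pct_variance: np.ndarray
    coords: pd.DataFrame   # variables × dims, loadings scaled by sqrt(eigval)
    cos2: pd.DataFrame     # squared coords: quality of representation


def pca(table: pd.DataFrame) -> PCAResult:
    """PCA of the standardized table (eigendecomposition of the correlation
    matrix).  Fails on constant columns or missing values."""
    num = table.select_dtypes("number")
    if len(num) < 3 or num.shape[1] < 2:
        raise ValueError("PCA needs at least 3 rows and 2 numeric columns")
    if num.isna().any().any():
        raise ValueError("PCA input contains missing values")
    sd = num.std(ddof=1)
    if (sd == 0).any():
        bad = list(sd.index[sd == 0])
        raise ValueError(f"constant column(s): {bad}")
    corr = np.corrcoef(num.to_numpy(), rowvar=False)
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    # deterministic sign: largest-|loading| entry of each axis positive
    for j in range(evecs.shape[1]):
        i = np.argmax(np.abs(evecs[:, j]))
        if evecs[i, j] < 0:
            evecs[:, j] = -evecs[:, j]
    coords = evecs * np.sqrt(evals)
    dims = [f"dim{j + 1}" for j in range(len(evals))]
    coords_df = pd.DataFrame(coords, index=num.columns, columns=dims)
    return PCAResult(
        eigenvalues=evals,
        pct_variance=100.0 * evals / evals.sum(),
        coords=coords_df,
        cos2=coords_df ** 2,
    )


def shapiro_flags(table: pd.DataFrame, alpha: float = 0.05) -> pd.Series:
    """Shapiro–Wilk normality flag per variable (True = normality rejected).

    Delegated to scipy; reported only as a flag motivating quartiles and
    rank-based correlation in the descriptive outputs.
    """
    num = table.select_dtypes("number")
    return pd.Series(
        {c: bool(sps.shapiro(num[c]).pvalue < alpha) for c in num.columns},
        name="non_normal")
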