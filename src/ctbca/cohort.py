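"""Cohort stratification and group-comparison statistics.

Implements the statistical toolbox used to characterise a dichotomised
cohort: median splits of a biomarker (< median = low, >= median = high),
splitting by a survival horizon, and the group tests — D'Agostino–Pearson
K^2 normality test, pooled/Welch two-sample t-test, Mann–Whitney U (exact
by enumeration for small untied samples, otherwise normal approximation
with tie and continuity corrections) and the two-sided Fisher exact test
(sum of all hypergeometric tables no more probable than the observed one).

The test statistics themselves are computed in-package; only tail
probabilities of the chi-square, t, normal and hypergeometric distributions
come from scipy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateInputError, SampleSizeError
from .indices import INDEX_NAMES

__all__ = [
    "TestResult",
    "GroupSplit",
    "CONTINUOUS_COVARIATES",
    "CATEGORICAL_COVARIATES",
    "median_split",
    "split_by_survival_horizon",
    "dagostino_pearson",
    "t_test_two_sided",
    "mann_whitney_u",
    "fisher_exact_2x2",
    "compare_index_expression",
    "characterize_groups",
]

#: continuous covariates reported as median (IQR) in cohort tables
CONTINUOUS_COVARIATES = ("age", "bmi", "gap_index", "fvc_pct", "dlco")
#: yes/no covariates reported as counts (column -> positive level)
CATEGORICAL_COVARIATES = {
    "sex": "male",
    "smoking": 1,
    "fibrotic": 1,
    "cardiovascular": 1,
    "diabetes": 1,
}


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    test_name: str
    n_per_group: tuple[int, ...]


@dataclass(frozen=True)
class GroupSplit:
    """A median split: label is ``low`` iff value < cutoff, else ``high``."""

    index_name: str
    cutoff: float
    labels: np.ndarray  # array of "low"/"high"

    @property
    def n_low(self) -> int:
        return int(np.sum(self.labels == "low"))

    @property
    def n_high(self) -> int:
        return int(np.sum(self.labels == "high"))


def median_split(values, index_name: str = "") -> GroupSplit:
    """Dichotomise at the sample median; ties at the cutoff go to ``high``.

    The cutoff is the middle order statistic for odd n and the mean of the
    two middle order statistics for even n.
    """
    values = np.asarray(values, dtype=np.float64)
    if values.size < 2:
        raise DegenerateInputError("median split needs at least two subjects")
    cutoff = float(np.median(values))
    labels = np.where(values >= cutoff, "high", "low")
    return GroupSplit(index_name=index_name, cutoff=cutoff, labels=labels)


def split_by_survival_horizon(
    cohort: pd.DataFrame, horizon: float
) -> tuple[pd.DataFrame, pd.DataFrame, int]:
    """Split subjects into died-before-horizon vs survived-past-horizon.

    Subjects censored before the horizon have unknown status and are
    excluded; their count is returned as the third element.
    """
    if horizon <= 0:
        raise DegenerateInputError("horizon must be positive")
    time = cohort["time"].to_numpy(dtype=float)
    event = cohort["event"].to_numpy(dtype=int)
    died = (time < horizon) & (event == 1)
    survived = time >= horizon
    excluded = (time < horizon) & (event == 0)
    return cohort[died], cohort[survived], int(excluded.sum())


def dagostino_pearson(x) -> TestResult:
    """D'Agostino–Pearson omnibus normality test (K^2).

    Sums the squared normalising transforms of sample skewness and
    kurtosis; K^2 is referred to chi-square with 2 df.  Requires n >= 20
    (the kurtosis transform is unreliable below that).
    """
    x = np.asarray(x, dtype=np.float64)
    n = x.size
    if n < 20:
        raise SampleSizeError(f"D'Agostino–Pearson requires n >= 20, got {n}")
    xc = x - x.mean()
    m2 = np.mean(xc**2)
    if m2 == 0:
        raise DegenerateInputError("zero variance sample")
    m3 = np.mean(xc**3)
    m4 = np.mean(xc**4)
    b1 = m3 / m2**1.5
    b2 = m4 / m2**2

    # skewness transform (D'Agostino 1970)
    y = b1 * math.sqrt((n + 1) * (n + 3) / (6.0 * (n - 2)))
    beta2 = 3.0 * (n**2 + 27 * n - 70) * (n + 1) * (n + 3) / ((n - 2.0) * (n + 5) * (n + 7) * (n + 9))
    w2 = -1.0 + math.sqrt(2.0 * (beta2 - 1.0))
    delta = 1.0 / math.sqrt(0.5 * math.log(w2))
    alpha = math.sqrt(2.0 / (w2 - 1.0))
    z_skew = delta * math.log(y / alpha + math.sqrt((y / alpha) ** 2 + 1.0))

    # kurtosis transform (Anscombe & Glynn 1983)
    e_b2 = 3.0 * (n - 1) / (n + 1)
    var_b2 = 24.0 * n * (n - 2) * (n - 3) / ((n + 1) ** 2 * (n + 3) * (n + 5))
    xk = (b2 - e_b2) / math.sqrt(var_b2)
    sqrt_beta1 = (
        6.0 * (n**2 - 5 * n + 2) / ((n + 7.0) * (n + 9))
        * math.sqrt(6.0 * (n + 3) * (n + 5) / (n * (n - 2.0) * (n - 3)))
    )
    a = 6.0 + 8.0 / sqrt_beta1 * (2.0 / sqrt_beta1 + math.sqrt(1.0 + 4.0 / sqrt_beta1**2))
    term = (1.0 - 2.0 / a) / (1.0 + xk * math.sqrt(2.0 / (a - 4.0)))
    z_kurt = ((1.0 - 2.0 / (9.0 * a)) - np.sign(term) * abs(term) ** (1.0 / 3.0)) / math.sqrt(
        2.0 / (9.0 * a)
    )

    k2 = z_skew**2 + z_kurt**2
    p = float(stats.chi2.sf(k2, df=2))
    return TestResult(statistic=float(k2), p_value=max(p, np.finfo(float).tiny),
                      test_name="dagostino_pearson", n_per_group=(n,))


def t_test_two_sided(x, y, equal_var: bool = True) -> TestResult:
    """Two-sample two-sided t-test, pooled variance by default (Welch optional)."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n1, n2 = x.size, y.size
    if n1 < 2 or n2 < 2:
        raise SampleSizeError("t-test requires at least two observations per group")
    v1 = x.var(ddof=1)
    v2 = y.var(ddof=1)
    diff = x.mean() - y.mean()
    if equal_var:
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        if sp2 == 0:
            if diff == 0:
                return TestResult(0.0, 1.0, "t_test_pooled", (n1, n2))
            raise DegenerateInputError("zero pooled variance with unequal means")
        t = diff / math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
        df = n1 + n2 - 2
        name = "t_test_pooled"
    else:
        if v1 == 0 and v2 == 0:
            if diff == 0:
                return TestResult(0.0, 1.0, "t_test_welch", (n1, n2))
            raise DegenerateInputError("zero variance in both groups with unequal means")
        se2 = v1 / n1 + v2 / n2
        t = diff / math.sqrt(se2)
        df = se2**2 / (v1**2 / (n1**2 * (n1 - 1)) + v2**2 / (n2**2 * (n2 - 1)))
        name = "t_test_welch"
    p = float(2.0 * stats.t.sf(abs(t), df=df))
    return TestResult(statistic=float(t), p_value=min(max(p, np.finfo(float).tiny), 1.0),
                      test_name=name, n_per_group=(n1, n2))


def _u_counts(n1: int, n2: int) -> np.ndarray:
    """Exact null distribution of the Mann–Whitney U statistic.

    counts[u] = number of arrangements of ranks giving U = u; recurrence
    c(n1, n2, u) = c(n1-1, n2, u-n2) + c(n1, n2-1, u).
    """
    max_u = n1 * n2
    # Gaussian binomial [n1+n2, n1]_q built as prod_{i=1..n1} (1-q^{n2+i})/(1-q^i);
    # all intermediate degrees stay within max_u so truncation is exact.
    p = np.zeros(max_u + 1, dtype=np.float64)
    p[0] = 1.0
    for i in range(1, n1 + 1):
        shift = n2 + i
        if shift <= max_u:
            p[shift:] -= p[: max_u + 1 - shift].copy()
        for u in range(i, max_u + 1):  # divide by (1 - q^i)
            p[u] += p[u - i]
    return p


def mann_whitney_u(x, y, exact_limit: int = 400) -> TestResult:
    """Two-sided Mann–Whitney U test.

    Exact p by enumerating the null U distribution when there are no ties
    and n1*n2 <= ``exact_limit``; otherwise a normal approximation with
    midrank tie correction and 0.5 continuity correction.  The reported
    statistic is U for the first sample; the two-sided p-value is twice the
    smaller tail, capped at 1.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n1, n2 = x.size, y.size
    if n1 < 1 or n2 < 1:
        raise SampleSizeError("both samples must be nonempty")
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)  # midranks for ties
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    n = n1 + n2
    _, tie_counts = np.unique(combined, return_counts=True)
    has_ties = np.any(tie_counts > 1)

    if not has_ties and n1 * n2 <= exact_limit:
        counts = _u_counts(n1, n2)
        total = counts.sum()
        u_int = int(round(u1))
        p_low = counts[: u_int + 1].sum() / total
        p_high = counts[u_int:].sum() / total
        p = min(1.0, 2.0 * min(p_low, p_high))
        name = "mann_whitney_exact"
    else:
        mu = n1 * n2 / 2.0
        tie_term = np.sum(tie_counts**3 - tie_counts) / (n * (n - 1.0))
        sigma2 = n1 * n2 / 12.0 * ((n + 1.0) - tie_term)
        if sigma2 <= 0:
            return TestResult(float(u1), 1.0, "mann_whitney_normal", (n1, n2))
        z = (u1 - mu - 0.5 * np.sign(u1 - mu)) / math.sqrt(sigma2)
        p = min(1.0, 2.0 * float(stats.norm.sf(abs(z))))
        name = "mann_whitney_normal"
    return TestResult(statistic=float(u1), p_value=max(p, np.finfo(float).tiny),
                      test_name=name, n_per_group=(n1, n2))


def fisher_exact_2x2(table) -> TestResult:
    """Two-sided Fisher exact test for a 2x2 contingency table.

    Sums hypergeometric probabilities of every table with the observed
    margins whose probability does not exceed the observed table's (within
    relative tolerance 1e-7).
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or np.any(t < 0):
        raise DegenerateInputError("table must be 2x2 with nonnegative counts")
    a, b = t[0]
    c, d = t[1]
    n = a + b + c + d
    r1, c1 = a + b, a + c
    if r1 == 0 or r1 == n or c1 == 0 or c1 == n:
        raise DegenerateInputError("Fisher exact test requires both margins positive")
    support = np.arange(max(0, r1 + c1 - n), min(r1, c1) + 1)
    pmf = stats.hypergeom.pmf(support, n, c1, r1)
    p_obs = stats.hypergeom.pmf(a, n, c1, r1)
    p = float(pmf[pmf <= p_obs * (1.0 + 1e-7)].sum())
    odds = (a * d) / (b * c) if b * c > 0 else math.inf
    return TestResult(statistic=float(odds), p_value=min(max(p, np.finfo(float).tiny), 1.0),
                      test_name="fisher_exact", n_per_group=(int(r1), int(c + d)))


def _route_two_sample(x, y, alpha: float = 0.05, equal_var: bool = True) -> TestResult:
    """t-test if both samples pass the normality test at ``alpha``, else
    Mann–Whitney U.  Samples too small for the normality test route to
    Mann–Whitney."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    try:
        normal = (
            dagostino_pearson(x).p_value > alpha
            and dagostino_pearson(y).p_value > alpha
        )
    except (SampleSizeError, DegenerateInputError):
        normal = False
    if normal:
        return t_test_two_sided(x, y, equal_var=equal_var)
    return mann_whitney_u(x, y)


def compare_index_expression(
    cohort: pd.DataFrame, horizon: float = 60.0, alpha: float = 0.05
) -> pd.DataFrame:
    """Compare each body-composition index between subjects who died before
    the horizon and those who survived past it.

    Returns one row per index with group means/SDs, the routed test and its
    p-value.  Censored-before-horizon subjects are excluded.
    """
    short, long_, n_excluded = split_by_survival_horizon(cohort, horizon)
    if len(short) == 0 or len(long_) == 0:
        raise DegenerateInputError("both horizon groups must be nonempty")
    rows = []
    for name in INDEX_NAMES:
        x = short[name].to_numpy(dtype=float)
        y = long_[name].to_numpy(dtype=float)
        res = _route_two_sample(x, y, alpha=alpha)
        rows.append(
            {
                "index": name,
                "mean_short": x.mean(),
                "sd_short": x.std(ddof=1),
                "mean_long": y.mean(),
                "sd_long": y.std(ddof=1),
                "n_short": x.size,
                "n_long": y.size,
                "n_excluded": n_excluded,
                "test": res.test_name,
                "statistic": res.statistic,
                "p_value": res.p_value,
            }
        )
    return pd.DataFrame(rows)


def characterize_groups(
    cohort: pd.DataFrame, split: GroupSplit, alpha: float = 0.05
) -> pd.DataFrame:
    """Describe low/high groups per covariate, with the appropriate test.

    Continuous covariates get median (Q1–Q3) per group and a
    normality-routed two-sample test; yes/no covariates get counts per
    group and a Fisher exact test.  A covariate that is degenerate (e.g.
    constant in both groups) yields a row with the error noted and NaN
    p-value; other rows are unaffected.
    """
    low = cohort[split.labels == "low"]
    high = cohort[split.labels == "high"]
    if len(low) == 0 or len(high) == 0:
        raise DegenerateInputError("both split groups must be nonempty")

    def q(s):
        v = s.dropna().to_numpy(dtype=float)
        return np.median(v), np.percentile(v, 25), np.percentile(v, 75)

    rows = []
    for cov in CONTINUOUS_COVARIATES:
        if cov not in cohort.columns:
            continue
        x = low[cov].dropna().to_numpy(dtype=float)
        y = high[cov].dropna().to_numpy(dtype=float)
        med_l, q1_l, q3_l = q(low[cov])
        med_h, q1_h, q3_h = q(high[cov])
        try:
            res = _route_two_sample(x, y, alpha=alpha)
            test, statistic, p = res.test_name, res.statistic, res.p_value
        except (DegenerateInputError, SampleSizeError) as e:
            test, statistic, p = f"error: {e}", np.nan, np.nan
        rows.append(
            {
                "covariate": cov,
                "kind": "continuous",
                "low_summary": f"{med_l:g} ({q1_l:g}-{q3_l:g})",
                "high_summary": f"{med_h:g} ({q1_h:g}-{q3_h:g})",
                "n_low": x.size,
                "n_high": y.size,
                "test": test,
                "statistic": statistic,
                "p_value": p,
            }
        )
    for cov, pos in CATEGORICAL_COVARIATES.items():
        if cov not in cohort.columns:
            continue
        a = int((low[cov] == pos).sum())
        b = int((high[cov] == pos).sum())
        table = [[a, len(low) - a], [b, len(high) - b]]
        try:
            res = fisher_exact_2x2(table)
            test, statistic, p = res.test_name, res.statistic, res.p_value
        except DegenerateInputError as e:
            test, statistic, p = f"error: {e}", np.nan, np.nan
        rows.append(
            {
                "covariate": cov,
                "kind": "categorical",
                "low_summary": f"{a}/{len(low)}",
                "high_summary": f"{b}/{len(high)}",
                "n_low": len(low),
                "n_high": len(high),
                "test": test,
                "statistic": statistic,
                "p_value": p,
            }
        )
    return pd.DataFrame(rows)
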