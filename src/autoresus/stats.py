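"""Cohort-level inference.

Implements the exact one-tailed Fisher test with Lancaster's mid-P
correction by hypergeometric enumeration, the (A/C)/(B/D) odds ratio,
logistic regression by IRLS with Wald intervals, the coupling regression
with a Wald-Wolfowitz runs test on residual signs, a slope-difference test,
and a two-sided variance F test.  Routine group comparisons (t tests etc.)
are delegated to scipy behind :func:`group_compare`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .core import InsufficientDataError, SeparationError, UndefinedResultError

__all__ = [
    "ContingencyTable",
    "LogisticResult",
    "RegressionResult",
    "odds_ratio",
    "hypergeom_support_pmf",
    "fisher_midp_one_tailed",
    "logistic_fit",
    "logistic_mortality",
    "coupling_regression",
    "runs_test_pvalue",
    "compare_slopes",
    "variance_f_test",
    "group_compare",
]


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 mortality table: a/b = experimental deaths/survivals, c/d =
    control deaths/survivals."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in "abcd":
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 0):
                raise ValueError(f"cell {name} must be a non-negative integer")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_dict(self) -> dict:
        return {"a": self.a, "b": self.b, "c": self.c, "d": self.d}


def odds_ratio(t: ContingencyTable, correction: float = 0.0) -> float:
    """(A/C)/(B/D).  ``correction`` (e.g. 0.5) is added to every cell on
    request; otherwise a zero cell in a denominator position is an error."""
    a, b, c, d = (t.a + correction, t.b + correction,
                  t.c + correction, t.d + correction)
    if c == 0 or d == 0:
        raise UndefinedResultError(
            "odds ratio undefined with a zero denominator cell "
            "(pass correction=0.5 for the Haldane correction)")
    return (a / c) / (b / d)


def hypergeom_support_pmf(t: ContingencyTable) -> tuple[np.ndarray, np.ndarray]:
    """Support and pmf of the experimental-deaths count under the
    fixed-margins hypergeometric null."""
    big_n = t.n
    deaths = t.a + t.c
    row = t.a + t.b
    lo = max(0, row - (big_n - deaths))
    hi = min(row, deaths)
    ks = np.arange(lo, hi + 1)
    pmf = sps.hypergeom.pmf(ks, big_n, deaths, row)
    return ks, pmf


def fisher_midp_one_tailed(t: ContingencyTable,
                           direction: str = "greater") -> float:
    """One-tailed Fisher exact p with Lancaster's mid-P correction.

    ``direction='greater'`` tests for an excess of deaths in the
    experimental group (the default prior hypothesis); the observed cell's
    probability is counted at half weight.
    """
    if direction not in ("greater", "less"):
        raise ValueError("direction must be 'greater' or 'less'")
    ks, pmf = hypergeom_support_pmf(t)
    if t.a not in ks:
        raise ValueError("observed count impossible under the table margins")
    if direction == "greater":
        tail = pmf[ks > t.a].sum()
    else:
        tail = pmf[ks < t.a].sum()
    return float(tail + 0.5 * pmf[ks == t.a].sum())


@dataclass
class LogisticResult:
    covariates: list[str]
    coefficients: dict[str, float]  # log-odds per unit
    std_errors: dict[str, float]
    odds_ratios: dict[str, float]
    conf_int: dict[str, tuple[float, float]]  # Wald 95% on the OR scale
    p_values: dict[str, float]
    n_iter: int
    converged: bool
    n: int


def logistic_fit(x: np.ndarray, y: np.ndarray, names: list[str] | None = None,
                 max_iter: int = 200, tol: float = 1e-10) -> LogisticResult:
    """Maximum-likelihood logistic regression via iteratively reweighted
    least squares; complete separation is flagged, never silently estimated.

    ``x`` excludes the intercept column, which is prepended internally.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[0] == 1 and x.shape[1] > 1 and len(np.asarray(y)) == x.shape[1]:
        x = x.T
    y = np.asarray(y, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    if len(np.unique(y)) < 2:
        raise ValueError("both outcome classes must be present")
    n, p = x.shape
    design = np.column_stack([np.ones(n), x])
    if names is None:
        names = [f"x{i}" for i in range(p)]
    cols = ["intercept"] + list(names)

    beta = np.zeros(p + 1)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = np.clip(design @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        z = eta + (y - mu) / w
        xtw = design.T * w
        try:
            beta_new = np.linalg.solve(xtw @ design, xtw @ z)
        except np.linalg.LinAlgError as exc:
            raise SeparationError(f"singular IRLS system: {exc}") from exc
        if np.max(np.abs(beta_new - beta)) < tol:
            beta = beta_new
            converged = True
            break
        beta = beta_new

    eta = design @ beta
    if np.max(np.abs(beta)) > 25 and np.all((eta > 0) == (y > 0.5)):
        raise SeparationError("complete separation: coefficients diverge")

    mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))
    w = np.clip(mu * (1.0 - mu), 1e-10, None)
    cov = np.linalg.inv((design.T * w) @ design)
    se = np.sqrt(np.diag(cov))
    zcrit = sps.norm.ppf(0.975)
    wald_z = beta / se
    pvals = 2.0 * sps.norm.sf(np.abs(wald_z))

    def _exp(v: float) -> float:
        return math.exp(v) if v < 700 else math.inf

    return LogisticResult(
        covariates=cols,
        coefficients=dict(zip(cols, beta.tolist())),
        std_errors=dict(zip(cols, se.tolist())),
        odds_ratios={c: _exp(b) for c, b in zip(cols, beta)},
        conf_int={c: (_exp(b - zcrit * s), _exp(b + zcrit * s))
                  for c, b, s in zip(cols, beta, se)},
        p_values=dict(zip(cols, pvals.tolist())),
        n_iter=it,
        converged=converged,
        n=n,
    )


def logistic_mortality(cohort, predictor: str,
                       covariates: tuple[str, ...] = ("genotype",)) -> LogisticResult:
    """Mortality (died yes/no) regressed on one baseline characteristic,
    controlling for genotype by default.

    ``cohort`` is a table-like object (DataFrame) with a boolean/0-1
    ``died`` column, the predictor column, and a ``genotype`` column coded
    experimental/control or 0/1.
    """
    y = np.asarray(cohort["died"], dtype=float)
    columns = [np.asarray(cohort[predictor], dtype=float)]
    names = [predictor]
    for cov in covariates:
        col = cohort[cov]
        vals = np.asarray(col)
        if vals.dtype.kind in "OUS":
            vals = (vals == "experimental").astype(float)
        columns.append(np.asarray(vals, dtype=float))
        names.append(cov)
    return logistic_fit(np.column_stack(columns), y, names=names)


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_nonzero_slope: float
    runs_test_p: float
    n: int
    x: np.ndarray = field(repr=False, default=None)
    y: np.ndarray = field(repr=False, default=None)
    residuals: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise ValueError("R^2 outside [0, 1]")
        if not (0.0 < self.runs_test_p <= 1.0):
            raise ValueError("runs test p outside (0, 1]")


def _runs_pmf(n1: int, n2: int) -> dict[int, float]:
    """Exact distribution of the number of runs given n1 and n2 symbols."""
    total = math.comb(n1 + n2, n1)
    pmf: dict[int, float] = {}
    for r in range(2, n1 + n2 + 1):
        if r % 2 == 0:
            k = r // 2
            ways = 2 * math.comb(n1 - 1, k - 1) * math.comb(n2 - 1, k - 1)
        else:
            k = (r - 1) // 2
            ways = (math.comb(n1 - 1, k) * math.comb(n2 - 1, k - 1)
                    + math.comb(n1 - 1, k - 1) * math.comb(n2 - 1, k))
        if ways:
            pmf[r] = ways / total
    return pmf


def runs_test_pvalue(signs: np.ndarray, exact_threshold: int = 20) -> float:
    """Wald-Wolfowitz runs test for too few runs (systematic deviation from
    linearity), P(R <= observed).

    Exact conditional distribution for sequences up to ``exact_threshold``
    long; normal approximation with continuity correction beyond.
    """
    signs = np.asarray(signs)
    signs = signs[signs != 0]
    n1 = int(np.sum(signs > 0))
    n2 = int(np.sum(signs < 0))
    n = n1 + n2
    if n1 == 0 or n2 == 0 or n < 2:
        return 1.0
    r_obs = 1 + int(np.sum(np.diff(np.sign(signs)) != 0))
    if n <= exact_threshold:
        pmf = _runs_pmf(n1, n2)
        return float(min(1.0, sum(p for r, p in pmf.items() if r <= r_obs)))
    mu = 1.0 + 2.0 * n1 * n2 / n
    var = 2.0 * n1 * n2 * (2.0 * n1 * n2 - n) / (n * n * (n - 1.0))
    z = (r_obs - mu + 0.5) / math.sqrt(var)
    return float(min(1.0, max(np.nextafter(0, 1), sps.norm.cdf(z))))


def coupling_regression(tau_f, tau_hr) -> RegressionResult:
    """OLS of breathing recovery latency on heart-rate recovery latency.

    Pairs must be finite (censored/unrecovered bouts excluded upstream).
    Reports slope/intercept, R^2, the t-test p for non-zero slope, and the
    runs-test p on residual signs ordered by the predictor.
    """
    y = np.asarray(tau_f, dtype=float)
    x = np.asarray(tau_hr, dtype=float)
    if x.shape != y.shape:
        raise ValueError("tau_f and tau_HR must be paired")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite; drop censored values first")
    n = x.size
    if n < 3:
        raise InsufficientDataError("need at least 3 paired recoveries")
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx == 0:
        raise UndefinedResultError("predictor has zero variance")
    slope = float(np.sum((x - x.mean()) * (y - y.mean())) / sxx)
    intercept = float(y.mean() - slope * x.mean())
    resid = y - (intercept + slope * x)
    sse = float(np.sum(resid ** 2))
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if sst == 0 else max(0.0, 1.0 - sse / sst)
    if n > 2 and sse > 0:
        se_slope = math.sqrt(sse / (n - 2) / sxx)
        t_stat = slope / se_slope
        p_slope = float(2.0 * sps.t.sf(abs(t_stat), n - 2))
    else:
        p_slope = 0.0 if slope != 0 else 1.0

    order = np.argsort(x, kind="stable")
    resid_scale = math.sqrt(sse / n) if sse > 0 else 0.0
    signs = np.sign(np.where(np.abs(resid[order]) > 1e-12 * max(resid_scale, 1.0),
                             resid[order], 0.0))
    runs_p = runs_test_pvalue(signs)
    return RegressionResult(slope=slope, intercept=intercept, r_squared=min(r2, 1.0),
                            p_nonzero_slope=p_slope, runs_test_p=runs_p, n=n,
                            x=x, y=y, residuals=resid)


def compare_slopes(x1, y1, x2, y2) -> float:
    """Two-sided t test for a difference between two regression slopes using
    the pooled residual variance (df = n1 + n2 - 4)."""
    x1 = np.asarray(x1, dtype=float)
    y1 = np.asarray(y1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    y2 = np.asarray(y2, dtype=float)
    n1, n2 = x1.size, x2.size
    if n1 < 3 or n2 < 3:
        raise InsufficientDataError("need >= 3 points per group")

    def _fit(x, y):
        sxx = float(np.sum((x - x.mean()) ** 2))
        if sxx == 0:
            raise UndefinedResultError("zero predictor variance")
        b = float(np.sum((x - x.mean()) * (y - y.mean())) / sxx)
        resid = y - (y.mean() + b * (x - x.mean()))
        return b, float(np.sum(resid ** 2)), sxx

    b1, sse1, sxx1 = _fit(x1, y1)
    b2, sse2, sxx2 = _fit(x2, y2)
    df = n1 + n2 - 4
    pooled = (sse1 + sse2) / df
    se = math.sqrt(pooled * (1.0 / sxx1 + 1.0 / sxx2))
    if se == 0:
        return 1.0 if b1 == b2 else 0.0
    t_stat = (b1 - b2) / se
    return float(2.0 * sps.t.sf(abs(t_stat), df))


def variance_f_test(x, y) -> float:
    """Two-sided F test on the ratio of two sample variances."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise InsufficientDataError("need >= 2 observations per sample")
    v1, v2 = np.var(x, ddof=1), np.var(y, ddof=1)
    if v1 == 0 or v2 == 0:
        raise UndefinedResultError("degenerate sample with zero variance")
    f_stat = v1 / v2
    df1, df2 = x.size - 1, y.size - 1
    p = 2.0 * min(sps.f.cdf(f_stat, df1, df2), sps.f.sf(f_stat, df1, df2))
    return float(min(1.0, p))


def group_compare(x, y, kind: str = "t") -> tuple[float, float]:
    """Thin facade over routine two-group comparisons."""
    if kind == "t":
        res = sps.ttest_ind(x, y)
    elif kind == "welch":
        res = sps.ttest_ind(x, y, equal_var=False)
    elif kind == "mannwhitney":
        res = sps.mannwhitneyu(x, y, alternative="two-sided")
    else:
        raise ValueError(f"unknown comparison kind {kind!r}")
    return float(res.statistic), float(res.pvalue)
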