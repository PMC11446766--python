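"""Clinical risk-factor statistics for a two-group cohort.

Univariate screening uses the pooled-variance two-sample t-test for
continuous indicators and the Pearson chi-square test (no continuity
correction) for binary ones — the conventions under which every
recomputable statistic of the source cohort's univariate table is
reproduced to the printed precision.  Multivariate analysis is a
maximum-likelihood logistic regression (fit via statsmodels' Newton/IRLS)
reporting beta, SE, the Wald statistic (beta/SE)^2 against chi-square(1),
odds ratios exp(beta) and confidence intervals.

Two CI conventions are provided: ``standard`` exp(beta +/- 1.96 SE) on
the odds-ratio scale, and ``paper_compat`` OR +/- 1.96 SE, which
reproduces the intervals printed in the source multivariate table (its
intervals match the latter arithmetic, not the standard one; neither is
asserted as correct here).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .cohort import CONTINUOUS, OUTCOME, CohortTable

Z_95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class TwoGroupSummary:
    """Per-group summary of one continuous variable."""

    mean1: float
    sd1: float
    n1: int
    mean2: float
    sd2: float
    n2: int

    def __post_init__(self):
        if self.n1 < 2 or self.n2 < 2:
            raise ValueError("each group needs n >= 2")
        if self.sd1 <= 0 or self.sd2 <= 0:
            raise ValueError("standard deviations must be positive")


@dataclass(frozen=True)
class UnivariateResult:
    variable: str
    test: str  # t | chi2
    statistic: float
    df: float
    p_value: float
    significant: bool
    warning: Optional[str] = None


@dataclass(frozen=True)
class LogisticFit:
    terms: tuple[str, ...]  # intercept last
    coefficients: np.ndarray
    standard_errors: np.ndarray
    wald_statistics: np.ndarray
    p_values: np.ndarray
    odds_ratios: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    converged: bool
    iterations: int
    log_likelihood: float

    def table(self) -> pd.DataFrame:
        """Coefficient table in the conventional layout."""
        return pd.DataFrame({
            "term": self.terms,
            "beta": self.coefficients,
            "SE": self.standard_errors,
            "Wald": self.wald_statistics,
            "P": self.p_values,
            "OR": self.odds_ratios,
            "CI_low": self.ci_low,
            "CI_high": self.ci_high,
        })


# ------------------------------------------------------------ univariate

def two_sample_t(s: TwoGroupSummary, alpha: float = 0.05,
                 variable: str = "") -> UnivariateResult:
    """Pooled-variance two-sample t-test from summary statistics."""
    sp2 = (((s.n1 - 1) * s.sd1 ** 2 + (s.n2 - 1) * s.sd2 ** 2)
           / (s.n1 + s.n2 - 2))
    se = np.sqrt(sp2 * (1.0 / s.n1 + 1.0 / s.n2))
    t = (s.mean1 - s.mean2) / se
    df = s.n1 + s.n2 - 2
    p = 2.0 * sps.t.sf(abs(t), df)
    return UnivariateResult(variable=variable, test="t", statistic=float(t),
                            df=float(df), p_value=float(p),
                            significant=bool(p < alpha))


def chi_square_2x2(a: int, b: int, c: int, d: int, alpha: float = 0.05,
                   variable: str = "") -> UnivariateResult:
    """Pearson chi-square on a 2x2 table, no continuity correction.

    Cells are (a, b) = group-1 yes/no, (c, d) = group-0 yes/no.
    """
    for v in (a, b, c, d):
        if v < 0:
            raise ValueError("cell counts must be non-negative")
    n = a + b + c + d
    margins = [(a + b), (c + d), (a + c), (b + d)]
    if any(m == 0 for m in margins) or n == 0:
        raise ValueError("chi-square requires positive margins")
    chi2 = n * (a * d - b * c) ** 2 / np.prod([float(m) for m in margins])
    p = sps.chi2.sf(chi2, df=1)
    return UnivariateResult(variable=variable, test="chi2",
                            statistic=float(chi2), df=1.0,
                            p_value=float(p), significant=bool(p < alpha))


def univariate_screen(table: CohortTable, alpha: float = 0.05
                      ) -> list[UnivariateResult]:
    """t / chi-square screen of every predictor against the outcome."""
    frame = table.frame
    y = frame[OUTCOME].to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("both outcome levels are required")
    g1 = frame[y == 1]
    g0 = frame[y == 0]
    results = []
    for col, kind in table.types.items():
        x1 = g1[col].dropna().to_numpy()
        x0 = g0[col].dropna().to_numpy()
        if np.all(frame[col].dropna() == frame[col].dropna().iloc[0]):
            results.append(UnivariateResult(
                variable=col, test="t" if kind == CONTINUOUS else "chi2",
                statistic=0.0, df=1.0, p_value=1.0, significant=False,
                warning="constant column"))
            continue
        if kind == CONTINUOUS:
            s = TwoGroupSummary(x1.mean(), x1.std(ddof=1), len(x1),
                                x0.mean(), x0.std(ddof=1), len(x0))
            results.append(two_sample_t(s, alpha=alpha, variable=col))
        else:
            a, b = int(x1.sum()), int(len(x1) - x1.sum())
            c, d = int(x0.sum()), int(len(x0) - x0.sum())
            results.append(chi_square_2x2(a, b, c, d, alpha=alpha, variable=col))
    return results


def screen_table(results: list[UnivariateResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "variable": r.variable, "test": r.test, "statistic": r.statistic,
        "df": r.df, "P": r.p_value, "significant": r.significant,
    } for r in results])


# ----------------------------------------------------------- multivariate

def _check_design(X: pd.DataFrame) -> None:
    arr = np.asarray(X, dtype=float)
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        # name columns involved in exact linear dependence via QR pivots
        _, r = np.linalg.qr(arr)
        small = np.abs(np.diag(r)) < 1e-8 * max(1.0, np.abs(np.diag(r)).max())
        names = [X.columns[i] for i in np.flatnonzero(small)]
        raise ValueError(f"design matrix is rank deficient; collinear "
                         f"columns include {names}")


def _check_separation(X: pd.DataFrame, y: np.ndarray) -> None:
    for col in X.columns:
        x = X[col].to_numpy(dtype=float)
        if x.max() == x.min():
            continue
        if min(x[y == 1].min(), np.inf) > max(x[y == 0].max(), -np.inf) \
                or x[y == 1].max() < x[y == 0].min():
            raise ValueError(f"perfect separation by predictor '{col}'")


def fit_logistic(X: pd.DataFrame, y, max_iter: int = 100,
                 tol: float = 1e-8) -> LogisticFit:
    """Maximum-likelihood logistic regression with intercept.

    Standard errors come from the inverse observed information; the Wald
    statistic is (beta/SE)^2 on chi-square(1).  Perfect separation and
    rank deficiency raise informative errors rather than returning a
    silently divergent fit.
    """
    X = pd.DataFrame(X)
    y = np.asarray(y)
    if not set(np.unique(y)) <= {0, 1}:
        raise ValueError("outcome must be binary 0/1")
    _check_separation(X, y)
    design = sm.add_constant(X.astype(float), prepend=False)
    design.columns = list(X.columns) + ["intercept"]
    _check_design(design)
    model = sm.Logit(y, design)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            res = model.fit(method="newton", maxiter=max_iter, tol=tol, disp=0)
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        raise ValueError(f"logistic fit failed: {exc}") from exc
    if not np.all(np.isfinite(res.bse)):
        raise ValueError("logistic fit produced non-finite standard errors")
    beta = np.asarray(res.params, dtype=float)
    se = np.asarray(res.bse, dtype=float)
    wald_stat = (beta / se) ** 2
    p = sps.chi2.sf(wald_stat, df=1)
    return LogisticFit(
        terms=tuple(design.columns),
        coefficients=beta,
        standard_errors=se,
        wald_statistics=wald_stat,
        p_values=p,
        odds_ratios=np.exp(beta),
        ci_low=np.exp(beta - Z_95 * se),
        ci_high=np.exp(beta + Z_95 * se),
        converged=bool(res.mle_retvals.get("converged", False)),
        iterations=int(res.mle_retvals.get("iterations", 0)),
        log_likelihood=float(res.llf),
    )


def multivariate_analysis(table: CohortTable, alpha: float = 0.05
                          ) -> LogisticFit:
    """Fit the outcome on all univariately significant predictors."""
    screen = univariate_screen(table, alpha=alpha)
    keep = [r.variable for r in screen if r.significant]
    if not keep:
        raise ValueError("no univariately significant predictors to model")
    frame = table.frame.dropna()
    return fit_logistic(frame[keep], frame[OUTCOME].to_numpy())


def wald(beta: float, se: float) -> tuple[float, float]:
    """Wald statistic (beta/SE)^2 and its chi-square(1) p-value."""
    if se <= 0:
        raise ValueError("SE must be positive")
    stat = (beta / se) ** 2
    return float(stat), float(sps.chi2.sf(stat, df=1))


def odds_ratio(beta: float, se: float, convention: str = "standard"
               ) -> tuple[float, float, float]:
    """OR = exp(beta) with a 95% CI.

    ``standard``: exp(beta +/- 1.96 SE).  ``paper_compat``: OR +/- 1.96 SE,
    matching the arithmetic of the source table's printed intervals.
    """
    if se <= 0:
        raise ValueError("SE must be positive")
    or_ = float(np.exp(beta))
    if convention == "standard":
        return or_, float(np.exp(beta - Z_95 * se)), float(np.exp(beta + Z_95 * se))
    if convention == "paper_compat":
        return or_, or_ - 1.96 * se, or_ + 1.96 * se
    raise ValueError("convention must be 'standard' or 'paper_compat'")


def predict_risk(fit: LogisticFit, covariates) -> np.ndarray:
    """Per-subject event probability from a fitted logistic model."""
    frame = pd.DataFrame(covariates)
    predictors = [t for t in fit.terms if t != "intercept"]
    missing = [p for p in predictors if p not in frame.columns]
    if missing:
        raise ValueError(f"missing covariates: {missing}")
    design = frame[predictors].to_numpy(dtype=float)
    coefs = np.asarray(fit.coefficients)
    eta = design @ coefs[:-1] + coefs[-1]
    return 1.0 / (1.0 + np.exp(-eta))
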