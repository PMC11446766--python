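"""Clinical statistics: published-table recomputation and MLE oracles."""

import numpy as np
import pandas as pd
import pytest

from ibaskit import cohort, stats

N = 150

# every recomputable continuous row of the published univariate table:
# (mean1, sd1, mean0, sd0, printed |t|)
CONTINUOUS_ROWS = [
    ("age", 64.18, 8.43, 60.87, 9.04, 3.280),
    ("duration", 10.87, 6.01, 9.11, 5.19, 2.715),
    ("serum_creatinine", 82.13, 33.19, 77.65, 41.06, 1.039),
    ("sbp", 140.18, 19.83, 135.23, 15.74, 2.395),
    ("dbp", 83.12, 9.13, 82.49, 9.58, 0.583),
    ("fasting_glucose", 7.84, 2.15, 7.33, 1.76, 2.248),
    ("postprandial_glucose", 12.45, 2.43, 11.88, 1.81, 2.304),
    ("bmi", 25.41, 3.41, 25.56, 3.61, 0.370),
    ("hba1c", 7.43, 1.31, 6.11, 0.75, 10.710),
    ("hdl", 1.31, 0.81, 1.91, 1.05, 5.541),
    ("ldl", 3.71, 1.13, 3.43, 0.83, 2.446),
    ("total_cholesterol", 5.48, 1.31, 5.52, 1.04, 0.293),
    ("triglyceride", 2.84, 1.03, 2.71, 0.99, 1.114),
    ("bun", 5.45, 1.74, 5.01, 1.66, 2.241),
    ("uacr", 21.24, 6.28, 6.32, 2.76, 26.638),
]

# 2x2 tables (group-1 yes/no, group-0 yes/no) and printed chi-square
CATEGORICAL_ROWS = [
    ("gender_male", 97, 53, 64, 86, 14.599),
    ("smoking", 71, 79, 52, 98, 4.975),
    ("drinking", 37, 113, 33, 117, 0.298),
    ("non_pharmacological", 54, 96, 91, 59, 18.274),
]


@pytest.mark.parametrize("name,m1,s1,m0,s0,t_printed", CONTINUOUS_ROWS,
                         ids=[r[0] for r in CONTINUOUS_ROWS])
def test_pooled_t_reproduces_published_statistics(name, m1, s1, m0, s0, t_printed):
    res = stats.two_sample_t(stats.TwoGroupSummary(m1, s1, N, m0, s0, N))
    assert abs(res.statistic) == pytest.approx(t_printed, abs=1e-3)
    assert res.df == 298


@pytest.mark.parametrize("name,a,b,c,d,chi2_printed", CATEGORICAL_ROWS,
                         ids=[r[0] for r in CATEGORICAL_ROWS])
def test_pearson_chi2_reproduces_published_statistics(name, a, b, c, d, chi2_printed):
    res = stats.chi_square_2x2(a, b, c, d)
    assert res.statistic == pytest.approx(chi2_printed, abs=1e-3)


def test_t_null_case_and_input_validation():
    res = stats.two_sample_t(stats.TwoGroupSummary(5.0, 1.0, 30, 5.0, 1.0, 30))
    assert res.statistic == 0.0 and res.p_value == pytest.approx(1.0)
    with pytest.raises(ValueError):
        stats.TwoGroupSummary(5.0, 1.0, 1, 5.0, 1.0, 30)


def test_chi2_identical_distributions_and_zero_margin():
    assert stats.chi_square_2x2(50, 50, 50, 50).statistic == 0.0
    with pytest.raises(ValueError, match="margins"):
        stats.chi_square_2x2(0, 0, 10, 10)


def test_univariate_screen_covers_all_predictors(paper_cohort):
    results = stats.univariate_screen(paper_cohort)
    assert len(results) == 19
    tests = {r.variable: r.test for r in results}
    assert tests["age_years"] == "t" and tests["gender_male"] == "chi2"


def test_constant_column_warns_instead_of_crashing(paper_cohort):
    frame = paper_cohort.frame.copy()
    frame["age_years"] = 50.0
    table = cohort.CohortTable(frame, dict(paper_cohort.types))
    res = {r.variable: r for r in stats.univariate_screen(table)}
    assert res["age_years"].warning == "constant column"
    assert not res["age_years"].significant


# -------------------------------------------------------------- logistic

def _table_2x2(n11, n10, n01, n00):
    """Toy data: exposed (x=1) n11 events / n10 non-events, etc."""
    x = np.r_[np.ones(n11 + n10), np.zeros(n01 + n00)]
    y = np.r_[np.ones(n11), np.zeros(n10), np.ones(n01), np.zeros(n00)]
    return pd.DataFrame({"x": x}), y.astype(int)


def test_logistic_matches_closed_form_2x2_estimator():
    X, y = _table_2x2(8, 2, 2, 8)
    fit = stats.fit_logistic(X, y)
    beta = fit.coefficients[fit.terms.index("x")]
    assert beta == pytest.approx(np.log(16.0), abs=1e-6)
    assert fit.converged


def test_logistic_matches_likelihood_grid_oracle():
    """Brute-force 200x200 grid over (slope, intercept): the IRLS fit's
    log-likelihood is at least the best grid point's, and the fitted
    parameters land within one grid cell of the grid argmax."""
    rng = np.random.default_rng(8)
    x = rng.normal(size=120)
    y = (rng.uniform(size=120) < 1 / (1 + np.exp(-(0.8 * x - 0.3)))).astype(int)
    fit = stats.fit_logistic(pd.DataFrame({"x": x}), y)
    b_hat, a_hat = fit.coefficients

    def loglik(b, a):
        eta = b * x + a
        return np.sum(y * eta - np.log1p(np.exp(eta)))

    bs = np.linspace(b_hat - 1.0, b_hat + 1.0, 200)
    as_ = np.linspace(a_hat - 1.0, a_hat + 1.0, 200)
    grid = np.array([[loglik(b, a) for a in as_] for b in bs])
    i, j = np.unravel_index(np.argmax(grid), grid.shape)
    assert fit.log_likelihood >= grid[i, j] - 1e-9
    resolution = 2.0 / 199
    assert abs(bs[i] - b_hat) <= resolution
    assert abs(as_[j] - a_hat) <= resolution


def test_logistic_label_swap_negates_coefficients():
    rng = np.random.default_rng(3)
    X = pd.DataFrame({"a": rng.normal(size=200), "b": rng.normal(size=200)})
    y = (rng.uniform(size=200) < 1 / (1 + np.exp(-X["a"]))).astype(int)
    f1 = stats.fit_logistic(X, y)
    f2 = stats.fit_logistic(X, 1 - y)
    assert np.allclose(f1.coefficients, -f2.coefficients, atol=1e-6)


def test_logistic_null_data_gives_small_coefficients():
    rng = np.random.default_rng(12)
    X = pd.DataFrame({f"x{i}": rng.normal(size=5000) for i in range(4)})
    y = rng.integers(0, 2, size=5000)
    fit = stats.fit_logistic(X, y)
    assert np.all(np.abs(fit.coefficients[:-1]) < 0.1)
    assert 0.1 < np.mean(fit.p_values[:-1] < 0.5) < 1.0  # p-values not degenerate


def test_perfect_separation_is_named():
    X = pd.DataFrame({"sep": np.r_[np.ones(10) * 2, np.zeros(10)]})
    y = np.r_[np.ones(10), np.zeros(10)].astype(int)
    with pytest.raises(ValueError, match="sep"):
        stats.fit_logistic(X, y)


def test_rank_deficiency_is_named():
    rng = np.random.default_rng(5)
    a = rng.normal(size=50)
    X = pd.DataFrame({"a": a, "twice_a": 2 * a})
    y = (rng.uniform(size=50) < 0.5).astype(int)
    with pytest.raises(ValueError, match="collinear"):
        stats.fit_logistic(X, y)


# --------------------------------------------------- Wald / OR / prediction

@pytest.mark.parametrize("beta,se,wald_printed", [
    (1.132, 0.208, 29.619),
    (0.672, 0.176, 14.579),
    (0.512, 0.236, 4.707),
    (0.0, 1.0, 0.0),
])
def test_wald_statistic(beta, se, wald_printed):
    stat, p = stats.wald(beta, se)
    assert stat == pytest.approx(wald_printed, abs=0.01)
    assert 0.0 <= p <= 1.0
    with pytest.raises(ValueError):
        stats.wald(1.0, 0.0)


@pytest.mark.parametrize("beta,or_printed", [
    (1.132, 3.102), (0.0, 1.0), (-0.642, 0.526),
])
def test_odds_ratio_value(beta, or_printed):
    or_, lo, hi = stats.odds_ratio(beta, 0.208)
    assert or_ == pytest.approx(or_printed, abs=1e-3)
    assert lo < or_ < hi


def test_paper_compat_ci_is_or_plus_minus_1_96_se():
    or_, lo, hi = stats.odds_ratio(1.132, 0.208, convention="paper_compat")
    assert lo == pytest.approx(3.102 - 1.96 * 0.208, abs=1e-3)
    assert hi == pytest.approx(3.102 + 1.96 * 0.208, abs=1e-3)


def _hand_fit(intercept, **betas):
    terms = tuple(betas) + ("intercept",)
    beta = np.array(list(betas.values()) + [intercept])
    se = np.ones_like(beta)
    return stats.LogisticFit(terms=terms, coefficients=beta,
                             standard_errors=se,
                             wald_statistics=(beta / se) ** 2,
                             p_values=np.ones_like(beta),
                             odds_ratios=np.exp(beta),
                             ci_low=np.exp(beta - 1.96), ci_high=np.exp(beta + 1.96),
                             converged=True, iterations=1, log_likelihood=0.0)


def test_predict_risk_link_identity_and_monotonicity():
    fit = _hand_fit(-0.972, male=1.132)
    p0 = stats.predict_risk(fit, pd.DataFrame({"male": [0.0]}))[0]
    p1 = stats.predict_risk(fit, pd.DataFrame({"male": [1.0]}))[0]
    assert p0 == pytest.approx(1 / (1 + np.exp(0.972)))
    assert p1 == pytest.approx(1 / (1 + np.exp(-0.16)), abs=1e-6)
    assert p1 > p0
    with pytest.raises(ValueError, match="male"):
        stats.predict_risk(fit, pd.DataFrame({"other": [1.0]}))


def test_multivariate_analysis_on_generated_cohort(paper_cohort):
    fit = stats.multivariate_analysis(paper_cohort)
    table = fit.table()
    assert fit.converged
    assert "intercept" in table.term.values
    # planted protective coding: non-pharmacological treatment lowers risk
    if "non_pharmacological_treatment" in table.term.values:
        row = table.set_index("term").loc["non_pharmacological_treatment"]
        assert row.OR < 1.0
    assert np.allclose(table.Wald, (table.beta / table.SE) ** 2, atol=1e-9)
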