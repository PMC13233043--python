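"""Cohort statistics: Welch contrasts, OLS regressions (raw and
standardized), marginal effects and bootstrap power, cross-checked against
hand-written closed-form oracles."""

import numpy as np
import pandas as pd
import pytest

from tauseed.stats import (fit_adjusted_regression, fit_simple_regression,
                           marginal_effect_line, pairwise_group_tests,
                           predict_subject_seeding, resampling_power,
                           stratified_fits, welch_test)
from tauseed.pet import ScanRecord
from tauseed.transport import TransportParams

import datetime as dt


# -- closed-form oracles (kept independent of the implementation) ----------

def _welch_oracle(x, y):
    from scipy.stats import t as tdist
    x, y = np.asarray(x, float), np.asarray(y, float)
    vx, vy = x.var(ddof=1) / len(x), y.var(ddof=1) / len(y)
    t = (x.mean() - y.mean()) / np.sqrt(vx + vy)
    df = (vx + vy) ** 2 / (vx ** 2 / (len(x) - 1) + vy ** 2 / (len(y) - 1))
    p = 2 * tdist.sf(abs(t), df)
    return t, df, p


def _ols_oracle(X, y):
    """Normal equations with classical standard errors."""
    from scipy.stats import t as tdist
    X = np.column_stack([np.ones(len(y)), X])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ beta
    dof = len(y) - X.shape[1]
    sigma2 = resid @ resid / dof
    cov = sigma2 * np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(cov))
    t = beta / se
    p = 2 * tdist.sf(np.abs(t), dof)
    crit = tdist.ppf(0.975, dof)
    return beta, se, t, p, (beta - crit * se, beta + crit * se)


# -- Welch -----------------------------------------------------------------

def test_welch_matches_closed_form():
    x, y = [1.0, 2.0, 3.0], [1.0, 2.0, 3.0, 4.0, 5.0]
    t, df, p = welch_test(x, y)
    t0, df0, p0 = _welch_oracle(x, y)
    assert t == pytest.approx(t0, abs=1e-10)
    assert df == pytest.approx(df0, abs=1e-10)
    assert p == pytest.approx(p0, abs=1e-10)


def test_welch_symmetry_and_identity():
    x, y = [1.0, 2.0, 4.0], [0.5, 2.5, 3.0, 5.0]
    t1, df1, p1 = welch_test(x, y)
    t2, df2, p2 = welch_test(y, x)
    assert t1 == pytest.approx(-t2)
    assert p1 == pytest.approx(p2)
    t0, _, p0 = welch_test(x, x)
    assert t0 == 0.0 and p0 == pytest.approx(1.0)
    with pytest.raises(ValueError):
        welch_test([1.0], [1.0, 2.0])


def test_pairwise_bonferroni():
    rng = np.random.default_rng(0)
    groups = {g: rng.normal(0, 1, 20) for g in "abcd"}
    results = pairwise_group_tests(groups)
    assert len(results) == 6
    for r in results:
        assert r.m == 6
        assert r.p_adjusted == pytest.approx(min(1.0, 6 * r.p_raw))
        assert r.p_adjusted >= r.p_raw
    # identical groups: nothing significant
    same = {g: np.array([1.0, 2.0, 3.0, 4.0]) for g in "ab"}
    (r,) = pairwise_group_tests(same)
    assert r.stars == "n.s."


def test_pairwise_skips_tiny_group():
    groups = {"a": [1.0, 2.0, 3.0], "b": [2.0, 3.0, 4.0], "c": [1.0]}
    with pytest.warns(UserWarning, match="'c'"):
        results = pairwise_group_tests(groups)
    assert len(results) == 1 and results[0].m == 1


# -- regressions -----------------------------------------------------------

def test_simple_regression_exact_line():
    x = np.array([0.0, 1.0, 2.0, 3.0])
    fit = fit_simple_regression(x, 2 * x)
    assert fit.term("seeding").raw_beta == pytest.approx(2.0, abs=1e-12)
    assert fit.r == pytest.approx(1.0)
    assert fit.term("seeding").p < 1e-12


def test_simple_regression_matches_normal_equations():
    x = np.array([0.3, 1.1, 2.0, 2.9, 4.2])
    y = np.array([1.0, 0.4, 2.5, 2.0, 3.9])
    fit = fit_simple_regression(x, y)
    beta, se, t, p, (lo, hi) = _ols_oracle(x[:, None], y)
    term = fit.term("seeding")
    assert term.raw_beta == pytest.approx(beta[1], abs=1e-10)
    assert term.se == pytest.approx(se[1], abs=1e-10)
    assert term.t == pytest.approx(t[1], abs=1e-10)
    assert term.p == pytest.approx(p[1], abs=1e-10)
    assert term.ci95_low == pytest.approx(lo[1], abs=1e-10)
    assert term.ci95_high == pytest.approx(hi[1], abs=1e-10)
    assert np.sign(fit.r) == np.sign(term.raw_beta)
    # standardized beta identity for continuous terms
    assert term.std_beta == pytest.approx(
        term.raw_beta * x.std(ddof=1) / y.std(ddof=1), abs=1e-12)
    with pytest.raises(ValueError, match="constant"):
        fit_simple_regression(np.ones(5), y)


def _cohort_frame(n=300, b_seed=3.0, b_age=0.02, seed=0):
    rng = np.random.default_rng(seed)
    seeding = rng.normal(0.15, 0.02, n)
    age = rng.normal(72, 7, n)
    sex = (rng.random(n) < 0.5).astype(float)
    apoe4 = (rng.random(n) < 0.3).astype(float)
    y = 0.5 + b_seed * seeding + b_age * age + 0.05 * rng.standard_normal(n)
    df = pd.DataFrame({"seeding": seeding, "age": age, "sex": sex,
                       "apoe4": apoe4, "tau": y})
    return df


def test_adjusted_regression_recovers_and_standardizes():
    df = _cohort_frame()
    fit = fit_adjusted_regression(df["seeding"], df[["age", "sex", "apoe4"]],
                                  df["tau"])
    term = fit.term("seeding")
    assert term.ci95_low < 3.0 < term.ci95_high
    # continuous terms standardized, indicators not
    assert fit.term("age").std_beta is not None
    assert fit.term("sex").std_beta is None
    assert fit.term("apoe4").std_beta is None
    assert term.std_beta == pytest.approx(
        term.raw_beta * df["seeding"].std(ddof=1) / df["tau"].std(ddof=1),
        rel=1e-9)


def test_adjusted_matches_oracle_on_small_fixture():
    df = _cohort_frame(n=9, seed=3)
    fit = fit_adjusted_regression(df["seeding"], df[["age", "sex", "apoe4"]],
                                  df["tau"])
    X = df[["seeding", "age", "sex", "apoe4"]].to_numpy()
    beta, se, t, p, (lo, hi) = _ols_oracle(X, df["tau"].to_numpy())
    for i, name in enumerate(["const", "seeding", "age", "sex", "apoe4"]):
        term = fit.term(name)
        assert term.raw_beta == pytest.approx(beta[i], abs=1e-10)
        assert term.se == pytest.approx(se[i], abs=1e-10)
        assert term.p == pytest.approx(p[i], abs=1e-10)


def test_adjusted_regression_collinearity_error():
    df = _cohort_frame(n=50)
    cov = df[["age", "sex", "apoe4"]].copy()
    cov["age2"] = cov["age"]
    with pytest.raises(ValueError, match="age"):
        fit_adjusted_regression(df["seeding"], cov, df["tau"])


def test_adjusted_beta_close_to_simple_when_covariates_independent():
    df = _cohort_frame(n=2000, b_age=0.0, seed=5)
    simple = fit_simple_regression(df["seeding"], df["tau"]).term("seeding")
    adjusted = fit_adjusted_regression(
        df["seeding"], df[["age", "sex", "apoe4"]], df["tau"]).term("seeding")
    assert adjusted.raw_beta == pytest.approx(simple.raw_beta, rel=0.05)


def test_stratified_fits_and_skipping():
    df = _cohort_frame(n=120)
    df["diagnosis"] = ["CN"] * 60 + ["MCI"] * 57 + ["AD"] * 3
    fits = stratified_fits(df)
    assert fits["CN"].n == 60
    assert fits["MCI"].n == 57
    assert isinstance(fits["AD"], str) and "skipped" in fits["AD"]


def test_marginal_effect_line_identities():
    df = _cohort_frame(n=200, seed=2)
    fit = fit_adjusted_regression(df["seeding"], df[["age", "sex", "apoe4"]],
                                  df["tau"])
    means = {c: df[c].mean() for c in ("age", "sex", "apoe4")}
    intercept, slope = marginal_effect_line(fit, means)
    assert slope == fit.term("seeding").raw_beta
    # evaluated at the mean seeding, the line passes through the mean outcome
    assert intercept + slope * df["seeding"].mean() == \
        pytest.approx(df["tau"].mean(), abs=1e-10)
    with pytest.raises(ValueError, match="adjusted"):
        marginal_effect_line(fit_simple_regression(df["seeding"], df["tau"]),
                             means)


# -- power -----------------------------------------------------------------

def test_resampling_power_deterministic_and_saturating():
    df = _cohort_frame(n=250, b_seed=30.0, seed=7)  # enormous effect
    p1 = resampling_power(df, n_target=100, reps=50, rng_seed=3)
    p2 = resampling_power(df, n_target=100, reps=50, rng_seed=3)
    assert p1 == p2
    assert p1 > 0.95
    with pytest.raises(ValueError):
        resampling_power(df, n_target=1000, reps=10)


# -- subject predictions ---------------------------------------------------

def test_predict_subject_seeding_uniform_and_deterministic(conn5, atlas5):
    scan = ScanRecord(subject_id="S1", modality="FDG",
                      date=dt.date(2016, 1, 1),
                      suvr=np.full(5, 1.3), atlas=atlas5)
    val = predict_subject_seeding(scan, conn5)
    assert val == pytest.approx(0.1, rel=1e-9)   # uniform field -> k/lam
    assert predict_subject_seeding(scan, conn5) == val


def test_prediction_decreases_with_target_anomaly(conn5, atlas5):
    # transport-dominated regime: raising the entorhinal SUVR lowers its
    # predicted seeding (concentration ~ 1/(1 + eps*A))
    params = TransportParams(rho=1e6)
    base = np.array([0.8, 0.8, 1.2, 1.2, 1.2])
    raised = base.copy()
    raised[:2] += 0.5
    mk = lambda v: ScanRecord(subject_id="S1", modality="FDG",
                              date=dt.date(2016, 1, 1), suvr=v, atlas=atlas5)
    assert predict_subject_seeding(mk(raised), conn5, params) < \
        predict_subject_seeding(mk(base), conn5, params)
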