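"""Cox engine correctness: partial-likelihood oracle agreement, baseline
hazard, diagnostics, splines, trend tests, Poisson rates."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from strokeprs.cox import (
    BASE_TIER_GENETIC,
    ConvergenceError,
    SeparationError,
    fit_stratified_cox,
    hazard_ratios,
    poisson_adjusted_rates,
    rcs_basis,
    rcs_dose_response,
    schoenfeld_ph_test,
    trend_test,
)
from tests.conftest import brute_force_partial_loglik


def test_beta_matches_grid_search_oracle(toy_survival):
    """The fitted coefficient maximizes the explicit 4-term Breslow partial
    likelihood (independent brute-force oracle) to 1e-4."""
    fit = fit_stratified_cox(toy_survival, ["x"], strata_col=None)
    oracle = optimize.minimize_scalar(
        lambda b: -brute_force_partial_loglik(toy_survival, b),
        bounds=(-5, 5), method="bounded", options={"xatol": 1e-10},
    ).x
    assert fit.params["x"] == pytest.approx(oracle, abs=1e-4)


@pytest.mark.parametrize("seed", [0, 1, 2, 3])
def test_beta_matches_oracle_on_random_small_fixtures(seed):
    rng = np.random.default_rng(seed)
    n = 8
    df = pd.DataFrame(
        {
            "followup_years": rng.exponential(5, n).round(2) + 0.01,
            "event": rng.integers(0, 2, n) | 1,  # guarantee events
            "x": rng.normal(size=n).round(2),
        }
    )
    df.loc[0, "event"] = 1
    fit = fit_stratified_cox(df, ["x"], strata_col=None)
    oracle = optimize.minimize_scalar(
        lambda b: -brute_force_partial_loglik(df, b),
        bounds=(-8, 8), method="bounded", options={"xatol": 1e-10},
    ).x
    assert fit.params["x"] == pytest.approx(oracle, abs=1e-4)


def test_constant_covariate_gives_null_hr(toy_survival):
    df = toy_survival.assign(x=1.0)
    fit = fit_stratified_cox(df, ["x"], strata_col=None)
    assert fit.params["x"] == 0.0
    assert hazard_ratios(fit).loc["x", "hr"] == 1.0


def test_agreement_with_lifelines_including_left_truncation():
    from lifelines import CoxPHFitter

    rng = np.random.default_rng(10)
    n = 800
    df = pd.DataFrame(
        {
            "x1": rng.normal(size=n), "x2": rng.integers(0, 2, n).astype(float),
            "sc": rng.integers(0, 2, n),
        }
    )
    t = rng.exponential(1 / (0.1 * np.exp(0.5 * df.x1 - 0.3 * df.x2)))
    c = rng.uniform(2, 12, n)
    df["followup_years"] = np.minimum(t, c)
    df["event"] = (t <= c).astype(int)
    fit = fit_stratified_cox(df, ["x1", "x2"], strata_col="sc")
    cph = CoxPHFitter()
    cph.fit(df, duration_col="followup_years", event_col="event", strata=["sc"])
    np.testing.assert_allclose(fit.params.to_numpy(), cph.params_[["x1", "x2"]].to_numpy(), atol=1e-6)
    np.testing.assert_allclose(
        np.sqrt(np.diag(fit.covariance)), cph.standard_errors_[["x1", "x2"]].to_numpy(), atol=1e-6
    )
    # delayed entry
    df["entry"] = df["followup_years"] * rng.uniform(0, 0.5, n)
    fit_lt = fit_stratified_cox(df, ["x1", "x2"], strata_col="sc", entry_col="entry")
    cph_lt = CoxPHFitter()
    cph_lt.fit(df, duration_col="followup_years", event_col="event", strata=["sc"], entry_col="entry")
    np.testing.assert_allclose(
        fit_lt.params.to_numpy(), cph_lt.params_[["x1", "x2"]].to_numpy(), atol=1e-6
    )


def test_breslow_baseline_equals_nelson_aalen_at_null_beta():
    """With beta = 0 (constant covariate) on tie-free data, the Breslow
    cumulative baseline hazard is exactly the Nelson-Aalen estimator."""
    from lifelines import NelsonAalenFitter

    rng = np.random.default_rng(3)
    n = 300
    t = rng.exponential(10, n)
    c = rng.uniform(2, 15, n)
    df = pd.DataFrame(
        {"followup_years": np.minimum(t, c), "event": (t <= c).astype(int), "x": 1.0}
    )
    fit = fit_stratified_cox(df, ["x"], strata_col=None)
    assert fit.params["x"] == 0.0
    naf = NelsonAalenFitter(nelson_aalen_smoothing=False)
    naf.fit(df["followup_years"], df["event"])
    bl = fit.baseline["_all"]
    na = naf.cumulative_hazard_.loc[bl["time"].to_numpy(), "NA_estimate"].to_numpy()
    np.testing.assert_allclose(bl["cumhaz"].to_numpy(), na, rtol=1e-10)


def test_stratified_fit_with_shared_baseline_approaches_unstratified():
    rng = np.random.default_rng(4)
    n = 20000
    df = pd.DataFrame({"x": rng.normal(size=n), "sc": rng.integers(0, 3, n)})
    t = rng.exponential(1 / (0.05 * np.exp(0.4 * df.x)))
    c = rng.uniform(5, 15, n)
    df["followup_years"] = np.minimum(t, c)
    df["event"] = (t <= c).astype(int)
    b_strat = fit_stratified_cox(df, ["x"], strata_col="sc").params["x"]
    b_unstrat = fit_stratified_cox(df, ["x"], strata_col=None).params["x"]
    assert abs(b_strat - b_unstrat) < 0.02


def test_separation_detected():
    df = pd.DataFrame(
        {
            "followup_years": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
            "event": [1, 1, 1, 0, 0, 0],
            "x": [1.0, 1.0, 1.0, 0.0, 0.0, 0.0],
        }
    )
    with pytest.raises((SeparationError, ConvergenceError)):
        fit_stratified_cox(df, ["x"], strata_col=None)


def test_missing_covariate_and_empty_stratum_rejected(toy_survival):
    df = toy_survival.copy()
    df.loc[0, "x"] = np.nan
    with pytest.raises(ValueError, match="missing"):
        fit_stratified_cox(df, ["x"], strata_col=None)
    df2 = toy_survival.assign(sc=[0, 0, 1, 1], event=[1, 1, 0, 0])
    with pytest.raises(ValueError, match="no events"):
        fit_stratified_cox(df2, ["x"], strata_col="sc")
    with pytest.raises(ValueError, match="covariate"):
        fit_stratified_cox(toy_survival, [], strata_col=None)


def test_schoenfeld_matches_lifelines_identity_transform(cohort_category):
    from lifelines import CoxPHFitter
    from lifelines.statistics import proportional_hazard_test

    cols = ["fruit_mid", "fruit_high", "age", "female"]
    df = cohort_category[cols + ["followup_years", "event"]]
    fit = fit_stratified_cox(df, cols, strata_col=None)
    ours = schoenfeld_ph_test(fit, df)
    cph = CoxPHFitter()
    cph.fit(df, duration_col="followup_years", event_col="event")
    ll = proportional_hazard_test(cph, df, time_transform="identity").summary
    for c in cols:
        assert ours.loc[c, "chi2"] == pytest.approx(ll.loc[c, "test_statistic"].item(), rel=1e-6)


def test_schoenfeld_detects_decaying_effect():
    """A covariate whose hazard ratio decays over time violates PH and is
    flagged in the majority of seeds."""
    hits = 0
    for seed in range(5):
        rng = np.random.default_rng(seed)
        n = 3000
        x = rng.integers(0, 2, n).astype(float)
        # piecewise hazard: strong effect before t=3, none after
        lam0 = 0.08
        t1 = rng.exponential(1 / (lam0 * np.exp(1.2 * x)))
        t = np.where(t1 < 3, t1, 3 + rng.exponential(1 / lam0, n))
        c = rng.uniform(5, 12, n)
        df = pd.DataFrame(
            {"followup_years": np.minimum(t, c), "event": (t <= c).astype(int), "x": x}
        )
        fit = fit_stratified_cox(df, ["x"], strata_col=None)
        hits += schoenfeld_ph_test(fit, df).loc["x", "p"] < 0.05
    assert hits >= 3


def test_rcs_basis_smoothness_and_linear_tails():
    knots = np.array([-1.0, 0.0, 1.5])
    x = np.linspace(-4, 5, 20001)
    basis = rcs_basis(x, knots)[:, 1]
    d2 = np.diff(basis, 2) / (x[1] - x[0]) ** 2
    assert np.all(np.abs(np.diff(d2)) < 1e-3)  # continuous second derivative
    assert np.allclose(d2[x[1:-1] < -1.5], 0, atol=1e-8)  # linear below first knot
    assert np.allclose(d2[x[1:-1] > 2.0], 0, atol=1e-6)  # linear above last knot
    with pytest.raises(ValueError):
        rcs_basis(x, np.array([0.0, 0.0, 1.0]))


def test_spline_reference_hr_is_one(cohort_category):
    res = rcs_dose_response(cohort_category, "prs_std", BASE_TIER_GENETIC)
    curve, knots = res["curve"], res["knots"]
    ref_hr = np.interp(knots[1], curve["prs_std"], curve["hr"])
    assert ref_hr == pytest.approx(1.0, abs=5e-3)
    assert 0 <= res["p_overall"] <= 1 and 0 <= res["p_nonlinear"] <= 1


def test_trend_test_strong_effect_and_binary_reduction(cohort_category):
    p = trend_test(cohort_category, "genetic_group", "prs_std", BASE_TIER_GENETIC)
    assert p < 0.001  # monotone genetic truth in the fixture
    # with two categories the trend test reduces to the binary Wald test
    sub = cohort_category[cohort_category["fruit_group"].isin(["low", "high"])].copy()
    sub["fruit_bin"] = (sub["fruit_group"] == "high").astype(int)
    p_trend = trend_test(sub, "fruit_bin", "fruit_g_day", ["age"])
    fit = fit_stratified_cox(sub, ["fruit_bin", "age"])
    p_wald = hazard_ratios(fit).loc["fruit_bin", "p"]
    assert p_trend == pytest.approx(p_wald, rel=1e-6)


def test_poisson_rate_reduces_to_crude_rate():
    rng = np.random.default_rng(0)
    df = pd.DataFrame(
        {
            "followup_years": rng.uniform(1, 10, 500),
            "event": rng.integers(0, 2, 500),
            "g": 1,
        }
    )
    rates = poisson_adjusted_rates(df, "g", adjust=[])
    crude = 1000 * df["event"].sum() / df["followup_years"].sum()
    assert rates["rate"].iloc[0] == pytest.approx(crude, rel=1e-8)


def test_poisson_adjusted_rates_order_with_genetic_risk(cohort_category):
    rates = poisson_adjusted_rates(cohort_category, "genetic_group")
    assert rates.loc["low", "rate"] < rates.loc["high", "rate"]
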