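"""Exclusion cascade, derived variables, and the descriptive table."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from strokeprs.prep import (
    FRUIT_LOW_BOUND_G_DAY,
    apply_exclusions,
    baseline_table,
    derive_clinical_flags,
    derive_diet_score,
    derive_fruit_group,
    derive_ideal_activity,
)


def _toy_raw():
    return pd.DataFrame(
        {
            "fruit_g_day": [50.0, np.nan, np.nan, 80.0, 90.0],
            "prevalent_disease": [0, 0, 1, 1, 0],
            "followup_years": [10.0, 9.0, 8.0, np.nan, np.nan],
            "event": [0, 0, 0, 0, 1],
        }
    )


def test_exclusion_order_of_precedence_on_toy_table():
    """A row flagged for both missing fruit and prevalence counts only under
    missing fruit; the audit conserves counts exactly."""
    cohort, audit = apply_exclusions(_toy_raw())
    assert audit.n_input == 5
    assert audit.n_missing_fruit == 2  # rows 1 and 2 (row 2 also prevalent)
    assert audit.n_prevalent == 1  # row 3 only
    assert audit.n_missing_followup == 1  # row 4
    assert audit.n_analytic == 1
    assert len(cohort) == 1
    assert audit.n_input == (
        audit.n_missing_fruit + audit.n_prevalent + audit.n_missing_followup + audit.n_analytic
    )


def test_no_flags_keeps_everyone():
    raw = _toy_raw().assign(
        fruit_g_day=1.0, prevalent_disease=0, followup_years=5.0
    )
    cohort, audit = apply_exclusions(raw)
    assert audit.n_analytic == audit.n_input == len(cohort)


@pytest.mark.parametrize(
    "intake,expected",
    [
        (25.0, "low"),  # 25 < 200/7
        (FRUIT_LOW_BOUND_G_DAY, "mid"),  # boundary belongs to mid
        (66.0, "mid"),  # typical stroke-case mean intake
        (100.0, "mid"),  # interval closed at 100
        (100.0001, "high"),  # 'high' requires strictly > 100 g/day
        (0.0, "low"),
    ],
)
def test_fruit_group_boundaries(intake, expected):
    assert derive_fruit_group([intake])[0] == expected


def test_fruit_group_rejects_negative():
    with pytest.raises(ValueError):
        derive_fruit_group([-1.0])


@settings(deadline=None, max_examples=200, derandomize=True)
@given(st.floats(min_value=0.0, max_value=1e4, allow_nan=False))
def test_fruit_group_partitions_nonnegative_reals(x):
    assert derive_fruit_group([x])[0] in ("low", "mid", "high")


@pytest.mark.parametrize(
    "args,expected",
    [
        ((50.0, 150.0, 250.0, 5.0), 4),  # all four ideal components met
        ((80.0, 100.0, 100.0, 1.0), 0),
        ((74.99, 125.0, 200.0, 3.0), 4),  # strict < for meat, >= for the rest
        ((75.0, 125.0, 200.0, 3.0), 3),
    ],
)
def test_diet_score_boundaries(args, expected):
    assert derive_diet_score(*args) == expected


@settings(deadline=None, max_examples=100, derandomize=True)
@given(*[st.floats(min_value=0, max_value=1e3, allow_nan=False) for _ in range(4)])
def test_diet_score_bounded_zero_to_four(a, b, c, d):
    assert 0 <= derive_diet_score(a, b, c, d) <= 4


@pytest.mark.parametrize(
    "mod,vig,level,ideal",
    [(100.0, 30.0, 160.0, True), (0.0, 75.0, 150.0, True), (149.0, 0.0, 149.0, False)],
)
def test_ideal_activity_weights_vigorous_twice(mod, vig, level, ideal):
    got_level, got_ideal = derive_ideal_activity(mod, vig)
    assert got_level == pytest.approx(level)
    assert got_ideal is ideal


def test_clinical_flags_and_bmi():
    df = pd.DataFrame(
        {
            "weight_kg": [70.0, 60.0],
            "height_m": [1.70, 1.70],
            "sbp": [142.0, 120.0],
            "dbp": [80.0, 70.0],
            "bp_med": [0, 0],
            "glucose_mg_dl": [100.0, 100.0],
            "glucose_med": [0, 0],
            "total_chol_mg_dl": [180.0, 180.0],
            "triglycerides_mg_dl": [100.0, 100.0],
            "ldl_mg_dl": [100.0, 100.0],
            "hdl_mg_dl": [50.0, 50.0],
            "lipid_med": [0, 0],
        }
    )
    flags = derive_clinical_flags(df)
    assert flags["bmi"].iloc[0] == pytest.approx(70 / 1.70**2, abs=1e-6)
    assert flags["hypertension"].tolist() == [1, 0]
    assert flags["diabetes"].tolist() == [0, 0]
    assert flags["dyslipidemia"].tolist() == [0, 0]


def test_derived_flags_idempotent(cohort_category):
    again = derive_clinical_flags(cohort_category)
    for col in ("hypertension", "diabetes", "dyslipidemia"):
        assert (again[col].to_numpy() == cohort_category[col].to_numpy()).all()
    fg = derive_fruit_group(cohort_category["fruit_g_day"])
    assert (np.asarray(fg.codes) == np.asarray(cohort_category["fruit_group"].cat.codes)).all()


def test_baseline_table_identical_groups_p_one():
    rng = np.random.default_rng(0)
    half = pd.DataFrame(
        {"age": rng.normal(55, 10, 200), "female": rng.integers(0, 2, 200)}
    )
    cohort = pd.concat(
        [half.assign(event=0), half.assign(event=1)], ignore_index=True
    )
    tab = baseline_table(cohort).set_index("variable")
    assert tab.loc["age", "p_value"] == pytest.approx(1.0)
    assert tab.loc["female", "p_value"] == pytest.approx(1.0)


def test_baseline_table_chi_square_matches_hand_computation():
    # 2x2 table: exposure 30/70 in controls, 45/55 in cases
    cohort = pd.DataFrame(
        {
            "female": [1] * 30 + [0] * 70 + [1] * 45 + [0] * 55,
            "event": [0] * 100 + [1] * 100,
        }
    )
    tab = baseline_table(cohort).set_index("variable")
    obs = np.array([[70, 30], [55, 45]])
    tot = obs.sum()
    exp = np.outer(obs.sum(1), obs.sum(0)) / tot
    chi2 = ((obs - exp) ** 2 / exp).sum()
    from scipy import stats

    assert tab.loc["female", "p_value"] == pytest.approx(stats.chi2.sf(chi2, 1), rel=1e-10)


def test_generator_marginals_in_descriptives(cohort_category):
    """Female proportion near the configured 58% in the analytic cohort."""
    assert abs(cohort_category["female"].mean() - 0.58) < 0.02
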