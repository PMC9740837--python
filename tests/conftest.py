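import numpy as np
import pandas as pd
import pytest

from strokeprs.pipeline import simulate_analytic_cohort
from strokeprs.simulate import GeneratorConfig


@pytest.fixture(scope="session")
def sim_category():
    """Moderate cohort generated in category-effect mode with the default
    genetic/fruit truths; shared by fitting-level tests."""
    cfg = GeneratorConfig(n_participants=6000, seed=7, effect_mode="category")
    return simulate_analytic_cohort(cfg)


@pytest.fixture(scope="session")
def cohort_category(sim_category):
    return sim_category["cohort"]


@pytest.fixture(scope="session")
def sim_null():
    """Cohort with null genetic and fruit effects (age/sex effects kept)."""
    cfg = GeneratorConfig(
        n_participants=5000, seed=11, effect_mode="category",
        true_hr_genetic=(1.0, 1.0), true_hr_fruit=(1.0, 1.0),
    )
    return simulate_analytic_cohort(cfg)


@pytest.fixture()
def toy_survival():
    """Four subjects, all events at times 1..4, one binary covariate."""
    return pd.DataFrame(
        {
            "followup_years": [1.0, 2.0, 3.0, 4.0],
            "event": [1, 1, 1, 1],
            "x": [1.0, 0.0, 1.0, 0.0],
        }
    )


def brute_force_partial_loglik(df, beta, covariate="x"):
    """Independent O(n^2) Breslow partial log-likelihood (oracle)."""
    t = df["followup_years"].to_numpy()
    d = df["event"].to_numpy()
    x = df[covariate].to_numpy()
    ll = 0.0
    for tk in np.unique(t[d == 1]):
        at_risk = t >= tk
        dk = (t == tk) & (d == 1)
        ll += beta * x[dk].sum() - dk.sum() * np.log(np.exp(beta * x[at_risk]).sum())
    return ll
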