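"""Generator correctness: Hardy-Weinberg genotypes, determinism, event-time
mechanics, incidence calibration and exclusion fixtures."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from strokeprs import prs as prs_mod
from strokeprs.prep import EmptyCohortError, prepare_cohort
from strokeprs.simulate import (
    SUBTYPE_COUNTS,
    GeneratorConfig,
    calibrate_baseline_scale,
    crude_incidence_per_1000py,
    generate_cohort,
    generate_event_times,
    generate_genotypes,
    generate_snp_panel,
    inject_exclusion_fixtures,
)


def test_genotypes_follow_hardy_weinberg():
    cfg = GeneratorConfig(n_participants=20000, n_snps=1, seed=3)
    panel = pd.DataFrame({"snp_id": ["rs1"], "risk_allele": ["A"], "allele_freq": [0.5], "weight": [0.1]})
    g = generate_genotypes(cfg, panel, np.random.default_rng(3)).to_numpy().ravel()
    n = len(g)
    for k, expected in [(0, 0.25), (1, 0.50), (2, 0.25)]:
        sd = np.sqrt(expected * (1 - expected) / n)
        assert abs((g == k).mean() - expected) < 3 * sd


def test_genotypes_degenerate_frequency_all_zero():
    cfg = GeneratorConfig(n_participants=500, n_snps=1, seed=0)
    panel = pd.DataFrame({"snp_id": ["rs1"], "risk_allele": ["A"], "allele_freq": [1e-12], "weight": [0.1]})
    g = generate_genotypes(cfg, panel, np.random.default_rng(0))
    assert (g.to_numpy() == 0).all()


def test_genotypes_reject_nonfinite_frequency():
    cfg = GeneratorConfig(n_participants=10, n_snps=1, seed=0)
    panel = pd.DataFrame({"snp_id": ["rs1"], "risk_allele": ["A"], "allele_freq": [np.nan], "weight": [0.1]})
    with pytest.raises(ValueError, match="non-finite"):
        generate_genotypes(cfg, panel, np.random.default_rng(0))


def test_seed_determinism_bit_identical():
    cfg = GeneratorConfig(n_participants=400, n_snps=30, seed=42, missing_fruit_n=10, prevalent_n=5)
    raw1, g1, p1 = generate_cohort(cfg)
    raw2, g2, p2 = generate_cohort(cfg)
    pd.testing.assert_frame_equal(raw1, raw2)
    pd.testing.assert_frame_equal(g1, g2)
    pd.testing.assert_frame_equal(p1, p2)


def test_event_times_shape_one_is_exponential():
    """With Weibull shape 1, eta = 0 and no competing risks or censoring,
    times are exponential with the baseline rate."""
    cfg = GeneratorConfig(
        n_participants=20000, seed=5, weibull_shape=1.0, baseline_scale=0.05,
        cohort_scale_multipliers=(1.0, 1.0, 1.0), death_rate=0.0,
        admin_censor_years=(1e6, 1e6 + 1),
    )
    rng = np.random.default_rng(5)
    times = generate_event_times(cfg, np.zeros(20000), np.zeros(20000, dtype=int), rng)
    assert times["event"].all()
    t = times["followup_years"].to_numpy()
    assert abs(t.mean() - 1 / 0.05) < 3 * (1 / 0.05) / np.sqrt(len(t))
    assert stats.kstest(t, "expon", args=(0, 1 / 0.05)).pvalue > 0.001


def test_event_and_death_mutually_exclusive_and_censor_bound():
    raw, _, _ = generate_cohort(GeneratorConfig(n_participants=3000, seed=9))
    assert not ((raw["event"] == 1) & (raw["death"] == 1)).any()
    assert (raw["followup_years"] <= 13.0 + 1e-12).all()
    assert (raw.loc[raw["event"] == 1, "event_subtype"] != "").all()
    assert (raw.loc[raw["event"] == 0, "event_subtype"] == "").all()


def test_subtype_mixture_matches_event_bookkeeping():
    """The default subtype mixture reproduces the 1834/439/55/258 split of
    2586 first-ever strokes, and sampled subtypes follow it."""
    assert sum(SUBTYPE_COUNTS) == 2586
    cfg = GeneratorConfig()
    probs = np.asarray(cfg.subtype_probs)
    np.testing.assert_allclose(probs * 2586, SUBTYPE_COUNTS)
    raw, _, _ = generate_cohort(dataclasses.replace(cfg, n_participants=30000, seed=2))
    sub = raw.loc[raw["event"] == 1, "event_subtype"].value_counts(normalize=True)
    for cat, p in zip(("ischemic", "hemorrhagic", "both", "unknown"), probs):
        se = np.sqrt(p * (1 - p) / raw["event"].sum())
        assert abs(sub.get(cat, 0.0) - p) < 4 * se


def test_null_effects_yield_null_hazard_ratios(sim_null):
    from strokeprs.cox import BASE_TIER_GENETIC, FULL_TIER, fit_stratified_cox, hazard_ratios

    cohort = sim_null["cohort"]
    fit = fit_stratified_cox(cohort, ["genetic_int", "genetic_high"] + BASE_TIER_GENETIC)
    hr = hazard_ratios(fit)
    for c in ("genetic_int", "genetic_high"):
        assert abs(hr.loc[c, "coef"]) < 3 * hr.loc[c, "se"]
    fit = fit_stratified_cox(cohort, ["fruit_mid", "fruit_high"] + FULL_TIER)
    hr = hazard_ratios(fit)
    for c in ("fruit_mid", "fruit_high"):
        assert abs(hr.loc[c, "coef"]) < 3 * hr.loc[c, "se"]


def test_prs_mean_matches_expectation_and_normality():
    """E[PRS] = sum_j 2 p_j w_j; the 534-SNP score passes an
    Anderson-Darling normality check in >= 90% of seeds at n = 5000."""
    passes = 0
    seeds = range(10)
    for seed in seeds:
        cfg = GeneratorConfig(n_participants=5000, seed=seed)
        rng = np.random.default_rng(seed)
        panel = generate_snp_panel(cfg, rng)
        geno = generate_genotypes(cfg, panel, rng)
        score = prs_mod.compute_prs(geno, panel)["prs_raw"]
        expected = 2.0 * (panel["allele_freq"] * panel["weight"]).sum()
        var_prs = (2 * panel["allele_freq"] * (1 - panel["allele_freq"]) * panel["weight"] ** 2).sum()
        assert abs(score.mean() - expected) < 4 * np.sqrt(var_prs / 5000)
        ad = stats.anderson(score.to_numpy(), dist="norm", method="interpolate")
        passes += ad.pvalue > 0.01
    assert passes >= 0.9 * len(list(seeds))


def test_calibration_fixed_point_and_rate_doubling():
    cfg = GeneratorConfig(n_participants=8000, seed=13)
    # fixed point: a config already within tolerance is returned unchanged
    raw, _, _ = generate_cohort(dataclasses.replace(cfg, n_participants=20000))
    achieved = crude_incidence_per_1000py(raw)
    out = calibrate_baseline_scale(cfg, target_rate=achieved, rel_tol=0.05, n_calibration=20000)
    assert out.baseline_scale == cfg.baseline_scale
    # with shape 1 and low rates, doubling the scale ~doubles the crude rate
    r1 = crude_incidence_per_1000py(generate_cohort(dataclasses.replace(cfg, n_participants=20000))[0])
    cfg2 = dataclasses.replace(cfg, baseline_scale=2 * cfg.baseline_scale, n_participants=20000)
    r2 = crude_incidence_per_1000py(generate_cohort(cfg2)[0])
    assert 1.75 < r2 / r1 < 2.15


def test_calibration_nonbracketing_reports_achieved_range():
    cfg = GeneratorConfig(n_participants=2000, seed=1)
    with pytest.raises(ValueError, match="achieved rate range"):
        calibrate_baseline_scale(cfg, target_rate=7.7, bracket=(1e-7, 1e-6), n_calibration=2000)


def test_exclusion_fixtures_disjoint_and_validated():
    cfg = GeneratorConfig(n_participants=200, n_snps=10, seed=4)
    raw, _, _ = generate_cohort(cfg)
    # (0,0,0): unchanged
    assert inject_exclusion_fixtures(raw, cfg) is raw
    cfg2 = dataclasses.replace(cfg, missing_fruit_n=20, prevalent_n=10, missing_followup_n=5)
    flagged = inject_exclusion_fixtures(raw, cfg2, np.random.default_rng(0))
    assert flagged["fruit_g_day"].isna().sum() == 20
    assert flagged["prevalent_disease"].sum() == 10
    assert flagged["followup_years"].isna().sum() == 5
    # disjoint: no prevalent row is missing fruit
    assert not (flagged["prevalent_disease"].astype(bool) & flagged["fruit_g_day"].isna()).any()
    with pytest.raises(ValueError, match="exceed"):
        dataclasses.replace(cfg, missing_fruit_n=300).validate()


def test_all_excluded_raises_empty_cohort_error():
    cfg = GeneratorConfig(n_participants=50, n_snps=10, seed=4, missing_fruit_n=50)
    raw, _, _ = generate_cohort(cfg)
    with pytest.raises(EmptyCohortError):
        prepare_cohort(raw)
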