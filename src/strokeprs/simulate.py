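"""Synthetic cohort generator with known ground truth.

Emulates a three-cohort Chinese prospective study of fruit intake, polygenic
stroke risk and incident stroke: 534 independent Hardy-Weinberg biallelic
SNPs with external weights, Table-1-like covariate marginals, a zero-inflated
lognormal fruit-intake distribution (mean ~83 g/day, tertile boundaries near
200 g/week and 100 g/day), Weibull proportional-hazards stroke times with
configurable genetic / fruit / interaction effects, exponential competing
non-stroke death, and uniform administrative censoring tuned to a median
follow-up near 11 years.  Exclusion-cascade fixtures (missing fruit intake,
prevalent disease, missing follow-up) can be injected for testing the
cohort-preparation stage.

Every run is fully determined by ``GeneratorConfig.seed``: sub-streams for
the SNP panel, genotypes, covariates, event times and exclusion fixtures are
spawned from a single ``numpy.random.SeedSequence`` in a fixed order.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import prs as prs_mod
from .prep import derive_fruit_group

# First-ever stroke subtype counts used for the default subtype mixture:
# ischemic / hemorrhagic / both / unknown.
SUBTYPE_COUNTS = (1834, 439, 55, 258)
SUBTYPE_CATEGORIES = ("ischemic", "hemorrhagic", "both", "unknown")

#: Crude stroke incidence (events per 1000 person-years) the default
#: configuration is calibrated to.
TARGET_INCIDENCE_PER_1000PY = 7.7

# Baseline Weibull scale calibrated once (seed 20070101, n=20000) so the
# default configuration hits the target crude incidence; see docs/methods.md.
DEFAULT_BASELINE_SCALE = 7.0770521288768175e-03


def default_subtype_probs() -> tuple[float, ...]:
    total = sum(SUBTYPE_COUNTS)
    return tuple(c / total for c in SUBTYPE_COUNTS)


def default_covariate_params() -> dict:
    """Covariate distribution parameters matched to the cohort's
    baseline-characteristics marginals (means/SDs/proportions)."""
    return {
        "prop_north": 0.49,
        "prop_urban": 0.16,
        "prop_high_school": 0.47,
        "prop_smoker": 0.23,
        "prop_alcohol": 0.23,
        "prop_family_history": 0.10,
        "bmi_mean_sd": (24.0, 3.5),
        "height_mean_sd": {"female": (1.58, 0.06), "male": (1.68, 0.06)},
        "vegetable_mean_sd": (335.0, 157.0),
        # physical activity: zero-inflated gamma minutes/week, tuned so that
        # ~63% reach the ideal level (moderate + 2*vigorous >= 150 min/week)
        "moderate_zero_prob": 0.20,
        "moderate_gamma": (1.6, 160.0),  # shape, scale
        "vigorous_zero_prob": 0.70,
        "vigorous_gamma": (1.5, 60.0),
        # diet components: lognormal / zero-inflated lognormal, tuned so the
        # ideal-diet proportion (score >= 2) is ~53%
        "red_meat_lognorm": (np.log(50.0), 0.5),
        "legumes_lognorm": (np.log(80.0), 0.7),
        "fish_zero_prob": 0.40,
        "fish_lognorm": (np.log(150.0), 0.8),
        "tea_zero_prob": 0.55,
        "tea_lognorm": (np.log(6.0), 0.8),
        # blood pressure / glucose / lipids (mg/dL) and medication use
        "sbp_mean_sd": (130.0, 20.0),
        "dbp_resid_sd": 8.0,  # DBP = 40 + 0.3*SBP + N(0, sd)
        "prop_bp_med": 0.08,
        "glucose_lognorm": (np.log(98.0), 0.17),
        "prop_glucose_med": 0.02,
        "tc_mean_sd": (190.0, 35.0),
        "tg_lognorm": (np.log(120.0), 0.5),
        "ldl_mean_sd": (110.0, 30.0),
        "hdl_mean_sd": (52.0, 12.0),
        "prop_lipid_med": 0.02,
        "pack_years_gamma": (1.5, 10.0),  # smokers only
        "alcohol_g_gamma": (1.5, 15.0),  # drinkers only
    }


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic cohort; the seed fully determines output.

    ``effect_mode`` selects how the true genetic/fruit effects enter the
    log-hazard:

    - ``"continuous"``: per-SD effect of the standardized PRS (default),
      plus fruit-category effects;
    - ``"category"``: log-HR per genetic risk group and fruit group, plus an
      optional extra log-HR for the (high genetic) x (low fruit) cell;
    - ``"cells"``: an explicit 3x3 grid ``cell_log_hr[genetic, fruit]`` of
      log-hazards relative to the (low genetic, high fruit) reference cell.
    """

    n_participants: int = 35000
    n_snps: int = 534
    seed: int = 0
    allele_freq_range: tuple[float, float] = (0.05, 0.95)
    weight_sd: float = 0.05
    n_subcohorts: int = 3
    age_mean_sd: tuple[float, float] = (55.0, 10.0)
    prop_female: float = 0.58
    # fruit intake: zero-inflated lognormal, mean ~83 g/day with tertile
    # boundaries near 200/7 and 100 g/day
    fruit_zero_prob: float = 0.31
    fruit_lognorm: tuple[float, float] = (4.577, 0.670)
    covariate_params: dict = field(default_factory=default_covariate_params)

    effect_mode: str = "continuous"
    prs_log_hr_per_sd: float = 0.147
    true_hr_genetic: tuple[float, float] = (1.19, 1.51)  # intermediate, high vs low
    true_hr_fruit: tuple[float, float] = (0.81, 0.69)  # mid, high vs low intake
    true_log_interaction: float = 0.0  # extra log-HR for high-genetic x low-fruit
    cell_log_hr: tuple | None = None  # 3x3 grid, "cells" mode only
    age_log_hr: float = 0.06  # per year, centered at the age mean
    male_log_hr: float = 0.20

    weibull_shape: float = 1.0
    baseline_scale: float = DEFAULT_BASELINE_SCALE
    cohort_scale_multipliers: tuple[float, ...] = (0.80, 1.00, 1.25)
    admin_censor_years: tuple[float, float] = (10.0, 13.0)
    death_rate: float = 0.010  # per-year hazard of competing non-stroke death
    subtype_probs: tuple[float, ...] = field(default_factory=default_subtype_probs)

    # exclusion-cascade fixtures
    missing_fruit_n: int = 0
    prevalent_n: int = 0
    missing_followup_n: int = 0

    def validate(self) -> None:
        lo, hi = self.allele_freq_range
        if not (np.isfinite(lo) and np.isfinite(hi) and 0.0 < lo <= hi < 1.0):
            raise ValueError("allele_freq_range must lie inside the open interval (0, 1)")
        if self.weibull_shape <= 0 or self.baseline_scale <= 0:
            raise ValueError("Weibull shape and baseline scale must be strictly positive")
        if any(m <= 0 for m in self.cohort_scale_multipliers):
            raise ValueError("cohort scale multipliers must be strictly positive")
        if self.death_rate < 0:
            raise ValueError("death rate must be non-negative")
        if abs(sum(self.subtype_probs) - 1.0) > 1e-8 or min(self.subtype_probs) < 0:
            raise ValueError("subtype_probs must be a probability vector summing to 1")
        if self.effect_mode not in ("continuous", "category", "cells"):
            raise ValueError(f"unknown effect_mode {self.effect_mode!r}")
        if self.effect_mode == "cells" and np.shape(self.cell_log_hr) != (3, 3):
            raise ValueError("cells mode requires a 3x3 cell_log_hr grid")
        n_excl = self.missing_fruit_n + self.prevalent_n + self.missing_followup_n
        if n_excl > self.n_participants:
            raise ValueError(
                f"exclusion fixtures ({n_excl}) exceed n_participants ({self.n_participants})"
            )

    # --- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["covariate_params"] = {
            k: (list(v) if isinstance(v, tuple) else v) for k, v in d["covariate_params"].items()
        }
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(json.loads(json.dumps(self.to_dict(), default=list)), fh)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls.from_dict(d)

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        kw = dict(d)
        for k in (
            "allele_freq_range", "age_mean_sd", "fruit_lognorm", "true_hr_genetic",
            "true_hr_fruit", "cohort_scale_multipliers", "admin_censor_years",
            "subtype_probs",
        ):
            if k in kw and kw[k] is not None:
                kw[k] = tuple(kw[k])
        if kw.get("cell_log_hr") is not None:
            kw["cell_log_hr"] = tuple(tuple(row) for row in kw["cell_log_hr"])
        return cls(**kw)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _streams(config: GeneratorConfig) -> dict[str, np.random.Generator]:
    names = ["panel", "genotypes", "covariates", "fruit", "events", "exclusions"]
    children = np.random.SeedSequence(config.seed).spawn(len(names))
    return {n: np.random.default_rng(s) for n, s in zip(names, children)}


# ---------------------------------------------------------------------------
# SNP panel and genotypes
# ---------------------------------------------------------------------------

def generate_snp_panel(config: GeneratorConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Draw a SNP weight table: ids, risk alleles, frequencies and weights."""
    config.validate()
    lo, hi = config.allele_freq_range
    m = config.n_snps
    freqs = rng.uniform(lo, hi, size=m)
    alleles = rng.choice(list("ACGT"), size=(m, 2))
    # ensure ref != alt
    same = alleles[:, 0] == alleles[:, 1]
    alleles[same, 1] = np.array([{"A": "G", "C": "T", "G": "A", "T": "C"}[a] for a in alleles[same, 0]])
    weights = rng.normal(0.0, config.weight_sd, size=m)
    return pd.DataFrame(
        {
            "snp_id": [f"rs{100000 + i}" for i in range(m)],
            "risk_allele": alleles[:, 1],
            "allele_freq": freqs,
            "weight": weights,
        }
    )


def generate_genotypes(
    config: GeneratorConfig, panel: pd.DataFrame, rng: np.random.Generator | int | None = None
) -> pd.DataFrame:
    """Draw an (n_participants x n_snps) 0/1/2 matrix, each SNP independently
    Hardy-Weinberg: P(0,1,2) = ((1-p)^2, 2p(1-p), p^2) for risk-allele
    frequency p, i.e. Binomial(2, p)."""
    if rng is None or isinstance(rng, int):
        rng = _streams(dataclasses.replace(config, seed=rng if rng is not None else config.seed))["genotypes"]
    p = panel["allele_freq"].to_numpy(dtype=float)
    if not np.all(np.isfinite(p)):
        raise ValueError("non-finite allele frequency in panel")
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("allele frequency outside [0, 1]")
    g = rng.binomial(2, p, size=(config.n_participants, len(p))).astype(np.int8)
    return pd.DataFrame(g, columns=list(panel["snp_id"]))


# ---------------------------------------------------------------------------
# Covariates
# ---------------------------------------------------------------------------

def generate_covariates(config: GeneratorConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_participants
    cp = config.covariate_params
    age = rng.normal(*config.age_mean_sd, size=n).clip(35.0, 95.0)
    female = (rng.random(n) < config.prop_female).astype(int)
    hm = cp["height_mean_sd"]
    height = np.where(
        female == 1,
        rng.normal(*hm["female"], size=n),
        rng.normal(*hm["male"], size=n),
    ).clip(1.3, 2.1)
    bmi = rng.normal(*cp["bmi_mean_sd"], size=n).clip(14.0, 45.0)
    weight = bmi * height**2

    moderate = np.where(
        rng.random(n) < cp["moderate_zero_prob"], 0.0, rng.gamma(*cp["moderate_gamma"], size=n)
    )
    vigorous = np.where(
        rng.random(n) < cp["vigorous_zero_prob"], 0.0, rng.gamma(*cp["vigorous_gamma"], size=n)
    )

    smoker = (rng.random(n) < cp["prop_smoker"]).astype(int)
    alcohol = (rng.random(n) < cp["prop_alcohol"]).astype(int)

    sbp = rng.normal(*cp["sbp_mean_sd"], size=n).clip(80, 240)
    dbp = (40.0 + 0.3 * sbp + rng.normal(0, cp["dbp_resid_sd"], size=n)).clip(40, 140)

    df = pd.DataFrame(
        {
            "age": age,
            "female": female,
            "region_north": (rng.random(n) < cp["prop_north"]).astype(int),
            "urban": (rng.random(n) < cp["prop_urban"]).astype(int),
            "edu_high_school": (rng.random(n) < cp["prop_high_school"]).astype(int),
            "smoker": smoker,
            "alcohol_drinker": alcohol,
            "family_history_stroke": (rng.random(n) < cp["prop_family_history"]).astype(int),
            "pack_years": np.where(smoker == 1, rng.gamma(*cp["pack_years_gamma"], size=n), 0.0),
            "alcohol_g_day": np.where(alcohol == 1, rng.gamma(*cp["alcohol_g_gamma"], size=n), 0.0),
            "height_m": height,
            "weight_kg": weight,
            "moderate_min_wk": moderate,
            "vigorous_min_wk": vigorous,
            "vegetable_g_day": rng.normal(*cp["vegetable_mean_sd"], size=n).clip(0, None),
            "red_meat_g_day": rng.lognormal(*cp["red_meat_lognorm"], size=n),
            "legumes_g_day": rng.lognormal(*cp["legumes_lognorm"], size=n),
            "fish_g_week": np.where(
                rng.random(n) < cp["fish_zero_prob"], 0.0, rng.lognormal(*cp["fish_lognorm"], size=n)
            ),
            "tea_times_week": np.where(
                rng.random(n) < cp["tea_zero_prob"], 0.0, rng.lognormal(*cp["tea_lognorm"], size=n)
            ),
            "sbp": sbp,
            "dbp": dbp,
            "bp_med": (rng.random(n) < cp["prop_bp_med"]).astype(int),
            "glucose_mg_dl": rng.lognormal(*cp["glucose_lognorm"], size=n),
            "glucose_med": (rng.random(n) < cp["prop_glucose_med"]).astype(int),
            "total_chol_mg_dl": rng.normal(*cp["tc_mean_sd"], size=n).clip(80, None),
            "triglycerides_mg_dl": rng.lognormal(*cp["tg_lognorm"], size=n),
            "ldl_mg_dl": rng.normal(*cp["ldl_mean_sd"], size=n).clip(30, None),
            "hdl_mg_dl": rng.normal(*cp["hdl_mean_sd"], size=n).clip(10, None),
            "lipid_med": (rng.random(n) < cp["prop_lipid_med"]).astype(int),
        }
    )
    return df


def generate_fruit_intake(config: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    """Two-part fruit intake in g/day: a point mass of (near) never-consumers
    and a lognormal for the rest."""
    n = config.n_participants
    zero = rng.random(n) < config.fruit_zero_prob
    mu, sigma = config.fruit_lognorm
    x = rng.lognormal(mu, sigma, size=n)
    x[zero] = 0.0
    return x


# ---------------------------------------------------------------------------
# True linear predictor and event times
# ---------------------------------------------------------------------------

def true_linear_predictor(
    config: GeneratorConfig,
    covariates: pd.DataFrame,
    prs_std: np.ndarray,
    genetic_group_codes: np.ndarray,
    fruit_group_codes: np.ndarray,
) -> np.ndarray:
    """Log relative hazard per participant under the configured truth.

    Covariate (age, sex) effects are always included; the genetic/fruit part
    depends on ``effect_mode``.  Group codes: 0=low, 1=intermediate/mid,
    2=high for both factors (fruit code 2 = intake > 100 g/day).
    """
    eta = config.age_log_hr * (covariates["age"].to_numpy() - config.age_mean_sd[0])
    eta = eta + config.male_log_hr * (1 - covariates["female"].to_numpy())
    g, f = genetic_group_codes, fruit_group_codes
    if config.effect_mode == "continuous":
        eta = eta + config.prs_log_hr_per_sd * prs_std
        log_hr_fruit = np.array([0.0, *np.log(config.true_hr_fruit)])
        eta = eta + log_hr_fruit[f]
    elif config.effect_mode == "category":
        log_hr_gen = np.array([0.0, *np.log(config.true_hr_genetic)])
        log_hr_fruit = np.array([0.0, *np.log(config.true_hr_fruit)])
        eta = eta + log_hr_gen[g] + log_hr_fruit[f]
        if config.true_log_interaction != 0.0:
            eta = eta + config.true_log_interaction * ((g == 2) & (f == 0))
    else:  # cells
        grid = np.asarray(config.cell_log_hr, dtype=float)
        eta = eta + grid[g, f]
    return eta


def generate_event_times(
    config: GeneratorConfig,
    linear_predictor: np.ndarray,
    subcohort: np.ndarray,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Draw (followup_years, event, death, subtype) per participant.

    The latent stroke time follows a Weibull proportional-hazards model with
    per-subcohort baseline cumulative hazard ``scale_s * t^shape`` times
    ``exp(eta)`` (inverse-transform sampling); competing non-stroke death is
    exponential; administrative censoring is uniform on the configured
    window.  The observed time is the minimum of the three.
    """
    config.validate()
    eta = np.asarray(linear_predictor, dtype=float)
    if not np.all(np.isfinite(eta)):
        raise ValueError("non-finite linear predictor")
    n = eta.size
    k = config.weibull_shape
    mult = np.asarray(config.cohort_scale_multipliers, dtype=float)
    scale = config.baseline_scale * mult[subcohort]
    u = rng.random(n)
    # P(T > t) = exp(-scale * t^k * e^eta)  =>  T = (-ln U / (scale e^eta))^(1/k)
    t_stroke = (-np.log(u) / (scale * np.exp(eta))) ** (1.0 / k)
    if config.death_rate > 0:
        t_death = rng.exponential(1.0 / config.death_rate, size=n)
    else:
        t_death = np.full(n, np.inf)
    t_censor = rng.uniform(*config.admin_censor_years, size=n)
    t_obs = np.minimum(np.minimum(t_stroke, t_death), t_censor)
    event = (t_obs == t_stroke).astype(int)
    death = ((t_obs == t_death) & (event == 0)).astype(int)
    subtype = np.full(n, "", dtype=object)
    n_ev = int(event.sum())
    if n_ev:
        subtype[event == 1] = rng.choice(SUBTYPE_CATEGORIES, size=n_ev, p=config.subtype_probs)
    return pd.DataFrame(
        {"followup_years": t_obs, "event": event, "death": death, "event_subtype": subtype}
    )


# ---------------------------------------------------------------------------
# Full cohort assembly
# ---------------------------------------------------------------------------

def generate_cohort(config: GeneratorConfig):
    """Generate a full raw cohort with ground truth.

    Returns
    -------
    (raw_table, genotypes, panel) where ``raw_table`` carries all covariates,
    follow-up data, exclusion-fixture flags and the ``true_linear_predictor``
    column kept for oracle tests (dropped on export).
    """
    config.validate()
    streams = _streams(config)
    panel = generate_snp_panel(config, streams["panel"])
    genotypes = generate_genotypes(config, panel, streams["genotypes"])
    cov = generate_covariates(config, streams["covariates"])
    fruit = generate_fruit_intake(config, streams["fruit"])

    score = prs_mod.compute_prs(genotypes, panel)
    genetic_group = prs_mod.assign_genetic_groups(score["prs_raw"].to_numpy())
    fruit_group = derive_fruit_group(fruit)

    n = config.n_participants
    ev_rng = streams["events"]
    subcohort = ev_rng.integers(0, config.n_subcohorts, size=n)
    eta = true_linear_predictor(
        config, cov, score["prs_std"].to_numpy(), np.asarray(genetic_group.codes),
        np.asarray(fruit_group.codes),
    )
    times = generate_event_times(config, eta, subcohort, ev_rng)

    raw = pd.concat(
        [
            pd.DataFrame(
                {
                    "participant_id": [f"P{i:06d}" for i in range(n)],
                    "subcohort": subcohort + 1,
                }
            ),
            cov,
            pd.DataFrame({"fruit_g_day": fruit, "prevalent_disease": np.zeros(n, dtype=int)}),
            times,
            pd.DataFrame({"true_linear_predictor": eta}),
        ],
        axis=1,
    )
    raw = inject_exclusion_fixtures(raw, config, streams["exclusions"])
    genotypes = genotypes.set_axis(raw["participant_id"], axis=0)
    return raw, genotypes, panel


def inject_exclusion_fixtures(
    table: pd.DataFrame, config: GeneratorConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Flag disjoint participant sets for the exclusion cascade, in order of
    precedence: missing fruit intake, prevalent disease, missing follow-up."""
    n_req = config.missing_fruit_n + config.prevalent_n + config.missing_followup_n
    if n_req > len(table):
        raise ValueError("exclusion fixture request exceeds table size")
    if n_req == 0:
        return table
    if rng is None:
        rng = _streams(config)["exclusions"]
    table = table.copy()
    idx = rng.permutation(len(table))[:n_req]
    a = config.missing_fruit_n
    b = a + config.prevalent_n
    table.iloc[idx[:a], table.columns.get_loc("fruit_g_day")] = np.nan
    table.iloc[idx[a:b], table.columns.get_loc("prevalent_disease")] = 1
    table.iloc[idx[b:], table.columns.get_loc("followup_years")] = np.nan
    return table


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

def crude_incidence_per_1000py(table: pd.DataFrame) -> float:
    """Events per 1000 person-years on rows with observed follow-up."""
    ok = table["followup_years"].notna()
    py = table.loc[ok, "followup_years"].sum()
    if py <= 0:
        raise ValueError("no person-years observed")
    return 1000.0 * table.loc[ok, "event"].sum() / py


def calibrate_baseline_scale(
    config: GeneratorConfig,
    target_rate: float = TARGET_INCIDENCE_PER_1000PY,
    rel_tol: float = 0.05,
    n_calibration: int = 20000,
    bracket: tuple[float, float] = (1e-5, 0.2),
    max_iter: int = 60,
) -> GeneratorConfig:
    """Bisect the baseline Weibull scale until the generated crude incidence
    is within ``rel_tol`` (relative) of ``target_rate`` per 1000 PY.

    Uses a fixed-size calibration cohort regenerated with the same seed at
    every evaluation (common random numbers), which makes the achieved rate
    monotone in the scale and the search deterministic.
    """
    if target_rate <= 0:
        raise ValueError("target rate must be positive")
    calib = dataclasses.replace(
        config, n_participants=n_calibration,
        missing_fruit_n=0, prevalent_n=0, missing_followup_n=0,
    )

    def rate_at(scale: float) -> float:
        c = dataclasses.replace(calib, baseline_scale=scale)
        raw, _, _ = generate_cohort(c)
        return crude_incidence_per_1000py(raw)

    lo, hi = bracket
    r_lo, r_hi = rate_at(lo), rate_at(hi)
    if not (r_lo <= target_rate <= r_hi):
        raise ValueError(
            f"bracket does not contain target: achieved rate range "
            f"[{r_lo:.3f}, {r_hi:.3f}] per 1000 PY vs target {target_rate}"
        )
    r_cur = rate_at(config.baseline_scale)
    if abs(r_cur - target_rate) <= rel_tol * target_rate:
        return config  # already within tolerance
    for _ in range(max_iter):
        mid = np.sqrt(lo * hi)  # bisect in log space
        r_mid = rate_at(mid)
        if abs(r_mid - target_rate) <= 0.2 * rel_tol * target_rate:
            break
        if r_mid < target_rate:
            lo = mid
        else:
            hi = mid
    return dataclasses.replace(config, baseline_scale=float(mid))


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def export_cohort_csv(raw: pd.DataFrame, path) -> None:
    """Write the cohort table (ground-truth column dropped) as UTF-8 CSV."""
    raw.drop(columns=["true_linear_predictor"], errors="ignore").to_csv(path, index=False)


def export_genotypes_csv(genotypes: pd.DataFrame, path) -> None:
    genotypes.to_csv(path, index_label="participant_id")


def export_panel_csv(panel: pd.DataFrame, path) -> None:
    panel.to_csv(path, index=False)


def export_vcf(genotypes: pd.DataFrame, panel: pd.DataFrame, path) -> None:
    """Minimal VCFv4.2 export, GT field only, one record per SNP."""
    samples = list(genotypes.index)
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        g = genotypes.to_numpy()
        for j, row in enumerate(panel.itertuples(index=False)):
            ref = "A" if row.risk_allele != "A" else "C"
            calls = "\t".join(gt_map[int(v)] for v in g[:, j])
            fh.write(f"1\t{j + 1}\t{row.snp_id}\t{ref}\t{row.risk_allele}\t.\tPASS\t.\tGT\t{calls}\n")
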