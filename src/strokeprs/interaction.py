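"""Joint genetic-risk x fruit-intake effects and interaction measures.

Covers the 3x3 joint hazard-ratio grid (reference: low genetic risk with
fruit intake > 100 g/day), the multiplicative interaction test (product term
between the extreme fruit and genetic categories), additive interaction via
RERI (relative excess risk due to interaction, ``HR11 - HR10 - HR01 + 1``)
and AP (attributable proportion, ``RERI / HR11``) with delta-method and
bootstrap confidence intervals, and a per-SNP x fruit additive-interaction
scan with Bonferroni correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cox import FULL_TIER, BASE_TIER_FRUIT, fit_stratified_cox, hazard_ratios
from .prep import FRUIT_GROUPS
from .prs import GENETIC_GROUPS

JOINT_REFERENCE = ("low", "high")  # (genetic group, fruit group)


def cell_columns(reference=JOINT_REFERENCE) -> list[str]:
    return [
        f"cell_{g}_{f}"
        for g in GENETIC_GROUPS
        for f in FRUIT_GROUPS
        if (g, f) != reference
    ]


def add_cell_indicators(cohort: pd.DataFrame, reference=JOINT_REFERENCE) -> pd.DataFrame:
    """Add 8 genetic x fruit cell indicator columns (reference cell omitted)."""
    work = cohort.copy()
    for g in GENETIC_GROUPS:
        for f in FRUIT_GROUPS:
            if (g, f) == reference:
                continue
            work[f"cell_{g}_{f}"] = (
                (work["genetic_group"] == g) & (work["fruit_group"] == f)
            ).astype(int)
    return work


def joint_hr_grid(
    cohort: pd.DataFrame,
    adjust: list[str] = FULL_TIER,
    reference=JOINT_REFERENCE,
    strata_col: str = "subcohort",
) -> dict:
    """Single stratified Cox fit with the 8 cell indicators + full-tier
    adjustment; returns the 9-cell grid of HRs (reference HR = 1) and the fit."""
    work = add_cell_indicators(cohort, reference)
    cols = cell_columns(reference)
    fit = fit_stratified_cox(work, cols + list(adjust), strata_col=strata_col)
    hr = hazard_ratios(fit)
    rows = []
    for g in GENETIC_GROUPS:
        for f in FRUIT_GROUPS:
            mask = (work["genetic_group"] == g) & (work["fruit_group"] == f)
            row = {
                "genetic_group": g,
                "fruit_group": f,
                "n": int(mask.sum()),
                "events": int(work.loc[mask, "event"].sum()),
            }
            if (g, f) == reference:
                row.update(hr=1.0, ci_lower=np.nan, ci_upper=np.nan, p=np.nan)
            else:
                r = hr.loc[f"cell_{g}_{f}"]
                row.update(hr=r["hr"], ci_lower=r["ci_lower"], ci_upper=r["ci_upper"], p=r["p"])
            rows.append(row)
    return {"grid": pd.DataFrame(rows), "fit": fit, "reference": reference}


def multiplicative_interaction(
    cohort: pd.DataFrame,
    adjust: list[str] = FULL_TIER,
    strata_col: str = "subcohort",
) -> dict:
    """Wald test of the product term between fruit intake (<200 g/week vs
    >100 g/day) and genetic risk (low vs high), restricted to the four
    extreme cells' participants, with full-tier adjustment."""
    sub = cohort[
        cohort["genetic_group"].isin(["low", "high"])
        & cohort["fruit_group"].isin(["low", "high"])
    ].copy()
    sub["gen_high"] = (sub["genetic_group"] == "high").astype(int)
    sub["fruit_low_cat"] = (sub["fruit_group"] == "low").astype(int)
    sub["product"] = sub["gen_high"] * sub["fruit_low_cat"]
    fit = fit_stratified_cox(
        sub, ["gen_high", "fruit_low_cat", "product"] + list(adjust), strata_col=strata_col
    )
    hr = hazard_ratios(fit)
    return {
        "p": float(hr.loc["product", "p"]),
        "hr_product": float(hr.loc["product", "hr"]),
        "fit": fit,
        "n": len(sub),
    }


def reri_ap_from_hrs(hr10: float, hr01: float, hr11: float) -> tuple[float, float]:
    """The definitional identities: RERI = HR11 - HR10 - HR01 + 1,
    AP = RERI / HR11."""
    reri = hr11 - hr10 - hr01 + 1.0
    return reri, reri / hr11


@dataclass
class AdditiveInteraction:
    reri: float
    ap: float
    hr10: float  # genetic exposed, fruit unexposed
    hr01: float  # genetic unexposed, fruit exposed (low intake)
    hr11: float  # doubly exposed
    reri_ci: tuple
    ap_ci: tuple
    p_additive: float
    coding: dict = field(default_factory=dict)
    reri_ci_boot: tuple | None = None
    ap_ci_boot: tuple | None = None
    n_bootstrap: int = 0


def reri_ap(
    cohort: pd.DataFrame,
    genetic_coding: str = "high_vs_low",
    adjust: list[str] = FULL_TIER,
    strata_col: str = "subcohort",
    n_bootstrap: int = 0,
    seed: int = 0,
) -> AdditiveInteraction:
    """Additive interaction between dichotomized fruit intake (<200 g/week =
    exposed, >=200 g/week = reference) and genetic risk.

    ``genetic_coding``: ``"high_vs_low"`` (top vs bottom PRS quintile,
    intermediate participants dropped, the default) or ``"high_vs_rest"``
    (top quintile vs quintiles 1-4).  Delta-method CIs use the full 3x3
    block of the fitted covariance of the three log-HRs; the optional
    bootstrap resamples participants stratified by sub-cohort.
    """
    if genetic_coding == "high_vs_low":
        sub = cohort[cohort["genetic_group"].isin(["low", "high"])].copy()
        gen = (sub["genetic_group"] == "high").to_numpy()
    elif genetic_coding == "high_vs_rest":
        sub = cohort.copy()
        gen = (sub["genetic_group"] == "high").to_numpy()
    else:
        raise ValueError(f"unknown genetic coding {genetic_coding!r}")
    fruit_low = (sub["fruit_group"] == "low").to_numpy()
    sub["i10"] = (gen & ~fruit_low).astype(int)
    sub["i01"] = (~gen & fruit_low).astype(int)
    sub["i11"] = (gen & fruit_low).astype(int)
    cells = {
        "reference (genetic-, fruit>=200g/wk)": (~gen & ~fruit_low),
        "genetic+ / fruit>=200g/wk": (gen & ~fruit_low),
        "genetic- / fruit<200g/wk": (~gen & fruit_low),
        "genetic+ / fruit<200g/wk": (gen & fruit_low),
    }
    for name, mask in cells.items():
        if sub.loc[mask, "event"].sum() < 1:
            raise ValueError(f"additive-interaction cell not estimable (no events): {name}")

    def estimate(data):
        fit = fit_stratified_cox(data, ["i10", "i01", "i11"] + list(adjust), strata_col=strata_col)
        b = fit.params[["i10", "i01", "i11"]].to_numpy()
        V = fit.covariance.loc[["i10", "i01", "i11"], ["i10", "i01", "i11"]].to_numpy()
        return b, V

    b, V = estimate(sub)
    hr10, hr01, hr11 = np.exp(b)
    reri, ap = reri_ap_from_hrs(hr10, hr01, hr11)
    # delta method on theta = (b10, b01, b11)
    g_reri = np.array([-hr10, -hr01, hr11])
    se_reri = float(np.sqrt(g_reri @ V @ g_reri))
    g_ap = np.array([-hr10 / hr11, -hr01 / hr11, (hr10 + hr01 - 1.0) / hr11])
    se_ap = float(np.sqrt(g_ap @ V @ g_ap))
    z = 1.959963984540054
    out = AdditiveInteraction(
        reri=float(reri),
        ap=float(ap),
        hr10=float(hr10),
        hr01=float(hr01),
        hr11=float(hr11),
        reri_ci=(reri - z * se_reri, reri + z * se_reri),
        ap_ci=(ap - z * se_ap, ap + z * se_ap),
        p_additive=float(2 * stats.norm.sf(abs(reri) / se_reri)) if se_reri > 0 else np.nan,
        coding={
            "genetic": genetic_coding,
            "fruit": "low (<200 g/week) vs reference (>=200 g/week)",
        },
    )
    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        reris, aps = [], []
        groups = [np.asarray(v) for v in sub.groupby(strata_col, observed=True).indices.values()]
        for _ in range(n_bootstrap):
            take = np.concatenate([rng.choice(g, size=len(g), replace=True) for g in groups])
            boot = sub.iloc[take]
            try:
                bb, _ = estimate(boot)
            except Exception:
                continue
            h10, h01, h11 = np.exp(bb)
            r, a = reri_ap_from_hrs(h10, h01, h11)
            reris.append(r)
            aps.append(a)
        if len(reris) < 0.95 * n_bootstrap:
            raise RuntimeError(
                f"too many bootstrap replicates failed ({n_bootstrap - len(reris)}/{n_bootstrap})"
            )
        out.reri_ci_boot = tuple(np.percentile(reris, [2.5, 97.5]))
        out.ap_ci_boot = tuple(np.percentile(aps, [2.5, 97.5]))
        out.n_bootstrap = n_bootstrap
    return out


def snp_by_fruit_scan(
    cohort: pd.DataFrame,
    genotypes: pd.DataFrame,
    panel: pd.DataFrame,
    adjust: list[str] = BASE_TIER_FRUIT,
    strata_col: str = "subcohort",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-SNP additive-interaction scan: for each SNP, the per-allele
    genotype effect, the dichotomized low-fruit effect and their product are
    fitted jointly; RERI and its delta-method p-value are computed from
    ``(HR10, HR01, HR11) = (e^{bg}, e^{bf}, e^{bg+bf+bint})``.  The
    Bonferroni threshold is ``alpha / n_snps``."""
    n_snps = len(panel)
    threshold = alpha / n_snps
    work = cohort.copy()
    work["fruit_low_cat"] = (work["fruit_group"] == "low").astype(int)
    geno = genotypes.loc[work["participant_id"]]
    rows = []
    for snp in panel["snp_id"]:
        work["_g"] = geno[snp].to_numpy(dtype=float)
        work["_gx"] = work["_g"] * work["fruit_low_cat"]
        fit = fit_stratified_cox(
            work, ["_g", "fruit_low_cat", "_gx"] + list(adjust), strata_col=strata_col
        )
        bg, bf, bi = fit.params[["_g", "fruit_low_cat", "_gx"]].to_numpy()
        V = fit.covariance.loc[["_g", "fruit_low_cat", "_gx"], ["_g", "fruit_low_cat", "_gx"]].to_numpy()
        h10, h01, h11 = np.exp(bg), np.exp(bf), np.exp(bg + bf + bi)
        reri, _ = reri_ap_from_hrs(h10, h01, h11)
        # gradient wrt (bg, bf, bint)
        grad = np.array([h11 - h10, h11 - h01, h11])
        se = float(np.sqrt(grad @ V @ grad))
        p = float(2 * stats.norm.sf(abs(reri) / se)) if se > 0 else np.nan
        rows.append({"snp_id": snp, "reri": float(reri), "se": se, "p": p})
    res = pd.DataFrame(rows)
    res["bonferroni_threshold"] = threshold
    res["bonferroni_significant"] = res["p"] < threshold
    return res
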