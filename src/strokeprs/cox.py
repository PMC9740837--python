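"""Stratified Cox proportional-hazards engine and diagnostics.

Implements the stratified partial likelihood with Breslow tie handling and
optional left truncation (delayed entry, for age-as-timescale models),
maximized by Newton-Raphson with step-halving.  Also provides the Breslow
per-stratum baseline cumulative hazard, a Grambsch-Therneau scaled-Schoenfeld
test of the proportional-hazards assumption, restricted-cubic-spline
dose-response curves, category-median trend tests, and Poisson-model
covariate-adjusted incidence rates.

The two standard adjustment tiers are exposed as module constants: the base
tier is age + sex for genetic analyses and additionally region, urbanization
and education for fruit-intake analyses; the full tier further adds smoking,
alcohol, physical activity, BMI, diet score and the daily-vegetable flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

BASE_TIER_GENETIC = ["age", "female"]
BASE_TIER_FRUIT = ["age", "female", "region_north", "urban", "edu_high_school"]
FULL_TIER_EXTRA = [
    "smoker", "alcohol_drinker", "physical_activity_min_wk", "bmi",
    "diet_score", "vegetable_daily_500",
]
FULL_TIER = BASE_TIER_FRUIT + FULL_TIER_EXTRA


class ConvergenceError(RuntimeError):
    """Newton-Raphson failed to converge; carries the iteration trace."""

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace or []


class SeparationError(RuntimeError):
    """Monotone partial likelihood (|beta| diverging beyond 20)."""


@dataclass
class CoxFit:
    """A fitted stratified Cox model with Breslow baseline hazards."""

    params: pd.Series
    covariance: pd.DataFrame
    log_likelihood: float
    n: int
    n_events: int
    baseline: dict  # stratum -> DataFrame(time, cumhaz)
    covariates: list
    duration_col: str
    event_col: str
    entry_col: str | None = None
    strata_col: str | None = None
    n_iter: int = 0
    final_grad_norm: float = np.nan
    stratum_sizes: dict = field(default_factory=dict)

    def linear_predictor(self, df: pd.DataFrame) -> np.ndarray:
        X = df[self.covariates].to_numpy(dtype=float)
        return X @ self.params.to_numpy()

    def cumhaz_at(self, stratum, times) -> np.ndarray:
        """Breslow cumulative baseline hazard, step-interpolated (flat
        carry-forward beyond the last event time; 0 before the first)."""
        bl = self.baseline[stratum]
        t = np.atleast_1d(np.asarray(times, dtype=float))
        idx = np.searchsorted(bl["time"].to_numpy(), t, side="right") - 1
        ch = np.concatenate([[0.0], bl["cumhaz"].to_numpy()])
        return ch[idx + 1]

    def last_event_time(self, stratum) -> float:
        return float(self.baseline[stratum]["time"].iloc[-1])


def _risk_set_sums(t_exit, t_entry, w, wx, wxx, query):
    """Suffix sums of (w, w*x, w*x*x') over the risk set {entry < t <= exit}
    at each query time, via sorted cumulative sums."""

    def suffix(values, keys, q):
        order = np.argsort(keys, kind="stable")
        cs = np.cumsum(values[order], axis=0)
        pos = np.searchsorted(keys[order], q, side="left")
        before = np.zeros((len(q),) + values.shape[1:])
        nz = pos > 0
        before[nz] = cs[pos[nz] - 1]
        return cs[-1] - before

    s0 = suffix(w, t_exit, query)
    s1 = suffix(wx, t_exit, query)
    s2 = suffix(wxx, t_exit, query)
    if t_entry is not None:
        s0 = s0 - suffix(w, t_entry, query)
        s1 = s1 - suffix(wx, t_entry, query)
        s2 = s2 - suffix(wxx, t_entry, query)
    return s0, s1, s2


def _stratum_blocks(df, covariates, duration_col, event_col, entry_col, strata_col):
    if strata_col is None:
        groups = [("_all", df)]
    else:
        groups = list(df.groupby(strata_col, observed=True))
    blocks = []
    for key, sub in groups:
        t = sub[duration_col].to_numpy(dtype=float)
        d = sub[event_col].to_numpy(dtype=int)
        e = sub[entry_col].to_numpy(dtype=float) if entry_col else None
        X = sub[covariates].to_numpy(dtype=float)
        if np.isnan(X).any() or np.isnan(t).any():
            raise ValueError("missing values in covariates or durations")
        if e is not None and np.any(e >= t):
            raise ValueError("entry time must be strictly before exit time")
        if d.sum() < 1:
            raise ValueError(f"stratum {key!r} has no events")
        blocks.append((key, t, d, e, X))
    return blocks


def _stratum_loglik(t, d, e, X, beta, want_resid=False):
    """Breslow log partial likelihood, score and information for one stratum."""
    eta = X @ beta
    w = np.exp(eta)
    wx = X * w[:, None]
    wxx = X[:, :, None] * X[:, None, :] * w[:, None, None]
    ev = d == 1
    times, counts = np.unique(t[ev], return_counts=True)
    s0, s1, s2 = _risk_set_sums(t, e, w, wx, wxx, times)
    dk = counts.astype(float)
    xbar = s1 / s0[:, None]
    ll = eta[ev].sum() - (dk * np.log(s0)).sum()
    score = X[ev].sum(axis=0) - (dk[:, None] * xbar).sum(axis=0)
    info = (dk[:, None, None] * (s2 / s0[:, None, None]
            - xbar[:, :, None] * xbar[:, None, :])).sum(axis=0)
    out = {"ll": ll, "score": score, "info": info,
           "event_times": times, "dk": dk, "s0": s0}
    if want_resid:
        # individual Schoenfeld residuals: x_i - xbar(t_i) at each event
        pos = np.searchsorted(times, t[ev])
        out["schoenfeld"] = X[ev] - xbar[pos]
        out["schoenfeld_times"] = t[ev]
    return out


def fit_stratified_cox(
    df: pd.DataFrame,
    covariates: list[str],
    duration_col: str = "followup_years",
    event_col: str = "event",
    strata_col: str | None = "subcohort",
    entry_col: str | None = None,
    max_iter: int = 50,
    score_tol: float = 1e-8,
    ll_rel_tol: float = 1e-10,
) -> CoxFit:
    """Maximize the stratified Breslow partial likelihood by Newton-Raphson.

    Covariate columns are centered internally for conditioning; reported
    coefficients, covariance and baseline hazards are on the original scale
    (the baseline refers to all covariates at zero).
    """
    if not covariates:
        raise ValueError("at least one covariate required")
    if strata_col in covariates:
        raise ValueError("strata variable cannot also be a covariate")
    blocks = _stratum_blocks(df, covariates, duration_col, event_col, entry_col, strata_col)
    p = len(covariates)
    xmean = df[covariates].to_numpy(dtype=float).mean(axis=0)
    cblocks = [(k, t, d, e, X - xmean) for k, t, d, e, X in blocks]
    for _, _, _, _, Xc in cblocks:
        if np.any(Xc.std(axis=0) == 0) and len(cblocks) == 1:
            pass  # constant covariate: beta stays 0, information singular handled below
    beta = np.zeros(p)
    trace = []
    ll_old = -np.inf
    for it in range(1, max_iter + 1):
        agg = [_stratum_loglik(t, d, e, X, beta) for _, t, d, e, X in cblocks]
        ll = sum(a["ll"] for a in agg)
        score = sum(a["score"] for a in agg)
        info = sum(a["info"] for a in agg)
        gnorm = float(np.max(np.abs(score)))
        trace.append({"iter": it, "loglik": ll, "max_score": gnorm})
        if np.max(np.abs(beta)) > 20:
            raise SeparationError(
                f"diverging coefficients (max |beta| = {np.max(np.abs(beta)):.2f} > 20): "
                "monotone likelihood / separation suspected"
            )
        converged = gnorm < score_tol or (
            np.isfinite(ll_old) and abs(ll - ll_old) <= ll_rel_tol * max(abs(ll), 1.0)
        )
        if converged:
            break
        # Newton step with ridge fallback for singular information
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            step = np.linalg.solve(info + 1e-10 * np.eye(p), score)
        # step-halving if the likelihood would decrease
        factor = 1.0
        for _ in range(20):
            cand = beta + factor * step
            ll_new = sum(
                _stratum_loglik(t, d, e, X, cand)["ll"] for _, t, d, e, X in cblocks
            )
            if ll_new >= ll - 1e-12:
                break
            factor /= 2.0
        beta = beta + factor * step
        ll_old = ll
    else:
        raise ConvergenceError(
            f"Newton-Raphson did not converge in {max_iter} iterations "
            f"(final max |score| = {gnorm:.3e})", trace
        )
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(info)

    # Breslow baselines on the uncentered scale: increments dk / S0_uncentered
    shift = float(np.exp(xmean @ beta))
    baseline, sizes = {}, {}
    n_events = 0
    for (key, t, d, e, X), a in zip(blocks, agg):
        inc = a["dk"] / (a["s0"] * shift)
        baseline[key] = pd.DataFrame({"time": a["event_times"], "cumhaz": np.cumsum(inc)})
        sizes[key] = len(t)
        n_events += int(d.sum())
    return CoxFit(
        params=pd.Series(beta, index=covariates),
        covariance=pd.DataFrame(cov, index=covariates, columns=covariates),
        log_likelihood=float(ll),
        n=len(df),
        n_events=n_events,
        baseline=baseline,
        covariates=list(covariates),
        duration_col=duration_col,
        event_col=event_col,
        entry_col=entry_col,
        strata_col=strata_col,
        n_iter=it,
        final_grad_norm=gnorm,
        stratum_sizes=sizes,
    )


def hazard_ratios(fit: CoxFit, alpha: float = 0.05) -> pd.DataFrame:
    """HRs with Wald confidence intervals, exp(beta +/- z * SE)."""
    se = np.sqrt(np.diag(fit.covariance.to_numpy()))
    z = stats.norm.ppf(1 - alpha / 2)
    b = fit.params.to_numpy()
    return pd.DataFrame(
        {
            "coef": b,
            "se": se,
            "hr": np.exp(b),
            "ci_lower": np.exp(b - z * se),
            "ci_upper": np.exp(b + z * se),
            "p": 2 * stats.norm.sf(np.abs(b) / np.where(se > 0, se, np.inf)),
        },
        index=fit.params.index,
    )


# ---------------------------------------------------------------------------
# Proportional-hazards diagnostics
# ---------------------------------------------------------------------------

def schoenfeld_ph_test(fit: CoxFit, df: pd.DataFrame) -> pd.DataFrame:
    """Grambsch-Therneau test on scaled Schoenfeld residuals vs event time.

    Returns one row per covariate plus a 'GLOBAL' row (score-type chi-square
    with the average-information approximation, as in standard software).
    """
    if not fit.covariates:
        raise ValueError("PH test undefined for a model with no covariates")
    blocks = _stratum_blocks(
        df, fit.covariates, fit.duration_col, fit.event_col, fit.entry_col, fit.strata_col
    )
    xmean = df[fit.covariates].to_numpy(dtype=float).mean(axis=0)
    beta = fit.params.to_numpy()
    resid, times = [], []
    for _, t, d, e, X in blocks:
        a = _stratum_loglik(t, d, e, X - xmean, beta, want_resid=True)
        resid.append(a["schoenfeld"])
        times.append(a["schoenfeld_times"])
    s = np.vstack(resid)
    g = np.concatenate(times)
    d_tot = s.shape[0]
    gc = g - g.mean()
    gss = float((gc**2).sum())
    u = gc @ s  # p-vector
    V = fit.covariance.to_numpy()  # = I^{-1}
    rows = []
    vu = V @ u
    for j, name in enumerate(fit.covariates):
        chi2 = d_tot * vu[j] ** 2 / (V[j, j] * gss)
        rows.append({"covariate": name, "chi2": chi2, "df": 1, "p": stats.chi2.sf(chi2, 1)})
    chi2_g = d_tot * float(u @ vu) / gss
    p_dim = len(fit.covariates)
    rows.append({"covariate": "GLOBAL", "chi2": chi2_g, "df": p_dim,
                 "p": stats.chi2.sf(chi2_g, p_dim)})
    return pd.DataFrame(rows).set_index("covariate")


# ---------------------------------------------------------------------------
# Restricted cubic splines
# ---------------------------------------------------------------------------

def rcs_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Restricted cubic spline basis with 3 knots: columns [x, C(x)].

    The nonlinear term C is the standard normalized truncated-power basis
    (linear beyond the boundary knots, continuous second derivatives).
    """
    k1, k2, k3 = knots
    if not k1 < k2 < k3:
        raise ValueError("knots must be strictly increasing")

    def pos3(v):
        return np.maximum(v, 0.0) ** 3

    c = (
        pos3(x - k1)
        - pos3(x - k2) * (k3 - k1) / (k3 - k2)
        + pos3(x - k3) * (k2 - k1) / (k3 - k2)
    ) / (k3 - k1) ** 2
    return np.column_stack([x, c])


def rcs_dose_response(
    df: pd.DataFrame,
    exposure: str,
    adjust: list[str],
    duration_col: str = "followup_years",
    event_col: str = "event",
    strata_col: str | None = "subcohort",
    n_grid: int = 101,
) -> dict:
    """Spline dose-response: 3 knots at the 25th/50th/75th percentiles, the
    median as the HR reference.  Returns p_overall (Wald on both spline
    coefficients), p_nonlinear (Wald on the nonlinear one) and the HR curve."""
    x = df[exposure].to_numpy(dtype=float)
    knots = np.quantile(x, [0.25, 0.50, 0.75])
    basis = rcs_basis(x, knots)
    work = df.copy()
    s_lin, s_nl = f"{exposure}_rcs1", f"{exposure}_rcs2"
    work[s_lin], work[s_nl] = basis[:, 0], basis[:, 1]
    fit = fit_stratified_cox(
        work, [s_lin, s_nl] + list(adjust), duration_col, event_col, strata_col
    )
    idx = [fit.covariates.index(s_lin), fit.covariates.index(s_nl)]
    b = fit.params.to_numpy()[idx]
    V = fit.covariance.to_numpy()[np.ix_(idx, idx)]
    chi2_overall = float(b @ np.linalg.solve(V, b))
    p_overall = stats.chi2.sf(chi2_overall, 2)
    chi2_nl = b[1] ** 2 / V[1, 1]
    p_nonlinear = stats.chi2.sf(chi2_nl, 1)
    grid = np.linspace(np.quantile(x, 0.01), np.quantile(x, 0.99), n_grid)
    gb = rcs_basis(grid, knots)
    rb = rcs_basis(np.array([knots[1]]), knots)
    log_hr = (gb - rb) @ b
    se = np.sqrt(np.einsum("ij,jk,ik->i", gb - rb, V, gb - rb))
    curve = pd.DataFrame(
        {
            exposure: grid,
            "hr": np.exp(log_hr),
            "ci_lower": np.exp(log_hr - 1.96 * se),
            "ci_upper": np.exp(log_hr + 1.96 * se),
        }
    )
    return {"p_overall": float(p_overall), "p_nonlinear": float(p_nonlinear),
            "knots": knots, "curve": curve, "fit": fit}


def trend_test(
    df: pd.DataFrame,
    group_col: str,
    exposure_col: str,
    adjust: list[str],
    duration_col: str = "followup_years",
    event_col: str = "event",
    strata_col: str | None = "subcohort",
) -> float:
    """Trend across ordered categories: each participant's exposure is
    replaced by the median of their category, entered as one continuous
    covariate; returns the Wald p-value."""
    work = df.copy()
    med = work.groupby(group_col, observed=True)[exposure_col].transform("median")
    work["_trend"] = med.astype(float)
    fit = fit_stratified_cox(work, ["_trend"] + list(adjust), duration_col, event_col, strata_col)
    return float(hazard_ratios(fit).loc["_trend", "p"])


# ---------------------------------------------------------------------------
# Poisson-adjusted incidence rates
# ---------------------------------------------------------------------------

def poisson_adjusted_rates(
    df: pd.DataFrame,
    group_col: str,
    duration_col: str = "followup_years",
    event_col: str = "event",
    adjust: list[str] = ("age", "female"),
    per: float = 1000.0,
) -> pd.DataFrame:
    """Covariate-adjusted incidence rates per ``per`` person-years from a
    log-linear Poisson model with a log person-time offset; each group's rate
    is predicted at the sample-mean adjustment covariates."""
    import statsmodels.api as sm

    groups = df[group_col].astype("category")
    dummies = pd.get_dummies(groups, prefix=group_col, dtype=float)
    X = pd.concat([dummies, df[list(adjust)].astype(float)], axis=1) if adjust else dummies
    y = df[event_col].to_numpy(dtype=float)
    offset = np.log(df[duration_col].to_numpy(dtype=float))
    model = sm.GLM(y, X.to_numpy(), family=sm.families.Poisson(), offset=offset)
    res = model.fit()
    rows = []
    means = df[list(adjust)].mean().to_numpy(dtype=float) if adjust else np.array([])
    for i, level in enumerate(dummies.columns):
        xv = np.zeros(X.shape[1])
        xv[i] = 1.0
        if adjust:
            xv[len(dummies.columns):] = means
        lin = float(xv @ res.params)
        se = float(np.sqrt(xv @ res.cov_params() @ xv))
        rows.append(
            {
                "group": level.replace(f"{group_col}_", "", 1),
                "rate": per * np.exp(lin),
                "ci_lower": per * np.exp(lin - 1.96 * se),
                "ci_upper": per * np.exp(lin + 1.96 * se),
            }
        )
    return pd.DataFrame(rows).set_index("group")
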