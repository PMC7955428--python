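"""Staged Cox proportional-hazards models for DistEn and mortality.

Model tiers nest a growing covariate roster around the exposure
(distribution entropy, standardized so hazard ratios are per 1-SD
*decrease*):

* **A** (core): age, sex, ethnicity, college education;
* **B**: A + deprivation score, BMI, smoking, alcohol, physical activity;
* **C**: B + cardiovascular risks/diseases (hypertension, cholesterol,
  peripheral vascular disease, diabetes, angina, prior MI, AF/arrhythmias);
* **D**: C + other comorbidities and medication count;
* **E**: D + autonomic measures (resting heart rate or mean RRI,
  log-RMSSD, mean arterial pressure).

Fits use the Efron approximation for tied event times (lifelines'
default).  Cause-specific mortality censors competing causes at the death
time.  The proportional-hazards assumption is checked with the global
scaled-Schoenfeld-residual chi-square test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.utils import concordance_index

TIER_COVARIATES: dict[str, list[str]] = {
    "A": ["age", "sex_male", "ethnicity_european", "education_college"],
    "B": ["tdi", "bmi", "smoking_former", "smoking_current", "alcohol_high", "physical_activity"],
    "C": ["hypertension", "cholesterol", "pvd", "diabetes", "angina", "mi", "af"],
    "D": [
        "cancer",
        "respiratory",
        "neurological",
        "psychiatric",
        "musculoskeletal",
        "gastrointestinal",
        "renal",
        "endocrine",
        "hematological",
        "n_medications",
    ],
    # tier E autonomic set is appended dynamically (HRV variable configurable)
}

_TIER_ORDER = ["A", "B", "C", "D", "E"]

OUTCOME_CAUSES = {"all_cause": None, "cvd": "cvd", "respiratory": "respiratory", "cancer": "cancer"}


def tier_covariates(tier: str, heart_rate_var: str = "rhr", hrv_var: str = "rmssd_log") -> list[str]:
    """Cumulative covariate roster for a model tier (nested A through E)."""
    if tier not in _TIER_ORDER:
        raise ValueError(f"tier must be one of {_TIER_ORDER}, got {tier!r}")
    cols: list[str] = []
    for t in _TIER_ORDER[: _TIER_ORDER.index(tier) + 1]:
        if t == "E":
            cols += [heart_rate_var, hrv_var, "map"]
        else:
            cols += TIER_COVARIATES[t]
    return cols


@dataclass(frozen=True)
class CoxSpec:
    tier: str = "A"
    outcome: str = "all_cause"
    exposure: str = "disten"
    per_sd_decrease: bool = True
    heart_rate_var: str = "rhr"
    hrv_var: str = "rmssd_log"
    compute_ph_test: bool = True

    def __post_init__(self) -> None:
        if self.outcome not in OUTCOME_CAUSES:
            raise ValueError(f"unknown outcome {self.outcome!r}")


@dataclass(frozen=True)
class CoxResult:
    hr_per_sd_decrease: float
    ci95: tuple[float, float]
    p_value: float
    concordance: float
    ph_global_chi2: float
    ph_p: float
    n: int
    n_events: int
    sd_used: float
    beta_per_unit: float
    tier: str
    outcome: str
    covariates: tuple[str, ...]


def standardize_exposure(
    cohort: pd.DataFrame, variable: str, sd: float | None = None
) -> tuple[pd.DataFrame, float]:
    """Append a z-scored column ``<variable>_z`` using the cohort SD.

    The recorded SD converts a per-unit log-hazard beta to the reported
    per-1-SD-decrease hazard ratio ``exp(-beta * sd)``.  Pass ``sd`` to
    standardize a subgroup on its parent cohort's scale, so subgroup HRs
    stay comparable.
    """
    if sd is None:
        sd = float(cohort[variable].std(ddof=0))
    if sd == 0.0 or not np.isfinite(sd):
        raise ValueError(f"variable {variable!r} has zero or undefined SD")
    out = cohort.copy()
    out[variable + "_z"] = (cohort[variable] - cohort[variable].mean()) / sd
    return out, sd


def _prepare_design(cohort: pd.DataFrame, spec: CoxSpec) -> tuple[pd.DataFrame, list[str]]:
    df = cohort.copy()
    if spec.hrv_var == "rmssd_log" and "rmssd_log" not in df.columns:
        df["rmssd_log"] = np.log(df["rmssd"])
    covs = tier_covariates(spec.tier, spec.heart_rate_var, spec.hrv_var)
    missing = [c for c in covs if c not in df.columns]
    if missing:
        raise ValueError(f"cohort lacks tier-{spec.tier} covariates: {missing}")
    cause = OUTCOME_CAUSES[spec.outcome]
    if cause is None:
        df["_event"] = df["event"].astype(int)
    else:
        # cause-specific hazard: competing causes censored at death time
        df["_event"] = ((df["event"] == 1) & (df["cause"] == cause)).astype(int)
    return df, covs


def _check_collinearity(df: pd.DataFrame, cols: list[str]) -> None:
    x = df[cols].to_numpy(dtype=float)
    x = x - x.mean(axis=0)
    rank = np.linalg.matrix_rank(x)
    if rank < len(cols):
        raise ValueError(
            f"design matrix is rank deficient ({rank} < {len(cols)}): "
            "exposure duplicates or is collinear with a covariate"
        )


def fit_cox(
    cohort: pd.DataFrame, spec: CoxSpec = CoxSpec(), exposure_sd: float | None = None
) -> CoxResult:
    """Fit one staged Cox model and report the HR per 1-SD decrease.

    Requires at least 10 events for the requested outcome.  Raises on a
    rank-deficient design (e.g. the exposure duplicating a covariate).
    ``exposure_sd`` fixes the standardization scale (used for subgroup
    fits reported on the parent cohort's SD).
    """
    df, covs = _prepare_design(cohort, spec)
    if int(df["_event"].sum()) < 10:
        raise ValueError(
            f"only {int(df['_event'].sum())} events for outcome {spec.outcome!r}; need >= 10"
        )
    df, sd_used = standardize_exposure(df, spec.exposure, exposure_sd)
    zcol = spec.exposure + "_z"
    model_cols = [zcol] + covs
    _check_collinearity(df, model_cols)

    fit_df = df[model_cols + ["followup", "_event"]]
    cph = _fit_cph(fit_df, "followup", "_event")  # Efron ties

    beta = float(cph.params_[zcol])
    se = float(cph.standard_errors_[zcol])
    p = float(cph.summary.loc[zcol, "p"])
    sign = -1.0 if spec.per_sd_decrease else 1.0
    hr = float(np.exp(sign * beta))
    lo, hi = sorted((float(np.exp(sign * (beta - 1.96 * se))), float(np.exp(sign * (beta + 1.96 * se)))))

    if spec.compute_ph_test:
        chi2, ph_p = ph_check(cph, fit_df)
    else:
        chi2, ph_p = float("nan"), float("nan")
    return CoxResult(
        hr_per_sd_decrease=hr,
        ci95=(lo, hi),
        p_value=p,
        concordance=float(cph.concordance_index_),
        ph_global_chi2=chi2,
        ph_p=ph_p,
        n=len(fit_df),
        n_events=int(fit_df["_event"].sum()),
        sd_used=sd_used,
        beta_per_unit=beta / sd_used,
        tier=spec.tier,
        outcome=spec.outcome,
        covariates=tuple(model_cols),
    )


def _fit_cph(fit_df: pd.DataFrame, duration_col: str, event_col: str) -> CoxPHFitter:
    """Newton-Raphson partial-likelihood fit with a tiny-ridge fallback.

    Sparse strata (few events, rare binary covariates) can put the
    unpenalized fit on a flat likelihood ridge; an L2 penalty of 1e-6 to
    1e-4 restores convergence with negligible shrinkage at these sample
    sizes.  Raises the original convergence diagnostic if all attempts
    fail.
    """
    from lifelines.exceptions import ConvergenceError

    last: Exception | None = None
    for penalizer in (0.0, 1e-6, 1e-4):
        try:
            cph = CoxPHFitter(penalizer=penalizer)
            cph.fit(fit_df, duration_col=duration_col, event_col=event_col)
            return cph
        except ConvergenceError as exc:
            last = exc
    raise last


def ph_check(
    fitted: CoxPHFitter, fit_df: pd.DataFrame, transform: str = "km"
) -> tuple[float, float]:
    """Global scaled-Schoenfeld-residual test of proportional hazards.

    Computes the chi-square statistic ``d * u' V u / sum((g - gbar)^2)``
    with ``u = sum_k (g_k - gbar) r_k`` over Schoenfeld residuals ``r_k``
    at the d event times, ``V`` the estimated covariance of beta-hat and
    ``g`` the transformed event time (default: one minus the Kaplan-Meier
    survival estimate, evaluated left-continuously).  Degrees of freedom
    equal the number of covariates.
    """
    from scipy.stats import chi2 as chi2_dist

    resid = fitted.compute_residuals(fit_df, kind="schoenfeld")
    # residual rows are indexed by subject; look their event times up
    event_times = fit_df.loc[resid.index, "followup"].to_numpy(dtype=float)
    order = np.argsort(event_times, kind="stable")
    r = resid.to_numpy(dtype=float)[order]
    times = event_times[order]

    g = _transform_times(fit_df, times, transform)
    gc = g - g.mean()
    u = gc @ r
    v = fitted.variance_matrix_.to_numpy(dtype=float)
    d = r.shape[0]
    denom = float((gc**2).sum())
    stat = float(d * u @ v @ u / denom)
    p = float(chi2_dist.sf(stat, df=r.shape[1]))
    return stat, p


def _transform_times(fit_df: pd.DataFrame, event_times: np.ndarray, transform: str) -> np.ndarray:
    if transform == "identity":
        return event_times.astype(float)
    if transform == "rank":
        return np.argsort(np.argsort(event_times, kind="stable"), kind="stable").astype(float)
    if transform == "log":
        return np.log(event_times.astype(float))
    if transform == "km":
        from lifelines import KaplanMeierFitter

        km = KaplanMeierFitter()
        km.fit(fit_df["followup"], fit_df["_event"] if "_event" in fit_df else fit_df["event"])
        # left-continuous KM at each event time
        sf = km.survival_function_
        grid = sf.index.to_numpy(dtype=float)
        surv = sf.iloc[:, 0].to_numpy(dtype=float)
        idx = np.searchsorted(grid, event_times, side="left") - 1
        prev = np.where(idx >= 0, surv[np.clip(idx, 0, None)], 1.0)
        return 1.0 - prev
    raise ValueError(f"unknown transform {transform!r}")


def interaction_analysis(
    cohort: pd.DataFrame,
    modifier: str | pd.Series,
    spec: CoxSpec = CoxSpec(),
) -> dict:
    """Effect modification of the DistEn-mortality association.

    ``modifier`` is a binary variable (column name or Series; NaN rows are
    dropped, which is how three-level strata such as age <55 vs >65 are
    contrasted).  Fits a product-term model on the restricted cohort and
    per-stratum models, returning the Wald p of the interaction and the
    per-stratum HRs per 1-SD decrease.
    """
    mod = cohort[modifier] if isinstance(modifier, str) else modifier
    mod = pd.Series(np.asarray(mod, dtype=float), index=cohort.index)
    sub = cohort.loc[mod.notna()].copy()
    modv = mod.dropna().astype(int)
    levels = sorted(modv.unique())
    if len(levels) != 2:
        raise ValueError(
            f"modifier must take exactly 2 values in the analysis cohort, got {levels}"
        )
    for lev in levels:
        if (modv == lev).sum() == 0:  # pragma: no cover - guarded above
            raise ValueError(f"empty stratum {lev}")

    df, covs = _prepare_design(sub, spec)
    df, sd_used = standardize_exposure(df, spec.exposure)
    zcol = spec.exposure + "_z"
    df["_modifier"] = modv.to_numpy()
    df["_product"] = df[zcol] * df["_modifier"]
    covs = [c for c in covs if c != "age" or not _is_age_modifier(modv, sub)]
    cols = [zcol, "_modifier", "_product"] + covs
    cph = _fit_cph(df[cols + ["followup", "_event"]], "followup", "_event")
    interaction_p = float(cph.summary.loc["_product", "p"])

    subgroup_hrs = {}
    for lev in levels:
        stratum = sub.loc[modv == lev]
        res = fit_cox(
            stratum,
            CoxSpec(
                tier=spec.tier,
                outcome=spec.outcome,
                exposure=spec.exposure,
                heart_rate_var=spec.heart_rate_var,
                hrv_var=spec.hrv_var,
                compute_ph_test=False,
            ),
            exposure_sd=sd_used,  # parent-cohort scale for comparability
        )
        subgroup_hrs[lev] = res
    return {
        "interaction_p": interaction_p,
        "subgroup": subgroup_hrs,
        "interaction_beta": float(cph.params_["_product"]),
        "n": len(df),
    }


def _is_age_modifier(modv: pd.Series, sub: pd.DataFrame) -> bool:
    # drop the linear age adjuster when the modifier is itself an age
    # dichotomy, to avoid near-collinear designs in the stratified sample
    if "age" not in sub.columns:
        return False
    grouped = sub.groupby(modv.to_numpy())["age"].mean()
    return bool(abs(grouped.diff().dropna()).max() > 8.0)


def age_strata(cohort: pd.DataFrame, young_below: float = 55.0, old_above: float = 65.0) -> pd.Series:
    """1 for age < young_below, 0 for age > old_above, NaN between."""
    age = cohort["age"]
    out = pd.Series(np.nan, index=cohort.index)
    out[age < young_below] = 1.0
    out[age > old_above] = 0.0
    return out


def cvd_risk_strata(cohort: pd.DataFrame) -> pd.Series:
    """1 for >= 3 CVD risk factors, 0 for none, NaN for 1-2 factors."""
    count = (
        cohort["hypertension"]
        + cohort["cholesterol"]
        + cohort["diabetes"]
        + cohort["smoking_current"]
        + cohort["angina"]
        + cohort["mi"]
    )
    out = pd.Series(np.nan, index=cohort.index)
    out[count >= 3] = 1.0
    out[count == 0] = 0.0
    return out


def concordance_comparison(
    cohort: pd.DataFrame,
    exposure_a: str = "disten",
    exposure_b: str = "rri_mean",
    adjusters: tuple[str, ...] = ("age", "sex_male", "education_college"),
    truncate_years: tuple[float, ...] | None = None,
    n_bootstrap: int = 0,
    seed: int = 0,
) -> pd.DataFrame:
    """Concordance (c-statistic) of two adjusted survival models.

    Fits ``exposure + adjusters`` Cox models for each exposure and
    compares their concordance, overall and optionally with follow-up
    truncated at each requested year.  With ``n_bootstrap > 0`` a
    percentile bootstrap CI of the difference is attached to each row.
    """
    horizons: list[float | None] = [None] if truncate_years is None else list(truncate_years)
    rng = np.random.default_rng(seed)
    rows = []

    def _fit_scores(df: pd.DataFrame, exposure: str) -> np.ndarray:
        cph = CoxPHFitter()
        cols = [exposure, *adjusters, "followup", "event"]
        cph.fit(df[cols], duration_col="followup", event_col="event")
        return -cph.predict_partial_hazard(df).to_numpy()

    score_a = _fit_scores(cohort, exposure_a)
    score_b = _fit_scores(cohort, exposure_b)

    for horizon in horizons:
        if horizon is None:
            t = cohort["followup"].to_numpy()
            e = cohort["event"].to_numpy()
        else:
            t = np.minimum(cohort["followup"].to_numpy(), horizon)
            e = (cohort["event"].to_numpy() == 1) & (cohort["followup"].to_numpy() <= horizon)
        c_a = concordance_index(t, score_a, e)
        c_b = concordance_index(t, score_b, e)
        row = {
            "horizon_years": np.nan if horizon is None else horizon,
            f"c_{exposure_a}": c_a,
            f"c_{exposure_b}": c_b,
            "c_difference": c_a - c_b,
        }
        if n_bootstrap > 0:
            diffs = np.empty(n_bootstrap)
            n = len(cohort)
            for b in range(n_bootstrap):
                idx = rng.integers(0, n, n)
                diffs[b] = concordance_index(t[idx], score_a[idx], e[idx]) - concordance_index(
                    t[idx], score_b[idx], e[idx]
                )
            row["c_difference_ci_low"] = float(np.percentile(diffs, 2.5))
            row["c_difference_ci_high"] = float(np.percentile(diffs, 97.5))
        rows.append(row)
    return pd.DataFrame(rows)


def adjusted_group_difference(
    cohort: pd.DataFrame,
    group_flag: str | pd.Series,
    adjusters: tuple[str, ...] = ("age", "sex_male", "ethnicity_european", "education_college"),
    outcome: str = "disten",
) -> tuple[float, float]:
    """Covariate-adjusted mean difference in DistEn, in cohort-SD units.

    Fits an ordinary linear model ``outcome ~ group + adjusters`` and
    returns (difference / SD(outcome), p-value) for group presence vs
    absence.
    """
    import statsmodels.api as sm

    flag = cohort[group_flag] if isinstance(group_flag, str) else group_flag
    flag = pd.Series(np.asarray(flag, dtype=float), index=cohort.index)
    sub = cohort.loc[flag.notna()]
    fv = flag.dropna()
    if fv.nunique() != 2:
        raise ValueError("group flag must take exactly 2 values with both groups nonempty")
    x = sm.add_constant(
        np.column_stack([fv.to_numpy()] + [sub[a].to_numpy(dtype=float) for a in adjusters])
    )
    model = sm.OLS(sub[outcome].to_numpy(dtype=float), x).fit()
    sd = float(sub[outcome].std(ddof=0))
    return float(model.params[1] / sd), float(model.pvalues[1])


def survival_curve_contrast(
    cohort: pd.DataFrame,
    spec: CoxSpec = CoxSpec(tier="E"),
    percentiles: tuple[float, float] = (10.0, 90.0),
) -> pd.DataFrame:
    """Model-predicted survival for low- vs high-DistEn profiles.

    Fits the requested tier and evaluates the predicted survival function
    for two pseudo-subjects at the cohort's covariate means whose exposure
    sits at the given percentiles (default: 10th vs 90th).  Returns a
    table of (time, survival_low, survival_high).
    """
    df, covs = _prepare_design(cohort, spec)
    df, sd_used = standardize_exposure(df, spec.exposure)
    zcol = spec.exposure + "_z"
    cols = [zcol] + covs
    cph = _fit_cph(df[cols + ["followup", "_event"]], "followup", "_event")

    lo_val, hi_val = (float(np.percentile(cohort[spec.exposure], p)) for p in percentiles)
    mean_exp = float(cohort[spec.exposure].mean())
    profile = df[cols].mean().to_frame().T
    low = profile.copy()
    low[zcol] = (lo_val - mean_exp) / sd_used
    high = profile.copy()
    high[zcol] = (hi_val - mean_exp) / sd_used
    sf = cph.predict_survival_function(pd.concat([low, high], ignore_index=True))
    out = pd.DataFrame(
        {
            "time": sf.index.to_numpy(dtype=float),
            "survival_low_percentile": sf.iloc[:, 0].to_numpy(),
            "survival_high_percentile": sf.iloc[:, 1].to_numpy(),
        }
    )
    out.attrs["exposure_values"] = (lo_val, hi_val)
    return out


def fit_table(
    cohort: pd.DataFrame,
    tiers: tuple[str, ...] = ("A", "B", "C", "D", "E"),
    outcomes: tuple[str, ...] = ("all_cause", "cvd", "respiratory", "cancer"),
    **spec_kwargs,
) -> pd.DataFrame:
    """Tier x outcome grid of hazard ratios per 1-SD decrease."""
    rows = []
    for tier in tiers:
        for outcome in outcomes:
            try:
                res = fit_cox(cohort, CoxSpec(tier=tier, outcome=outcome, **spec_kwargs))
            except ValueError as exc:
                rows.append({"tier": tier, "outcome": outcome, "error": str(exc)})
                continue
            rows.append(
                {
                    "tier": tier,
                    "outcome": outcome,
                    "hr_per_sd_decrease": res.hr_per_sd_decrease,
                    "ci_low": res.ci95[0],
                    "ci_high": res.ci95[1],
                    "p": res.p_value,
                    "concordance": res.concordance,
                    "n_events": res.n_events,
                }
            )
    return pd.DataFrame(rows)
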