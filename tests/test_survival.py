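"""Cox models: per-SD convention, recovery, PH test, interactions."""

import subprocess
import sys

import numpy as np
import pandas as pd
import pytest

from disten.survival import (
    CoxSpec,
    adjusted_group_difference,
    age_strata,
    concordance_comparison,
    cvd_risk_strata,
    fit_cox,
    interaction_analysis,
    ph_check,
    standardize_exposure,
    tier_covariates,
)
from disten.synth import CohortGenParams, generate_cohort


def _latent_cohort(seed=0, n=3000, **kwargs):
    return generate_cohort(
        CohortGenParams(n_subjects=n, seed=seed, metrics_mode="latent", **kwargs)
    )


class TestStandardize:
    def test_zscore_properties(self, small_cohort):
        out, sd = standardize_exposure(small_cohort, "disten")
        z = out["disten_z"]
        assert z.mean() == pytest.approx(0.0, abs=1e-10)
        assert z.std(ddof=0) == pytest.approx(1.0, rel=1e-10)
        assert sd == pytest.approx(small_cohort["disten"].std(ddof=0))

    def test_zero_sd_rejected(self, small_cohort):
        coh = small_cohort.copy()
        coh["flat"] = 1.0
        with pytest.raises(ValueError, match="zero"):
            standardize_exposure(coh, "flat")

    def test_scale_invariance_of_per_sd_hr(self):
        # doubling the exposure's units leaves the per-SD HR unchanged
        coh = _latent_cohort(seed=21, n=4000)
        r1 = fit_cox(coh, CoxSpec(tier="A"))
        coh2 = coh.copy()
        coh2["disten"] = coh2["disten"] * 2.0
        r2 = fit_cox(coh2, CoxSpec(tier="A"))
        assert r2.hr_per_sd_decrease == pytest.approx(r1.hr_per_sd_decrease, rel=1e-8)


class TestTiers:
    def test_nested_covariate_sets(self):
        rosters = [set(tier_covariates(t)) for t in "ABCDE"]
        for small, big in zip(rosters, rosters[1:]):
            assert small < big

    def test_unknown_tier_rejected(self):
        with pytest.raises(ValueError):
            tier_covariates("F")


class TestFitCox:
    def test_null_effect_hr_near_one(self):
        # ~600 events per replicate keep the null sampling SE of the log-HR
        # near 0.04, so the +-10% band is a ~2.3 sigma check
        hrs = [
            fit_cox(
                _latent_cohort(
                    seed=s, n=5000, log_hazard_per_sd=0.0, target_event_rate=0.12
                ),
                CoxSpec(tier="A", compute_ph_test=False),
            ).hr_per_sd_decrease
            for s in range(20)
        ]
        inside = sum(0.9 <= hr <= 1.1 for hr in hrs)
        assert inside >= 19

    def test_planted_effect_recovered(self):
        hrs = [
            fit_cox(
                _latent_cohort(seed=100 + s, n=7631, log_hazard_per_sd=np.log(1.5)),
                CoxSpec(tier="A", compute_ph_test=False),
            ).hr_per_sd_decrease
            for s in range(10)
        ]
        assert np.mean(hrs) == pytest.approx(1.5, abs=0.08)

    def test_exposure_duplicating_covariate_flagged(self):
        coh = _latent_cohort(seed=4)
        coh["disten"] = coh["age"]  # exact duplicate of an adjuster
        with pytest.raises(ValueError, match="rank deficient|collinear"):
            fit_cox(coh, CoxSpec(tier="A"))

    def test_too_few_events_rejected(self):
        coh = _latent_cohort(seed=6, n=300, target_event_rate=0.059)
        with pytest.raises(ValueError, match="events"):
            fit_cox(coh, CoxSpec(tier="A", outcome="respiratory"))

    def test_cause_specific_events_reconcile(self, small_cohort):
        total = 0
        for outcome in ("cvd", "respiratory", "cancer"):
            res = fit_cox(small_cohort, CoxSpec(tier="A", outcome=outcome, compute_ph_test=False))
            total += res.n_events
        other = (small_cohort["cause"] == "other").sum()
        assert total + other == small_cohort["event"].sum()

    def test_log_rmssd_used_in_tier_e(self, small_cohort):
        res = fit_cox(small_cohort, CoxSpec(tier="E", compute_ph_test=False))
        assert "rmssd_log" in res.covariates
        assert "rhr" in res.covariates and "map" in res.covariates


class TestPHCheck:
    def test_deterministic(self):
        coh = _latent_cohort(seed=8, n=1500)
        r1 = fit_cox(coh, CoxSpec(tier="A"))
        r2 = fit_cox(coh, CoxSpec(tier="A"))
        assert r1.ph_global_chi2 == r2.ph_global_chi2

    def test_matches_r_survival_cox_zph(self, tmp_path):
        # independent oracle: R survival::cox.zph on the same small cohort
        coh = _latent_cohort(seed=42, n=800)
        df, _ = standardize_exposure(coh, "disten")
        cols = ["disten_z", "age", "sex_male", "followup", "event"]
        csv = tmp_path / "cohort.csv"
        df[cols].to_csv(csv, index=False)

        from lifelines import CoxPHFitter

        fit_df = df[cols].rename(columns={"event": "_event"})
        cph = CoxPHFitter().fit(fit_df, "followup", "_event")
        chi2, p = ph_check(cph, fit_df, transform="km")

        script = f"""
        library(survival)
        d <- read.csv("{csv}")
        fit <- coxph(Surv(followup, event) ~ disten_z + age + sex_male, data=d, ties="efron")
        z <- cox.zph(fit, transform="km", global=TRUE)
        cat(z$table["GLOBAL", "chisq"], z$table["GLOBAL", "p"], sep="\\n")
        """
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, check=True
        )
        r_chi2, r_p = (float(v) for v in out.stdout.strip().splitlines()[-2:])
        # same quadratic form; small differences from R's exact variance
        assert chi2 == pytest.approx(r_chi2, rel=0.10)
        assert p == pytest.approx(r_p, abs=0.05)

    def test_power_against_reversing_effect(self):
        rejections = 0
        for s in range(15):
            coh = _latent_cohort(
                seed=600 + s, n=1500, effect_reversal_time=3.9, log_hazard_per_sd=np.log(1.8)
            )
            rejections += fit_cox(coh, CoxSpec(tier="A")).ph_p < 0.05
        assert rejections > 15 * 0.5


class TestInteraction:
    def test_constant_modifier_rejected(self, small_cohort):
        with pytest.raises(ValueError, match="2 values"):
            interaction_analysis(small_cohort, pd.Series(1.0, index=small_cohort.index))

    def test_directional_recovery(self):
        ok_dir = 0
        for s in range(10):
            coh = _latent_cohort(
                seed=3100 + s,
                n=6000,
                log_hazard_per_sd=np.log(1.5),
                young_effect_multiplier=2.0,
                target_event_rate=0.10,
            )
            res = interaction_analysis(coh, age_strata(coh))
            ok_dir += (
                res["subgroup"][1].hr_per_sd_decrease > res["subgroup"][0].hr_per_sd_decrease
            )
        assert ok_dir >= 9

    def test_null_interaction_calibrated(self):
        ps = []
        for s in range(15):
            coh = _latent_cohort(seed=4200 + s, n=4000, target_event_rate=0.10)
            ps.append(interaction_analysis(coh, age_strata(coh))["interaction_p"])
        assert np.mean(np.asarray(ps) > 0.05) >= 0.8

    def test_cvd_risk_strata_definition(self, small_cohort):
        strata = cvd_risk_strata(small_cohort)
        count = (
            small_cohort["hypertension"]
            + small_cohort["cholesterol"]
            + small_cohort["diabetes"]
            + small_cohort["smoking_current"]
            + small_cohort["angina"]
            + small_cohort["mi"]
        )
        assert (strata[count >= 3] == 1).all()
        assert (strata[count == 0] == 0).all()
        assert strata[(count > 0) & (count < 3)].isna().all()


class TestConcordance:
    def test_identical_exposures_zero_difference(self, small_cohort):
        coh = small_cohort.copy()
        coh["disten_copy"] = coh["disten"]
        table = concordance_comparison(coh, "disten", "disten_copy")
        assert table["c_difference"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_informative_beats_noise_exposure(self):
        coh = _latent_cohort(seed=31, n=5000)
        rng = np.random.default_rng(0)
        coh["noise_exposure"] = rng.normal(size=len(coh))
        table = concordance_comparison(coh, "disten", "noise_exposure")
        assert table["c_difference"].iloc[0] > 0

    def test_bootstrap_ci_covers_zero_under_exchangeable_null(self):
        coh = _latent_cohort(seed=32, n=2000)
        rng = np.random.default_rng(1)
        coh["noise_a"] = rng.normal(size=len(coh))
        coh["noise_b"] = rng.normal(size=len(coh))
        table = concordance_comparison(coh, "noise_a", "noise_b", n_bootstrap=100, seed=2)
        assert table["c_difference_ci_low"].iloc[0] <= 0 <= table["c_difference_ci_high"].iloc[0]

    def test_truncation_grid(self, small_cohort):
        table = concordance_comparison(small_cohort, truncate_years=(2.0, 5.0, 7.8))
        assert len(table) == 3
        assert table["horizon_years"].tolist() == [2.0, 5.0, 7.8]


class TestSurvivalCurveContrast:
    def test_low_decile_has_worse_survival(self, small_cohort):
        from disten.survival import survival_curve_contrast

        table = survival_curve_contrast(small_cohort, CoxSpec(tier="A", compute_ph_test=False))
        assert (table["survival_low_percentile"] <= table["survival_high_percentile"] + 1e-12).all()
        assert table["survival_low_percentile"].iloc[-1] < table["survival_high_percentile"].iloc[-1]
        lo, hi = table.attrs["exposure_values"]
        assert lo < hi


class TestAdjustedGroupDifference:
    def test_null_difference_small(self):
        coh = _latent_cohort(seed=41, n=5000)
        rng = np.random.default_rng(3)
        coh["random_flag"] = (rng.random(len(coh)) < 0.5).astype(int)
        d, _ = adjusted_group_difference(coh, "random_flag")
        assert abs(d) < 0.05

    def test_planted_shift_recovered(self):
        coh = _latent_cohort(seed=43, n=5000)
        rng = np.random.default_rng(5)
        coh["flagged"] = (rng.random(len(coh)) < 0.3).astype(int)
        sd = coh["disten"].std(ddof=0)
        coh.loc[coh.flagged == 1, "disten"] -= 0.4 * sd
        d, p = adjusted_group_difference(coh, "flagged")
        assert d == pytest.approx(-0.4, abs=0.1)
        assert p < 1e-6

    def test_constant_flag_rejected(self, small_cohort):
        with pytest.raises(ValueError):
            adjusted_group_difference(small_cohort, pd.Series(0.0, index=small_cohort.index))

    def test_high_cvd_risk_group_has_lower_disten(self, small_cohort):
        d, p = adjusted_group_difference(small_cohort, cvd_risk_strata(small_cohort))
        assert d < 0
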