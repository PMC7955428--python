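"""Staged Cox models of mortality risk per 1-SD decrease in DistEn.

Simulates a screening cohort in which lower heartbeat complexity carries
a planted 36% hazard increase per 1-SD decrease, then fits the nested
model tiers: A demographics; B +lifestyle; C +cardiovascular risks;
D +comorbidities; E +autonomic measures (RHR, log-RMSSD, MAP).  Because
the generator plants the effect directly on DistEn, adjustment should
leave the hazard ratio near 1.36 in every tier.
"""

import numpy as np

from disten.survival import CoxSpec, age_strata, concordance_comparison, fit_cox, interaction_analysis
from disten.synth import CohortGenParams, generate_cohort

cohort = generate_cohort(CohortGenParams(n_subjects=7631, seed=1))
print(f"cohort: n={len(cohort)}, deaths={int(cohort.event.sum())} "
      f"({cohort.event.mean() * 100:.1f}%), DistEn {cohort.disten.mean():.3f} "
      f"(SD {cohort.disten.std():.3f})")

print("\ntier  HR/SD-decrease  95% CI          concordance")
for tier in "ABCDE":
    r = fit_cox(cohort, CoxSpec(tier=tier, compute_ph_test=False))
    print(f"  {tier}   {r.hr_per_sd_decrease:.3f}          "
          f"({r.ci95[0]:.3f}-{r.ci95[1]:.3f})   {r.concordance:.3f}")

r = fit_cox(cohort, CoxSpec(tier="A"))
print(f"\nproportional hazards (global chi2 test): chi2={r.ph_global_chi2:.2f}, "
      f"p={r.ph_p:.2f} -> no violation detected")

comp = concordance_comparison(cohort, "disten", "rri_mean")
print(f"c-statistic, DistEn vs mean-RRI model: "
      f"{comp.iloc[0, 1]:.3f} vs {comp.iloc[0, 2]:.3f} "
      f"(difference {comp.c_difference.iloc[0]:+.3f})")

res = interaction_analysis(cohort, age_strata(cohort))
print(f"age interaction p={res['interaction_p']:.2f}; "
      f"HR <55y {res['subgroup'][1].hr_per_sd_decrease:.2f} vs "
      f">65y {res['subgroup'][0].hr_per_sd_decrease:.2f} "
      "(no modification planted here)")
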