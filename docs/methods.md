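# Methods

## Distribution entropy

DistEn treats an RR-interval (RRI) series as a trajectory in a
reconstructed state space and asks how the pairwise geometry of that
trajectory is distributed, rather than how often it recurs within a
threshold.  The estimator:

1. **Embedding.**  Delay vectors `u(i) = (x(i), x(i+τ), …, x(i+(m−1)τ))`
   for `i = 1 … N − mτ` (defaults `m = 3`, `τ = 1`).  This conventional
   index range discards one vector the data could support (start indices
   up to `N − (m−1)τ` are constructible); `EmbeddingConfig(all_vectors=True)`
   switches to the inclusive range.  The difference is one vector in
   ~135 and is numerically negligible, but both conventions are exposed
   because published analyses are not explicit about it.
2. **Distances.**  Chebyshev distance over all ordered pairs `i ≠ j`.
   Because the distance is symmetric, ordered and unordered conventions
   give identical probabilities; `EmbeddingConfig(ordered_pairs=...)`
   only changes the reported pair count.  Internally the condensed
   (unordered) distance set is computed once via `scipy.spatial.pdist`.
3. **Histogram.**  `B = 256` equal-width bins spanning
   `[min(d), max(d)]` of the observed off-diagonal distances.  The bin
   index is `floor((d − dmin)·B/(dmax − dmin))` clipped to `B − 1`
   (interior edges left-closed, final bin right-closed).  The data-driven
   range is what makes DistEn exactly invariant under affine maps
   `x → a·x + c` (a > 0): distances scale by `a` and the edges scale with
   them.  A degenerate distance matrix (`dmin = dmax`, e.g. a constant
   series) puts all mass in one bin — DistEn 0, no division by zero.
4. **Entropy.**  `−(1/log₂B) Σ p_t log₂ p_t` with `0·log 0 ≡ 0`, so the
   value is normalised to `[0, 1]`.

Tunables: `m ≥ 1` (3 is standard for heartbeat series; 2–4 leave rank
orderings intact), `τ ≥ 1` beats, `B ≥ 2` (128–512 behave equivalently;
256 balances resolution against the ~9,000 pairs a 2-minute record
yields).

## Time-domain HRV

RHR = 60000 / mean RRI (ms) in bpm.  RMSSD = root mean square of the
`n−1` successive differences; SDNN = sample SD (n−1 denominator);
pNNx = percentage of *absolute* successive differences *strictly* greater
than x ms (x = 5, 10, 20).  Absolute differences and the strict
inequality are the field conventions; both are asserted by tests against
explicit-loop oracles.  RMSSD is returned in raw ms; the survival module
log-transforms it where it enters a model.

## Quality control

Records pass four exclusion stages in a fixed order, each report carrying
the first triggered reason:

1. **RRI range** — any interval strictly `> 2000` ms or `< 428` ms
   (momentary rate outside 30–140 bpm) excludes the record; the bounds
   themselves are acceptable (strict inequalities).
2. **Length** — duration outside cohort mean ± 2 SD (two-sided).
3. **Noise** — the noise score is the overall SD, over all full 3-beat
   windows, of the within-window sample SD (both SDs with n−1
   denominators; the window and outer denominators are a documented
   choice, as published descriptions omit them).  Records whose score
   *strictly exceeds* the cohort's 98th percentile are excluded.  The
   percentile uses the ceiling order statistic (`numpy` method
   `"higher"`): the cutoff is the smallest observed score with ≥98% of
   the cohort at or below it, so exactly the top 2% (by count) fall
   strictly above it and a cohort of identical records excludes nothing.
4. **Pacemaker** — a metadata flag supplied with the cohort (device
   history, not waveform inspection).

Cohort-level statistics are computed once and **frozen**: length mean/SD
from stage-1 survivors, the noise percentile from stage-1–2 survivors
(the narrative order of the exclusions; whether the original analyses
recomputed thresholds iteratively is unknowable, and freezing makes QC
idempotent — re-running on the filtered output with the frozen manifest
excludes nothing further).  Fewer than 10 records require explicitly
supplied frozen thresholds.

## R-peak detection

A generic Pan-Tompkins-family detector: 2nd-order Butterworth bandpass
(5–15 Hz, zero-phase), squared derivative, 150 ms moving-window
integration, `scipy.signal.find_peaks` with an adaptive height threshold
(20% of the 99th percentile of the integrated energy) and a refractory
distance of `min_rri` (428 ms default), then refinement of each candidate
to the local maximum of the raw signal within ±100 ms.  The refractory
constraint is re-enforced after refinement.  A flat trace returns an
empty peak set with a warning (a QC outcome, not a crash).  The detector
is deliberately pluggable — any annotation source can construct an
`RPeakSet` directly — since production QRS detectors (with sub-sample
interpolation, multi-lead fusion, morphology rules) are out of scope.

## Synthetic data

### RRI process

`generate_rri` draws

    x_i = mean + resp·sin(2πf·t_i + φ) + drift_i + switch_i + AR(1)_i + ε_i,

truncated to [428, 2000] ms: a respiratory sinusoid (default 0.25 Hz ≈ a
4.7-beat period at 71 bpm, random phase), an optional slow half-sine
baseline drift, optional smooth two-level *switching* (sigmoid
transitions between two autonomic set-points), a persistent AR(1)
component (`ar_coef = 0` disables it entirely, so zeroing `noise_sd`,
`resp_amp` and `ar_coef` yields an exactly constant series), and white
beat-to-beat noise.  All randomness derives from the record's seed.

### The complexity knob

`rri_params_for_complexity(c, …)` maps a latent complexity `c ∈ [0, 1]`
to process parameters.  Rising `c` increases the white-noise SD
(0.5 → 22.5 ms), respiratory amplitude (0.8 → 20.8 ms) and slow drift
(0 → 60 ms) — all of which spread the pairwise-distance histogram and
raise DistEn — while shrinking and smoothing the switching component
(amplitude `420·(1−c)^1.35` ms, transition width 0.6 → 3 beats).  Large,
*slow* level shifts are the mechanism that produces genuinely
low-complexity records: they stretch the distance range so the bulk of
pairs crowds into a few bins (low DistEn) while barely inflating
successive differences (so RMSSD stays low, preserving the positive
DistEn–RMSSD association seen in real cohorts).  The constants were
calibrated once, by a design-time parameter sweep, so that sweeping `c`
spans DistEn ≈ 0.28–0.98 and a screening-age cohort centres near 0.85
(SD ≈ 0.1).  The coupling is a documented modelling device, not a
biological claim.

### Cohorts

`generate_cohort` draws covariates from distributions typical of a
middle/older-aged volunteer cohort (age ~N(59.5, 7.6²), 40% male, 87%
European ancestry, BMI ~N(29.4, 5.9²), smoking 12.5%/48% current/former,
16 comorbidity flags at realistic prevalences, ~3.9 medications).  A
latent complexity per subject is linear in standardized age, sex, BMI
and high-CVD-risk status (≥3 of hypertension, high cholesterol,
diabetes, current smoking, angina, prior MI) plus Gaussian noise;
resting heart rate is drawn negatively correlated (ρ = −0.33) with that
latent.  Each subject's RRI series (duration ~N(117, 6²) s) then yields
DistEn, RHR, mean RRI, RMSSD and SDNN — so the generator's associations
(DistEn↓ with RHR, DistEn↑ with RMSSD, DistEn↓ with age/BMI/CVD risk)
*emerge from the beat-level simulation* rather than being pasted onto
the table.  Signs and orderings are the targets; the generator does not
chase specific r² values.

Event times are exponential given covariates (Weibull shape exposed):
`λ_i = λ0·exp(β_sd·(−z_i) + Σ β_j x_ij)` with `z_i` the cohort-realised
DistEn z-score, so `exp(β_sd)` is the *true* hazard ratio per 1-SD
decrease.  Default planted values: `β_sd = ln 1.36` and per-unit
log-hazards for age (0.056/y), male sex, smoking and diabetes.
Covariates that influence both hazard and complexity (age, sex) are in
every model tier, so tier A recovers the planted effect essentially
unbiasedly; smoking and diabetes affect the hazard but not the
complexity latent, leaving only the (small, rare-event) non-collapsibility
attenuation.  λ0 is calibrated by root-finding so the *expected* event
proportion under administrative censoring (7.8 y default) equals the
target (5.9% default); an unreachable target raises a calibration error
with the attainable range.  Options plant an age-dependent effect
(`young_effect_multiplier`, applied below age 55) and a sign reversal of
the DistEn effect at a chosen time (`effect_reversal_time`,
piecewise-exponential) for interaction and proportional-hazards power
studies.  One root seed spawns independent substreams for covariates,
latents, metrics and events, so cohorts are reproducible and subjects
have independent per-record streams.

`metrics_mode="latent"` replaces the beat-level simulation with draws
from tabulated conditional moments of (DistEn, log RMSSD) given `c`
(measured once from the frozen generator); it exists for large
simulation studies of the survival layer (PH calibration, interaction
power) where per-beat simulation adds nothing, and is validated against
the RRI-backed moments in the tests.

### What the generator does *not* emulate

Real P/T-wave morphology, ectopy classification, arrhythmias, competing
risk structure beyond a cause label, informative censoring, covariate
measurement error and missingness.  Passing tests therefore demonstrate
the *statistical machinery* — estimator correctness, QC accounting,
hazard recovery, test calibration — under the assumed data-generating
structure, not clinical validity on any real population.

## Survival models

Nested tiers: **A** age, sex, ethnicity, college education; **B** + TDI,
BMI, smoking (former/current indicators), alcohol, physical activity;
**C** + hypertension, cholesterol, PVD, diabetes, angina, prior MI,
AF/arrhythmias; **D** + cancer, respiratory, neurological, psychiatric,
musculoskeletal, gastrointestinal, renal, endocrine, hematological
disease and medication count; **E** + resting heart rate (or mean RRI —
the heart-rate variable is configurable), log-RMSSD (the HRV variable is
configurable) and MAP entered untransformed.  Continuous adjusters enter
linearly; fits use `lifelines.CoxPHFitter` (Efron tie handling).  Wald
CIs and p-values throughout.  Sparse strata occasionally put the
unpenalized Newton fit on a flat ridge; the fitter retries with an L2
penalty of 1e-6 then 1e-4, negligible shrinkage at these sample sizes.

**Per-SD convention.**  The exposure is z-scored on the analysis cohort
(population SD); the reported quantity is `exp(−β·σ)` per 1-SD
*decrease*.  Subgroup fits inside `interaction_analysis` reuse the parent
cohort's SD so subgroup hazard ratios are on a common scale.

**Cause-specific mortality** censors competing-cause deaths at the death
time (standard cause-specific Cox); per-cause event counts reconcile
with the cohort total by construction.

**Proportional hazards.**  The global scaled-Schoenfeld test: with
Schoenfeld residuals `r_k` at the `d` event times and a transformed time
`g` (default 1 − left-continuous Kaplan-Meier estimate; identity, rank
and log also available), the statistic is

    χ² = d · uᵀ V̂ u / Σ(g_k − ḡ)²,   u = Σ (g_k − ḡ) r_k,

with `V̂` the estimated covariance of the coefficients, referred to a
chi-square with one degree of freedom per covariate.  It agrees with R's
`survival::cox.zph` global test to within a few percent on shared data
(the R implementation uses the exact per-event variances) and its
rejection rate under proportional hazards is 2–10% at the 5% level in
the calibration simulation.

**Interactions.**  Binary modifiers (NaN rows dropped, which is how
age <55 vs >65 and CVD-risk high-vs-low contrasts are formed); the Wald
p of the product term plus per-stratum HRs.  When the modifier is an age
dichotomy the linear age adjuster is dropped from the product model to
avoid near-collinearity in the restricted sample.

**Concordance comparison.**  Two exposures are compared by fitting each
with the same adjusters and computing Harrell's c on the fitted risk
scores, optionally truncating follow-up at a grid of horizons, with an
optional percentile bootstrap CI for the difference.

**Adjusted group differences** in DistEn use OLS
(`statsmodels`) of DistEn on the group flag plus adjusters (age, sex,
ethnicity, education by default), reported in cohort-SD units.

## Simulation scales used by the tests

The acceptance-style checks run at the scale the emulated study design
implies where that is cheap (25 cohorts of n=7631 for hazard recovery;
100 cohorts of n=1000 for PH calibration; 50 cohorts of n=6000 with a
10% event rate for interaction power — the event rate chosen so stratum
event counts give the directional comparison ~90% power) and at reduced
replicate counts for the unit-level calibration checks.  The null HR
calibration runs at a 12% event rate because ±10% bounds on a null HR
correspond to ~2.3 SE only once a replicate has ~600 events.

## Known limitations

* The detector is generic; it targets clean resting single-lead traces
  and makes no claim on ambulatory or arrhythmic ECG.
* DistEn's low range (< 0.3) is reachable only by strongly degenerate
  or quantized series; the generator's sweep spans what the emulated
  population exhibits (~0.28–0.98).
* Cause-specific analyses ignore competing-risk dependence (no
  Fine–Gray subdistribution hazards).
* The exponential event-time model has a constant baseline hazard;
  Weibull shape is exposed but the calibration targets only the overall
  event proportion, not the hazard's time profile.
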