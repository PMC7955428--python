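# disten

Distribution entropy of short resting heartbeat recordings: quality
control, time-domain HRV, and mortality-risk modelling.

## The problem

Physiological complexity — the structured unpredictability of healthy
beat-to-beat heart rate fluctuations — declines with age, disease and
frailty, and entropy estimators are the standard way to quantify it.
Classical estimators (approximate entropy, sample entropy) need long
recordings because they count state-space recurrences under a hard
distance threshold; on a routine 2-minute resting ECG (~120 beats) they
degenerate.  **Distribution entropy (DistEn)** avoids the threshold
entirely: it uses the *full distribution* of pairwise distances between
embedded states, so it remains stable on exactly the short recordings a
screening visit produces.

For an RR-interval series `x(1..N)`, the `m`-dimensional delay vectors
(delay `τ`)

    u(i) = (x(i), x(i+τ), …, x(i+(m−1)τ)),   1 ≤ i ≤ N − mτ,

give pairwise Chebyshev distances `d(i,j) = max_k |x(i+kτ) − x(j+kτ)|`
for all `i ≠ j`.  Binning these into `B` equal-width bins with empirical
probabilities `{p_t}` yields

    DistEn(m, τ, B) = −(1 / log₂ B) Σ_t p_t log₂ p_t  ∈ [0, 1],

computed here with `m = 3`, `τ = 1`, `B = 256` by default.  Higher values
mean higher complexity; epidemiologically, *lower* DistEn marks higher
mortality risk, so hazard ratios are reported per **1-SD decrease**.

The package provides the full analysis chain for that epidemiological
question, plus a synthetic-cohort generator with the statistical
structure such studies assume (so everything is testable without any
restricted data):

| module | what it does |
| --- | --- |
| `disten.synth` | RRI processes, ECG pulse trains, survival cohorts with planted per-SD hazards |
| `disten.beats` | bandpass + adaptive-threshold R-peak detection, RRI extraction |
| `disten.qc` | staged exclusion cascade (RRI range, record length, noise score, pacemaker) |
| `disten.hrv` | RHR, RMSSD, SDNN, pNN5/10/20 |
| `disten.entropy` | DistEn, distance distributions, length-stability profiling |
| `disten.survival` | nested Cox tiers A–E (Efron ties), PH checks, interactions, concordance, adjusted group differences |
| `disten.pipeline` / `disten.cli` | end-to-end runs with manifests; `disten` console command |

## Worked example

Simulate a screening cohort of 7631 middle/older-aged adults (~5.9%
deaths over 7.8 years of follow-up) in which the generator plants a 36%
hazard increase per 1-SD decrease in DistEn, then fit the nested Cox
tiers (`python examples/04_cohort_and_mortality_models.py`):

```
cohort: n=7631, deaths=439 (5.8%), DistEn 0.871 (SD 0.098)

tier  HR/SD-decrease  95% CI          concordance
  A   1.391          (1.309-1.479)   0.698
  B   1.379          (1.294-1.469)   0.707
  C   1.383          (1.297-1.473)   0.709
  D   1.381          (1.296-1.472)   0.713
  E   1.367          (1.275-1.466)   0.714

proportional hazards (global chi2 test): chi2=4.70, p=0.45 -> no violation detected
c-statistic, DistEn vs mean-RRI model: 0.698 vs 0.673 (difference +0.025)
```

Each tier's hazard ratio stays near the planted 1.36 because the effect
was planted on DistEn itself: adjustment for lifestyle, cardiovascular
risk, comorbidities and autonomic measures (tiers B–E) removes
confounding but not the direct effect.  The concordance comparison shows
the DistEn model ranks survival better than a mean-RRI model with the
same demographic adjusters.

The other examples each demonstrate one capability: entropy of short
recordings (`01`), ECG → RRI extraction (`02`), the QC cascade (`03`),
and DistEn's stability across record lengths (`05`).

Command-line equivalents:

```sh
disten simulate --n-subjects 500 --seed 1 --out run/ --rri-files
disten qc run/rri --out qc_report.csv
disten disten run/rri/S000003.txt
disten fit run/cohort.csv --tiers A,B,C,D,E
disten run-all --mode simulate --n-subjects 500 --seed 1 --out run_all/
```

## Notes

See `docs/methods.md` for the model and estimator details, the
synthetic-data design and its limitations, and the numerical choices
(binning rule, tie handling, degenerate inputs).
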