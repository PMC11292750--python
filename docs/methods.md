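# Methods

## The outcome score

For a patient whose index stroke admission begins on day `t0`, DAOH over a
horizon of `H` days (default 90) is the number of days in the half-open
window `[t0, t0 + H)` spent neither in hospital nor dead:

```
DAOH_H = H − (days in hospital) − (days dead)
```

Hospital time includes acute, rehabilitation and residential-care episodes;
noncontiguous stays are summed after the episode intervals are merged.
Every day in the window has exactly one status, with priority
**dead > in-hospital > home**, so the three counts always partition the
horizon in the standard variant.

Day-counting conventions (the data sources this score is computed from do
not dictate them, so they are declared here and isolated in one function):

- **Half-open intervals** `[admit, discharge)`: the admission day is
  in-hospital, the discharge day is out. This makes length of stay equal
  `discharge − admit` and puts the late mode of the DAOH-90 distribution at
  `90 − LOS` (85 for a typical 5-day index stay).
- **Same-day transfer merging**: a new admission on the previous discharge
  day continues the same stay (transfer to rehabilitation is continuous
  care), so abutting intervals merge.
- **Death day counts as dead**, and a hospital interval is truncated at the
  death day, preventing double counting when a patient dies in hospital.
- Episodes that end on or before the index day are pre-index history:
  ignored with a logged warning. Episodes straddling the window are clipped.

The **death-recoded variant** (`death_zero`) sets the score to 0 for any
patient who dies within the horizon, addressing the criticism that a patient
discharged early who then dies can outscore a survivor with a long stay.
The day accounting is left unchanged, so the recoded score is always ≤ the
standard score, with equality exactly for 90-day survivors (or the
degenerate case where the standard score is already 0).

A brute-force day-by-day classifier (`daoh_oracle`) re-derives every score
by iterating the window literally; the interval engine must agree with it
exactly, and this equivalence is exercised on randomized scenarios with
overlapping episodes, in- and out-of-hospital deaths and horizons 1–90.

## The synthetic registry

No public episode-level stroke registry accompanies this package, so the
generator emulates the *structure* of an administrative feed: one mandatory
index admission per patient, possible disjoint readmissions (acute, rehab,
residential) within the 90-day window, deaths in- and out-of-hospital, an
mRS-90 interview score, and baseline covariates with injected missingness.

A latent severity ties the outcomes together:

```
S = Σ_c loading_c · z(covariate_c) + ε,   ε ~ Normal(0, noise_sd)
```

with standardized age, admission NIHSS and ASPECTS as the loaded covariates
(defaults 0.3, 1.0, −0.4; noise_sd 0.8). Downstream, all on `S`:

| channel | model | defaults |
|---|---|---|
| index LOS (days) | lognormal(`los_log_mean` + `los_severity_gain`·S, `los_log_sd`), rounded, ≥ 1 | 1.6, 0.5, 0.7 → ~5-day median |
| readmissions per 90 d | Poisson(`base`·exp(`gain`·S)), placed disjointly after discharge | 0.3, 0.5 |
| death within 90 d | Bernoulli(logistic(`intercept` + `slope`·S)), day uniform over the window | −3.0, 1.5 → ~15% deaths |
| mRS-90 | ordered logit: #{cutpoints below S + logistic noise}, capped at 5 for survivors | cutpoints (−1.85, −0.32, 0.79, 2.35, 4.09, 6.0) |

mRS = 6 is forced exactly when the patient dies within the window, so
`mRS = 6 ⇔ in-window death` holds by construction for every generated
patient. Defaults were chosen so the marginals loosely resemble a large
reperfusion-therapy cohort (median NIHSS ≈ 14, ASPECTS ≈ 8, ~15% 90-day
mortality, ~10% ICU, bimodal DAOH with peaks near 0 and 85) — sanity
anchors, not calibration targets. Under the defaults Spearman
rho(DAOH-90, mRS-90) is about −0.6, the same sign and order of magnitude
as reported for real registry cohorts (≈ −0.79); the generator makes no
attempt to match that magnitude exactly.

Two structural notes that matter for interpreting tests:

- **A pure null needs no deaths.** Because death both removes DAOH days and
  forces mRS = 6, any baseline death rate couples the two outcomes even
  with all severity loadings at zero. Independence tests therefore also
  disable baseline deaths (`death_logit_intercept = −30`).
- Death-day placement uniform over the window is an arbitrary but declared
  choice; episodes may extend past the drawn death day and are truncated by
  the engine, which is how in-hospital deaths arise.

What the generator does **not** emulate: real missingness mechanisms
(injection is completely at random), hospital-transfer event types, seasonal
or calendar effects, inter-rater mRS noise, and any fitted resemblance to a
specific registry's marginals. Passing tests show the pipeline recovers
structure it induced — not that it would reproduce any particular cohort's
published statistics.

## The validity battery

- **Spearman correlation**: Pearson correlation of midranks, pairwise
  deletion; two-sided p from the t-approximation with n−2 df, replaced by
  the exact permutation distribution for n ≤ 10 (enumerated in chunks).
- **Mann–Whitney U**: midrank ties; two-sided p from the normal
  approximation with tie-corrected variance and continuity correction;
  exact enumeration of all `C(n1+n2, n1)` assignments when both groups ≤ 8.
- **Subgroup report**: per prognostic factor (binary flags; continuous
  variables split at the cohort median, `value ≥ median` = present), median
  DAOH and mRS by level, present-minus-absent differences, Mann–Whitney
  p-values for both outcomes, and the within-level Spearman rho(DAOH, mRS).
  Even-sized medians average the two central order statistics. A
  single-level factor yields a row with differences marked unavailable.
- **ROC**: AUC = P(score of a random good-outcome patient exceeds a random
  bad-outcome one), ties ½ — identically U/(n_pos·n_neg). Good outcome is
  mRS ≤ k for k ∈ {0, 1, 2, 3}; higher DAOH should predict it. The 95% CI
  is DeLong's analytic interval (verified against R `pROC` to 1e-9 on a
  frozen fixture); a seeded stratified percentile bootstrap (2000 resamples)
  is available behind a flag.
- **Logistic models**: maximum likelihood by IRLS, convergence when the
  log-likelihood moves < 1e-8, max 100 iterations (then an error carrying
  the iteration trace). Complete separation is detected as diverging
  coefficients (|β| > 30 on the standardized working scale) and surfaced as
  a warning, never silently. Listwise deletion within each model, with
  `n_used` reported. Default predictors: age, sex, admission NIHSS,
  ASPECTS, recanalization, ICU admission — a conventional stroke-prognosis
  set, fully configurable. Outcomes: mRS ≤ 2 (functional independence) and
  DAOH > 70; the c-statistic is the in-sample AUC of fitted probabilities.
- Two-sided tests throughout, no multiplicity adjustment; p-values are
  reported unclipped (no 2.2e-16 floor).

Missing data are handled by pairwise deletion everywhere except inside a
logistic model, which deletes listwise.

## Pipeline and reproducibility

`run_pipeline` funnels all randomness through one seeded generator, writes
`patients.csv`, `episodes.csv`, `daoh.csv`, `report.json`,
`roc_curves.csv` and `manifest.json`, and is byte-deterministic given seed
and config — only the manifest carries a timestamp. Degenerate statistics
(e.g. a cohort where everyone dies immediately) are reported as structured
errors inside the report instead of aborting the run.

## Problem sizes

Simulation-based checks use cohorts of n = 2000 (correlation sign and
monotonicity in the death-slope grid), n = 5000 rows for logistic
coefficient recovery (within 3 SE), 1000 randomized patients for engine ↔
oracle equivalence, and 100 random datasets (n ≤ 200) for the exact AUC–U
identity. These sizes give sampling noise well inside the asserted
tolerances while keeping the whole suite under a minute of compute.

## Known limitations

- DAOH weighs ICU, rehabilitation and residential days equally; care
  intensity is out of scope by design.
- Day-level granularity only; hour-level stays are rounded by the source
  data convention, not by this package.
- The generator's distributions are artifact choices for controllable
  monotone structure, not fitted models of any registry.
- Quantile-regression analyses of DAOH and comparisons with patient-reported
  instruments are out of scope.
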