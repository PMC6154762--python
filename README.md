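# rxmonitor

Laboratory-monitoring quality indicators for children and adolescents who
start antipsychotic therapy, computed from administrative claims.

Antipsychotic initiation in pediatric patients carries a known risk of
type-II diabetes and hyperprolactinemia, so practice guidelines recommend
glucose testing (blood glucose or HbA1c) and, in some jurisdictions,
prolactin testing around drug initiation and at intervals thereafter.
Claims databases are the natural place to measure whether that monitoring
actually happens — but doing it correctly requires a chain of
pharmacoepidemiological machinery: identifying *new* users, deciding when a
patient has *discontinued* therapy (so they no longer need monitoring),
restricting each follow-up window to patients still on therapy, treating
discontinuation as a *competing risk* for time-to-first-test, and accounting
for the clustering of patients within medical institutions when modeling
correlates of monitoring. `rxmonitor` implements that chain as a tested,
reusable pipeline, together with a synthetic claims generator that provides
exact per-patient ground truth, so every stage is verifiable without access
to any real (and typically non-public) claims database.

## What it computes

Given four claims tables (enrollment, prescriptions, procedures, diagnoses,
in a documented CSV dialect) the pipeline produces:

1. **Person linkage.** Records carry two opaque identifiers (`id1` from the
   insurance certificate, `id2` from demographics), either of which may be
   missing or break over time. Persons are resolved by union-find transitive
   closure over shared identifier components.
2. **New-user cohort.** The index date is the earliest antipsychotic fill in
   the accrual window. Patients are excluded, in a fixed order, for: a fill
   in the 180-day washout; enrollment not covering [index−180, index] or
   [index, index+480]; a definitive preexisting diabetes diagnosis
   (ICD-10 E10/E11/E13/E14 with fourth digit .1–.5 or .9) on or before the
   index date; or incomplete claims coverage. Covariates are taken at the
   index date (provider type, setting, prescriber, sex, age group, index
   drug, FGA/SGA/both, chlorpromazine-equivalent daily dose category).
3. **Persistence.** A refill-gap algorithm: coverage ends at
   max(fill day + days supply); if the next fill arrives more than 30 grace
   days after coverage ends, the discontinuation date is the last covered
   day. A patient is an *H*-day persistent user if therapy continued at
   least *H* days after the index date (H ∈ {90, 270, 450}).
4. **Windowed monitoring incidence.** For windows baseline [−30, 0],
   1–3 months [1, 90], 4–9 months [91, 270] and 10–15 months [271, 450]
   (days relative to index, inclusive), the incidence proportion of patients
   with ≥1 qualifying test, with 95% Wilson score intervals. Each follow-up
   window's denominator is the corresponding persistent-user group. Regular
   (consecutive) monitoring requires a test in *every* window up to the one
   of interest; a three-window variant uses a combined 0–3-month window
   [−30, 90].
5. **Time to initial monitoring.** The Aalen–Johansen estimator of the
   cause-specific cumulative incidence, with nonpersistence as a competing
   event and censoring at 450 days:
   F_k(t) = Σ_{t_i ≤ t} S(t_i−) · d_ki / n_i, where S is the all-cause
   product-limit survival; S(t) + Σ_k F_k(t) = 1 holds to machine precision.
6. **Correlates of baseline monitoring.** Modified-Poisson regression
   (log-link Poisson GEE, independence working correlation, cluster-robust
   sandwich variance with patients clustered in institutions). Exponentiated
   coefficients are incidence proportion ratios (IPRs); adjusted incidence
   proportions come from marginal standardization (set every subject's
   covariate to each level, average the predicted probabilities).
7. **Disclosure control.** Rendered counts ≤9 are masked as "≤9" and masked
   proportions are shown as upper bounds with the numerator replaced by 9 —
   applied at render time only, never to the computation.

The synthetic generator (`rxmonitor.synthetic_claims`) emulates the claims
structure end to end — institution clustering, identifier fragmentation,
enrollment truncation, washout violators, preexisting diabetes, Bernoulli
refill chains, and per-window monitoring probabilities modified by
covariates on the log scale — and emits a truth record per patient.

## Worked example

```python
from rxmonitor import GeneratorParams, generate_population, RunConfig, run_pipeline, cif_at

params = GeneratorParams(n_patients=2000, n_institutions=250, seed=42)
db, truth = generate_population(params)
bundle = run_pipeline(RunConfig(seed=42), db=db)

sc = bundle.metadata["stage_counts"]
print(sc["cohort"], "of", sc["candidates"], "candidates retained")
print(bundle.rendered_table2())
```

With this seed the run retains **1,597 of 2,000** candidates (403 excluded:
304 prior use, 43 insufficient pre-enrollment, 34 insufficient
post-enrollment, 22 preexisting diabetes — see `bundle.exclusions.counts`),
of whom **48.9% / 13.1% / 5.9%** are 90- / 270- / 450-day persistent users.
The rendered glucose monitoring table:

```
   window n_persistent n_monitored proportion ci_low ci_high regular_proportion
 baseline         1597         391       24.5   22.4    26.7                  -
     m1_3          781         137       17.5   15.0    20.4                5.1
     m4_9          210          67       31.9   26.0    38.5              <=4.3
   m10_15           95          24       25.3   17.6    34.8              <=9.5
all_three           95         <=9      <=9.5      -       -              <=9.5
```

Reading it: 24.5% of the cohort had a glucose test in the baseline window
(the configured generator probability of 13.5%, inflated by the generator's
covariate effects); among 90-day persistent users, 17.5% were tested at 1–3
months but only 5.1% consecutively at both baseline and 1–3 months; cells
with ≤9 patients are masked with the numerator-9 upper-bound convention.
The glucose cumulative incidence of first testing
(`cif_at(bundle.cif["glucose"], t, "monitored")`) rises steeply to 0.245 by
the index date, then gradually to 0.355 at 180 days and 0.376 at 450 days —
the characteristic competing-risk shape when discontinuation removes
patients from monitoring eligibility. In the correlates model, girls are
more likely than boys to receive baseline glucose testing (crude IPR 1.71,
95% CI 1.43–2.04; adjusted IPR 1.68), consistent with the generator's
built-in log effect of 0.40 (ratio 1.49) within sampling error.

A shell workflow is available via the `rxmonitor` CLI
(`simulate`, `build-cohort`, `persistence`, `monitoring`, `cif`,
`correlates`, `report`).

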