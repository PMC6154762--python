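# Methods

This note documents the models and procedures implemented in `rxmonitor`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic-data experiments do and do not show
about real claims data.

## Data model and person linkage

All dates are integer day offsets from a run-level epoch; every analysis
rule is expressed in days relative to the index date, so calendar handling
is deliberately out of scope. Records reference a pair of opaque
identifiers. Linkage forms the transitive closure over pairs sharing a
non-empty `id1` **or** a non-empty `id2` (union-find); an empty component
carries no identity information and never links. The resolved partition is
idempotent: re-resolving the output reproduces it.

Where linked records disagree on sex or age, the conflict is logged as a
warning and the first record is used; enrollment rows of one person are
merged to their union span. Real claims extracts would demand a richer
reconciliation policy; the generator never produces such conflicts, so this
path is only a guard rail.

The claims-completeness interval defaults to the enrollment span but can be
supplied explicitly via optional `complete_start`/`complete_end` enrollment
columns, which makes "incomplete claim information" an explicit, testable
input rather than an undocumented judgement.

## New-user selection

A candidate is a person aged ≤18 with an antipsychotic fill in the accrual
window; the index date is the earliest such fill. Exclusions are evaluated
in a fixed order (washout violation, pre-enrollment, post-enrollment,
preexisting diabetes, incomplete claims) and only the first failing rule is
logged, so the exclusion log is deterministic and the counts reconcile:
candidates = retained + Σ exclusions.

Decisions where the selection rules' wording leaves room:

- The washout window is [index−180, index−1]; the index fill itself cannot
  violate washout (the index is, by definition, a prescription).
- "Preexisting" diabetes means a *definitive* diagnosis dated ≤ index
  (inclusive): a same-day diagnosis precedes any monitoring decision.
  Suspected (rule-out) diagnoses never exclude.
- Age is frozen at the index date.

## Refill-gap persistence

Walking fills in date order, coverage ends at the running maximum of
fill day + days supply. If the next fill arrives strictly more than
`grace_days` (default 30) after coverage ends, therapy is discontinued at
the last covered day. Numerical conventions, all unit-tested:

- The grace boundary is inclusive: a refill exactly at coverage_end + 30
  continues therapy. The refill-gap rule as usually stated does not
  disambiguate this; the
  inclusive reading is the one consistent with "within the subsequent 30
  days".
- Early or overlapping refills extend coverage to the max coverage end; no
  stockpiling carry-over is modeled.
- Same-day duplicate fills contribute once, with the longest supply.
- After the final fill, a discontinuation is assigned only if the grace
  window closes before the 450-day horizon; if the grace window straddles
  the horizon the patient counts as persistent throughout (their allowed
  refill interval had not yet elapsed at end of follow-up). A later fill
  beyond the grace window, by contrast, proves a stop-and-restart and
  assigns the discontinuation regardless of the horizon.
- Persistence at horizon H uses discontinuation_day ≥ H: discontinuing
  exactly at the horizon still counts as "at least H days".
- All antipsychotics are pooled: a switch between agents extends coverage.

The algorithm is verified against an independent day-by-day coverage
simulation on 1,000 random fill sequences, plus monotonicity (adding a fill
never hastens discontinuation) and nesting (450-day ⊆ 270-day ⊆ 90-day
persistent sets) property tests.

## Windowed monitoring incidence

Windows are inclusive day intervals relative to index: baseline [−30, 0],
1–3 months [1, 90], 4–9 months [91, 270], 10–15 months [271, 450], combined
0–3 months [−30, 90]. A test on the index day itself is baseline, not
1–3 months. Denominators: whole cohort at baseline; the 90-/270-/450-day
persistent groups for the three follow-up windows. A person counts once per
window however many tests they had ("proportion of patients monitored").

Regular (consecutive) monitoring at window k requires a test in every
window through k. The three-window scheme (combined 0–3 months, 4–9 months,
10–15 months) uses the 450-day persistent group as denominator — the only
group observable in all three windows.

Confidence intervals are 95% Wilson score intervals (claims-report tables
rarely name their CI method; Wilson has good small-sample behavior and needs
no simulation). Bounds are clamped to [0, 1] and are exact at x = 0 and x = n.
Empirical coverage is verified at ≥93% over 500 replicates for
p ∈ {0.01, 0.14, 0.5} at n = 200.

## Time to initial monitoring under competing risk

Follow-up runs from day −30 (protocol start) to day 450. The first
qualifying test is the event of interest; discontinuation is a competing
event; patients with neither are censored at 450. With distinct event times
t_i, at-risk counts n_i and cause-k event counts d_ki:

    S(t)   = ∏_{t_i ≤ t} (1 − d_i / n_i)          (all-cause product-limit)
    F_k(t) = Σ_{t_i ≤ t} S(t_i−) · d_ki / n_i      (cause-specific CIF)

Conventions: curves are right-continuous step functions; events precede
censoring at ties; a same-day test and discontinuation resolve to
"monitored" by default (the test was still performed) — the tie rule is a
configuration knob. No variance estimation is provided (point curves only).
Correctness checks: mass conservation S + ΣF = 1 within 1e-12 everywhere;
exact reduction to the Kaplan–Meier complement when the competing cause is
absent (cross-checked against lifelines); a four-subject hand-computed
example; and convergence to the closed-form cause-specific exponential CIF
under constant hazards.

## Modified-Poisson correlates model

The binary outcome (baseline monitoring of a given kind) is modeled with
Poisson estimating equations and log link, clustered on institution, with an
independence working correlation and the cluster-robust sandwich
covariance. Independence keeps point estimates identical to the pooled
Poisson GLM solution (asserted to 1e-8), and exp(β) is directly the
incidence proportion ratio. The fit is delegated to statsmodels' GEE;
convergence tolerance 1e-8 with a 100-iteration cap, non-convergence is an
error. Reference levels follow the reporting convention: clinic, inpatient,
nonpsychiatrist, boys, 16–18 years, aripiprazole, 0–99 mg. Individual drug
and drug type (FGA/SGA/both) are mutually exclusive covariates (main vs
sensitivity analysis) because they are collinear by construction.

Adjusted incidence proportions use marginal standardization over the full
cohort (not outcome subsets). Log-link predictions can exceed 1; they are
averaged as-is with a warning, which is the known behavior of the
modified-Poisson approach rather than a defect to be clipped.

The crude IPR from counts alone uses the Katz log-ratio variance
1/x1 − 1/n1 + 1/x0 − 1/n0 — algebraically the subject-as-cluster sandwich
variance of the saturated univariable fit. In the rendered correlates table
the crude CI instead comes from the univariable institution-clustered fit.

Robust SEs are validated against a 1,000-replicate cluster bootstrap (within
15%) on 50 clusters × 40 subjects with known log effects; the simulated
cluster random effect exploits the collapsibility of the log link, so the
marginal slopes equal the conditional ones.

A factor level with zero events has no finite log-link estimate; such levels
are removed from the model data and reported with dashes, and a model with
fewer than 10 total events is skipped outright. This mirrors how sparse
levels appear as dashes in reported tables under cell suppression.

## Synthetic generator: what it emulates, and what it does not

Defaults encode the emulated population's reference marginals: girl
fraction 0.422, age-group weights (.010, .067, .303, .261, .359), the
reference drug mix over eight named antipsychotics plus an "others"
representative, per-window monitoring probabilities (glucose .135/.108/
.157/.156; prolactin .006/.011/.021/.019), hospital/inpatient/psychiatrist
fractions (.422/.059/.551), and a refill continuation probability of 0.84,
which at the default 7/14/30-day supply mix (weights .25/.25/.50) yields
~46–49% 90-day persistence, matching the emulated population's 46.4%.

Structural features: patients cluster in institutions with gamma-weighted
sizes (dispersion knob); 10% of patients have their records split across
two identifier pairs sharing one component (so linkage must reunify them);
15% are washout violators (their violating fill is placed before the
accrual window so their truth label is well-defined); 5% have truncated
enrollment (half pre-, half post-index); 2% carry definitive preexisting
diabetes, and suspected diagnoses are sprinkled in to confirm they never
exclude. Refills are back-to-back by default; a jitter knob adds 0–k day
gaps to exercise the grace period. Monitoring indicators are drawn per
window with probability min(0.99, p_window · exp(Σ covariate effects)) and
placed uniformly in the window. The truth record stores the index date, the
discontinuation day (by construction equal to the persistence algorithm
applied to the emitted fills), per-window monitoring indicators, and the
eligibility flag with its exclusion reason in the same precedence order the
cohort builder uses.

`background_test_rate` (unrelated-evaluation tests, a homogeneous Poisson
process over enrollment) defaults to 0 so that the configured window
probabilities are exactly the ground truth the pipeline should recover;
raising it contaminates observed monitoring upward, emulating tests ordered
for unrelated medical reasons — a caveat real claims analyses cannot avoid.

Known departures from real data, hence limits on what passing tests show:

- The refill chain has a constant per-cycle hazard (no patient frailty), so
  long-horizon persistence decays geometrically: 270-/450-day persistence is
  markedly lower than in real cohorts even when 90-day persistence matches.
- Monitoring draws are independent across windows and of the refill chain;
  real testing is autocorrelated within patient and entangled with visits.
- Covariate effects act multiplicatively on the probability (exactly the
  log-link model's world), capped at 0.99 — model misspecification is
  therefore *not* exercised.
- Coding dictionaries are synthetic; only the three monitoring procedure
  codes are real-world values.

## Problem sizes and determinism

All randomness flows from explicit integer seeds (`GeneratorParams.seed`,
the run config seed, derived streams below 2^31). Test problem sizes were
chosen to make Monte-Carlo assertions sharp while keeping the suite quick:
n = 5,000 patients for window-probability recovery (3-binomial-SD bands),
2,000 for the persistence closed form, 50 × 40 with 1,000 bootstrap
replicates for the sandwich check, 500 replicates for Wilson coverage, ten
300-patient seeds for truth-vs-pipeline eligibility equality, and a
one-patient database for the single-fill discontinuation reference case
(day 14) recomputed by `scripts/acceptance.py`.
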