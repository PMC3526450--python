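# Methods

This note records the modelling assumptions, numerical conventions and design
choices behind the RAC-E pipeline, in the order the pipeline runs.

## Data model

Three pre-linked tables: `separations` (one row per completed admission
episode: dates, ICD-10 principal diagnosis, AR-DRG, age, sex, seven
comorbidity flags, an area-level socioeconomic score, transfer flag),
`costs` (16 cost categories per separation), `deaths` (all-cause death
dates).  Dates are ISO-8601; a "year" is 365.25 days everywhere in the
package.  Record linkage is out of scope: a shared `patient_id` is assumed
correct.

A *transfer chain* — a separation whose admission is within one day of the
previous separation's discharge, with the transfer flag set — is merged into
a single episode before any cohort logic.  The episode keeps the admitting
hospital's identity and codes (care is attributed to the admitting hospital)
and the union of the member separations' costs.

## Cohort and endpoints

Index events: first admission in the window with ICD I60–I64 and a B70 DRG;
B02/B04/A06 DRG admissions are never index events (they still count as
"documented stroke" for the lookback rule).  Exclusions: death within 5 days
of the index admission (inclusive), any stroke-coded separation in the
365-day lookback.

Intermediate endpoints are assessed over a two-year window from the index
separation.  The first qualifying admission wins: stroke principal diagnosis
(recurrent stroke) or a DRG in the derived cardiac set (major cardiac
event).  An event is non-fatal only if the patient survives more than 28
days from the event admission date (counted from admission, not
separation).  Death within the window and before any event — or within 28
days of one — is the death endpoint.  Everyone else is `no_event`, with the
endpoint date set to the index separation date; deaths *after* the two-year
window are then death events in the no-event extrapolation dataset.  Without
that window the no-event survival dataset would contain no deaths at all and
could not support a survival model; the window also matches the "death
within 2 years" framing of the intermediate outcome.

The cardiac admission set is derived from the data: circulatory DRGs
(prefix "F", configurable) among the index cohort's readmissions whose
1-year (365.25-day) mortality from the readmission date is ≥ 40%.  Threshold
0 is accepted as the degenerate "all observed DRGs" case.  Same-day stroke
and cardiac admissions resolve to recurrent stroke (the condition of
interest); the priority is configurable.

## Survival models

The flexible parametric model writes the log cumulative hazard as a
restricted cubic spline in log time plus linear covariate effects.  The
spline basis is `[1, z, v_1(z), …, v_K(z)]` with `v_j` cubic between the
boundary knots and linear beyond them; K interior knots sit at equally
spaced centiles of the uncensored log event times, boundary knots at their
min/max.  K = 0 is the Weibull special case (shape `γ₁`, and `exp(γ₀)` the
rate constant), used as a closed-form oracle in the tests.

The right-censored log-likelihood is maximised by BFGS with an analytic
gradient; starting values come from the exponential fit (`γ₁ = 1`,
`γ₀ = ln(events / total time)`), spline terms start at zero, so fits are
deterministic.  The hazard-positivity constraint (`ds/d ln t > 0` at event
times) is enforced by linearly extending `log` below 1e−5 — a smooth barrier
that keeps the optimiser in the feasible region without hard failures.  The
fitted baseline is checked for monotone cumulative hazard on a 1,000-point
grid.  Standard errors come from the numerically differentiated Hessian.
The fit agrees with R's `flexsurvspline` (same knot convention) to ~1e−5 on
shared data; one test exercises that oracle when Rscript is available.

Model selection: backwards stepwise on Wald p-values (threshold 0.05; Wald
rather than likelihood-ratio for speed — at these sample sizes the two are
near-identical), then pairwise interactions among survivors kept only when
AIC improves, then an AIC scan over 1–5 interior knots.  Endpoint datasets
with fewer than 3 deaths (possible in small simulation replicates) fall back
to a Laplace-smoothed constant-hazard model.

**Annual cycle and discounting.** Year *a* after a reference date covers
`(a−1, a]` years; year *a* carries the discount factor `(1+r)^−a`
(end-of-year convention), with `r = 0.05` by default.  A patient's annual
conditional survival probabilities are `S(a)/S(a−1)` on the model time
scale; discounted mean survival to age 100 is `Σ_a S(a)(1+r)^−a`.  Age
enters as a covariate (centred at 70, per decade); conditioning on the
starting age happens through model time since the endpoint plus that
covariate.

## Cost models

Annual panels contain one row per patient per *full* year of life after the
endpoint; the year's cost is the 16-category total over related admissions
assigned by admission date to the half-open year `(a−1, a]` (an admission at
elapsed time zero — the event admission itself — belongs to year 1).
Partial final years are dropped.  "Related" admissions are those with an
I6x principal diagnosis or a DRG in the derived cardiac set.  The I6x prefix
is deliberately wider than the event-qualifying I60–I64: follow-up
cerebrovascular care (e.g. sequelae, I69) must carry costs without being an
endpoint event, otherwise the no-event cohort would have identically zero
annual costs and no cost model.

Two-part models: logistic (any cost) × GLM (positive amount), predictions
multiply (`E[C] = p·m`; no smearing correction is needed since the magnitude
part is a GLM, not log-OLS).  The GLM family comes from the modified Park
test — squared raw residuals regressed on log fitted values with a log-link
quasi-GLM; slope rounded to the nearest variance power in {0,1,2,3}
(gaussian/poisson/gamma/inverse-gaussian), ties toward the lower power.  The
auxiliary regression uses a gamma family (squared residuals are positive
a.s., and their heavy right tail makes the gamma estimator much less noisy
than a Poisson-type fit; a Poisson fallback covers exact zeros).  The link is
chosen among {log, identity, square root} by counting passes (p > 0.05) of
the Pearson residual-correlation test, the Pregibon link test (squared
linear predictor added to the fit) and a modified Hosmer–Lemeshow F-test on
decile-of-fitted mean residuals; ties and total failure go to log.  The
logistic part reports a Ramsey RESET p-value (powers 2–3 of the linear
predictor, Wald test).

Ten cost regressions: first-year and subsequent-year two-part pairs for the
stroke and cardiac endpoints, one pair for no-event (the first/subsequent
split follows "first year post-event" literally; the no-event cohort gets a
single model).

Sparse-panel behaviour is deliberately conservative: fewer than ~30 rows
(or positive rows) drops to an intercept-only part; fewer than 5 positive
rows moment-matches the mean.  Covariate effects estimated on a dozen
observations produced occasional exploding log-link predictions in
simulation replicates; the guards trade a little flexibility for stability,
and the thresholds align with the Park test's own 30-row floor.

## Observed and expected lifetimes, risk adjustment

Observed lifetime values combine the within-period part (index admission to
endpoint: relevant admission costs discounted by their year index; life
years as discounted whole-year terms plus a fractional final-year term) with
the extrapolated tail (survival profile and two-part cost predictions from
the endpoint), brought back to the index date by the factor `(1+r)^−u` for
an endpoint `u` years after the index.  Death-endpoint patients use observed
values only.  The endpoint's own admission is excluded from the within
period (it belongs to extrapolation year 1, which the first-year cost model
predicts).

Expected models are fitted to the pooled cohort's observed lifetime values
using covariates *at the index event*: a GLM for cost (family/link by the
same Park/link machinery) and a flexible parametric model for lifetime
survival, whose conditional mean is obtained by trapezoid quadrature of
S(t|x).  Hospital identity is rejected as a covariate by construction —
including it would absorb exactly the contrasts being estimated.  Adjusted
values are `observed − expected` per patient; hospital means feed the
comparison.

Calibration: with an intercept in both expected models the grand mean of
adjusted costs is near zero but not exactly zero (log-link nonlinearity),
and the survival model's quadrature mean carries a small distributional
bias; the suite asserts |grand mean adjusted cost| < 2% of mean cost and
|grand mean adjusted LY| < 0.15 years.  Hospital *contrasts* are unaffected
by a common offset.

Because the extrapolation models pool hospitals (no hospital terms), a true
hospital effect is recovered only through the within-period part of the
lifetime values.  In the injected-effect experiments a 1.5× cost multiplier
at one of two equal-share hospitals moves the adjusted-cost contrast by
about `0.5 ×` the within-period baseline cost — the pipeline's expected
recovery, not an estimation failure — and the tests assert against that
derivable quantity (`observed_cost_within` is exposed for this).

Dominance is strict (another hospital has lower mean cost *and* higher mean
survival); extended dominance is not applied.  ICERs are computed between
successive non-dominated hospitals in ascending-cost order; a zero survival
difference leaves the ICER undefined rather than infinite.

## Probabilistic sensitivity analysis

The multi-stage bootstrap resamples with replacement at the patient level
(all of a patient's annual rows move together, preserving within-patient
correlation): first each of the 3 survival datasets and 5 cost panels, with
the 13 models refitted under frozen base-case specifications (covariate
sets, knot locations, family and link) and warm starts; then every cohort
patient's lifetime values are recomputed; then the pooled lifetime dataset
is resampled and the expected models refitted.  Freezing the specification
follows the reading that coefficients, not model choices, are re-estimated
per replicate; re-running selection per replicate is available behind the
config flag but defaults off.  Replicate `r` draws all randomness from the
substream `(master seed, r)`, so results are independent of execution order
and runs are resumable.  Failed replicates are excluded and counted; more
than 10% failures aborts.  The identity-resample mode reuses the base-case
coefficients directly (same data implies the same MLE) so that "reproduces
the base case exactly" is exact, not solver-tolerance-equal.

CEACs: at each willingness-to-pay λ the hospital(s) maximising net monetary
benefit `λ·adjusted LY − adjusted cost` win the replicate, ties split
equally; probabilities therefore sum to one at every threshold.

## Synthetic data

The generator emulates the linked structure the analysis assumes:
per-hospital admission shares with optional age-mix shifts (casemix
confounding), covariates (age, sex, seven comorbidity flags, SES score),
index admissions with B70A/B/C severity tiers (tier-specific length of stay,
in-hospital death risk, and admission cost levels), competing exponential
clocks for recurrent stroke, cardiac events and death (first event wins;
day-grid ties resolve death > stroke > cardiac), endpoint-specific post-event
death hazards (cardiac 0.70/year so the derived cardiac DRG set is
unambiguous at the 40% rule; a low-mortality "chest pain" DRG provides
negative controls), gamma-distributed annual related-care costs with a
point mass at zero and a log-link age effect (so the Park test's correct
answer is 2 and the correct link is log), and injected per-hospital cost
multipliers and log-hazard offsets as ground truth.  One RNG substream per
output table, all derived from the master seed, keeps tables independently
reproducible.  Default rates give an endpoint mix (roughly 40/30/12/11
percent no-event/death/cardiac/stroke over the four-year accrual window)
comparable to an elderly stroke cohort.

What the generator does **not** emulate: linkage error, coding error or
drift, within-year cost seasonality, non-proportional hazards, competing
dependence between event clocks, and community/outpatient costs.  Passing
recovery tests therefore demonstrates the pipeline's correctness under its
own assumptions, not robustness to violations of them.

## Study sizes used by the test and acceptance runs

Chosen as the package's own simulation-study design: recovery experiments
use two equal-share hospitals, 500 patients per replicate, 200 null
replicates (age-confounded, mean age 68 vs 80) and 100 replicates per
injected effect (cost multiplier 1.5; log-hazard offset +0.3), with the
frozen lean specification (age/sex/SES covariates, one interior knot); the
PSA study uses a 500-patient cohort and 200 bootstrap iterations.  The
session fixture for unit tests is a 1,200-patient four-hospital dataset.

## Known limitations

- Time-varying covariate effects, delayed entry and cure models are out of
  scope for the survival component.
- The expected-survival model treats discounted life-years as a positive
  continuous outcome for the spline model; its conditional mean is obtained
  by quadrature and carries a small bias that cancels in hospital contrasts
  but not in the grand mean.
- Hospital effects on post-endpoint trajectories are attenuated by design
  (pooled extrapolation models); RAC-E contrasts are driven by the observed
  period plus casemix-adjusted composition of endpoints.
- Only simple (strict) dominance is reported.
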