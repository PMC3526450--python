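# race-e — risk adjusted cost-effectiveness analysis of hospital services

`race_e` compares the long-run costs and survival of patients treated at
different hospitals using linked administrative data: hospital separations
(admission episodes with ICD-10 / AR-DRG codes), separation-level costs in 16
categories, and all-cause death dates, all pre-linked on a shared patient id.
It was built for acute stroke services but the pipeline is generic to any
condition with a codeable index event.

The problem it addresses: raw comparisons of hospitals are confounded by
casemix — a hospital treating younger, less deprived patients will look
cheaper and more effective regardless of the care it delivers.  Risk adjusted
cost-effectiveness (RAC-E) analysis removes that confounding by comparing each
hospital's **observed minus expected** lifetime values, where "expected" comes
from regressions on patient characteristics at the index event that are
deliberately blind to hospital identity and to what happened afterwards.

## The method

1. **Cohort.** Index stroke admissions are ICD-10 principal diagnosis I60–I64
   with an AR-DRG B70 stroke code (severity tiers B70A/B/C); craniotomy
   (B02), extracranial vascular (B04) and tracheostomy/long ventilation (A06)
   DRGs are excluded, as are deaths within 5 days of admission and patients
   with a documented stroke in the year before the index.
2. **Intermediate endpoints.** Each patient's first qualifying event within
   two years of the index separation assigns one of four mutually exclusive
   endpoints: non-fatal recurrent stroke (a stroke-coded readmission survived
   more than 28 days), non-fatal major cardiac event (readmission in a
   circulatory DRG whose empirical 1-year mortality among the cohort's
   readmissions is ≥ 40% — the set is derived from the data), death (without,
   or within 28 days of, a non-fatal event), or no subsequent event.
3. **Survival extrapolation.** For each non-death endpoint cohort a flexible
   parametric (Royston–Parmar) model is fitted: the log cumulative hazard is
   a restricted cubic spline in log time plus linear covariate effects,

   ln H(t | x) = s(ln t; γ) + xβ,  S(t | x) = exp(−H(t | x)).

   Covariates enter by backwards stepwise selection (Wald p ≤ 0.05),
   pairwise interactions are kept only if AIC improves, and 1–5 interior
   knots are scanned by AIC.  Annual conditional survival probabilities give
   each patient a discounted (5%/year) mean survival to age 100.
4. **Cost extrapolation.** Annual stroke/cardiac-related hospital costs per
   full year of life are modelled in two parts: logistic regression for any
   cost (checked with a Ramsey RESET test) times a GLM for the positive
   amount, with the variance family chosen by the modified Park test and the
   link by Pearson-correlation / Pregibon / modified Hosmer–Lemeshow scoring.
   First-year and subsequent-year models are separate for the stroke and
   cardiac endpoints (10 cost regressions in all).  Discounted lifetime cost
   is Σ_a S_a · Ĉ_a · (1+r)^−a.
5. **Risk adjustment and cost-effectiveness.** Observed lifetime values
   (observed to the endpoint + extrapolated beyond; observed only for deaths)
   are pooled, expected-value models (a GLM and a flexible parametric
   survival model on index covariates, hospital excluded) are fitted, and
   adj = observed − expected per patient.  Hospital means of the adjusted
   values feed strict dominance classification and incremental
   cost-effectiveness ratios (ICER = Δcost/Δlife-years).
6. **Uncertainty.** A multi-stage bootstrap resamples, at the patient level,
   the 13 extrapolation datasets and then the pooled lifetime dataset,
   refitting all models with frozen specifications for (by default) 2,000
   iterations, yielding cost-effectiveness acceptability curves: the
   probability each hospital maximises net monetary benefit λ·LY − cost at
   each willingness-to-pay λ.

Because the real linked data are confidential, the package ships a
synthetic-data generator (`race_e.simulate`) that emulates the full linked
structure — competing exponential event clocks, gamma annual costs with a
point mass at zero, per-hospital cost multipliers and log-hazard offsets —
with known ground truth, so every stage is testable end to end.

## Worked example

```bash
race-e simulate --n-patients 2000 --seed 7 --out data/
race-e -v run --data data/ --out results/
```

The `run` command prints the adjusted cost-effectiveness result; with seed 7
it prints (abridged — runs are deterministic, so the same seed reproduces
these numbers exactly):

```
{
  "ordering": ["A", "D", "C", "B"],
  "dominated_by": {"A": [], "B": ["C"], "C": [], "D": ["A"]},
  "dominant": [],
  "icers": [
    {"from": "A", "to": "C",
     "delta_cost": 1419.1889721557989,
     "delta_ly": 0.07435561543496774,
     "icer": 19086.50696862347}
  ],
  "means": {
    "A": {"mean_cost": -1037.73, "mean_survival": 0.0700},
    "B": {"mean_cost":   463.72, "mean_survival": 0.1147},
    "C": {"mean_cost":   381.46, "mean_survival": 0.1444},
    "D": {"mean_cost":   105.58, "mean_survival": -0.0736}
  }
}
```

Read this as: mean adjusted (observed − expected) values per hospital —
hospital A's patients cost about $1,038 *less* than casemix predicts; D is
strictly dominated by A (A is cheaper than expected by more, with higher
adjusted survival), B by C; moving from A's practice to C's buys adjusted
life-years at about $19,100 each.  On this null simulation (no true hospital
effects were injected) those contrasts are pure sampling noise, which is
exactly what the CEACs then quantify.  `results/` contains `patient_lifetimes.csv`
(per-patient observed / expected / adjusted values), `hospital_summary.csv`,
`ce_result.json`, fitted models as JSON, the echoed config, and a manifest
with the config digest and seed.  Add `--with-psa` for bootstrap CEACs
(`psa_iterations.csv`, `ceac.csv`), or run `race-e psa` separately.

## Layout

```
src/race_e/
  simulate.py    synthetic linked data with ground truth
  cohort.py      index selection, cardiac DRG derivation, endpoint classification
  spline.py      restricted cubic spline basis (log-time scale)
  survival.py    flexible parametric survival models + selection + profiles
  costs.py       annual panels, Park/link/RESET diagnostics, two-part models
  race.py        observed/expected lifetimes, risk adjustment, dominance/ICER
  psa.py         multi-stage bootstrap and CEACs
  pipeline.py    configuration and end-to-end orchestration
  cli.py         `race-e` command-line interface
docs/methods.md  modelling assumptions, conventions, and limitations
```
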