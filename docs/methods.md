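# Methods

## The validation task

The pipeline externally validates fixed risk scores rather than fitting new
models. The prediction problem: among women newly diagnosed with atrial
fibrillation (AF), rank 1-year risk of a stroke recorded with an inpatient or
ER visit. Performance is measured per database because transportability — how
a model behaves on populations unlike its development data — is exactly what
differs across databases.

## Cohort definitions

**Index.** A person enters at the earliest AF event date participating in a
satisfied qualifying rule: (a) two AF records on *distinct* calendar dates
(the first record is the index; duplicate same-day claims do not confirm a
diagnosis), (b) one AF record in an inpatient setting, or (c) one AF record
with an ECG in the closed window [index−30, index] (an ECG on the AF date is
clinically the confirming test, so the tie is resolved inclusively). When
several rules share the earliest date, the reported rule follows the priority
inpatient > two-records > ECG; the date is unaffected.

**Inclusion.** Female sex; age at index within bounds (T1: 65–95, T2:
unbounded), with age computed as index year minus birth year — day-precision
birthdates are neither available in claims data nor needed by any score band;
one observation period covering [index−730, index] (the washout); no stroke
and no anticoagulant event at any offset ≤ 0. The prior-event lookback is all
available history, and offset 0 counts as prior — consequently a stroke on the
index date excludes the patient rather than labelling them.

**Outcome and time-at-risk.** Label 1 iff a stroke-set event with
inpatient/ER context occurs at a day offset in the closed window [1, 365];
`event_day` is the earliest such offset. Patients whose observation ends
before day 365 are retained with their observed label (no censoring weights);
this matches reporting raw percentages and is a known limitation.

**Sensitivity analysis.** Anticoagulants given during time-at-risk can prevent
the predicted outcome, penalising a model for being right. The sensitivity
population removes every patient with an anticoagulant at offset 1–365 unless
their stroke occurred on or before the anticoagulant day; retained treated
patients keep their label and record the anticoagulant offset as
`censor_day`.

## Predictors and missing data

Condition flags use a lifetime lookback (any concept-set event at offset ≤ 0);
no record means the condition is absent. Smoking status and family history are
imputed to 0 when unrecorded, and the availability mask distinguishes
`observed` from `imputed`. Ethnicity, blood pressure, cholesterol ratio and
the Townsend deprivation score are structurally absent — they are dropped from
validation rather than modelled as missing. `chf_or_liver_disease` is the OR
of its two components by construction. Because the cohort excludes prior
stroke, the prior-stroke/TIA flag is identically zero in-cohort; in the
synthetic vocabulary the prior-stroke/TIA concept set shares the stroke codes
(TIA is not separately represented), which makes that invariant exact.

## Score replication

The five models are declarative point/coefficient tables
(`data/scores.yaml`), each restricted to its published covariates that survive
the missing-data policy. The source study of this design prints covariate
membership but not weights, so the weights are transcribed from the models'
own development publications (cited per entry in the fixture) and frozen under
exhaustive enumeration tests (range, endpoints, monotonicity). Choices worth
noting:

- ATRIA and Framingham use their **no-prior-stroke** variants; Framingham's
  systolic-blood-pressure points are dropped without renormalisation.
- Q-Stroke is a reduced linear predictor: rounded log hazard ratios from the
  published female model, with the continuous age effect discretised into
  decade bands. Since AUROC and logistic recalibration are invariant to
  monotone transforms, no 10-year-risk conversion is attempted; raw scores
  feed evaluation for all five models and absolute risk comes only from
  recalibration.
- Correct replication of existing models is the acknowledged weak point of any
  external validation; keeping the weights in a human-readable fixture with
  per-value provenance makes the replication explicit and auditable.

## Evaluation

**AUROC** uses the rank (Mann–Whitney) formulation with midranks, so tie
credit of ½ is exact; an O(n²) pairwise oracle and scikit-learn cross-check it
in tests. **Confidence intervals** use the DeLong structural-components
variance with normal critical values, truncated to [0, 1], and are produced
only when the outcome count is under 1000 (the convention for reporting
uncertainty only where estimates are imprecise); the boundary is sharp: 999
outcomes yield a CI, 1000 do not. The CI method is not dictated by the design
being reproduced; DeLong is the standard asymptotic choice and a stratified
bootstrap agrees with it in tests.

**Recalibration** interprets "fitting a linear model to the predicted scores"
as linear *on the log-odds scale*: a logistic MLE of outcome on
intercept + gradient·score. An identity-link OLS variant is available via
`link="identity"` for comparison, but the logistic link is the default because
its outputs are probabilities and its intercept-only degenerate case has the
clean closed form logit(outcome rate). Constant scores return gradient 0 and
that closed form; complete separation returns `converged=False` (detected via
optimizer failure or diverging estimates).

**Calibration deciles** rank patients by recalibrated risk and split them into
ten near-equal groups with stable tie-breaking by input order — integer point
scores create massive ties, and equal-count groups keep the table defined
where value-binning would not. Group sizes differ by at most one and partition
the cohort exactly.

**Aggregation** over databases is unweighted mean and (min, max) range,
computed from unrounded cell values and rounded only for display; databases
with fewer than 100 outcomes are reported per-cell but excluded from
aggregates, and a database with no inpatient/ER stroke events anywhere
(detected from the generator profile when available, otherwise by scanning) is
marked not evaluable rather than producing a degenerate AUROC.

## The synthetic-data generator

Each person gets demographics, one observation period (a configurable fraction
with ≥730 days of pre-index history; post-index observation always covers the
full 365-day time-at-risk so the realized outcome rate is exactly calibrated),
one qualifying AF presentation from a configurable rule mix, and pre-index
condition history from age-dependent prevalences. Latent 1-year risk is
`expit(b0 + β·features)` with β defaults chosen so the fixture scores reach
AUROCs in the 0.6 region typical of this task; `b0` is solved by root-finding
so the *expected eligible-cohort* outcome rate equals the profile's target
(rates are reported within target populations, so that is the quantity to
calibrate). Stroke days are uniform on 1..365 given a case — 1-year risk is
modelled as binary and no hazard shape is assumed. Treatment by indication:
anticoagulant probability is `expit(logit(treated_fraction) +
assignment_slope·(risk log-odds − eligible mean))`; with probability
`efficacy` (default 0.5) an anticoagulant dated before the counterfactual
stroke day deletes the stroke event. Defaults: 55% female, 85% washout
coverage, 35% treated, assignment slope 1.

A single integer seed drives named substreams (persons, history, outcomes,
treatment), so generation is deterministic and byte-identical given
(profile, seed), and extending one stage does not perturb the others.

Six presets span the heterogeneity the pipeline must survive: age truncation
below and above 65, target rates 1.2–4.6%, a 2000-person hospital database
whose cohorts stay under 100 outcomes, and a primary-care profile that emits
strokes only with outpatient context (and no inpatient records at all), which
the network study must flag as not evaluable. Preset covariate prevalences are
plausible constructions (hypertension very common, rising cardiovascular and
renal disease with age), not estimates of any real database.

What the generator does **not** emulate: correlation between comorbidities
beyond shared age dependence, longitudinal treatment switching and dosing,
competing mortality risk, coding intensity differences, or multi-period
observation with gaps. Passing tests therefore demonstrate that the pipeline's
logic is correct under a known mechanism — not that any score is clinically
valid, nor that real-data AUROCs would match the synthetic ones.

## Problem sizes and numerics

Tests and the acceptance script run the network at preset sizes (2k–30k
persons per database, ~100k persons per full study) and use 20-seed
replications for stochastic properties — large enough for the binomial and
asymptotic checks they make, small enough to run interactively. Rate
calibration is checked at n = 50,000 against binomial standard errors;
recalibration recovery at n = 100,000 against reported standard errors; AUROC
equality against the brute-force oracle at 1e-12; decile conservation exactly.
Intercept root-finding brackets [−30, 10] on the log-odds scale and fails with
an instructive message if the target rate is unreachable for the configured
prevalences and effects.
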