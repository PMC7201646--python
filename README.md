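# strokevalnet

External validation of clinical stroke-risk scores in women newly diagnosed
with atrial fibrillation (AF), rebuilt as a tested, reusable pipeline that runs
end-to-end on synthetic multi-database data with known ground truth.

Multi-site validation networks evaluate a prediction model on many
heterogeneous observational databases (claims, EHR, primary care) that share a
common data layout. The real databases in such studies are proprietary; this
package instead ships a synthetic-data generator whose profiles emulate the
salient heterogeneity of such a network — per-database age truncation (an
under-65 claims database, a 65+ Medicare-style database), 1-year stroke rates
from ~1% to ~5%, a small hospital database with fewer than 100 outcomes, a
primary-care database with no inpatient stroke records at all, and
treatment-by-indication anticoagulant prescribing — so that every stage of the
validation pipeline is testable against a known risk mechanism.

## What it computes

For each database, within a target population of women with newly diagnosed AF
(qualifying index: two AF records on distinct dates, one inpatient AF record,
or one AF record with an ECG in the prior 30 days; ≥730 days of pre-index
observation; no prior stroke or anticoagulant), predict an inpatient/ER-coded
stroke in days 1–365 after the index date. Two populations are used: **T1**
(ages 65–95) and **T2** (all ages), each with a sensitivity variant that
censors patients at the first anticoagulant during time-at-risk unless the
stroke came first.

Five point/coefficient risk models are replicated declaratively
(`src/strokevalnet/data/scores.yaml`): **CHADS₂**, **CHA₂DS₂-VASc**, **ATRIA**
and **Framingham** (both no-prior-stroke variants) and **Q-Stroke** (female
model, reduced to claims-recordable terms). Per (database, population, model)
cell the pipeline reports:

- AUROC (c-statistic) via the rank/Mann–Whitney formulation, ties credited ½;
- a 95% DeLong confidence interval, shown only when the outcome count is
  below 1000;
- a logistic recalibration (`P(stroke) = expit(a + b·score)`) fitted by
  maximum likelihood, giving a database-specific intercept and gradient;
- ten equal-count calibration deciles comparing mean recalibrated risk with
  the observed outcome fraction.

Across databases, each (population, model) gets an unweighted mean AUROC and
range over the databases with ≥100 outcomes; databases that cannot record the
outcome are marked not evaluable.

## Worked example

```python
import strokevalnet as sv

profile = sv.make_profile("medicare_65plus", n_persons=20000)
db, truth = sv.generate_database(profile, seed=7)

result = sv.evaluate_model(
    sv.builtin_score_definitions()["CHA2DS2VASc"], db, population="T2"
)
print(result.n, result.outcome_count, round(result.auroc, 3))
print(tuple(round(x, 3) for x in result.auroc_ci))
print(round(result.recalibration.intercept, 2), round(result.recalibration.gradient, 3))
```

prints

```
7560 275 0.61
(0.577, 0.643)
-4.84 0.375
```

i.e. 7560 eligible women, 275 (3.6%) with a stroke in days 1–365,
CHA₂DS₂-VASc AUROC 0.61 (95% CI 0.58–0.64, shown because 275 < 1000), and a
recalibration mapping each score point to +0.38 on the log-odds scale from a
baseline of −4.84 — the moderate discrimination typical of point scores on
this task.

The `analysis/` scripts run the full study narrative: `01` simulates the
six-database network, `02` tabulates cohort attrition, `03` summarises score
distributions, `04` validates all five models per database, and `05` renders
the network report (`results/network_report/`). Run them from `analysis/` in
order; tables land in `results/`.

The command-line interface mirrors the library:
`strokevalnet simulate|validate-db|cohort|validate|study`.

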